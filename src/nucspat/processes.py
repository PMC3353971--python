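"""Point processes inside a region: CSR and thinned alternatives.

Complete spatial randomness (CSR) places points independently and uniformly
in the region.  The three alternatives — *polar*, *center* and *boundary* —
are inhomogeneous processes obtained by thinning CSR candidates: a candidate
at location x survives with probability ``exp(-k * d(x))`` where d is the
distance to the feature the process aggregates toward (the x-axis poles, the
boundary mean, or the boundary surface) and k controls the strength of the
preference (k = 0 recovers CSR).  Pattern sizes are drawn from a Poisson
distribution truncated below (redraw while < min_n) whose underlying rate is
adjusted so the stated mean is the mean of the truncated law.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal

import numpy as np
from scipy.optimize import brentq
from scipy.stats import poisson

from .geometry import Region

__all__ = [
    "ProcessKind",
    "ProcessSpec",
    "PointPattern",
    "sample_csr",
    "draw_pattern_size",
    "distance_feature",
    "retention_probability",
    "sample_thinned",
]

ProcessKind = Literal["csr", "polar", "center", "boundary"]
PROCESS_KINDS: tuple[str, ...] = ("csr", "polar", "center", "boundary")

# samplers abort when the empirical acceptance rate falls below these
_CSR_MIN_ACCEPT = 1e-3
_THIN_MIN_ACCEPT = 1e-4


@dataclass(frozen=True)
class ProcessSpec:
    """Parameters of a (possibly thinned) point process.

    ``expected_n`` is the mean of the truncated pattern-size law; ``min_n``
    is the lower truncation point (patterns with fewer points are never
    produced); ``k`` is the thinning strength, dimensionless in units of
    inverse distance (k = 1 in the reference experiments).
    """

    kind: ProcessKind
    expected_n: float
    k: float = 1.0
    min_n: int = 5

    def __post_init__(self) -> None:
        if self.kind not in PROCESS_KINDS:
            raise ValueError(f"unknown process kind {self.kind!r}")
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if not self.expected_n > self.min_n >= 0:
            raise ValueError("require expected_n > min_n >= 0")


@dataclass
class PointPattern:
    """An ordered set of 3D coordinates tied to its containing region."""

    points: np.ndarray
    region: Region = field(repr=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if not np.isfinite(self.points).all():
            raise ValueError("points must be finite")
        if len(self.points) and not np.all(self.region.contains(self.points)):
            raise ValueError("every point must lie inside the region")

    def __len__(self) -> int:
        return len(self.points)


def sample_csr(region: Region, n: int, rng: np.random.Generator) -> PointPattern:
    """n independent uniform points inside the region (rejection from its box)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return PointPattern(_csr_points(region, n, rng), region)


def _csr_points(region: Region, n: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = region.bounding_box
    out = np.empty((n, 3))
    have = 0
    drawn = 0
    while have < n:
        m = max(2 * (n - have), 64)
        cand = rng.uniform(lo, hi, size=(m, 3))
        keep = cand[region.contains(cand)]
        drawn += m
        if drawn >= 10_000 and (have + len(keep)) / drawn < _CSR_MIN_ACCEPT:
            raise RuntimeError(
                "degenerate region: CSR acceptance rate below "
                f"{_CSR_MIN_ACCEPT} after {drawn} draws"
            )
        take = min(len(keep), n - have)
        out[have : have + take] = keep[:take]
        have += take
    return out


@lru_cache(maxsize=None)
def _truncated_rate(expected_n: float, min_n: int) -> float:
    """Underlying Poisson rate whose >=min_n truncation has the given mean."""
    if min_n <= 0:
        return float(expected_n)

    j = np.arange(min_n)

    def trunc_mean(lam: float) -> float:
        pj = poisson.pmf(j, lam)
        tail = 1.0 - pj.sum()
        if tail <= 0:
            return float(min_n)
        return (lam - (j * pj).sum()) / tail

    # trunc_mean increases from min_n (lam -> 0) and is >= lam
    return float(brentq(lambda lam: trunc_mean(lam) - expected_n, 1e-9, expected_n))


def draw_pattern_size(
    expected_n: float, min_n: int, rng: np.random.Generator
) -> int:
    """Truncated-Poisson pattern size: redraw while the draw is below min_n.

    The rate of the underlying Poisson is adjusted (1-D root finding) so the
    mean of the *truncated* law equals ``expected_n``; the adjustment is
    negligible for expected_n >= 16 but exact in general.
    """
    if not expected_n > min_n:
        raise ValueError("require expected_n > min_n")
    lam = _truncated_rate(float(expected_n), int(min_n))
    while True:
        v = int(rng.poisson(lam))
        if v >= min_n:
            return v


def distance_feature(region: Region, points, kind: str) -> np.ndarray | float:
    """Distance from each point to the feature a thinned process aggregates to.

    polar    — minimum x-axis-component distance to the two poles;
    center   — Euclidean distance to the mean of the boundary surface;
    boundary — distance to the nearest point of the boundary.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    single = np.asarray(points).ndim == 1
    if kind == "polar":
        p1, p2 = region.poles
        d = np.minimum(np.abs(pts[:, 0] - p1[0]), np.abs(pts[:, 0] - p2[0]))
    elif kind == "center":
        d = np.linalg.norm(pts - region.boundary_mean, axis=1)
    elif kind == "boundary":
        d = np.asarray(region.boundary_distances(pts))
    else:
        raise ValueError(f"unknown distance feature {kind!r}")
    return float(d[0]) if single else d


def retention_probability(d, k: float):
    """Survival probability of a thinning candidate: exp(-k * d)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    p = np.exp(-k * d)
    return float(p) if p.ndim == 0 else p


def sample_thinned(
    region: Region, spec: ProcessSpec, rng: np.random.Generator
) -> PointPattern:
    """Sample one pattern from the specified (possibly thinned) process.

    The pattern size is drawn first; CSR candidates are then generated and
    retained with probability ``exp(-k * d)`` until the size is reached.
    """
    n = draw_pattern_size(spec.expected_n, spec.min_n, rng)
    if spec.kind == "csr" or spec.k == 0:
        return PointPattern(_csr_points(region, n, rng), region)
    out = np.empty((n, 3))
    have = 0
    drawn = 0
    while have < n:
        m = max(2 * (n - have), 64)
        cand = _csr_points(region, m, rng)
        d = distance_feature(region, cand, spec.kind)
        keep = cand[rng.random(m) < np.exp(-spec.k * d)]
        drawn += m
        if drawn >= 100_000 and (have + len(keep)) / drawn < _THIN_MIN_ACCEPT:
            raise RuntimeError(
                "thinning acceptance rate below "
                f"{_THIN_MIN_ACCEPT}: k={spec.k} too large for this region"
            )
        take = min(len(keep), n - have)
        out[have : have + take] = keep[:take]
        have += take
    return PointPattern(out, region)
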