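"""Nuclear boundary geometry.

A *region* is a bounded volume of 3-space that acts as the universe for all
point sampling and spatial tests: it answers membership queries, knows its
volume, its poles (intersection with the x-axis), the mean of its boundary
surface, the distance from an interior location to the boundary, and its
maximum chord (the largest inter-point distance obtainable inside it, used
to normalise distances when aggregating across nuclei).

Two concrete regions are provided:

* :class:`PiecewiseEllipsoidRegion` — the synthetic cell-like boundary built
  from eight ellipsoid octants that share semi-axes across coordinate-plane
  faces, so the surface is continuous.  Four stereotype shape classes
  (sphere, ellipsoid, and their bottom-flattened variants) and a "thin"
  modifier (height divided by 5) emulate the variability of real nuclei.
* :class:`VoxelMaskRegion` — a carrier for user-supplied segmented nuclei
  given as a binary voxel stack with physical voxel spacing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from functools import cached_property
from typing import Iterable, Literal

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import ConvexHull, cKDTree

__all__ = [
    "HalfAxisParams",
    "Region",
    "PiecewiseEllipsoidRegion",
    "VoxelMaskRegion",
    "ShapeClassSpec",
    "SHAPE_CLASSES",
    "make_shape_class",
    "perturb_params",
]

# dense boundary sample sizes (cached per region instance)
_N_DENSE_BOUNDARY = 8192
_N_CHORD_SAMPLES = 2048
# multiplicative perturbation factors are redrawn while 1+eps <= this floor
_PERTURB_FLOOR = 0.2


def _as_points(points) -> tuple[np.ndarray, bool]:
    """Coerce a single (3,) coordinate or an (n, 3) array to (n, 3).

    Returns the array and whether the input was a single point.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        if pts.shape != (3,):
            raise ValueError("a point must have exactly 3 coordinates")
        return pts[None, :], True
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    return pts, False


def _fibonacci_directions(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit directions (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (1.0 + math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


@dataclass(frozen=True)
class HalfAxisParams:
    """Six positive semi-axis lengths of a piecewise-ellipsoid boundary.

    The octant containing sign direction ``(s_x, s_y, s_z)`` uses the
    semi-axes ``(a_{s_x}, b_{s_y}, c_{s_z})``; octants that share a
    coordinate-plane face therefore share the two semi-axes of that face,
    which makes the assembled surface continuous.  The baseline sphere has
    all six values equal to 1 (dimensionless model units).
    """

    a_plus: float
    a_minus: float
    b_plus: float
    b_minus: float
    c_plus: float
    c_minus: float

    _FIELDS = ("a_plus", "a_minus", "b_plus", "b_minus", "c_plus", "c_minus")

    def __post_init__(self) -> None:
        for name in self._FIELDS:
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self._FIELDS], dtype=float)

    @classmethod
    def from_array(cls, values: Iterable[float]) -> "HalfAxisParams":
        vals = list(values)
        if len(vals) != 6:
            raise ValueError("expected 6 semi-axis values")
        return cls(*map(float, vals))

    def to_dict(self) -> dict[str, float]:
        return {f: float(getattr(self, f)) for f in self._FIELDS}

    @classmethod
    def from_dict(cls, d: dict) -> "HalfAxisParams":
        return cls(**{f: float(d[f]) for f in cls._FIELDS})


class Region:
    """Abstract bounded 3D volume — the support of every point process."""

    # --- membership -------------------------------------------------
    def contains(self, points) -> np.ndarray | bool:
        """True for every point inside or on the boundary."""
        raise NotImplementedError

    # --- scalar geometry --------------------------------------------
    @property
    def volume(self) -> float:
        raise NotImplementedError

    @property
    def centroid(self) -> np.ndarray:
        """Volumetric centre of gravity."""
        raise NotImplementedError

    @property
    def boundary_mean(self) -> np.ndarray:
        """Area-weighted mean of the boundary surface (the Center-process anchor)."""
        raise NotImplementedError

    @property
    def poles(self) -> tuple[np.ndarray, np.ndarray]:
        """The two intersections of the shape with the x-axis."""
        raise NotImplementedError

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) corners of an axis-aligned box enclosing the region."""
        raise NotImplementedError

    def max_chord(self) -> float:
        """Largest Euclidean distance between two points of the closed region."""
        raise NotImplementedError

    # --- boundary ----------------------------------------------------
    def boundary_distance(self, point) -> float:
        """Distance from an interior point to the nearest boundary point."""
        raise NotImplementedError

    def boundary_distances(self, points) -> np.ndarray:
        """Vectorised nearest-boundary distances (dense-sample accuracy)."""
        raise NotImplementedError

    def sample_boundary_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n points lying on the boundary surface."""
        raise NotImplementedError


class PiecewiseEllipsoidRegion(Region):
    """Cell-like boundary assembled from eight ellipsoid octants.

    A point (x, y, z) is inside iff ``(x/a)^2 + (y/b)^2 + (z/c)^2 <= 1``
    where (a, b, c) are the semi-axes of the octant selected by the signs of
    the coordinates.  The volume is the sum of the eight octant volumes,
    ``(pi/6) (a+ + a-)(b+ + b-)(c+ + c-)``.
    """

    def __init__(self, params: HalfAxisParams):
        if not isinstance(params, HalfAxisParams):
            params = HalfAxisParams.from_dict(params)
        self.params = params

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PiecewiseEllipsoidRegion({self.params.to_dict()})"

    # semi-axes for each point, chosen by coordinate sign (>= 0 -> plus)
    def _axes(self, pts: np.ndarray) -> np.ndarray:
        p = self.params
        a = np.where(pts[:, 0] >= 0, p.a_plus, p.a_minus)
        b = np.where(pts[:, 1] >= 0, p.b_plus, p.b_minus)
        c = np.where(pts[:, 2] >= 0, p.c_plus, p.c_minus)
        return np.column_stack([a, b, c])

    def octant_residual(self, points) -> np.ndarray:
        """``(x/a)^2 + (y/b)^2 + (z/c)^2 - 1`` for each point (<= 0 inside)."""
        pts, single = _as_points(points)
        q = np.square(pts / self._axes(pts)).sum(axis=1) - 1.0
        return q[0] if single else q

    def contains(self, points):
        pts, single = _as_points(points)
        ok = np.square(pts / self._axes(pts)).sum(axis=1) <= 1.0 + 1e-12
        return bool(ok[0]) if single else ok

    @property
    def volume(self) -> float:
        p = self.params
        return (
            math.pi
            / 6.0
            * (p.a_plus + p.a_minus)
            * (p.b_plus + p.b_minus)
            * (p.c_plus + p.c_minus)
        )

    @property
    def centroid(self) -> np.ndarray:
        # octant of an ellipsoid has volume pi*abc/6 and centroid (3a/8, 3b/8, 3c/8)
        p = self.params
        cx = cy = cz = 0.0
        vol = 0.0
        for sx, ax in ((1, p.a_plus), (-1, p.a_minus)):
            for sy, bx in ((1, p.b_plus), (-1, p.b_minus)):
                for sz, cx_ in ((1, p.c_plus), (-1, p.c_minus)):
                    v = math.pi * ax * bx * cx_ / 6.0
                    vol += v
                    cx += v * sx * 3.0 * ax / 8.0
                    cy += v * sy * 3.0 * bx / 8.0
                    cz += v * sz * 3.0 * cx_ / 8.0
        return np.array([cx, cy, cz]) / vol

    @property
    def poles(self) -> tuple[np.ndarray, np.ndarray]:
        p = self.params
        return (
            np.array([p.a_plus, 0.0, 0.0]),
            np.array([-p.a_minus, 0.0, 0.0]),
        )

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        p = self.params
        lo = np.array([-p.a_minus, -p.b_minus, -p.c_minus])
        hi = np.array([p.a_plus, p.b_plus, p.c_plus])
        return lo, hi

    # --- boundary machinery -----------------------------------------
    def _map_directions(self, dirs: np.ndarray) -> np.ndarray:
        """Map unit directions to the boundary: u -> (a u_x, b u_y, c u_z).

        Axes are picked per octant of u; the image has the same coordinate
        signs, so it satisfies that octant's ellipsoid equation exactly.
        """
        return dirs * self._axes(dirs)

    @cached_property
    def _dense_boundary(self) -> tuple[np.ndarray, np.ndarray]:
        """(points, area weights) from a Fibonacci lattice of directions.

        The weight of direction u with octant axes (a, b, c) is the surface
        Jacobian sqrt((bc u_x)^2 + (ac u_y)^2 + (ab u_z)^2), so weighted
        sums approximate surface (area) integrals.
        """
        dirs = _fibonacci_directions(_N_DENSE_BOUNDARY)
        axes = self._axes(dirs)
        pts = dirs * axes
        a, b, c = axes[:, 0], axes[:, 1], axes[:, 2]
        w = np.sqrt(
            (b * c * dirs[:, 0]) ** 2
            + (a * c * dirs[:, 1]) ** 2
            + (a * b * dirs[:, 2]) ** 2
        )
        return pts, w

    @cached_property
    def _boundary_tree(self) -> cKDTree:
        return cKDTree(self._dense_boundary[0])

    @cached_property
    def boundary_mean(self) -> np.ndarray:
        pts, w = self._dense_boundary
        return (pts * w[:, None]).sum(axis=0) / w.sum()

    def sample_boundary_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 1:
            raise ValueError("n must be >= 1")
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        return self._map_directions(dirs)

    def boundary_distances(self, points) -> np.ndarray:
        pts, single = _as_points(points)
        d, _ = self._boundary_tree.query(pts)
        return float(d[0]) if single else d

    def _surface_point(self, angles: np.ndarray) -> np.ndarray:
        th, ph = angles
        u = np.array(
            [math.sin(th) * math.cos(ph), math.sin(th) * math.sin(ph), math.cos(th)]
        )
        return self._map_directions(u[None, :])[0]

    def boundary_distance(self, point) -> float:
        q, _ = _as_points(point)
        q = q[0]
        if not self.contains(q):
            raise ValueError("point lies outside the region")
        pts, _ = self._dense_boundary
        _, idx = self._boundary_tree.query(q)
        seed = pts[idx]
        u0 = seed / np.maximum(np.linalg.norm(seed), 1e-300)
        th0 = math.acos(np.clip(u0[2], -1.0, 1.0))
        ph0 = math.atan2(u0[1], u0[0])

        def objective(angles):
            return np.linalg.norm(self._surface_point(angles) - q)

        res = minimize(
            objective,
            x0=np.array([th0, ph0]),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 400},
        )
        return float(min(res.fun, np.linalg.norm(seed - q)))

    @cached_property
    def _max_chord(self) -> float:
        pts = self._map_directions(_fibonacci_directions(_N_CHORD_SAMPLES))
        # best pair among dense samples, then local refinement over 4 angles
        best = 0.0
        best_pair = (0, 0)
        chunk = 256
        for i in range(0, len(pts), chunk):
            block = pts[i : i + chunk]
            d2 = ((block[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
            j = np.unravel_index(np.argmax(d2), d2.shape)
            if d2[j] > best:
                best = d2[j]
                best_pair = (i + j[0], j[1])
        p0, p1 = pts[best_pair[0]], pts[best_pair[1]]

        def angles_of(p):
            u = p / np.linalg.norm(p)
            return [math.acos(np.clip(u[2], -1, 1)), math.atan2(u[1], u[0])]

        def neg_dist(x):
            return -np.linalg.norm(self._surface_point(x[:2]) - self._surface_point(x[2:]))

        res = minimize(
            neg_dist,
            x0=np.array(angles_of(p0) + angles_of(p1)),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 800},
        )
        return float(max(-res.fun, math.sqrt(best)))

    def max_chord(self) -> float:
        return self._max_chord


class VoxelMaskRegion(Region):
    """Region defined by a binary voxel mask with physical voxel spacing.

    ``mask`` is indexed ``[z, y, x]`` (the natural order of a TIFF z-stack);
    ``spacing`` is the physical size of one voxel along (x, y, z).  World
    coordinates place the centre of voxel ``(iz, iy, ix)`` at
    ``(ix*sx, iy*sy, iz*sz)``.
    """

    def __init__(self, mask: np.ndarray, spacing: tuple[float, float, float]):
        mask = np.asarray(mask)
        if mask.ndim != 3:
            raise ValueError("mask must be a 3D (z, y, x) array")
        self.mask = mask.astype(bool)
        if not self.mask.any():
            raise ValueError("mask is empty (no foreground voxels)")
        spacing = tuple(float(s) for s in spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError("spacing must be three positive values (sx, sy, sz)")
        self.spacing = np.array(spacing)
        from skimage.measure import label

        if label(self.mask).max() > 1:
            warnings.warn(
                "mask has more than one connected component", stacklevel=2
            )

    @cached_property
    def _voxel_centers(self) -> np.ndarray:
        iz, iy, ix = np.nonzero(self.mask)
        return np.column_stack([ix, iy, iz]) * self.spacing

    def contains(self, points):
        pts, single = _as_points(points)
        idx = np.rint(pts / self.spacing).astype(int)  # (ix, iy, iz)
        nz, ny, nx = self.mask.shape
        ok = (
            (idx[:, 0] >= 0)
            & (idx[:, 0] < nx)
            & (idx[:, 1] >= 0)
            & (idx[:, 1] < ny)
            & (idx[:, 2] >= 0)
            & (idx[:, 2] < nz)
        )
        out = np.zeros(len(pts), dtype=bool)
        if ok.any():
            sel = idx[ok]
            out[ok] = self.mask[sel[:, 2], sel[:, 1], sel[:, 0]]
        return bool(out[0]) if single else out

    @property
    def volume(self) -> float:
        return float(self.mask.sum() * self.spacing.prod())

    @cached_property
    def centroid(self) -> np.ndarray:
        return self._voxel_centers.mean(axis=0)

    @cached_property
    def _surface(self) -> tuple[np.ndarray, np.ndarray]:
        """Marching-cubes boundary (vertices in world xyz, triangle faces)."""
        from skimage.measure import marching_cubes

        sz, sy, sx = self.spacing[2], self.spacing[1], self.spacing[0]
        padded = np.pad(self.mask.astype(np.float32), 1)
        verts, faces, _, _ = marching_cubes(padded, 0.5, spacing=(sz, sy, sx))
        verts -= np.array([sz, sy, sx])  # undo the pad offset
        return verts[:, ::-1].copy(), faces  # (z,y,x) -> (x,y,z)

    @cached_property
    def boundary_mean(self) -> np.ndarray:
        verts, faces = self._surface
        tri = verts[faces]
        centers = tri.mean(axis=1)
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        return (centers * areas[:, None]).sum(axis=0) / areas.sum()

    @property
    def poles(self) -> tuple[np.ndarray, np.ndarray]:
        verts, _ = self._surface
        return verts[np.argmax(verts[:, 0])], verts[np.argmin(verts[:, 0])]

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        c = self._voxel_centers
        return c.min(axis=0) - self.spacing / 2, c.max(axis=0) + self.spacing / 2

    @cached_property
    def _boundary_tree(self) -> cKDTree:
        return cKDTree(self._surface[0])

    def boundary_distances(self, points) -> np.ndarray:
        pts, single = _as_points(points)
        d, _ = self._boundary_tree.query(pts)
        return float(d[0]) if single else d

    def boundary_distance(self, point) -> float:
        q, _ = _as_points(point)
        if not self.contains(q[0]):
            raise ValueError("point lies outside the region")
        return float(self.boundary_distances(q)[0])

    @cached_property
    def _max_chord(self) -> float:
        verts, _ = self._surface
        hull = verts[ConvexHull(verts).vertices]
        d2 = ((hull[:, None, :] - hull[None, :, :]) ** 2).sum(-1)
        return float(math.sqrt(d2.max()))

    def max_chord(self) -> float:
        return self._max_chord

    def sample_boundary_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 1:
            raise ValueError("n must be >= 1")
        verts, faces = self._surface
        tri = verts[faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        pick = rng.choice(len(faces), size=n, p=areas / areas.sum())
        u, v = rng.random(n), rng.random(n)
        flip = u + v > 1
        u[flip], v[flip] = 1 - u[flip], 1 - v[flip]
        t = tri[pick]
        return t[:, 0] + u[:, None] * (t[:, 1] - t[:, 0]) + v[:, None] * (t[:, 2] - t[:, 0])


# ---------------------------------------------------------------------------
# shape classes and perturbation
# ---------------------------------------------------------------------------

ShapeClassId = Literal["sphere", "ellipsoid", "flat_sphere", "flat_ellipsoid"]
Thickness = Literal["thick", "thin"]

SHAPE_CLASSES: tuple[str, ...] = ("sphere", "ellipsoid", "flat_sphere", "flat_ellipsoid")
THIN_FACTOR = 5.0


@dataclass(frozen=True)
class ShapeClassSpec:
    """One of the four stereotype nucleus shapes, thick or thin.

    The ellipsoid classes extrude the sphere along the positive x-axis
    (a_plus = 2); the flat classes flatten the underside (c_minus = 0.5).
    Thin variants divide both c semi-axes by 5.
    """

    class_id: ShapeClassId
    thickness: Thickness = "thick"

    def __post_init__(self) -> None:
        if self.class_id not in SHAPE_CLASSES:
            raise ValueError(f"unknown shape class {self.class_id!r}")
        if self.thickness not in ("thick", "thin"):
            raise ValueError(f"unknown thickness {self.thickness!r}")


def make_shape_class(spec: ShapeClassSpec) -> HalfAxisParams:
    """Baseline semi-axis parameters for a shape class."""
    if isinstance(spec, tuple):
        spec = ShapeClassSpec(*spec)
    params = HalfAxisParams(1, 1, 1, 1, 1, 1)
    if spec.class_id in ("ellipsoid", "flat_ellipsoid"):
        params = replace(params, a_plus=2.0)
    if spec.class_id in ("flat_sphere", "flat_ellipsoid"):
        params = replace(params, c_minus=0.5)
    if spec.thickness == "thin":
        params = replace(
            params,
            c_plus=params.c_plus / THIN_FACTOR,
            c_minus=params.c_minus / THIN_FACTOR,
        )
    return params


def perturb_params(
    params: HalfAxisParams, sigma: float, rng: np.random.Generator
) -> HalfAxisParams:
    """Randomly perturb each semi-axis: value * (1 + eps), eps ~ N(0, sigma^2).

    Each factor is redrawn until ``1 + eps > 0.2`` so a perturbed shape can
    never collapse or invert.  The same sigma applies to all six parameters.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    values = params.as_array()
    factors = np.empty(6)
    for i in range(6):
        while True:
            f = 1.0 + rng.normal(0.0, sigma)
            if f > _PERTURB_FLOOR:
                factors[i] = f
                break
    return HalfAxisParams.from_array(values * factors)
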