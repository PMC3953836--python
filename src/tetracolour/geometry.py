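"""Morphospace occupancy geometry: convex-hull volumes, hull overlap, and
minimum-volume enclosing ellipsoids (MVEE) used as convergence target
regions.

Boundary convention: a point exactly on a hull facet or on the ellipsoid
surface counts as *inside*. This matters for the convergence counter and is
part of the public contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError

__all__ = [
    "Hull3D",
    "EllipsoidRegion",
    "DegenerateGeometryError",
    "hull_volume",
    "overlap_fraction",
    "OverlapResult",
    "min_ellipsoid",
    "contains",
]

_BOUNDARY_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised when a point set has too little affine spread for the
    requested construction."""


@dataclass(frozen=True)
class Hull3D:
    """A 3-D convex hull. ``degenerate`` hulls (fewer than 4 points, or all
    points coplanar) carry zero volume and no facets."""

    points: np.ndarray
    vertices: np.ndarray
    facets: np.ndarray
    volume: float
    equations: np.ndarray  # rows (a, b, c, d): inside iff a*x+b*y+c*z+d <= 0
    degenerate: bool = False

    def contains_point(self, p: np.ndarray, tol: float = _BOUNDARY_TOL) -> bool:
        if self.degenerate:
            return False
        p = np.asarray(p, dtype=float)
        return bool(np.all(self.equations[:, :3] @ p + self.equations[:, 3] <= tol))

    def contains_points(self, pts: np.ndarray, tol: float = _BOUNDARY_TOL) -> np.ndarray:
        """Vectorised membership for an (n, 3) array."""
        if self.degenerate:
            return np.zeros(len(pts), dtype=bool)
        vals = np.asarray(pts, dtype=float) @ self.equations[:, :3].T + self.equations[:, 3]
        return np.all(vals <= tol, axis=1)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        v = self.points[self.vertices] if not self.degenerate else self.points
        return v.min(axis=0), v.max(axis=0)


def hull_volume(points: np.ndarray) -> Hull3D:
    """Exact convex hull of a 3-D point set.

    Degenerate inputs (< 4 points, or rank < 3) return a flagged hull with
    volume 0 instead of raising.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError(f"expected (n, 3) points, got shape {pts.shape}")
    if len(pts) < 4 or np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-12) < 3:
        return Hull3D(
            points=pts,
            vertices=np.arange(len(pts)),
            facets=np.empty((0, 3), dtype=int),
            volume=0.0,
            equations=np.empty((0, 4)),
            degenerate=True,
        )
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return Hull3D(
            points=pts,
            vertices=np.arange(len(pts)),
            facets=np.empty((0, 3), dtype=int),
            volume=0.0,
            equations=np.empty((0, 4)),
            degenerate=True,
        )
    return Hull3D(
        points=pts,
        vertices=hull.vertices,
        facets=hull.simplices,
        volume=float(hull.volume),
        equations=hull.equations,
    )


@dataclass(frozen=True)
class OverlapResult:
    overlap_volume: float
    fraction_of_a: float
    fraction_of_b: float
    fraction_of_union: float
    mode: str
    standard_error: float | None = None  # of overlap_volume, MC mode only


def _chebyshev_center(halfspaces: np.ndarray) -> np.ndarray | None:
    """Largest-inscribed-sphere centre of {x : A x + b <= 0}; None if the
    region is empty or has (numerically) no interior."""
    A, b = halfspaces[:, :3], halfspaces[:, 3]
    norms = np.linalg.norm(A, axis=1)
    res = linprog(
        c=[0.0, 0.0, 0.0, -1.0],
        A_ub=np.column_stack([A, norms]),
        b_ub=-b,
        bounds=[(None, None)] * 3 + [(0, None)],
        method="highs",
    )
    if not res.success or res.x[3] <= 1e-12:
        return None
    return res.x[:3]


def overlap_fraction(
    a: Hull3D,
    b: Hull3D,
    mode: str = "exact",
    n: int = 1_000_000,
    seed: int = 0,
) -> OverlapResult:
    """Volume of the intersection of two hulls, as absolute volume and as
    fractions of hull ``a``, hull ``b``, and of their union.

    ``'exact'`` intersects the two half-space systems and takes the hull of
    the resulting vertices; ``'monte_carlo'`` rejection-samples the joint
    bounding box with a seeded generator and reports a standard error.
    Disjoint hulls give 0, not an error.
    """
    if a.degenerate or b.degenerate:
        raise DegenerateGeometryError("overlap requires two non-degenerate hulls")
    if mode not in ("exact", "monte_carlo"):
        raise ValueError(f"mode must be 'exact' or 'monte_carlo', got {mode!r}")

    se: float | None = None
    if mode == "exact":
        halfspaces = np.vstack([a.equations, b.equations])
        interior = _chebyshev_center(halfspaces)
        if interior is None:
            inter_vol = 0.0
        else:
            hs = HalfspaceIntersection(halfspaces, interior)
            inter_vol = float(ConvexHull(hs.intersections).volume)
    else:
        lo_a, hi_a = a.bounding_box()
        lo_b, hi_b = b.bounding_box()
        lo, hi = np.maximum(lo_a, lo_b), np.minimum(hi_a, hi_b)
        if np.any(hi <= lo):
            inter_vol, se = 0.0, 0.0
        else:
            rng = np.random.default_rng(seed)
            pts = rng.uniform(lo, hi, size=(n, 3))
            hit = a.contains_points(pts) & b.contains_points(pts)
            box_vol = float(np.prod(hi - lo))
            p = hit.mean()
            inter_vol = p * box_vol
            se = box_vol * float(np.sqrt(p * (1.0 - p) / n))

    union_vol = a.volume + b.volume - inter_vol
    return OverlapResult(
        overlap_volume=inter_vol,
        fraction_of_a=inter_vol / a.volume,
        fraction_of_b=inter_vol / b.volume,
        fraction_of_union=inter_vol / union_vol,
        mode=mode,
        standard_error=se,
    )


@dataclass(frozen=True)
class EllipsoidRegion:
    """Ellipsoid {p : (p - center)^T shape^-1 (p - center) <= radius^2}.

    ``shape`` is symmetric positive-definite; ``rank_deficient`` marks
    regions built from (near-)coplanar generators whose smallest axis was
    regularised.
    """

    center: np.ndarray
    shape: np.ndarray
    radius: float = 1.0
    label: str = ""
    rank_deficient: bool = False

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float)
        S = np.asarray(self.shape, dtype=float)
        if c.shape != (3,) or S.shape != (3, 3):
            raise ValueError("center must be length 3, shape must be 3x3")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("shape matrix must be symmetric")
        eigvals = np.linalg.eigvalsh(S)
        if eigvals.min() <= 0:
            raise ValueError("shape matrix must be positive-definite")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        c.setflags(write=False)
        S.setflags(write=False)
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "shape", S)

    def mahalanobis_sq(self, pts: np.ndarray) -> np.ndarray:
        """(p-c)^T shape^-1 (p-c) for one point or an (n, 3) array."""
        d = np.atleast_2d(np.asarray(pts, dtype=float)) - self.center
        sol = np.linalg.solve(self.shape, d.T)
        return np.einsum("ij,ji->i", d, sol)

    def contains_points(self, pts: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
        return self.mahalanobis_sq(pts) <= self.radius**2 * (1.0 + rtol)

    def volume(self) -> float:
        return float(
            4.0 / 3.0 * np.pi * self.radius**3 * np.sqrt(np.linalg.det(self.shape))
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "center": self.center.tolist(),
            "shape": self.shape.tolist(),
            "radius": self.radius,
            "label": self.label,
            "rank_deficient": self.rank_deficient,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "EllipsoidRegion":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            center=np.array(d["center"]),
            shape=np.array(d["shape"]),
            radius=d["radius"],
            label=d.get("label", ""),
            rank_deficient=d.get("rank_deficient", False),
        )


def contains(region: EllipsoidRegion, p: np.ndarray, rtol: float = 1e-9) -> bool:
    """Ellipsoid membership; the boundary counts as inside."""
    return bool(region.contains_points(np.asarray(p, dtype=float))[0]) if np.ndim(p) == 1 else bool(
        region.contains_points(p, rtol=rtol)[0]
    )


def min_ellipsoid(
    points: np.ndarray,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    label: str = "",
    on_degenerate: str = "raise",
) -> EllipsoidRegion:
    """Minimum-volume enclosing ellipsoid by Khachiyan's barycentric
    coordinate-ascent algorithm.

    All input points satisfy the membership inequality of the returned
    region (the radius is inflated to cover the iteration tolerance).
    Coplanar input either raises :class:`DegenerateGeometryError`
    (``on_degenerate='raise'``) or returns a regularised, flagged region
    (``'flag'``).
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = P.shape
    if d != 3:
        raise ValueError(f"expected (n, 3) points, got shape {P.shape}")
    if on_degenerate not in ("raise", "flag"):
        raise ValueError("on_degenerate must be 'raise' or 'flag'")
    rank = np.linalg.matrix_rank(P - P.mean(axis=0), tol=1e-12) if n > 1 else 0
    rank_deficient = n < 4 or rank < 3
    if rank_deficient and on_degenerate == "raise":
        raise DegenerateGeometryError(
            f"need >= 4 affinely independent points for an MVEE (got n={n}, rank={rank})"
        )

    if rank_deficient:
        # Regularised fallback: covariance-shaped region with tiny axes padded.
        center = P.mean(axis=0)
        cov = np.cov(P.T) if n > 1 else np.eye(3)
        cov = np.atleast_2d(cov)
        w, V = np.linalg.eigh((cov + cov.T) / 2.0)
        scale = max(w.max(), 1.0)
        w = np.maximum(w, 1e-12 * scale)
        S = (V * w) @ V.T
        region = EllipsoidRegion(center, S, 1.0, label=label, rank_deficient=True)
        r2 = max(region.mahalanobis_sq(P).max(), 1e-12)
        return EllipsoidRegion(
            center, S, float(np.sqrt(r2)), label=label, rank_deficient=True
        )

    # Khachiyan barycentric ascent with away steps (linear convergence).
    Q = np.vstack([P.T, np.ones(n)])  # (4, n)
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        X = Q @ (u[:, None] * Q.T)
        M = np.einsum("ij,ji->i", Q.T, np.linalg.solve(X, Q))
        j_add = int(np.argmax(M))
        if M[j_add] / 4.0 - 1.0 <= tol:
            break
        support = u > 0
        j_away = int(np.flatnonzero(support)[np.argmin(M[support])])
        if M[j_add] - 4.0 >= 4.0 - M[j_away]:
            step = (M[j_add] - 4.0) / (4.0 * (M[j_add] - 1.0))
            u *= 1.0 - step
            u[j_add] += step
        else:
            step = (M[j_away] - 4.0) / (4.0 * (M[j_away] - 1.0))  # negative
            step = max(step, -u[j_away] / (1.0 - u[j_away]))
            u *= 1.0 - step
            u[j_away] += step
            u = np.maximum(u, 0.0)
    center = P.T @ u
    cov = (P.T * u) @ P - np.outer(center, center)
    A = np.linalg.inv(cov) / 3.0  # (p-c)^T A (p-c) <= 1 encloses all points (up to tol)
    S = np.linalg.inv(A)
    S = (S + S.T) / 2.0
    region = EllipsoidRegion(center, S, 1.0, label=label)
    # guarantee the membership invariant exactly for the generating points
    r = float(np.sqrt(max(region.mahalanobis_sq(P).max(), 1e-300)))
    return EllipsoidRegion(center, S, max(1.0, r), label=label)
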