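"""Mitochondrion-to-nucleus distances.

Two routes, matching the two imaging modalities:

* **2D fluorescence** — the nucleus is summarized as its moment-equivalent
  ellipse and the minimum distance from a mitochondrion centre to the ellipse
  boundary is found exactly.  Minimizing the squared distance subject to the
  ellipse constraint (a Lagrange-multiplier problem) reduces, after moving to
  the ellipse's standard frame and substituting
  ``x = ±a*sqrt(1 - y^2/b^2)``, to a degree-4 polynomial in ``y`` with at
  most four real roots in general position; the candidate boundary points are
  enumerated and the nearest is returned.

* **3D volume EM** — distances are read off an anisotropy-aware Euclidean
  distance transform of the nucleus mask, per instance either at the centroid
  or as the minimum over the instance's voxels.

All distances are reported in the physical units of the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import VolumeGrid, NM_PER_UM

__all__ = [
    "Ellipse",
    "DistanceResult",
    "fit_nucleus_ellipse",
    "point_to_ellipse_distance",
    "sample_ellipse_boundary",
    "mito_nucleus_distances_3d",
]

_IMPLICIT_TOL = 1e-9


@dataclass(frozen=True)
class Ellipse:
    """A 2D ellipse: center, semi-axes ``a >= b > 0``, tilt of the major axis.

    ``theta`` is the angle (radians) of the major axis against +x, normalized
    to [0, pi).
    """

    center: tuple[float, float]
    a: float
    b: float
    theta: float = 0.0

    def __post_init__(self):
        if not (self.a >= self.b > 0):
            raise ValueError(f"ellipse axes must satisfy a >= b > 0, got a={self.a}, b={self.b}")
        object.__setattr__(self, "theta", float(self.theta) % np.pi)
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))

    def to_standard(self, points: np.ndarray) -> np.ndarray:
        """Map points from the original frame to the axis-aligned, centred frame."""
        p = np.atleast_2d(points) - np.asarray(self.center)
        c, s = np.cos(self.theta), np.sin(self.theta)
        rot = np.array([[c, s], [-s, c]])
        return p @ rot.T

    def from_standard(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        c, s = np.cos(self.theta), np.sin(self.theta)
        rot = np.array([[c, -s], [s, c]])
        return p @ rot.T + np.asarray(self.center)

    def implicit(self, points: np.ndarray) -> np.ndarray:
        """``(x/a)^2 + (y/b)^2 - 1`` evaluated in the standard frame (0 on the boundary)."""
        q = self.to_standard(points)
        return (q[:, 0] / self.a) ** 2 + (q[:, 1] / self.b) ** 2 - 1.0


@dataclass(frozen=True)
class DistanceResult:
    distance: float
    closest_point: tuple[float, float]
    n_candidates: int


def fit_nucleus_ellipse(mask: np.ndarray) -> Ellipse:
    """Moment-equivalent ellipse of a 2D binary nucleus mask.

    Center = centroid; axes and tilt from the eigendecomposition of the
    second-order central moments (semi-axis = 2*sqrt(eigenvalue), the exact
    relation for a filled ideal ellipse).  Pixel centers sit at integer
    (x, y) coordinates; x is the column index, y the row index.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("fit_nucleus_ellipse expects a 2D mask")
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty nucleus mask")
    pts = np.column_stack([cols, rows]).astype(float)  # (x, y)
    center = pts.mean(axis=0)
    d = pts - center
    # +1/12 per axis: variance of the unit-square pixel footprint, so a
    # single-row mask is not degenerate and ideal-ellipse moments are matched.
    cov = d.T @ d / pts.shape[0] + np.eye(2) / 12.0
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] <= 0:
        raise ValueError("degenerate (collinear) nucleus mask")
    b, a = 2.0 * np.sqrt(evals)
    major = evecs[:, 1]
    theta = float(np.arctan2(major[1], major[0])) % np.pi
    return Ellipse((float(center[0]), float(center[1])), float(a), float(b), theta)


def _quartic_y_roots(a: float, b: float, px: float, py: float) -> np.ndarray:
    """Real roots of the stationarity quartic in y (standard frame).

    Squaring ``sqrt(1 - y^2/b^2) * ((b^2 - a^2) y - b^2 py) = -s a px y``
    gives ``(1 - y^2/b^2) ((b^2-a^2) y - b^2 py)^2 = a^2 px^2 y^2``,
    a degree-4 polynomial solved via the companion matrix (np.roots).
    """
    c2 = b * b - a * a
    c1 = -(b * b) * py
    # (1 - y^2/b^2)(c2 y + c1)^2 - a^2 px^2 y^2 = 0
    # expand (c2 y + c1)^2 = c2^2 y^2 + 2 c1 c2 y + c1^2
    k = 1.0 / (b * b)
    coeffs = np.array(
        [
            -k * c2 * c2,                       # y^4
            -k * 2 * c1 * c2,                   # y^3
            c2 * c2 - k * c1 * c1 - (a * px) ** 2,  # y^2
            2 * c1 * c2,                        # y^1
            c1 * c1,                            # y^0
        ]
    )
    if not np.any(coeffs[:-1]):
        return np.array([])
    roots = np.roots(coeffs)
    scale = np.maximum(1.0, np.abs(roots))
    real = roots[np.abs(roots.imag) <= 1e-9 * scale].real
    return real


def point_to_ellipse_distance(point, ellipse: Ellipse) -> DistanceResult:
    """Exact minimum distance from a 2D point to an ellipse boundary.

    The ellipse is moved to its standard frame (centred, axis-aligned) and the
    stationarity condition of the Lagrange system is reduced to a quartic in
    ``y``; real roots are clamped to [-b, b], both signs of
    ``x = ±a*sqrt(1-y^2/b^2)`` are evaluated (the substitution loses the
    sign), the four axis endpoints are included to cover the degenerate
    branches, and the closest candidate is mapped back to the original frame.

    ``n_candidates`` counts the *stationary* candidates examined: the real
    quartic roots in general position (at most 4), or the analytic candidates
    on the degenerate branches.
    """
    a, b = ellipse.a, ellipse.b
    p = ellipse.to_standard(np.asarray(point, dtype=float))[0]
    px, py = float(p[0]), float(p[1])

    candidates: list[tuple[float, float]] = []
    if px == 0.0 and py == 0.0:
        # center: nearest boundary point is on the minor axis (tie broken
        # toward the minor axis by convention)
        best = np.array([0.0, b])
        n_cand = 1
    else:
        ys = _quartic_y_roots(a, b, px, py)
        n_cand = int(min(len(ys), 4)) if ys.size else 0
        for y in ys:
            y = float(np.clip(y, -b, b))
            w = np.sqrt(max(0.0, 1.0 - (y / b) ** 2))
            x = a * w
            candidates.append((x, y))
            candidates.append((-x, y))
        # axis endpoints: stationary when the point lies on an axis (the
        # quartic degenerates there); harmless extras otherwise
        candidates.extend([(a, 0.0), (-a, 0.0), (0.0, b), (0.0, -b)])
        if n_cand == 0:
            n_cand = 4  # degenerate branch: the four endpoints examined
        cand = np.asarray(candidates)
        d2 = (cand[:, 0] - px) ** 2 + (cand[:, 1] - py) ** 2
        best = cand[int(np.argmin(d2))]

    dist = float(np.hypot(best[0] - px, best[1] - py))
    closest = ellipse.from_standard(best)[0]
    return DistanceResult(dist, (float(closest[0]), float(closest[1])), n_cand)


def sample_ellipse_boundary(
    ellipse: Ellipse,
    n: int,
    seed: int | None = None,
    angles: np.ndarray | None = None,
) -> np.ndarray:
    """``n`` points exactly on the ellipse boundary (parametric form).

    With ``angles`` given they are used directly; otherwise parameters are
    drawn uniformly on [0, 2*pi) from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if angles is None:
        rng = np.random.default_rng(seed)
        angles = rng.uniform(0.0, 2.0 * np.pi, size=n)
    t = np.asarray(angles, dtype=float)
    std = np.column_stack([ellipse.a * np.cos(t), ellipse.b * np.sin(t)])
    return ellipse.from_standard(std)


def nucleus_distance_field(nucleus_mask: VolumeGrid) -> np.ndarray:
    """Physical Euclidean distance (nm) to the nearest nucleus voxel; 0 inside."""
    mask = np.asarray(nucleus_mask.data).astype(bool)
    if not mask.any():
        raise ValueError("empty nucleus mask")
    return ndimage.distance_transform_edt(~mask, sampling=nucleus_mask.voxel_size)


def mito_nucleus_distances_3d(
    instances: VolumeGrid,
    nucleus_mask: VolumeGrid,
    mode: str = "surface",
) -> dict[int, float]:
    """Per-instance distance (µm) to the nucleus in a 3D volume.

    Distances come from an anisotropy-aware Euclidean distance transform of
    the nucleus mask.  ``mode="surface"`` (default) takes the minimum over the
    instance's voxels; ``mode="centroid"`` reads the field at the voxel
    nearest the instance centroid.  Instances overlapping the nucleus
    footprint get distance 0.
    """
    if instances.shape != nucleus_mask.shape:
        raise ValueError("instance and nucleus grids must be aligned")
    if mode not in ("surface", "centroid"):
        raise ValueError(f"unknown mode {mode!r}")
    dist_nm = nucleus_distance_field(nucleus_mask)
    labels = np.asarray(instances.data)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    out: dict[int, float] = {}
    if mode == "surface":
        mins = ndimage.minimum(dist_nm, labels=labels, index=ids)
        for i, m in zip(ids, np.atleast_1d(mins)):
            out[int(i)] = float(m) / NM_PER_UM
    else:
        centroids = ndimage.center_of_mass(np.ones_like(labels), labels=labels, index=ids)
        for i, c in zip(ids, centroids):
            k, j, ii = (int(round(v)) for v in c)
            out[int(i)] = float(dist_nm[k, j, ii]) / NM_PER_UM
    return out
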