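"""Ground-truthed synthetic scenes for the imaging pipeline.

Emulates the statistical structure of serial block-face EM volumes of tumour
cells — an ellipsoidal nucleus, tubular mitochondria and spherical lipid
droplets on an anisotropic voxel grid (default 50 nm sections, 5 nm pixels)
— plus binary time-lapse series with a planted displacement velocity for the
motility statistic.  Every instance's true parameters are recorded so each
downstream measurement has an exact oracle.

Mitochondria are rasterized capsules: a smoothed 3D random-walk axis of the
drawn length, dilated by the tubule radius.  Short lengths give the
"fragmented" phenotype, long lengths the "elongated" one; placement is
either "perinuclear" (centroid within a shell outside the nucleus surface)
or "dispersed" (uniform over the cytoplasm).  Instances never overlap
(rejection sampling with a bounded retry budget).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .grids import VolumeGrid, voxel_volume_um3, NM_PER_UM
from .motility import MotilitySeries
from .spatial import sample_ellipse_boundary  # noqa: F401  (re-exported oracle helper)

__all__ = [
    "NucleusSpec",
    "MitoShapeParams",
    "IntensityModel",
    "SceneSpec",
    "GroundTruth",
    "generate_cell_volume",
    "generate_motility_series",
    "render_motility_grayscale",
    "sample_ellipse_boundary",
    "CLASS_NAMES",
]

CLASS_NAMES = {0: "background", 1: "nucleus", 2: "mitochondrion", 3: "lipid_droplet"}

_MAX_RETRIES = 1000


@dataclass
class NucleusSpec:
    """Ellipsoidal nucleus: semi-axes and center in nm (z, y, x), Euler tilt (rad)."""

    semi_axes: tuple[float, float, float] = (1100.0, 1150.0, 1150.0)
    center: tuple[float, float, float] = (1600.0, 1250.0, 1250.0)
    euler_zyx: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class MitoShapeParams:
    """Tubule radius and length distribution (log-normal in physical length)."""

    radius_nm: float = 100.0
    length_mean_um: float = 1.2
    length_sd_um: float = 0.6


@dataclass
class IntensityModel:
    """Per-class grayscale means on [0, 1] plus additive Gaussian noise.

    EM-like defaults: dark organelles on a bright resin background, very
    bright osmiophilic lipid droplets.
    """

    class_means: dict[int, float] = field(
        default_factory=lambda: {0: 0.8, 1: 0.45, 2: 0.2, 3: 0.9}
    )
    noise_sd: float = 0.05


@dataclass
class SceneSpec:
    """Full description of one synthetic SBEM-like scene."""

    grid_shape: tuple[int, int, int] = (64, 500, 500)
    voxel_size: tuple[float, float, float] = (50.0, 5.0, 5.0)  # nm, (dz, dy, dx)
    nucleus: NucleusSpec = field(default_factory=NucleusSpec)
    n_mitochondria: int = 25
    mito_shape: MitoShapeParams | None = None
    fragmentation_mode: str = "elongated"  # or "fragmented"
    placement_mode: str = "dispersed"  # or "perinuclear"
    perinuclear_shell_nm: float = 1000.0
    n_lipid_droplets: int = 5
    ld_radius_mean_nm: float = 300.0
    ld_radius_sd_nm: float = 50.0
    intensity: IntensityModel = field(default_factory=IntensityModel)
    seed: int = 0

    def __post_init__(self):
        if self.mito_shape is None:
            # fragmented networks are short stubs, elongated ones long tubules
            if self.fragmentation_mode == "fragmented":
                self.mito_shape = MitoShapeParams(length_mean_um=0.4, length_sd_um=0.15)
            else:
                self.mito_shape = MitoShapeParams()
        self.validate()

    def validate(self):
        if self.n_mitochondria < 0 or self.n_lipid_droplets < 0:
            raise ValueError("instance counts must be >= 0")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if any(s <= 0 for s in self.nucleus.semi_axes):
            raise ValueError("nucleus semi-axes must be positive")
        if self.mito_shape.radius_nm <= 0 or self.mito_shape.length_mean_um <= 0:
            raise ValueError("mitochondrion radius and length must be positive")
        if self.fragmentation_mode not in ("elongated", "fragmented"):
            raise ValueError(f"unknown fragmentation_mode {self.fragmentation_mode!r}")
        if self.placement_mode not in ("perinuclear", "dispersed"):
            raise ValueError(f"unknown placement_mode {self.placement_mode!r}")
        extent = np.asarray(self.grid_shape) * np.asarray(self.voxel_size)
        c = np.asarray(self.nucleus.center, dtype=float)
        if any(self.nucleus.euler_zyx):
            r = np.full(3, max(self.nucleus.semi_axes))  # bounding sphere when tilted
        else:
            r = np.asarray(self.nucleus.semi_axes, dtype=float)
        if np.any(c - r < 0) or np.any(c + r > extent):
            raise ValueError(
                "nucleus does not fit inside the grid: "
                f"center {tuple(c)} nm, semi-axes {tuple(r)} nm, extent {tuple(extent)} nm"
            )


@dataclass
class GroundTruth:
    """Per-voxel class/instance labels plus the planted instance parameters.

    ``instance_table`` columns: instance_id, class_id, class_name,
    centroid_{z,y,x}_um, voxel_count, true_volume_um3 (voxel count x voxel
    volume, exact), true_length_um (planted axis length; NaN for non-tubular
    instances), true_radius_nm.
    """

    class_volume: VolumeGrid
    instance_volume: VolumeGrid
    instance_table: pd.DataFrame


class PlacementError(RuntimeError):
    """Raised when an instance cannot be placed without overlap."""


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the underlying normal for a log-normal with given mean/sd."""
    if sd <= 0:
        return np.log(mean), 0.0
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def _rasterize_ellipsoid(shape, voxel_size, center_nm, semi_axes_nm, euler_zyx) -> np.ndarray:
    vs = np.asarray(voxel_size, dtype=float)
    c = np.asarray(center_nm, dtype=float)
    rmax = float(max(semi_axes_nm))
    lo = np.maximum(0, np.floor((c - rmax) / vs).astype(int))
    hi = np.minimum(np.asarray(shape), np.ceil((c + rmax) / vs).astype(int) + 1)
    dz = (np.arange(lo[0], hi[0]) * vs[0] - c[0])[:, None, None]
    dy = (np.arange(lo[1], hi[1]) * vs[1] - c[1])[None, :, None]
    dx = (np.arange(lo[2], hi[2]) * vs[2] - c[2])[None, None, :]
    rot = Rotation.from_euler("zyx", euler_zyx).as_matrix()
    az, ay, ax = semi_axes_nm
    # coordinates in the ellipsoid frame, (z, y, x) components via broadcasting
    lz = rot[0, 0] * dz + rot[0, 1] * dy + rot[0, 2] * dx
    ly = rot[1, 0] * dz + rot[1, 1] * dy + rot[1, 2] * dx
    lx = rot[2, 0] * dz + rot[2, 1] * dy + rot[2, 2] * dx
    inside_local = (lz / az) ** 2 + (ly / ay) ** 2 + (lx / ax) ** 2 <= 1.0
    mask = np.zeros(shape, dtype=bool)
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = inside_local
    return mask


def _capsule_axis(rng, start_nm, length_nm, step_nm=25.0, wobble=0.25) -> np.ndarray:
    """Smoothed 3D random-walk polyline of total arc length ``length_nm``."""
    n_steps = max(1, int(np.ceil(length_nm / step_nm)))
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    pts = [np.asarray(start_nm, dtype=float)]
    for _ in range(n_steps):
        d = d + wobble * rng.normal(size=3)
        d /= np.linalg.norm(d)
        pts.append(pts[-1] + d * min(step_nm, length_nm - (len(pts) - 1) * step_nm))
    return np.asarray(pts)


# sub-voxel probe offsets along z, as fractions of dz: the section spacing is
# coarse relative to the tubule radius, so a voxel is counted inside when at
# least half of its z extent is covered (midpoint rule with 8 probes)
_Z_PROBES = (np.arange(8) + 0.5) / 8.0 - 0.5


def _rasterize_capsule(shape, voxel_size, axis_nm, radius_nm) -> np.ndarray | None:
    """Boolean mask of voxels covered by the capsule; None if it leaves the grid.

    Distance to the polyline is evaluated per segment on a segment-local
    sub-box, at 8 z probes per voxel; a voxel is inside when at least half the
    probes fall within the radius (approximates >= 50% z coverage on
    anisotropic grids).
    """
    vs = np.asarray(voxel_size, dtype=float)
    lo_nm = axis_nm.min(axis=0) - radius_nm
    hi_nm = axis_nm.max(axis=0) + radius_nm
    extent = np.asarray(shape) * vs
    if np.any(lo_nm < 0) or np.any(hi_nm > extent):
        return None
    lo = np.maximum(0, np.floor(lo_nm / vs).astype(int))
    hi = np.minimum(np.asarray(shape), np.ceil(hi_nm / vs).astype(int) + 1)
    box_shape = tuple(hi - lo)
    d2min = np.full((len(_Z_PROBES),) + box_shape, np.inf, dtype=np.float32)
    r2 = radius_nm**2
    for p0, p1 in zip(axis_nm[:-1], axis_nm[1:]):
        seg = p1 - p0
        seg_len2 = float(seg @ seg)
        s_lo_nm = np.minimum(p0, p1) - radius_nm - vs  # margin for probe offsets
        s_hi_nm = np.maximum(p0, p1) + radius_nm + vs
        s_lo = np.maximum(lo, np.floor(s_lo_nm / vs).astype(int))
        s_hi = np.minimum(hi, np.ceil(s_hi_nm / vs).astype(int) + 1)
        if np.any(s_lo >= s_hi):
            continue
        zz = (np.arange(s_lo[0], s_hi[0]) * vs[0])[:, None, None]
        yy = (np.arange(s_lo[1], s_hi[1]) * vs[1])[None, :, None]
        xx = (np.arange(s_lo[2], s_hi[2]) * vs[2])[None, None, :]
        wy, wx = yy - p0[1], xx - p0[2]
        view = tuple(slice(a - b, c - b) for a, b, c in zip(s_lo, lo, s_hi))
        for pi, frac in enumerate(_Z_PROBES):
            wz = zz + frac * vs[0] - p0[0]
            if seg_len2 == 0.0:
                t = 0.0
            else:
                t = (wz * seg[0] + wy * seg[1] + wx * seg[2]) / seg_len2
                t = np.clip(t, 0.0, 1.0)
            d2 = (wz - t * seg[0]) ** 2 + (wy - t * seg[1]) ** 2 + (wx - t * seg[2]) ** 2
            target = d2min[pi][view]
            np.minimum(target, d2.astype(np.float32), out=target)
    inside = (d2min <= r2).sum(axis=0) >= 4
    if not inside.any():
        return None
    mask = np.zeros(shape, dtype=bool)
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = inside
    return mask


def _rasterize_sphere(shape, voxel_size, center_nm, radius_nm) -> np.ndarray | None:
    axis = np.asarray([center_nm], dtype=float)
    return _rasterize_capsule(shape, voxel_size, np.vstack([axis, axis]), radius_nm)


def _touches_occupied(mask: np.ndarray, class_vol: np.ndarray) -> bool:
    """True if the mask is within two voxels of occupied voxels.

    Keeping two empty voxels between instances guarantees that both plain
    connected-component labelling and the classical pipeline (whose median
    filter would bridge single-voxel gaps) recover the planted instance
    count.
    """
    sl = ndimage.find_objects(mask.astype(np.int8), max_label=1)[0]
    grown = tuple(slice(max(0, s.start - 2), min(d, s.stop + 2))
                  for s, d in zip(sl, mask.shape))
    local = ndimage.binary_dilation(mask[grown],
                                    structure=ndimage.generate_binary_structure(3, 3),
                                    iterations=2)
    return bool((class_vol[grown][local] != 0).any())


def _sample_position(rng, shape, voxel_size, accept) -> np.ndarray | None:
    """One uniformly drawn voxel-center position (nm) satisfying ``accept(k, j, i)``."""
    k = int(rng.integers(0, shape[0]))
    j = int(rng.integers(0, shape[1]))
    i = int(rng.integers(0, shape[2]))
    if not accept(k, j, i):
        return None
    return np.array([k, j, i], dtype=float) * np.asarray(voxel_size)


def generate_cell_volume(spec: SceneSpec) -> tuple[VolumeGrid, GroundTruth]:
    """Render one synthetic cell volume with exact per-instance ground truth.

    Deterministic: the same ``spec`` (including ``spec.seed``) yields
    bit-identical grayscale and label arrays.  Raises :class:`PlacementError`
    naming the offending class if an instance cannot be placed without
    overlap within the retry budget.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    vs = spec.voxel_size

    class_vol = np.zeros(shape, dtype=np.uint8)
    inst_vol = np.zeros(shape, dtype=np.int32)

    nuc = _rasterize_ellipsoid(shape, vs, spec.nucleus.center, spec.nucleus.semi_axes,
                               spec.nucleus.euler_zyx)
    class_vol[nuc] = 1
    inst_vol[nuc] = 1
    records = [
        dict(instance_id=1, class_id=1, true_length_um=np.nan,
             true_radius_nm=float(np.mean(spec.nucleus.semi_axes))),
    ]
    next_id = 2

    # cytoplasm geometry: distance (nm) outside the nucleus surface
    dist_out = ndimage.distance_transform_edt(~nuc, sampling=vs)

    def _accept_cytoplasm(k, j, i):
        return dist_out[k, j, i] > 0

    def _accept_perinuclear(k, j, i):
        return 0 < dist_out[k, j, i] <= spec.perinuclear_shell_nm

    # lipid droplets first (they are few and bulky)
    if spec.n_lipid_droplets > 0:
        for _ in range(spec.n_lipid_droplets):
            for attempt in range(_MAX_RETRIES):
                r = max(25.0, rng.normal(spec.ld_radius_mean_nm, spec.ld_radius_sd_nm))
                center = _sample_position(rng, shape, vs, _accept_cytoplasm)
                if center is None:
                    continue
                mask = _rasterize_sphere(shape, vs, center, r)
                if mask is None or _touches_occupied(mask, class_vol):
                    continue
                class_vol[mask] = 3
                inst_vol[mask] = next_id
                records.append(dict(instance_id=next_id, class_id=3,
                                    true_length_um=np.nan, true_radius_nm=float(r)))
                next_id += 1
                break
            else:
                raise PlacementError(
                    f"could not place lipid droplet {next_id} within {_MAX_RETRIES} retries "
                    "(scene too crowded)"
                )

    if spec.n_mitochondria > 0:
        accept = _accept_perinuclear if spec.placement_mode == "perinuclear" else _accept_cytoplasm
        mu, sigma = _lognormal_params(spec.mito_shape.length_mean_um,
                                      spec.mito_shape.length_sd_um)
        for _ in range(spec.n_mitochondria):
            for attempt in range(_MAX_RETRIES):
                length_um = float(np.exp(mu + sigma * rng.standard_normal())) if sigma > 0 \
                    else spec.mito_shape.length_mean_um
                start = _sample_position(rng, shape, vs, accept)
                if start is None:
                    continue
                axis = _capsule_axis(rng, start, length_um * NM_PER_UM)
                mask = _rasterize_capsule(shape, vs, axis, spec.mito_shape.radius_nm)
                if mask is None or _touches_occupied(mask, class_vol):
                    continue
                class_vol[mask] = 2
                inst_vol[mask] = next_id
                records.append(dict(instance_id=next_id, class_id=2,
                                    true_length_um=length_um,
                                    true_radius_nm=spec.mito_shape.radius_nm))
                next_id += 1
                break
            else:
                raise PlacementError(
                    f"could not place mitochondrion {next_id} within {_MAX_RETRIES} retries "
                    "(scene too crowded)"
                )

    # exact per-instance bookkeeping
    vox_um3 = voxel_volume_um3(vs)
    ids = [r["instance_id"] for r in records]
    counts = ndimage.sum_labels(np.ones(shape, dtype=np.int64), labels=inst_vol, index=ids)
    centroids = ndimage.center_of_mass(np.ones(shape), labels=inst_vol, index=ids)
    for rec, n_vox, com in zip(records, counts, centroids):
        rec["class_name"] = CLASS_NAMES[rec["class_id"]]
        rec["voxel_count"] = int(n_vox)
        rec["true_volume_um3"] = int(n_vox) * vox_um3
        rec["centroid_z_um"] = com[0] * vs[0] / NM_PER_UM
        rec["centroid_y_um"] = com[1] * vs[1] / NM_PER_UM
        rec["centroid_x_um"] = com[2] * vs[2] / NM_PER_UM
    table = pd.DataFrame.from_records(records)[
        ["instance_id", "class_id", "class_name", "centroid_z_um", "centroid_y_um",
         "centroid_x_um", "voxel_count", "true_volume_um3", "true_length_um",
         "true_radius_nm"]
    ]

    means = np.array([spec.intensity.class_means.get(c, 0.0) for c in range(4)])
    gray = means[class_vol] + rng.normal(0.0, spec.intensity.noise_sd, size=shape)
    gray = gray.astype(np.float32)

    grid = VolumeGrid(gray, vs)
    truth = GroundTruth(VolumeGrid(class_vol, vs), VolumeGrid(inst_vol, vs), table)
    return grid, truth


def generate_motility_series(
    mask_spec,
    velocity_px_per_frame: float,
    n_frames: int = 10,
    dt_s: float = 20.0,
    direction: tuple[float, float] = (0.0, 1.0),
    seed: int | None = None,
) -> tuple[MotilitySeries, float]:
    """Binary time-lapse with a planted constant displacement velocity.

    ``mask_spec`` is either a 2D boolean reference mask, or a dict
    ``{"shape": (h, w), "n_blobs": k, "blob_radius": r}`` from which a random
    blob mask is drawn with ``seed``.  Frame 1 is the reference; frame n is
    the reference translated by ``round(velocity * (n-1))`` pixels along
    ``direction`` (a (dy, dx) unit direction).  Returns the series and the
    planted velocity (px/frame).
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if velocity_px_per_frame < 0:
        raise ValueError("velocity must be >= 0")
    rng = np.random.default_rng(seed)
    if isinstance(mask_spec, dict):
        h, w = mask_spec["shape"]
        ref = np.zeros((h, w), dtype=bool)
        rr = mask_spec.get("blob_radius", 4)
        for _ in range(mask_spec.get("n_blobs", 5)):
            cy = rng.integers(rr, h - rr)
            cx = rng.integers(rr, w - rr)
            yy, xx = np.ogrid[:h, :w]
            ref |= (yy - cy) ** 2 + (xx - cx) ** 2 <= rr**2
    else:
        ref = np.asarray(mask_spec).astype(bool)
        if ref.ndim != 2:
            raise ValueError("reference mask must be 2D")
    if not ref.any():
        raise ValueError("reference mask is empty")
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    frames = [ref]
    for n in range(2, n_frames + 1):
        off = velocity_px_per_frame * (n - 1) * d
        oy, ox = int(round(off[0])), int(round(off[1]))
        shifted = np.zeros_like(ref)
        src = shifted.copy()
        h, w = ref.shape
        ys = slice(max(0, oy), min(h, h + oy))
        xs = slice(max(0, ox), min(w, w + ox))
        ys_src = slice(max(0, -oy), min(h, h - oy))
        xs_src = slice(max(0, -ox), min(w, w - ox))
        shifted[ys, xs] = ref[ys_src, xs_src]
        if ref.any() and not shifted.any():
            raise ValueError(f"object translated fully out of frame at frame {n}")
        frames.append(shifted)
    return MotilitySeries(np.stack(frames), dt=dt_s), float(velocity_px_per_frame)


def render_motility_grayscale(
    series: MotilitySeries,
    foreground: float = 1.0,
    background: float = 0.0,
    noise_sd: float = 0.2,
    seed: int | None = None,
) -> np.ndarray:
    """Grayscale rendering of a binary series (fluorescence-like, additive noise).

    ``(foreground - background) / noise_sd`` is the nominal SNR.
    """
    rng = np.random.default_rng(seed)
    img = np.where(series.frames, foreground, background).astype(float)
    return img + rng.normal(0.0, noise_sd, size=img.shape)
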