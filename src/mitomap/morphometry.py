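"""Per-mitochondrion 3D morphometry: volume, surface area, length, sphericity.

All measurements are in physical units.  Volume is exact (voxel count times
voxel volume).  Surface area comes from a marching-cubes isosurface of the
instance after resampling to isotropic spacing — voxel-face counting would
overestimate the area of smooth organelles by roughly half and break the
sphericity bound.  Sphericity is the isoperimetric quotient

    psi = pi^(1/3) * (6 V)^(2/3) / A,

1 for a sphere and decreasing with elongation.  "Length" is the geodesic
length of the longest shortest-path through the instance's 3D skeleton,
extended by the local radius (distance to the surface) at the two path ends,
so a straight tubule of axis length L and radius r measures about L + 2r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage import measure
from skimage.morphology import skeletonize

from .grids import VolumeGrid, NM_PER_UM

__all__ = [
    "MitoRecord",
    "label_components",
    "measure_components",
    "summarize_distributions",
    "CONNECTIVITY_STRUCTS",
]

CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class MitoRecord:
    """One mitochondrion's morphometry row.

    Units: volume µm³, surface_area µm², length µm, centroid (x, y, z) µm.
    ``nucleus_distance`` (µm) and ``compartment`` are filled by the spatial
    and compartment stages.
    """

    instance_id: int
    voxel_count: int
    volume: float
    surface_area: float
    length: float
    sphericity: float
    centroid: tuple[float, float, float]
    nucleus_distance: float | None = None
    compartment: str | None = None


def label_components(mask: VolumeGrid, connectivity: int = 26) -> VolumeGrid:
    """Connected-component labeling of a binary volume.

    ``connectivity`` is 6 (faces), 18 (faces+edges) or 26 (full); labels are
    dense positive integers and their union is exactly the foreground.
    """
    data = np.asarray(mask.data)
    vals = np.unique(data)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("label_components expects a binary (0/1) volume")
    if connectivity not in CONNECTIVITY_STRUCTS:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    labels, _ = ndimage.label(data.astype(bool), structure=CONNECTIVITY_STRUCTS[connectivity])
    return mask.like(labels.astype(np.int32))


_MAX_RESAMPLED_VOXELS = 500_000  # keeps meshing/skeletonization tractable per instance


def _isotropic(instance: np.ndarray, voxel_size) -> tuple[np.ndarray, float]:
    """Resample a binary sub-volume to isotropic spacing (linear interp).

    The target spacing is the finest axis spacing, coarsened just enough to
    keep the resampled instance under ~0.5M voxels so surface meshing and
    skeletonization stay tractable on large tubules.
    """
    vs = np.asarray(voxel_size, dtype=float)
    extent = np.asarray(instance.shape) * vs
    target = float(max(vs.min(), (np.prod(extent) / _MAX_RESAMPLED_VOXELS) ** (1 / 3)))
    zoom = vs / target
    if np.allclose(zoom, 1.0):
        return instance.astype(np.float32), target
    out = ndimage.zoom(instance.astype(np.float32), zoom, order=1, grid_mode=False)
    return out, target


def _surface_area_um2(iso: np.ndarray, spacing_nm: float) -> float:
    # mild Gaussian smoothing before meshing removes the voxel staircase,
    # which otherwise inflates the area of smooth organelles by ~8%
    padded = ndimage.gaussian_filter(np.pad(iso, 2), sigma=1.0)
    if padded.max() < 0.5:  # too thin to carry an isosurface after resampling
        return 0.0
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                                spacing=(spacing_nm,) * 3)
    return float(measure.mesh_surface_area(verts, faces)) / NM_PER_UM**2


def _skeleton_length_um(iso_bool: np.ndarray, spacing_nm: float) -> float:
    """Longest geodesic through the skeleton plus the end-point radii (µm)."""
    skel = skeletonize(iso_bool)
    coords = np.argwhere(skel)
    n = len(coords)
    edt = ndimage.distance_transform_edt(iso_bool) * spacing_nm
    if n == 0:
        return 0.0
    if n == 1:
        return float(2 * edt[tuple(coords[0])]) / NM_PER_UM
    # sparse graph over 26-neighbouring skeleton voxels, weights in nm
    index = -np.ones(skel.shape, dtype=np.int64)
    index[tuple(coords.T)] = np.arange(n)
    rows, cols, w = [], [], []
    offsets = np.array([o for o in np.ndindex(3, 3, 3)]) - 1
    offsets = offsets[np.any(offsets != 0, axis=1)]
    for off in offsets:
        nb = coords + off
        ok = np.all((nb >= 0) & (nb < skel.shape), axis=1)
        j = np.full(n, -1, dtype=np.int64)
        j[ok] = index[tuple(nb[ok].T)]
        hit = j >= 0
        rows.append(np.arange(n)[hit])
        cols.append(j[hit])
        w.append(np.full(hit.sum(), np.linalg.norm(off) * spacing_nm))
    g = coo_matrix((np.concatenate(w), (np.concatenate(rows), np.concatenate(cols))),
                   shape=(n, n)).tocsr()
    # double-sweep diameter (exact on trees, which skeletons essentially are)
    d0 = dijkstra(g, indices=0, directed=False)
    d0[~np.isfinite(d0)] = -1
    far1 = int(np.argmax(d0))
    d1 = dijkstra(g, indices=far1, directed=False)
    d1[~np.isfinite(d1)] = -1
    far2 = int(np.argmax(d1))
    length_nm = float(d1[far2])
    length_nm += float(edt[tuple(coords[far1])]) + float(edt[tuple(coords[far2])])
    return length_nm / NM_PER_UM


def measure_components(instances: VolumeGrid, length_method: str = "skeleton") -> list[MitoRecord]:
    """Morphometry for every instance in a labelled volume.

    ``length_method`` is "skeleton" (longest skeleton geodesic, default) or
    "major_axis" (physical extent along the principal axis).  Single-voxel
    instances use closed-form voxel measures so every record is total.
    """
    if length_method not in ("skeleton", "major_axis"):
        raise ValueError(f"unknown length_method {length_method!r}")
    labels = np.asarray(instances.data)
    vs = np.asarray(instances.voxel_size, dtype=float)
    vox_um3 = float(np.prod(vs)) / NM_PER_UM**3
    ids = np.unique(labels)
    ids = ids[ids > 0]
    records: list[MitoRecord] = []
    slices = ndimage.find_objects(labels)
    for inst_id in ids:
        sl = slices[inst_id - 1]
        sub = labels[sl] == inst_id
        count = int(sub.sum())
        volume = count * vox_um3
        com = ndimage.center_of_mass(sub)
        centroid_zyx = [(s.start + c) * v / NM_PER_UM for s, c, v in zip(sl, com, vs)]
        if count == 1:
            dz, dy, dx = vs / NM_PER_UM
            area = 2 * (dz * dy + dz * dx + dy * dx)
            length = float(max(vs)) / NM_PER_UM
            psi = float(np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area)
            records.append(MitoRecord(int(inst_id), count, volume, area, length, psi,
                                      tuple(centroid_zyx[::-1])))
            continue
        iso, spacing = _isotropic(np.pad(sub, 1), vs)  # 1-voxel background margin
        iso_bool = iso >= 0.5
        area = _surface_area_um2(iso, spacing)
        if area <= 0:
            dz, dy, dx = vs / NM_PER_UM
            area = count * 2 * (dz * dy + dz * dx + dy * dx)  # degenerate fallback
        if length_method == "skeleton":
            length = _skeleton_length_um(iso_bool, spacing)
            if length == 0.0:
                length = float(max(np.asarray(sub.shape) * vs)) / NM_PER_UM
        else:
            pts = np.argwhere(sub) * vs
            pts = pts - pts.mean(axis=0)
            axis_dir = np.linalg.svd(pts, full_matrices=False)[2][0]
            proj = pts @ axis_dir
            length = float(proj.max() - proj.min()) / NM_PER_UM
        psi = float(np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area)
        records.append(MitoRecord(int(inst_id), count, volume, area, length, psi,
                                  tuple(centroid_zyx[::-1])))
    return records


def summarize_distributions(records, metric: str, bins: int | np.ndarray = 30):
    """Normalized density table over one morphometry metric.

    Returns ``(density, bin_edges)`` with ``sum(density * diff(edges)) == 1``.
    ``metric`` is one of volume, length, sphericity, nucleus_distance.
    """
    allowed = {"volume", "length", "sphericity", "nucleus_distance"}
    if metric not in allowed:
        raise ValueError(f"metric must be one of {sorted(allowed)}")
    if not records:
        raise ValueError("no records to summarize")
    vals = np.array([getattr(r, metric) for r in records], dtype=float)
    if np.any(np.isnan(vals)):
        raise ValueError(f"metric {metric!r} not filled for all records")
    if vals.min() == vals.max():
        edges = np.array([vals.min() - 0.5, vals.max() + 0.5])
        return np.array([1.0 / (edges[1] - edges[0])]), edges
    density, edges = np.histogram(vals, bins=bins, density=True)
    return density, edges
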