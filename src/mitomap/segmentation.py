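"""Segmentation evaluation and the classical whole-cell instance pipeline.

Semantic maps are trinary: 0 background, 1 nucleus, 2 mitochondria.
Evaluation follows the usual one-vs-rest confusion counts per foreground
class:

    DICE = 2TP / (2TP + FP + FN)      IoU = TP / (TP + FP + FN)
    precision = TP / (TP + FP)        recall = TP / (TP + FN)

with the macro average taken over the foreground classes.  A class absent
from both prediction and truth is vacuously perfect (all four metrics 1), so
macro averages stay defined on sparse tiles.

The classical instance pipeline mirrors the interactive workflow used for
whole-cell labelling of block-face EM stacks: median filter, optional
percentile contrast rescale, threshold (Otsu by default, fixed optional),
marker-based separation of touching objects (distance-transform watershed)
and connected-component labelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, filters, segmentation as skseg

from .grids import VolumeGrid
from .morphometry import CONNECTIVITY_STRUCTS

__all__ = ["SegMetrics", "evaluate_segmentation", "classical_instance_segmentation"]


@dataclass
class SegMetrics:
    """DICE / IoU / precision / recall per foreground class and macro-averaged.

    ``per_class`` maps class id -> dict of the four metrics; ``pooled``
    carries the pixel-pooled (micro) precision/recall over foreground classes.
    """

    dice: float
    iou: float
    precision: float
    recall: float
    per_class: dict[int, dict[str, float]]
    pooled: dict[str, float]


def _class_metrics(pred: np.ndarray, truth: np.ndarray, cls: int) -> dict[str, float]:
    p = pred == cls
    t = truth == cls
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    if tp + fp + fn == 0:  # absent from both maps: vacuously perfect
        return {"dice": 1.0, "iou": 1.0, "precision": 1.0, "recall": 1.0,
                "tp": 0, "fp": 0, "fn": 0}
    return {
        "dice": 2 * tp / (2 * tp + fp + fn),
        "iou": tp / (tp + fp + fn),
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "recall": tp / (tp + fn) if tp + fn else 0.0,
        "tp": tp, "fp": fp, "fn": fn,
    }


def evaluate_segmentation(
    pred: np.ndarray,
    truth: np.ndarray,
    foreground_classes: tuple[int, ...] = (1, 2),
) -> SegMetrics:
    """Compare two class maps of identical shape; labels in {0, 1, 2}."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    per = {c: _class_metrics(pred, truth, c) for c in foreground_classes}
    macro = {k: float(np.mean([per[c][k] for c in foreground_classes]))
             for k in ("dice", "iou", "precision", "recall")}
    tp = sum(per[c]["tp"] for c in foreground_classes)
    fp = sum(per[c]["fp"] for c in foreground_classes)
    fn = sum(per[c]["fn"] for c in foreground_classes)
    pooled = {
        "precision": tp / (tp + fp) if tp + fp else 1.0,
        "recall": tp / (tp + fn) if tp + fn else 1.0,
    }
    per_clean = {c: {k: v for k, v in per[c].items() if k in
                     ("dice", "iou", "precision", "recall")} for c in per}
    return SegMetrics(macro["dice"], macro["iou"], macro["precision"], macro["recall"],
                      per_clean, pooled)


def classical_instance_segmentation(
    volume: VolumeGrid,
    median_size: int = 3,
    threshold: float | None = None,
    bright_objects: bool = True,
    contrast_percentiles: tuple[float, float] | None = None,
    separate_touching: bool = True,
    min_marker_distance_vox: int = 3,
    connectivity: int = 26,
) -> VolumeGrid:
    """Median filter -> threshold -> watershed separation -> labelling.

    ``threshold=None`` uses Otsu on the filtered volume; pass a fixed value
    to reproduce an interactive choice.  ``bright_objects`` selects whether
    the foreground is above or below the threshold.  Returns a dense positive
    instance labelling (empty, with a warning, if nothing survives the
    threshold).
    """
    data = np.asarray(volume.data, dtype=float)
    smoothed = ndimage.median_filter(data, size=median_size)
    if contrast_percentiles is not None:
        lo, hi = np.percentile(smoothed, contrast_percentiles)
        smoothed = exposure.rescale_intensity(smoothed, in_range=(lo, hi))
    thr = filters.threshold_otsu(smoothed) if threshold is None else threshold
    fg = smoothed >= thr if bright_objects else smoothed <= thr
    if not fg.any():
        warnings.warn("all voxels classified as background after thresholding", stacklevel=2)
        return volume.like(np.zeros(volume.shape, dtype=np.int32))
    struct = CONNECTIVITY_STRUCTS[connectivity]
    if separate_touching:
        dist = ndimage.distance_transform_edt(fg, sampling=volume.voxel_size)
        footprint = np.ones((min_marker_distance_vox,) * 3)
        peaks = (dist == ndimage.maximum_filter(dist, footprint=footprint)) & fg
        markers, n_markers = ndimage.label(peaks, structure=struct)
        if n_markers == 0:
            labels, _ = ndimage.label(fg, structure=struct)
        else:
            labels = skseg.watershed(-dist, markers=markers, mask=fg)
    else:
        labels, _ = ndimage.label(fg, structure=struct)
    # densify label ids
    ids = np.unique(labels)
    ids = ids[ids > 0]
    remap = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    remap[ids] = np.arange(1, len(ids) + 1, dtype=np.int32)
    return volume.like(remap[labels])
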