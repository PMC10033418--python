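"""Time-lapse mitochondrial motility statistic.

A field of view is imaged every ``dt`` seconds (default 20 s, 10 frames).
Frame 1 is the reference configuration.  For each later frame ``n``:

    overlap_area(n) = |mask(n) AND mask(1)|          (pixels)
    travel_area(n)  = |mask(n)| - overlap_area(n)
    ratio(n)        = travel_area(n) / overlap_area(n)

An ordinary least-squares line ``ratio = a * t + b`` is fitted to the
retained (time, ratio) points; the slope ``a`` (s^-1) is the motility
readout.  Frames whose overlap with the reference is zero have no defined
ratio and are excluded from the regression, with the exclusion recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import filters, restoration

__all__ = [
    "MotilitySeries",
    "MotilityResult",
    "binarize_series",
    "displacement_ratios",
    "motility_slope",
    "analyze_motility",
]


@dataclass
class MotilitySeries:
    """Ordered binary masks at uniform time spacing; frame 0 is the reference."""

    frames: np.ndarray  # (n_frames, h, w) bool
    dt: float = 20.0  # seconds between frames

    def __post_init__(self):
        self.frames = np.asarray(self.frames).astype(bool)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("a motility series needs >= 2 frames of equal shape")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Time stamps in seconds: 0, dt, 2*dt, ..."""
        return np.arange(self.n_frames) * self.dt


@dataclass
class MotilityResult:
    ratios: dict[int, float]  # frame number (2-based, matching n=2..N) -> ratio
    times: dict[int, float]  # frame number -> (n-1)*dt seconds
    slope: float | None = None  # s^-1
    intercept: float | None = None
    excluded_frames: list[tuple[int, str]] = field(default_factory=list)


def binarize_series(
    images: np.ndarray,
    dt: float = 20.0,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    background_radius: float | None = None,
    shared_threshold: bool = False,
) -> MotilitySeries:
    """Threshold a grayscale time-lapse stack into a binary series.

    Optional rolling-ball background subtraction (``background_radius`` in
    pixels) precedes thresholding.  ``method`` is "otsu" (default) or
    "fixed" with ``fixed_threshold``.  By default each frame is thresholded
    independently; ``shared_threshold`` reuses frame 1's threshold for all
    frames.
    """
    stack = np.asarray(images, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("expected a stack of >= 2 grayscale frames")
    if background_radius is not None:
        bg = np.stack([restoration.rolling_ball(f, radius=background_radius) for f in stack])
        stack = stack - bg
    masks = np.zeros(stack.shape, dtype=bool)
    thr0: float | None = None
    for i, frame in enumerate(stack):
        if method == "fixed":
            if fixed_threshold is None:
                raise ValueError("method='fixed' requires fixed_threshold")
            thr = fixed_threshold
        elif method == "otsu":
            if shared_threshold and thr0 is not None:
                thr = thr0
            elif frame.min() == frame.max():
                warnings.warn(f"frame {i} is constant; produced an empty mask", stacklevel=2)
                continue
            else:
                thr = filters.threshold_otsu(frame)
                if shared_threshold and thr0 is None:
                    thr0 = thr
        else:
            raise ValueError(f"unknown threshold method {method!r}")
        masks[i] = frame >= thr
    return MotilitySeries(masks, dt=dt)


def displacement_ratios(series: MotilitySeries) -> MotilityResult:
    """Per-frame displacement ratios against the reference frame.

    Frame numbering follows the acquisition convention: the reference is
    frame 1, ratios are defined for n = 2..N at times (n-1)*dt.
    """
    ref = series.frames[0]
    if not ref.any():
        raise ValueError("reference frame (frame 1) is empty; overlap is undefined")
    ratios: dict[int, float] = {}
    times: dict[int, float] = {}
    excluded: list[tuple[int, str]] = []
    for idx in range(1, series.n_frames):
        n = idx + 1
        mask = series.frames[idx]
        overlap = int(np.count_nonzero(mask & ref))
        area = int(np.count_nonzero(mask))
        t = idx * series.dt
        if overlap == 0:
            excluded.append((n, "zero overlap with reference frame"))
            continue
        ratios[n] = (area - overlap) / overlap
        times[n] = t
    if excluded:
        warnings.warn(
            "excluded frames from motility regression: "
            + ", ".join(f"frame {n} ({why})" for n, why in excluded),
            stacklevel=2,
        )
    return MotilityResult(ratios=ratios, times=times, excluded_frames=excluded)


def motility_slope(result: MotilityResult) -> MotilityResult:
    """Fill in the OLS slope/intercept of ratio against time (seconds)."""
    if len(result.ratios) < 2:
        raise ValueError(
            "need >= 2 retained (time, ratio) points for the regression; "
            f"exclusions: {result.excluded_frames}"
        )
    frames = sorted(result.ratios)
    t = np.array([result.times[n] for n in frames], dtype=float)
    r = np.array([result.ratios[n] for n in frames], dtype=float)
    slope, intercept = np.polyfit(t, r, 1)
    # exact zeros for the static case (polyfit returns ~1e-18 residue)
    if np.all(r == 0.0):
        slope, intercept = 0.0, 0.0
    result.slope = float(slope)
    result.intercept = float(intercept)
    return result


def analyze_motility(series: MotilitySeries) -> MotilityResult:
    """Ratios + regression in one call."""
    return motility_slope(displacement_ratios(series))
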