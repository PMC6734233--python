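"""Deterministic BOLD preprocessing: motion scrubbing, trimming,
intensity normalization, temporal band-pass filtering, spatial smoothing.

Inputs are assumed already motion-corrected and co-registered to a common
grid; the operations here are the scriptable, parameter-driven steps of a
standard resting-state pipeline.  Defaults: frames with framewise
displacement (FD) above 0.5 mm are censored, the first 12 s of each run are
discarded, runs are rescaled to a global mean of 10,000, band-passed to
0.009-0.08 Hz, and smoothed with a 6 mm FWHM Gaussian kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "PreprocConfig",
    "framewise_displacement",
    "trim_and_scrub",
    "intensity_normalize",
    "bandpass_filter",
    "spatial_smooth",
]

#: Gaussian FWHM -> standard deviation: 1 / (2 sqrt(2 ln 2)).
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class PreprocConfig:
    fd_threshold_mm: float = 0.5
    discard_initial_s: float = 12.0
    target_mean: float = 10_000.0
    band_low_hz: float = 0.009
    band_high_hz: float = 0.08
    smoothing_fwhm_mm: float = 6.0
    head_radius_mm: float = 50.0
    filter_order: int = 4

    def __post_init__(self) -> None:
        if self.fd_threshold_mm <= 0:
            raise ValueError("fd_threshold_mm must be positive")
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("need 0 < band_low_hz < band_high_hz")


def framewise_displacement(
    motion: np.ndarray, head_radius_mm: float = 50.0
) -> np.ndarray:
    """Power-style framewise displacement from a 6 x T motion trace.

    ``FD_t = sum |delta translations| + r * sum |delta rotations|`` with
    rotations (radians) converted to arc length on a sphere of radius
    ``head_radius_mm``.  Rows 0-2 are translations in mm, rows 3-5 rotations
    in radians.  Returns T-1 values, one per frame transition.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[0] != 6:
        raise ValueError("motion trace must have shape (6, T)")
    if motion.shape[1] < 2:
        raise ValueError("need at least 2 frames to compute FD")
    bad = np.argwhere(~np.isfinite(motion))
    if bad.size:
        raise ValueError(
            f"non-finite motion parameter at frame {int(bad[0][1])}"
        )
    d = np.abs(np.diff(motion, axis=1))
    return d[:3].sum(axis=0) + head_radius_mm * d[3:].sum(axis=0)


def _per_frame_fd(motion: np.ndarray, head_radius_mm: float) -> np.ndarray:
    """FD attributed to each frame: frame t carries the (t-1 -> t)
    transition; frame 0 carries 0."""
    return np.r_[0.0, framewise_displacement(motion, head_radius_mm)]


def trim_and_scrub(
    series: np.ndarray,
    motion: np.ndarray | None,
    config: PreprocConfig,
    tr_s: float,
    *,
    fd: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Discard initial frames, then censor high-motion frames.

    The first ``ceil(discard_initial_s / tr_s)`` frames are removed, then any
    frame whose own FD (the displacement of the transition *into* it) exceeds
    ``fd_threshold_mm``.  Time is the leading axis of ``series``.

    The per-frame FD may be supplied directly via ``fd`` (as returned by a
    previous call), which makes the operation idempotent: re-applying it with
    the returned FD vector and ``discard_initial_s = 0`` is the identity.

    Returns ``(retained_indices, trimmed_series, trimmed_fd)``.
    """
    series = np.asarray(series)
    if fd is None:
        if motion is None:
            raise ValueError("provide either a motion trace or per-frame fd")
        fd = _per_frame_fd(motion, config.head_radius_mm)
    fd = np.asarray(fd, dtype=float)
    if fd.shape[0] != series.shape[0]:
        raise ValueError(
            f"series has {series.shape[0]} frames but fd has {fd.shape[0]}"
        )
    n_trim = math.ceil(config.discard_initial_s / tr_s)
    candidates = np.arange(series.shape[0])[n_trim:]
    retained = candidates[fd[candidates] <= config.fd_threshold_mm]
    if retained.size == 0:
        raise ValueError("no usable volumes after trimming and scrubbing")
    return retained, series[retained], fd[retained]


def intensity_normalize(
    volumes: np.ndarray,
    target_mean: float = 10_000.0,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Scale a 4D run by one global factor so its in-mask mean equals
    ``target_mean``.  Returns the scaled data and the factor applied."""
    volumes = np.asarray(volumes, dtype=float)
    current = volumes[mask].mean() if mask is not None else volumes.mean()
    if not np.isfinite(current) or current <= 0:
        raise ValueError(
            f"cannot normalize: in-mask mean is {current!r} (must be > 0)"
        )
    factor = target_mean / current
    return volumes * factor, factor


def bandpass_filter(
    series: np.ndarray,
    tr_s: float,
    band_low_hz: float = 0.009,
    band_high_hz: float = 0.08,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the leading (time) axis.

    Forward-backward filtering (``sosfiltfilt``) is used so that no phase
    distortion is introduced into subsequent correlation estimates.  The
    series is demeaned internally; the DC component is removed by
    construction.
    """
    nyquist = 0.5 / tr_s
    if not 0 < band_low_hz < band_high_hz < nyquist:
        raise ValueError(
            f"band ({band_low_hz}, {band_high_hz}) Hz must lie inside "
            f"(0, {nyquist}) Hz at TR = {tr_s} s"
        )
    series = np.asarray(series, dtype=float)
    sos = signal.butter(
        order, [band_low_hz, band_high_hz], btype="bandpass", fs=1.0 / tr_s,
        output="sos",
    )
    demeaned = series - series.mean(axis=0, keepdims=True)
    return signal.sosfiltfilt(sos, demeaned, axis=0)


def spatial_smooth(
    volumes: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: float | tuple[float, float, float],
) -> np.ndarray:
    """Gaussian spatial smoothing of a 3D volume or 4D (X, Y, Z, T) run.

    The kernel standard deviation per axis is ``fwhm / (2 sqrt(2 ln 2))``
    divided by the voxel size; the image sum is conserved up to boundary
    truncation.  ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    volumes = np.asarray(volumes, dtype=float)
    if fwhm_mm == 0:
        return volumes.copy()
    vox = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    sigma = FWHM_TO_SIGMA * fwhm_mm / vox
    if volumes.ndim == 4:
        sigma = np.r_[sigma, 0.0]  # do not smooth across time
    elif volumes.ndim != 3:
        raise ValueError("volumes must be 3D or 4D")
    return ndimage.gaussian_filter(volumes, sigma=sigma, mode="constant")
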