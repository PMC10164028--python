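"""ROI-time-series cleaning: nuisance regression, detrend, band-pass, scrubbing.

The pipeline order is fixed: nuisance regression -> linear detrend ->
zero-phase band-pass (0.009-0.08 Hz) -> framewise-displacement scrubbing.
Filtering precedes scrubbing because the zero-phase filter requires uniform
sampling; scrubbing removes flagged volumes afterwards.  Framewise
displacement follows the Power et al. formulation: the sum of absolute
backward differences of the 3 translations plus the 3 rotations converted to
arc length on a 50 mm sphere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synthetic import MotionParams, ROITimeSeries
from .util import ConfigurationError, FormatError, log

FD_THRESHOLD_MM = 0.5
MIN_USABLE_VOLUMES = 10


@dataclass
class FDSeries:
    """Per-volume framewise displacement (mm); first volume defined as 0."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("framewise displacement must be non-negative")


def framewise_displacement(motion: MotionParams,
                           head_radius_mm: float = 50.0) -> FDSeries:
    """FD_t = sum|d translations| + r * sum|d rotations|, FD_0 = 0."""
    vals = motion.values
    if vals.shape[1] != 6:
        raise FormatError("motion parameters must have 6 columns")
    diffs = np.abs(np.diff(vals, axis=0))
    fd = diffs[:, :3].sum(axis=1) + head_radius_mm * diffs[:, 3:].sum(axis=1)
    return FDSeries(values=np.concatenate([[0.0], fd]))


def scrub(ts: ROITimeSeries, fd: FDSeries,
          threshold: float = FD_THRESHOLD_MM) -> tuple[ROITimeSeries, bool]:
    """Drop volumes with FD strictly greater than ``threshold``.

    Returns the scrubbed series plus a usability flag: blocks with fewer than
    10 surviving volumes are flagged unusable (and should be excluded
    downstream) rather than raising.
    """
    if fd.values.shape[0] != ts.n_volumes:
        raise FormatError("FD series and time series lengths differ")
    keep = fd.values <= threshold
    n_kept = int(keep.sum())
    usable = n_kept >= MIN_USABLE_VOLUMES
    if not usable:
        log.warning("scrub: only %d volumes survive FD > %.2f; block unusable",
                    n_kept, threshold)
        return ts, False
    mask = ts.volume_mask.copy()
    mask[np.nonzero(mask)[0][~keep]] = False
    return ROITimeSeries(values=ts.values[keep], tr=ts.tr, volume_mask=mask), True


def nuisance_regress(ts: ROITimeSeries, confounds: np.ndarray) -> ROITimeSeries:
    """Residualize each ROI on [intercept | confound columns].

    Collinear or zero confound columns are dropped with a warning; the output
    is exactly orthogonal to every retained confound column.
    """
    conf = np.asarray(confounds, dtype=float)
    if conf.ndim == 1:
        conf = conf[:, None]
    if conf.shape[0] != ts.n_volumes:
        raise FormatError("confounds and time series lengths differ")
    design = np.column_stack([np.ones(ts.n_volumes), conf])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        kept = [0]
        for c in range(1, design.shape[1]):
            trial = design[:, kept + [c]]
            if np.linalg.matrix_rank(trial) > len(kept):
                kept.append(c)
        warnings.warn(
            f"nuisance_regress: dropped {design.shape[1] - len(kept)} "
            "collinear confound column(s)", stacklevel=2)
        design = design[:, kept]
    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    resid = ts.values - design @ beta
    return ROITimeSeries(values=resid, tr=ts.tr, volume_mask=ts.volume_mask)


def bandpass(ts: ROITimeSeries, low_hz: float = 0.009,
             high_hz: float = 0.08, order: int = 2) -> ROITimeSeries:
    """Zero-phase Butterworth band-pass (default 0.009-0.08 Hz).

    ``order`` is the Butterworth design order per band edge (the band-pass
    has 2*order poles; zero-phase filtering doubles the effective order).
    """
    nyquist = 0.5 / ts.tr
    if high_hz >= nyquist:
        raise ConfigurationError(
            f"band edge {high_hz} Hz not below Nyquist {nyquist:.4f} Hz at tr={ts.tr}")
    if not 0 < low_hz < high_hz:
        raise ConfigurationError("need 0 < low_hz < high_hz")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=1.0 / ts.tr, output="sos")
    filtered = signal.sosfiltfilt(sos, ts.values, axis=0)
    return ROITimeSeries(values=np.ascontiguousarray(filtered), tr=ts.tr,
                         volume_mask=ts.volume_mask)


def detrend_linear(ts: ROITimeSeries) -> ROITimeSeries:
    """Remove the per-ROI least-squares line (idempotent)."""
    if ts.n_volumes < 3:
        raise ConfigurationError("need at least 3 volumes to detrend")
    t = np.arange(ts.n_volumes, dtype=float)
    design = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    return ROITimeSeries(values=ts.values - design @ beta, tr=ts.tr,
                         volume_mask=ts.volume_mask)


def preprocess_block(ts: ROITimeSeries,
                     confounds: np.ndarray | None = None,
                     motion: MotionParams | None = None,
                     fd_threshold: float = FD_THRESHOLD_MM,
                     low_hz: float = 0.009, high_hz: float = 0.08,
                     ) -> tuple[ROITimeSeries, bool]:
    """Full cleaning chain for one block; returns (series, usable flag).

    Motion parameters, when present, contribute both nuisance regressors and
    the FD trace used for scrubbing.
    """
    nuisance = []
    if confounds is not None:
        nuisance.append(np.asarray(confounds, dtype=float))
    if motion is not None:
        nuisance.append(motion.values)
    if nuisance:
        ts = nuisance_regress(ts, np.column_stack(nuisance))
    ts = detrend_linear(ts)
    ts = bandpass(ts, low_hz=low_hz, high_hz=high_hz)
    if motion is not None:
        fd = framewise_displacement(motion)
        ts, usable = scrub(ts, fd, threshold=fd_threshold)
    else:
        usable = True
    return ts, usable


def preprocess_study(study) -> None:
    """Clean every block of a StudyDataset in place, setting usability flags."""
    for block in study.blocks:
        block.ts, block.usable = preprocess_block(
            block.ts, confounds=block.confounds, motion=block.motion)
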