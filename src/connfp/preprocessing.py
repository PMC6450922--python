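"""Per-run time-series conditioning and cohort-level motion QC.

Processing order is frozen as detrend/demean -> bandpass -> FC estimation.
The bandpass is a zero-phase (forward-backward) Butterworth filter; the
default passband 0.01634--0.15 Hz targets resting-state fluctuations at
TR = 0.72 s, and its low edge sets the sliding-window length used by the
dynamic-FC pipeline (1/f_min ~ 61 s).

Motion QC excludes subjects whose run-averaged framewise displacement lies
more than four standard deviations above the cohort mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .io_core import FCMatrix, TimeSeriesMatrix, ValidationError

__all__ = [
    "PreprocessConfig",
    "MotionRecord",
    "detrend_demean",
    "bandpass",
    "motion_exclude",
    "average_runs",
    "preprocess_run",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Bandpass settings. ``filter_order`` is the Butterworth design order;
    forward-backward application doubles the effective order."""

    f_min: float = 0.01634  # Hz
    f_max: float = 0.15     # Hz
    filter_order: int = 2

    def validate_for(self, tr_seconds: float) -> None:
        nyquist = 1.0 / (2.0 * tr_seconds)
        if not (0.0 < self.f_min < self.f_max):
            raise ValidationError("need 0 < f_min < f_max")
        if self.f_max >= nyquist:
            raise ValidationError(
                f"f_max={self.f_max} Hz must be below the Nyquist frequency "
                f"{nyquist:.4g} Hz for TR={tr_seconds}s"
            )
        if self.filter_order < 1:
            raise ValidationError("filter_order must be a positive integer")


@dataclass(frozen=True)
class MotionRecord:
    """Per-subject run-averaged framewise displacement (mm)."""

    subject_id: str
    mean_fd: float

    def __post_init__(self) -> None:
        if self.mean_fd < 0:
            raise ValidationError("mean framewise displacement must be >= 0")


def _clone(ts: TimeSeriesMatrix, values: np.ndarray) -> TimeSeriesMatrix:
    return TimeSeriesMatrix(
        values=values, tr_seconds=ts.tr_seconds, node_ids=list(ts.node_ids),
        subject_id=ts.subject_id, session_id=ts.session_id, run_id=ts.run_id,
    )


def detrend_demean(ts: TimeSeriesMatrix) -> TimeSeriesMatrix:
    """Remove, per node, the least-squares line over time (slope and mean)."""
    out = signal.detrend(ts.values, axis=0, type="linear")
    return _clone(ts, out)


def bandpass(ts: TimeSeriesMatrix, cfg: PreprocessConfig | None = None) -> TimeSeriesMatrix:
    """Zero-phase Butterworth band-pass of every node series."""
    cfg = cfg or PreprocessConfig()
    cfg.validate_for(ts.tr_seconds)
    fs = 1.0 / ts.tr_seconds
    sos = signal.butter(cfg.filter_order, [cfg.f_min, cfg.f_max],
                        btype="bandpass", fs=fs, output="sos")
    out = signal.sosfiltfilt(sos, ts.values, axis=0)
    return _clone(ts, out)


def preprocess_run(ts: TimeSeriesMatrix, cfg: PreprocessConfig | None = None) -> TimeSeriesMatrix:
    """The full conditioning chain: detrend/demean then bandpass."""
    return bandpass(detrend_demean(ts), cfg)


def motion_exclude(records: Sequence[MotionRecord]) -> np.ndarray:
    """Boolean inclusion mask: False where mean FD > cohort mean + 4 SD.

    The standard deviation is taken over all records with the unbiased
    (n-1) denominator; the comparison is strict, so a zero-spread cohort
    excludes nobody.
    """
    if len(records) < 2:
        raise ValidationError("motion QC needs at least 2 records")
    fd = np.array([r.mean_fd for r in records], dtype=float)
    threshold = fd.mean() + 4.0 * fd.std(ddof=1)
    return ~(fd > threshold)


def average_runs(fc_a: FCMatrix, fc_b: FCMatrix) -> FCMatrix:
    """Element-wise mean of the two phase-encoding runs of one session."""
    if fc_a.n_nodes != fc_b.n_nodes:
        raise ValidationError("run FC matrices differ in size")
    if fc_a.method_tag != fc_b.method_tag:
        raise ValidationError(
            f"method_tag mismatch: {fc_a.method_tag} vs {fc_b.method_tag}"
        )
    if fc_a.node_ids is not None and fc_b.node_ids is not None \
            and fc_a.node_ids != fc_b.node_ids:
        raise ValidationError("node id mismatch between runs")
    return FCMatrix(
        values=(fc_a.values + fc_b.values) / 2.0,
        method_tag=fc_a.method_tag,
        node_ids=fc_a.node_ids,
    )
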