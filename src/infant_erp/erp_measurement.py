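"""Condition-wise ERP averaging and ROI/time-window measurement.

Two measurement types are supported: windowed mean amplitude (averaging
all datapoints inside the window over the ROI channels) and negative
peak, where the most negative sample is found per ROI electrode and the
per-electrode amplitudes and latencies are then averaged.  The
peak-of-ROI-average alternative is available behind a switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import EpochSet
from .study_design import AnalysisWindow, RoiSpec, default_analysis_plan


@dataclass(frozen=True)
class ErpAverage:
    """Per-subject, per-condition average waveform (channels x samples)."""

    data: np.ndarray
    montage: object
    t_min_ms: float
    condition: str
    modality: str
    n_trials: int
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("average contains non-finite values")

    @property
    def sampling_rate(self) -> float:
        return self.montage.sampling_rate

    @property
    def times_ms(self) -> np.ndarray:
        return self.t_min_ms + np.arange(self.data.shape[1]) * 1000.0 / self.sampling_rate


def average_epochs(epochs: EpochSet, condition: str, subject_id: str = "") -> ErpAverage:
    """Pointwise mean over the retained epochs of one condition."""
    conds = np.asarray(epochs.conditions)
    pick = ~epochs.rejected & (conds == condition)
    n = int(pick.sum())
    if n == 0:
        raise ValueError(f"no retained {condition!r} epochs to average")
    return ErpAverage(
        data=epochs.data[pick].mean(axis=0),
        montage=epochs.montage,
        t_min_ms=epochs.t_min_ms,
        condition=condition,
        modality=epochs.modality,
        n_trials=n,
        subject_id=subject_id,
    )


def _window_mask(erp: ErpAverage, t_start_ms: float, t_end_ms: float) -> np.ndarray:
    t = erp.times_ms
    mask = (t >= t_start_ms - 1e-9) & (t < t_end_ms - 1e-9)
    if not mask.any():
        raise ValueError("window contains no samples")
    return mask


def _roi_rows(erp: ErpAverage, roi: RoiSpec) -> list[int]:
    return [erp.montage.index(label) for label in roi.channel_labels]


def mean_amplitude(erp: ErpAverage, roi: RoiSpec, window: AnalysisWindow | tuple[float, float]) -> float:
    """Mean over the ROI channels' samples inside the half-open window."""
    t_start, t_end = (window.t_start, window.t_end) if isinstance(window, AnalysisWindow) else window
    mask = _window_mask(erp, t_start, t_end)
    return float(erp.data[np.ix_(_roi_rows(erp, roi), np.nonzero(mask)[0])].mean())


def negative_peak(
    erp: ErpAverage,
    roi: RoiSpec,
    window: AnalysisWindow | tuple[float, float],
    per_electrode: bool = True,
) -> tuple[float, float]:
    """Most negative deflection in the window: (amplitude µV, latency ms).

    Default finds the minimum per ROI electrode and averages amplitudes
    and latencies across electrodes (ties resolve to the earliest
    latency).  With ``per_electrode=False`` the minimum of the
    ROI-average waveform is taken instead.
    """
    t_start, t_end = (window.t_start, window.t_end) if isinstance(window, AnalysisWindow) else window
    mask = _window_mask(erp, t_start, t_end)
    cols = np.nonzero(mask)[0]
    seg = erp.data[np.ix_(_roi_rows(erp, roi), cols)]
    times = erp.times_ms[cols]
    if not per_electrode:
        seg = seg.mean(axis=0, keepdims=True)
    idx = np.argmin(seg, axis=1)  # earliest on ties
    amps = seg[np.arange(seg.shape[0]), idx]
    return float(amps.mean()), float(times[idx].mean())


@dataclass(frozen=True)
class SubjectErps:
    subject_id: str
    group: str
    averages: dict[tuple[str, str], ErpAverage]  # (modality, condition) -> average


def measure_subject(
    subject: SubjectErps,
    plan: list[tuple[RoiSpec, AnalysisWindow]] | None = None,
) -> pd.DataFrame:
    """Long-format measurement rows for one subject over the analysis plan."""
    plan = plan if plan is not None else default_analysis_plan()
    rows = []
    for (modality, condition), erp in sorted(subject.averages.items()):
        for roi, window in plan:
            if window.modality != modality:
                continue
            base = {
                "subject": subject.subject_id,
                "group": subject.group,
                "condition": condition,
                "modality": modality,
                "roi": roi.name,
                "window": window.name,
                "n_trials": erp.n_trials,
            }
            if window.measure == "mean_amplitude":
                rows.append({**base, "measure": "mean_amplitude_uv",
                             "value": mean_amplitude(erp, roi, window)})
            else:
                amp, lat = negative_peak(erp, roi, window)
                rows.append({**base, "measure": "peak_amplitude_uv", "value": amp})
                rows.append({**base, "measure": "peak_latency_ms", "value": lat})
    return pd.DataFrame(rows)


def build_measurement_table(
    subjects: list[SubjectErps],
    plan: list[tuple[RoiSpec, AnalysisWindow]] | None = None,
) -> pd.DataFrame:
    """Concatenate per-subject measurements for all included subjects."""
    frames = [measure_subject(s, plan) for s in subjects]
    if not frames:
        return pd.DataFrame(
            columns=["subject", "group", "condition", "modality", "roi",
                     "window", "n_trials", "measure", "value"]
        )
    return pd.concat(frames, ignore_index=True)


def grand_average(erps: list[ErpAverage]) -> ErpAverage:
    """Unweighted mean across subjects' averages (same condition/modality)."""
    if not erps:
        raise ValueError("nothing to average")
    data = np.mean([e.data for e in erps], axis=0)
    first = erps[0]
    return ErpAverage(
        data=data,
        montage=first.montage,
        t_min_ms=first.t_min_ms,
        condition=first.condition,
        modality=first.modality,
        n_trials=len(erps),
        subject_id="grand",
    )


def grand_average_frame(erp: ErpAverage) -> pd.DataFrame:
    """Waveform as time x channel table for plotting/export."""
    df = pd.DataFrame(erp.data.T, columns=erp.montage.labels)
    df.insert(0, "time_ms", erp.times_ms)
    return df
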