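"""Continuous EEG to clean epochs.

Order of operations mirrors standard infant-ERP practice: the band-pass
is applied first on the continuous data, then linked-mastoid
re-referencing, epoching around stimulus triggers, baseline correction,
and gliding-window artifact rejection.  Ocular artifacts are rejected,
not corrected; there is no channel interpolation.

The rejection rule marks an epoch whenever the sample standard deviation
within any 200 ms window — slid sample by sample across the whole epoch,
baseline included — exceeds 80 µV on an EOG channel or 50 µV on any
other channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import signal

from .synthetic_eeg import AUDITORY_MARKERS, VISUAL_MARKERS, ContinuousRecording

EPOCH_TMIN_MS = -200.0
EPOCH_TMAX_MS = 1500.0
BASELINE_MS = (-200.0, 0.0)


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase FIR band-pass (Hamming-window design)."""

    low_cut_hz: float = 0.3
    high_cut_hz: float = 20.0
    n_taps: int = 1501

    def __post_init__(self) -> None:
        if not 0 <= self.low_cut_hz < self.high_cut_hz:
            raise ValueError("need 0 <= low < high")
        if self.n_taps % 2 == 0:
            raise ValueError("n_taps must be odd for exact delay compensation")

    def design(self, sampling_rate: float) -> np.ndarray:
        if self.high_cut_hz >= sampling_rate / 2:
            raise ValueError("high cut must be below Nyquist")
        return signal.firwin(
            self.n_taps,
            [self.low_cut_hz, self.high_cut_hz],
            pass_zero=False,
            window="hamming",
            fs=sampling_rate,
        )


def fir_bandpass(recording: ContinuousRecording, spec: FilterSpec) -> ContinuousRecording:
    """Apply the band-pass to all EEG channels (scalp, mastoid, reference).

    Single linear-phase pass with exact group-delay compensation, so the
    magnitude response is that of the designed filter and the phase shift
    is zero at every frequency.  Bipolar EOG channels are left unfiltered.
    Events are unchanged.
    """
    if recording.n_samples <= spec.n_taps:
        raise ValueError("recording shorter than the filter")
    taps = spec.design(recording.montage.sampling_rate)
    pad = spec.n_taps // 2
    rows = [
        i
        for i, (_, role) in enumerate(recording.montage.channels)
        if role in ("scalp", "mastoid", "reference")
    ]
    data = recording.data.copy()
    padded = np.pad(data[rows], ((0, 0), (pad, pad)), mode="reflect")
    filtered = signal.fftconvolve(padded, taps[None, :], mode="same", axes=1)
    data[rows] = filtered[:, pad:-pad]
    return replace(recording, data=data)


def rereference_linked_mastoids(recording: ContinuousRecording) -> ContinuousRecording:
    """Re-express scalp channels (and the recovered Cz) against the
    average of the two mastoids.  EOG channels are untouched.

    Cz — identically zero while it served as the recording reference —
    becomes a data channel equal to minus the linked-mastoid average.
    """
    montage = recording.montage
    mastoids = montage.labels_for("mastoid")
    if len(mastoids) != 2:
        raise ValueError("montage must have two mastoid channels")
    ref = recording.data[[montage.index(m) for m in mastoids]].mean(axis=0)
    data = recording.data.copy()
    for i, (_, role) in enumerate(montage.channels):
        if role in ("scalp", "mastoid", "reference"):
            data[i] = data[i] - ref
    return replace(recording, data=data)


@dataclass(frozen=True)
class EpochSet:
    """Stimulus-locked trials x channels x samples for one modality."""

    data: np.ndarray  # trials x channels x samples, µV
    montage: object  # Montage; channel axis follows montage order
    modality: Literal["auditory", "visual"]
    conditions: tuple[str, ...]  # per-trial: own | stranger
    trial_indices: tuple[int, ...]  # event order within the modality
    t_min_ms: float = EPOCH_TMIN_MS
    rejected: np.ndarray = field(default=None)  # per-trial bool
    reasons: tuple[str | None, ...] = ()
    n_edge_dropped: int = 0

    def __post_init__(self) -> None:
        if self.rejected is None:
            object.__setattr__(self, "rejected", np.zeros(self.data.shape[0], bool))
        if not self.reasons:
            object.__setattr__(self, "reasons", tuple([None] * self.data.shape[0]))
        if len(self.rejected) != self.data.shape[0]:
            raise ValueError("rejection mask length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def sampling_rate(self) -> float:
        return self.montage.sampling_rate

    @property
    def times_ms(self) -> np.ndarray:
        return self.t_min_ms + np.arange(self.data.shape[2]) * 1000.0 / self.sampling_rate

    def sample_slice(self, t_start_ms: float, t_end_ms: float) -> np.ndarray:
        """Boolean sample mask for the half-open window [t_start, t_end)."""
        t = self.times_ms
        return (t >= t_start_ms - 1e-9) & (t < t_end_ms - 1e-9)

    def retained(self) -> np.ndarray:
        return ~self.rejected

    def subset(self, mask: np.ndarray) -> "EpochSet":
        """Trial subset (boolean mask or index array); metadata follows."""
        mask = np.asarray(mask)
        idx = np.nonzero(mask)[0] if mask.dtype == bool else mask
        return replace(
            self,
            data=self.data[idx],
            conditions=tuple(np.asarray(self.conditions)[idx]),
            trial_indices=tuple(int(i) for i in np.asarray(self.trial_indices)[idx]),
            rejected=self.rejected[idx],
            reasons=tuple(np.asarray(self.reasons, dtype=object)[idx]),
        )

    def retained_count(self, condition: str) -> int:
        conds = np.asarray(self.conditions)
        return int((~self.rejected & (conds == condition)).sum())


def extract_epochs(
    recording: ContinuousRecording,
    marker_type: Literal["auditory", "visual"],
    t_min_ms: float = EPOCH_TMIN_MS,
    t_max_ms: float = EPOCH_TMAX_MS,
) -> EpochSet:
    """Cut one epoch per matching event; time zero at event onset.

    The epoch covers the half-open interval [t_min, t_max); events whose
    epoch would run past either recording edge are dropped and counted in
    ``n_edge_dropped``.
    """
    fs = recording.montage.sampling_rate
    markers = AUDITORY_MARKERS if marker_type == "auditory" else VISUAL_MARKERS
    n_samp = int(round((t_max_ms - t_min_ms) * fs / 1000.0))
    offset = int(round(t_min_ms * fs / 1000.0))
    epochs, conds, indices = [], [], []
    dropped = 0
    for order, (sample, marker) in enumerate(recording.events_of(markers)):
        start = sample + offset
        if start < 0 or start + n_samp > recording.n_samples:
            dropped += 1
            continue
        epochs.append(recording.data[:, start : start + n_samp])
        conds.append("own" if marker.endswith("own") else "stranger")
        indices.append(order)
    data = np.stack(epochs) if epochs else np.empty((0, len(recording.montage.labels), n_samp))
    return EpochSet(
        data=data,
        montage=recording.montage,
        modality=marker_type,
        conditions=tuple(conds),
        trial_indices=tuple(indices),
        t_min_ms=t_min_ms,
        n_edge_dropped=dropped,
    )


def baseline_correct(epochs: EpochSet, window_ms: tuple[float, float] = BASELINE_MS) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over the baseline window."""
    mask = epochs.sample_slice(*window_ms)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    baseline = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - baseline)


def sliding_window_sd(x: np.ndarray, window: int) -> np.ndarray:
    """Population SD over every length-``window`` sliding window (step 1).

    ``x`` is (..., samples); returns (..., samples - window + 1).
    Implemented with cumulative sums; clipped at zero to absorb rounding.
    """
    c1 = np.cumsum(np.concatenate([np.zeros_like(x[..., :1]), x], axis=-1), axis=-1)
    c2 = np.cumsum(np.concatenate([np.zeros_like(x[..., :1]), x * x], axis=-1), axis=-1)
    s1 = c1[..., window:] - c1[..., :-window]
    s2 = c2[..., window:] - c2[..., :-window]
    var = s2 / window - (s1 / window) ** 2
    return np.sqrt(np.clip(var, 0.0, None))


def reject_artifacts(
    epochs: EpochSet,
    window_ms: float = 200.0,
    sd_eog_uv: float = 80.0,
    sd_scalp_uv: float = 50.0,
) -> EpochSet:
    """Gliding-window SD rejection over the full epoch span.

    An epoch is rejected iff any window on any channel exceeds the
    threshold for that channel's role (EOG channels get ``sd_eog_uv``,
    every other channel ``sd_scalp_uv``).  The recorded reason names the
    first offending channel and window start.  Already-rejected epochs
    keep their mark.
    """
    fs = epochs.sampling_rate
    window = int(round(window_ms * fs / 1000.0))
    if window > epochs.data.shape[2]:
        raise ValueError("rejection window longer than the epoch")
    thresholds = np.array(
        [sd_eog_uv if role == "eog" else sd_scalp_uv for _, role in epochs.montage.channels]
    )
    sds = sliding_window_sd(epochs.data, window)  # trials x channels x windows
    over = sds > thresholds[None, :, None]
    rejected = epochs.rejected.copy()
    reasons = list(epochs.reasons)
    labels = epochs.montage.labels
    for trial in np.nonzero(over.any(axis=(1, 2)))[0]:
        ch, win = np.unravel_index(np.argmax(over[trial]), over[trial].shape)
        if not rejected[trial]:
            start_ms = epochs.t_min_ms + win * 1000.0 / fs
            reasons[trial] = (
                f"sd {sds[trial, ch, win]:.1f} µV on {labels[ch]} at {start_ms:.0f} ms"
            )
            rejected[trial] = True
    return replace(epochs, rejected=rejected, reasons=tuple(reasons))


def mark_not_looking(epochs: EpochSet, rate: float, seed: int) -> EpochSet:
    """Flag a random fraction of visual trials as not-looking (video edit)."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    drop = rng.random(epochs.n_trials) < rate
    rejected = epochs.rejected | drop
    reasons = tuple(
        r if not (d and r is None) else ("not looking" if d else r)
        for r, d in zip(epochs.reasons, drop)
    )
    return replace(epochs, rejected=rejected, reasons=reasons)


@dataclass(frozen=True)
class InclusionReport:
    subject_id: str
    modality: str
    retained: dict[str, int]  # condition -> retained trial count
    included: bool


def apply_inclusion(
    counts: dict[str, dict[str, dict[str, int]]],
    min_trials: int = 10,
) -> list[InclusionReport]:
    """Per-subject inclusion: at least ``min_trials`` artifact-free trials
    in each condition, assessed separately per modality.

    ``counts`` maps subject_id -> modality -> condition -> retained count.
    """
    reports = []
    for subject_id, per_modality in counts.items():
        for modality, by_cond in per_modality.items():
            included = all(
                by_cond.get(c, 0) >= min_trials for c in ("own", "stranger")
            )
            reports.append(
                InclusionReport(
                    subject_id=subject_id,
                    modality=modality,
                    retained=dict(by_cond),
                    included=included,
                )
            )
    return reports


def preprocess_recording(
    recording: ContinuousRecording,
    filter_spec: FilterSpec | None = None,
    window_ms: float = 200.0,
    sd_eog_uv: float = 80.0,
    sd_scalp_uv: float = 50.0,
    min_trials: int = 10,
) -> dict[str, EpochSet]:
    """Full continuous-to-epochs chain for one subject.

    Returns baseline-corrected, artifact-screened epoch sets keyed by
    modality (``auditory``, ``visual``).
    """
    filtered = fir_bandpass(recording, filter_spec or FilterSpec())
    reref = rereference_linked_mastoids(filtered)
    out = {}
    for modality in ("auditory", "visual"):
        ep = extract_epochs(reref, modality)
        ep = baseline_correct(ep)
        ep = reject_artifacts(ep, window_ms=window_ms, sd_eog_uv=sd_eog_uv, sd_scalp_uv=sd_scalp_uv)
        out[modality] = ep
    return out


def rejection_log(subject_id: str, epochs: EpochSet) -> pd.DataFrame:
    rows = [
        {"subject": subject_id, "modality": epochs.modality, "trial": i, "reason": r}
        for i, r in enumerate(epochs.reasons)
        if epochs.rejected[i]
    ]
    return pd.DataFrame(rows, columns=["subject", "modality", "trial", "reason"])
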