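"""Synthetic two-group infant EEG cohorts with injected ERP components.

Raw infant recordings for this design are not publicly available, so the
pipeline is exercised on simulated data: per-channel 1/f background noise,
four stimulus-locked ERP components with configurable condition/group
effect structure, and blink/movement artifacts that the downstream
gliding-window rejection is meant to catch.

Component waveforms are Hann bumps.  A bump of amplitude ``A`` whose
support exactly spans a measurement window and peaks at its centre has a
window-mean of ``A/2`` (:data:`HANN_WINDOW_MEAN_FACTOR`), which gives the
pipeline an analytic end-to-end identity to verify against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Mapping

import numpy as np

from .study_design import (
    ISI_RANGE_MS,
    ITI_RANGE_MS,
    NAME_WINDOW_MS,
    OBJECT_DURATION_MS,
    Montage,
    TrialSchedule,
    build_montage,
    generate_schedule,
)

Marker = Literal["name_own", "name_stranger", "object_after_own", "object_after_stranger"]

#: mean of a full Hann bump over its own support
HANN_WINDOW_MEAN_FACTOR = 0.5

#: post-stimulus span covered by injected component waveforms (ms)
POST_STIMULUS_SPAN_MS = 1500.0

AUDITORY_MARKERS = ("name_own", "name_stranger")
VISUAL_MARKERS = ("object_after_own", "object_after_stranger")


@dataclass(frozen=True)
class ContinuousRecording:
    """Multichannel EEG in microvolts with a stimulus event list."""

    montage: Montage
    data: np.ndarray  # channels x samples, µV
    events: tuple[tuple[int, str], ...]  # (sample_index, marker)

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] != len(self.montage.labels):
            raise ValueError("data must be channels x samples matching the montage")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        idx = [s for s, _ in self.events]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("event sample indices must be strictly increasing")
        if idx and (idx[0] < 0 or idx[-1] >= self.data.shape[1]):
            raise ValueError("event sample index out of bounds")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def events_of(self, markers: tuple[str, ...]) -> list[tuple[int, str]]:
        return [(s, m) for s, m in self.events if m in markers]


@dataclass(frozen=True)
class ComponentSpec:
    """One injectable ERP component.

    ``amplitude_uv`` and ``latency_shift_ms`` map ``(group, condition)``
    keys — e.g. ``("ten", "own")`` — to the scalar used for that cell.
    The Hann bump support has the width of ``window`` and is centred on
    ``peak_latency_ms + latency_shift_ms[cell]``; amplitude sign is
    carried by ``amplitude_uv``.
    """

    name: str
    marker: Literal["auditory", "visual"]
    window: tuple[float, float]  # ms post-stimulus
    peak_latency_ms: float
    topography: Mapping[str, float]
    amplitude_uv: Mapping[tuple[str, str], float]
    latency_shift_ms: Mapping[tuple[str, str], float] = field(default_factory=dict)
    shape: str = "hann_bump"

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not lo < hi:
            raise ValueError("component window must have t_start < t_end")
        if not lo <= self.peak_latency_ms <= hi:
            raise ValueError("peak latency must lie inside the window")
        if not all(np.isfinite(list(self.topography.values()))):
            raise ValueError("topography weights must be finite")

    def cell_amplitude(self, group: str, condition: str) -> float:
        return float(self.amplitude_uv.get((group, condition), 0.0))

    def cell_shift(self, group: str, condition: str) -> float:
        return float(self.latency_shift_ms.get((group, condition), 0.0))


@dataclass(frozen=True)
class NoiseSpec:
    """Background-noise and artifact generation parameters."""

    spectral_exponent: float = 1.0  # power ~ 1/f^beta
    rms_uv: float = 15.0
    blink_rate_per_min: float = 0.0
    blink_amp_uv: float = 250.0
    blink_duration_ms: float = 400.0
    movement_rate_per_min: float = 0.0
    movement_amp_uv: float = 150.0
    movement_duration_ms: float = 600.0

    def __post_init__(self) -> None:
        if self.rms_uv < 0:
            raise ValueError("rms must be >= 0")
        if self.blink_rate_per_min < 0 or self.movement_rate_per_min < 0:
            raise ValueError("artifact rates must be >= 0")


#: attenuated frontal spread of ocular potentials, relative to VEOG
BLINK_SPREAD = {"VEOG": 1.0, "Fp1": 0.2, "Fp2": 0.2, "F3": 0.08, "Fz": 0.08, "F4": 0.08, "F7": 0.06, "F8": 0.06}

FRONTOCENTRAL = ("F3", "FC3", "C3", "F4", "FC4", "C4")
PARIETAL = ("P3", "Pz", "P4")


def default_components() -> tuple[ComponentSpec, ...]:
    """Effect template used by the default simulation.

    - early fronto-central positivity (100-380 ms): own > stranger only in
      the one-control-name group (3 µV configured difference);
    - parietal negativity (200-600 ms peak): own more negative only in the
      ten-control-names group;
    - fronto-central negative peak (450-700 ms): 40 ms later after the own
      name in both groups, no amplitude difference;
    - late fronto-central negativity (890-1000 ms): more negative after
      the own name in both groups, left-lateralized weights.
    """
    fc = {ch: 1.0 for ch in FRONTOCENTRAL}
    fc_left = {"F3": 1.0, "FC3": 1.0, "C3": 1.0, "F4": 0.6, "FC4": 0.6, "C4": 0.6}
    par = {ch: 1.0 for ch in PARIETAL}
    return (
        ComponentSpec(
            name="anterior_shift",
            marker="auditory",
            window=(100.0, 380.0),
            peak_latency_ms=240.0,
            topography=fc,
            amplitude_uv={
                ("ten", "own"): 4.0,
                ("ten", "stranger"): 4.0,
                ("one", "own"): 7.0,
                ("one", "stranger"): 4.0,
            },
        ),
        ComponentSpec(
            name="n200_600",
            marker="auditory",
            window=(200.0, 600.0),
            peak_latency_ms=400.0,
            topography=par,
            amplitude_uv={
                ("ten", "own"): -9.0,
                ("ten", "stranger"): -5.0,
                ("one", "own"): -5.0,
                ("one", "stranger"): -5.0,
            },
        ),
        ComponentSpec(
            name="nc",
            marker="visual",
            window=(450.0, 700.0),
            peak_latency_ms=575.0,
            topography=fc,
            amplitude_uv={(g, c): -10.0 for g in ("ten", "one") for c in ("own", "stranger")},
            latency_shift_ms={
                ("ten", "own"): 20.0,
                ("ten", "stranger"): -20.0,
                ("one", "own"): 20.0,
                ("one", "stranger"): -20.0,
            },
        ),
        ComponentSpec(
            name="extended_nc",
            marker="visual",
            window=(890.0, 1000.0),
            peak_latency_ms=945.0,
            topography=fc_left,
            amplitude_uv={
                ("ten", "own"): -8.0,
                ("ten", "stranger"): -4.0,
                ("one", "own"): -8.0,
                ("one", "stranger"): -4.0,
            },
        ),
    )


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects_per_group: int = 15
    components: tuple[ComponentSpec, ...] = field(default_factory=default_components)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    subject_amp_sd: float = 0.3  # per-subject multiplier ~ N(1, sd), truncated at 0
    lead_in_s: float = 2.0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ValueError("need at least one subject per group")
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError("component names must be unique")


def _one_over_f_noise(n_samples: int, beta: float, rms: float, rng: np.random.Generator) -> np.ndarray:
    """Single-channel 1/f^beta noise scaled to the requested RMS."""
    if rms == 0:
        return np.zeros(n_samples)
    white = rng.standard_normal(n_samples)
    if beta == 0:
        x = white
    else:
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n_samples)
        scale = np.ones_like(freqs)
        nonzero = freqs > 0
        scale[nonzero] = freqs[nonzero] ** (-beta / 2.0)
        scale[0] = 0.0  # no DC
        x = np.fft.irfft(spec * scale, n=n_samples)
    x -= x.mean()
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def simulate_background(
    n_samples: int,
    montage: Montage,
    noise: NoiseSpec,
    seed: int | np.random.Generator,
) -> ContinuousRecording:
    """Event-free background recording: independent 1/f noise per channel.

    The reference channel (Cz) is identically zero, as in a recording
    referenced to it.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = np.zeros((len(montage.labels), n_samples))
    for i, (label, role) in enumerate(montage.channels):
        if role == "reference":
            continue
        data[i] = _one_over_f_noise(n_samples, noise.spectral_exponent, noise.rms_uv, rng)
    return ContinuousRecording(montage=montage, data=data, events=())


def component_waveform(
    spec: ComponentSpec,
    group: str,
    condition: str,
    sampling_rate: float,
    span_ms: float = POST_STIMULUS_SPAN_MS,
) -> np.ndarray:
    """Sampled post-stimulus waveform of one component for one design cell.

    Returns the waveform on the grid t = 0, 1/fs, ... covering
    ``[0, span_ms)`` relative to stimulus onset: a Hann bump whose support
    has the window's width, centred on the shifted peak latency.
    """
    amp = spec.cell_amplitude(group, condition)
    shift = spec.cell_shift(group, condition)
    peak = spec.peak_latency_ms + shift
    lo, hi = spec.window
    if not lo <= peak <= hi:
        raise ValueError(f"shifted peak {peak} ms outside window {spec.window}")
    width = hi - lo
    n = int(round(span_ms * sampling_rate / 1000.0))
    t = np.arange(n) * 1000.0 / sampling_rate
    x = (t - peak) / width
    w = np.where(np.abs(x) <= 0.5, 0.5 * (1.0 + np.cos(2.0 * np.pi * x)), 0.0)
    return amp * w


def _trial_timing(schedule: TrialSchedule, fs: float, lead_in_s: float) -> list[tuple[int, str, int, str]]:
    """Event layout: per trial (name_sample, name_marker, object_sample, object_marker)."""
    out = []
    t_ms = lead_in_s * 1000.0
    for trial in schedule.trials:
        name_sample = int(round(t_ms * fs / 1000.0))
        obj_ms = t_ms + NAME_WINDOW_MS + trial.isi_ms
        obj_sample = int(round(obj_ms * fs / 1000.0))
        suffix = "own" if trial.condition == "own" else "stranger"
        out.append((name_sample, f"name_{suffix}", obj_sample, f"object_after_{suffix}"))
        t_ms = obj_ms + OBJECT_DURATION_MS + trial.iti_ms
    return out


def simulate_subject(
    config: SimulationConfig,
    schedule: TrialSchedule,
    group: str,
    seed: int | np.random.Generator,
    montage: Montage | None = None,
) -> ContinuousRecording:
    """One subject's continuous recording for a trial schedule.

    Each name onset receives the auditory components, each object onset
    the visual components, with amplitudes scaled by per-subject
    multipliers (one per component, N(1, sd) truncated at 0) and spread
    over channels by the component topography.
    """
    montage = montage or build_montage()
    fs = montage.sampling_rate
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    timing = _trial_timing(schedule, fs, config.lead_in_s)
    last_obj = timing[-1][2]
    span = int(round(POST_STIMULUS_SPAN_MS * fs / 1000.0))
    n_samples = last_obj + span + int(round(config.lead_in_s * fs))

    background = simulate_background(n_samples, montage, config.noise, rng)
    data = background.data.copy()

    multipliers = {
        c.name: max(0.0, 1.0 + config.subject_amp_sd * rng.standard_normal())
        for c in config.components
    }

    events: list[tuple[int, str]] = []
    for trial, (name_s, name_m, obj_s, obj_m) in zip(schedule.trials, timing):
        events.append((name_s, name_m))
        events.append((obj_s, obj_m))
        for comp in config.components:
            onset = name_s if comp.marker == "auditory" else obj_s
            wave = component_waveform(comp, group, trial.condition, fs)
            wave = wave * multipliers[comp.name]
            for label, weight in comp.topography.items():
                if weight == 0.0:
                    continue
                i = montage.index(label)
                data[i, onset : onset + wave.size] += weight * wave
    events.sort(key=lambda e: e[0])
    return ContinuousRecording(montage=montage, data=data, events=tuple(events))


def _hann_sine_burst(n: int, amp: float) -> np.ndarray:
    """Biphasic transient: one sine cycle under a Hann envelope."""
    t = np.arange(n) / max(n - 1, 1)
    return amp * np.sin(2.0 * np.pi * t) * 0.5 * (1.0 - np.cos(2.0 * np.pi * t))


def inject_artifacts(
    recording: ContinuousRecording,
    noise: NoiseSpec,
    seed: int | np.random.Generator,
) -> ContinuousRecording:
    """Add blink and movement artifacts at Poisson times; events preserved.

    Blinks are large biphasic transients on VEOG with attenuated frontal
    spread; movements are broadband noise bursts on a random subset of
    scalp channels.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = recording.data.copy()
    montage = recording.montage
    fs = montage.sampling_rate
    minutes = recording.n_samples / fs / 60.0

    def poisson_times(rate_per_min: float) -> np.ndarray:
        n = rng.poisson(rate_per_min * minutes)
        return np.sort(rng.integers(0, recording.n_samples, size=n))

    blink_n = int(round(noise.blink_duration_ms * fs / 1000.0))
    for start in poisson_times(noise.blink_rate_per_min):
        stop = min(start + blink_n, recording.n_samples)
        burst = _hann_sine_burst(blink_n, noise.blink_amp_uv)[: stop - start]
        for label, weight in BLINK_SPREAD.items():
            if label in montage.labels:
                data[montage.index(label), start:stop] += weight * burst

    move_n = int(round(noise.movement_duration_ms * fs / 1000.0))
    scalp_idx = [montage.index(lab) for lab in montage.labels_for("scalp")]
    for start in poisson_times(noise.movement_rate_per_min):
        stop = min(start + move_n, recording.n_samples)
        picked = rng.choice(scalp_idx, size=max(1, len(scalp_idx) // 3), replace=False)
        for i in picked:
            data[i, start:stop] += noise.movement_amp_uv * rng.standard_normal(stop - start)

    return replace(recording, data=data)


def simulate_cohort(
    config: SimulationConfig,
) -> Iterator[tuple[str, str, TrialSchedule, ContinuousRecording]]:
    """Yield (subject_id, group, schedule, recording) for the whole cohort.

    All randomness (schedules, noise, artifacts, subject multipliers)
    derives from ``config.seed`` via spawned seed sequences.
    """
    root = np.random.SeedSequence(config.seed)
    groups = ["ten"] * config.n_subjects_per_group + ["one"] * config.n_subjects_per_group
    children = root.spawn(len(groups))
    for i, (group, child) in enumerate(zip(groups, children)):
        rng = np.random.default_rng(child)
        schedule = generate_schedule(int(rng.integers(0, 2**31)))
        rec = simulate_subject(config, schedule, group, rng)
        rec = inject_artifacts(rec, config.noise, rng)
        yield f"sub-{i + 1:02d}", group, schedule, rec
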