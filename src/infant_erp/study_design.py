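"""Fixed experimental design: montage, ROIs, analysis windows, trial schedule.

The experiment is a 2 (Group: ``ten`` vs ``one`` control name, between
subjects) x 2 (Name: ``own`` vs ``stranger``, within subjects) design with
200 trials per subject.  Each trial pairs an auditory name with a visual
object; ERP analyses are carried out on fixed regions of interest and time
windows defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal

import numpy as np
import pandas as pd

Role = Literal["scalp", "eog", "mastoid", "reference"]
Condition = Literal["own", "stranger"]

SAMPLING_RATE_HZ = 250.0
#: online acquisition anti-alias low-pass, expressed as a fraction of fs
ONLINE_LOWPASS_FRACTION = 0.27

NAME_WINDOW_MS = 1500.0
OBJECT_DURATION_MS = 1000.0
ISI_RANGE_MS = (750.0, 850.0)
ITI_RANGE_MS = (800.0, 1200.0)
NAME_DURATION_RANGE_MS = (396.0, 989.0)

N_TRIALS = 200
N_OBJECTS = 10
BLOCK_SIZE = 20
MAX_RUN_LENGTH = 2

#: 23 scalp sites of the 10-20 system (extended); Cz is the recording
#: reference and therefore not a scalp data channel during acquisition.
SCALP_CHANNELS = (
    "Fp1", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "FC3", "FC4",
    "T3", "C3", "C4", "T4",
    "CP3", "CPz", "CP4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)


def online_lowpass_hz(sampling_rate: float = SAMPLING_RATE_HZ) -> float:
    """Cutoff of the online acquisition low-pass (fraction of fs)."""
    return ONLINE_LOWPASS_FRACTION * sampling_rate


@dataclass(frozen=True)
class Montage:
    """Channel labels with roles, plus the sampling rate."""

    channels: tuple[tuple[str, Role], ...]
    sampling_rate: float = SAMPLING_RATE_HZ

    def __post_init__(self) -> None:
        labels = [c[0] for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        roles = [c[1] for c in self.channels]
        if roles.count("scalp") != 23:
            raise ValueError("montage must have exactly 23 scalp channels")
        if roles.count("reference") != 1:
            raise ValueError("montage must have exactly one reference")
        if roles.count("mastoid") != 2:
            raise ValueError("montage must have exactly two mastoids")
        if roles.count("eog") < 2:
            raise ValueError("montage must have at least two EOG channels")

    @property
    def labels(self) -> list[str]:
        return [c[0] for c in self.channels]

    def labels_for(self, role: Role) -> list[str]:
        return [c[0] for c in self.channels if c[1] == role]

    def role_of(self, label: str) -> Role:
        for lab, role in self.channels:
            if lab == label:
                return role
        raise KeyError(label)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(label) from None


def build_montage(sampling_rate: float = SAMPLING_RATE_HZ) -> Montage:
    """Default recording montage: 23 scalp channels referenced to Cz,
    two mastoids and bipolar horizontal/vertical EOG."""
    channels: list[tuple[str, Role]] = [(lab, "scalp") for lab in SCALP_CHANNELS]
    channels.append(("Cz", "reference"))
    channels.extend([("M1", "mastoid"), ("M2", "mastoid")])
    channels.extend([("HEOG", "eog"), ("VEOG", "eog")])
    return Montage(channels=tuple(channels), sampling_rate=sampling_rate)


@dataclass(frozen=True)
class RoiSpec:
    name: str
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.channel_labels:
            raise ValueError("ROI must contain at least one channel")


ROI_LEFT_FRONTOCENTRAL = RoiSpec("left_frontocentral", ("F3", "FC3", "C3"))
ROI_RIGHT_FRONTOCENTRAL = RoiSpec("right_frontocentral", ("F4", "FC4", "C4"))
ROI_PARIETAL = RoiSpec("parietal", ("P3", "Pz", "P4"))


@dataclass(frozen=True)
class AnalysisWindow:
    """A named measurement window on one stimulus modality."""

    name: str
    t_start: float  # ms post-stimulus
    t_end: float    # ms post-stimulus
    measure: Literal["mean_amplitude", "negative_peak"]
    modality: Literal["auditory", "visual"]

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("t_start must be < t_end")


WINDOW_ANTERIOR_SHIFT = AnalysisWindow("anterior_shift", 100.0, 380.0, "mean_amplitude", "auditory")
WINDOW_N200_600 = AnalysisWindow("n200_600", 200.0, 600.0, "negative_peak", "auditory")
WINDOW_NC = AnalysisWindow("nc", 450.0, 700.0, "negative_peak", "visual")
WINDOW_EXTENDED_NC = AnalysisWindow("extended_nc", 890.0, 1000.0, "mean_amplitude", "visual")


def default_analysis_plan() -> list[tuple[RoiSpec, AnalysisWindow]]:
    """The fixed (ROI, window) pairs entering the statistical analyses."""
    return [
        (ROI_LEFT_FRONTOCENTRAL, WINDOW_ANTERIOR_SHIFT),
        (ROI_RIGHT_FRONTOCENTRAL, WINDOW_ANTERIOR_SHIFT),
        (ROI_PARIETAL, WINDOW_N200_600),
        (ROI_LEFT_FRONTOCENTRAL, WINDOW_NC),
        (ROI_RIGHT_FRONTOCENTRAL, WINDOW_NC),
        (ROI_LEFT_FRONTOCENTRAL, WINDOW_EXTENDED_NC),
        (ROI_RIGHT_FRONTOCENTRAL, WINDOW_EXTENDED_NC),
    ]


@dataclass(frozen=True)
class Trial:
    index: int
    condition: Condition
    object_id: int
    name_duration_ms: float
    isi_ms: float
    iti_ms: float


@dataclass(frozen=True)
class TrialSchedule:
    """200 ordered trials obeying the scheduling constraints.

    Invariants: 100 trials per condition; no three identical conditions in
    a row; within every consecutive block of 20 trials each object appears
    exactly twice, once per condition.
    """

    trials: tuple[Trial, ...]

    def __post_init__(self) -> None:
        validate_schedule(self)

    @property
    def conditions(self) -> list[Condition]:
        return [t.condition for t in self.trials]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [t.index for t in self.trials],
                "condition": [t.condition for t in self.trials],
                "object_id": [t.object_id for t in self.trials],
                "name_duration_ms": [t.name_duration_ms for t in self.trials],
                "isi_ms": [t.isi_ms for t in self.trials],
                "iti_ms": [t.iti_ms for t in self.trials],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialSchedule":
        trials = tuple(
            Trial(
                index=int(r["index"]),
                condition=str(r["condition"]),
                object_id=int(r["object_id"]),
                name_duration_ms=float(r["name_duration_ms"]),
                isi_ms=float(r["isi_ms"]),
                iti_ms=float(r["iti_ms"]),
            )
            for _, r in df.iterrows()
        )
        return cls(trials=trials)


def max_run_length(conditions: list[str]) -> int:
    best = run = 1
    for prev, cur in zip(conditions, conditions[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best if conditions else 0


def validate_schedule(schedule: TrialSchedule) -> None:
    trials = schedule.trials
    if len(trials) != N_TRIALS:
        raise ValueError(f"schedule must have {N_TRIALS} trials")
    conds = [t.condition for t in trials]
    if conds.count("own") != N_TRIALS // 2:
        raise ValueError("schedule must have 100 trials per condition")
    if max_run_length(conds) > MAX_RUN_LENGTH:
        raise ValueError("more than two identical conditions in a row")
    for b in range(N_TRIALS // BLOCK_SIZE):
        block = trials[b * BLOCK_SIZE : (b + 1) * BLOCK_SIZE]
        seen = {(t.object_id, t.condition) for t in block}
        expected = {(o, c) for o in range(1, N_OBJECTS + 1) for c in ("own", "stranger")}
        if seen != expected:
            raise ValueError(f"block {b} does not present every object once per condition")
    for t in trials:
        if not ISI_RANGE_MS[0] <= t.isi_ms <= ISI_RANGE_MS[1]:
            raise ValueError("isi out of range")
        if not ITI_RANGE_MS[0] <= t.iti_ms <= ITI_RANGE_MS[1]:
            raise ValueError("iti out of range")
        if not NAME_DURATION_RANGE_MS[0] <= t.name_duration_ms <= NAME_DURATION_RANGE_MS[1]:
            raise ValueError("name duration out of range")


class ScheduleGenerationError(RuntimeError):
    """Raised when the constrained sampler exhausts its retry budget."""


def generate_schedule(
    seed: int,
    name_duration_ms: float | None = None,
    max_retries: int = 10_000,
) -> TrialSchedule:
    """Sample a 200-trial schedule satisfying all design constraints.

    Each block of 20 trials (10 objects x 2 conditions) is shuffled by
    rejection sampling until the run-length constraint holds, including
    across the boundary with the previous block.  Deterministic per seed.

    Parameters
    ----------
    seed : int
        Seed for the constrained sampler.
    name_duration_ms : float, optional
        Fixed name duration for every trial; by default durations are
        drawn uniformly from the documented range.
    max_retries : int
        Per-block retry budget; exceeding it raises
        :class:`ScheduleGenerationError`.
    """
    rng = np.random.default_rng(seed)
    pairs = [(o, c) for o in range(1, N_OBJECTS + 1) for c in ("own", "stranger")]
    trials: list[Trial] = []
    tail: list[str] = []  # last two conditions so far
    for _ in range(N_TRIALS // BLOCK_SIZE):
        for attempt in range(max_retries):
            order = rng.permutation(len(pairs))
            conds = tail + [pairs[i][1] for i in order]
            if max_run_length(conds) <= MAX_RUN_LENGTH:
                break
        else:
            raise ScheduleGenerationError(
                f"no valid block ordering found in {max_retries} retries"
            )
        for i in order:
            obj, cond = pairs[i]
            dur = (
                float(name_duration_ms)
                if name_duration_ms is not None
                else float(rng.uniform(*NAME_DURATION_RANGE_MS))
            )
            trials.append(
                Trial(
                    index=len(trials),
                    condition=cond,
                    object_id=obj,
                    name_duration_ms=dur,
                    isi_ms=float(rng.uniform(*ISI_RANGE_MS)),
                    iti_ms=float(rng.uniform(*ITI_RANGE_MS)),
                )
            )
        tail = [t.condition for t in trials[-MAX_RUN_LENGTH:]]
    return TrialSchedule(trials=tuple(trials))


def visual_angle(extent_cm: float, distance_cm: float) -> float:
    """Visual angle in degrees subtended by ``extent_cm`` at ``distance_cm``.

    Uses the standard small-stimulus geometry 2*arctan(extent / (2*distance)).
    """
    if distance_cm <= 0:
        raise ValueError("distance must be positive")
    if extent_cm < 0:
        raise ValueError("extent must be non-negative")
    return math.degrees(2.0 * math.atan2(extent_cm, 2.0 * distance_cm))


@dataclass(frozen=True)
class NameLengthTable:
    """Per-infant name durations: 15 rows per group; for the ten-name
    group the control entry is that infant's average over 10 names."""

    rows: tuple[tuple[str, float, float], ...]  # (group, own_ms, control_ms)

    def __post_init__(self) -> None:
        if len(self.rows) != 30:
            raise ValueError("name length table must have 30 rows")
        for group, own, ctl in self.rows:
            if group not in ("ten", "one"):
                raise ValueError(f"unknown group {group!r}")
            if own <= 0 or ctl <= 0:
                raise ValueError("name lengths must be positive")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NameLengthTable":
        rows = tuple(
            (str(r["group"]), float(r["own_ms"]), float(r["control_ms"]))
            for _, r in df.iterrows()
        )
        return cls(rows=rows)


def load_name_lengths() -> NameLengthTable:
    """Packaged per-infant name-duration table."""
    with resources.files("infant_erp.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    return NameLengthTable.from_frame(df)


def summarize_name_lengths(table: NameLengthTable) -> tuple[int, int, int]:
    """Equal-weight means (own, control, overall), rounded to integer ms."""
    own = [r[1] for r in table.rows]
    ctl = [r[2] for r in table.rows]
    own_mean = float(np.mean(own))
    ctl_mean = float(np.mean(ctl))
    overall = float(np.mean(own + ctl))
    return round(own_mean), round(ctl_mean), round(overall)
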