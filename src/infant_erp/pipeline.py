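"""Reproducible simulate -> preprocess -> measure -> stats runs.

Each stage reads only the artifact tree written by the previous stage,
so a run directory is self-describing and resumable:

    run/
      config.json             frozen RunConfig + provenance
      raw/<subject>.npy       continuous data (channels x samples, µV)
      raw/<subject>.events.json
      raw/<subject>.schedule.csv
      raw/manifest.csv        subject_id, group
      epochs/<subject>.<modality>.npz (+ .json metadata)
      epochs/rejection_log.csv
      epochs/inclusion.csv
      measures/measurements.csv
      measures/grand_average.<modality>.<condition>.csv
      stats/anova_<window>.csv, stats/nonparametric.txt
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .erp_measurement import (
    SubjectErps,
    average_epochs,
    build_measurement_table,
    grand_average,
    grand_average_frame,
)
from .preprocessing import (
    EpochSet,
    FilterSpec,
    apply_inclusion,
    preprocess_recording,
    rejection_log,
)
from .stats import (
    format_anova,
    mixed_anova_2x2,
    mixed_anova_2x2x2,
    posthoc_tests,
    wilcoxon_effect,
)
from .study_design import (
    ROI_LEFT_FRONTOCENTRAL,
    ROI_PARIETAL,
    ROI_RIGHT_FRONTOCENTRAL,
    TrialSchedule,
    build_montage,
)
from .synthetic_eeg import (
    ComponentSpec,
    ContinuousRecording,
    NoiseSpec,
    SimulationConfig,
    default_components,
    simulate_cohort,
)


@dataclass(frozen=True)
class RejectionConfig:
    window_ms: float = 200.0
    sd_eog_uv: float = 80.0
    sd_scalp_uv: float = 50.0


@dataclass(frozen=True)
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    rejection: RejectionConfig = field(default_factory=RejectionConfig)
    min_trials: int = 10

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                d = {}
                for f in dataclasses.fields(obj):
                    d[f.name] = enc(getattr(obj, f.name))
                return d
            if isinstance(obj, dict):
                return {
                    (k if isinstance(k, str) else "|".join(k)): enc(v) for k, v in obj.items()
                }
            if isinstance(obj, tuple):
                return [enc(v) for v in obj]
            return obj

        return enc(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sim = d.get("simulation", {})
        comps = tuple(
            ComponentSpec(
                name=c["name"],
                marker=c["marker"],
                window=tuple(c["window"]),
                peak_latency_ms=c["peak_latency_ms"],
                topography=dict(c["topography"]),
                amplitude_uv={tuple(k.split("|")): v for k, v in c["amplitude_uv"].items()},
                latency_shift_ms={tuple(k.split("|")): v for k, v in c.get("latency_shift_ms", {}).items()},
            )
            for c in sim.get("components", [])
        ) or default_components()
        simulation = SimulationConfig(
            n_subjects_per_group=sim.get("n_subjects_per_group", 15),
            components=comps,
            noise=NoiseSpec(**sim.get("noise", {})),
            seed=sim.get("seed", 0),
            subject_amp_sd=sim.get("subject_amp_sd", 0.3),
            lead_in_s=sim.get("lead_in_s", 2.0),
        )
        return cls(
            simulation=simulation,
            filter=FilterSpec(**d.get("filter", {})),
            rejection=RejectionConfig(**d.get("rejection", {})),
            min_trials=d.get("min_trials", 10),
        )


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(config: RunConfig, run_dir: Path) -> None:
    doc = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "python": platform.python_version(),
    }
    (run_dir / "config.json").write_text(json.dumps(doc, indent=2))


def load_config(run_dir: Path) -> RunConfig:
    doc = json.loads((run_dir / "config.json").read_text())
    return RunConfig.from_dict(doc["config"])


def stage_simulate(config: RunConfig, run_dir: Path) -> None:
    raw = run_dir / "raw"
    raw.mkdir(parents=True, exist_ok=True)
    write_provenance(config, run_dir)
    manifest = []
    for subject_id, group, schedule, rec in simulate_cohort(config.simulation):
        np.save(raw / f"{subject_id}.npy", rec.data.astype(np.float32))
        (raw / f"{subject_id}.events.json").write_text(
            json.dumps([[int(s), m] for s, m in rec.events])
        )
        schedule.to_frame().to_csv(raw / f"{subject_id}.schedule.csv", index=False)
        manifest.append({"subject_id": subject_id, "group": group})
    pd.DataFrame(manifest).to_csv(raw / "manifest.csv", index=False)


def _load_recording(raw: Path, subject_id: str) -> ContinuousRecording:
    data = np.load(raw / f"{subject_id}.npy").astype(np.float64)
    events = tuple(
        (int(s), m) for s, m in json.loads((raw / f"{subject_id}.events.json").read_text())
    )
    return ContinuousRecording(montage=build_montage(), data=data, events=events)


def _save_epochs(path_stem: Path, epochs: EpochSet) -> None:
    np.savez(f"{path_stem}.npz", data=epochs.data.astype(np.float32), rejected=epochs.rejected)
    meta = {
        "modality": epochs.modality,
        "conditions": list(epochs.conditions),
        "trial_indices": list(epochs.trial_indices),
        "t_min_ms": epochs.t_min_ms,
        "reasons": list(epochs.reasons),
        "n_edge_dropped": epochs.n_edge_dropped,
    }
    Path(f"{path_stem}.json").write_text(json.dumps(meta))


def _load_epochs(path_stem: Path) -> EpochSet:
    arrays = np.load(f"{path_stem}.npz")
    meta = json.loads(Path(f"{path_stem}.json").read_text())
    return EpochSet(
        data=arrays["data"].astype(np.float64),
        montage=build_montage(),
        modality=meta["modality"],
        conditions=tuple(meta["conditions"]),
        trial_indices=tuple(meta["trial_indices"]),
        t_min_ms=meta["t_min_ms"],
        rejected=arrays["rejected"],
        reasons=tuple(meta["reasons"]),
        n_edge_dropped=meta["n_edge_dropped"],
    )


def stage_preprocess(config: RunConfig, run_dir: Path) -> None:
    raw = run_dir / "raw"
    out = run_dir / "epochs"
    out.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(raw / "manifest.csv")
    logs, counts = [], {}
    for subject_id in manifest["subject_id"]:
        rec = _load_recording(raw, subject_id)
        epoch_sets = preprocess_recording(
            rec,
            filter_spec=config.filter,
            window_ms=config.rejection.window_ms,
            sd_eog_uv=config.rejection.sd_eog_uv,
            sd_scalp_uv=config.rejection.sd_scalp_uv,
        )
        counts[subject_id] = {}
        for modality, ep in epoch_sets.items():
            _save_epochs(out / f"{subject_id}.{modality}", ep)
            logs.append(rejection_log(subject_id, ep))
            counts[subject_id][modality] = {
                c: ep.retained_count(c) for c in ("own", "stranger")
            }
    pd.concat(logs, ignore_index=True).to_csv(out / "rejection_log.csv", index=False)
    reports = apply_inclusion(counts, min_trials=config.min_trials)
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "modality": r.modality,
                "retained_own": r.retained.get("own", 0),
                "retained_stranger": r.retained.get("stranger", 0),
                "included": r.included,
            }
            for r in reports
        ]
    ).to_csv(out / "inclusion.csv", index=False)


def stage_measure(config: RunConfig, run_dir: Path) -> None:
    epochs_dir = run_dir / "epochs"
    out = run_dir / "measures"
    out.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(run_dir / "raw" / "manifest.csv")
    inclusion = pd.read_csv(epochs_dir / "inclusion.csv")
    included = {
        (r["subject_id"], r["modality"]): bool(r["included"]) for _, r in inclusion.iterrows()
    }
    subjects = []
    per_cell: dict[tuple[str, str], list] = {}
    for _, row in manifest.iterrows():
        subject_id, group = row["subject_id"], row["group"]
        averages = {}
        for modality in ("auditory", "visual"):
            if not included.get((subject_id, modality), False):
                continue
            ep = _load_epochs(epochs_dir / f"{subject_id}.{modality}")
            for condition in ("own", "stranger"):
                erp = average_epochs(ep, condition, subject_id)
                averages[(modality, condition)] = erp
                per_cell.setdefault((modality, condition), []).append(erp)
        if averages:
            subjects.append(SubjectErps(subject_id=subject_id, group=group, averages=averages))
    table = build_measurement_table(subjects)
    table.to_csv(out / "measurements.csv", index=False)
    for (modality, condition), erps in sorted(per_cell.items()):
        ga = grand_average(erps)
        grand_average_frame(ga).to_csv(
            out / f"grand_average.{modality}.{condition}.csv", index=False
        )


def _hemisphere(roi: str) -> str | None:
    if roi.startswith("left"):
        return "left"
    if roi.startswith("right"):
        return "right"
    return None


def stage_stats(config: RunConfig, run_dir: Path) -> None:
    out = run_dir / "stats"
    out.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(run_dir / "measures" / "measurements.csv")
    table["hemisphere"] = table["roi"].map(_hemisphere)
    text = []

    def anova_for(window: str, measure: str, bilateral: bool) -> pd.DataFrame:
        sub = table[(table["window"] == window) & (table["measure"] == measure)].copy()
        if sub.empty:
            return pd.DataFrame()
        if bilateral:
            res = mixed_anova_2x2x2(sub, within=("condition", "hemisphere"))
        else:
            res = mixed_anova_2x2(sub, within="condition")
        res.insert(0, "measure", measure)
        res.insert(0, "window", window)
        res.to_csv(out / f"anova_{window}_{measure}.csv", index=False)
        text.append(f"== {window} / {measure} ==\n{format_anova(res)}\n")
        return res

    anova_for("anterior_shift", "mean_amplitude_uv", bilateral=True)
    anova_for("n200_600", "peak_amplitude_uv", bilateral=False)
    anova_for("n200_600", "peak_latency_ms", bilateral=False)
    anova_for("nc", "peak_amplitude_uv", bilateral=True)
    anova_for("nc", "peak_latency_ms", bilateral=True)
    anova_for("extended_nc", "mean_amplitude_uv", bilateral=True)

    # per-subject own-minus-stranger differences and sign tests
    nonparam = []
    for window, measure, direction in (
        ("anterior_shift", "mean_amplitude_uv", "positive"),
        ("n200_600", "peak_amplitude_uv", "negative"),
        ("nc", "peak_latency_ms", "positive"),
        ("extended_nc", "mean_amplitude_uv", "negative"),
    ):
        sub = table[(table["window"] == window) & (table["measure"] == measure)]
        if sub.empty:
            continue
        pivot = sub.pivot_table(index="subject", columns="condition", values="value")
        diffs = (pivot["own"] - pivot["stranger"]).to_numpy()
        res = wilcoxon_effect(diffs, direction=direction)
        nonparam.append(f"{window} / {measure}: {res}")
        ph = posthoc_tests(sub)
        text.append(f"{window} / {measure} own-vs-stranger paired t({ph.df:.0f}) = "
                    f"{ph.statistic:.2f}, P = {ph.p:.4f}")
    (out / "nonparametric.txt").write_text("\n".join(nonparam) + "\n")
    (out / "report.txt").write_text("\n".join(text) + "\n")


def run_all(config: RunConfig, run_dir: Path) -> Path:
    run_dir = Path(run_dir)
    stage_simulate(config, run_dir)
    stage_preprocess(config, run_dir)
    stage_measure(config, run_dir)
    stage_stats(config, run_dir)
    return run_dir
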