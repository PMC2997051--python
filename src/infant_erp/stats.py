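"""Mixed-design statistics for the measurement table.

All design factors have exactly two levels, which keeps the mixed-model
ANOVA algebraically simple: every within-subject effect reduces to a
unit-norm contrast variable computed per subject, tested against its own
subject-by-factor error term; the between factor is tested on subject
means against subjects-within-groups error.  Sphericity corrections are
moot with two levels.  Partial eta squared accompanies every effect.

Group sizes may differ (after subject exclusion); in that case effects
involving the between factor use unweighted (cell-means) marginal means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .erp_measurement import average_epochs, mean_amplitude, negative_peak
from .preprocessing import EpochSet
from .study_design import AnalysisWindow, RoiSpec

ANOVA_COLUMNS = [
    "effect", "df_effect", "df_error", "ss_effect", "ss_error", "F", "p", "partial_eta_sq",
]


def _f_row(effect: str, ss_eff: float, ss_err: float, df_eff: int, df_err: int) -> dict:
    ss_eff = max(ss_eff, 0.0)
    ss_err = max(ss_err, 0.0)
    if ss_err <= 0.0:
        if ss_eff <= 0.0:
            f, p, eta = 0.0, 1.0, 0.0
        else:
            f, p, eta = math.inf, 0.0, 1.0
    else:
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        f = ms_eff / ms_err
        p = float(sps.f.sf(f, df_eff, df_err))
        eta = ss_eff / (ss_eff + ss_err)
    return {
        "effect": effect,
        "df_effect": df_eff,
        "df_error": df_err,
        "ss_effect": ss_eff,
        "ss_error": ss_err,
        "F": f,
        "p": p,
        "partial_eta_sq": eta,
    }


def _score_effects(z: np.ndarray, groups: np.ndarray, name: str, between_name: str) -> list[dict]:
    """ANOVA rows for one unit-norm contrast score: its main effect and,
    with two groups, its interaction with the between factor."""
    levels = sorted(set(groups))
    n = len(z)
    if len(levels) == 1:
        grand = z.mean()
        ss_eff = n * grand**2
        ss_err = float(((z - grand) ** 2).sum())
        return [_f_row(name, ss_eff, ss_err, 1, n - 1)]
    if len(levels) != 2:
        raise ValueError("the between factor must have two levels")
    z1, z2 = (z[groups == g] for g in levels)
    n1, n2 = len(z1), len(z2)
    m1, m2 = z1.mean(), z2.mean()
    inv = 1.0 / n1 + 1.0 / n2
    grand = (m1 + m2) / 2.0
    ss_main = 4.0 * grand**2 / inv
    ss_int = (m1 - m2) ** 2 / inv
    ss_err = float(((z1 - m1) ** 2).sum() + ((z2 - m2) ** 2).sum())
    df_err = n - 2
    return [
        _f_row(name, ss_main, ss_err, 1, df_err),
        _f_row(f"{between_name} x {name}", ss_int, ss_err, 1, df_err),
    ]


def _subject_cells(
    df: pd.DataFrame, dv: str, subject: str, within: list[str]
) -> tuple[np.ndarray, list[str], list[list[str]]]:
    """(subjects x cells) matrix with cells ordered lexicographically by
    the within-factor levels; raises on missing or duplicated cells."""
    levels = [sorted(df[w].unique()) for w in within]
    for w, lv in zip(within, levels):
        if len(lv) != 2:
            raise ValueError(f"within factor {w!r} must have exactly 2 levels, got {lv}")
    pivot = df.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    if pivot.isna().any().any():
        missing = pivot[pivot.isna().any(axis=1)].index.tolist()
        raise ValueError(f"missing within-cells for subjects: {missing}")
    counts = df.groupby([subject, *within]).size()
    if (counts != 1).any():
        raise ValueError("duplicated observations per design cell")
    order = (
        pd.MultiIndex.from_product(levels, names=within) if len(within) > 1 else pd.Index(levels[0], name=within[0])
    )
    pivot = pivot.reindex(columns=order)
    return pivot.to_numpy(), list(pivot.index), levels


def mixed_anova(
    df: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    between: str | None = "group",
    within: list[str] | None = None,
) -> pd.DataFrame:
    """Mixed-design ANOVA for one between factor (optional, 2 levels) and
    one or two within factors (2 levels each).

    Returns one row per effect with SS, df, F, exact p and partial eta
    squared.  Every subject must contribute all within cells exactly once.
    """
    within = within or []
    if not 1 <= len(within) <= 2:
        raise ValueError("need one or two within factors")
    cells, subject_ids, levels = _subject_cells(df, dv, subject, within)
    n_cells = cells.shape[1]

    if between is not None:
        grp = df.groupby(subject)[between].agg(lambda s: s.iloc[0])
        groups = np.asarray([grp[s] for s in subject_ids])
    else:
        groups = np.asarray(["all"] * len(subject_ids))

    rows: list[dict] = []
    # between-subjects stratum on subject means, rescaled by the cell count
    w = cells.mean(axis=1)
    glv = sorted(set(groups))
    if len(glv) == 2:
        w1, w2 = (w[groups == g] for g in glv)
        inv = 1.0 / len(w1) + 1.0 / len(w2)
        ss_g = n_cells * (w1.mean() - w2.mean()) ** 2 / inv
        ss_s = n_cells * float(((w1 - w1.mean()) ** 2).sum() + ((w2 - w2.mean()) ** 2).sum())
        rows.append(_f_row(between, ss_g, ss_s, 1, len(w) - 2))

    # within strata via unit-norm contrast scores
    if len(within) == 1:
        contrasts = {within[0]: np.array([1.0, -1.0])}
    else:
        h = 0.5
        contrasts = {
            within[0]: np.array([h, h, -h, -h]),
            within[1]: np.array([h, -h, h, -h]),
            f"{within[0]} x {within[1]}": np.array([h, -h, -h, h]),
        }
    for name, c in contrasts.items():
        c = c / np.linalg.norm(c)
        z = cells @ c
        rows.extend(_score_effects(z, groups, name, between or "group"))
    return pd.DataFrame(rows, columns=ANOVA_COLUMNS)


def mixed_anova_2x2x2(
    df: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    between: str = "group",
    within: tuple[str, str] = ("condition", "hemisphere"),
) -> pd.DataFrame:
    return mixed_anova(df, dv=dv, subject=subject, between=between, within=list(within))


def mixed_anova_2x2(
    df: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    between: str = "group",
    within: str = "condition",
) -> pd.DataFrame:
    return mixed_anova(df, dv=dv, subject=subject, between=between, within=[within])


def format_anova(table: pd.DataFrame) -> str:
    """Human-readable report, one effect per line."""
    lines = []
    for _, r in table.iterrows():
        lines.append(
            f"{r['effect']}: F({r['df_effect']:.0f},{r['df_error']:.0f}) = {r['F']:.2f}, "
            f"P = {r['p']:.4f}, etap2 = {r['partial_eta_sq']:.3f}"
        )
    return "\n".join(lines)


@dataclass(frozen=True)
class PostHocResult:
    name: str
    statistic: float
    df: float
    p: float
    p_scheffe: float | None = None
    degenerate: bool = False


def scheffe_adjusted_p(t: float, df_error: float, n_cells: int) -> float:
    """Scheffe-adjusted p for a cell-mean contrast with t statistic.

    The squared t is referred to (n_cells - 1) * F(n_cells - 1, df_error).
    Always at least as large as the unadjusted p.
    """
    if n_cells < 2:
        raise ValueError("need at least two cells")
    return float(sps.f.sf(t**2 / (n_cells - 1), n_cells - 1, df_error))


def paired_t(x: np.ndarray, y: np.ndarray, n_cells: int | None = None) -> PostHocResult:
    """Paired t test; a zero-variance nonzero difference is flagged
    degenerate instead of producing an infinite statistic."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    n = len(d)
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            res = PostHocResult("paired_t", 0.0, df, 1.0)
        else:
            res = PostHocResult("paired_t", math.nan, df, math.nan, degenerate=True)
        return res
    t = d.mean() / (sd / math.sqrt(n))
    p = float(2 * sps.t.sf(abs(t), df))
    ps = scheffe_adjusted_p(t, df, n_cells) if n_cells else None
    return PostHocResult("paired_t", float(t), df, p, p_scheffe=ps)


def independent_t(x: np.ndarray, y: np.ndarray, n_cells: int | None = None) -> PostHocResult:
    """Student's (pooled-variance) independent-samples t test."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / df
    if sp2 == 0:
        if x.mean() == y.mean():
            return PostHocResult("independent_t", 0.0, df, 1.0)
        return PostHocResult("independent_t", math.nan, df, math.nan, degenerate=True)
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = float(2 * sps.t.sf(abs(t), df))
    ps = scheffe_adjusted_p(t, df, n_cells) if n_cells else None
    return PostHocResult("independent_t", float(t), df, p, p_scheffe=ps)


def posthoc_tests(
    table: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    factor: str = "condition",
    levels: tuple[str, str] = ("own", "stranger"),
    group: str | None = None,
    group_col: str = "group",
    n_cells: int | None = 4,
) -> PostHocResult:
    """Paired comparison of two within-factor levels, optionally inside
    one group, with a Scheffe-adjusted p alongside the raw p."""
    df = table if group is None else table[table[group_col] == group]
    pivot = df.pivot_table(index=subject, columns=factor, values=dv, aggfunc="mean")
    for lv in levels:
        if lv not in pivot.columns:
            raise ValueError(f"level {lv!r} absent from factor {factor!r}")
    return paired_t(pivot[levels[0]].to_numpy(), pivot[levels[1]].to_numpy(), n_cells=n_cells)


@dataclass(frozen=True)
class NonParamResult:
    n_positive: int
    n_total: int
    z: float
    p: float

    def __str__(self) -> str:
        return f"{self.n_positive} out of {self.n_total}, Z = {self.z:.2f}, P = {self.p:.4f}"


def _signed_rank_exact_p(ranks: np.ndarray, t_min: float) -> float:
    """Exact two-sided p for the signed-rank statistic by dynamic
    programming over the sign-flip distribution (handles tied ranks via
    doubled integer ranks)."""
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    t2 = int(round(2 * t_min))
    cdf = counts[: t2 + 1].sum() / counts.sum()
    return min(1.0, 2.0 * cdf)


def wilcoxon_effect(
    differences: np.ndarray,
    direction: str = "positive",
    exact_max_n: int = 25,
) -> NonParamResult:
    """Signed-rank test on per-subject condition differences.

    Zeros are dropped before ranking (Wilcoxon's original treatment) but
    still count toward ``n_total``; ``n_positive`` counts strict
    differences in the predicted direction.  ``z`` is the
    continuity-corrected normal statistic on the smaller rank sum (hence
    non-positive); ``p`` is exact for up to ``exact_max_n`` nonzero
    differences, normal-approximate beyond.
    """
    d = np.asarray(differences, float)
    if d.size == 0:
        raise ValueError("no differences supplied")
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    n_total = d.size
    n_positive = int((d > 0).sum()) if direction == "positive" else int((d < 0).sum())
    nz = d[d != 0]
    if nz.size == 0:
        raise ValueError("all differences are zero")
    ranks = sps.rankdata(np.abs(nz))
    w_pos = float(ranks[nz > 0].sum())
    m = nz.size
    total = m * (m + 1) / 2.0
    t_min = min(w_pos, total - w_pos)
    mu = total / 2.0
    sigma = math.sqrt(m * (m + 1) * (2 * m + 1) / 24.0)
    if t_min == mu:
        z = 0.0
    else:
        z = (t_min - mu + 0.5) / sigma
    if m <= exact_max_n:
        p = _signed_rank_exact_p(ranks, t_min)
    else:
        p = min(1.0, float(2 * sps.norm.sf(abs(z))))
    return NonParamResult(n_positive=n_positive, n_total=n_total, z=float(z), p=float(p))


def _half_boundary(epochs: EpochSet) -> int:
    if not epochs.trial_indices:
        return 0
    return (max(epochs.trial_indices) + 2) // 2


def split_half_analysis(
    epoch_sets: dict[str, EpochSet],
    groups: dict[str, str],
    rois: list[RoiSpec],
    window: AnalysisWindow,
    min_trials: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recompute one measure separately for the first and second half of
    the experiment and test for interactions with the Half factor.

    Trials are partitioned by presentation order (first 100 vs last 100
    events of the modality).  The measure is averaged across the supplied
    ROIs (collapsing hemispheres, keeping the design at two within
    factors: condition and half).  Returns (anova_table, long_table).
    """
    rows = []
    for subject_id, epochs in epoch_sets.items():
        boundary = _half_boundary(epochs)
        idx = np.asarray(epochs.trial_indices)
        for half, mask in (("first", idx < boundary), ("second", idx >= boundary)):
            sub = epochs.subset(mask)
            for condition in ("own", "stranger"):
                if sub.retained_count(condition) < min_trials:
                    raise ValueError(
                        f"{subject_id}: fewer than {min_trials} retained "
                        f"{condition!r} trials in the {half} half"
                    )
                erp = average_epochs(sub, condition, subject_id)
                if window.measure == "mean_amplitude":
                    value = float(np.mean([mean_amplitude(erp, roi, window) for roi in rois]))
                else:
                    value = float(np.mean([negative_peak(erp, roi, window)[0] for roi in rois]))
                rows.append(
                    {
                        "subject": subject_id,
                        "group": groups[subject_id],
                        "condition": condition,
                        "half": half,
                        "value": value,
                    }
                )
    table = pd.DataFrame(rows)
    anova = mixed_anova(table, within=["condition", "half"])
    return anova, table


@dataclass(frozen=True)
class MedianSplitResult:
    median: float
    below: tuple[str, ...]
    above: tuple[str, ...]
    t: float
    df: float
    p: float


def median_split_snr_check(
    values: dict[str, float],
    trial_counts: dict[str, float],
) -> MedianSplitResult:
    """Trial-count (SNR) control: split subjects at the cohort median of
    retained trials and compare the supplied per-subject measure between
    the below-median and at-or-above-median subgroups (Student's t)."""
    subjects = sorted(values)
    counts = np.array([trial_counts[s] for s in subjects], float)
    med = float(np.median(counts))
    below = tuple(s for s, c in zip(subjects, counts) if c < med)
    above = tuple(s for s, c in zip(subjects, counts) if c >= med)
    if not below or not above:
        raise ValueError("median split produced an empty subgroup")
    res = independent_t(
        np.array([values[s] for s in below]),
        np.array([values[s] for s in above]),
    )
    return MedianSplitResult(median=med, below=below, above=above, t=res.statistic, df=res.df, p=res.p)
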