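"""Derived measures and the group-level statistical battery.

Facilitation is the threshold change produced by the flankers, in
decibels: ``-20 log10(threshold / baseline)``; positive values mean the
flankers lowered the detection threshold.  Jitter tolerance is the 75%
point of the contour psychometric function.  The battery mirrors the
standard analysis of a two-group psychophysics study: mixed
(between x within) ANOVAs with partial eta squared, Bonferroni-corrected
t-tests, Pearson correlations, and the Fisher r-to-z comparison of two
independent correlations.

The mixed ANOVA is computed by pingouin (classical balanced-design sums
of squares); everything here assumes the balanced designs the simulated
sessions produce and raises on unbalanced input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .observer import FIXATION_LIMIT_DEG

__all__ = [
    "StatReport",
    "facilitation_db",
    "facilitation_table",
    "filter_fixation",
    "mixed_anova",
    "t_tests",
    "pearson_r",
    "fisher_compare",
    "closure_effect",
    "StudyAnalysis",
]


@dataclass
class StatReport:
    """One test result: statistic, df, p and (when defined) effect size."""

    effect: str
    statistic: float
    stat_name: str  # "F", "t", "Z" or "r"
    df: tuple
    p: float
    effect_size: float | None = None  # partial eta squared for ANOVA rows
    correction: str | None = None
    note: str | None = None

    def __str__(self) -> str:
        df = ",".join(f"{d:g}" for d in self.df)
        s = f"{self.effect}: {self.stat_name}({df}) = {self.statistic:.3f}, p = {self.p:.4f}"
        if self.effect_size is not None:
            s += f", eta_p^2 = {self.effect_size:.3f}"
        if self.correction:
            s += f" [{self.correction}]"
        return s


def facilitation_db(baseline: float, threshold: float) -> float:
    """Facilitation in dB: ``-20 log10(threshold / baseline)``.

    Positive when the flanked threshold is below baseline (facilitation),
    negative for suppression; antisymmetric under swapping the arguments.
    """
    if baseline <= 0 or threshold <= 0:
        raise ValueError("thresholds must be > 0")
    return -20.0 * math.log10(threshold / baseline)


def facilitation_table(thresholds: pd.DataFrame) -> pd.DataFrame:
    """Per-participant facilitation from a long threshold table.

    Expects columns ``participant, group, condition, threshold`` with a
    ``"baseline"`` condition row per participant; returns one row per
    participant x offset condition with the threshold and facilitation.
    """
    out = []
    for pid, sub in thresholds.groupby("participant"):
        base_rows = sub[sub["condition"] == "baseline"]
        if base_rows.empty:
            raise ValueError(f"participant {pid} lacks a baseline threshold")
        base = float(base_rows["threshold"].iloc[0])
        for _, row in sub[sub["condition"] != "baseline"].iterrows():
            out.append(
                {
                    "participant": pid,
                    "group": row["group"],
                    "offset": int(row["condition"]),
                    "baseline": base,
                    "threshold": row["threshold"],
                    "facilitation_db": facilitation_db(base, row["threshold"]),
                }
            )
    return pd.DataFrame(out).sort_values(["participant", "offset"]).reset_index(
        drop=True
    )


def filter_fixation(
    trials: pd.DataFrame,
    limit: float = FIXATION_LIMIT_DEG,
    gaze_col: str = "gaze_deviation",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop trials whose gaze deviation exceeds ``limit`` degrees.

    Trials with a missing gaze record are retained (and counted
    separately), mirroring sessions where eye tracking only covered part
    of the trials.  Returns (retained trials, per-participant report).
    """
    gaze = trials[gaze_col]
    missing = gaze.isna()
    keep = missing | (gaze <= limit)
    report = (
        trials.assign(_missing=missing, _kept=keep)
        .groupby("participant")
        .agg(
            n_trials=("_kept", "size"),
            n_missing_gaze=("_missing", "sum"),
            n_retained=("_kept", "sum"),
        )
        .reset_index()
    )
    report["n_dropped"] = report["n_trials"] - report["n_retained"]
    report["retained_fraction"] = report["n_retained"] / report["n_trials"]
    return trials[keep].copy(), report


# --------------------------------------------------------------------------
# Inferential statistics


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    between: str,
) -> list[StatReport]:
    """Two-way mixed ANOVA (one between-subject, one within-subject factor).

    Classical balanced-design sums of squares with partial eta squared
    ``SS_effect / (SS_effect + SS_error)``; raises on unbalanced
    within-factor levels.  Returns reports for the between main effect,
    the within main effect and the interaction.
    """
    import pingouin as pg

    counts = data.groupby([subject, within])[dv].count().unstack()
    if counts.isna().any().any() or (counts != 1).any().any():
        raise ValueError("each subject needs exactly one observation per level")
    table = pg.mixed_anova(
        data=data, dv=dv, within=within, subject=subject, between=between
    )
    reports = []
    label = {0: f"{between} (between)", 1: f"{within} (within)", 2: "interaction"}
    for i, row in table.iterrows():
        reports.append(
            StatReport(
                effect=label.get(i, str(row["Source"])),
                statistic=float(row["F"]),
                stat_name="F",
                df=(float(row["DF1"]), float(row["DF2"])),
                p=float(row["p_unc"]),
                effect_size=float(row["np2"]),
            )
        )
    return reports


def t_tests(
    samples: list[tuple[str, np.ndarray, np.ndarray]],
    kind: str = "independent",
    bonferroni: int | None = None,
) -> list[StatReport]:
    """Two-sided t-tests with optional Bonferroni correction.

    ``samples`` is a list of (label, x, y); ``kind`` is "paired" or
    "independent".  Corrected p-values are ``min(1, p * factor)``.  A
    comparison with zero variance and zero difference is flagged (t is
    undefined) rather than silently dropped.
    """
    if kind not in {"paired", "independent"}:
        raise ValueError("kind must be 'paired' or 'independent'")
    factor = bonferroni or 1
    reports = []
    for label, x, y in samples:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) < 2 or len(y) < 2:
            raise ValueError("need n >= 2 per sample")
        if kind == "paired":
            d = x - y
            if np.allclose(d.std(ddof=1), 0) and np.allclose(d.mean(), 0):
                reports.append(
                    StatReport(label, 0.0, "t", (len(d) - 1,), 1.0,
                               note="undefined t: zero variance, zero difference"))
                continue
            t, p = sps.ttest_rel(x, y)
            df = (len(x) - 1,)
        else:
            if (np.allclose(np.std(x, ddof=1), 0)
                    and np.allclose(np.std(y, ddof=1), 0)
                    and np.allclose(np.mean(x), np.mean(y))):
                reports.append(
                    StatReport(label, 0.0, "t", (len(x) + len(y) - 2,), 1.0,
                               note="undefined t: zero variance, zero difference"))
                continue
            t, p = sps.ttest_ind(x, y)
            df = (len(x) + len(y) - 2,)
        reports.append(
            StatReport(
                effect=label,
                statistic=float(t),
                stat_name="t",
                df=df,
                p=min(1.0, float(p) * factor),
                correction=f"bonferroni x{factor}" if factor > 1 else None,
            )
        )
    return reports


def pearson_r(x, y) -> StatReport:
    """Pearson correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    return StatReport(
        effect="pearson", statistic=float(r), stat_name="r",
        df=(len(x) - 2,), p=float(p),
    )


def fisher_compare(r1: float, n1: int, r2: float, n2: int) -> StatReport:
    """Compare two independent correlations via Fisher's r-to-z.

    ``Z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))`` with a
    two-sided normal p-value; antisymmetric under swapping the two
    correlations.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in both samples")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| must be < 1")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * sps.norm.sf(abs(z))
    return StatReport(
        effect="fisher r-to-z", statistic=z, stat_name="Z", df=(), p=float(p)
    )


def closure_effect(tolerances: pd.DataFrame) -> pd.DataFrame:
    """Per-group closure benefit: square minus lines tolerance.

    Expects a long table with columns ``participant, group, shape,
    tolerance``; participants missing either shape are excluded (their
    ids appear in the ``excluded`` attribute of the result).  Returns a
    per-group summary of the paired differences.
    """
    wide = tolerances.pivot_table(
        index=["participant", "group"], columns="shape", values="tolerance"
    ).reset_index()
    missing = wide[wide[["lines", "square"]].isna().any(axis=1)]
    wide = wide.dropna(subset=["lines", "square"]).copy()
    wide["closure_benefit"] = wide["square"] - wide["lines"]
    summary = (
        wide.groupby("group")["closure_benefit"]
        .agg(["mean", "std", "count"])
        .rename(columns={"count": "n"})
        .reset_index()
    )
    summary.attrs["excluded"] = list(missing["participant"])
    summary.attrs["per_participant"] = wide
    return summary


# --------------------------------------------------------------------------
# Whole-study analysis


class StudyAnalysis:
    """The full statistical battery applied to one simulated study.

    Built from a :class:`~visint.runner.StudyData`; ``run()`` computes the
    baseline group comparison, the group x offset mixed ANOVA on
    facilitation with Bonferroni post-hocs, the group x shape mixed ANOVA
    on jitter tolerance, the closure-benefit summary and the per-group
    lines/square correlations with their Fisher comparison.
    """

    def __init__(self, study):
        self.study = study

    def run(self) -> "StudyReport":
        study = self.study
        groups = sorted(study.thresholds["group"].unique()) if len(
            study.thresholds) else sorted(study.tolerances["group"].unique())
        reports: dict[str, object] = {}

        if len(study.thresholds):
            fac = facilitation_table(study.thresholds)
            reports["facilitation"] = fac
            base = study.thresholds.query("condition == 'baseline'")
            pivot = {g: base.loc[base["group"] == g, "threshold"].to_numpy()
                     for g in groups}
            reports["baseline_ttest"] = t_tests(
                [("baseline threshold", pivot[groups[0]], pivot[groups[1]])]
            )[0]
            reports["cf_anova"] = mixed_anova(
                fac, dv="facilitation_db", within="offset",
                subject="participant", between="group",
            )
            posthoc = []
            offsets = sorted(fac["offset"].unique())
            for off in offsets:
                sub = fac[fac["offset"] == off]
                posthoc.append(
                    (
                        f"offset {off}",
                        sub.loc[sub["group"] == groups[0],
                                "facilitation_db"].to_numpy(),
                        sub.loc[sub["group"] == groups[1],
                                "facilitation_db"].to_numpy(),
                    )
                )
            reports["cf_posthoc"] = t_tests(
                posthoc, kind="independent", bonferroni=len(offsets)
            )

        if len(study.tolerances):
            tol = study.tolerances[
                study.tolerances["shape"].isin(["lines", "square"])
            ]
            reports["ci_anova"] = mixed_anova(
                tol, dv="tolerance", within="shape",
                subject="participant", between="group",
            )
            reports["closure"] = closure_effect(tol)
            wide = tol.pivot_table(
                index=["participant", "group"], columns="shape",
                values="tolerance",
            ).reset_index()
            # the correlation comparison needs n > 3 per group
            if all((wide["group"] == g).sum() > 3 for g in groups):
                corr = {}
                for g in groups:
                    sub = wide[wide["group"] == g]
                    corr[g] = (pearson_r(sub["lines"], sub["square"]), len(sub))
                reports["ci_correlations"] = corr
                (r1, n1), (r2, n2) = (
                    (corr[groups[0]][0].statistic, corr[groups[0]][1]),
                    (corr[groups[1]][0].statistic, corr[groups[1]][1]),
                )
                reports["fisher"] = fisher_compare(r1, n1, r2, n2)

        return StudyReport(groups=groups, results=reports)


@dataclass
class StudyReport:
    """Bundled analysis results with a plain-text rendering."""

    groups: list
    results: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Study analysis", "=" * 60]
        r = self.results
        if "baseline_ttest" in r:
            lines += ["", "Contrast detection (collinear facilitation)", "-" * 44]
            lines.append(str(r["baseline_ttest"]))
            fac = r["facilitation"]
            for g in self.groups:
                sub = fac[fac["group"] == g]["facilitation_db"]
                lines.append(
                    f"  {g} facilitation: M = {sub.mean():.2f} dB, "
                    f"SD = {sub.std(ddof=1):.2f}"
                )
            lines += [str(x) for x in r["cf_anova"]]
            lines += ["post-hoc group comparisons per offset:"]
            lines += ["  " + str(x) for x in r["cf_posthoc"]]
        if "ci_anova" in r:
            lines += ["", "Contour integration", "-" * 44]
            lines += [str(x) for x in r["ci_anova"]]
            closure = r["closure"]
            for _, row in closure.iterrows():
                lines.append(
                    f"  {row['group']} closure benefit (square - lines): "
                    f"M = {row['mean']:.2f} deg, SD = {row['std']:.2f}"
                )
            if "ci_correlations" in r:
                for g, (rep, n) in r["ci_correlations"].items():
                    lines.append(
                        f"  {g} lines-square correlation: r = {rep.statistic:.2f}, "
                        f"p = {rep.p:.4f} (n = {n})"
                    )
                lines.append(str(r["fisher"]))
        return "\n".join(lines)
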