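"""Trial statistics: pre/post changes, arm comparisons, compliance, predictors.

Implements the comparison layer of a two-arm dietary trial (time-restricted
eating, TRE, versus standard dietary advice, SDA): paired t-tests on within-
participant changes, unpaired Student t-tests with confidence intervals for
the between-arm difference (TRE - SDA by convention), rule-based compliance
classification from food-log deltas, and exploratory Pearson correlations
between weight loss and candidate predictors.  No multiplicity correction is
applied anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedTestResult",
    "BetweenGroupResult",
    "ComplianceReport",
    "paired_change_test",
    "between_group_difference",
    "mann_whitney",
    "classify_compliance",
    "compliance_table",
    "trial_summary",
    "explore_weight_predictors",
]

TRE_DURATION_TARGET = 12.0  # hours: the assigned eating window


@dataclass(frozen=True)
class PairedTestResult:
    mean_change: float
    sd_change: float
    t: float
    p: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class BetweenGroupResult:
    difference: float          # mean(a) - mean(b)
    ci_low: float
    ci_high: float
    t: float
    p: float
    df: float
    degenerate: bool = False


@dataclass(frozen=True)
class ComplianceReport:
    participant_id: str
    arm: str
    d_nova1_pp: float | None     # percentage-point change, intervention - observation
    d_nova4_pp: float | None
    d_duration: float | None     # hours
    intervention_duration: float | None
    compliant: bool | None
    rule: str


def paired_change_test(pre: Sequence[float], post: Sequence[float]) -> PairedTestResult:
    """Two-sided paired t-test on post-minus-pre change scores.

    Identical samples give t = 0, p = 1.  A non-zero constant shift has zero
    change variance and no finite t statistic; it is reported degenerate.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be paired (equal length)")
    n = pre.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = post - pre
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(0.0, 0.0, 0.0, 1.0, n)
        return PairedTestResult(mean, 0.0, math.nan, math.nan, n, degenerate=True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTestResult(mean, sd, float(t), float(p), n)


def between_group_difference(
    changes_a: Sequence[float],
    changes_b: Sequence[float],
    level: float = 0.95,
    equal_var: bool = True,
) -> BetweenGroupResult:
    """Unpaired two-sided t-test on change scores, with a t-based CI.

    The difference is mean(a) - mean(b); by package convention the first
    group is TRE and the second SDA.  ``equal_var=True`` gives the classic
    Student test (pooled variance); Welch is available for unequal spread.
    """
    a = np.asarray(changes_a, dtype=float)
    b = np.asarray(changes_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 observations per group")
    diff = float(a.mean() - b.mean())
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            return BetweenGroupResult(0.0, 0.0, 0.0, 0.0, 1.0, float(na + nb - 2))
        return BetweenGroupResult(
            diff, math.nan, math.nan, math.nan, math.nan, float(na + nb - 2), degenerate=True
        )
    if equal_var:
        df = na + nb - 2.0
        pooled = ((na - 1) * va + (nb - 1) * vb) / df
        se = math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    else:
        sea2, seb2 = va / na, vb / nb
        se = math.sqrt(sea2 + seb2)
        df = (sea2 + seb2) ** 2 / (sea2**2 / (na - 1) + seb2**2 / (nb - 1))
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df=df)
    crit = stats.t.ppf(0.5 + level / 2.0, df=df)
    return BetweenGroupResult(
        diff, diff - crit * se, diff + crit * se, float(t), float(p), float(df)
    )


def mann_whitney(changes_a: Sequence[float], changes_b: Sequence[float]) -> tuple[float, float]:
    """Non-parametric alternative for the weight comparison (U statistic, p)."""
    res = stats.mannwhitneyu(changes_a, changes_b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def classify_compliance(
    participant_id: str,
    arm: str,
    d_nova1_pp: float | None = None,
    d_nova4_pp: float | None = None,
    d_duration: float | None = None,
    intervention_duration: float | None = None,
    tre_threshold: float = TRE_DURATION_TARGET,
) -> ComplianceReport:
    """Rule-based compliance with the allocated intervention.

    SDA: compliant iff the NOVA4 event proportion strictly decreased and the
    NOVA1 proportion strictly increased between phases.  TRE: compliant iff
    the intervention-phase eating duration is within the assigned window
    (``<= tre_threshold`` hours, default 12).  Missing phase data leave
    compliance undetermined (None).
    """
    if arm == "SDA":
        rule = "SDA: dNOVA4 < 0 and dNOVA1 > 0"
        if d_nova1_pp is None or d_nova4_pp is None or (
            isinstance(d_nova1_pp, float) and math.isnan(d_nova1_pp)
        ) or (isinstance(d_nova4_pp, float) and math.isnan(d_nova4_pp)):
            compliant = None
        else:
            compliant = d_nova4_pp < 0.0 and d_nova1_pp > 0.0
    elif arm == "TRE":
        rule = f"TRE: intervention eating duration <= {tre_threshold} h"
        if intervention_duration is None or (
            isinstance(intervention_duration, float) and math.isnan(intervention_duration)
        ):
            compliant = None
        else:
            compliant = intervention_duration <= tre_threshold
    else:
        raise ValueError(f"unknown arm {arm!r}")
    return ComplianceReport(
        participant_id=str(participant_id),
        arm=arm,
        d_nova1_pp=d_nova1_pp,
        d_nova4_pp=d_nova4_pp,
        d_duration=d_duration,
        intervention_duration=intervention_duration,
        compliant=compliant,
        rule=rule,
    )


def compliance_table(
    proportions_obs: pd.DataFrame,
    proportions_int: pd.DataFrame,
    windows: pd.DataFrame,
    arms: Mapping[str, str],
    tre_threshold: float = TRE_DURATION_TARGET,
) -> pd.DataFrame:
    """Build the per-participant compliance report for randomised participants.

    ``proportions_*`` are per-phase outputs of
    :func:`chronofood.nova_annotation.category_proportions`; ``windows`` the
    per-phase table from :func:`chronofood.eating_window.window_table`;
    ``arms`` maps participant id to "TRE"/"SDA".  Proportion deltas are in
    percentage points.
    """
    wins = windows.set_index(["participant_id", "phase"])["duration"]
    rows = []
    for pid, arm in arms.items():
        d1 = d4 = None
        if pid in proportions_obs.index and pid in proportions_int.index:
            d1 = 100.0 * (proportions_int.loc[pid, "p_NOVA1"] - proportions_obs.loc[pid, "p_NOVA1"])
            d4 = 100.0 * (proportions_int.loc[pid, "p_NOVA4"] - proportions_obs.loc[pid, "p_NOVA4"])
        dur_obs = wins.get((pid, "observation"))
        dur_int = wins.get((pid, "intervention"))
        d_dur = None
        if dur_obs is not None and dur_int is not None:
            d_dur = float(dur_int - dur_obs)
        rep = classify_compliance(
            pid, arm,
            d_nova1_pp=d1, d_nova4_pp=d4,
            d_duration=d_dur,
            intervention_duration=None if dur_int is None else float(dur_int),
            tre_threshold=tre_threshold,
        )
        rows.append(rep.__dict__)
    return pd.DataFrame(rows)


def trial_summary(
    pre: pd.DataFrame,
    post: pd.DataFrame,
    arms: Mapping[str, str],
    outcomes: Sequence[str] | None = None,
    percent_outcomes: Sequence[str] = ("weight",),
    level: float = 0.95,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-outcome pre/post and between-arm comparison table.

    ``pre`` and ``post`` are participant-indexed measurement tables.  Change
    scores are percent-of-initial for outcomes listed in
    ``percent_outcomes`` (weight by default) and raw differences otherwise.
    The between-group difference is TRE - SDA with a Student t-based CI.
    Only participants present in both tables contribute.
    """
    common = pre.index.intersection(post.index)
    pre, post = pre.loc[common], post.loc[common]
    arm_series = pd.Series({pid: arms[pid] for pid in common if pid in arms})
    if outcomes is None:
        outcomes = [c for c in pre.columns if c in post.columns and pd.api.types.is_numeric_dtype(pre[c])]
    rows = []
    for outcome in outcomes:
        changes = {}
        for arm in ("TRE", "SDA"):
            ids = arm_series.index[arm_series == arm]
            ids = [i for i in ids if pd.notna(pre.loc[i, outcome]) and pd.notna(post.loc[i, outcome])]
            pr = pre.loc[ids, outcome].to_numpy(dtype=float)
            po = post.loc[ids, outcome].to_numpy(dtype=float)
            if outcome in percent_outcomes:
                chg = 100.0 * (po - pr) / pr
            else:
                chg = po - pr
            changes[arm] = chg
            if len(pr) >= 2:
                test = paired_change_test(np.zeros_like(chg), chg)
                rows.append(
                    {
                        "outcome": outcome,
                        "arm": arm,
                        "n": len(pr),
                        "pre_mean": pr.mean(),
                        "pre_sd": pr.std(ddof=1),
                        "post_mean": po.mean(),
                        "post_sd": po.std(ddof=1),
                        "change_mean": test.mean_change,
                        "change_sd": test.sd_change,
                        "paired_p": test.p,
                        "percent_change": outcome in percent_outcomes,
                    }
                )
        if len(changes.get("TRE", ())) >= 2 and len(changes.get("SDA", ())) >= 2:
            bg = between_group_difference(changes["TRE"], changes["SDA"], level=level, equal_var=equal_var)
            for row in rows:
                if row["outcome"] == outcome and "between_diff" not in row:
                    row["between_diff"] = bg.difference
                    row["between_ci_low"] = bg.ci_low
                    row["between_ci_high"] = bg.ci_high
                    row["between_p"] = bg.p
    return pd.DataFrame(rows)


def explore_weight_predictors(
    weight_changes: pd.Series,
    covariates: pd.DataFrame,
    sex_column: str = "sex",
) -> pd.DataFrame:
    """Exploratory Pearson correlations between weight change and covariates.

    Continuous covariates get a correlation coefficient and p-value; the sex
    column (if present) is handled as a two-sample comparison of weight
    change between groups.  Covariates with zero variance are reported with
    missing statistics.
    """
    common = weight_changes.index.intersection(covariates.index)
    y = weight_changes.loc[common].astype(float)
    rows = []
    for col in covariates.columns:
        x = covariates.loc[common, col]
        if col == sex_column:
            groups = [y[x == g].to_numpy() for g in pd.unique(x.dropna())]
            if len(groups) == 2 and all(len(g) >= 2 for g in groups):
                bg = between_group_difference(groups[0], groups[1])
                rows.append(
                    {"covariate": col, "kind": "two_sample", "rho": np.nan,
                     "statistic": bg.difference, "p": bg.p, "n": int(sum(len(g) for g in groups))}
                )
            else:
                rows.append({"covariate": col, "kind": "two_sample", "rho": np.nan,
                             "statistic": np.nan, "p": np.nan, "n": int(x.notna().sum())})
            continue
        x = pd.to_numeric(x, errors="coerce")
        mask = x.notna() & y.notna()
        n = int(mask.sum())
        if n < 3 or x[mask].std(ddof=0) == 0 or y[mask].std(ddof=0) == 0:
            rows.append({"covariate": col, "kind": "pearson", "rho": np.nan,
                         "statistic": np.nan, "p": np.nan, "n": n})
            continue
        rho, p = stats.pearsonr(x[mask], y[mask])
        rows.append({"covariate": col, "kind": "pearson", "rho": float(rho),
                     "statistic": float(rho), "p": float(p), "n": n})
    return pd.DataFrame(rows)
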