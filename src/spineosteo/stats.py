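"""Cohort statistics for the osteotomy-volume experiment.

Condition summaries (mean +- SD), two-sample t-tests (paired by subject by
default, since every synthetic subject contributes all angle conditions)
and one-way ANOVA across angle groups, with the conventional significance
flags (* p < 0.05, ** p < 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

CONDITION_KEYS = ["group", "angle_deg", "diameter_mm", "attempts"]


@dataclass
class ComparisonResult:
    groups: tuple
    statistic: float
    p_value: float
    test: str
    flag: str = ""
    note: str = ""

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value out of [0, 1]")
        self.flag = significance_flag(self.p_value)


def significance_flag(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def summarize(volumes: pd.DataFrame,
              value: str = "removed_volume_mm3") -> pd.DataFrame:
    """Per-condition mean +- SD table (unbiased SD, n-1).

    Conditions with fewer than two subjects are omitted with a warning
    column left in place; condition keys are (group, angle, diameter,
    attempts).
    """
    df = volumes[volumes.get("error", "").astype(str) == ""]
    rows = []
    for keys, sub in df.groupby(CONDITION_KEYS):
        vals = sub[value].to_numpy(float)
        if len(vals) < 2:
            continue
        rows.append(dict(zip(CONDITION_KEYS, keys),
                         n=len(vals),
                         mean=float(np.mean(vals)),
                         sd=float(np.std(vals, ddof=1))))
    out = pd.DataFrame(rows)
    return out.sort_values(CONDITION_KEYS[1:]).reset_index(drop=True)


def pairwise_test(a: np.ndarray, b: np.ndarray,
                  paired: bool = True,
                  labels: tuple = ("a", "b")) -> ComparisonResult:
    """Two-sided t-test between two conditions.

    Paired by subject by default (each subject contributes both
    conditions); identical zero-variance samples yield p = 1 by convention
    with a note.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per group")
    if paired and len(a) != len(b):
        raise ValueError("paired test requires equal sample sizes")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return ComparisonResult(labels, 0.0, 1.0,
                                    "t-paired" if paired else "t-unpaired",
                                    note="degenerate: zero variance, "
                                         "equal means")
        # zero variance but different means: certain difference
        return ComparisonResult(labels, np.inf, 0.0,
                                "t-paired" if paired else "t-unpaired",
                                note="degenerate: zero variance, "
                                     "different means")
    if paired:
        res = sps.ttest_rel(a, b)
        name = "t-paired"
    else:
        res = sps.ttest_ind(a, b)
        name = "t-unpaired"
    stat = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(p):
        stat, p = 0.0, 1.0
    return ComparisonResult(labels, stat, p, name)


def anova(*groups: np.ndarray, labels: tuple = ()) -> ComparisonResult:
    """One-way ANOVA across three or more angle groups."""
    if len(groups) < 3:
        raise ValueError("ANOVA needs >= 3 groups; use pairwise_test for 2")
    arrays = [np.asarray(g, float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise ValueError("need at least two observations per group")
    if all(np.ptp(g) == 0 for g in arrays) and \
            len({float(g[0]) for g in arrays}) == 1:
        return ComparisonResult(labels or tuple(range(len(groups))),
                                0.0, 1.0, "anova",
                                note="degenerate: identical constant groups")
    res = sps.f_oneway(*arrays)
    stat, p = float(res.statistic), float(res.pvalue)
    if np.isnan(p):
        stat, p = 0.0, 1.0
    return ComparisonResult(labels or tuple(range(len(groups))),
                            stat, p, "anova")


def angle_contrasts(volumes: pd.DataFrame, paired: bool = True,
                    holm: bool = False) -> pd.DataFrame:
    """The angle-pair comparisons reported for each diameter x attempts cell.

    Within PEID (20/30/40) and PTED (50/60/70) all three angle pairs are
    tested, plus the across-group 40 vs 50 contrast.  No multiple-testing
    correction by default (Holm optionally).
    """
    df = volumes[volumes.get("error", "").astype(str) == ""]
    pairs = [(20, 30), (20, 40), (30, 40), (50, 60), (50, 70), (60, 70),
             (40, 50)]
    rows = []
    for (dia, att), sub in df.groupby(["diameter_mm", "attempts"]):
        piv = sub.pivot(index="subject", columns="angle_deg",
                        values="removed_volume_mm3")
        for a, b in pairs:
            if a not in piv.columns or b not in piv.columns:
                continue
            res = pairwise_test(piv[a].to_numpy(), piv[b].to_numpy(),
                                paired=paired, labels=(a, b))
            rows.append({"diameter_mm": dia, "attempts": att,
                         "angle_a": a, "angle_b": b,
                         "statistic": res.statistic, "p_value": res.p_value,
                         "flag": res.flag})
    out = pd.DataFrame(rows)
    if holm and len(out):
        order = np.argsort(out["p_value"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p_value"].iloc[idx])
            adj[idx] = min(1.0, running)
        out["p_holm"] = adj
        out["flag"] = [significance_flag(p) for p in adj]
    return out
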