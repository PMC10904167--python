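"""Cohort statistics.

Fluorescence milestones are compared between groups with rank-based tests:
Mann-Whitney U for independent groups, Wilcoxon signed-rank for paired
(first vs second assessment) comparisons, with the exact null distribution
for small samples and the tie-corrected normal approximation otherwise.
Shapiro-Wilk normality is computed as a diagnostic but the nonparametric p
value is always the one reported.  Frequency tables use Fisher's exact test.
Significance is ascribed at p < 0.05; no multiplicity correction is applied
across the many metric-region comparisons, and the rendered report says so.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ingest import QFlapError
from .regions import REGION_ORDER

ALPHA = 0.05
EXACT_N_MAX = 25  # combined sample size up to which exact null is used

#: milestone columns reported in the group-comparison tables
TABLE_METRICS = ["latency", "peak_time", "F_max", "T_max", "upslope", "nT_max", "nF_max"]


class StatsError(QFlapError):
    pass


@dataclass
class StatResult:
    test: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    paired: bool
    flagged: bool = False  # test undefined / degenerate input
    note: str = ""
    shapiro_p: tuple = field(default=())

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.p_value) and self.p_value < ALPHA)


def _has_ties(*samples) -> bool:
    allv = np.concatenate(samples)
    return len(np.unique(allv)) < len(allv)


WILCOXON_EXACT_N_MAX = 12  # sign patterns enumerated up to 2^12


def _wilcoxon_exact(diffs: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank test by enumerating all sign patterns.

    Handles tied magnitudes through midranks (which scipy's exact method
    does not); zeros must already be removed.  The two-sided p is the null
    probability of a rank sum at least as far from its centre as observed.
    """
    d = np.asarray(diffs, dtype=float)
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    centre = ranks.sum() / 2.0
    dev_obs = abs(w_obs - centre)
    signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(bool)
    w_all = signs @ ranks
    p = float(np.mean(np.abs(w_all - centre) >= dev_obs - 1e-12))
    return w_obs, p


def compare_groups(values_a, values_b, paired: bool = False) -> StatResult:
    """Two-group comparison of one milestone.

    Unpaired: two-sided Mann-Whitney U.  Paired: two-sided Wilcoxon
    signed-rank on the differences.  Exact null when the combined n is at
    most 25 and the data permit (no ties for MWU, no zero/tied differences
    for Wilcoxon); tie-corrected normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if paired:
        if len(values_a) != len(values_b):
            raise StatsError("paired comparison requires equal-length samples")
        pairs = np.column_stack([np.asarray(values_a, float), np.asarray(values_b, float)])
        pairs = pairs[np.isfinite(pairs).all(axis=1)]
        a, b = pairs[:, 0], pairs[:, 1]
    if len(a) < 3 or len(b) < 3:
        raise StatsError("each group needs n >= 3")

    shapiro = (float(sps.shapiro(a).pvalue) if len(a) >= 3 else np.nan,
               float(sps.shapiro(b).pvalue) if len(b) >= 3 else np.nan)

    if paired:
        d = a - b
        if np.all(d == 0):
            return StatResult("wilcoxon", np.nan, np.nan, len(a), len(b), True,
                              flagged=True, note="all paired differences are zero",
                              shapiro_p=shapiro)
        nz = d[d != 0]
        if len(nz) <= WILCOXON_EXACT_N_MAX:
            stat, p = _wilcoxon_exact(nz)
            return StatResult("wilcoxon", stat, p, len(a), len(b), True,
                              shapiro_p=shapiro)
        res = sps.wilcoxon(a, b, alternative="two-sided", method="approx")
        return StatResult("wilcoxon", float(res.statistic), float(res.pvalue),
                          len(a), len(b), True, shapiro_p=shapiro)

    exact = (len(a) + len(b) <= EXACT_N_MAX) and not _has_ties(a, b)
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return StatResult("mann-whitney-u", float(res.statistic), float(res.pvalue),
                      len(a), len(b), False, shapiro_p=shapiro)


def fisher_exact_2x2(table) -> StatResult:
    """Two-sided Fisher exact test on a 2x2 count table.

    Sums hypergeometric probabilities of all tables (same margins) no more
    probable than the observed one.  A zero margin makes the table
    uninformative: p = 1 with a warning.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise StatsError("expected a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(np.int64)
        if np.any(t < 0):
            raise StatsError("counts must be non-negative integers")
    n1, n2 = int(t[0].sum()), int(t[1].sum())
    c1, c2 = int(t[:, 0].sum()), int(t[:, 1].sum())
    if 0 in (n1, n2, c1, c2):
        warnings.warn("2x2 table has an empty margin; Fisher test is uninformative",
                      stacklevel=2)
        return StatResult("fisher-exact", np.nan, 1.0, n1, n2, False,
                          flagged=True, note="zero margin")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return StatResult("fisher-exact", float(odds), float(p), n1, n2, False)


# ---------------------------------------------------------------------------
# Results tables

GROUPINGS = {
    # grouping name -> (column, value for group 1, value for group 2, paired)
    "ibr_vs_delayed": ("arm", "ibr", "delayed_first", False),
    "first_vs_second": ("arm", "delayed_first", "delayed_second", True),
    "prc": ("prc", False, True, False),
}


def build_results_tables(
    cases: pd.DataFrame,
    grouping: str,
    metrics: list[str] | None = None,
    regions: list[str] | None = None,
) -> pd.DataFrame:
    """Group-comparison table: one row per metric x region.

    ``cases`` holds one row per breast with metadata columns (``case_id``,
    ``arm``, ``prc``) and feature columns named ``"<metric>|<region>"``.  The
    paired grouping (first vs second assessment) matches rows by ``case_id``
    and requires a non-empty overlap.  Rows where a group has n < 3 are
    emitted without a p value.
    """
    if grouping not in GROUPINGS:
        raise StatsError(f"unknown grouping {grouping!r}; choose from {sorted(GROUPINGS)}")
    col, v1, v2, paired = GROUPINGS[grouping]
    if col not in cases.columns:
        raise StatsError(f"grouping column {col!r} missing from case table")
    g1 = cases[cases[col] == v1]
    g2 = cases[cases[col] == v2]
    if paired:
        common = pd.Index(g1["case_id"]).intersection(g2["case_id"])
        if len(common) == 0:
            raise StatsError("paired grouping has no case ids present in both groups")
        g1 = g1.set_index("case_id").loc[common]
        g2 = g2.set_index("case_id").loc[common]

    metrics = metrics or TABLE_METRICS
    regions = regions or REGION_ORDER
    rows = []
    for metric in metrics:
        for region in regions:
            feat = f"{metric}|{region}"
            if feat not in cases.columns:
                continue
            x1 = g1[feat].to_numpy(dtype=float)
            x2 = g2[feat].to_numpy(dtype=float)
            x1 = x1[np.isfinite(x1)]
            x2 = x2[np.isfinite(x2)]
            row = {
                "metric": metric,
                "region": region,
                "group1": str(v1),
                "group2": str(v2),
                "mean1": x1.mean() if len(x1) else np.nan,
                "sd1": x1.std(ddof=1) if len(x1) > 1 else np.nan,
                "n1": len(x1),
                "mean2": x2.mean() if len(x2) else np.nan,
                "sd2": x2.std(ddof=1) if len(x2) > 1 else np.nan,
                "n2": len(x2),
            }
            if len(x1) >= 3 and len(x2) >= 3:
                if paired:
                    both = np.isfinite(g1[feat].to_numpy(float)) & np.isfinite(
                        g2[feat].to_numpy(float))
                    res = compare_groups(g1[feat].to_numpy(float)[both],
                                         g2[feat].to_numpy(float)[both], paired=True)
                else:
                    res = compare_groups(x1, x2)
                row["p_value"] = res.p_value
                row["test"] = res.test
                row["significant"] = res.significant
            else:
                row["p_value"] = np.nan
                row["test"] = ""
                row["significant"] = False
            rows.append(row)
    return pd.DataFrame(rows)


def render_report(table: pd.DataFrame, title: str) -> str:
    """Markdown rendering of a results table, mean +/- SD with stars at p<0.05."""
    lines = [f"# {title}", ""]
    lines.append("| metric | region | group 1 (mean ± SD, n) | group 2 (mean ± SD, n) | p |")
    lines.append("|---|---|---|---|---|")
    for _, r in table.iterrows():
        star = "*" if r.get("significant") else ""
        p = f"{r['p_value']:.3f}{star}" if np.isfinite(r["p_value"]) else "-"
        lines.append(
            f"| {r['metric']} | {r['region']} "
            f"| {r['mean1']:.2f} ± {r['sd1']:.2f} (n={r['n1']}) "
            f"| {r['mean2']:.2f} ± {r['sd2']:.2f} (n={r['n2']}) | {p} |"
        )
    lines.append("")
    lines.append("Rank-based tests (Mann-Whitney U / Wilcoxon signed-rank), "
                 "two-sided, * = p < 0.05. No multiple-comparison correction is "
                 "applied across rows; each breast is treated as one record.")
    return "\n".join(lines)
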