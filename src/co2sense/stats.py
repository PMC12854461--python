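"""The study's statistical battery.

Nonparametric group comparisons run a Kruskal-Wallis omnibus gate
followed by all pairwise two-sided Wilcoxon tests (rank-sum for
independent groups, signed-rank for paired designs) with Holm
step-down correction; following the source convention the adjusted
p-values are called Q-values.  Parametric onset-rate comparisons use a
one-way ANOVA, Tukey's HSD over all pairs, and a compact letter display
assembled by the insert-absorb algorithm.  qPCR relative quantification
implements the ddCt and dCt conventions with technical replicates
collapsed by arithmetic mean and amplification efficiency fixed at 2;
per-replicate RQs are rescaled so the calibrator sample's mean RQ is
exactly 1 (under that normalization the two conventions coincide).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ComparisonResult",
    "RQResult",
    "ConstantInputError",
    "holm_adjust",
    "wilcoxon_pair",
    "kw_pairwise_wilcoxon_holm",
    "anova_tukey_cld",
    "letter_display",
    "qpcr_rq",
    "pearson_r",
]


class ConstantInputError(ValueError):
    """A statistic is undefined because an input has zero variance."""


@dataclass
class ComparisonResult:
    omnibus_test: str
    omnibus_statistic: float
    omnibus_p: float
    pairs: pd.DataFrame   # columns: group1, group2, statistic, p, q, test


@dataclass
class RQResult:
    method: str
    reference_gene: str
    calibrator: str
    per_replicate: pd.DataFrame   # columns: sample, bio_replicate, delta_ct, rq
    mean_rq: pd.Series            # sample -> mean RQ (calibrator mean == 1)


# --------------------------------------------------------------------------
# multiple-testing correction
# --------------------------------------------------------------------------

def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (reported as Q-values)."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


# --------------------------------------------------------------------------
# rank-based two-sample tests
# --------------------------------------------------------------------------

def wilcoxon_pair(x, y, paired: bool = False) -> tuple[float, float]:
    """Two-sided Wilcoxon test for one pair of samples.

    Unpaired: Mann-Whitney rank-sum, exact for small samples without
    ties, normal approximation with tie correction otherwise.  Paired:
    signed-rank on the differences (requires equal sizes).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test requires equal sample sizes")
        res = sps.wilcoxon(x, y, alternative="two-sided", method="auto")
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def kw_pairwise_wilcoxon_holm(
    groups: Mapping[str, Sequence[float]],
    paired: bool = False,
) -> ComparisonResult:
    """Kruskal-Wallis omnibus plus all pairwise Wilcoxon tests, Holm-adjusted."""
    labels = list(groups)
    samples = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for k, v in samples.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    if paired:
        sizes = {len(v) for v in samples.values()}
        if len(sizes) > 1:
            raise ValueError("paired comparisons require equal group sizes")
    h, p_omni = sps.kruskal(*samples.values())
    rows = []
    for a, b in combinations(labels, 2):
        stat, p = wilcoxon_pair(samples[a], samples[b], paired=paired)
        rows.append({"group1": a, "group2": b, "statistic": stat, "p": p,
                     "test": "wilcoxon_signed_rank" if paired else "wilcoxon_rank_sum"})
    pairs = pd.DataFrame(rows)
    pairs["q"] = holm_adjust(pairs["p"].to_numpy())
    pairs = pairs[["group1", "group2", "statistic", "p", "q", "test"]]
    return ComparisonResult(
        omnibus_test="kruskal_wallis",
        omnibus_statistic=float(h),
        omnibus_p=float(p_omni),
        pairs=pairs,
    )


# --------------------------------------------------------------------------
# ANOVA + Tukey HSD + compact letter display
# --------------------------------------------------------------------------

def letter_display(labels: Sequence[str],
                   significant_pairs: Sequence[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display by the insert-absorb algorithm.

    Groups sharing a letter are not significantly different; groups in a
    significant pair never share a letter.
    """
    labels = list(labels)
    sig = {frozenset(p) for p in significant_pairs}
    for pair in sig:
        if len(pair) != 2 or not pair <= set(labels):
            raise ValueError(f"bad significant pair {sorted(pair)}")
    columns: list[set[str]] = [set(labels)]
    for pair in sig:
        a, b = sorted(pair, key=labels.index)
        new_cols: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                keep_b = col - {a}
                keep_a = col - {b}
                new_cols.extend([keep_a, keep_b])
            else:
                new_cols.append(col)
        # absorb: drop any column contained in another
        absorbed: list[set[str]] = []
        for col in new_cols:
            if any(col < other or (col == other and col in absorbed)
                   for other in new_cols if other is not col):
                continue
            if col in absorbed:
                continue
            absorbed.append(col)
        columns = absorbed
    columns.sort(key=lambda col: min(labels.index(g) for g in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    if len(columns) > len(alphabet):
        raise ValueError("too many letter groups")
    out = {g: "" for g in labels}
    for letter, col in zip(alphabet, columns):
        for g in labels:
            if g in col:
                out[g] += letter
    return out


def anova_tukey_cld(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, str], dict]:
    """One-way ANOVA, Tukey HSD on all pairs, and the letter display.

    Returns (pairwise table, letters, omnibus dict).  Tukey HSD uses the
    studentized-range distribution with the classical pooled variance.
    """
    labels = list(groups)
    samples = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for k, v in samples.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    pooled_var = np.concatenate(list(samples.values())).var()
    if pooled_var == 0:
        raise ConstantInputError("all observations identical: F undefined")
    f_stat, f_p = sps.f_oneway(*samples.values())
    values = np.concatenate([samples[k] for k in labels])
    group_vec = np.concatenate([[k] * len(samples[k]) for k in labels])
    tk = pairwise_tukeyhsd(values, group_vec, alpha=alpha)
    tbl = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    pairwise = pd.DataFrame({
        "group1": tbl["group1"].astype(str),
        "group2": tbl["group2"].astype(str),
        "mean_diff": tbl["meandiff"].astype(float),
        "p_adj": np.asarray(tk.pvalues, dtype=float),
        "reject": np.asarray(tk.reject, dtype=bool),
    })
    sig = [
        (r.group1, r.group2) for r in pairwise.itertuples() if r.reject
    ]
    letters = letter_display(labels, sig)
    omnibus = {"test": "one_way_anova", "F": float(f_stat), "p": float(f_p)}
    return pairwise, letters, omnibus


# --------------------------------------------------------------------------
# qPCR relative quantification
# --------------------------------------------------------------------------

def qpcr_rq(
    ct: pd.DataFrame,
    reference_gene: str,
    calibrator: str,
    method: str = "ddct",
    target_gene: Optional[str] = None,
) -> RQResult:
    """Relative quantification from a long-format Ct table.

    ``ct`` needs columns gene, sample, bio_replicate, tech_replicate, ct.
    Technical replicates are averaged (arithmetic mean of Ct) first, then
    dCt = Ct_target - Ct_reference per biological replicate.  ddct:
    RQ = 2**-(dCt - mean dCt of the calibrator); dct: 2**-dCt.  In both
    conventions the per-replicate RQs are finally rescaled by the
    calibrator sample's mean RQ, so the calibrator's mean RQ is exactly
    1 (which makes the two conventions numerically identical).
    """
    if method not in ("ddct", "dct"):
        raise ValueError(f"unknown method {method!r}")
    required = {"gene", "sample", "bio_replicate", "tech_replicate", "ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"Ct table missing columns {sorted(required - set(ct.columns))}")
    genes = set(ct["gene"])
    if reference_gene not in genes:
        raise ValueError(f"reference gene {reference_gene!r} not measured")
    if target_gene is None:
        targets = genes - {reference_gene}
        if len(targets) != 1:
            raise ValueError("target_gene must be given when the table has "
                             "more than one non-reference gene")
        target_gene = targets.pop()
    samples = set(ct["sample"])
    if calibrator not in samples:
        raise ValueError(f"calibrator {calibrator!r} not among samples")
    ref_samples = set(ct.loc[ct["gene"] == reference_gene, "sample"])
    if not samples <= ref_samples:
        raise ValueError("reference gene must be measured in every sample")

    tech_mean = (
        ct.groupby(["gene", "sample", "bio_replicate"], sort=False)["ct"]
        .mean()
        .unstack("gene")
    )
    if tech_mean[[target_gene, reference_gene]].isna().any().any():
        raise ValueError("missing gene measurements for some biological replicate")
    dct = (tech_mean[target_gene] - tech_mean[reference_gene]).rename("delta_ct")
    per = dct.reset_index()

    if method == "ddct":
        cal_mean_dct = per.loc[per["sample"] == calibrator, "delta_ct"].mean()
        per["rq"] = 2.0 ** -(per["delta_ct"] - cal_mean_dct)
    else:
        per["rq"] = 2.0 ** -(per["delta_ct"])
    cal_mean_rq = per.loc[per["sample"] == calibrator, "rq"].mean()
    per["rq"] = per["rq"] / cal_mean_rq
    mean_rq = per.groupby("sample", sort=False)["rq"].mean()
    return RQResult(
        method=method,
        reference_gene=reference_gene,
        calibrator=calibrator,
        per_replicate=per,
        mean_rq=mean_rq,
    )


# --------------------------------------------------------------------------
# correlation
# --------------------------------------------------------------------------

def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for constant input")
    return float(sps.pearsonr(x, y).statistic)
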