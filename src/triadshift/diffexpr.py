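"""Expressed-gene calling, differential expression and qualitative changes.

A gene is *expressed in a condition* iff its condition mean reaches the
abundance threshold (default 0.5 FPKM), and *expressed overall* iff it is
expressed in at least one condition. Differential expression between the
reference and test conditions combines a Welch unequal-variance t-test on
log2(x + pseudocount) replicate values with a fold-change gate on the
pseudocounted condition means: a gene is called up (down) iff its
BH-adjusted p is below the FDR level AND |log2FC| exceeds log2(fold).

Qualitative changes trump the quantitative classes: a gene with every
reference replicate below the threshold whose test-condition mean reaches
it is *activated*; the mirror image is *silenced*. These genes are reported
separately from up/down, mirroring the separate accounting of
presence/absence changes versus quantitative regulation.
"""

from __future__ import annotations

from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .errors import DesignMismatchError, ValueOutOfRangeError
from .iodata import ExpressionMatrix

__all__ = [
    "STATUSES",
    "call_expressed",
    "call_qualitative",
    "bh_adjust",
    "test_differential",
    "proportion_test",
    "tally_by_chromosome",
]

#: every gene receives exactly one of these
STATUSES = ("up", "down", "activated", "silenced", "unchanged", "not_expressed")


def call_expressed(matrix: ExpressionMatrix, threshold: float = 0.5) -> pd.DataFrame:
    """Per-gene, per-condition expressed flags plus an ``overall`` column."""
    if threshold < 0:
        raise ValueOutOfRangeError("threshold must be >= 0")
    out = {}
    for cond in matrix.conditions:
        out[cond] = matrix.condition_means(cond) >= threshold
    df = pd.DataFrame(out)
    df["overall"] = df.any(axis=1)
    return df


def call_qualitative(
    matrix: ExpressionMatrix,
    reference: str,
    test: str,
    threshold: float = 0.5,
) -> pd.Series:
    """Activated/silenced calls: presence/absence switches between conditions.

    activated: every reference replicate < threshold AND test mean >= threshold;
    silenced: every test replicate < threshold AND reference mean >= threshold.
    """
    ref = matrix.replicates(reference)
    tst = matrix.replicates(test)
    ref_all_below = (ref.to_numpy() < threshold).all(axis=1)
    tst_all_below = (tst.to_numpy() < threshold).all(axis=1)
    ref_mean_ok = ref.to_numpy().mean(axis=1) >= threshold
    tst_mean_ok = tst.to_numpy().mean(axis=1) >= threshold
    status = np.where(
        ref_all_below & tst_mean_ok,
        "activated",
        np.where(tst_all_below & ref_mean_ok, "silenced", "none"),
    )
    return pd.Series(status, index=matrix.gene_ids, name="qualitative")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueOutOfRangeError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _welch_log_p(ref: np.ndarray, tst: np.ndarray, pseudocount: float) -> np.ndarray:
    """Welch t-test p-values per gene on log2(x + pseudocount) replicates.

    Zero-variance-in-both genes get p = 1 when the means are equal and p = 0
    otherwise (an infinitely confident call, by convention).
    """
    lr = np.log2(ref + pseudocount)
    lt = np.log2(tst + pseudocount)
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant-replicate genes trip scipy's catastrophic-cancellation
        # warning; those p-values are overridden below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = st.ttest_ind(lt, lr, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # exact constant-replicate detection: np.var of identical values is not 0.0
    ref_const = (lr == lr[:, :1]).all(axis=1)
    tst_const = (lt == lt[:, :1]).all(axis=1)
    both_const = ref_const & tst_const
    equal_means = np.isclose(lr.mean(axis=1), lt.mean(axis=1))
    p[both_const & equal_means] = 1.0
    p[both_const & ~equal_means] = 0.0
    # one-sided degeneracies (a single constant group) can still yield NaN
    p[np.isnan(p) & equal_means] = 1.0
    p[np.isnan(p) & ~equal_means] = 0.0
    return p


def test_differential(
    matrix: ExpressionMatrix,
    reference: str,
    test: str,
    pseudocount: float = 1.0,
    fdr: float = 0.05,
    fold: float = 2.0,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Call differential expression of the test condition against the reference.

    Returns a per-gene table with columns ``mean_reference``, ``mean_test``,
    ``log2fc`` (test over reference, pseudocounted means), ``pvalue``,
    ``padj`` (BH over the expressed-overall genes) and ``status`` (one of
    :data:`STATUSES`). Genes not expressed in either condition are
    ``not_expressed`` and carry NaN p-values.
    """
    if fold <= 1:
        raise ValueOutOfRangeError("fold must exceed 1")
    for cond in (reference, test):
        if cond not in matrix.conditions:
            raise DesignMismatchError(f"condition {cond!r} absent from design")
        if len(matrix.samples_for(cond)) < 2:
            raise DesignMismatchError(f"condition {cond!r} has fewer than 2 replicates")

    ref = matrix.replicates(reference).to_numpy()
    tst = matrix.replicates(test).to_numpy()
    mean_ref = ref.mean(axis=1)
    mean_tst = tst.mean(axis=1)
    log2fc = np.log2((mean_tst + pseudocount) / (mean_ref + pseudocount))

    expressed = call_expressed(matrix, threshold)
    overall = expressed["overall"].to_numpy()

    pvalue = np.full(len(mean_ref), np.nan)
    padj = np.full(len(mean_ref), np.nan)
    pvalue[overall] = _welch_log_p(ref[overall], tst[overall], pseudocount)
    if overall.any():
        padj[overall] = bh_adjust(pvalue[overall])

    qual = call_qualitative(matrix, reference, test, threshold).to_numpy()
    cut = np.log2(fold)
    status = np.full(len(mean_ref), "unchanged", dtype=object)
    sig = overall & (padj < fdr)
    status[sig & (log2fc > cut)] = "up"
    status[sig & (log2fc < -cut)] = "down"
    status[qual == "activated"] = "activated"  # qualitative calls take precedence
    status[qual == "silenced"] = "silenced"
    status[~overall] = "not_expressed"

    out = pd.DataFrame(
        {
            "mean_reference": mean_ref,
            "mean_test": mean_tst,
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": padj,
            "status": status,
        },
        index=matrix.gene_ids,
    )
    out.index.name = "gene_id"
    out.attrs["params"] = {
        "reference": reference,
        "test": test,
        "pseudocount": pseudocount,
        "fdr": fdr,
        "fold": fold,
        "threshold": threshold,
    }
    return out


class ProportionTestResult(NamedTuple):
    statistic: float  # Yates-corrected chi-squared, NaN for the exact branch
    pvalue: float
    method: str  # "chi2_yates" or "exact_binomial"


def proportion_test(n_up: int, n_down: int) -> ProportionTestResult:
    """Two-sided one-sample test of n_up/(n_up+n_down) against 0.5.

    The conventional prop-test: chi-squared with Yates continuity correction;
    for small totals (< 50) an exact two-sided binomial test is used instead.
    """
    n_up, n_down = int(n_up), int(n_down)
    if n_up < 0 or n_down < 0:
        raise ValueOutOfRangeError("counts must be non-negative")
    n = n_up + n_down
    if n == 0:
        raise ValueOutOfRangeError("n_up + n_down must be positive")
    if n < 50:
        p = st.binomtest(n_up, n, 0.5).pvalue
        return ProportionTestResult(float("nan"), float(p), "exact_binomial")
    diff = abs(n_up - n / 2.0)
    corr = min(0.5, diff)  # continuity correction never overshoots the null
    stat = (diff - corr) ** 2 / (n / 4.0)
    p = st.chi2.sf(stat, df=1)
    return ProportionTestResult(float(stat), float(p), "chi2_yates")


def tally_by_chromosome(
    degs: pd.DataFrame, gene_locations: Mapping[str, str]
) -> pd.DataFrame:
    """Per-chromosome counts of regulated genes, split by direction.

    Activated genes count toward ``up`` and silenced toward ``down`` (the
    qualitative switches being extreme quantitative changes); genes missing
    from the mapping land in an ``unplaced`` bucket. The per-chromosome
    counts partition the regulated set.
    """
    sel = degs[degs["status"].isin(["up", "down", "activated", "silenced"])]
    chrom = pd.Series(
        [gene_locations.get(g, "unplaced") for g in sel.index], index=sel.index
    )
    direction = sel["status"].map(
        {"up": "up", "activated": "up", "down": "down", "silenced": "down"}
    )
    tab = pd.crosstab(chrom, direction)
    for c in ("up", "down"):
        if c not in tab.columns:
            tab[c] = 0
    tab = tab[["up", "down"]]
    tab["total"] = tab.sum(axis=1)
    tab.index.name = "chromosome"
    return tab.reset_index()
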