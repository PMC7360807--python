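"""Seven-category homoeolog expression-bias classification and shift tracing.

A triad's expression state in one condition is its triple of relative
abundances (a, b, d) = (mA, mB, mD) / (mA + mB + mD) over the three
subgenome members' condition means. Each expressed triad is assigned the
bias category whose idealized profile is nearest in Euclidean distance:

========  ==============  =================
category  meaning         idealized profile
========  ==============  =================
balanced  all three equal (1/3, 1/3, 1/3)
A_dominant    only A      (1, 0, 0)
B_dominant    only B      (0, 1, 0)
D_dominant    only D      (0, 0, 1)
A_suppressed  A missing   (0, 1/2, 1/2)
B_suppressed  B missing   (1/2, 0, 1/2)
D_suppressed  D missing   (1/2, 1/2, 0)
========  ==============  =================

Ties (measure-zero for continuous data, but real in toy examples) break
deterministically in the order above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .errors import EmptyIntersectionError, MissingGeneError, NotOnSimplexError
from .iodata import ExpressionMatrix, TriadMap

__all__ = [
    "CATEGORIES",
    "PROFILES",
    "classify_profiles",
    "classify_triad",
    "normalize_triads",
    "classify_triads",
    "summarize_categories",
    "ShiftMatrix",
    "trace_shifts",
    "cluster_subgenome_profiles",
]

#: fixed category order; also the tie-break order for nearest-profile assignment
CATEGORIES: tuple[str, ...] = (
    "balanced",
    "A_dominant",
    "B_dominant",
    "D_dominant",
    "A_suppressed",
    "B_suppressed",
    "D_suppressed",
)

#: idealized (A, B, D) relative-abundance profile of each category
PROFILES: np.ndarray = np.array(
    [
        [1 / 3, 1 / 3, 1 / 3],
        [1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0],
        [0.0, 0.5, 0.5],
        [0.5, 0.0, 0.5],
        [0.5, 0.5, 0.0],
    ]
)

#: dominant<->suppressed pairs within the same subgenome ("direct opposite" shifts)
_OPPOSITES = frozenset(
    {
        ("A_dominant", "A_suppressed"),
        ("A_suppressed", "A_dominant"),
        ("B_dominant", "B_suppressed"),
        ("B_suppressed", "B_dominant"),
        ("D_dominant", "D_suppressed"),
        ("D_suppressed", "D_dominant"),
    }
)

_SIMPLEX_TOL = 1e-6


def classify_profiles(
    rel: np.ndarray, profiles: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each simplex point the nearest idealized profile.

    Parameters
    ----------
    rel
        Array of shape (n, 3) of relative abundances on the unit simplex.
    profiles
        Optional override of the 7x3 profile matrix (sensitivity analysis).

    Returns
    -------
    (category indices into CATEGORIES, Euclidean distance to the winner)
    """
    rel = np.atleast_2d(np.asarray(rel, dtype=float))
    if rel.shape[1] != 3:
        raise NotOnSimplexError("expected triples (a, b, d)")
    if (rel < -_SIMPLEX_TOL).any() or (np.abs(rel.sum(axis=1) - 1.0) > _SIMPLEX_TOL).any():
        raise NotOnSimplexError("relative abundances must be >= 0 and sum to 1")
    P = PROFILES if profiles is None else np.asarray(profiles, dtype=float)
    d2 = ((rel[:, None, :] - P[None, :, :]) ** 2).sum(axis=2)
    idx = d2.argmin(axis=1)  # argmin takes the first minimum: fixed tie-break order
    dist = np.sqrt(d2[np.arange(len(rel)), idx])
    return idx, dist


def classify_triad(rel, profiles: np.ndarray | None = None) -> str:
    """Category name of a single (a, b, d) triple."""
    idx, _ = classify_profiles(np.asarray(rel, dtype=float)[None, :], profiles)
    return CATEGORIES[int(idx[0])]


def normalize_triads(
    matrix: ExpressionMatrix,
    triads: TriadMap,
    condition: str,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-triad relative abundances of the three members in one condition.

    A triad is *expressed* in the condition iff the sum of its three member
    condition means reaches ``threshold``; non-expressed triads keep NaN
    relative abundances and are excluded from classification downstream.
    """
    means = matrix.condition_means(condition)
    member_ids = triads.gene_ids
    missing = member_ids.difference(means.index)
    if len(missing):
        raise MissingGeneError(
            f"triad members absent from expression matrix: {list(missing[:5])}"
        )
    m = means.loc[member_ids].to_numpy().reshape(-1, 3)
    total = m.sum(axis=1)
    expressed = total >= threshold
    rel = np.full_like(m, np.nan)
    np.divide(m, total[:, None], out=rel, where=total[:, None] > 0)
    return pd.DataFrame(
        {
            "triad_id": triads.table["triad_id"].to_numpy(),
            "condition": condition,
            "mean_A": m[:, 0],
            "mean_B": m[:, 1],
            "mean_D": m[:, 2],
            "total": total,
            "a": rel[:, 0],
            "b": rel[:, 1],
            "d": rel[:, 2],
            "expressed": expressed,
        }
    )


def classify_triads(
    matrix: ExpressionMatrix,
    triads: TriadMap,
    condition: str,
    threshold: float = 0.5,
    syntenic_only: bool = True,
    profiles: np.ndarray | None = None,
) -> pd.DataFrame:
    """Normalize and classify every expressed triad in one condition.

    Non-syntenic triads are excluded by default; pass ``syntenic_only=False``
    to classify them too.
    """
    use = triads.syntenic_only() if syntenic_only else triads
    out = normalize_triads(matrix, use, condition, threshold)
    out["category"] = pd.Series(pd.NA, index=out.index, dtype="object")
    out["distance"] = np.nan
    mask = out["expressed"].to_numpy()
    if mask.any():
        rel = out.loc[mask, ["a", "b", "d"]].to_numpy()
        idx, dist = classify_profiles(rel, profiles)
        out.loc[mask, "category"] = [CATEGORIES[i] for i in idx]
        out.loc[mask, "distance"] = dist
    return out


def summarize_categories(classifications: pd.DataFrame) -> pd.DataFrame:
    """Counts and proportions per category over the expressed triads."""
    expressed = classifications[classifications["expressed"]]
    counts = expressed["category"].value_counts()
    counts = counts.reindex(CATEGORIES, fill_value=0)
    total = int(counts.sum())
    prop = counts / total if total else counts.astype(float)
    return pd.DataFrame(
        {"category": CATEGORIES, "count": counts.to_numpy(), "proportion": prop.to_numpy()}
    )


@dataclass
class ShiftMatrix:
    """7x7 contingency of bias categories between two conditions.

    Rows are the reference-condition category, columns the test-condition
    category, over the triads expressed in both conditions. The diagonal
    holds conserved triads.
    """

    counts: pd.DataFrame  # CATEGORIES x CATEGORIES
    n_direct_opposite: int

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def conserved(self) -> int:
        return int(np.diag(self.counts.to_numpy()).sum())

    @property
    def shifted(self) -> int:
        return self.total - self.conserved

    @property
    def conserved_fraction(self) -> float:
        return self.conserved / self.total

    def reference_margin(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def test_margin(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_long(self) -> pd.DataFrame:
        """Long format (reference_category, test_category, count) for alluvial plots."""
        long = self.counts.stack().rename("count").reset_index()
        long.columns = ["reference_category", "test_category", "count"]
        return long[long["count"] > 0].reset_index(drop=True)


def trace_shifts(ref_cls: pd.DataFrame, test_cls: pd.DataFrame) -> ShiftMatrix:
    """Trace each triad's category from the reference to the test condition.

    Only triads expressed (hence classified) in *both* conditions enter the
    contingency table; the others are dropped from the intersection.
    """
    r = ref_cls[ref_cls["expressed"]].set_index("triad_id")["category"]
    t = test_cls[test_cls["expressed"]].set_index("triad_id")["category"]
    shared = r.index.intersection(t.index)
    if len(shared) == 0:
        raise EmptyIntersectionError("no triads classified in both conditions")
    r = r.loc[shared]
    t = t.loc[shared]
    counts = pd.crosstab(r, t).reindex(index=CATEGORIES, columns=CATEGORIES, fill_value=0)
    counts.index.name = "reference_category"
    counts.columns.name = "test_category"
    n_opp = sum(
        int(counts.loc[a, b]) for (a, b) in _OPPOSITES
    )
    return ShiftMatrix(counts=counts, n_direct_opposite=n_opp)


def cluster_subgenome_profiles(
    matrix: ExpressionMatrix,
    triads: TriadMap,
    conditions: list[str] | None = None,
    syntenic_only: bool = True,
    log: bool = True,
):
    """Correlate and cluster (condition x subgenome) triad-expression vectors.

    For each condition and each subgenome, the vector of the triad members'
    condition means (log2(x+1) by default) is built; Pearson correlations
    between all such vectors are clustered by average linkage on 1 - r.

    Returns
    -------
    dict with ``correlations`` (DataFrame), ``linkage`` (scipy linkage
    matrix, None if fewer than 2 vectors) and ``leaf_order`` (labels).
    """
    use = triads.syntenic_only() if syntenic_only else triads
    conds = conditions if conditions is not None else matrix.conditions
    member_ids = use.gene_ids
    vectors = {}
    for cond in conds:
        means = matrix.condition_means(cond)
        missing = member_ids.difference(means.index)
        if len(missing):
            raise MissingGeneError(
                f"triad members absent from expression matrix: {list(missing[:5])}"
            )
        m = means.loc[member_ids].to_numpy().reshape(-1, 3)
        if log:
            m = np.log2(m + 1.0)
        for j, sub in enumerate("ABD"):
            vectors[f"{cond}_{sub}"] = m[:, j]
    labels = list(vectors)
    X = np.stack([vectors[k] for k in labels])
    corr = pd.DataFrame(np.corrcoef(X), index=labels, columns=labels)
    if len(labels) < 2:
        return {"correlations": corr, "linkage": None, "leaf_order": labels}
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # guard against fp asymmetry
    Z = sch.linkage(squareform(dist, checks=False), method="average")
    order = [labels[i] for i in sch.leaves_list(Z)]
    return {"correlations": corr, "linkage": Z, "leaf_order": order}
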