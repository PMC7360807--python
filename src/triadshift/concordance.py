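"""Concordance between pyrosequencing ratios and RNA-seq relative abundances.

Pyrosequencing reads out the per-triad percentage of transcripts carrying
each subgenome's diagnostic SNP — an orthogonal measurement of the same
(a, b, d) simplex point the RNA-seq classification is built on. "In line
with" is operationalized as a per-triad Euclidean distance on the simplex
no larger than ``max_distance`` (default 0.15), plus a global Pearson
correlation over all paired subgenome fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .errors import MalformedTableError, MissingTriadError

__all__ = ["ConcordanceReport", "concordance_report"]

#: assay rounding slack on the percentage sum
_SUM_TOL = 0.5


@dataclass
class ConcordanceReport:
    table: pd.DataFrame  # per-triad distances and pass flags
    pearson_r: float
    max_distance: float

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def n_pass(self) -> int:
        return int(self.table["passed"].sum())

    @property
    def all_pass(self) -> bool:
        return bool(self.table["passed"].all())

    def summary(self) -> dict:
        return {
            "n_triads": self.n,
            "n_pass": self.n_pass,
            "pearson_r": self.pearson_r,
            "max_distance": self.max_distance,
        }


def concordance_report(
    pyro: pd.DataFrame,
    rnaseq: pd.DataFrame,
    max_distance: float = 0.15,
) -> ConcordanceReport:
    """Compare assayed subgenome percentages against RNA-seq relative abundances.

    Parameters
    ----------
    pyro
        Table with columns triad_id, pct_A, pct_B, pct_D (percentages
        summing to 100 within assay rounding).
    rnaseq
        A classification table (from :func:`~triadshift.homoeobias.classify_triads`)
        for the condition of interest, with columns triad_id, a, b, d,
        expressed.
    max_distance
        Pass threshold on the per-triad simplex Euclidean distance.
    """
    pct = pyro[["pct_A", "pct_B", "pct_D"]].to_numpy(dtype=float)
    if (pct < 0).any():
        raise MalformedTableError("pyro percentages must be non-negative")
    sums = pct.sum(axis=1)
    if (np.abs(sums - 100.0) > _SUM_TOL).any():
        raise MalformedTableError(
            "pyro percentages must sum to 100 within assay rounding"
        )
    cls = rnaseq[rnaseq["expressed"]].set_index("triad_id")
    missing = [t for t in pyro["triad_id"] if t not in cls.index]
    if missing:
        raise MissingTriadError(
            f"assayed triads without RNA-seq classification: {missing[:5]}"
        )
    obs = pct / sums[:, None]  # renormalize: assay rounding
    exp = cls.loc[pyro["triad_id"], ["a", "b", "d"]].to_numpy(dtype=float)
    dist = np.sqrt(((obs - exp) ** 2).sum(axis=1))
    if np.allclose(obs.ravel(), obs.ravel()[0]) or np.allclose(exp.ravel(), exp.ravel()[0]):
        r = float("nan")  # correlation undefined for constant vectors
    else:
        r = float(pearsonr(obs.ravel(), exp.ravel()).statistic)
    table = pd.DataFrame(
        {
            "triad_id": pyro["triad_id"].to_numpy(),
            "obs_a": obs[:, 0],
            "obs_b": obs[:, 1],
            "obs_d": obs[:, 2],
            "rnaseq_a": exp[:, 0],
            "rnaseq_b": exp[:, 1],
            "rnaseq_d": exp[:, 2],
            "distance": dist,
            "passed": dist <= max_distance,
        }
    )
    return ConcordanceReport(table=table, pearson_r=r, max_distance=max_distance)
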