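"""Ground-truth generator for two-condition wheat-like expression data.

The generator emulates the downstream structure of a nonaploid-vs-hexaploid
leaf transcriptome comparison: a gene-by-sample FPKM-scale matrix over two
conditions (3 replicates each), a map of A/B/D homoeolog triads with a known
bias category per condition, singleton genes carrying injected quantitative
(>= 2-fold) and qualitative (activated/silenced) expression changes, a flat
GO-style annotation with one term enriched among the down-shifted genes, and
a pyrosequencing-style table of per-triad subgenome percentages.

Model
-----
Per triad, an intended bias category is drawn per condition from the
configured category weights; a configurable fraction of triads is forced to
differ between conditions ("shifted"). Relative abundances (a, b, d) are
drawn from a Dirichlet centred on the category's idealized profile (zero
components replaced by eps = 0.01 and renormalized) with concentration
kappa; conserved triads reuse one draw for both conditions so that, absent
injected effects, their member means are identical across conditions and
the differential-expression null holds. Triad totals and singleton means are
log-normal; replicates multiply the mean by log-normal noise with a given
coefficient of variation.

Everything is driven by one seed: the same configuration and seed reproduce
the dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InfeasibleConfigError
from .homoeobias import CATEGORIES, PROFILES
from .iodata import ExpressionMatrix, GeneSetAnnotation, TriadMap

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "epsilon_profiles",
    "generate_dataset",
    "generate_pyro_table",
    "DEFAULT_REFERENCE_PROPORTIONS",
    "DEFAULT_TEST_PROPORTIONS",
]


def _normalized(weights: Sequence[float]) -> tuple[float, ...]:
    w = np.asarray(weights, dtype=float)
    return tuple(w / w.sum())


#: hexaploid-role defaults: 72.6% balanced, 6.1% dominant, 21.3% suppressed,
#: each unbalanced class split evenly over its three subgenomes
DEFAULT_REFERENCE_PROPORTIONS: tuple[float, ...] = _normalized(
    [0.726, 0.061 / 3, 0.061 / 3, 0.061 / 3, 0.213 / 3, 0.213 / 3, 0.213 / 3]
)

#: nonaploid-role defaults: 77.5% balanced, 4.3% dominant, 18.3% suppressed
#: (weights normalized: the printed percentages round to a 100.1 total)
DEFAULT_TEST_PROPORTIONS: tuple[float, ...] = _normalized(
    [0.775, 0.043 / 3, 0.043 / 3, 0.043 / 3, 0.183 / 3, 0.183 / 3, 0.183 / 3]
)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic dataset, with study-scale defaults.

    Defaults mirror the downstream shape of the wheat comparison: 9,574
    expressed syntenic triads plus 20,714 singleton genes (49,436 genes in
    total), two conditions x 3 replicates, 25.2% of genes given a >= 2-fold
    shift with 64.2% of them up, 357 activated and 100 silenced genes, and
    18.8% of triads changing bias category between conditions.
    """

    n_triads: int = 9574
    n_singletons: int = 20714
    reference_condition: str = "hexaploid"
    test_condition: str = "nonaploid"
    n_replicates_reference: int = 3
    n_replicates_test: int = 3
    category_proportions_reference: tuple[float, ...] = DEFAULT_REFERENCE_PROPORTIONS
    category_proportions_test: tuple[float, ...] = DEFAULT_TEST_PROPORTIONS
    concentration: float = 200.0  # Dirichlet kappa: tightness around the profile
    epsilon: float = 0.01  # zero-replacement in idealized profiles
    expr_mu: float = 3.0  # ln-scale location of totals (median ~ 20 FPKM)
    expr_sigma: float = 1.2  # ln-scale spread of totals
    rep_cv: float = 0.1  # replicate coefficient of variation
    deg_fraction: float = 0.252  # fraction of all genes given a fold shift
    deg_up_share: float = 0.642  # share of injected shifts that are up
    deg_fold: float = 4.0  # injected fold factor (>= 2)
    n_activated: int = 357
    n_silenced: int = 100
    shift_fraction: float = 0.188  # triads whose category differs between conditions
    expression_threshold: float = 0.5
    n_go_terms: int = 150
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_triads", "n_singletons", "n_activated", "n_silenced", "n_go_terms"):
            if getattr(self, name) < 0:
                raise InfeasibleConfigError(f"{name} must be >= 0")
        for name, w in (
            ("category_proportions_reference", self.category_proportions_reference),
            ("category_proportions_test", self.category_proportions_test),
        ):
            w = np.asarray(w, dtype=float)
            if w.shape != (7,) or (w < 0).any():
                raise InfeasibleConfigError(f"{name} must be 7 non-negative weights")
            if abs(w.sum() - 1.0) > 1e-9:
                raise InfeasibleConfigError(f"{name} must sum to 1 (got {w.sum():.12f})")
        if self.concentration <= 0:
            raise InfeasibleConfigError("concentration must be > 0")
        if not 0 <= self.deg_fraction <= 1:
            raise InfeasibleConfigError("deg_fraction must be in [0, 1]")
        if not 0 <= self.deg_up_share <= 1:
            raise InfeasibleConfigError("deg_up_share must be in [0, 1]")
        if not 0 <= self.shift_fraction <= 1:
            raise InfeasibleConfigError("shift_fraction must be in [0, 1]")
        if self.deg_fold < 2:
            raise InfeasibleConfigError("deg_fold must be >= 2")
        if self.rep_cv < 0:
            raise InfeasibleConfigError("rep_cv must be >= 0")
        if self.expression_threshold <= 0:
            raise InfeasibleConfigError("expression_threshold must be > 0")
        if min(self.n_replicates_reference, self.n_replicates_test) < 1:
            raise InfeasibleConfigError("each condition needs >= 1 replicate")
        if self.reference_condition == self.test_condition:
            raise InfeasibleConfigError("condition names must differ")
        if self.n_activated + self.n_silenced + self.n_injected_degs > self.n_singletons:
            raise InfeasibleConfigError(
                "n_activated + n_silenced + injected DEGs exceed the singleton pool "
                f"({self.n_activated} + {self.n_silenced} + {self.n_injected_degs} "
                f"> {self.n_singletons})"
            )

    @property
    def n_genes(self) -> int:
        return 3 * self.n_triads + self.n_singletons

    @property
    def n_injected_degs(self) -> int:
        return int(round(self.deg_fraction * self.n_genes))

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "GeneratorConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise InfeasibleConfigError(f"unknown generator fields: {sorted(unknown)}")
        cfg = cls(**d)  # type: ignore[arg-type]
        for name in ("category_proportions_reference", "category_proportions_test"):
            setattr(cfg, name, tuple(float(x) for x in getattr(cfg, name)))
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        for name in ("category_proportions_reference", "category_proportions_test"):
            d[name] = list(d[name])
        return d


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset.

    ``triads``: per triad the intended category and the true relative
    abundances in each condition, plus a ``shifted`` flag. ``genes``: per
    gene its stratum (triad member or singleton), injected fold-shift
    direction and qualitative label. Each generated gene appears in exactly
    one stratum row.
    """

    triads: pd.DataFrame
    genes: pd.DataFrame
    config: GeneratorConfig
    enriched_term: str | None = None

    def balanced_triads(self, condition: str = "reference") -> pd.DataFrame:
        col = f"category_{condition}"
        if col not in self.triads.columns:
            raise KeyError(f"condition role must be 'reference' or 'test', got {condition!r}")
        return self.triads[self.triads[col] == "balanced"]

    def genes_with(self, *, deg: str | None = None, qualitative: str | None = None) -> list[str]:
        sel = self.genes
        if deg is not None:
            sel = sel[sel["deg"] == deg]
        if qualitative is not None:
            sel = sel[sel["qualitative"] == qualitative]
        return list(sel["gene_id"])


def epsilon_profiles(epsilon: float = 0.01) -> np.ndarray:
    """The 7 idealized profiles with zeros replaced by eps, renormalized.

    These are the Dirichlet mean vectors: keeping every component positive
    keeps the Dirichlet proper while preserving the extreme dominant and
    suppressed shapes.
    """
    prof = PROFILES.copy()
    prof[prof == 0] = epsilon
    return prof / prof.sum(axis=1, keepdims=True)


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative log-normal noise with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=shape)


def _category_coupling(
    p_ref: np.ndarray, p_tst: np.ndarray, s: float
) -> np.ndarray | None:
    """Joint 7x7 category distribution with margins (p_ref, p_tst) and
    off-diagonal mass exactly ``s``.

    The diagonal interpolates between its feasibility floor
    max(0, (p_ref + p_tst - s)/2) and ceiling min(p_ref, p_tst); the
    off-diagonal block is fitted by iterative proportional scaling to the
    remaining row/column excesses. Returns None when no such joint exists
    (e.g. s below the total-variation distance of the margins).
    """
    mins = np.minimum(p_ref, p_tst)
    lower = np.maximum(0.0, (p_ref + p_tst - s) / 2.0)
    target = 1.0 - s  # diagonal mass
    if not (lower.sum() - 1e-12 <= target <= mins.sum() + 1e-12):
        return None
    denom = (mins - lower).sum()
    gamma = 0.0 if denom <= 0 else (target - lower.sum()) / denom
    diag = lower + np.clip(gamma, 0.0, 1.0) * (mins - lower)
    r = np.maximum(p_ref - diag, 0.0)
    t = np.maximum(p_tst - diag, 0.0)
    off = np.outer(r, t)
    np.fill_diagonal(off, 0.0)
    if off.sum() == 0:
        return np.diag(diag) if s < 1e-12 else None
    for _ in range(500):
        rows = off.sum(axis=1)
        off *= np.divide(r, rows, out=np.ones_like(r), where=rows > 0)[:, None]
        cols = off.sum(axis=0)
        off *= np.divide(t, cols, out=np.ones_like(t), where=cols > 0)[None, :]
        if abs(off.sum(axis=1) - r).max() < 1e-12:
            break
    if abs(off.sum(axis=1) - r).max() > 1e-9 or abs(off.sum(axis=0) - t).max() > 1e-9:
        return None
    joint = np.diag(diag) + off
    return joint / joint.sum()


def _draw_categories(
    rng: np.random.Generator, cfg: GeneratorConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intended category index per triad and condition, plus the shifted mask.

    When a joint coupling with both conditions' marginal proportions and
    ``shift_fraction`` off-diagonal mass exists, categories are drawn from
    it, so each condition's summary matches its configured proportions AND
    the intended-shift fraction is honored. Otherwise (infeasible margins,
    e.g. shift_fraction below their total-variation distance) the reference
    margin and the shift fraction take priority: shifted triads redraw a
    different category from the test-condition weights.
    """
    p_ref = np.asarray(cfg.category_proportions_reference, dtype=float)
    p_tst = np.asarray(cfg.category_proportions_test, dtype=float)
    joint = _category_coupling(p_ref, p_tst, cfg.shift_fraction)
    if joint is not None:
        flat = rng.choice(49, size=cfg.n_triads, p=joint.ravel())
        cat_ref, cat_tst = flat // 7, flat % 7
        return cat_ref, cat_tst, cat_tst != cat_ref
    cat_ref = rng.choice(7, size=cfg.n_triads, p=p_ref)
    shifted = rng.random(cfg.n_triads) < cfg.shift_fraction
    cat_tst = cat_ref.copy()
    for c in range(7):
        idx = np.flatnonzero(shifted & (cat_ref == c))
        if idx.size == 0:
            continue
        w = p_tst.copy()
        w[c] = 0.0  # a shifted triad must land on a different category
        if w.sum() == 0:
            w = np.ones(7)
            w[c] = 0.0
        cat_tst[idx] = rng.choice(7, size=idx.size, p=w / w.sum())
    shifted = cat_tst != cat_ref  # realized flag (empty redraw groups stay put)
    return cat_ref, cat_tst, shifted


def _draw_relative_abundances(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    cat_ref: np.ndarray,
    cat_tst: np.ndarray,
    shifted: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Dirichlet draws around each category's eps-profile.

    Conserved triads share one draw across conditions (see module docstring);
    shifted triads draw independently per condition.
    """
    prof = epsilon_profiles(cfg.epsilon)
    alpha = cfg.concentration * prof
    rel_ref = np.empty((cfg.n_triads, 3))
    for c in range(7):
        idx = np.flatnonzero(cat_ref == c)
        if idx.size:
            rel_ref[idx] = rng.dirichlet(alpha[c], size=idx.size)
    rel_tst = rel_ref.copy()
    for c in range(7):
        idx = np.flatnonzero(shifted & (cat_tst == c))
        if idx.size:
            rel_tst[idx] = rng.dirichlet(alpha[c], size=idx.size)
    return rel_ref, rel_tst


def _qualitative_values(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    n: int,
    n_off_reps: int,
    n_on_reps: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Replicate values for genes off in one condition and on in the other.

    The off side keeps every replicate strictly below the expression
    threshold; the on side is drawn log-normally, floored well above the
    threshold, and rescaled if noise ever drags its realized mean below the
    threshold — the construction guarantees the qualitative call.
    """
    thr = cfg.expression_threshold
    off = rng.uniform(0.0, 0.4 * thr, size=(n, n_off_reps))
    on_mean = np.maximum(rng.lognormal(cfg.expr_mu, cfg.expr_sigma, size=n), 4.0 * thr)
    on = on_mean[:, None] * _lognormal_noise(rng, cfg.rep_cv, (n, n_on_reps))
    realized = on.mean(axis=1)
    low = realized < thr
    if low.any():
        on[low] *= (1.05 * thr / realized[low])[:, None]
    return off, on


def _repair_spurious_qualitative(
    ref_vals: np.ndarray,
    tst_vals: np.ndarray,
    protected: np.ndarray,
    threshold: float,
) -> int:
    """Bump one replicate to the threshold wherever an unlabelled gene would
    satisfy the activated or silenced rule, so the labelled genes are
    recovered *exactly*. Returns the number of repaired genes."""
    repaired = 0
    for off, on in ((ref_vals, tst_vals), (tst_vals, ref_vals)):
        hit = (
            ~protected
            & (off.max(axis=1) < threshold)
            & (on.mean(axis=1) >= threshold)
        )
        idx = np.flatnonzero(hit)
        if idx.size:
            off[idx, off[idx].argmax(axis=1)] = threshold
            repaired += idx.size
    return repaired


def _generate_annotation(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    gene_ids: np.ndarray,
    down_genes: np.ndarray,
) -> tuple[GeneSetAnnotation, str | None]:
    """Flat GO-style annotation; term sizes log-uniform in [10, 500].

    The first term is deliberately over-represented among the injected
    down-shifted genes (half of its members drawn from that list), mirroring
    a down-regulated functional module."""
    n_genes = len(gene_ids)
    if cfg.n_go_terms == 0:
        return GeneSetAnnotation(pd.DataFrame({"gene_id": [], "term_id": []})), None
    lo, hi = np.log(10.0), np.log(500.0)
    sizes = np.round(np.exp(rng.uniform(lo, hi, size=cfg.n_go_terms))).astype(int)
    sizes = np.minimum(sizes, n_genes)
    genes_col, terms_col = [], []
    enriched_term: str | None = None
    for t, size in enumerate(sizes):
        term = f"GO:{t:07d}"
        if t == 0 and len(down_genes) > 0:
            enriched_term = term
            k_down = min(size // 2, len(down_genes))
            members = np.concatenate(
                [
                    rng.choice(down_genes, size=k_down, replace=False),
                    rng.choice(gene_ids, size=size - k_down, replace=False),
                ]
            )
            members = pd.unique(members)
        else:
            members = rng.choice(gene_ids, size=size, replace=False)
        genes_col.extend(members)
        terms_col.extend([term] * len(members))
    ann = GeneSetAnnotation(pd.DataFrame({"gene_id": genes_col, "term_id": terms_col}))
    return ann, enriched_term


def generate_dataset(
    config: GeneratorConfig | None = None,
) -> tuple[ExpressionMatrix, TriadMap, GeneSetAnnotation, SyntheticTruth]:
    """Generate a complete two-condition dataset with ground truth.

    Returns the expression matrix (with design), the triad map, the GO-style
    annotation and the :class:`SyntheticTruth`. Fixed config + seed give
    bit-identical output.
    """
    cfg = config if config is not None else GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    thr = cfg.expression_threshold
    nr, nt = cfg.n_replicates_reference, cfg.n_replicates_test

    # --- triads: categories, relative abundances, totals ---------------------
    cat_ref, cat_tst, shifted = _draw_categories(rng, cfg)
    rel_ref, rel_tst = _draw_relative_abundances(rng, cfg, cat_ref, cat_tst, shifted)
    totals = rng.lognormal(cfg.expr_mu, cfg.expr_sigma, size=cfg.n_triads)
    triad_ref_means = (totals[:, None] * rel_ref).ravel()  # triad-major A,B,D
    triad_tst_means = (totals[:, None] * rel_tst).ravel()

    triad_ids = np.array([f"triad{i:05d}" for i in range(cfg.n_triads)])
    gene_A = np.array([f"t{i:05d}A" for i in range(cfg.n_triads)])
    gene_B = np.array([f"t{i:05d}B" for i in range(cfg.n_triads)])
    gene_D = np.array([f"t{i:05d}D" for i in range(cfg.n_triads)])
    triad_gene_ids = np.stack([gene_A, gene_B, gene_D], axis=1).ravel()
    singleton_ids = np.array([f"s{i:05d}" for i in range(cfg.n_singletons)])

    # --- singletons: qualitative labels and injected fold shifts --------------
    base = rng.lognormal(cfg.expr_mu, cfg.expr_sigma, size=cfg.n_singletons)
    perm = rng.permutation(cfg.n_singletons)
    n_act, n_sil, n_deg = cfg.n_activated, cfg.n_silenced, cfg.n_injected_degs
    act_idx = perm[:n_act]
    sil_idx = perm[n_act : n_act + n_sil]
    deg_idx = perm[n_act + n_sil : n_act + n_sil + n_deg]
    n_up = int(round(cfg.deg_up_share * n_deg))
    up_idx, down_idx = deg_idx[:n_up], deg_idx[n_up:]

    sing_ref_means = base.copy()
    sing_tst_means = base.copy()
    # floor injected genes so both condition means stay safely expressed
    sing_ref_means[up_idx] = np.maximum(sing_ref_means[up_idx], 2.0 * thr)
    sing_tst_means[up_idx] = sing_ref_means[up_idx] * cfg.deg_fold
    sing_ref_means[down_idx] = np.maximum(sing_ref_means[down_idx], 2.0 * thr * cfg.deg_fold)
    sing_tst_means[down_idx] = sing_ref_means[down_idx] / cfg.deg_fold

    # --- replicate values -----------------------------------------------------
    mean_ref = np.concatenate([triad_ref_means, sing_ref_means])
    mean_tst = np.concatenate([triad_tst_means, sing_tst_means])
    n_genes = cfg.n_genes
    ref_vals = mean_ref[:, None] * _lognormal_noise(rng, cfg.rep_cv, (n_genes, nr))
    tst_vals = mean_tst[:, None] * _lognormal_noise(rng, cfg.rep_cv, (n_genes, nt))

    off_act, on_act = _qualitative_values(rng, cfg, n_act, nr, nt)
    off_sil_on, on_sil_off = _qualitative_values(rng, cfg, n_sil, nt, nr)
    g_act = 3 * cfg.n_triads + act_idx
    g_sil = 3 * cfg.n_triads + sil_idx
    ref_vals[g_act], tst_vals[g_act] = off_act, on_act
    ref_vals[g_sil], tst_vals[g_sil] = on_sil_off, off_sil_on

    protected = np.zeros(n_genes, dtype=bool)
    protected[g_act] = True
    protected[g_sil] = True
    _repair_spurious_qualitative(ref_vals, tst_vals, protected, thr)

    # --- assemble artifacts ---------------------------------------------------
    gene_ids = np.concatenate([triad_gene_ids, singleton_ids])
    ref_cols = [f"{cfg.reference_condition}_{r + 1}" for r in range(nr)]
    tst_cols = [f"{cfg.test_condition}_{r + 1}" for r in range(nt)]
    values = pd.DataFrame(
        np.hstack([ref_vals, tst_vals]), index=pd.Index(gene_ids, name="gene_id"),
        columns=ref_cols + tst_cols,
    )
    design = pd.DataFrame(
        {
            "condition": [cfg.reference_condition] * nr + [cfg.test_condition] * nt,
            "replicate": list(range(1, nr + 1)) + list(range(1, nt + 1)),
        },
        index=pd.Index(ref_cols + tst_cols, name="sample_id"),
    )
    matrix = ExpressionMatrix(values=values, design=design)
    triad_map = TriadMap(
        pd.DataFrame(
            {
                "triad_id": triad_ids,
                "gene_A": gene_A,
                "gene_B": gene_B,
                "gene_D": gene_D,
                "syntenic": True,
            }
        )
    )

    deg_label = np.full(cfg.n_singletons, "none", dtype=object)
    deg_label[up_idx] = "up"
    deg_label[down_idx] = "down"
    qual_label = np.full(cfg.n_singletons, "none", dtype=object)
    qual_label[act_idx] = "activated"
    qual_label[sil_idx] = "silenced"
    genes_truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "stratum": ["triad_member"] * (3 * cfg.n_triads) + ["singleton"] * cfg.n_singletons,
            "triad_id": list(np.repeat(triad_ids, 3)) + [""] * cfg.n_singletons,
            "subgenome": list(np.tile(["A", "B", "D"], cfg.n_triads)) + [""] * cfg.n_singletons,
            "deg": ["none"] * (3 * cfg.n_triads) + list(deg_label),
            "qualitative": ["none"] * (3 * cfg.n_triads) + list(qual_label),
        }
    )
    cat_names = np.asarray(CATEGORIES, dtype=object)
    triads_truth = pd.DataFrame(
        {
            "triad_id": triad_ids,
            "category_reference": cat_names[cat_ref],
            "category_test": cat_names[cat_tst],
            "shifted": shifted,
            "a_reference": rel_ref[:, 0],
            "b_reference": rel_ref[:, 1],
            "d_reference": rel_ref[:, 2],
            "a_test": rel_tst[:, 0],
            "b_test": rel_tst[:, 1],
            "d_test": rel_tst[:, 2],
            "total": totals,
        }
    )

    down_genes = singleton_ids[down_idx]
    annotation, enriched_term = _generate_annotation(rng, cfg, gene_ids, down_genes)
    truth = SyntheticTruth(
        triads=triads_truth, genes=genes_truth, config=cfg, enriched_term=enriched_term
    )
    return matrix, triad_map, annotation, truth


def generate_pyro_table(
    truth: SyntheticTruth,
    n_triads_assayed: int = 18,
    pyro_noise_sd: float = 3.0,
    condition: str = "reference",
    seed: int | None = None,
) -> pd.DataFrame:
    """Pyrosequencing-style subgenome percentages for balanced triads.

    Arbitrarily (but reproducibly) selects ``n_triads_assayed`` triads whose
    intended category in ``condition`` ('reference' or 'test') is balanced,
    and reports their true relative abundances as percentages with additive
    zero-truncated Gaussian noise (sd ``pyro_noise_sd``, percent units),
    renormalized to sum to 100.
    """
    balanced = truth.balanced_triads(condition)
    if n_triads_assayed > len(balanced):
        raise InfeasibleConfigError(
            f"requested {n_triads_assayed} assayed triads but only "
            f"{len(balanced)} balanced triads exist"
        )
    if pyro_noise_sd < 0:
        raise InfeasibleConfigError("pyro_noise_sd must be >= 0")
    rng = np.random.default_rng(truth.config.seed + 10007 if seed is None else seed)
    pick = rng.choice(len(balanced), size=n_triads_assayed, replace=False)
    rows = balanced.iloc[np.sort(pick)]
    rel = rows[[f"{c}_{condition}" for c in ("a", "b", "d")]].to_numpy()
    pct = rel * 100.0
    if pyro_noise_sd > 0:
        pct = np.maximum(pct + rng.normal(0.0, pyro_noise_sd, size=pct.shape), 0.0)
    pct = pct / pct.sum(axis=1, keepdims=True) * 100.0
    return pd.DataFrame(
        {
            "triad_id": rows["triad_id"].to_numpy(),
            "pct_A": pct[:, 0],
            "pct_B": pct[:, 1],
            "pct_D": pct[:, 2],
            "snp_label": [f"SNP_{t}" for t in rows["triad_id"]],
        }
    )
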