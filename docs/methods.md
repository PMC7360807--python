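# Methods

This note documents the statistical procedures triadshift implements, the
model behind its synthetic-data generator, the defaults and why they were
chosen, and what the package deliberately does not do.

## Differential expression

The pipeline starts from an FPKM-scale gene-by-sample matrix; read
alignment and abundance estimation are upstream of it. A gene is
*expressed in a condition* when its condition mean reaches the expression
threshold (default **0.5 FPKM** — the threshold is not standardized across
studies, so it is a prominent, configurable parameter), and *expressed
overall* when expressed in at least one condition.

Between a reference and a test condition, each expressed-overall gene is
tested with **Welch's unequal-variance t-test on log2(x + pseudocount)**
replicate values (pseudocount default 1.0), followed by Benjamini–Hochberg
adjustment across the expressed-overall genes. A gene is called **up**
(**down**) when its adjusted *p* is below the FDR level (default 0.05)
*and* the fold change of the pseudocounted condition means exceeds the
fold cutoff (default 2, i.e. |log2FC| > 1). The fold criterion is
interpreted as a linear ratio. This simple replicate-level test was chosen
deliberately over re-implementing any specific DE tool's dispersion model:
the calling criterion (FDR-adjusted *p* < 0.05 plus fold change > 2) is the
contract, and a transparent test keeps the criterion auditable. With three
replicates per condition, Welch's test is conservative; genes with constant
replicates in both conditions get *p* = 1 when the means are equal and
*p* = 0 otherwise, by convention (NumPy's variance of identical values is
not exactly zero, so constancy is detected by equality, not by `var == 0`).

**Qualitative changes trump quantitative ones.** A gene is **activated**
when every reference replicate lies below the expression threshold and the
test-condition mean reaches it; **silenced** is the mirror image.
Activated/silenced genes are excluded from the up/down classes and
reported separately, because a presence/absence switch is a different
biological statement than a fold change, and because pseudocounted fold
changes on near-zero baselines are not meaningful. Every gene therefore
carries exactly one status: up, down, activated, silenced, unchanged or
not_expressed.

The **up-vs-down proportion test** is the conventional one-sample prop
test of n_up/(n_up+n_down) against 0.5: chi-squared with Yates continuity
correction (the correction is clipped so a perfectly balanced split gives
*p* = 1), with an exact two-sided binomial fallback when fewer than 50
genes are being compared. Per-chromosome tallies count up+activated and
down+silenced genes per chromosome label, with genes missing from the
location map collected in an `unplaced` bucket.

## Homoeolog expression bias

Per triad and condition the three members' condition means (m_A, m_B, m_D)
are normalized to relative abundances on the unit simplex. A triad is
expressed in a condition when m_A + m_B + m_D reaches the expression
threshold; only triads expressed in a condition are classified there, and
only triads expressed in *both* conditions enter shift tracing. Condition
means (not per-replicate values) feed the normalization, matching how
FPKM-based cluster and bias analyses are usually run.

Classification is **nearest idealized profile in Euclidean distance**
among seven fixed centroids: balanced (1/3, 1/3, 1/3), X-dominant (the
unit vectors) and X-suppressed (zero for X, 1/2 elsewhere), for
X ∈ {A, B, D}. Ties — measure-zero for continuous data but real in toy
examples — break deterministically in the order balanced, A-, B-,
D-dominant, A-, B-, D-suppressed. The profiles are module constants but
can be overridden for sensitivity analysis. Classification is invariant to
any common positive rescaling of the expression matrix.

Shift tracing builds the 7×7 contingency of (reference category → test
category) over the shared expressed triads; the diagonal is the conserved
set, and dominant↔suppressed transitions within the same subgenome are
additionally counted as "direct opposite" shifts. Non-syntenic triads are
excluded by default (the analysis concerns syntenic triads), with a flag
to include them. Subgenome-level structure is summarized by Pearson
correlation of per-(condition × subgenome) vectors of log2(mean + 1)
member abundances, clustered by average linkage on 1 − r.

## Gene-set enrichment

Over-representation of a query gene set (a DEG class, the activated or the
silenced list) in a flat gene→term annotation is tested with the exact
upper hypergeometric tail P(X ≥ k) for k query hits among K annotated
genes, a query of n and a population of N. The **population is the
expressed-overall gene set**, not the whole annotation universe — testing
DEGs against genes that could never have been called is the classic way to
manufacture spurious enrichment. Terms are restricted to the population
and filtered to 5 ≤ K ≤ 2000 (both configurable) before testing; BH runs
across exactly the tested terms. Only over-representation is tested. GO
DAG propagation and term-ancestry handling are out of scope: annotations
are tested as provided.

## Pyrosequencing concordance

Pyrosequencing of subgenome-diagnostic SNPs yields per-triad percentages
of transcripts from each subgenome — an orthogonal readout of the same
simplex point the RNA-seq classification uses. Because "in line with" has
no canonical numeric form, it is operationalized as: per-triad Euclidean
distance between the renormalized assay fractions and the RNA-seq relative
abundances **≤ 0.15** (configurable), plus a global Pearson correlation
over all paired fractions. Assay percentages are accepted when they sum to
100 within 0.5 (assay rounding) and renormalized exactly before
comparison. For reference, 0.15 corresponds to ~8.7 percentage points of
disagreement spread over three subgenomes; with balanced triads (the only
ones assayable with a single diagnostic SNP per subgenome) and a few
percent of assay noise, true concordance lands well inside this bound
while a genuine category disagreement (e.g. balanced vs suppressed,
centroid distance 0.41) lands far outside it.

## The synthetic-data generator

The generator emulates the downstream structure of a nonaploid-vs-hexaploid
leaf comparison; its defaults are the study-scale conditions:

| parameter | default | meaning |
|---|---|---|
| n_triads | 9,574 | expressed syntenic triads |
| n_singletons | 20,714 | non-triad genes (total 49,436) |
| replicates | 3 + 3 | reference and test condition |
| category proportions (ref) | 72.6 / 6.1 / 21.3 % | balanced / dominant / suppressed, unbalanced split evenly over subgenomes |
| category proportions (test) | 77.5 / 4.3 / 18.3 % | weights normalized; the printed values round to 100.1 % |
| shift_fraction | 0.188 | triads whose intended category differs between conditions |
| concentration κ | 200 | Dirichlet tightness around the category centroid |
| expr_mu, expr_sigma | 3.0, 1.2 | ln-scale location/spread of triad totals and singleton means (median ≈ 20 FPKM, a plausible leaf-transcriptome scale; no distributional ground truth exists for these) |
| rep_cv | 0.10 | replicate coefficient of variation (consistent with replicate correlations ≥ 0.96) |
| deg_fraction | 0.252 | injected ≥ 2-fold shifts, as a fraction of all genes |
| deg_up_share | 0.642 | injected shifts that are up |
| deg_fold | 4 | injected fold factor |
| n_activated / n_silenced | 357 / 100 | qualitative switches |

**Categories.** Intended per-triad categories for the two conditions are
drawn jointly from a 7×7 coupling whose margins are the two conditions'
configured proportions and whose off-diagonal mass is exactly
`shift_fraction`: the diagonal interpolates between its feasibility floor
and ceiling, and the off-diagonal block is fitted by iterative
proportional scaling. This honors all three published summaries at once —
each condition's category proportions and the conserved fraction. When no
such coupling exists (`shift_fraction` below the total-variation distance
of the margins, e.g. a zero-shift null with unequal margins), the
reference margin and the shift fraction take priority and shifted triads
redraw a different category from the test-condition weights.

**Abundances.** Relative abundances are Dirichlet draws with mean equal to
the category centroid (zeros replaced by ε = 0.01 and renormalized, which
keeps the Dirichlet proper while preserving the extreme shapes) and
concentration κ. **Conserved triads reuse one draw for both conditions;
only shifted triads draw per condition.** This is a deliberate model
choice: with independent per-condition draws, every conserved triad would
carry a real (if small) between-condition mean difference, and the
"no injected effects" configuration would not actually be a null for the
differential-expression stage. Triad totals are log-normal and shared
between conditions; member means are total × relative abundance;
replicates multiply means by log-normal noise with mean 1 and CV rep_cv.
Values are FPKM-scale log-normals rather than negative-binomial counts
because the pipeline operates on FPKM values, not raw counts; technical
and biological replicates are not distinguished, matching the 3-vs-3
design being emulated.

**Injected effects** live among singleton genes so the triad truth stays
exact: fold shifts multiply or divide the test-condition mean by
`deg_fold` (base means floored at 2×threshold×fold so injected genes stay
expressed on both sides); activated genes get uniform sub-threshold
reference replicates and a log-normal test mean floored at 4×threshold
(rescaled in the rare case noise drags the realized mean below threshold);
silenced genes mirror this. A final repair pass bumps one replicate to the
threshold for any *unlabelled* gene that would satisfy the qualitative
rule — mostly members of bias-shifted triads whose homoeolog genuinely
crosses the threshold — so the labelled activated/silenced sets are
recovered *exactly*, which the tests rely on. Consequence worth knowing:
because category shifts produce genuine expression changes in triad
members, the realized fraction of regulated genes exceeds `deg_fraction`
(≈ 33 % against 25.2 % injected at the defaults); the injected set itself
is recovered with its configured size and direction split.

The GO-style annotation draws term sizes log-uniformly in [10, 500] and
members uniformly, with the first term deliberately over-represented
among the injected down-shifted genes (half of its members), mirroring a
down-regulated functional module. The pyrosequencing table picks balanced
triads reproducibly, adds zero-truncated Gaussian noise (default sd 3
percentage points) to the true percentages and renormalizes rows to 100.

Everything flows from one integer seed; identical config + seed give
bit-identical output.

**What the generator does not emulate** — and hence what green tests do
not demonstrate about real data: count-level sampling noise and
mean–dispersion coupling; transcriptome-size differences between ploidies
(fold changes are simulated around an unchanged global scale, so the
package, like the analysis it reproduces, would understate DEGs if total
mRNA per cell changed); correlated expression between triad members and
genomic neighbors; annotation DAG structure; chromosome assignments
(location maps are supplied externally). Distributional defaults for FPKM
levels are plausibility choices, not fits to wheat data.

## Numerical and testing choices

- BH adjustment delegates to `statsmodels.multipletests("fdr_bh")`, the
  hypergeometric tail to `scipy.stats.hypergeom.sf`, Welch's test to
  `scipy.stats.ttest_ind`, the exact binomial to `scipy.stats.binomtest`
  and clustering to `scipy.cluster.hierarchy`; the test suite checks each
  against independent brute-force enumeration (exact integer arithmetic
  where possible) rather than against the same library.
- Simplex membership is validated with tolerance 1e-6; classification ties
  resolve by the fixed category order (first minimum).
- The hypergeometric tail is clipped into (0, 1] — the exact tail of an
  admissible configuration is positive even when the floating-point
  survival function underflows.
- Degenerate inputs have defined behaviour: all-zero triads are flagged
  not-expressed and excluded; a zero-variance gene pair yields p ∈ {0, 1}
  as above; an empty enrichment query or an empty shift intersection is an
  error, not an empty result.
- Test problem sizes are scaled to keep the full suite around a minute on
  one core (e.g. classification recovery runs at the full 9,574 triads
  but the DEG-recall run uses 16,000 genes); the acceptance script runs
  the synthetic pipeline at the full study scale.

## Known limitations

- The expressed-gene criterion (0.5 FPKM on condition means) is a
  convention, not a reproduction of any specific tool's internal call;
  absolute expressed-gene counts depend on it.
- With three replicates, Welch's test has little power for fold changes
  near the gate; recall guarantees in the tests hold for strong (≥ 8-fold)
  injected effects.
- The concordance criterion (distance ≤ 0.15) is a package convention for
  "in line with"; the reported global correlation should be read alongside
  it, and is attenuated when all assayed triads are balanced (little
  between-triad variance).
- One-condition designs, multi-condition (> 2) contrasts and isoform-level
  analysis are out of scope.
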