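# triadshift

Transcriptome dysregulation and homoeolog expression-bias analysis for
allopolyploid wheat, built for two-condition comparisons such as a
nonaploid (BBBAAADDD) individual against its isogenic hexaploid (BBAADD)
siblings.

Bread wheat carries three related subgenomes (A, B, D); many genes exist as
**triads** — one homoeologous copy per subgenome in 1:1:1 correspondence.
Two questions drive this package:

1. **How much of the transcriptome is dysregulated** between two conditions
   or ploidy states? Differential expression is called on an FPKM-scale
   gene-by-sample matrix with the twofold criterion (BH-adjusted *p* < 0.05
   **and** fold change > 2), and qualitative switches are reported
   separately: a gene is *activated* when every reference replicate is below
   the expression threshold but the test-condition mean reaches it, and
   *silenced* in the mirror case.
2. **Is the relative contribution of the three homoeologs preserved?** Per
   triad and condition the relative abundances
   (a, b, d) = (m_A, m_B, m_D) / (m_A + m_B + m_D) are computed from
   condition means and the triad is assigned one of seven bias categories
   by minimal Euclidean distance to idealized profiles: balanced
   (1/3, 1/3, 1/3), single-homoeolog dominant — e.g. A-dominant (1, 0, 0) —
   and single-homoeolog suppressed — e.g. A-suppressed (0, 1/2, 1/2).
   Category shifts between conditions are traced in a 7×7 contingency
   (alluvial) matrix.

Around this core: hypergeometric GO over-representation tests of any DEG
class against the expressed background (P(X ≥ k) under
hypergeometric(N, K, n), BH across terms), concordance checks of RNA-seq
relative abundances against pyrosequencing-style subgenome percentages, and
a seeded synthetic-data generator that emulates the full study structure
(49,436 genes, 9,574 syntenic triads, 3 + 3 replicates, injected fold
shifts, activations/silencings and bias-category shifts) with exact ground
truth, so the entire pipeline is testable without any data download.

## Worked example

```python
import triadshift as ts

cfg = ts.GeneratorConfig(n_triads=1000, n_singletons=2000, n_activated=30,
                         n_silenced=10, deg_fraction=0.1, seed=42)
matrix, triads, annotation, truth = ts.generate_dataset(cfg)

deg = ts.test_differential(matrix, "hexaploid", "nonaploid", fdr=0.05, fold=2.0)
print(deg["status"].value_counts().to_dict())

cls_hex = ts.classify_triads(matrix, triads, "hexaploid")
cls_non = ts.classify_triads(matrix, triads, "nonaploid")
print(ts.summarize_categories(cls_hex).to_string(index=False))

shifts = ts.trace_shifts(cls_hex, cls_non)
print(f"traced={shifts.total} conserved={shifts.conserved} "
      f"({100 * shifts.conserved_fraction:.1f}%)")

pyro = ts.generate_pyro_table(truth, n_triads_assayed=18, pyro_noise_sd=3.0)
rep = ts.concordance_report(pyro, cls_hex, max_distance=0.15)
print(f"concordance: {rep.n_pass}/{rep.n} pass, r={rep.pearson_r:.3f}")
```

prints

```
{'unchanged': 4035, 'up': 471, 'down': 290, 'not_expressed': 164, 'activated': 30, 'silenced': 10}
    category  count  proportion
    balanced    718    0.718719
  A_dominant     21    0.021021
  B_dominant     18    0.018018
  D_dominant     32    0.032032
A_suppressed     74    0.074074
B_suppressed     70    0.070070
D_suppressed     66    0.066066
traced=999 conserved=810 (81.1%)
concordance: 18/18 pass, r=0.737
```

Reading this: of 5,000 generated genes, 761 pass the twofold + FDR gate
(the 500 injected shifts plus members of triads whose bias category truly
changed), and the 30 activated / 10 silenced genes are recovered exactly.
In the hexaploid role ~72% of expressed triads are balanced, suppressed
categories outnumber dominant ones, 81.1% of triads keep their category
across conditions, and all 18 assayed balanced triads agree with the
RNA-seq relative abundances within a simplex distance of 0.15.

The same stages are available from the shell:

```bash
triadshift simulate --config gen.yaml --out data/
triadshift deg --matrix data/matrix.tsv --design data/design.tsv \
    --ref hexaploid --test nonaploid --fold 2 --fdr 0.05 --out deg.tsv
triadshift bias --matrix data/matrix.tsv --design data/design.tsv \
    --triads data/triads.tsv --ref hexaploid --test nonaploid --out-prefix bias
triadshift enrich --query down.txt --annotation data/annotation.tsv \
    --population expressed.txt --out enr.tsv
triadshift concord --pyro data/pyro.tsv --bias bias_classification_hexaploid.tsv \
    --out concord.tsv
triadshift run --config pipeline.yaml   # everything, one YAML, one seed
```

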