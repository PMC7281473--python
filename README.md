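# retinomimic

Analysis pipeline for studying how breast-cancer cell lines respond to
all-trans retinoic acid (ATRA), the active vitamin A metabolite and pan-RAR
agonist. Sensitive lines respond to the retinoid with a "viral mimicry"
program: endogenous retrovirus (ENV) transcripts are reactivated and drive
interferon-stimulated and antigen-presentation gene expression without any
exogenous virus. The package is aimed at computational biologists who want
the bespoke statistics of that analysis — the drug-sensitivity score, the
repeat-element quantification, the sensitivity-association screen and the
gene-set layer — as tested, reusable, scikit-learn-style components, with a
synthetic-data generator that reproduces the study design (16 cell lines, 8
luminal / 8 basal, vehicle vs ATRA, triplicates) with known ground truth.

## What it computes

**ATRA-score** (`retinomimic.dose_response`). From replicate viability
fractions over a log-spaced dose grid (five concentrations, 0.001–10 µM),
each line's growth-inhibition curve gives

* AUC — the trapezoidal mean inhibition over log10(concentration),
  normalized to [0, 1];
* Amax — the maximal per-dose mean inhibition;
* ATRA-score — log2(AUC × Amax), min-max rescaled across the cohort so 0 is
  total resistance and 1 maximal sensitivity.

Lines split into HIGH/LOW groups at a 0.17 score threshold (ties are LOW),
or into HIGH/INTERMEDIATE/LOW ternary classes.

**Repeat annotation** (`retinomimic.annotation`). RepeatMasker-style repeat
intervals are merged with a gene/exon GTF; any repeat sharing ≥ 1 bp with a
gene-associated exon (strand-agnostic, 1-based inclusive coordinates) is
discarded as a false-positive guard. Survivors are grouped into repeat
families and one all-member meta-gene, and written as a custom GTF.

**Differential expression** (`retinomimic.counts_de`). Median-of-ratios
size factors, per-feature negative-binomial dispersions (method-of-moments
shrunk toward a mean–dispersion trend), a vectorized NB Wald test of
ATRA vs DMSO (t reference with n − 2 df), independent filtering of low-count
features, and Benjamini–Hochberg FDR. The same machinery serves genes and
TE families.

**Sensitivity association** (`retinomimic.sensitivity`). Per gene, the
per-line ATRA/DMSO log2 fold-change is correlated with the per-line
ATRA-score; genes pass with BH-adjusted correlation p < FDR, |r| above a
floor and enough usable lines, and split into up/down sets by slope sign.

**Viral-mimicry readout** (`retinomimic.te_mimicry`). Family-level
induction (instance-count sums), per-line median ENV induction (median of
linear family fold-changes), and per-subtype ordinary least squares of the
median induction on the ATRA-score, reported as R² — the statistic that
separates score-coupled (basal) from score-independent (luminal) ENV
activation.

**Gene-set layer** (`retinomimic.enrichment`). Pre-ranked competitive
testing (two-sided Wilcoxon rank-sum of in-set vs out-of-set statistics,
BH across the collection) and single-sample GSEA: with genes ranked by
decreasing expression, the score is the summed difference between the
weighted in-set ECDF (weights |expression|^α, α = 0.25) and the out-of-set
ECDF. HIGH vs LOW cohorts are compared per set with Welch t-tests.

## Worked example

```python
from retinomimic import SimulationConfig, simulate_study, AtraScorer

study = simulate_study(SimulationConfig(), seed=17)
scorer = AtraScorer(threshold=0.17).fit(study.assays)
print(scorer.scores_.round(4).head(8).to_string())
```

```
              auc    amax  log2_product  atra_score binary_class sensitivity_class
cell_line
LUM01      0.0119  0.0295      -11.4754      0.0000          LOW               LOW
LUM02      0.0338  0.1683       -7.4565      0.3837         HIGH      INTERMEDIATE
LUM03      0.0604  0.2825       -5.8732      0.5349         HIGH              HIGH
LUM04      0.1082  0.4496       -4.3613      0.6792         HIGH              HIGH
LUM05      0.1871  0.6046       -3.1441      0.7954         HIGH              HIGH
LUM06      0.2833  0.7266       -2.2802      0.8779         HIGH              HIGH
LUM07      0.3949  0.8031       -1.6569      0.9374         HIGH              HIGH
LUM08      0.5344  0.9063       -1.0458      0.9957         HIGH              HIGH
```

The least sensitive line anchors 0, the most sensitive 1, and scores rise
monotonically with the planted potency. The full pipeline — simulate,
score, build the exon-filtered repeat annotation, test differential
expression, screen score-associated genes, quantify ENV induction and run
the gene-set layer — is one call (or `retinomimic run` from the shell):

```python
from retinomimic.pipeline import RunConfig, run_pipeline
report = run_pipeline(RunConfig(outdir="demo", seed=17))
```

Key entries of the printed report for that seed:

```
"annotation": {"n_input_repeats": 264, "n_retained": 240, "n_discarded": 24,
               "n_families": 8, "metagene_size": 240}
"assoc":      {"n_selected": 142, "n_up": 68, "n_down": 74}
"env":        {"all": 0.319, "basal": 0.782, "luminal": 0.013}
```

All 24 exon-overlapping decoy repeats are discarded; 142 of the 200 planted
score-correlated genes are recovered at FDR 0.05 with the default |r| ≥ 0.5
floor; and the ENV medians reproduce the qualitative viral-mimicry
contrast — induction tracks sensitivity in basal lines (R² = 0.78) but not
in luminal lines (R² = 0.01).

The CLI exposes each stage separately: `retinomimic simulate | score |
build-annotation | de | assoc | env | ssgsea | enrich | run`.

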