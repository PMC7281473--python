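# Methods

## Dose-response scoring

Viability fractions (relative to vehicle control) are measured at five
log-spaced ATRA concentrations (0.001, 0.01, 0.1, 1, 10 µM) with replicate
wells. Replicates are averaged first; inhibition is 1 − mean viability,
clamped to [0, 1]. The area under the inhibition curve is integrated on the
log10-concentration axis — the natural axis for a log-spaced design — and
divided by the log10 range, making AUC a dimensionless mean inhibition in
[0, 1]. Amax is interpreted as the maximal observed per-dose mean
inhibition (efficacy); this is the one genuinely open reading of "maximal
area" and the one consistent with a score whose ceiling is "maximal
sensitivity". The raw statistic is log2(AUC × Amax); the product is floored
at 2⁻²⁰ before the log so a totally resistant line maps to a finite cohort
floor instead of −∞. Cohort scores are min-max rescaled to [0, 1]; a cohort
whose raw values are all identical has no defined rescaling and is
rejected. The binary HIGH/LOW split defaults to 0.17 with ties assigned to
LOW (the conservative sensitivity call); ternary boundaries default to
(0.17, 0.5) and are configuration, since no canonical ternary cut points
exist. Curve fitting (four-parameter logistic, IC50) is deliberately out of
scope: the score is a model-free summary.

## Repeat annotation

Coordinates are GTF convention throughout — 1-based, inclusive on both
ends; two intervals overlap iff `a.start ≤ b.end and b.start ≤ a.end`. The
exon mask is strand-agnostic and triggers on a single shared base: repeat
quantification is vulnerable to exonic reads regardless of strand, so
unstranded masking is the conservative false-positive guard. "Gene-
associated exons" means every exon feature of every annotated gene, with no
biotype, UTR or intron refinement. Family labels come from a user-supplied
repeat-name → family table (RepeatMasker repClass/repFamily style) rather
than a hard-coded list; the meta-gene is the union of all family members,
so family counts (instance sums) add exactly to the meta-gene count in
every sample. The GTF reader/writer is a small line-oriented implementation
so that custom repeat attributes round-trip losslessly and parse errors
carry line numbers; output ordering is fixed, which makes written
annotations byte-stable.

## Differential expression

The model per feature i and sample j is y_ij ~ NB(µ_ij, α_i) with
log µ_ij = log s_j + b0_i + b1_i x_j, where s_j is the sample size factor
(median-of-ratios over features positive in all samples), x_j indicates
treatment, and Var = µ + αµ². All features are fit simultaneously by a
vectorized IRLS (two coefficients per feature, closed-form 2×2 solves), so
tens of thousands of features fit in well under a second; the per-feature
coefficients and standard errors match a reference GLM implementation to
numerical precision (tested).

Dispersions are method-of-moments — α = (v − x̄·mean(1/s)) / x̄² with v the
pooled within-condition variance of normalized counts — shrunk 50/50 in log
space toward a log-log linear mean–dispersion trend fitted across features,
and floored at 1e-8. The trend is skipped when fewer than ten features
carry a positive raw estimate (e.g. tiny family-level matrices). This is
deliberately lighter than a full empirical-Bayes treatment; the design goal
is stability at n = 3 per condition, and the calibration below is the
criterion, not agreement with any particular external implementation.

The Wald statistic b1/SE refers to a t distribution with n − 2 degrees of
freedom rather than the normal: with triplicates the plugged-in dispersions
are noisy and the normal reference is visibly anticonservative (measured
~0.10 empirical type-I at nominal 0.05 in the 3 vs 3 NB simulation), while
the t reference restores control (~0.03–0.04 measured) and converges to the
normal as n grows. Power at a 4× mean shift (mean 100, dispersion 0.1,
3 vs 3) is ~0.99. Log2 fold-changes are b1/ln 2; per-line fold-changes use
a symmetric pseudocount of 0.5 on mean normalized counts so sparse features
stay finite and unchanged features map to exactly 0.

Independent filtering scans 50 evenly spaced quantiles (0–0.95) of the mean
normalized count, sets features below each candidate threshold aside,
applies BH to the remainder and keeps the threshold maximizing rejections
at the target FDR; ties resolve to the smallest threshold (filter no more
than necessary), so a flat-mean or alpha = 1 input filters nothing. Raw
p-values are never altered by filtering; filtered features simply carry no
adjusted p-value. BH itself is the plain step-up procedure, checked against
an independent implementation to 1e-12.

A caution that matters for repeat elements: median-of-ratios assumes most
features do not change. A repeat-only matrix in which most families respond
to treatment violates this and the estimated factors absorb the induction;
the ENV functions therefore accept (and the pipeline supplies) size factors
estimated from the canonical-gene matrix, mirroring quantification of
repeats alongside genes in one annotation.

## Sensitivity association

For each gene the per-line log2 fold-change is regressed on the per-line
score (fold-changes, not raw counts, because that is the scale on which the
response heat-maps are drawn). Pearson r, least-squares slope and the
two-sided correlation-test p (t with n − 2 df) feed a transparent filter
chain: BH-adjusted p < 0.05, |r| ≥ 0.5, and at least 8 of 16 lines with a
usable fold-change. The original study applied unpublished filters before
reporting its selected-gene counts, so the exact counts are not a
reproduction target; the chain here is fully configurable and its operating
characteristics (recall ≥ 0.9, realized FDR ≤ 0.1 on planted effects with
|slope| ≥ 1 and noise sd 0.25) are what the tests pin down. Selected genes
split into up/down sets by slope sign; zero slopes are excluded.

## Viral-mimicry quantification

Family counts are member-instance sums (count additivity is what makes the
meta-gene construction coherent; the meta-gene is tested as one extra
aggregate feature and provides the per-line significance call). The
per-line summary is the median over families of the linear fold-change
2^log2FC. The figure legend this mirrors admits a second reading —
fold-change of the median family expression — which is available behind
`mode="fc_of_medians"`; the median-of-fold-changes default matches the
"median induction values of the single classes" phrasing. Subtype-wise OLS
of the median induction on the score reports R², slope and intercept per
group (all/luminal/basal); a constant response is flagged degenerate with
R² defined as 0.

## Synthetic data

The generator emulates the study design: 16 lines (8 luminal, 8 basal),
DMSO vs ATRA, 3 paired replicates, 5-dose curves with 6 viability
replicates. Every random draw descends from one seed through named
substreams, so outputs are byte-reproducible and stages can be regenerated
independently.

* Dose-response: a single latent sensitivity s ∈ [0.05, 0.95] per line
  (evenly spread within each subtype) sets Emax = 0.15 + 0.8 s and
  EC50 = 10^(1.5 − 3 s) µM on a Hill curve (coefficient 1.2); replicate
  noise is Gaussian (sd 0.05 by default), truncated at zero viability. The
  potency ordering is s itself.
* Gene counts: NB with log-normal baseline means (median ~100, log-sd 1)
  and trend dispersions α = 0.05 + 5/mean; mild log-normal library-size
  variation (sd 0.1). 200 of 2,000 genes are planted with treatment
  log2FC = slope × s (+ Gaussian noise, sd 0.25), slopes ±U(1, 2.5).
* Repeats: 240 instances in 8 families (a desk-scale reduction of the
  42-family grouping) plus 24 decoys planted inside exons of a toy
  two-chromosome annotation so the overlap filter has real work; basal
  lines receive family induction proportional to s (slopes U(1.5, 2.5)),
  luminal lines receive score-independent induction (family constants
  U(0.5, 1.5) plus per-line deviations). The luminal per-line deviations
  are sampled and then projected exactly orthogonal to the luminal
  sensitivity vector: "score-independent" is planted as an exact null, not
  merely in expectation. With only 8 luminal lines, iid line-level noise
  would leave the null R² distributed Beta(1/2, 3) — median ~0.09 — no
  matter how small the noise, so chance correlations would routinely exceed
  any small threshold; structured score-orthogonal variation is both the
  cleaner ground truth and consistent with the observation that the least
  sensitive luminal lines can show the strongest ENV induction.

What the generator does not emulate: read-level artifacts (mapping
ambiguity, GC bias), inter-gene correlation, batch structure, cell-line
identity effects beyond a scalar sensitivity, and real repeat-family
composition. Passing tests therefore demonstrate correctness and
calibration of the statistics under the declared generative model, not
performance on the deposited study data.

## Numerical and scale choices

Simulations in the tests and the acceptance script run at desk scale —
2,000–10,000 gene features, 240 repeat instances, 20-seed replication — at
which every stage completes in seconds while Monte-Carlo error stays well
inside the asserted margins. Degenerate inputs have defined behaviour
throughout: all-zero features are flagged and excluded from testing, a
single concentration or an all-identical cohort is an input error, constant
medians give R² 0 with a flag, and ssGSEA ties break on stable gene-id
order. The ssGSEA weight is |expression|^α (α = 0.25 default); at α = 0 the
score is purely rank-based and invariant to monotone transforms of the
expression values — at α > 0 it is not, which is the intended behaviour of
the weighted statistic. The competitive pre-ranked test is a plain rank-sum
test: inter-gene correlation is not modelled, so its p-values are
exchangeability p-values, best read as a ranking of set-level signal
strength (direction + FDR) rather than strict error control under
correlation — the documented limitation of replacing a correlation-adjusted
competitive test.

## Known limitations

Exact numerical agreement with the DESeq2/Camera tool stack is a non-goal;
calibration and recovery are the contracts. The Wald test is unreliable for
features where one condition is all zeros (coefficients diverge toward the
boundary); such features are reported with large standard errors rather
than special-cased. The association screen treats pooled lines as fixed
replicates (no random line effect). The HIGH/INTERMEDIATE/LOW ternary
boundaries are conventions, not estimates.
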