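# Methods

This note documents the statistical procedures implemented in `atrasens`,
the choices made where the methodology is genuinely open, and what the
synthetic-data generators do and do not emulate.

## Experimental ATRA-score

A cell line's response to ATRA is the vehicle-normalized growth curve at a
fixed exposure day: response(c) = 100 · mean(viability at c) /
mean(viability at vehicle), with replicates averaged arithmetically before
the ratio. The sensitivity statistic is the trapezoidal area under this
curve with **log₁₀(concentration in µM) as the abscissa**. Doses are
log-spaced (0.001–10 µM), so integrating on the log scale weights each
dilution step equally; integrating on the linear scale would let the top
decade dominate the area almost entirely. Vehicle (concentration 0) is
excluded from integration since log₁₀ 0 is undefined.

Panel AUCs are mapped to scores by inverted min–max rescaling,
scoreᵢ = (max AUC − AUCᵢ)/(max AUC − min AUC), which pins the endpoints:
the most inhibited line is exactly 1.00 and the least inhibited exactly
0.00. The map is invariant to shifting or positively scaling all AUCs and
reverses the AUC ordering; it is undefined (and rejected) when all AUCs
coincide. Scores at or **above** the 0.55 threshold are called "high"
sensitivity — the ≥ convention is adopted uniformly for the experimental
and the predicted score; in practice no observed score sits exactly on
the threshold. Day 6 is the scoring basis; other days are accepted and
flagged in the output metadata. Responses above 100 % (growth stimulation
at low dose) are kept, not clipped: clipping would bias the area with no
methodological justification. Out of scope by design: IC50/EC50 curve
fitting and statistical comparison of curves.

## Sensitivity signature

Per gene, Spearman's ρ between basal log₂-CPM expression and the panel
ATRA-scores, over the samples shared by the two inputs (≥ 3 required).
Ties receive average ranks. Two-sided p-values come from the exhaustive
permutation distribution when n ≤ 8 (all n! orderings, feasible and
exact) and from the standard t-approximation
t = ρ√((n−2)/(1−ρ²)) otherwise. Constant genes get NaN statistics and
cannot enter the signature. No multiple-testing correction is applied at
this screen: the selection rule is a raw p < 0.01 together with
|ρ| > 0.4. The absolute value matters: both directly (ρ > 0) and
inversely (ρ < 0) correlated genes are retained, in separate arms.

The connectivity filter takes the candidate list and one undirected
interaction graph (e.g. a STRING export; edge-confidence filtering is
optional and off by default) and keeps genes with **degree ≥ 2 in the
subgraph induced by the candidates** — a single pass, not an iterative
2-core peel. The induced-subgraph reading reflects that the retained
signature is displayed and interpreted as networks among the selected
genes themselves; candidates absent from the graph count as degree 0 and
are listed in a warning. The whole derivation is deterministic.

## Similarity-scores and predicted ATRA-scores

The per-sample statistic is the ssGSEA-type running sum: rank all genes
of the sample by decreasing expression (average ranks for ties; exact
ties in expression are ordered by gene id for determinism) and accumulate
the difference between the in-set ECDF, whose steps are weighted by
(ascending rank)^α normalized to sum 1, and the uniform out-of-set ECDF
with steps 1/(N−m). The reported score is the sum of this difference over
all positions (the "integral" form); a signed maximum-deviation (KS-like)
variant is available behind `method="ks_max"` for sensitivity analysis.
α = 0.25. The statistic is rank-based, hence invariant under strictly
increasing transforms of the expression profile and under gene order.

A directional signature gives Similarity = ES(direct) − ES(inverse); an
arm with no gene in the matrix contributes 0 (at least one arm must be
present). This difference-of-arms combination is the standard treatment
of a directional signature; it makes the Similarity-score antisymmetric
under swapping the arms. Cohort Similarity-scores are min–max rescaled to
predicted ATRA-scores in [0, 1] — deliberately mirroring the experimental
score's construction — and thresholded at 0.55. **The predicted score is
cohort-relative**: it preserves the similarity ranking exactly within the
cohort but is not calibrated across cohorts, and a cohort with
(near-)identical similarities is rejected as degenerate. No additional
cross-sample normalization of the enrichment scores is applied before the
rescaling, which would absorb it anyway.

## Subtype classification

Nearest-template prediction: restrict to the template genes present in
the matrix, z-score each gene across the cohort (population SD;
zero-variance genes are dropped with a warning), and encode class k as
the ±1 centroid (+1 at class-k genes, −1 at the other template genes).
Each sample is assigned to the class with the smallest Euclidean
distance; the margin (second-best minus best) is reported and exact ties
break to the first class label with a warning. Standardization across the
cohort is required for distances to be comparable across genes and makes
the classifier invariant to per-gene affine transforms; it also makes the
procedure transductive (calls depend on the cohort being classified).

Cross-validation: repeated random splits (default fraction 0.5, 100
permutations). Per split, empirical class centroids are the means of the
training samples' standardized profiles grouped by reference label, and
accuracy is measured on the test half. Reference labels default to the
full-cohort template calls — the practical choice when no external truth
exists — but an optional `labels` argument accepts independent labels.
The distinction matters: with data-derived reference labels the estimate
is optimistically biased (the labels are a function of the same
expression values the centroids are trained on, so under pure noise the
agreement sits well above chance), whereas with externally supplied
labels a noise cohort averages exactly 50 % and a 3-SD-shifted cohort
≥ 95 %. Calibration tests therefore use the generator's true labels.
When checking the null expectation, the Monte-Carlo unit is the cohort:
per-permutation accuracies within one cohort are strongly correlated, so
the null check replicates over independent cohorts and uses the spread of
cohort means as its standard error. Splits missing a class are resampled
(bounded retries). Cohort clustering uses Ward's minimum-variance linkage
on Euclidean distances (SciPy), whose merge heights are non-decreasing.

## Consensus sets

Per DE table, up = {g : FDR < 0.1, log₂FC > 0} and down symmetric, with a
strict inequality at the threshold and log₂FC = 0 excluded. Group
consensus sets are plain intersections across member lines; genes missing
from any member table are treated as not significant there, so consensus
sets can only shrink as lines are added. No fold-change magnitude filter
is applied. Differential testing itself is upstream of this package.

## Synthetic data

The generators emulate the shapes and magnitudes of the study design the
pipeline targets; all draws are from per-generator RNG streams derived
from the config seed, so each output is reproducible in isolation.

* **Growth panels** (default 27 lines, doses 0.001/0.01/0.1/1/10 µM, days
  3/6/9, 10 replicate cultures per point): viability follows a Hill
  inhibition model, baseline · [1 − (Emax/100)·cʰ/(EC50ʰ + cʰ)], with
  multiplicative Gaussian noise (SD 5 % of signal — a typical
  plate-assay CV) and an exposure-time efficacy ramp (full effect at day
  6). EC50 is drawn log-uniformly over 0.003–30 µM and Emax uniformly
  over 20–95 %, spanning clearly sensitive to clearly resistant lines.
  True AUCs come from a 10⁴-point trapezoid of the noiseless day-6 curve.
* **Expression panels** (default 1,000 genes, 27 samples): background
  genes are N(μ_g, 1) on the log₂-CPM scale with gene-specific means
  drawn from U(2, 8); the planted 20 direct / 10 inverse genes add
  ±5 · score. With scores spread over [0, 1] (SD ≈ 0.27) this puts the
  planted per-gene Spearman near 0.8 — strong but realistic for a
  signature worth finding, and comfortably above the |ρ| > 0.4 rule.
* **Interaction graphs**: planted signature genes wired as a clique
  (default) or a cycle (degree exactly 2); every other pair edged with
  probability 0.01, a sparsity comparable to a confidence-filtered
  interaction network.
* **Subtype cohorts** (default 171 template genes, 30 + 30 samples):
  class-k samples shifted ±3 SD on the two template halves.
* **DE tables** (default 3 lines, 500 background genes): planted common
  genes get FDR ~ U(0, 0.05) with direction-consistent log₂FC in every
  line; 5 % of background genes per line are line-specific significants;
  everything else has FDR ~ U(0.2, 1), leaving a deliberate gap at 0.1.

What the generators do **not** emulate: count-level RNA-seq noise
(negative-binomial dispersion, library-size effects), batch structure,
correlated co-expression modules, scale-free interaction topology, or
crossing dose–response curves with non-monotone potency. Passing tests
therefore demonstrate correctness and calibration of the *procedures*
under their stated assumptions, not performance on real cohorts — in
particular, real signature recovery depends on effect sizes and network
completeness the simulation fixes by construction.

## Numerical notes and limitations

* Trapezoidal AUC on the 5-point half-decade grid is within ~2 % of a
  fine-grid integral for smooth Hill curves; very steep curves increase
  the quadrature error, which can reorder lines whose true AUCs are
  nearly equal.
* The t-approximated Spearman p is slightly anticonservative at moderate
  n (empirical type-I ≈ 0.011 at the 0.01 level for n = 27), which is
  accounted for when interpreting the screen's false-positive rate.
* Exact-tie handling is deterministic everywhere (average ranks; gene-id
  or class-label order as the final tie-break) so reruns are
  byte-identical.
* Problem sizes used in the test and acceptance suites (27-line panels,
  1,000-gene screens over 20–50 replicate simulations, 100-sample
  cohorts, 100-permutation cross-validations) were chosen as the
  smallest designs at which the targeted properties are statistically
  decidable.
* Reproducing the original 42-gene signature content, the 26/16 arm
  split, cohort-level 165/210 calls or the published consensus counts
  requires the external cohorts (CCLE, TCGA), a specific interaction-
  database version and the upstream differential-testing runs; those
  quantities are inputs-dependent and are intentionally not asserted.
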