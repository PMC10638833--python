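# atrasens

Quantifying and predicting the sensitivity of gastric-cancer cells to
all-trans retinoic acid (ATRA) from transcriptomic and dose–response data.

ATRA, the active metabolite of vitamin A, inhibits the growth of roughly
half of gastric-cancer cell lines. `atrasens` implements the analysis
chain that turns this observation into a predictive tool, for
computational biologists working on drug-sensitivity stratification:

1. **ATRA-score** (`atrasens.dose_response`). Growth of each cell line
   under increasing ATRA concentrations (0.001–10 µM) is normalized to
   vehicle-treated controls (100 %) and summarised by the trapezoidal
   area under the curve over log₁₀ concentration,
   AUCᵢ = ∫ response(log₁₀ c) d log₁₀ c. Panel AUCs are inverted and
   min–max rescaled, scoreᵢ = (max AUC − AUCᵢ)/(max AUC − min AUC), so the
   most inhibited line scores 1.00 and the least inhibited 0.00; lines
   with score ≥ 0.55 are called ATRA-sensitive.
2. **Sensitivity signature** (`atrasens.signature`). Basal log₂-CPM
   expression of every gene is correlated with the panel's ATRA-scores
   (Spearman ρ, two-sided p; exact permutation null for n ≤ 8). Genes
   with p < 0.01 and |ρ| > 0.4 form a candidate list split into *direct*
   (ρ > 0) and *inverse* (ρ < 0) arms, then pruned to genes with degree
   ≥ 2 in the protein-interaction subgraph induced by the candidates.
3. **Similarity-score prediction** (`atrasens.enrichment`). For each
   sample of a new cohort, a single-sample rank-based enrichment score
   (ssGSEA-type running sum, exponent α = 0.25) is computed per signature
   arm; the Similarity-score ES(direct) − ES(inverse) is min–max rescaled
   across the cohort to a predicted ATRA-score in [0, 1] and thresholded
   at 0.55.
4. **Subtype classification** (`atrasens.subtype`). Nearest-template
   prediction over a gene template (e.g. the 171-gene G-INT/G-DIFF
   template): per-gene z-scores, ±1 class centroids, Euclidean
   assignment, with random-split cross-validation (100 permutations) and
   Ward/Euclidean cohort clustering.
5. **Consensus differential expression** (`atrasens.consensus`).
   Intersection of per-line significantly (FDR < 0.1) up-/down-regulated
   gene sets within cell-line groups, and overlaps across groups.
6. **Synthetic studies** (`atrasens.simulate`). Deterministic generators
   for all five input kinds with known ground truth (Hill-curve growth
   panels, planted score-correlated signatures, planted interaction
   clusters, mean-shifted subtype cohorts, planted consensus genes), so
   the whole pipeline is testable without any download.

The main entry points are scikit-learn-style estimators — `AtraScorer`,
`SensitivitySignatureScreen`, `SimilarityScorePredictor`,
`NearestTemplateClassifier` — with plain functions underneath, plus an
`atrasens` command-line tool.

## Worked example

Generate a synthetic 27-line study and run the chain:

```sh
atrasens simulate --seed 7 --out sim/
atrasens score    --growth sim/growth.tsv --day 6 --threshold 0.55 --out scores.tsv
atrasens signature --expr sim/expression.tsv --scores scores.tsv \
                   --graph sim/interactions.tsv --out sig.gmt
atrasens predict  --expr sim/expression.tsv --signature sig.gmt --out pred.tsv
```

`scores.tsv` starts:

```
cell_line  auc      atra_score  call
LINE01     243.159  0.74        high
LINE02     311.740  0.40        low
LINE03     376.224  0.08        low
```

LINE01's growth curve encloses the smallest area (strong inhibition), so
its rescaled ATRA-score 0.74 exceeds the 0.55 threshold and the line is
called sensitive. The signature step reports

```
signature: 21 direct, 11 inverse -> sig.gmt
```

— the screen plus connectivity filter recovered the planted 20-direct /
10-inverse signature (with one borderline background gene). Prediction
then yields per-sample Similarity-scores and calls:

```
sample   es_direct  es_inverse  similarity  predicted_score  call
LINE01   363.63     -279.90     643.53      0.75             high
LINE02   265.69     -116.81     382.50      0.46             low
```

`atrasens subtype --expr sim/subtype_expression.tsv --template
sim/subtype_template.tsv --cv 100 --seed 7 --out calls.tsv` classifies the
60-sample cohort and prints `CV accuracy 1.000 +/- 0.000` (the synthetic
classes are separated by 3 SD), and `atrasens consensus --manifest
sim/groups.yaml --out cons/` reports the planted 12 common up- and 9
common down-regulated genes. `atrasens run --config pipeline.yaml`
executes all stages with a JSON run report.

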