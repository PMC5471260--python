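# radsem

Semantic–radiomic association analysis for CT tumor volumes.

Radiologists describe lung tumors with qualitative **semantic** features —
cavitation, air bronchogram, calcification (binary), and texture, border
definition, contour, lobulation, spiculation, concavity (ordinal). Radiomics
describes the same tumors with quantitative features computed from the
segmented CT volume. `radsem` implements the full analysis linking the two:

1. **Feature extraction** — 48 original-image features per tumor
   (13 shape, 12 first-order statistics, 17 GLCM, 1 GLSZM size-zone
   variability, 5 run-length), plus 12 + 23 statistics/texture features on
   every filtered image of a configurable LoG + wavelet filter bank
   (default 13 filtered images → 503 features in total).
2. **Redundancy pruning** — pairwise Spearman correlation; in every pair
   with |ρ| ≥ 0.85 the member with the highest average |ρ| is excluded.
3. **Association screening** — for binary semantic features the folded ROC
   AUC (AUC ≥ 0.5 reported with a proportional/inverse direction, i.e.
   AUC<sub>inv-prop</sub> = 1 − AUC) with Noether's test
   z = (AUC − ½)/√((n₀+n₁+1)/(12 n₀ n₁)); for ordinal features Spearman's ρ
   with the Kruskal–Wallis test; Benjamini–Hochberg FDR within each semantic
   feature's family, significance at q ≤ 0.05; strength bins
   (0.5, 0.7] weak, (0.7, 0.9] moderate, (0.9, 1] excellent for AUC and
   |ρ| ≤ 0.5 / 0.7 / 0.9 cut-points for correlations.
4. **Synthetic cohort** — because no patient scans ship with the package, a
   phantom generator renders CT-like tumor volumes whose geometry and
   interior are driven by the nine semantic scores (star-convex radial
   surface with score-controlled lobulation/spiculation amplitudes, carved
   concavity bites, air cavities, bronchogram tubes, calcification spots,
   texture-dependent density, border blur and noise). Score marginals
   default to a realistic lung-adenocarcinoma cohort distribution.

The core estimators follow scikit-learn conventions
(`RadiomicFeatureExtractor`, `SpearmanRedundancyFilter`,
`AssociationScreen`) and compose with sklearn pipelines; module-level
functions (`extract_features`, `prune_redundant`, `build_report`, …) are
thin wrappers.

## Worked example

Generate a 200-phantom cohort, extract the 48 original features, prune, and
screen associations:

```python
from radsem import (AssociationScreen, CohortTable, RadiomicFeatureExtractor,
                    SpearmanRedundancyFilter)
from radsem.synthetic import make_cohort

subjects = make_cohort(200, seed=1)                 # ~1 min on one CPU
features = RadiomicFeatureExtractor().fit().transform(subjects)
pruned = SpearmanRedundancyFilter(threshold=0.85).fit_transform(features)
cohort = CohortTable([s.semantic for s in subjects])
screen = AssociationScreen(alpha=0.05).fit(features, cohort.frame.reset_index())

b = screen.binary_
cell = b[(b.radiomic == "orig.shape.sphericity") & (b.semantic == "cavitation")]
print(cell[["auc_raw", "auc_folded", "direction", "q", "strength"]])
```

```
    auc_raw  auc_folded direction         q strength
2  0.317675    0.682325   inverse  0.000022     weak
```

Cavitating phantoms are *less* spherical (raw AUC 0.32 folds to 0.68 with
direction "inverse", q ≈ 2e-5): the screening recovers the built-in
phenotype. Likewise size-zone variability vs cavitation folds to 0.737
"proportional" (cavitation ⇒ more heterogeneous texture), and sphericity is
negatively rank-correlated with lobulation (ρ = −0.441), spiculation
(ρ = −0.363) and concavity (ρ = −0.430).

The same pipeline runs from the shell on NIfTI/NRRD files:

```bash
radsem run-all --config cfg.yaml --seed 1 --out run/
# stages: generate | extract | select | associate  (each also callable alone)
```

Each run directory is self-describing: `config.yaml`, a digest-based
`manifest.json` (used by `--resume`), the feature tables, the selection
report, and the long-format association report mirroring the binary
(AUC/direction/q) and categorical (ρ/KW-q) matrices.

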