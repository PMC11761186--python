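# attnsig

Attention-CNN survival scoring of H&E histology, with immune-signature
enrichment and spatial-transcriptome integration.

## The problem

Tumor histology carries prognostic information — tumor-infiltrating
immune cells in particular are associated with longer survival in
high-grade serous ovarian cancer — but deep models trained on H&E slides
are hard to interpret. This package implements, as a tested and reusable
pipeline, an analysis that (1) trains an attention-augmented
convolutional classifier to predict long (&ge; 36 months) overall
survival from H&E tiles, (2) evaluates the resulting ensemble "H&E-based
survival score" with survival statistics, (3) asks *which* immune gene
signatures differ between low- and high-score patients (GSEA), and
(4) tests spatially whether the model's attention signal co-locates with
that signature's per-spot enrichment on Visium-style spatial
transcriptomics. Synthetic generators with planted ground truth stand in
for real cohorts, so every stage is verifiable: parameter recovery and
statistical calibration are asserted by the test suite, not eyeballed.

It is aimed at computational-pathology and spatial-omics researchers who
want the statistical machinery (from-scratch Kaplan–Meier/log-rank/AUROC,
weighted-KS GSEA and ssGSEA, spot registration and correlation) and a
desk-scale, dependency-light model to exercise it end to end.

## The model

A four-stage convolutional backbone with two interpolation attention
modules. Each module projects the deeper stage to a single channel
(1×1 conv), squashes it with a sigmoid, bilinearly upsamples the gate to
the shallower stage's grid, scales the shallow features by the gate, and
global-average-pools the result. The concatenation

&nbsp;&nbsp;&nbsp;&nbsp;[backbone output (1000) ‖ attention-1 pool (256) ‖ attention-2 pool (1024)]  → 2280

feeds a 128/32/2 fully connected head (ReLU, dropout 0.2, softmax).
Training minimises the focal loss −α(1−p_t)^γ ln p_t (γ=2, α=0.25) with
Adam (lr 2·10⁻⁴, ×0.1 every 7 epochs). Five-fold cross-validation trains
each fold several times, keeps the checkpoint with the best validation
AUROC, and scores images with the fold-model ensemble's mean
positive-class probability. Scores are evaluated with the log-rank test
(step-wise optimal cutoff search), hazard ratios and AUROC; expression is
contrasted between median-split score groups by permutation GSEA; and
per-spot ssGSEA scores are correlated with ln(attention) by Spearman rank
correlation in the tumor cluster.

The network and its backward pass are written directly on numpy
(im2col convolutions, manual gradients, verified against finite
differences), so the package has no deep-learning framework dependency.
A `tiny` backbone (concat width 90) mirrors the full topology at a scale
that trains in seconds on one CPU.

## Worked example

```python
from attnsig.workflow import RunConfig, run_pipeline

cfg = RunConfig(seed=7, n_patients=80, test_fraction=0.5, image_size=64,
                epochs=3, repeats_per_fold=1, k_folds=3, n_genes=200,
                signature_size=25, n_perm=200, learning_rate=1e-3)
manifest = run_pipeline(cfg, "runs/demo")
```

This simulates a cohort of 80 patients (planted infiltrate density d,
overall survival ~ Exponential with rate h₀·e^(−2d)), trains the tiny
classifier with 3-fold cross-validation, scores the held-out half, and
runs the survival, enrichment and spatial stages. Output actually
printed by this run:

```
fold AUROCs: [0.7302, 0.963, 0.7679]          # per-fold validation AUROC
survival.json: {
  "n_patients": 40,
  "stepwise_cutoff": 0.5646581078569094,       # score cutoff minimising log-rank p
  "stepwise_logrank_p": 0.035454315673715917,  # survival split on held-out patients
  "hazard_ratio_high_vs_low": 0.38839301035290386,
  "significant": true
}
enrichment.csv (head):
                set_name       es      nes        p      fdr  size
SYN_IMMUNE_INFILTRATE_UP 0.659789 1.948997 0.010309 0.026013    25
                DECOY_14 0.406355 1.364761 0.142857 0.708854    25
```

High scores mean predicted long survival, so the high-score group has a
hazard ratio below 1 (here 0.39, log-rank p = 0.035), and the planted
infiltrate-coupled signature tops the enrichment table (p = 0.010,
FDR = 0.026) while decoy sets do not. At this deliberately small demo
scale the spatial correlation of the trained model's attention with
per-spot enrichment was not significant (rho = 0.086, p = 0.56) — the
spatial power analysis in the test suite uses the ground-truth infiltrate
map and 20 seeds instead. The desk-scale defaults (`RunConfig.tiny()`:
420 patients, 5×2×6 fold/repeat/epoch training) recover the planted
effect with held-out AUROC near its information ceiling (~0.71) and
strongly significant survival splits.

The same stages are scriptable from a shell:

```sh
attnsig simulate --n-patients 120 --out runs/c
attnsig train --images runs/c/images --clinical runs/c/clinical.csv \
              --index runs/c/image_index.csv --k 5 --repeats 2 --epochs 6 \
              --lr 1e-3 --out runs/c/models
attnsig score --models runs/c/models --images runs/c/images \
              --index runs/c/image_index.csv -o runs/c/scores.csv
attnsig survival --scores runs/c/scores.csv --clinical runs/c/clinical.csv \
                 --endpoint os --cutoff stepwise -o runs/c/survival.json
attnsig run --profile tiny --seed 1 --out runs/full   # everything at once
```

## Layout

- `src/attnsig/nn/` – numpy layers, manual backprop, Adam
- `src/attnsig/model.py` – the attention classifier, focal loss, heatmaps
- `src/attnsig/pipeline.py` – cohort prep, tiling, folds, training, ensembling
- `src/attnsig/estimators.py` – scikit-learn style wrappers
- `src/attnsig/survival.py` – KM, log-rank, AUROC, cutoff search, HR, chi-square
- `src/attnsig/enrichment.py` – GSEA, ssGSEA, Benjamini–Hochberg
- `src/attnsig/spatial.py` – spot IO/registration/clustering/correlation
- `src/attnsig/synthetic.py` – cohort, tissue-image and spatial generators
- `src/attnsig/workflow.py`, `cli.py` – orchestration and the `attnsig` CLI
- `docs/methods.md` – model, statistics, synthetic-data assumptions, limitations
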