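# habitatpipe

Habitat imaging of tumors from intravoxel incoherent motion (IVIM)
diffusion MRI, for predicting pathologic complete response (pCR) to
neoadjuvant chemotherapy.  The package takes multi-b-value diffusion-weighted
volumes with a tumor mask and runs the full analysis chain:

1. **IVIM parameter mapping** — voxelwise biexponential fit
   `S(b) = S0[f·exp(−b·D*) + (1−f)·exp(−b·D)]`, segmented initialization
   refined by bounded nonlinear least squares, yielding D, f, D* and S0 maps;
2. **habitat segmentation** — pooled K-means on the (f, D) maps splits tumor
   voxels into physiologically ordered subregions (label 1 high perfusion,
   label 2 high cellularity, label 3 necrotic-like), with bootstrap-stability
   selection of the number of habitats;
3. **habitat radiomics** — volume, volume ratio and 18 first-order
   statistics per habitat and channel;
4. **staged feature selection** — ICC reproducibility filter, training-set
   z-scoring, Pearson redundancy filter (|r| > 0.9), cross-validated LASSO,
   and recursive feature elimination;
5. **outcome models** — logistic regression or SVM over habitat, whole-tumor,
   conventional-MRI and immunohistochemistry feature blocks and their
   combinations;
6. **evaluation** — rank-based AUC with DeLong confidence intervals, Youden
   operating points, the full confusion-metric battery (incl. Matthews
   correlation), the DeLong test for correlated ROC curves, decision-curve
   analysis, and the contingency/group-comparison statistics of a clinical
   covariate table.

Because clinical breast-MRI cohorts are private, the package ships a
first-class synthetic-phantom module: tumors composed of 2–4 habitats with
known IVIM parameters, Rician noise at a chosen SNR, and patient cohorts
whose binary outcome is driven by habitat composition through a logistic
model.  Every stage is tested against this ground truth.

## Worked example

```python
import numpy as np
from habitatpipe.phantom import (PhantomSpec, make_cohort,
                                 strong_effect_cohort, well_separated_habitats)
from habitatpipe.pipeline import run_pipeline

pspec = PhantomSpec(grid_shape=(12, 12, 8),
                    habitats=well_separated_habitats(), noise_sigma=2.0)
cspec = strong_effect_cohort(n_patients=140, seed=11)
phantoms, manifest = make_cohort(pspec, cspec)

res = run_pipeline(phantoms, manifest, K=3, variant="Habitats",
                   rfe_target=6, seed=0)
print(f"prevalence      {manifest['outcome'].mean():.3f}")
print(f"selected        {res.selection_report.selected}")
print(f"train AUC       {res.roc_train.auc:.3f}")
print(f"test AUC        {res.roc_test.auc:.3f} "
      f"(95% CI {res.roc_test.ci_low:.3f}-{res.roc_test.ci_high:.3f})")
```

Output:

```
prevalence      0.293
selected        ['D_habitat1_minimum', 'f_habitat2_median', 'habitat3_volume',
                 'f_habitat3_maximum', 'f_habitat3_variance', 'D_habitat3_entropy']
train AUC       0.941
test AUC        0.840 (95% CI 0.719-0.960)
```

The cohort generator plants a strong dependence of response on habitat
composition (more perfused/cellular tumor → higher response probability,
more necrotic tumor → lower).  The pipeline — IVIM fitting, pooled
clustering, feature extraction and selection, all blind to the ground
truth — recovers that signal on held-out patients: the selected features
concentrate on the planted habitats (notably the necrotic habitat-3 volume
and its f/D statistics), and the held-out AUC approaches the generator's
oracle discriminability (~0.90).

A command-line interface mirrors the library
(`habitatpipe simulate | fit-ivim | run | clinstats`); see `--help`.

## Layout

```
src/habitatpipe/
  ivim.py        biexponential model, voxel/volume fitting
  phantom.py     synthetic tumors, cohorts, Rician noise, NIfTI IO
  habitats.py    pooled K-means, label ordering, bootstrap K selection
  features.py    first-order statistics, feature tables
  selection.py   ICC / z-score / Pearson / LASSO / RFE chain
  models.py      model variants, classifiers, stratified CV
  evaluation.py  ROC, Youden, confusion metrics, DeLong, DCA
  clinstats.py   chi-square and two-group comparisons
  pipeline.py    end-to-end orchestration
  cli.py         command-line entry points
docs/methods.md  model, conventions, design choices, limitations
```
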