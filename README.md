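# msiclf

Supervised classification of MALDI mass-spectrometry-imaging (MSI) tissue
microarrays (TMAs): from imzML pixel spectra to per-patient tissue-group
diagnoses, with patient-safe cross-validation throughout.

## Who this is for

MALDI MSI acquires one tryptic-peptide mass spectrum per spatial pixel of a
tissue section. On a TMA, hundreds of such spectra cover each patient tissue
core, and the clinical question — is this patient's tissue tumour or normal?
does this primary tumour have nodal metastases? — is asked per *tissue group*
(all spectra of one tissue type from one patient), not per pixel. `msiclf` is
for researchers who have pathologist-annotated MSI TMA cohorts (or want to
prototype against realistic synthetic ones) and need a reproducible,
leakage-safe binary classification pipeline.

## The method

1. **Harmonize**: different TMA acquisitions have slightly different m/z
   axes. A shared grid of `B = round((max − min)/w)` bins (width `w = 3` Da
   by default) spans the global m/z range over all datasets; every m/z point
   is assigned to its nearest bin center and intensities are summed per bin
   (total intensity is conserved exactly), then square-rooted to compress the
   dynamic range. On the real acquisition range 799.757–4496.840 Da this
   yields 1232 features.
2. **Classify spectra**: two neural networks trained on the same rows — a
   multilayer perceptron (1232→1024→512→1, ReLU/sigmoid, 1,787,905
   parameters at the real feature width, positive-class loss weight 2.5) and
   a 12-layer 1-D convolutional network (kernel 9, no biases, batch
   normalization before layers 1–11, global average pooling, 72,802
   parameters independent of input length). Both are implemented in numpy
   with seeded SGD-with-momentum training. The per-spectrum confidence is
   the mean of the two sigmoid outputs; 0.5 is the decision threshold
   (strictly below → negative).
3. **Fuse per group**: a tissue group's decision is the thresholded *median*
   of its spectra's confidences.
4. **Validate**: leave-one-TMA-out cross-validation (hold out a whole
   physical array per fold) or balanced k-fold (10 validation groups per
   class per fold). Every split is checked for patient-level leakage.
   Reports: accuracy, balanced accuracy, sensitivity, specificity, rank-based
   ROC AUC per fold (unweighted means across folds) plus per-group accuracy.

A seeded synthetic cohort generator (Gaussian peptide-like peaks with
amplitude decaying in m/z, class-discriminating fold changes, log-normal
patient and pixel noise, per-TMA axis jitter, paired or imbalanced cohort
layouts) exercises every stage with no external data. See
[docs/methods.md](docs/methods.md) for the full model description.

## Worked example

Simulate a 3-TMA cohort of 24 patients (each with a normal and a tumour
tissue group; 5 of 30 peptide peaks carry a 3-fold tumour effect), featurize
it, and run leave-one-TMA-out cross-validation:

```sh
cat > run.yaml <<'EOF'
seed: 7
sim:
  n_tmas: 3
  n_patients_both: 24
  spectra_per_core: [6, 10]
  axis_points: 1000
  mz_min: 800.0
  mz_max: 950.0
  n_peaks: 30
  n_effect_peaks: 5
  fold_change: 3.0
EOF
msiclf simulate  --config run.yaml --out data
msiclf featurize --config run.yaml --in data --out feats
msiclf crossval  --config run.yaml --in data --out cv
```

which prints:

```
wrote 3 imzML file(s), 1151 spectra to data
feature matrix: 1151 spectra x 50 bins -> feats/features.npz
{
  "mean_spectrum_metrics": {
    "accuracy": 0.9514784753064031,
    "balanced_accuracy": 0.9280752522799633,
    "sensitivity": 1.0,
    "specificity": 0.8561505045599267,
    "auc": 1.0
  },
  "mean_group_accuracy": 0.9791666666666666,
  "n_folds": 3
}
```

Reading the numbers: the 150 Da range at 3 Da width gives 50 bins; across the
three folds the ensemble ranks validation spectra perfectly (mean AUC 1.0)
and, after median fusion, classifies 97.9% of held-out tissue groups
correctly. The fixed 0.5 threshold trades specificity (0.86) for perfect
sensitivity on this small cohort — the usual picture when a threshold is not
calibrated per dataset. `cv/` contains per-fold metrics, per-group
predictions, per-class group accuracies, and a manifest with the full
configuration and seed; identical seeds reproduce every number.

The same pipeline is available as a library:

```python
from msiclf import (SimConfig, generate_cohort, assign_groups,
                    compute_bin_spec, run_cross_validation)
from msiclf.featurize import dataset_extremes

cohort = generate_cohort(SimConfig(seed=7))
groups = assign_groups(cohort.spectra, cohort.annotations)
spec = compute_bin_spec(list(dataset_extremes(cohort.spectra).values()), width=3.0)
result = run_cross_validation(groups, spec, design="leave_one_tma_out", seed=7)
print(result.mean_spectrum_metrics, result.mean_group_accuracy)
```

For real data, point `read_imzml`/`read_annotations` at your imzML files and
a per-pixel annotation table (columns `tma_id, x, y, patient_id, group_id,
label`).

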