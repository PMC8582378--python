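# Methods

## The problem and the pipeline

MALDI mass-spectrometry imaging of a tissue-microarray (TMA) section produces
one tryptic-peptide spectrum per spatial pixel — hundreds of spectra per
tissue core, many cores per patient. The clinically relevant unit is the
*tissue group*: all spectra of one tissue type from one patient. `msiclf`
classifies tissue groups in two stages: a per-spectrum binary classifier
("one spectrum is one sample") whose confidences are then fused per group by
the median ("one tissue group is one sample"), with all evaluation done under
patient-safe cross-validation.

The pipeline stages are:

1. **Ingestion** (`msi_io`). Continuous-mode imzML/ibd pairs are read with
   pyimzml, one `RawSpectrum` per pixel. Tissue groups are formed by joining
   pixel coordinates against a per-pixel annotation table (`tma_id, x, y,
   patient_id, group_id, label`); a rectangular-region shorthand and a
   label-by-file-identity entry point are provided for the two common
   annotation layouts. Zero-intensity pixels (tissue voids) are dropped with a
   logged count. TIC normalization (rescaling each spectrum to total ion count
   1.0) is available but off by default, since vendor-exported imaging data is
   typically already TIC-normalized.

2. **Feature harmonization** (`featurize`). Different TMA acquisitions have
   slightly different m/z axes (point counts and global extremes drift).
   A shared grid of B bins of width w (default 3 Da) is built over the global
   m/z range pooled across all datasets, with
   `B = round((global_max - global_min) / w)` and B centers linearly spaced
   over `[global_min, global_max]` inclusive. Each m/z point is assigned to
   its *nearest* bin center (equivalent to midpoint boundaries) and
   intensities are summed per bin, so total intensity is conserved exactly.
   A square-root transform then compresses the dynamic range, which is
   dominated by much higher mean intensities at low m/z.

3. **Classification** (`models`, `nn`). Two networks see the same binned
   spectra:
   * **MLP** — dense layers input→1024→512→1 with biases, ReLU hidden
     activations, sigmoid output; binary cross-entropy, SGD with momentum
     0.9, batch 512, 20 epochs at learning rate 0.01 then 10 at 0.001, and a
     2.5× loss weight on positive samples. At the real feature width of 1232
     bins this is 1,787,905 trainable parameters.
   * **1-D conv net** — 12 convolution layers, kernel 9, no biases; strides
     4 (layer 1), 3 (layers 6 and 10), else 1; filter counts
     (32,16,16,16,16,32,32,32,32,32,64,1); batch normalization (2 trainable
     parameters per input channel) before layers 1–11, ReLU before layers
     2–12, global average pooling of the final single-channel map into a
     sigmoid. Trained with batch 512, momentum 0.9, per-layer weight decay
     0.001 on the convolution weights, 5 epochs at 0.1, 5 at 0.01, 1 at
     0.001, no class weighting. 72,802 trainable parameters regardless of
     input length.

   The ensemble confidence is the plain mean of the two sigmoid outputs;
   thresholding at 0.5 with "strictly below → negative" gives the
   per-spectrum decision.

4. **Cross-validation and fusion** (`crossval`). *Leave-one-TMA-out* holds
   out every group on one physical array per fold (patients must not straddle
   TMAs). *Balanced k-fold* samples a fixed number of validation groups per
   class per fold (default 10×10), independently per fold and without
   replacement within a fold, so a small class recurs across folds; the
   training set excludes every group of a validated patient. Per fold we
   report spectrum-level accuracy, balanced accuracy, sensitivity,
   specificity, and rank-based ROC AUC (ties count ½), plus the fraction of
   groups classified correctly after median fusion (overall and per class).
   Aggregates are unweighted means over folds; pooled-spectrum metrics are
   logged for diagnostics only. Patient disjointness of every split is
   asserted on every run.

## Why the networks are implemented in numpy

The two classifiers are part of the method itself, and their exact
architecture — parameter counts included — is a contract this package keeps.
They are implemented directly on numpy (im2col convolutions dispatched to
BLAS, hand-written backward passes, seeded SGD with momentum). This keeps the
dependency footprint small, makes training bit-reproducible for a fixed seed
on one platform, and lets the analytic parameter enumeration be verified
against the instantiated networks in the test suite. scikit-learn is used for
metrics only.

## Architecture reconstruction choices

Two details of the conv net's published description are internally
inconsistent, and were resolved in favour of the printed parameter count of
72,802:

* batch normalization precedes layers 1–11 only (normalizing the input of
  layer 12 as well would give 72,930 parameters);
* the filter counts are (32,16,16,16,16,32,32,32,32,32,64,1).

Other open choices: "same" convolution padding (global average pooling makes
the output length-agnostic, so padding affects internals only); plain SGD
with momentum, no Nesterov; batch-norm running statistics updated with
smoothing 0.1 and used at inference; He initialization for ReLU layers,
Glorot for the sigmoid output; learning-rate stages restart exactly on epoch
boundaries with no early stopping; weight decay applies to convolution
weights, not to the normalization scale/shift.

## Numerical conventions

* Bin-count rounding is nearest-integer (a range/width ratio of 1232.36 gives
  1232 bins; ceiling would give 1233).
* Nearest-bin ties (a point exactly halfway between two centers) go to the
  lower-index bin, which keeps binning deterministic and order-independent.
* Out-of-range m/z points clamp to the end bins rather than being dropped, so
  intensity conservation holds exactly.
* Median fusion of an even number of confidences is the mean of the two
  middle values; a median exactly at the threshold classifies positive.
* AUC is computed by scikit-learn's rank-based ROC area, which equals the
  all-pairs win/tie oracle exactly; folds with a single class report NaN AUC
  and NaN for the undefined rate while the other metrics are still returned.
* Networks compute in float32; fixed seeds reproduce training exactly on the
  same platform (member i of an ensemble draws from an independent stream
  spawned from the run seed).

## The synthetic cohort generator

`synthetic.generate_cohort` emulates the statistical shape of a real
tryptic-peptide TMA cohort so the whole pipeline can be exercised without any
external data:

* per-TMA m/z axes of configurable length whose extremes jitter by ±0.5 Da
  (default) across TMAs, forcing the harmonization step to do real work;
* a shared set of Gaussian peaks (default 60, σ = 1 Da) drawn uniformly over
  the usable range but kept ≥ 4 Da apart, with base amplitudes decaying
  exponentially with m/z (scale 250 Da) times a log-normal draw (σ = 0.5) —
  reproducing the much higher mean intensities at low m/z;
* a configurable subset of peaks (default 10) scaled by a fold change
  (default 3) in positive-class tissue;
* per-patient log-normal peak effects (σ = 0.2), per-pixel log-normal noise
  (σ = 0.3), and a small half-normal additive baseline (1% of unit peak
  height);
* two cohort layouts: *paired* (most patients contribute a normal and a
  tumour group, with 2 and 4 cores respectively, plus optional
  single-class patients) and *single* (one group per patient with class
  imbalance);
* desk-scale defaults: 2000-point axes, 10–40 spectra per core, 3 TMAs of 8
  both-class patients.

What it does **not** emulate: isotope envelopes, matrix clusters,
mass-calibration drift, within-core spatial gradients, correlated noise
between adjacent pixels, or chemically realistic peptide masses. Passing the
recovery experiments below therefore shows the pipeline is correct and can
recover a multiplicative class effect under realistic noise and imbalance —
it does not certify the accuracy levels reachable on real cohorts.

## Verification experiments

The acceptance tests run two full pipeline experiments on one CPU:

* **Recovery**: a paired cohort of 6 TMAs × 20 both-class patients,
  2000-point axes over 800–1100 Da (100 bins at 3 Da width), 3–6 spectra per
  core (≈3200 spectra, 240 groups), fold change 3 at 10 of 60 peaks. The
  full leave-one-TMA-out run with both networks and median fusion must reach
  mean per-group accuracy ≥ 0.95 and mean per-spectrum AUC ≥ 0.95 (measured:
  1.00 and 1.00 at seed 11).
* **Null control**: the same cohort with fold change 1.0 must give mean
  per-spectrum AUC within 0.5 ± 0.1 (measured: 0.498), confirming that the
  patient-safe splits leak no signal.

The m/z span and per-core spectrum counts of these experiments are smaller
than the generator defaults so that both six-fold, two-network runs complete
in a few minutes; the problem sizes are stated here as the package's own
verification scale.

## Known limitations

* Only continuous-mode imzML is supported; processed-mode files with
  wildly heterogeneous per-pixel axes are out of scope (the binning step
  absorbs sub-bin jitter only).
* No peak picking, deisotoping, recalibration, or baseline subtraction —
  input is assumed baseline-corrected.
* No threshold selection or confidence calibration: 0.5 is used throughout.
* Training runs on a single CPU thread via BLAS; at the real scale
  (≈190k spectra × 1232 bins) a GPU framework would be the practical choice,
  and the numpy engine here targets desk-scale validation.
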