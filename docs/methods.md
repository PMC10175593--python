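# Methods

## Problem setting

A sample panel couples up to four instrument blocks measured on the
same herbal samples: electronic nose (EN, 10 metal-oxide gas sensors),
electronic tongue (ET, 6 taste sensors), electronic eye (EE, 65
color-number counts) and near-infrared spectra (NIR, ~2075 absorbance
values on a 12,000–4,000 cm⁻¹ grid). Each sample carries two labels:
authenticity (authentic FC vs counterfeit) and species (FU, FP, FD
authentic; FUS counterfeit — the label tables enforce FUS ⇔
counterfeit). Mid-level fusion selects discriminant variables per
block, concatenates them, and fits one classifier on the fused matrix.

## Models

### PLS-DA

Classes are indicator-coded with one {0,1} column per class (also in
the binary case, so VIP treats both classes symmetrically). X is
mean-centered (optionally autoscaled), Y mean-centered internally.
Components are extracted sequentially with X-deflation only: the
weight vector of each component is the leading left singular vector of
XᵀY computed on the current residual. This is the exact fixed point of
the NIPALS inner loop (power iteration on XᵀYYᵀX), so the model is the
NIPALS model at machine precision while avoiding the slow-convergence
regime where the two leading covariance eigenvalues nearly tie. The
sign is fixed so each score correlates positively with the
maximal-variance Y column, the inner loop's conventional start.
Regression coefficients are B = W(PᵀW)⁻¹Qᵀ; prediction is the argmax
of the predicted indicators with ties logged and resolved toward the
first class in coding order. The latent-variable count is the smallest
A maximizing LOOCV accuracy; one model with the maximal A is fitted
per fold and truncated coefficient matrices give every candidate's
prediction, so the search costs n fits rather than n·A.

VIP is the multi-response form VIPⱼ = √(p·Σₐ SSYₐ wⱼₐ² / Σₐ SSYₐ),
SSYₐ = (tₐᵀtₐ)‖qₐ‖², which satisfies Σⱼ VIPⱼ² = p; the selection
threshold defaults to 1 (the mean of the squared scores). If a block's
selection comes back empty the top-1 VIP variable is kept with a
warning so fusion never silently loses a block.

### PCA-DA

PCA via SVD of the centered matrix, then Gaussian linear discriminant
functions with pooled within-class covariance on the leading scores;
priors proportional to class sizes; every sample receives a class
(no "unclassified" outcome). `n_pc="auto"` maximizes LOOCV accuracy
(smallest count on ties) up to min(n − g − 1, rank, `max_pc`). The
default `max_pc = 10` bounds the search: pooled-covariance LDA on
scores rarely improves past ~10 components on sensor panels of this
size, and the cap keeps the stepwise loop (which refits the search
after every elimination) at interactive speed. Within one LOOCV fold
the LDA statistics for k components are the leading k×k blocks of the
full-score statistics, so all candidate counts share one SVD per fold.

### Wilks'-lambda stepwise elimination

Univariate Λ = SSW/SST per variable (bounded in [0,1], affine
invariant; smaller = more discriminating). Note the ratio is
within-to-**total**, the standard definition, which matches "smaller
is better". Backward elimination removes the largest-Λ variable of the
remaining set, refits PCA-DA (auto component count) and keeps the
removal while LOOCV accuracy has not dropped below the best seen;
otherwise it undoes the removal and stops. The loop never empties the
set and its trace (accuracy before any removal and after each
committed one) is returned. A separate report-level flag marks fused
variables with Λ < 0.3 as influential; this threshold plays no role in
the stepwise rule itself.

### CARS wavelength selection

N = 100 Monte-Carlo runs (10-fold RMSECV, calibration ratio 0.8 —
standard for the method). The inner PLS component count is chosen once
on the full data by RMSECV and then fixed, for stability and runtime.
Each run draws ⌈0.8·n⌉ samples without replacement, fits PLS on the
currently retained wavelengths, and weights each wavelength by the row
norm of its coefficient matrix (the classification response is the
indicator coding; which labeling drives the response is the caller's
choice, species coding in the pipeline default). The exponentially
decreasing schedule rᵢ = a·e^(−k·i) (r₁ = 1, r_N = 2/p) caps the
retained count; the top-weight wavelengths up to the cap survive
outright, and adaptive reweighted sampling then draws **p** times with
replacement among the survivors in proportion to weight, the union
becoming the next retained set. Drawing a constant p times (rather
than shrinking the draw count with rᵢ) is what produces the
characteristic two-stage decline — fast elimination early, refined
competition late; shrinking draws collapse the set within a few runs
once coefficient weights concentrate. The winning subset minimizes
RMSECV over all samples, earliest run on ties; a fixed seed makes the
whole competition bit-reproducible.

### Evaluation

LOOCV refits pretreatment and classifier on every training fold with
the hyperparameters fixed; by default variable selection is **not**
refit per fold (selection happens once, before model construction),
which matches the study sequence but optimistically biases the fused
accuracy — a nested mode refits selection per fold at ~n× cost.
Metrics: Ac = trace/total; binary Se/Sp/Pre with authentic FC as the
positive class; multi-class values are macro-averaged one-vs-rest with
empty classes skipped under a warning. ROC curves sweep the unique
scores (binary tasks only); AUC equals the Mann-Whitney pair count.
Group differences in single sensor responses use Welch's two-sided
t-test.

## Synthetic panels

The generator emulates what the analysis assumes, with defaults at the
study's design point: 4 classes × 20 samples, blocks of 10/6/65
variables plus a 2075-point NIR grid, 3 replicates per sample averaged
into the analysis matrix.

- **Sensor blocks (EN/ET/EE).** Nonnegative responses = class mean +
  Gaussian noise (sd 1 per replicate), clipped at 0. Class means
  differ only on planted variables (5/3/10 per block, mirroring the
  selected-variable counts such panels report), spread Δ in units of
  the noise sd, Δ = 3 by default. Per variable the counterfeit class
  takes the extreme offset (random sign) and the authentic congeners
  share the interior levels: a counterfeit of a different species is
  more distinct from every authentic class than the congeners are from
  each other, and this keeps planted variables discriminative for both
  tasks. The EE block is a sparse-histogram mimic: non-planted bins
  sit near zero.
- **NIR.** Spectrum = linear baseline + 12 Gaussian peaks (σ = 120
  cm⁻¹) + i.i.d. noise (sd 0.01); 5 peaks carry class-dependent
  amplitudes with the same Δ convention. Informative grid points are
  those within one FWHM of a class-dependent peak center, which makes
  "recovery" well defined on a continuous grid.

One seeded generator drives everything; config + seed fully determine
the panel. What the generator does **not** emulate: instrument drift,
batch effects, heavy-tailed sensor noise, inter-variable correlation
within a block beyond the NIR peak structure, or the actual chemistry
behind the sensors' responses — passing recovery tests shows the
selection machinery works under the assumed signal structure, not that
real panels carry such clean structure.

## Study conditions used by the automated checks

Chosen once as realistic design points, reported here as the package's
own choices: recovery checks run 20 seeds at the generator defaults
(EN block); CARS recovery uses 60 samples × 200 wavelengths with 5
class-dependent peaks of 8 (a down-scaled grid with the same peak
geometry); the fusion-benefit check uses Δ = 0.6 and a 300-point grid,
where single blocks reach ~0.8–0.95 LOOCV accuracy — a weak-signal
regime in which fusion has room to help; null calibration uses Δ = 0.
The worked-example metrics rebuild confusion matrices from the
published misclassification records of a four-instrument Fritillaria
study (85 %, 71.25 %, 97.5 %, 97.5 %, 95 %, 97.5 % species-model
accuracies); the destination classes of the electronic-tongue record
are not itemized in that record, so its errors are routed to arbitrary
placeholder destinations, which leaves the accuracy untouched.

## Numerical choices and degenerate inputs

- Ties: argmax class ties resolve to the first class in coding order
  (logged); equal LOOCV accuracies resolve to the smaller component
  count; equal RMSECV to the earliest CARS run.
- Pretreatment is always refit on training rows inside any
  cross-validation loop; autoscaling a zero-variance column is an
  error naming the column, as are missing values, duplicate sample
  ids, single-class tasks and rank-exhausted component requests.
- Fused matrices default to autoscaling because blocks carry
  heterogeneous units (counts vs absorbance); per-block pretreatment
  defaults to mean centering for all blocks.
- The e-eye binning scheme is treated as opaque named variables; no
  color model is assumed.

## Known limitations

- Default (non-nested) LOOCV shares the variable selection across
  folds; its accuracy is optimistic for small panels. Use
  `nested=True` for an honest but ~n× slower estimate.
- PLS-DA's argmax rule has no reject option; strongly imbalanced
  panels may want threshold calibration, which is out of scope.
- CARS assumes mean-centered PLS throughout; derivative/SNV/MSC
  spectral pretreatments are not implemented.
- Published per-model Se/Sp/Pre values for the worked examples are not
  all mutually consistent with their printed misclassification lists
  under standard macro definitions, so only accuracies are rebuilt.
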