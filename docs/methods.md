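# Methods

`prostadiff` implements a quantitative diffusion-MRI analysis of prostate
tissue: forward signal models of increasing biophysical specificity (ADC,
IVIM, DKI, VERDICT), voxel-wise parameter estimation by a neural network
trained purely on synthetic signals, and the group-level statistics that ask
whether those parameters separate clinically significant cancer
(true-positive lesions, TP), benign disease that mimics cancer on mp-MRI
(false-positive lesions, FP — atrophy, inflammation, high-grade PIN) and
normal tissue (NT).  Because no clinical dataset ships with the package, a
synthetic cohort generator stands in for patient data; everything downstream
of it is the same code a user would run on real volumes.

## Units and acquisition model

Canonical units keep `b·d` of order one: b in ms/μm² (1 ms/μm² = 1000 s/mm²),
diffusivities in μm²/ms, radii in μm, times in ms, gradient amplitude in T/m.
A measurement is a pulsed-gradient spin-echo (PGSE) row (b, δ, Δ, TE, TR, G)
obeying b = γ²G²δ²(Δ − δ/3) with γ = 2.6752218744·10⁸ rad s⁻¹ T⁻¹; the
package cross-checks stored b against (G, δ, Δ) at 0.1% and refuses
inconsistent rows.  The bundled prostate scheme has five diffusion-weighted
measurements at b = 90, 500, 1500, 2000, 3000 s/mm², each paired with its own
b = 0 acquisition at matched timings (10 rows total).  The published protocol
prints only the b-values and the TE/TR ranges, so the per-b gradient timings
in the fixture are representative values consistent with those ranges, not
the clinical settings.

## Forward models

All models are isotropic and normalized to S(b=0) = 1.

* **ADC** — S = exp(−b·d).
* **IVIM** — S = f·exp(−b(D+D*)) + (1−f)·exp(−bD): two non-exchanging pools;
  f is the fast ("vascular") signal fraction, D* the pseudo-diffusivity
  excess of the fast pool.
* **DKI** — S = exp(−b·D_K + b²·D_K²·K/6): quadratic kurtosis correction to
  the log-signal.  The expression is evaluated as printed at every b; beyond
  the convexity bound b > 3/(D_K·K) it turns non-monotone, which is logged
  as a warning rather than clipped.
* **VERDICT** — S = f_VASC·S_astrosticks(d_VASC) + f_IC·S_sphere(R, d_IC)
  + f_EES·S_ball(d_EES), with f_VASC stored as the residual 1 − f_IC − f_EES.
  The astrosticks compartment is the orientation average of randomly oriented
  sticks, S = √π erf(√(bd)) / (2√(bd)), with the bd → 0 limit evaluated by
  series.  The intracellular compartment is restricted diffusion in
  impermeable spheres under the Gaussian phase distribution (GPD)
  approximation; the series runs over the first 20 positive roots of
  j₁′(x) = 0, bracketed per interval (mπ, (m+1)π) and polished to 10⁻¹²
  (20 vs 40 roots changes the signal by < 10⁻⁸ over the clinical regime).
  A cellularity index f_IC/R³ is derived.

The fixed compartment diffusivities default to d_IC = 2.0 and
d_VASC = 8.0 μm²/ms — the standard prostate-VERDICT convention — and are
config-overridable; a warning at config load reminds the user they are model
constants, not fitted.  The GPD signal is cross-checked in the tests against
an independent Monte-Carlo random-walk simulator (10⁵ walkers, 10 μs steps,
radial boundary reflection) that accumulates spin phase directly; agreement
is within 1% over the clinical regime grid.

## Synthetic data

Training corpora draw each parameter independently and uniformly from
biophysically plausible intervals: f ∈ [0.01, 0.99], D, D* ∈ [0.5, 3] μm²/ms
(IVIM); D_K ∈ [0.5, 3], K ∈ [0.01, 2.99] (DKI); f_IC, f_EES ∈ [0.01, 0.99],
R ∈ [0.01, 15] μm, d_EES ∈ [0.5, 3] μm²/ms (VERDICT, rejection-sampled to
f_IC + f_EES ≤ 1, which preserves the marginals' support while honoring the
sum constraint).  Rician noise — the magnitude of a complex Gaussian
perturbation, √((S+ε₁)² + ε₂²) — is added at σ = 1/SNR relative to the unit
b = 0 amplitude (the only consistent reading of "SNR = 35" for normalized
signals); default SNR is 35.  Because all four models are isotropic, the
acquisition's three orthogonal gradient directions differ only in noise, so
the simulator averages three independently noised replicates per row
(reducing the noise SD by √3).  The default corpus is 100,000 voxels, split
80% training / 20% validation.  One root seed spawns per-stage child
streams, so every stage is independently reproducible.

The cohort generator emulates the study design: 19 patients with a TP lesion
ROI plus a contralateral NT ROI, and 19 patients with an FP lesion ROI
(background tissue behaves like NT but is not recorded as an ROI).  Each ROI
draws one parameter vector per model from a class-conditional truncated
normal, adds small voxel-wise jitter, and synthesizes noisy signals — ADC
volumes on the clinical 4-b scheme (b = 0, 150, 500, 1000 s/mm²), the other
models on the 10-row scheme.  The class means are *synthetic constructions*
chosen from prostate-literature ranges so that the qualitative orderings
expected of these tissues hold (f_IC and K: TP > FP > NT; d, D, D_K, d_EES,
f, f_EES: TP < FP; D: FP < NT); the magnitudes of separation are not
calibrated to any clinical dataset.  Passing cohort-level tests therefore
shows that the pipeline *propagates* designed tissue differences into the
correct statistical conclusions — it says nothing about effect sizes, inter-
patient covariance, partial-volume or registration effects in real data.
Each cohort is generated per model: every model's volumes come from its own
parameters, which is what lets each model's designed effect directions be
encoded independently (a single shared generative model could not realize
all printed orderings at once).

## Parameter estimation

The estimator is a multilayer perceptron (scikit-learn `MLPRegressor`):
three hidden layers of 150 ReLU neurons, Adam with initial learning rate
10⁻³ and first-moment decay 0.9, minibatches of 100 voxels, mean-squared
error on min-max-scaled targets, up to 1000 epochs with early stopping
(patience 10 epochs; the 20% validation split is the optimizer's own
hold-out) and restoration of the best-validation-epoch weights.  Inputs are
min-max normalized to [0, 1] *per feature* from the training corpus; targets
are scaled by their prior intervals, and predictions are inverse-mapped and
clipped to the priors (regression can extrapolate; clipping keeps physical
validity and mirrors bounded NLLS).  VERDICT predictions are augmented with
f_VASC = max(0, 1 − f_IC − f_EES) and cellularity.  The recorded validation
loss curve is the per-epoch validation MSE in scaled-target units (derived
from the optimizer's per-epoch validation score against a fixed split).

The independent oracle is bounded multi-start nonlinear least squares:
the sum-of-squares objective is first evaluated on a coarse grid of four
points per parameter axis (vectorized over all voxels), then trust-region
reflective refinement runs from the three best starts per voxel within the
prior box; the VERDICT fraction-sum constraint enters as a penalty residual.
Voxels with no measurable decay are flagged degenerate rather than raised.

The clinical-style ADC map is an ordinary least-squares fit of ln S on −b
with free intercept, using **all b-values except b = 0**, which suppresses
the perfusion (fast-pool) contribution; non-positive signals are excluded
per voxel and voxels with fewer than two usable points are marked missing
(NaN in memory, a sentinel recorded in the NIfTI header on disk, since NIfTI
has no native missing value).  Unweighted OLS on the log-signal is the
conventional estimator for this computation.

### Identifiability under the 10-measurement scheme

The acquisition is optimized for VERDICT, and not every companion-model
parameter is identifiable under it at SNR 35.  Held-out recovery (Pearson r,
20,000 voxels) is ≈ 0.99 for D_K, ≈ 0.91 for f_IC, ≈ 0.85 for D and f_EES,
≈ 0.83 for R and ≈ 0.72 for d_EES — but only ≈ 0.55 for the IVIM perfusion
fraction f.  That ceiling is a property of the data, not the network: a
random forest trained on the same corpus reaches r ≈ 0.54 and the NLLS
oracle ≈ 0.28.  With the biexponential as written, the fast pool decays at
D + D* ≤ 6 μm²/ms, overlapping the slow-pool range, so f trades off against
D* almost freely at noise SD ≈ 0.017.  Voxel-wise IVIM-f estimates should
therefore be read as heavily prior-shrunk; ROI medians still rank tissues
correctly (the shrinkage is monotone), which is why cohort-level IVIM
statistics remain informative.

For the network-vs-NLLS equivalence check, the regressors are trained
noise-free (the question is whether the two estimators implement the same
inverse mapping, not noise robustness), and agreement is gated on the
parameters identifiable under this acquisition — IVIM f and D, DKI D_K,
VERDICT f_IC and f_EES; IVIM D*, VERDICT R and d_EES sit along nearly flat
likelihood directions, where "the" least-squares solution is itself
ill-defined, and are reported without gating.  Even so gated, agreement is
limited by the IVIM inverse map: near the low-D* corner of the prior the
map from signals to (f, D) is extremely steep, NLLS tracks it exactly while
the fixed 3×150 network smooths it, and the network side changes little
with training size — the acceptance suite reports the achieved agreement
and treats the published-architecture limit as a finding, not a bug.

## Statistics

ROI medians (one per patient × class × parameter) are the analysis unit.
Group comparisons use the Wilcoxon signed-rank test preceded by
Shapiro–Wilk, pairing by sorted patient index — the paired test is applied
to structurally unpaired groups deliberately, for fidelity to the emulated
analysis; a Mann–Whitney fallback sits behind the `unpaired` flag (and is
required when group sizes differ).  Zero differences are discarded (classic
policy), the exact null distribution is used for n ≤ 25 pairs and the normal
approximation above, and no multiple-testing correction is applied by
default (matching the emulated analysis; Benjamini–Hochberg can be applied
to the returned p-values if desired).  ROC analysis fixes the score
orientation once per parameter from the group medians and reports it, never
silently flipping per curve; AUC is the rank-sum formulation with tie
half-credit, which equals the trapezoidal area under the empirical curve.
PPV/NPV-maximizing thresholds come from an exhaustive sweep over midpoints
between adjacent sorted unique scores (±∞ included), skipping undefined
ratios, with ties broken toward the larger predicted group.  Correlations
are voxel-level Pearson r² with the sign of the slope, over the canonical
cross-model pairs (D_K, D, K, D* against f_IC, f_EES, f_VASC, d_EES).

## Problem sizes

Default sizes are the study's native ones: 100,000 training signals per
model (80/20 split), 20,000 held-out voxels for recovery, 2,000 voxels for
the estimator-equivalence check (700 IVIM, 700 DKI, 600 VERDICT), 19+19
patients with 54-voxel ROIs on a 6×6×3 per-patient grid for the cohort.
The equivalence-check networks train on 30,000 noise-free signals with a
300-epoch cap — noise-free regression converges quickly, and the cap bounds
the run without changing the outcome.  The Monte-Carlo sphere oracle uses
10⁵ walkers at a 3-point regime grid.

## Known limitations

* The cohort generator draws parameters independently per model and per
  ROI; real tissue induces correlated parameters across models and spatial
  autocorrelation within ROIs.
* No scanner artefacts (motion, eddy currents, Gibbs ringing) are
  simulated; the emulated pipeline removes these in preprocessing steps that
  are out of scope here.
* Relaxation weighting (TE/TR dependence) is not modelled; all compartments
  share one T2, as in plain VERDICT.
* The exact clinical values of d_IC and d_VASC could not be confirmed from
  the source text (typographically lost); the defaults follow the standard
  prostate-VERDICT convention and are flagged at config load.
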