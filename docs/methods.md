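# Methods

## Signal model

Each voxel's diffusion-weighted signal is modelled as a two-compartment
bi-exponential in the diffusion weighting b (s/mm²):

S(b) = S(0) [ f·e^{−b(D + D\*)} + (1 − f)·e^{−bD} ]

D is the molecular-diffusion coefficient (tissue water, mm²/s), D\* the
pseudo-diffusion coefficient of capillary microcirculation, and f the
fraction of the b = 0 signal in the perfusing compartment.  The perfusion
exponent is D + D\* (not D\* alone, a convention some IVIM code uses); this
is applied identically in the forward model and in every fitter, and it
makes the b → 0 apparent diffusion coefficient exactly ADC = D + f·D\*.
Assumptions inherited from the model: mono-exponential behaviour of each
compartment (no kurtosis), no exchange between compartments, and a single
measured S(0).

## The four estimators

All methods are *segmented*: D is estimated first, then the perfusion
parameters with D fixed.

* **S** — D from an ordinary least-squares fit of ln S against b over
  b ≥ b_t (closed form, deterministic; non-positive signals are excluded
  and at least three points are required).  Then (f, D\*) by bounded
  trust-region least squares of the full model over all b-values with D and
  the measured S(0) fixed.
* **OS** — same first stage; f = 1 − S_int/S(0) directly from the fitted
  intercept; D\* is the sole nonlinear parameter.
* **AS** — same first stage; the signal is transformed to
  f̃(b) = 1 − [S(b)/S(0)]·e^{bD}, which under an exact D equals
  f(1 − e^{−bD\*}).  f̃ is fitted with f₀(1 − e^{−bD\*}) + ε over all
  acquired b-values (including the pinned zero at b = 0); ε absorbs error
  in the measured S(0), and the asymptote f₀ is the f estimate.  Negative
  f̃ values under noise are retained — clipping them would bias f₀.
* **opAS** — threshold-free.  The tail estimate D̃(b_t) is computed for
  every acquired b-value that leaves at least four points in the tail
  (b_t ∈ {0, 20, …, 350} for the default 18-value scheme) and the series is
  fitted with D̃(b_t) = ADC − P(1 − e^{−b_t·D\*_tmp}), P standing for the
  product f₀·D\*.  The b_t → ∞ limit D = ADC − P removes the threshold
  dependence; f₀ and D\* then come from the same f̃ stage as AS.  Note that
  this ADC is the decay constant of the *whole-curve* mono-exponential fit
  (the b_t = 0 member of the series), which for realistic b ranges lies well
  below the b → 0 tangent D + f·D\*; only the difference ADC − P is
  quantitatively meaningful, and D\*_tmp is discarded in favour of the f̃
  stage's D\*.

## Numerical choices

* **Bounds.**  f and f₀ are *fitted* in [−1, 1]; D\* in [1/b_max, 0.5] mm²/s;
  ε in [−0.5, 0.5]; trend stage: ADC in [1e-6, 0.1], P in [0, 0.1],
  D\*_tmp in [1/max(b_t), 0.5].
  The lower bound 1/b_max on D\* is an identifiability floor: below it the
  saturation term 1 − e^{−bD\*} is linear over the entire acquisition, only
  the product f₀·D\* is determined, and the optimizer would park at an
  arbitrary point of a flat valley (observed to inflate mean f₀ by an order
  of magnitude at low-f cells before the floor was added).
* **Raw vs. physical estimates.**  Allowing f < 0 in the fit matters for
  benchmarking: with truth near f = 0 a [0, 1]-constrained estimator can
  only err upward, so its replicate mean is biased by construction.
  `FitResult.estimates` carries the raw values (used by the simulation
  study, the batch CSV writer and the parameter maps); `FitResult.params`
  carries the same values clipped to f ∈ [0, 1], D ≥ 0, with clips noted in
  the result message.
* **Initialisation.**  f₀ starts at max(1 − S_int/S(0), 0.01) where an
  intercept is available (S, OS, AS) and at the mean of the last four f̃
  points (the model's own asymptote estimate) for opAS; D\* starts at 10·D;
  ε at 0; ADC at D̃(min b_t); P at max(D̃(min b_t) − D̃(max b_t), 1e-6).
* **Failure handling.**  Optimizer non-convergence returns the initial
  values flagged `converged=False`; the opAS trend stage falls back to
  D̃(max b_t).  Voxelwise fitting therefore never aborts on a degenerate
  voxel (all-zero, non-positive tail, flat signal).
* **Duplicate b-values** are averaged before fitting
  (`SignalCurve.from_measurements`); exactly one b = 0 sample is assumed
  afterwards.

Design options that were evaluated and rejected: inverse-variance (GLS)
weighting of the D̃(b_t) trend fit and of the f̃ fit (reduces noisy-cell
bias but degrades noiseless recovery beyond the 5 % contract); a symmetric
P bound (lets D overshoot ADC at low SNR and pins f₀ at its lower bound);
shorter b_t series (≥5–7 tail points; breaks noiseless recovery at
D\* = 10e-3).

## Error metrics

For N replicate estimates θᵢ of a true value θ_T:
NME = mean((θᵢ − θ_T)/θ_T) (signed bias); CoV = population SD / |mean|
(the 1/N variance, not 1/(N−1); the magnitude in the denominator keeps CoV
a non-negative dispersion measure when raw estimates of a near-zero
parameter average slightly negative); NRMSE = RMS error / θ_T.  These
satisfy NRMSE² = NME² + normalized population variance.  Flux truth is
f_true·D\*_true and the flux estimate is f̂·D̂\* from the same replicate.
Non-converged replicates are included (an optional flag recomputes without
them).

## Synthetic data

* **Replicate curves.**  Grid: D fixed at 1.0e-3 mm²/s; f from 0.02 to 0.50
  in steps of 0.02; D\* from 2.0e-3 to 60e-3 in steps of 2.0e-3; 18
  b-values (0, 20–100 step 10, 150–500 step 50 s/mm²); SNR ∈ {10, 20, 40}
  with SNR = S(0)/σ; 1000 replicates per cell.  Rician noise is realised as
  the magnitude of a complex Gaussian perturbation, √((S+n₁)² + n₂²), drawn
  independently per b-value and per replicate.  S(0) is normalised to 1 —
  all parameters are scale-free, so nothing is lost.  The reduced-scale
  preset used by the acceptance checks thins this to f ∈ {0.02, 0.10, 0.26,
  0.50} × D\* ∈ {2, 10, 30, 60}e-3, SNR ∈ {10, 40}, 200 replicates; it
  changes sampling density only, never the per-cell computation path.
* **Phantom.**  Two ellipsoidal "femoral heads" in a signal-free background:
  a perfused control (D = 1.0e-3, D\* = 30e-3, f = 0.12) and an ischemic
  region (D = 1.6e-3, D\* = 5e-3, f = 0.03) in one volume, default shape
  24×12×5 voxels, emulating a bilateral-hip acquisition of a bone-marrow
  ischemia model.  The cohort study generates n = 11 such subjects (seeded
  independently), fits voxelwise maps per method, takes ROI medians on the
  *central slice* of each region (the convention for manually drawn
  femoral-head ROIs), and runs two-sided paired t-tests on the
  ischemic-minus-control differences with the sample (N−1) SD.

The generators emulate thermal (Rician) noise only: no motion, eddy
currents, partial volume, susceptibility distortion, or between-subject
biological variability (all cohort subjects share the same true
parameters).  Passing benchmarks therefore demonstrates estimator
behaviour under the stated noise model, not performance on real
acquisitions, where inter-subject spread and artifacts add variance that
the paired tests here do not see.

## Imaging pipeline

4D NIfTI plus FSL-style `.bval` sidecar; b-value order is taken from the
sidecar and sorted internally with the volume re-indexed.  The default
voxel mask keeps b = 0 intensities above 5 % of the in-volume 99th
percentile.  Non-fitted voxels carry NaN (never zero); per-voxel failures
are recorded in a convergence mask.  Each voxel's fit depends only on its
own curve, so maps are independent of iteration order, and all randomness
in the package flows through explicit seeds — reruns are byte-identical.

## Known limitations

* **Noiseless high-perfusion corner.**  Over the full noiseless grid, opAS
  recovers f and D\* within 5 % wherever D\* ≥ 10e-3, and D within 5 % for
  D\* ≥ 6e-3 *except* 11 cells with f ≥ 0.46 and D\* ∈ [8e-3, 16e-3], where
  the error reaches 7 %.  A brute-force grid search over the trend model
  reaches the same (slightly worse) error there: the miss is intrinsic to
  approximating the finite-tail D̃(b_t) series with the saturation form,
  not an optimizer artifact.  This corner is the opposite of the
  low-perfusion regime the method targets.
* **Normalized metrics at near-zero truth.**  At f = 0.02 or
  D\* = 2.0e-3 the truth is comparable to (or below) the noise scale, so
  NMEs of order 1–10 occur for every method, |NME| aggregates are dominated
  by these cells, and the CoV denominator can approach zero for the flux.
  Method comparisons in that regime reflect estimator *conventions* (where
  a bounded fit parks an unidentified parameter) as much as information in
  the data.
* **D\* remains the hardest parameter.**  Even the threshold-free method
  overestimates D\* grossly when the true value sits at the identifiability
  floor; its advantage is a roughly two- to four-fold reduction of that
  error relative to the threshold-based fits, not an absolute rescue.
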