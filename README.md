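# ivimseg

Segmented intravoxel-incoherent-motion (IVIM) fitting for diffusion-weighted
MRI, with a focus on **low-perfused tissues** such as bone marrow, where the
perfusion signal is weak and conventional threshold-based fitting becomes
unreliable.

IVIM models the per-voxel diffusion signal decay as a two-compartment
bi-exponential,

```
S(b) = S(0) [ f e^{-b (D + D*)} + (1 - f) e^{-b D} ]
```

with molecular-diffusion coefficient *D* (mm²/s), pseudo-diffusion
coefficient *D\** (microcirculation, mm²/s), and pseudo-diffusion fraction
*f*.  The package implements four segmented estimators of (D, D\*, f):

| method | D stage | perfusion stage |
|--------|---------|-----------------|
| **S**  | log-linear fit over b ≥ b_t | (f, D\*) by nonlinear LS, D and S(0) fixed |
| **OS** | same | f = 1 − S_int/S(0) from the intercept; only D\* fitted |
| **AS** | same | fit of the residual curve f̃(b) = 1 − [S(b)/S(0)]e^{bD} with f₀(1 − e^{−bD\*}) + ε |
| **opAS** | threshold-free: D̃(b_t) computed for a series of thresholds and extrapolated to b_t → ∞ via D̃(b_t) = ADC − P(1 − e^{−b_t D\*}), D = ADC − P | as AS |

The b-threshold b_t is the weighting above which perfusion is assumed
negligible; any error in the D it yields propagates into f and D\*, which is
the dominant failure mode when D\* is only a few times larger than D.  opAS
removes the threshold choice entirely, which is what makes it attractive for
low-perfusion imaging.

Around the fitters the package provides a Rician-noise replicate simulator
and two-region phantom generator, the standard estimator-benchmarking
metrics (NME, CoV, NRMSE), a voxelwise parameter-mapping pipeline for 4D
NIfTI volumes with FSL-style `.bval` sidecars, and a CLI.

## Worked example

A noiseless low-perfusion curve (D\* only four times D) makes the
threshold-contamination mechanism visible without any noise in the way:

```python
from ivimseg import IVIMParams, SignalCurve, ivim_signal, fit_opAS, fit_S
from ivimseg.simulate import DEFAULT_BVALUES

truth = IVIMParams(D=1.0e-3, Dstar=4e-3, f=0.10)      # low-perfusion voxel
curve = SignalCurve(DEFAULT_BVALUES, ivim_signal(truth, DEFAULT_BVALUES, S0=1.0))

for res in (fit_S(curve, b_t=100.0), fit_opAS(curve)):
    e = res.estimates
    print(f"{res.method:>4}: D={e['D']:.2e}  D*={e['Dstar']:.2e}  f={e['f']:.3f}")
```

```
   S: D=1.14e-03  D*=1.10e-02  f=0.029
opAS: D=1.06e-03  D*=5.68e-03  f=0.066
```

At this D\* the perfusion term has not fully decayed above b_t = 100 s/mm²,
so the segmented fit's tail D absorbs it (+14 %), which in turn drags f down
to a third of the truth and nearly triples D\*; the threshold-free opAS fit
halves every one of those errors.  `FitResult.estimates` holds the raw
estimator values used for benchmarking; `FitResult.params` holds the same
values clipped to their physical ranges.

The replicate study and the paired phantom cohort are driven from
`ivimseg.experiments` or the CLI:

```bash
ivimseg simulate --f 0.1 --dstar 0.03 --snr 40 --reps 100 --seed 0 --out curves.csv
ivimseg fit-csv curves.csv --method opAS --out fits.csv
ivimseg study config.yaml --kind simulation --outdir results/
```

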