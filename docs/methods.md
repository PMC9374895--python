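# Methods

This note documents the models, estimators and numerical choices in
`tensorhrf`, the defaults of the synthetic generator and what they do and
do not emulate, and the known limitations.

## 1. Neural simulator

### Modified Stuart–Landau oscillators

Each node j carries two oscillator pairs. The *slow* pair (u_j, v_j)
follows the Cartesian Stuart–Landau (Hopf normal form) equations

    du/dt = (α_s − u² − v²) u − ω_s v + G Σ_i C_ij u_i + β η
    dv/dt = (α_s − u² − v²) v + ω_s u + G Σ_i C_ij v_i + β η

with ω_s = 2π·0.08 Hz, linear inter-node coupling through the structural
matrix C scaled by the global gain G = 0.3, and additive white Gaussian
noise of amplitude β. The *fast* pair (x_j, y_j) has no inter-node
coupling; its bifurcation parameter is time-varying, driven by the slow
pair:

    dx/dt = (α_f u_j − x² − y²) x − ω_f y + β η
    dy/dt = (α_f v_j − x² − y²) y + ω_f x + β η

so the fast amplitude tracks the rectified slow trajectory (limit-cycle
radius √α for α > 0, silence for α ≤ 0). Frequencies are stated in Hz and
enter as ω = 2πf. Fast frequencies are hemisphere-split: 2 Hz on the
right, 10 Hz on the left.

### Defaults and why

| parameter | default | rationale |
| --- | --- | --- |
| α_s | 0.05 | near the bifurcation: the slow amplitude is noise-driven, giving rich, broadband amplitude dynamics, and the weakly nonlinear fast oscillator emits little harmonic distortion into neighbouring bands |
| β | 0.05 | enough state noise to drive the slow amplitude through regimes without burying the oscillation |
| α_f | 2π·f_fast per node | relaxation rate proportional to rotation rate: preserves the spectral peak at f_fast (strong relaxation would pin the oscillator and collapse its spectrum) while the envelope follows the modulator with little lag |
| G | 0.3 | global coupling gain |
| connectome weight scale | 0.1 (mean node strength) | identical-frequency slow oscillators synchronise easily; at mean strength 1 the network locks globally and every BOLD signal correlates with every region's envelope, destroying spatial/spectral specificity. 0.1 keeps mean cross-node slow correlation ≈ 0.2 (partial, structured coupling) |
| inter-hemisphere scale | 0.25 | tractography connectomes are intra-hemisphere dominated; this keeps each hemisphere's slow dynamics more internally coherent |
| dt | 1 ms | ≥ 4 integration samples per period up to the 50 Hz gamma edge |
| stored rate | 200 Hz | Nyquist-safe for the 32–50 Hz band |
| transient | 20 s | flagged on the output and removed before analysis |

Integration uses a Stratonovich–Heun predictor–corrector with one shared
Wiener increment per step (additive noise, so Stratonovich = Itô); with
β = 0 it reduces to deterministic Heun. Initial conditions are small
random perturbations of the origin from the same seed stream.

Synthetic connectomes draw log-normal weights on a Bernoulli(density)
edge set, symmetrise, scale hemisphere-crossing edges, and normalise the
mean node strength — a stand-in for tractography matrices that preserves
the features that matter here (symmetry, non-negativity, hemispheric
block structure, bounded total drive).

### Measured LFP

The *measured* LFP adds an incoherent sensor-noise floor (default 10% of
each node's signal SD) to the simulated trajectory; the floor enters the
band-amplitude analysis path only, never the hemodynamic drive. This
choice is load-bearing. State noise passes *through* the oscillator, so
the envelope of every band — including bands far from the oscillation —
is gain-modulated by the slow dynamics and hence coherent with the
BOLD-generating amplitude; after the 32-s estimation kernels smooth away
the incoherent part of an envelope, even a small coherent fraction yields
a high cell correlation, and the ordinary-least-squares kernels of such
noisy-but-coherent regressors are inflated by the inverse of their
attenuation. Together these invert the spectral ordering that the CPD
should recover. An observation floor is incoherent by construction,
restores the selectivity of the soft threshold, and mirrors the empirical
observation that a little input measurement noise *improves* band
separation.

## 2. Hemodynamics

The balloon model (flow-inducing signal s, flow f, venous volume v,
deoxyhemoglobin q) uses the standard constants τ_s = 1.54 s,
τ_f = 2.46 s, τ_0 = 0.98 s, α = 0.32, E0 = 0.34, V0 = 0.02, ε = 0.54,
with k1 = 7E0, k2 = 2, k3 = 2E0 − 0.2. Regional variability enters
through the autoregulation constant τ_f, drawn per node from a log-normal
with variate mean 2.46 s and SD 0.212 s (the underlying normal parameters
are solved from these moments). τ_f controls the post-stimulus
undershoot: the depth/peak ratio falls monotonically from ≈ 0.31 at
τ_f = 0.8 s to ≈ 0 at τ_f = 8 s, so both undershoot and no-undershoot
regimes exist.

The neural drive is the squared LFP, standardised per node (zero mean,
unit SD). Standardisation keeps every node in the model's quasi-linear
input range regardless of oscillator amplitude — the same range in which
the model's linearity is quantified (median linear-reconstruction
correlation ≈ 0.95 for unit-variance white-noise drive). Integration is
deterministic fixed-step RK4 at the input step (sub-stepped ×5 when the
input arrives at 4 Hz); oxygen extraction and volume terms are guarded
against non-physical f, v ≤ 0.

## 3. Physiology and SLFOs

Respiration is a standard stochastic Stuart–Landau oscillator at 0.25 Hz
(α = 1, β = 0.1), low-passed at 1 Hz before any differentiation — the raw
stochastic path has an unbounded derivative which would drive the cardiac
modulation negative. The PPG oscillator is a two-cell system with
tanh(k·x) outputs (μ = 0.5, p1 = −0.3, p2 = 0.3, b = 1, k = 1.5) whose
inverse time-constant 1/τ(t) = a·dRW/dt + c (a = 7, c = 14) couples the
cardiac cycle rate to respiration (respiratory sinus arrhythmia); the
autonomous cycle sits near 1 beat/s. A parameter-regime error is raised —
not clipped — if 1/τ goes non-positive. With these constants and output
nonlinearity the x₂ waveform has a single systolic maximum per cycle; a
distinct diastolic secondary peak does not emerge anywhere in k ∈ [1, 5],
so tests assert periodicity, rate and RSA coupling rather than a
double-peak shape.

Heart rate is the reciprocal inter-beat interval (systolic peaks above
the 60th amplitude percentile, ≥ 0.4 s apart), assigned at interval
midpoints and linearly interpolated to the working grid; respiratory flow
is the squared derivative of the respiration waveform. SLFO = CRF * (HR −
mean) + RRF * (RF − mean), using the standard double-gamma cardiac and
respiratory response functions; ≥ 98% of SLFO power lies below 0.2 Hz at
the defaults. Node susceptibility weights are a smoothed log-normal
random field over the node index, normalised to mean 1 — a synthetic
stand-in for empirical SLFO-association maps.

## 4. Band amplitudes and confound injection

Band envelopes use linear-phase FIR band-passes (Hamming window,
transition min(f_lo/2, 1 Hz)) applied in zero-phase 'same' alignment,
followed by the analytic-signal magnitude. The transition rule matters: a
2 Hz oscillation must not leak through the 4–8 Hz filter's edge, because
any coherent leakage survives the later kernel smoothing. Envelopes are
truncated (20 s transient), linearly detrended, anti-alias filtered and
polyphase-resampled to 4 Hz, forming the amplitude tensor
(space × frequency × time).

Confounds follow a 5×5×5 grid with coefficients {0, 0.1, 0.46, 2.15, 10}:

* **input noise (ki)** — white noise pushed through the *identical*
  band-pass → Hilbert → decimate path (its envelope is marginally
  Rayleigh), mean-centred, scaled to ki × the cell's SD, added per cell;
* **output noise (ko)** — white noise at ko × the node's BOLD SD;
* **SLFOs (kp)** — the global SLFO signal scaled per node by
  kp × susceptibility weight × BOLD SD.

## 5. SSRF estimation

The lag basis is the spherical-Laguerre family sampled as
x·e^{−x/2}·L_p^{(2)}(x) with x = 2·decay·t, ℓ2-normalised per column:
every column is exactly zero at lag 0 (no instantaneous pathway), decays
essentially to zero by the 32-s memory end across the whole sweep range
[0.40, 3.00], and larger decay compresses the support monotonically.
Three functions balance flexibility against variance.

Estimation z-scores both signals, convolves the input with each basis
column at the input rate (decimating the convolved regressors afterwards
when the input runs faster than BOLD — down-sampling after convolution
loses less information), and solves ordinary least squares with an
explicit rank check. No regularisation: 3 coefficients against hundreds
of samples. The decay rate (and, when requested, the soft-threshold
percentile) is chosen by sweeping a grid and maximising the final
goodness-of-fit of the whole pipeline, ties to the smallest decay.

## 6. HRF tensor, rescaling, CPD

SSRFs are stacked lag × space × frequency (× subject); missing cells are
an error, never imputed. Soft-threshold rescaling convolves each cell's
(z-scored) amplitude signal with its kernel, correlates with the real
BOLD, sets θ to the requested percentile of |r| over cells, and scales
each cell by sign(r)·max(|r| − θ, 0): the percentile operates on |r| and
the sign is preserved, so anti-correlated cells survive with negative
weight. Order-4 tensors are preprocessed by dividing each subject slab by
its RMS and centring across the frequency mode.

CPD uses alternating least squares: uniform random init, default 10
restarts (fewer in surrogate loops), tolerance 1e-8 on the relative-error
change, max 500 sweeps, seed-controlled; the relative reconstruction
error is non-increasing within a restart and the best restart is
returned (flagged if unconverged). Non-temporal factor columns are unit
ℓ2-norm with the scale λ ≥ 0 absorbed into the temporal factor, so the
HRF waveform keeps physical scale; components are ordered by energy.
Reconstruction contracts the amplitude tensor with the spatial then
spectral factors (N-mode products), convolves causally with the temporal
factor, z-scores, and correlates with the reference BOLD; with rank > 1
the per-component estimates are combined by OLS with intercept
(collinear estimates dropped with a warning).

`NodePipeline` caches the convolved-basis design matrices and their QR
factorisations, which depend only on the amplitude tensor and basis, so
surrogate-heavy procedures re-run the full path at ~10 ms per call; it is
exactly equivalent to the reference path (tested).

## 7. Inference

Phase randomisation preserves rFFT magnitudes (DC and Nyquist untouched)
with i.i.d. uniform phases elsewhere; the full estimation path is re-run
on every surrogate. The empirical p-value uses the add-one estimator
(1 + #{r_null ≥ r_obs})/(1 + n). Two decision rules are provided:
Bonferroni on the empirical p (α/n_tests) and the 95th-percentile rule.
Note the granularity constraint: with 99 surrogates the smallest
attainable p is 1/100, so Bonferroni across many tests requires more
surrogates, while the percentile rule remains usable. Defaults: 199
surrogates in tests, 999 for reported runs.

The residual block-bootstrap cuts residuals into contiguous blocks
(default length ⌈√n⌉), resamples with replacement and adds them back to
the estimate — a more liberal null appropriate for narrowband signals
where phase randomisation is stringent.

The delete-d jackknife removes d (default 2) scattered time points from
both series at the common grid, re-runs the pipeline, aligns each CPD
result to the full-data reference (exhaustive permutation maximising
summed per-component products of absolute congruences; per-mode signs
made nonnegative with parity constrained to +1 per component, the
least-confident mode flipped when needed — only signs are applied, never
magnitudes), and reports element-wise median and 5th/95th percentile
envelopes. Failed or unalignable iterations are excluded and counted.

## 8. What the generator does and does not emulate

The simulator reproduces the structural features the estimator relies on:
band-limited oscillations with slow, connectome-coupled amplitude
dynamics; regionally variable hemodynamics; physiologically shaped
confounds with spatial structure; realistic sampling-rate asymmetry
(200 Hz LFP, 4 Hz analysis grid). It does not emulate: volume conduction
or sensor mixing (each node is observed directly), MR acquisition
artefacts (gradient/ballistocardiogram residue, motion, slice timing),
1/f background spectra, non-stationary band frequencies, or conduction
delays. Passing tests therefore demonstrate the estimator's correctness
under the stated generative assumptions, not robustness to EEG-fMRI
artefact regimes.

## 9. Problem sizes used in validation

The validation suite runs a 10-node network (5 per hemisphere) for 600
analysed seconds for spectral-recovery and noise-robustness checks, the
full 66-node geometry for 280 analysed seconds for tensor-shape checks, a
4-node noise-free closed loop for HRF-waveform recovery, 99 surrogates
per null with the 95th-percentile rule, and 20 repetitions of the
balloon linearity experiment (600 s at 4 Hz each). These sizes were
chosen so the entire validation runs comfortably on a laptop-class
single core while leaving each check's statistical power intact.

## 10. Known limitations

* Soft-threshold cell weights mix correlation with regression gain; for
  coherent-but-noisy cells the OLS kernel inflation can offset the
  correlation ordering (see §1, measured-LFP floor). Real measurement
  noise mitigates this; heavily model-generated data without any
  observation noise will not separate bands cleanly.
* ALS-CPD has no regularisation (smoothness/non-negativity); rank
  selection is caller-specified (1 or 2), never automatic.
* The jackknife deletes scattered time points, which slightly perturbs
  the convolution structure around each gap; envelopes at very small n
  include that perturbation.
* The PPG model produces single-peaked pulses (no dicrotic notch) under
  the tanh output nonlinearity.
* The decay sweep optimises in-sample goodness-of-fit; no held-out
  validation is performed anywhere in the pipeline.
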