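# tensorhrf

Spatial–spectral correlates of BOLD-fMRI from electrophysiology, via
canonical polyadic decomposition (CPD) of hemodynamic-response-function
(HRF) tensors — together with the whole-brain simulator used to validate
the method.

## The problem

Electrophysiological recordings (LFP/EEG) and BOLD-fMRI see the same
neural activity through very different windows: band-limited oscillatory
amplitudes at millisecond resolution versus a slow, regionally variable
hemodynamic blur. Linking them requires answering three questions at once:
*which* regions, *which* frequency bands, and *through what* hemodynamic
response function a BOLD signal reflects oscillatory amplitude dynamics —
without assuming a canonical HRF shape.

`tensorhrf` addresses this jointly. For one BOLD signal y(t) and a set of
band-amplitude signals x_{i,b}(t) (region i, band b), a spatial–spectral
response function (SSRF) h_{i,b}(τ) is estimated for every (i, b) pair by
least squares on a spherical-Laguerre basis (3 functions, 32 s memory,
decay rate swept over a grid). The SSRFs are stacked into an **HRF
tensor** H ∈ ℝ^{lag × space × frequency} (order 4 with a subject mode),
sparsified by soft-thresholding each cell's predicted-BOLD correlation,
and decomposed as

  H ≈ Σ_{n=1..N}  a_n ∘ b_n ∘ c_n

where a_n is the dominant HRF waveform and b_n, c_n the spatial and
spectral weightings. Contracting the amplitude tensor with b_n and c_n
(N-mode products) gives a *compound signal*; convolved with a_n it
estimates the BOLD signal, and the Pearson correlation r of that estimate
against y(t) is the goodness-of-fit, tested against a phase-randomisation
null (or a residual block-bootstrap), with delete-2 jackknife envelopes
for the CPD factors.

The package also contains the full generative model used to validate the
framework: a network of modified Stuart–Landau oscillators (a slow,
connectome-coupled pair modulating the bifurcation parameter of a fast
oscillator per node) producing LFP-like signals; balloon-model BOLD with
log-normally sampled regional autoregulation constants; and simulated
respiration/PPG physiology whose heart-rate and respiratory-flow signals,
convolved with the standard cardiac/respiratory response functions, form
systemic low-frequency oscillation (SLFO) confounds with spatially
structured node weights. Input noise, output noise and SLFOs can be
injected under the 5×5×5 scaling grid {0, 0.1, 0.46, 2.15, 10}³.

Intended users: researchers in multimodal neuroimaging who want either a
data-driven HRF/spatial/spectral estimator for band-amplitude + BOLD
time-series, or a controllable whole-brain test bed for such estimators.

## Worked example

```python
import numpy as np
from tensorhrf import (RunConfig, simulate_dataset, NodePipeline,
                       spherical_laguerre_basis)

config = RunConfig()
config.simulation.n_nodes = 10      # 5 right-hemisphere nodes @ 2 Hz,
config.simulation.duration = 620.0  # 5 left @ 10 Hz, 0.08 Hz modulation
data = simulate_dataset(config, seed=11)

amp = data["amplitude"]             # (10 nodes, 5 bands, 2401) @ 4 Hz
bold = data["bold_clean"].values    # (10, 2401) @ 4 Hz
basis = spherical_laguerre_basis(n_basis=3, decay=1.0, length_s=32.0, fs=4.0)
pipe = NodePipeline(amp, basis, percentile=25.0, rank=1, seed=1)

bands = ["delta", "theta", "alpha", "beta", "gamma"]
for node in (0, 9):
    cpd, estimate, r = pipe(bold[node])
    top = bands[int(np.argmax(np.abs(cpd.spectral[:, 0])))]
    print(f"node {node}: r = {r:.3f}, dominant band = {top}")
```

Output:

```
node 0: r = 0.877, dominant band = delta
node 9: r = 0.760, dominant band = alpha
```

Node 0 sits in the right hemisphere, where the fast oscillators are tuned
to 2 Hz, so its BOLD signal is explained by delta-band (1–4 Hz) amplitude;
node 9 is left-hemisphere (10 Hz) and recovers alpha (8–12 Hz). The r
values are the correlations between each node's BOLD signal and its
CPD-based reconstruction from the band-amplitude tensor.

A command-line interface drives the same path end to end:

```bash
tensorhrf simulate --out runs/demo --seed 11
tensorhrf estimate --data runs/demo --out runs/demo_est --rank 1
tensorhrf infer    --data runs/demo --estimates runs/demo_est \
                   --out runs/demo_inf --mode phase --jackknife 100
```

All artefacts are TSV + JSON with manifests recording seeds and
configuration; re-running a manifest reproduces outputs bit-exactly.

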