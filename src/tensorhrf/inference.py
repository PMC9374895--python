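"""Surrogate-based inference and CPD stability assessment.

Statistical significance of the BOLD goodness-of-fit is assessed against a
null distribution built by phase-randomising the BOLD signal and re-running
the entire estimation path (SSRF estimation, tensor rescaling, CPD,
reconstruction, correlation) on each surrogate.  Phase randomisation keeps
the amplitude spectrum — hence the autocovariance — of the BOLD signal and
destroys only its phase relation to the amplitude signals, which is the
coupling the method claims to detect.  A residual block-bootstrap provides
a more liberal alternative null.  CPD stability is quantified with a
delete-d jackknife whose per-iteration factors are matched to the
full-data decomposition (permutation + admissible sign flips) before
percentile envelopes are formed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .signal_prep import AmplitudeTensor
from .tensor_cpd import CPDResult

__all__ = [
    "NullDistribution",
    "InferenceResult",
    "JackknifeSummary",
    "phase_randomize",
    "build_null",
    "test_significance",
    "block_bootstrap_residuals",
    "align_cpd_components",
    "apply_alignment",
    "jackknife_cpd",
]


@dataclass
class NullDistribution:
    r_null: np.ndarray
    n_surrogates: int
    method: str = "phase_randomisation"
    n_failed: int = 0

    def __post_init__(self):
        self.r_null = np.asarray(self.r_null, dtype=float)
        if np.any(np.abs(self.r_null) > 1 + 1e-12):
            raise ValueError("null correlations must lie in [-1, 1]")


@dataclass
class InferenceResult:
    r_obs: float
    p_empirical: float
    alpha_level: float
    n_tests: int
    reject: bool


@dataclass
class JackknifeSummary:
    """Element-wise median and 5th/95th percentile envelopes per factor."""

    median: dict
    p05: dict
    p95: dict
    n_iterations: int
    n_excluded: int = 0


def phase_randomize(signal: np.ndarray, seed: int | None = None) -> np.ndarray:
    """Surrogate with the original amplitude spectrum and random phases.

    DC and (for even length) Nyquist bins are untouched; all other phases
    are i.i.d. uniform with Hermitian symmetry, so the output is real with
    the original mean, variance and autocovariance (in expectation).
    """
    x = np.asarray(signal, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("signal too short to phase-randomise")
    rng = np.random.default_rng(seed)
    spec = np.fft.rfft(x)
    k = len(spec)
    randomisable = slice(1, k - 1 if n % 2 == 0 else k)
    phases = rng.uniform(0, 2 * np.pi, len(range(*randomisable.indices(k))))
    spec[randomisable] = np.abs(spec[randomisable]) * np.exp(1j * phases)
    return np.fft.irfft(spec, n=n)


def build_null(run_pipeline_fn, bold: np.ndarray, n_surrogates: int = 199,
               seed: int | None = None) -> NullDistribution:
    """Null distribution of goodness-of-fit over phase-randomised BOLD.

    ``run_pipeline_fn(surrogate_bold) -> r`` must execute the full
    estimation path against the surrogate.  Surrogates whose pipeline run
    fails are skipped and counted.
    """
    if n_surrogates < 19:
        raise ValueError("need at least 19 surrogates for a 5% test")
    rng = np.random.default_rng(seed)
    r_null = []
    n_failed = 0
    for _ in range(n_surrogates):
        surrogate = phase_randomize(bold, seed=int(rng.integers(2 ** 31)))
        try:
            r = float(run_pipeline_fn(surrogate))
        except Exception:
            n_failed += 1
            continue
        if np.isfinite(r):
            r_null.append(r)
        else:
            n_failed += 1
    return NullDistribution(r_null=np.array(r_null), n_surrogates=len(r_null),
                            n_failed=n_failed)


def test_significance(r_obs: float, null: NullDistribution,
                      alpha: float = 0.05, n_tests: int = 1,
                      mode: str = "bonferroni_percentile") -> InferenceResult:
    """Empirical p-value and rejection decision.

    ``p = (1 + #{r_null >= r_obs}) / (1 + n_surrogates)`` (add-one
    estimator, so p is never 0).  ``bonferroni_percentile`` rejects when
    ``p < alpha / n_tests``; ``percentile95`` rejects when ``r_obs``
    exceeds the 95th percentile of the null.
    """
    if null.n_surrogates == 0:
        raise ValueError("empty null distribution")
    if mode not in ("bonferroni_percentile", "percentile95"):
        raise ValueError(f"unknown mode {mode!r}")
    r_null = null.r_null
    p = (1 + int(np.sum(r_null >= r_obs))) / (1 + null.n_surrogates)
    if mode == "bonferroni_percentile":
        reject = p < alpha / n_tests
    else:
        reject = r_obs > np.percentile(r_null, 95)
    return InferenceResult(r_obs=float(r_obs), p_empirical=float(p),
                           alpha_level=alpha, n_tests=n_tests,
                           reject=bool(reject))


def block_bootstrap_residuals(bold: np.ndarray, estimate: np.ndarray,
                              block_len: int | None = None,
                              n_replicates: int = 100,
                              seed: int | None = None) -> np.ndarray:
    """Residual block-bootstrap replicates of the BOLD signal.

    Residuals (bold - estimate) are cut into contiguous blocks of
    ``block_len`` (default ceil(sqrt(n))), resampled with replacement,
    concatenated to the original length and added back to the estimate.
    Returns an (n_replicates, n) array.
    """
    y = np.asarray(bold, dtype=float)
    e = np.asarray(estimate, dtype=float)
    n = len(y)
    if len(e) != n:
        raise ValueError("bold and estimate must share one grid")
    if block_len is None:
        block_len = int(np.ceil(np.sqrt(n)))
    if block_len < 1 or block_len > n:
        raise ValueError("block_len must lie in [1, len(bold)]")
    resid = y - e
    # contiguous non-overlapping segmentation; a trailing partial block is
    # kept in the pool so every residual sample can be drawn
    blocks = [resid[s:s + block_len] for s in range(0, n, block_len)]
    n_draw = n // block_len + 1
    rng = np.random.default_rng(seed)
    reps = np.empty((n_replicates, n))
    for i in range(n_replicates):
        picks = rng.integers(0, len(blocks), size=n_draw)
        r = np.concatenate([blocks[p] for p in picks])[:n]
        while len(r) < n:  # partial blocks drawn; top up
            r = np.concatenate([r, blocks[rng.integers(0, len(blocks))]])[:n]
        reps[i] = e + r
    return reps


# ---------------------------------------------------------------------------
# CPD component alignment and jackknife
# ---------------------------------------------------------------------------


def _congruence(u, v):
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def align_cpd_components(reference: CPDResult, candidate: CPDResult):
    """Resolve CPD permutation and sign ambiguity against a reference.

    The permutation maximises the summed product over modes of absolute
    congruences (exhaustive search; ranks used here are small).  Per
    matched component, each mode's sign makes its congruence nonnegative;
    because only sign changes with product +1 over modes leave the
    reconstructed tensor unchanged, an odd number of flips is repaired by
    flipping the mode with the weakest |congruence|.  Magnitudes are never
    applied.

    Returns ``(permutation, signs)`` with signs of shape (n_modes, rank):
    ``candidate`` component ``perm[j]`` matches reference component ``j``
    after multiplying mode ``m`` by ``signs[m, j]``.
    """
    if reference.rank != candidate.rank:
        raise ValueError("rank mismatch")
    ref_f = reference.factors
    cand_f = candidate.factors
    if any(r.shape != c.shape for r, c in zip(ref_f, cand_f)):
        raise ValueError("mode extent mismatch")
    rank = reference.rank
    n_modes = len(ref_f)
    # congruence of every (ref component j, cand component l) pair
    C = np.ones((rank, rank))
    sgn = np.ones((n_modes, rank, rank))
    for m in range(n_modes):
        for j in range(rank):
            for l in range(rank):
                c = _congruence(ref_f[m][:, j], cand_f[m][:, l])
                C[j, l] *= abs(c)
                sgn[m, j, l] = 1.0 if c >= 0 else -1.0
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(rank)):
        score = sum(C[j, perm[j]] for j in range(rank))
        if score > best_score:
            best_perm, best_score = perm, score
    signs = np.ones((n_modes, rank))
    for j in range(rank):
        l = best_perm[j]
        s = sgn[:, j, l].copy()
        if np.prod(s) < 0:
            # parity repair: flip the least-confident mode
            cong = [abs(_congruence(ref_f[m][:, j], cand_f[m][:, l]))
                    for m in range(n_modes)]
            s[int(np.argmin(cong))] *= -1
        signs[:, j] = s
    return np.array(best_perm), signs


def apply_alignment(candidate: CPDResult, permutation, signs) -> CPDResult:
    """Return the candidate with components permuted and sign-corrected."""
    perm = np.asarray(permutation)
    factors = [f[:, perm] * signs[m][None, :]
               for m, f in enumerate(candidate.factors)]
    return CPDResult(rank=candidate.rank, temporal=factors[0],
                     spatial=factors[1], spectral=factors[2],
                     subject=factors[3] if candidate.subject is not None else None,
                     weights=candidate.weights[perm], fit=candidate.fit,
                     converged=candidate.converged)


def jackknife_cpd(run_pipeline_fn, amplitude_tensor: AmplitudeTensor,
                  bold: np.ndarray, n_delete: int = 2,
                  n_iterations: int = 100,
                  seed: int | None = None) -> JackknifeSummary:
    """Delete-d jackknife of the CPD outputs.

    Per iteration, ``n_delete`` time points (on the common amplitude/BOLD
    grid) are removed from both series before the full pipeline re-runs via
    ``run_pipeline_fn(amplitude_tensor, bold) -> CPDResult``; the resulting
    factors are aligned to the full-data decomposition and summarised
    element-wise by the median and the 5th/95th percentiles.
    """
    if n_delete < 0:
        raise ValueError("n_delete must be nonnegative")
    reference = run_pipeline_fn(amplitude_tensor, bold)
    rng = np.random.default_rng(seed)
    n_times = amplitude_tensor.values.shape[2]
    y = np.asarray(bold, dtype=float)
    mode_names = ["temporal", "spatial", "spectral"] + (
        ["subject"] if reference.subject is not None else [])
    stacks = {name: [] for name in mode_names}
    n_excluded = 0
    for _ in range(n_iterations):
        if n_delete > 0:
            drop = rng.choice(n_times, size=n_delete, replace=False)
            keep = np.setdiff1d(np.arange(n_times), drop)
            sub = AmplitudeTensor(values=amplitude_tensor.values[:, :, keep],
                                  fs=amplitude_tensor.fs,
                                  band_spec=amplitude_tensor.band_spec,
                                  node_names=list(amplitude_tensor.node_names),
                                  source_fs=amplitude_tensor.source_fs,
                                  source_n=amplitude_tensor.source_n,
                                  t_trunc=amplitude_tensor.t_trunc)
            y_sub = y[keep[keep < len(y)]]
        else:
            sub, y_sub = amplitude_tensor, y
        try:
            cand = run_pipeline_fn(sub, y_sub)
            perm, signs = align_cpd_components(reference, cand)
            aligned = apply_alignment(cand, perm, signs)
        except Exception:
            n_excluded += 1
            continue
        for name, f in zip(mode_names, aligned.factors):
            stacks[name].append(f)
    if not stacks[mode_names[0]]:
        raise RuntimeError("every jackknife iteration failed")
    med, p05, p95 = {}, {}, {}
    for name in mode_names:
        arr = np.stack(stacks[name])
        med[name] = np.median(arr, axis=0)
        p05[name] = np.percentile(arr, 5, axis=0)
        p95[name] = np.percentile(arr, 95, axis=0)
    n_ok = len(stacks[mode_names[0]])
    return JackknifeSummary(median=med, p05=p05, p95=p95,
                            n_iterations=n_ok, n_excluded=n_excluded)


def write_inference_json(result: InferenceResult, null: NullDistribution, path):
    payload = {"r_obs": result.r_obs, "p_empirical": result.p_empirical,
               "alpha_level": result.alpha_level, "n_tests": result.n_tests,
               "reject": result.reject, "method": null.method,
               "n_surrogates": null.n_surrogates, "n_failed": null.n_failed}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
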