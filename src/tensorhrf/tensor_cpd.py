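"""HRF tensors, canonical polyadic decomposition, and BOLD reconstruction.

The SSRFs estimated for one BOLD signal are stacked into an HRF tensor
(lag x space x frequency, plus a subject mode for multi-subject data).
Soft-threshold rescaling sparsifies it: each cell's kernel is scaled by the
soft-thresholded correlation between its predicted BOLD and the real BOLD.
Canonical polyadic decomposition (CPD) then extracts rank-R structure

    X  =  sum_i  a_i o b_i o c_i (o d_i)

whose temporal factors are the dominant HRF waveforms and whose remaining
factors are spatial / spectral (/ subject) weightings.  Contracting the
amplitude tensor with the spatial and spectral factors (N-mode products)
yields a compound signal; convolved with the temporal factor it estimates
the BOLD signal, and the Pearson correlation of that estimate with the
real BOLD is the pipeline's goodness-of-fit.

CPD is computed by alternating least squares (ALS) with random restarts;
the relative reconstruction error is monotone non-increasing within each
restart.  Factors carry the usual CPD indeterminacies (scale, sign,
permutation); non-temporal factor columns are returned unit-norm with the
component scale lambda >= 0 absorbed into the temporal factor.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hrf_core import LaguerreBasis, SSRF, estimate_ssrf
from .signal_prep import AmplitudeTensor

__all__ = [
    "HRFTensor",
    "CPDResult",
    "build_hrf_tensor",
    "estimate_hrf_tensor",
    "rescale_soft_threshold",
    "center_scale_order4",
    "cpd_als",
    "nmode_vector_product",
    "reconstruct_bold",
    "fit_multicomponent",
    "run_node_pipeline",
    "NodePipeline",
]


@dataclass
class HRFTensor:
    """Stack of SSRF kernels: lag x space x frequency (x subject)."""

    values: np.ndarray
    fs: float
    rescaled: bool = False
    percentile: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (3, 4):
            raise ValueError("HRF tensor must be order 3 or 4")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("HRF tensor entries must be finite")

    @property
    def order(self) -> int:
        return self.values.ndim


@dataclass
class CPDResult:
    """Rank-R CPD factors.

    ``temporal`` (lag x R) carries the physical scale: its columns are the
    unit temporal shapes times ``weights``; ``spatial``, ``spectral`` and
    (optionally) ``subject`` columns are unit l2-norm.
    """

    rank: int
    temporal: np.ndarray
    spatial: np.ndarray
    spectral: np.ndarray
    subject: np.ndarray | None = None
    weights: np.ndarray = field(default_factory=lambda: np.array([]))
    fit: float = np.nan
    converged: bool = True
    error_history: np.ndarray | None = None  # per-sweep relative error (best restart)

    @property
    def factors(self) -> list[np.ndarray]:
        out = [self.temporal, self.spatial, self.spectral]
        if self.subject is not None:
            out.append(self.subject)
        return out

    def to_tensor(self) -> np.ndarray:
        return _cp_to_tensor([self.temporal, self.spatial, self.spectral]
                             + ([self.subject] if self.subject is not None else []))


# ---------------------------------------------------------------------------
# tensor assembly and preprocessing
# ---------------------------------------------------------------------------


def build_hrf_tensor(ssrf_collection: dict, fs: float) -> HRFTensor:
    """Assemble SSRFs keyed by (space, frequency[, subject]) into a tensor.

    Every cell of the full grid must be present exactly once and all
    kernels must share one length; missing cells raise rather than being
    imputed.
    """
    if not ssrf_collection:
        raise ValueError("empty SSRF collection")
    keys = list(ssrf_collection.keys())
    order = len(keys[0]) + 1
    if any(len(k) != order - 1 for k in keys):
        raise ValueError("inconsistent key arity in SSRF collection")
    axes = [sorted({k[d] for k in keys}) for d in range(order - 1)]
    expected = set(itertools.product(*axes))
    got = set(keys)
    if got != expected:
        missing = sorted(expected - got)[:5]
        raise ValueError(f"SSRF collection is not a full grid; e.g. missing {missing}")
    kernels = {k: np.asarray(v.kernel if isinstance(v, SSRF) else v, dtype=float)
               for k, v in ssrf_collection.items()}
    lengths = {len(v) for v in kernels.values()}
    if len(lengths) != 1:
        raise ValueError("kernels of unequal length")
    L = lengths.pop()
    shape = (L, *(len(a) for a in axes))
    values = np.empty(shape)
    index = [{v: i for i, v in enumerate(a)} for a in axes]
    for k, kern in kernels.items():
        values[(slice(None), *(index[d][k[d]] for d in range(order - 1)))] = kern
    return HRFTensor(values=values, fs=fs)


def estimate_hrf_tensor(amplitude_tensor: AmplitudeTensor, bold: np.ndarray,
                        basis: LaguerreBasis) -> HRFTensor:
    """Estimate one SSRF per (node, band) against a single BOLD signal."""
    n_nodes, n_bands, _ = amplitude_tensor.shape
    coll = {}
    for i in range(n_nodes):
        for b in range(n_bands):
            coll[(i, b)] = estimate_ssrf(amplitude_tensor.values[i, b], bold,
                                         basis, fs_in=amplitude_tensor.fs,
                                         fs_bold=amplitude_tensor.fs,
                                         source=(i, b))
    return build_hrf_tensor(coll, fs=basis.fs)


def rescale_soft_threshold(hrf_tensor: HRFTensor,
                           amplitude_tensor: AmplitudeTensor,
                           bold: np.ndarray, percentile: float) -> HRFTensor:
    """Soft-threshold rescaling of an order-3 HRF tensor.

    Per (space, frequency) cell, the amplitude signal (z-scored, matching
    the estimation path) is convolved with the cell's kernel and
    correlated with the real BOLD signal; the threshold theta is the given
    percentile of |r| over all cells, and the cell is scaled by
    ``sign(r) * max(|r| - theta, 0)``.  Cells with a zero-variance
    prediction get r = 0.
    """
    if not 0 <= percentile < 100:
        raise ValueError("percentile must lie in [0, 100)")
    if hrf_tensor.order != 3:
        raise ValueError("soft-threshold rescaling applies to order-3 tensors")
    L, n_nodes, n_bands = hrf_tensor.values.shape
    y = np.asarray(bold, dtype=float)
    r = np.zeros((n_nodes, n_bands))
    for i in range(n_nodes):
        for b in range(n_bands):
            x = amplitude_tensor.values[i, b]
            xz = (x - x.mean()) / x.std() if x.std() > 0 else x - x.mean()
            pred = np.convolve(xz, hrf_tensor.values[:, i, b])[:len(y)]
            if pred.std() == 0 or y.std() == 0:
                continue
            n = min(len(pred), len(y))
            r[i, b] = np.corrcoef(pred[:n], y[:n])[0, 1]
    theta = np.percentile(np.abs(r), percentile)
    scale = np.sign(r) * np.maximum(np.abs(r) - theta, 0.0)
    return HRFTensor(values=hrf_tensor.values * scale[None, :, :],
                     fs=hrf_tensor.fs, rescaled=True, percentile=percentile)


def center_scale_order4(hrf_tensor: HRFTensor) -> HRFTensor:
    """Preprocess an order-4 tensor: scale subject slabs, centre frequencies.

    Each subject slab is divided by its root-mean-square, then the mean
    over the frequency axis is removed for every (lag, space, subject)
    triple.
    """
    if hrf_tensor.order != 4:
        raise ValueError("subject scaling requires an order-4 tensor")
    X = hrf_tensor.values.copy()
    rms = np.sqrt(np.mean(X ** 2, axis=(0, 1, 2)))
    if np.any(rms == 0):
        raise ValueError("degenerate subject slab with zero RMS")
    X = X / rms[None, None, None, :]
    X = X - X.mean(axis=2, keepdims=True)
    return HRFTensor(values=X, fs=hrf_tensor.fs, rescaled=hrf_tensor.rescaled,
                     percentile=hrf_tensor.percentile)


# ---------------------------------------------------------------------------
# canonical polyadic decomposition (alternating least squares)
# ---------------------------------------------------------------------------


def _khatri_rao(mats):
    """Column-wise Khatri-Rao product of a list of matrices."""
    out = mats[0]
    for m in mats[1:]:
        out = (out[:, None, :] * m[None, :, :]).reshape(-1, out.shape[1])
    return out


def _unfold(X, mode):
    return np.moveaxis(X, mode, 0).reshape(X.shape[mode], -1)


def _cp_to_tensor(factors):
    rank = factors[0].shape[1]
    shape = tuple(f.shape[0] for f in factors)
    full = _khatri_rao(factors[1:]) @ factors[0].T  # (prod rest) x I0
    return np.moveaxis(full.T.reshape(shape), 0, 0)


def cpd_als(tensor, rank: int, n_restarts: int = 10, tol: float = 1e-8,
            max_iter: int = 500, seed: int | None = None) -> CPDResult:
    """Rank-R CPD by alternating least squares with random restarts.

    Factors are initialised uniform on [-1, 1]; each ALS sweep solves the
    linear least-squares problem for one mode with the others fixed, so the
    relative reconstruction error is non-increasing.  The restart with the
    lowest final error is returned.  If no restart reaches ``tol`` change
    within ``max_iter`` sweeps the best iterate is returned flagged
    ``converged=False``.
    """
    X = tensor.values if isinstance(tensor, HRFTensor) else np.asarray(tensor, float)
    if rank < 1:
        raise ValueError("rank must be at least 1")
    order = X.ndim
    if order not in (3, 4):
        raise ValueError("CPD implemented for order-3/4 tensors")
    rng = np.random.default_rng(seed)
    norm_x = np.linalg.norm(X)
    if norm_x == 0:
        raise ValueError("cannot decompose an all-zero tensor")
    unfolds = [_unfold(X, m) for m in range(order)]

    best = None
    for _restart in range(n_restarts):
        factors = [rng.uniform(-1, 1, size=(X.shape[m], rank))
                   for m in range(order)]
        prev_err = np.inf
        converged = False
        history = []
        for _it in range(max_iter):
            for m in range(order):
                others = [factors[k] for k in range(order) if k != m]
                # Gram of the Khatri-Rao design: Hadamard of the Grams
                G = np.ones((rank, rank))
                for f in others:
                    G *= f.T @ f
                # unfold keeps remaining modes in original order (last
                # fastest), so the Khatri-Rao follows the same order
                kr = _khatri_rao(others)
                mttkrp = unfolds[m] @ kr
                try:
                    factors[m] = np.linalg.solve(G, mttkrp.T).T
                except np.linalg.LinAlgError:
                    factors[m] = (np.linalg.pinv(G) @ mttkrp.T).T
            err = np.linalg.norm(X - _cp_to_tensor(factors)) / norm_x
            history.append(err)
            if abs(prev_err - err) < tol:
                converged = True
                prev_err = err
                break
            prev_err = err
        if best is None or prev_err < best[1]:
            best = (factors, prev_err, converged, history)

    factors, err, converged, history = best
    # normalise: unit-norm non-temporal columns, scale into the temporal mode
    lam = np.ones(rank)
    for m in range(1, order):
        norms = np.linalg.norm(factors[m], axis=0)
        norms[norms == 0] = 1.0
        factors[m] = factors[m] / norms
        lam *= norms
    temporal = factors[0] * lam
    tnorm = np.linalg.norm(temporal, axis=0)
    order_idx = np.argsort(-tnorm)  # components by descending energy
    temporal = temporal[:, order_idx]
    factors = [temporal] + [factors[m][:, order_idx] for m in range(1, order)]
    weights = tnorm[order_idx]
    return CPDResult(rank=rank, temporal=factors[0], spatial=factors[1],
                     spectral=factors[2],
                     subject=factors[3] if order == 4 else None,
                     weights=weights, fit=float(err), converged=converged,
                     error_history=np.asarray(history))


def nmode_vector_product(tensor: np.ndarray, vector: np.ndarray, mode: int):
    """Contract a tensor with a vector along one mode (order drops by 1)."""
    X = np.asarray(tensor, dtype=float)
    v = np.asarray(vector, dtype=float)
    if X.shape[mode] != len(v):
        raise ValueError(f"vector length {len(v)} != extent {X.shape[mode]} "
                         f"of mode {mode}")
    return np.tensordot(X, v, axes=([mode], [0]))


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------


def _zscore(x):
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def reconstruct_bold(amplitude_tensor: AmplitudeTensor, cpd: CPDResult,
                     component: int = 0, bold_ref: np.ndarray | None = None):
    """Compound signal, BOLD estimate and goodness-of-fit for one component.

    The amplitude tensor (space x frequency x time) is contracted with the
    component's spatial then spectral factors; the resulting compound
    signal is causally convolved with the temporal factor (the HRF) and
    z-scored.  Returns ``(compound, estimate, r)`` where ``r`` is the
    Pearson correlation with ``bold_ref`` (NaN if no reference given).
    """
    A = amplitude_tensor.values
    w_space = cpd.spatial[:, component]
    w_freq = cpd.spectral[:, component]
    if np.all(w_space == 0) or np.all(w_freq == 0):
        raise ValueError("zero factor: compound signal undefined")
    compound = nmode_vector_product(nmode_vector_product(A, w_space, 0),
                                    w_freq, 0)
    h = cpd.temporal[:, component]
    estimate = _zscore(np.convolve(compound, h)[:len(compound)])
    r = np.nan
    if bold_ref is not None:
        y = np.asarray(bold_ref, dtype=float)
        n = min(len(estimate), len(y))
        r = float(np.corrcoef(estimate[:n], y[:n])[0, 1])
    return compound, estimate, r


def fit_multicomponent(estimates, bold_ref):
    """OLS fit of the BOLD signal on one estimate per CPD component.

    Collinear estimates are dropped (with a warning) before fitting.
    Returns ``(combined_estimate, r)``.
    """
    import warnings

    y = np.asarray(bold_ref, dtype=float)
    E = [np.asarray(e, dtype=float) for e in estimates]
    if not E:
        raise ValueError("need at least one estimate")
    n = min([len(y)] + [len(e) for e in E])
    y = y[:n]
    kept = []
    for e in E:
        cand = kept + [e[:n]]
        X = np.column_stack([np.ones(n)] + cand)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            warnings.warn("dropping collinear BOLD estimate from joint fit")
            continue
        kept = cand
    X = np.column_stack([np.ones(n)] + kept)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    combined = X @ beta
    r = float(np.corrcoef(combined, y)[0, 1])
    return combined, r


# ---------------------------------------------------------------------------
# the per-node pipeline (estimate -> rescale -> CPD -> reconstruct)
# ---------------------------------------------------------------------------


class NodePipeline:
    """Reusable single-BOLD-signal analysis path with precomputed designs.

    The convolved-basis regressors depend only on the amplitude tensor and
    the basis, not on the BOLD signal, so surrogate-heavy procedures
    (phase-randomisation nulls, jackknives over BOLD variants) can reuse
    one QR factorisation per (node, band) cell.  Calling the object with a
    BOLD signal runs: SSRF least squares for every cell, soft-threshold
    rescaling, rank-R CPD, reconstruction, and returns
    ``(cpd_result, estimate, r)``.
    """

    def __init__(self, amplitude_tensor: AmplitudeTensor,
                 basis: LaguerreBasis, percentile: float = 0.0,
                 rank: int = 1, n_restarts: int = 10,
                 seed: int | None = None):
        self.amp = amplitude_tensor
        self.basis = basis
        self.percentile = percentile
        self.rank = rank
        self.n_restarts = n_restarts
        self.seed = seed
        n_nodes, n_bands, n_times = amplitude_tensor.shape
        self._qr = {}
        self._design = np.empty((n_nodes, n_bands, n_times, basis.n_basis))
        B = basis.at_rate(amplitude_tensor.fs).matrix
        for i in range(n_nodes):
            for b in range(n_bands):
                x = amplitude_tensor.values[i, b]
                sd = x.std()
                xz = (x - x.mean()) / sd if sd > 0 else x - x.mean()
                X = np.column_stack([
                    np.convolve(xz, B[:, p])[:n_times]
                    for p in range(basis.n_basis)])
                self._design[i, b] = X
                self._qr[(i, b)] = np.linalg.qr(X, mode="reduced")

    def __call__(self, bold: np.ndarray):
        n_nodes, n_bands, n_times = self.amp.shape
        y = np.asarray(bold, dtype=float)
        n = min(n_times, len(y))
        y = y[:n]
        sd = y.std()
        yz = (y - y.mean()) / sd if sd > 0 else y - y.mean()
        L = self.basis.n_lags
        kernels = np.empty((L, n_nodes, n_bands))
        r = np.zeros((n_nodes, n_bands))
        for i in range(n_nodes):
            for b in range(n_bands):
                Q, R = self._qr[(i, b)]
                coeffs = np.linalg.solve(R, Q[:n].T @ yz) if n == Q.shape[0] \
                    else np.linalg.lstsq(self._design[i, b][:n], yz,
                                         rcond=None)[0]
                kernels[:, i, b] = self.basis.matrix @ coeffs
                pred = self._design[i, b][:n] @ coeffs
                if pred.std() > 0:
                    r[i, b] = np.corrcoef(pred, yz)[0, 1]
        theta = np.percentile(np.abs(r), self.percentile)
        scale = np.sign(r) * np.maximum(np.abs(r) - theta, 0.0)
        tensor = HRFTensor(values=kernels * scale[None], fs=self.basis.fs,
                           rescaled=True, percentile=self.percentile)
        cpd = cpd_als(tensor, rank=self.rank, n_restarts=self.n_restarts,
                      seed=self.seed)
        if self.rank == 1:
            _, estimate, rr = reconstruct_bold(self.amp, cpd, 0, yz)
        else:
            ests = [reconstruct_bold(self.amp, cpd, c)[1]
                    for c in range(self.rank)]
            estimate, rr = fit_multicomponent(ests, yz)
        return cpd, estimate, rr


def run_node_pipeline(amplitude_tensor: AmplitudeTensor, bold: np.ndarray,
                      basis: LaguerreBasis, percentile: float = 0.0,
                      rank: int = 1, n_restarts: int = 10,
                      seed: int | None = None):
    """Full single-BOLD-signal analysis path.

    SSRF estimation for every (node, band) cell, soft-threshold rescaling,
    rank-R CPD, reconstruction of the BOLD estimate (multi-regressor OLS
    when rank > 1) and its correlation with the real BOLD signal.

    Returns ``(cpd_result, estimate, r)``.
    """
    hrf = estimate_hrf_tensor(amplitude_tensor, bold, basis)
    hrf = rescale_soft_threshold(hrf, amplitude_tensor, bold, percentile)
    cpd = cpd_als(hrf, rank=rank, n_restarts=n_restarts, seed=seed)
    if rank == 1:
        _, estimate, r = reconstruct_bold(amplitude_tensor, cpd, 0, bold)
    else:
        ests = [reconstruct_bold(amplitude_tensor, cpd, c)[1]
                for c in range(rank)]
        estimate, r = fit_multicomponent(ests, bold)
    return cpd, estimate, r


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------


def write_cpd_result(cpd: CPDResult, out_dir):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"rank": cpd.rank, "weights": cpd.weights.tolist(),
                "fit": cpd.fit, "converged": bool(cpd.converged),
                "modes": ["temporal", "spatial", "spectral"]
                + (["subject"] if cpd.subject is not None else [])}
    (out_dir / "cpd.json").write_text(json.dumps(manifest, indent=1))
    for name, mat in zip(manifest["modes"], cpd.factors):
        np.savetxt(out_dir / f"factor_{name}.tsv", mat, delimiter="\t",
                   fmt="%.8g")


def read_cpd_result(out_dir) -> CPDResult:
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "cpd.json").read_text())
    mats = {name: np.atleast_2d(np.loadtxt(out_dir / f"factor_{name}.tsv",
                                           delimiter="\t"))
            for name in manifest["modes"]}
    for name in mats:
        if mats[name].shape[1] != manifest["rank"] and mats[name].shape[0] == manifest["rank"]:
            mats[name] = mats[name].T
    return CPDResult(rank=manifest["rank"], temporal=mats["temporal"],
                     spatial=mats["spatial"], spectral=mats["spectral"],
                     subject=mats.get("subject"),
                     weights=np.array(manifest["weights"]),
                     fit=manifest["fit"], converged=manifest["converged"])
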