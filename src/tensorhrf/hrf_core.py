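"""Spatial-spectral response function (SSRF) estimation.

Each SSRF is the linear impulse response from one band-amplitude signal to
one BOLD signal, estimated by ordinary least squares on a small spherical-
Laguerre basis.  The basis functions start at exactly zero amplitude and
decay within a finite memory (default 32 s), so three coefficients suffice
for hemodynamic-response-like kernels even at fMRI sampling rates.  A
single decay-rate parameter controls the temporal support of the basis and
is selected by sweeping a grid and maximising the goodness-of-fit of the
full downstream pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import eval_genlaguerre

__all__ = [
    "LaguerreBasis",
    "SSRF",
    "spherical_laguerre_basis",
    "estimate_ssrf",
    "sweep_decay",
    "DEFAULT_DECAY_GRID",
    "EMPIRICAL_DECAY_GRID",
    "EMPIRICAL_PERCENTILES",
]

#: decay-rate sweep for simulated data: 0.40 ... 3.00 in steps of 0.05
DEFAULT_DECAY_GRID = tuple(np.round(np.arange(0.40, 3.0001, 0.05), 2))
#: sweep used for empirical multi-subject analyses, with the soft-threshold
#: percentile swept jointly
EMPIRICAL_DECAY_GRID = tuple(np.round(np.arange(0.8, 4.8001, 0.2), 1))
EMPIRICAL_PERCENTILES = (0, 25, 50, 75)


class SingularDesignError(np.linalg.LinAlgError):
    """The convolved-basis regression matrix is rank deficient."""


class SweepFailedError(RuntimeError):
    """Every grid point of a decay sweep failed to evaluate."""


@dataclass
class LaguerreBasis:
    """Sampled spherical-Laguerre basis, lag x n_basis.

    Column p samples ``x * exp(-x / 2) * L_p^(2)(x)`` with
    ``x = 2 * decay * t`` on the lag grid (generalised Laguerre polynomial
    of order 2, the radial part of the spherical construction with the
    volume measure absorbed), unit l2-normalised.  Every column is exactly
    zero at lag 0 and has decayed essentially to zero by the memory end
    for the whole sweep range; larger ``decay`` compresses the temporal
    support.
    """

    n_basis: int
    decay: float
    length_s: float
    fs: float
    matrix: np.ndarray

    @property
    def n_lags(self) -> int:
        return self.matrix.shape[0]

    def at_rate(self, fs: float) -> "LaguerreBasis":
        """The same analytic basis resampled at another rate."""
        if fs == self.fs:
            return self
        return spherical_laguerre_basis(self.n_basis, self.decay,
                                        self.length_s, fs)


def spherical_laguerre_basis(n_basis: int = 3, decay: float = 1.0,
                             length_s: float = 32.0,
                             fs: float = 4.0) -> LaguerreBasis:
    """First ``n_basis`` spherical Laguerre functions on the lag grid."""
    if n_basis < 1:
        raise ValueError("n_basis must be at least 1")
    if decay <= 0:
        raise ValueError("decay must be positive")
    t = np.arange(int(round(length_s * fs))) / fs
    x = 2.0 * decay * t
    cols = []
    for p in range(n_basis):
        col = x * np.exp(-x / 2.0) * eval_genlaguerre(p, 2, x)
        norm = np.linalg.norm(col)
        cols.append(col / norm if norm > 0 else col)
    return LaguerreBasis(n_basis=n_basis, decay=decay, length_s=length_s,
                         fs=fs, matrix=np.column_stack(cols))


@dataclass
class SSRF:
    """One estimated spatial-spectral response function."""

    coeffs: np.ndarray
    kernel: np.ndarray
    source: tuple = ()

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.kernel = np.asarray(self.kernel, dtype=float)


def _zscore(x):
    x = np.asarray(x, dtype=float)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def estimate_ssrf(input_amp: np.ndarray, bold: np.ndarray,
                  basis: LaguerreBasis, fs_in: float | None = None,
                  fs_bold: float | None = None,
                  source: tuple = ()) -> SSRF:
    """Least-squares SSRF between one amplitude signal and one BOLD signal.

    Both signals are z-scored.  The input is convolved (causally) with each
    basis column evaluated at the input rate; if the input runs faster than
    BOLD the convolved regressors are decimated to the BOLD rate, so no
    information is lost to down-sampling before the convolution.  The
    coefficient vector solves ordinary least squares; the returned kernel
    is ``basis.matrix @ coeffs`` at the basis' own rate.
    """
    fs_in = fs_in or basis.fs
    fs_bold = fs_bold or basis.fs
    x = _zscore(input_amp)
    y = _zscore(bold)
    b_in = basis.at_rate(fs_in)
    regs = [np.convolve(x, b_in.matrix[:, p])[:len(x)]
            for p in range(basis.n_basis)]
    if fs_in != fs_bold:
        from .signal_prep import truncate_detrend_decimate

        regs = [truncate_detrend_decimate(r, fs_in, fs_bold) for r in regs]
    n = min(len(y), min(len(r) for r in regs))
    X = np.column_stack([r[:n] for r in regs])
    if np.linalg.matrix_rank(X) < basis.n_basis:
        raise SingularDesignError("convolved-basis design is rank deficient")
    coeffs, *_ = np.linalg.lstsq(X, y[:n], rcond=None)
    return SSRF(coeffs=coeffs, kernel=basis.matrix @ coeffs, source=source)


def sweep_decay(grid, pipeline_fn, percentile_grid=None):
    """Select the decay rate (and optionally percentile) maximising fit.

    ``pipeline_fn(decay)`` — or ``pipeline_fn(decay, percentile)`` when a
    percentile grid is given — must run the full estimation path and return
    a scalar goodness-of-fit (Pearson r).  Failing grid points are skipped;
    ties break towards the smallest decay (then smallest percentile).
    Returns ``(best_decay, best_score)`` or
    ``(best_decay, best_percentile, best_score)``.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("sweep grid must be non-empty")
    best = None
    n_failed = 0
    points = ([(d,) for d in grid] if percentile_grid is None
              else [(d, p) for d in grid for p in percentile_grid])
    for point in points:
        try:
            score = pipeline_fn(*point)
        except Exception:
            n_failed += 1
            continue
        if not np.isfinite(score):
            n_failed += 1
            continue
        if best is None or score > best[-1]:
            best = (*point, score)
    if best is None:
        raise SweepFailedError(f"all {n_failed} sweep evaluations failed")
    return best
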