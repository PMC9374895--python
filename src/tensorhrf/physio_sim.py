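"""Cardiac/respiratory simulation and systemic low-frequency oscillations.

Respiration is a standard stochastic Stuart-Landau oscillator near 0.25 Hz.
Cardiac pulses (as seen by photoplethysmography, PPG) come from a two-cell
nonlinear oscillator whose integration time-constant is modulated by the
respiration waveform's derivative, reproducing respiratory sinus
arrhythmia::

    dx1/dt = (1/tau(t)) * (-x1 + (1 + mu) * y1 - b * y2 + p1)
    dx2/dt = (1/tau(t)) * (-x2 + (1 + mu) * y2 + b * y1 + p2)
    y_i    = tanh(k * x_i)
    1/tau(t) = a * dRW/dt + c

The PPG signal is x2.  Beat-to-beat heart rate (HR) is the reciprocal
inter-beat interval; respiratory flow (RF) is the squared derivative of
the respiration waveform.  HR and RF, convolved with the cardiac and
respiratory response functions (CRF of Chang et al. 2009; RRF of Birn et
al. 2008), sum to a single systemic low-frequency oscillation (SLFO)
confound that is later added to BOLD with spatially structured node
weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, filtfilt, find_peaks

from .neural_sim import integrate_stratonovich_heun, slo_drift

__all__ = [
    "PPGParams",
    "PhysioBundle",
    "simulate_respiration",
    "simulate_ppg",
    "extract_heart_rate",
    "respiratory_flow",
    "cardiac_response_function",
    "respiratory_response_function",
    "make_slfo",
    "node_slfo_weights",
    "simulate_physio",
    "write_physio_tsv",
]


class PPGRegimeError(ValueError):
    """The respiratory modulation drove 1/tau(t) non-positive."""


@dataclass(frozen=True)
class PPGParams:
    """Constants of the two-cell PPG oscillator (dimensionless)."""

    mu: float = 0.5
    p1: float = -0.3
    p2: float = 0.3
    b: float = 1.0
    a: float = 7.0
    c: float = 14.0
    k: float = 1.5


@dataclass
class PhysioBundle:
    """Simulated physiological signals on a common uniform grid."""

    ppg: np.ndarray
    rw: np.ndarray
    hr: np.ndarray
    rf: np.ndarray
    slfo: np.ndarray
    fs: float

    def __post_init__(self):
        lengths = {len(self.ppg), len(self.rw), len(self.hr), len(self.rf),
                   len(self.slfo)}
        if len(lengths) != 1:
            raise ValueError("physio signals must share one grid")
        if np.any(self.rf < 0):
            raise ValueError("respiratory flow must be nonnegative")
        if np.any(self.hr <= 0):
            raise ValueError("heart rate must be positive")


def simulate_respiration(duration: float, f_resp: float = 0.25,
                         alpha: float = 1.0, beta: float = 0.1,
                         dt: float = 1e-3, seed: int | None = None) -> np.ndarray:
    """Respiration waveform: stochastic standard SLO, x-variable returned."""
    if f_resp <= 0:
        raise ValueError("f_resp must be positive")
    omega = 2 * np.pi * f_resp

    def drift(s):
        dx, dy = slo_drift((s[0], s[1]), alpha, omega)
        return np.array([dx, dy])

    traj = integrate_stratonovich_heun(drift, beta, [0.1, 0.0], dt, duration,
                                       seed=seed)
    return traj[:, 0]


def smooth_respiration(rw: np.ndarray, dt: float, cutoff: float = 1.0) -> np.ndarray:
    """Zero-phase low-pass of a stochastic respiration path.

    The SLO's additive white noise gives the raw path an unbounded
    derivative; physiological airflow is smooth, so the waveform is
    low-passed (4th-order Butterworth, default 1 Hz cutoff, well above any
    breathing rate) before anything differentiates it.
    """
    b, a = butter(4, cutoff * 2 * dt)
    return filtfilt(b, a, rw)


def simulate_ppg(rw: np.ndarray, params: PPGParams | None = None,
                 dt: float = 1e-3, seed: int | None = None,
                 noise_amp: float = 0.0) -> np.ndarray:
    """Integrate the PPG oscillator driven by a respiration waveform.

    The inverse time-constant ``1/tau(t) = a * dRW/dt + c`` couples the
    cardiac cycle rate to respiration.  Raises :class:`PPGRegimeError` if
    the modulation drives ``1/tau`` non-positive anywhere (the oscillator
    would run backwards in time rather than merely slow down).
    """
    p = params or PPGParams()
    rw = np.asarray(rw, dtype=float)
    drw = np.gradient(rw, dt)
    inv_tau = p.a * drw + p.c
    if np.any(inv_tau <= 0):
        raise PPGRegimeError(
            "1/tau(t) <= 0: respiratory modulation exceeds the admissible "
            f"regime (min {inv_tau.min():.3g}); reduce a or the RW slope")
    rng = np.random.default_rng(seed)
    x1, x2 = 0.1, 0.0
    out = np.empty(len(rw))
    out[0] = x2
    sqrt_dt = np.sqrt(dt)

    def f(x1, x2, it):
        y1 = np.tanh(p.k * x1)
        y2 = np.tanh(p.k * x2)
        dx1 = it * (-x1 + (1 + p.mu) * y1 - p.b * y2 + p.p1)
        dx2 = it * (-x2 + (1 + p.mu) * y2 + p.b * y1 + p.p2)
        return dx1, dx2

    for t in range(1, len(rw)):
        it = inv_tau[t - 1]
        if noise_amp > 0:
            dw1, dw2 = noise_amp * sqrt_dt * rng.standard_normal(2)
        else:
            dw1 = dw2 = 0.0
        d10, d20 = f(x1, x2, it)
        x1p = x1 + d10 * dt + dw1
        x2p = x2 + d20 * dt + dw2
        d11, d21 = f(x1p, x2p, inv_tau[t])
        x1 = x1 + 0.5 * (d10 + d11) * dt + dw1
        x2 = x2 + 0.5 * (d20 + d21) * dt + dw2
        out[t] = x2
    return out


def extract_heart_rate(ppg: np.ndarray, fs: float, fs_out: float,
                       n_out: int | None = None) -> np.ndarray:
    """Beat-to-beat heart rate in beats/s on a uniform output grid.

    Systolic peaks are local maxima above the 60th amplitude percentile
    separated by at least 0.4 s (so diastolic secondary peaks are skipped);
    HR over each inter-beat interval is its reciprocal, assigned at the
    interval midpoint and linearly interpolated onto the ``fs_out`` grid
    (edges held constant).
    """
    ppg = np.asarray(ppg, dtype=float)
    peaks, _ = find_peaks(ppg, height=np.percentile(ppg, 60),
                          distance=max(1, int(0.4 * fs)))
    if len(peaks) < 3:
        raise ValueError("insufficient beats: need at least 3 systolic peaks")
    t_peaks = peaks / fs
    ibi = np.diff(t_peaks)
    hr = 1.0 / ibi
    t_hr = 0.5 * (t_peaks[:-1] + t_peaks[1:])
    if n_out is None:
        n_out = int(round(len(ppg) / fs * fs_out))
    t_grid = np.arange(n_out) / fs_out
    return np.interp(t_grid, t_hr, hr)


def respiratory_flow(rw: np.ndarray, dt: float) -> np.ndarray:
    """Squared central-difference derivative of the respiration waveform."""
    rw = np.asarray(rw, dtype=float)
    if len(rw) < 2:
        raise ValueError("need at least 2 samples")
    return np.gradient(rw, dt) ** 2


def cardiac_response_function(t: np.ndarray) -> np.ndarray:
    """Standard CRF (Chang, Cunningham & Glover 2009), t in seconds."""
    t = np.asarray(t, dtype=float)
    return (0.6 * t ** 2.7 * np.exp(-t / 1.6)
            - 16.0 / np.sqrt(2 * np.pi * 9.0) * np.exp(-((t - 12.0) ** 2) / 18.0))


def respiratory_response_function(t: np.ndarray) -> np.ndarray:
    """Standard RRF (Birn et al. 2008), t in seconds."""
    t = np.asarray(t, dtype=float)
    return (0.6 * t ** 2.1 * np.exp(-t / 1.6)
            - 0.0023 * t ** 3.54 * np.exp(-t / 4.25))


def make_slfo(hr: np.ndarray, rf: np.ndarray, fs: float,
              kernel_len_s: float = 60.0) -> np.ndarray:
    """SLFO = conv(HR - mean, CRF) + conv(RF - mean, RRF).

    Means are removed so the confound is a zero-mean fluctuation; the
    causal convolutions are truncated to the input length.
    """
    hr = np.asarray(hr, dtype=float)
    rf = np.asarray(rf, dtype=float)
    if len(hr) != len(rf):
        raise ValueError("hr and rf must share one grid")
    t = np.arange(int(kernel_len_s * fs)) / fs
    crf = cardiac_response_function(t)
    rrf = respiratory_response_function(t)
    n = len(hr)
    card = np.convolve(hr - hr.mean(), crf)[:n] / fs
    resp = np.convolve(rf - rf.mean(), rrf)[:n] / fs
    return card + resp


def node_slfo_weights(n_nodes: int, smoothness: float = 2.0, sd: float = 0.5,
                      seed: int | None = None) -> np.ndarray:
    """Spatially structured nonnegative node weights, mean-normalised to 1.

    A synthetic stand-in for empirical maps of regional SLFO
    susceptibility: a Gaussian-smoothed random field over the node index is
    exponentiated (log-normal weights) and normalised to mean 1.
    ``smoothness`` is the kernel SD in node-index units (0 gives i.i.d.
    weights); ``sd = 0`` gives exactly uniform weights.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be at least 1")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_nodes)
    if smoothness > 0 and n_nodes > 1:
        z = gaussian_filter1d(z, smoothness, mode="wrap")
        s = z.std()
        if s > 0:
            z = z / s
    w = np.exp(sd * z)
    return w / w.mean()


def simulate_physio(duration: float, fs_out: float, *, f_resp: float = 0.25,
                    resp_alpha: float = 1.0, resp_beta: float = 0.1,
                    ppg_params: PPGParams | None = None, dt: float = 1e-3,
                    seed: int | None = None) -> PhysioBundle:
    """Convenience driver: respiration -> PPG -> HR/RF -> SLFO.

    All derived signals are resampled/interpolated onto the ``fs_out``
    grid.
    """
    rng = np.random.default_rng(seed)
    rw_fine = simulate_respiration(duration, f_resp, resp_alpha, resp_beta,
                                   dt, seed=int(rng.integers(2 ** 31)))
    rw_fine = smooth_respiration(rw_fine, dt)
    ppg_fine = simulate_ppg(rw_fine, ppg_params, dt,
                            seed=int(rng.integers(2 ** 31)))
    n_out = int(round(duration * fs_out))
    stride = int(round(1.0 / (dt * fs_out)))
    rw = rw_fine[::stride][:n_out]
    ppg = ppg_fine[::stride][:n_out]
    hr = extract_heart_rate(ppg_fine, 1.0 / dt, fs_out, n_out=n_out)
    rf = respiratory_flow(rw_fine, dt)[::stride][:n_out]
    slfo = make_slfo(hr, rf, fs_out)
    n = min(len(rw), len(ppg), len(hr), len(rf), len(slfo))
    return PhysioBundle(ppg=ppg[:n], rw=rw[:n], hr=hr[:n], rf=rf[:n],
                        slfo=slfo[:n], fs=fs_out)


def write_physio_tsv(bundle: PhysioBundle, path):
    t = np.arange(len(bundle.ppg)) / bundle.fs
    cols = np.column_stack([t, bundle.ppg, bundle.rw, bundle.hr, bundle.rf,
                            bundle.slfo])
    header = "time\tppg\trw\thr\trf\tslfo"
    np.savetxt(path, cols, delimiter="\t", header=header, comments="",
               fmt="%.8g")
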