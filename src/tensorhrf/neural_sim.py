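"""Synthetic connectomes and coupled Stuart-Landau oscillator networks.

Local field potentials are modelled per cortical node by a pair of
Stuart-Landau oscillators (SLOs), the normal form of a supercritical Hopf
bifurcation.  A *slow* SLO pair (u, v), tuned near the BOLD fluctuation
time-scale (~0.08 Hz), is coupled across nodes through a structural
connectivity matrix; its trajectory serves as a time-varying bifurcation
parameter for an uncoupled *fast* SLO pair (x, y) oscillating in a standard
electrophysiological band.  The fast oscillation amplitude therefore tracks
the rectified slow modulator (limit-cycle radius sqrt(alpha) when
alpha > 0, silence otherwise), producing LFP-like signals whose band
envelopes carry slow network dynamics.

All stochastic integration uses a Stratonovich-Heun predictor-corrector
scheme with additive white Gaussian noise (for which the Stratonovich and
Ito interpretations coincide).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ConnectomeSpec",
    "SLOParams",
    "NeuralTimeseries",
    "make_synthetic_connectome",
    "slo_drift",
    "integrate_stratonovich_heun",
    "simulate_network",
    "write_connectome_tsv",
    "read_connectome_tsv",
    "write_timeseries_tsv",
    "read_timeseries_tsv",
]


class IntegrationDivergedError(RuntimeError):
    """Raised when an SDE trajectory leaves the finite domain."""

    def __init__(self, step: int):
        super().__init__(f"non-finite state encountered at step {step}")
        self.step = step


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ConnectomeSpec:
    """Node set with symmetric nonnegative coupling matrix.

    ``C[i, j]`` scales the influence of node ``i`` on node ``j``; the
    diagonal is zero (no self-coupling).
    """

    n_nodes: int
    C: np.ndarray
    hemisphere_label: list[str]
    node_names: list[str]

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        if self.n_nodes < 2:
            raise ValueError("a connectome needs at least 2 nodes")
        if self.C.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("coupling matrix shape does not match n_nodes")
        if not np.all(np.isfinite(self.C)):
            raise ValueError("coupling weights must be finite")
        if np.any(self.C < 0):
            raise ValueError("coupling weights must be nonnegative")
        if not np.allclose(self.C, self.C.T):
            raise ValueError("coupling matrix must be symmetric")
        if np.any(np.diag(self.C) != 0):
            raise ValueError("coupling matrix diagonal must be zero")
        if len(self.hemisphere_label) != self.n_nodes:
            raise ValueError("one hemisphere label per node required")
        if len(self.node_names) != self.n_nodes:
            raise ValueError("one name per node required")


@dataclass
class SLOParams:
    """Parameters of the two-subpopulation SLO network.

    Frequencies are given in Hz; the angular frequencies entering the
    equations of motion are ``omega = 2*pi*f``.  ``alpha_f`` scales the slow
    trajectory into the fast oscillator's time-varying bifurcation
    parameter, ``alpha_s`` is the (fixed) slow bifurcation parameter, ``G``
    the global coupling gain and ``beta`` the additive noise amplitude.
    """

    alpha_f: np.ndarray
    alpha_s: np.ndarray
    f_fast: np.ndarray
    f_slow: np.ndarray
    G: float = 0.3
    beta: float = 0.02
    dt: float = 1e-3
    fs_out: float = 200.0

    def __post_init__(self):
        for name in ("alpha_f", "alpha_s", "f_fast", "f_slow"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.fs_out > 1.0 / self.dt:
            raise ValueError("fs_out cannot exceed the integration rate 1/dt")
        if self.G < 0:
            raise ValueError("G must be nonnegative")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")

    @classmethod
    def default_for(cls, connectome: ConnectomeSpec, *, alpha_f=None,
                    alpha_s: float = 0.05, f_fast_right: float = 2.0,
                    f_fast_left: float = 10.0, f_slow: float = 0.08,
                    G: float = 0.3, beta: float = 0.05, dt: float = 1e-3,
                    fs_out: float = 200.0) -> "SLOParams":
        """Hemisphere-split tuning: 2 Hz fast SLOs on the right, 10 Hz on
        the left, 0.08 Hz slow SLOs everywhere.

        By default ``alpha_f`` is set per node to ``2*pi*f_fast`` so the
        fast oscillator's amplitude relaxation rate scales with its
        rotation rate: slow enough to preserve a near-sinusoidal waveform
        (limiting harmonic leakage into higher bands), fast enough that
        the Hilbert envelope tracks the rectified slow modulator with
        little lag.
        """
        n = connectome.n_nodes
        ff = np.where(np.asarray(connectome.hemisphere_label) == "right",
                      f_fast_right, f_fast_left).astype(float)
        if alpha_f is None:
            alpha_f = 2 * np.pi * ff
        return cls(
            alpha_f=np.broadcast_to(np.asarray(alpha_f, dtype=float), (n,)).copy(),
            alpha_s=np.full(n, alpha_s),
            f_fast=ff,
            f_slow=np.full(n, f_slow),
            G=G, beta=beta, dt=dt, fs_out=fs_out,
        )


@dataclass
class NeuralTimeseries:
    """Simulated node-wise neural trajectories.

    ``fast_x`` is the LFP-like fast-subpopulation x-variable
    (node x time); ``slow_uv`` stacks the slow pair (node x time x 2).
    ``t0`` flags the initial transient (seconds) downstream stages should
    truncate.
    """

    fast_x: np.ndarray
    slow_uv: np.ndarray
    fs: float
    t0: float = 20.0

    def __post_init__(self):
        self.fast_x = np.asarray(self.fast_x, dtype=float)
        self.slow_uv = np.asarray(self.slow_uv, dtype=float)
        if not np.all(np.isfinite(self.fast_x)) or not np.all(np.isfinite(self.slow_uv)):
            raise ValueError("neural trajectories must be finite")
        if self.fast_x.shape[0] != self.slow_uv.shape[0]:
            raise ValueError("fast and slow trajectories disagree on node count")

    @property
    def n_nodes(self) -> int:
        return self.fast_x.shape[0]


# ---------------------------------------------------------------------------
# connectome generation
# ---------------------------------------------------------------------------


def make_synthetic_connectome(n_nodes: int, density: float = 0.3,
                              weight_scale: float = 1.0,
                              seed: int | None = None,
                              inter_hemisphere_scale: float = 0.25) -> ConnectomeSpec:
    """Random symmetric connectome with log-normal weights.

    Each unordered node pair receives an edge with probability ``density``;
    edge weights are drawn log-normally and symmetrised, then scaled so the
    mean node strength (row sum) equals ``weight_scale``.  This keeps the
    total coupling drive per node comparable across network sizes and
    densities.  The first ceil(n/2) nodes are tagged ``right`` and the rest
    ``left``, matching the hemisphere-split oscillator tuning used in the
    simulations.  Connections crossing the hemisphere boundary are scaled
    by ``inter_hemisphere_scale``, mimicking the intra-hemispheric
    dominance of tractography-based connectomes.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be at least 2")
    if not 0 <= density <= 1:
        raise ValueError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n_nodes, k=1)
    weights = rng.lognormal(mean=0.0, sigma=0.5, size=len(iu[0]))
    mask = rng.random(len(iu[0])) < density
    C = np.zeros((n_nodes, n_nodes))
    C[iu] = weights * mask
    C = C + C.T
    n_right = (n_nodes + 1) // 2
    hemi_idx = np.array([0] * n_right + [1] * (n_nodes - n_right))
    cross = hemi_idx[:, None] != hemi_idx[None, :]
    C[cross] *= inter_hemisphere_scale
    mean_strength = C.sum(axis=0).mean()
    if mean_strength > 0:
        C *= weight_scale / mean_strength
    hemis = ["right"] * n_right + ["left"] * (n_nodes - n_right)
    names = [f"node{idx:02d}_{h[0].upper()}" for idx, h in enumerate(hemis)]
    return ConnectomeSpec(n_nodes=n_nodes, C=C, hemisphere_label=hemis,
                          node_names=names)


# ---------------------------------------------------------------------------
# Stuart-Landau drift and stochastic integration
# ---------------------------------------------------------------------------


def slo_drift(state, alpha, omega, coupling_input=(0.0, 0.0), G=0.0):
    """Deterministic part of the Cartesian Stuart-Landau equations.

    dx/dt = (alpha - x^2 - y^2) x - omega y + G * coupling_x
    dy/dt = (alpha - x^2 - y^2) y + omega x + G * coupling_y

    ``omega`` is in rad/s.  Works element-wise on arrays.
    """
    x, y = state
    cx, cy = coupling_input
    r2 = x * x + y * y
    dx = (alpha - r2) * x - omega * y + G * cx
    dy = (alpha - r2) * y + omega * x + G * cy
    return dx, dy


def integrate_stratonovich_heun(drift_fn, noise_amp, x0, dt, duration,
                                seed=None, store_every: int = 1):
    """Integrate dX = f(X) dt + beta dW with the Stratonovich-Heun scheme.

    ``drift_fn(x) -> dx`` operates on a state vector; noise is additive and
    state-independent so the Heun predictor-corrector with a shared Wiener
    increment per step integrates the Stratonovich (= Ito) SDE.  With
    ``noise_amp = 0`` this is the deterministic Heun (trapezoidal) method.

    Returns an array of shape (n_stored, state_dim) containing the initial
    state and every ``store_every``-th step thereafter.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration <= dt:
        raise ValueError("duration must exceed dt")
    if noise_amp < 0:
        raise ValueError("noise_amp must be nonnegative")
    rng = np.random.default_rng(seed)
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    n_steps = int(round(duration / dt))
    out = np.empty((n_steps // store_every + 1, x.size))
    out[0] = x
    sqrt_dt = np.sqrt(dt)
    n_out = 1
    for step in range(1, n_steps + 1):
        dw = noise_amp * sqrt_dt * rng.standard_normal(x.size) if noise_amp > 0 else 0.0
        f0 = np.asarray(drift_fn(x))
        x_pred = x + f0 * dt + dw
        f1 = np.asarray(drift_fn(x_pred))
        x = x + 0.5 * (f0 + f1) * dt + dw
        if not np.all(np.isfinite(x)):
            raise IntegrationDivergedError(step)
        if step % store_every == 0:
            out[n_out] = x
            n_out += 1
    return out[:n_out]


def simulate_network(connectome: ConnectomeSpec, slo_params: SLOParams,
                     duration: float, seed: int | None = None,
                     t0: float = 20.0) -> NeuralTimeseries:
    """Simulate the two-subpopulation SLO network.

    Per node j the slow pair (u_j, v_j) follows a standard SLO with fixed
    bifurcation parameter ``alpha_s`` and inter-node coupling
    ``G * sum_i C[i, j] * u_i`` (resp. ``v_i``); the fast pair (x_j, y_j)
    follows an SLO whose bifurcation parameter is the time-varying
    ``alpha_f * u_j(t)`` in the x-equation and ``alpha_f * v_j(t)`` in the
    y-equation, with no inter-node coupling.  Both pairs receive
    independent additive noise of amplitude ``beta``.

    The integration runs at ``slo_params.dt`` and the trajectory is stored
    at ``slo_params.fs_out`` (which must divide 1/dt).  The first ``t0``
    seconds are kept in the output but flagged for truncation downstream.
    """
    p = slo_params
    n = connectome.n_nodes
    if duration - t0 < 60.0:
        raise ValueError("duration must leave at least 60 s after the transient")
    stride = int(round(1.0 / (p.dt * p.fs_out)))
    if abs(stride * p.dt * p.fs_out - 1.0) > 1e-9:
        raise ValueError("fs_out must divide the integration rate 1/dt")
    rng = np.random.default_rng(seed)

    omega_f = 2 * np.pi * p.f_fast
    omega_s = 2 * np.pi * p.f_slow
    C = connectome.C
    dt, beta, G = p.dt, p.beta, p.G
    sqrt_dt = np.sqrt(dt)

    # small random perturbation around the origin, same seed stream
    x = 0.01 * rng.standard_normal(n)
    y = 0.01 * rng.standard_normal(n)
    u = 0.01 * rng.standard_normal(n)
    v = 0.01 * rng.standard_normal(n)

    n_steps = int(round(duration / dt))
    n_stored = n_steps // stride + 1
    fast_x = np.empty((n, n_stored))
    slow_uv = np.empty((n, n_stored, 2))
    fast_x[:, 0] = x
    slow_uv[:, 0, 0] = u
    slow_uv[:, 0, 1] = v

    def drift(x, y, u, v):
        r2f = x * x + y * y
        au = p.alpha_f * u
        av = p.alpha_f * v
        dx = (au - r2f) * x - omega_f * y
        dy = (av - r2f) * y + omega_f * x
        r2s = u * u + v * v
        cu = C.T @ u  # C[i, j] weighting of partner i onto node j
        cv = C.T @ v
        du = (p.alpha_s - r2s) * u - omega_s * v + G * cu
        dv = (p.alpha_s - r2s) * v + omega_s * u + G * cv
        return dx, dy, du, dv

    chunk = 4096  # pre-draw noise in chunks to bound memory
    noise = None
    k = 1
    for step in range(1, n_steps + 1):
        if beta > 0:
            j = (step - 1) % chunk
            if j == 0:
                noise = beta * sqrt_dt * rng.standard_normal((chunk, 4, n))
            dwx, dwy, dwu, dwv = noise[j]
        else:
            dwx = dwy = dwu = dwv = 0.0
        fx0, fy0, fu0, fv0 = drift(x, y, u, v)
        xp = x + fx0 * dt + dwx
        yp = y + fy0 * dt + dwy
        up = u + fu0 * dt + dwu
        vp = v + fv0 * dt + dwv
        fx1, fy1, fu1, fv1 = drift(xp, yp, up, vp)
        x = x + 0.5 * (fx0 + fx1) * dt + dwx
        y = y + 0.5 * (fy0 + fy1) * dt + dwy
        u = u + 0.5 * (fu0 + fu1) * dt + dwu
        v = v + 0.5 * (fv0 + fv1) * dt + dwv
        if step % stride == 0:
            if not (np.all(np.isfinite(x)) and np.all(np.isfinite(u))):
                raise IntegrationDivergedError(step)
            fast_x[:, k] = x
            slow_uv[:, k, 0] = u
            slow_uv[:, k, 1] = v
            k += 1

    return NeuralTimeseries(fast_x=fast_x[:, :k], slow_uv=slow_uv[:, :k, :],
                            fs=p.fs_out, t0=t0)


# ---------------------------------------------------------------------------
# external interfaces
# ---------------------------------------------------------------------------


def write_connectome_tsv(connectome: ConnectomeSpec, path):
    """Write the coupling matrix as TSV with node-name header row/column and
    node metadata as a JSON sidecar (<path>.json)."""
    path = Path(path)
    names = connectome.node_names
    with open(path, "w") as fh:
        fh.write("node\t" + "\t".join(names) + "\n")
        for i, name in enumerate(names):
            row = "\t".join(f"{w:.10g}" for w in connectome.C[i])
            fh.write(f"{name}\t{row}\n")
    meta = {"n_nodes": connectome.n_nodes,
            "hemisphere_label": connectome.hemisphere_label,
            "node_names": names}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_connectome_tsv(path) -> ConnectomeSpec:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    rows = [line.rstrip("\n").split("\t") for line in path.read_text().splitlines()]
    names = rows[0][1:]
    C = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
    return ConnectomeSpec(n_nodes=len(names), C=C,
                          hemisphere_label=meta["hemisphere_label"],
                          node_names=names)


def write_timeseries_tsv(values: np.ndarray, fs: float, path, names=None):
    """Write a node x time matrix as TSV: first column time (s), one column
    per node."""
    values = np.atleast_2d(values)
    n, m = values.shape
    names = names or [f"node{idx:02d}" for idx in range(n)]
    t = np.arange(m) / fs
    with open(path, "w") as fh:
        fh.write("time\t" + "\t".join(names) + "\n")
        for j in range(m):
            fh.write(f"{t[j]:.6f}\t" + "\t".join(f"{values[i, j]:.8g}" for i in range(n)) + "\n")


def read_timeseries_tsv(path):
    """Read a TSV written by :func:`write_timeseries_tsv`.

    Returns (values node x time, fs, names)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    t = df["time"].to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    names = [c for c in df.columns if c != "time"]
    return df[names].to_numpy().T, float(fs), names
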