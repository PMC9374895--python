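"""Band-amplitude tensors and confound injection.

LFP-like signals are band-pass filtered into standard electrophysiological
bands, Hilbert-transformed to amplitude envelopes, truncated, detrended and
decimated to a common low rate (default 4 Hz), and stacked into an
amplitude tensor organised space x frequency x time.  Three confound
classes can then be injected under a 5 x 5 x 5 scaling grid:

* input measurement noise (ki): white Gaussian noise pushed through the
  same band-pass -> Hilbert -> decimate path as the data, so it carries the
  Rayleigh-envelope statistics that the amplitude transform imposes;
* output measurement noise (ko): white Gaussian noise added to BOLD;
* physiological confounds (kp): the SLFO signal, scaled per node by a
  spatially structured susceptibility weight times the uniform kp.

Noise scales are defined relative to the SD of the signal they corrupt so
the grid coefficients are comparable across nodes and bands.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import detrend, fftconvolve, firwin, hilbert, resample_poly

from .hemo_sim import BOLDTimeseries
from .neural_sim import NeuralTimeseries

__all__ = [
    "BandSpec",
    "STANDARD_BANDS",
    "AmplitudeTensor",
    "NoiseRegime",
    "bandpass_hilbert",
    "truncate_detrend_decimate",
    "build_amplitude_tensor",
    "noise_grid",
    "NOISE_GRID_VALUES",
    "inject_input_noise",
    "inject_output_confounds",
    "write_amplitude_tensor",
    "read_amplitude_tensor",
]

#: the five grid values: 0 plus a log-spaced sequence between 0.1 and 10
NOISE_GRID_VALUES = (0.0, 0.1, 0.46, 2.15, 10.0)


@dataclass(frozen=True)
class BandSpec:
    """Ordered list of (name, f_lo, f_hi) frequency bands in Hz."""

    bands: tuple = (
        ("delta", 1.0, 4.0),
        ("theta", 4.0, 8.0),
        ("alpha", 8.0, 12.0),
        ("beta", 12.0, 32.0),
        ("gamma", 32.0, 50.0),
    )

    def __post_init__(self):
        if not self.bands:
            raise ValueError("band list must be non-empty")
        for name, lo, hi in self.bands:
            if not 0 < lo < hi:
                raise ValueError(f"band {name}: need 0 < f_lo < f_hi")

    @property
    def names(self):
        return [b[0] for b in self.bands]

    def __len__(self):
        return len(self.bands)


STANDARD_BANDS = BandSpec()


@dataclass
class AmplitudeTensor:
    """Band-amplitude signals, space x frequency x time.

    ``source_fs``/``source_n``/``t_trunc`` record the pre-decimation path
    so input-noise surrogates can be pushed through the identical chain.
    """

    values: np.ndarray
    fs: float
    band_spec: BandSpec
    node_names: list[str] = field(default_factory=list)
    source_fs: float | None = None
    source_n: int | None = None
    t_trunc: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("amplitude tensor must be space x frequency x time")
        if np.any(np.isnan(self.values)):
            raise ValueError("amplitude tensor contains NaN")
        if self.values.shape[1] != len(self.band_spec):
            raise ValueError("frequency axis does not match the band list")
        if not self.node_names:
            self.node_names = [f"node{idx:02d}" for idx in range(self.values.shape[0])]

    @property
    def shape(self):
        return self.values.shape


@dataclass(frozen=True)
class NoiseRegime:
    """Scaling coefficients for SLFO (kp), input (ki) and output (ko) noise."""

    kp: float
    ki: float
    ko: float

    def __post_init__(self):
        if self.kp < 0 or self.ki < 0 or self.ko < 0:
            raise ValueError("noise coefficients must be nonnegative")


# ---------------------------------------------------------------------------
# filtering and decimation
# ---------------------------------------------------------------------------


def _fir_bandpass(band, fs):
    """Linear-phase FIR band-pass with a transition width tied to the band.

    The Hamming-window transition is ``min(f_lo / 2, 1 Hz)`` so that
    activity one band below is attenuated into the stop band rather than
    leaking through a sloppy edge (a 2 Hz carrier must not contaminate the
    4-8 Hz envelope).
    """
    _, lo, hi = band
    nyq = fs / 2
    if not lo < hi < nyq:
        raise ValueError(f"band ({lo}, {hi}) outside Nyquist range (0, {nyq})")
    transition = min(lo / 2.0, 1.0)
    numtaps = int(3.3 * fs / transition) | 1  # odd -> symmetric, type-I
    return firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)


def bandpass_hilbert(signal: np.ndarray, band, fs: float) -> np.ndarray:
    """Zero-phase band-pass then analytic-signal magnitude.

    ``band`` is a (name, f_lo, f_hi) triple.  The symmetric FIR is applied
    in 'same' alignment, which is exactly zero-phase; output length equals
    input length (edge samples within half a filter length are transient-
    contaminated and are removed by the downstream truncation stage).
    """
    signal = np.asarray(signal, dtype=float)
    taps = _fir_bandpass(band, fs)
    narrow = fftconvolve(signal, taps, mode="same")
    return np.abs(hilbert(narrow))


def truncate_detrend_decimate(signal: np.ndarray, fs_in: float, fs_out: float,
                              t_trunc: float = 0.0) -> np.ndarray:
    """Remove the initial transient, detrend linearly, anti-alias and resample.

    The rate change uses polyphase resampling (rational approximation of
    ``fs_out/fs_in``) whose FIR low-pass cuts below ``fs_out/2``.
    """
    from fractions import Fraction

    signal = np.asarray(signal, dtype=float)
    if fs_out > fs_in:
        raise ValueError("fs_out must not exceed fs_in")
    n_skip = int(round(t_trunc * fs_in))
    if n_skip >= signal.shape[-1]:
        raise ValueError("signal shorter than the truncation interval")
    x = detrend(signal[..., n_skip:], type="linear")
    if fs_in == fs_out:
        return x
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return resample_poly(x, frac.numerator, frac.denominator, axis=-1)


def build_amplitude_tensor(neural: NeuralTimeseries,
                           band_spec: BandSpec = STANDARD_BANDS,
                           fs_out: float = 4.0,
                           t_trunc: float | None = None) -> AmplitudeTensor:
    """Band-pass + Hilbert every (node, band) pair, then truncate/decimate.

    ``t_trunc`` defaults to the transient flagged on the neural data.
    """
    if t_trunc is None:
        t_trunc = neural.t0
    n_nodes = neural.n_nodes
    envs = np.stack([
        np.stack([bandpass_hilbert(neural.fast_x[i], band, neural.fs)
                  for band in band_spec.bands])
        for i in range(n_nodes)
    ])  # node x band x time at neural.fs
    flat = envs.reshape(n_nodes * len(band_spec), -1)
    dec = truncate_detrend_decimate(flat, neural.fs, fs_out, t_trunc)
    values = dec.reshape(n_nodes, len(band_spec), -1)
    return AmplitudeTensor(values=values, fs=fs_out, band_spec=band_spec,
                           source_fs=neural.fs, source_n=neural.fast_x.shape[1],
                           t_trunc=t_trunc)


# ---------------------------------------------------------------------------
# noise regimes
# ---------------------------------------------------------------------------


def noise_grid(values=NOISE_GRID_VALUES) -> list[NoiseRegime]:
    """All (kp, ki, ko) tuples in lexicographic order: 5^3 = 125 regimes."""
    return [NoiseRegime(kp, ki, ko)
            for kp, ki, ko in itertools.product(values, repeat=3)]


def inject_input_noise(tensor: AmplitudeTensor, ki: float,
                       seed: int | None = None) -> AmplitudeTensor:
    """Add band-limited envelope noise to every (node, band) signal.

    For each cell, white Gaussian noise is generated at the pre-decimation
    rate, band-passed into the cell's band, converted to its analytic-
    signal magnitude and decimated through the identical path as the data.
    The resulting envelope (marginally Rayleigh before mean-centring) is
    mean-centred, scaled to ``ki`` times the data signal's SD and added.
    ``ki = 0`` returns the input unchanged.
    """
    if ki < 0:
        raise ValueError("ki must be nonnegative")
    if ki == 0:
        return tensor
    rng = np.random.default_rng(seed)
    fs_native = tensor.source_fs or 200.0
    n_native = tensor.source_n or int(
        (tensor.values.shape[2] / tensor.fs + tensor.t_trunc) * fs_native)
    n_nodes, n_bands, n_times = tensor.values.shape
    out = tensor.values.copy()
    for b, band in enumerate(tensor.band_spec.bands):
        taps = _fir_bandpass(band, fs_native)
        for i in range(n_nodes):
            white = rng.standard_normal(n_native)
            narrow = fftconvolve(white, taps, mode="same")
            env = np.abs(hilbert(narrow))
            env = truncate_detrend_decimate(env, fs_native, tensor.fs,
                                            tensor.t_trunc)[:n_times]
            env = env - env.mean()
            sd = env.std()
            data_sd = tensor.values[i, b].std()
            if data_sd == 0:
                data_sd = 1.0  # zero signal: fall back to absolute scaling
            if sd > 0:
                out[i, b, :len(env)] += ki * data_sd * env / sd
    return AmplitudeTensor(values=out, fs=tensor.fs, band_spec=tensor.band_spec,
                           node_names=list(tensor.node_names),
                           source_fs=tensor.source_fs, source_n=tensor.source_n,
                           t_trunc=tensor.t_trunc)


def inject_output_confounds(bold: BOLDTimeseries, slfo: np.ndarray,
                            node_weights: np.ndarray, kp: float, ko: float,
                            seed: int | None = None) -> BOLDTimeseries:
    """BOLD_j + kp * w_j * slfo + ko * AWGN, per node j.

    The SLFO enters scaled by the node susceptibility weight ``w_j`` times
    the uniform coefficient ``kp``; both confounds are expressed relative
    to each node's BOLD SD.  ``kp = ko = 0`` is the identity.
    """
    values = bold.values
    n_nodes, n_times = values.shape
    slfo = np.asarray(slfo, dtype=float)
    if kp > 0 and len(slfo) != n_times:
        raise ValueError("slfo must live on the BOLD grid")
    node_weights = np.asarray(node_weights, dtype=float)
    if kp > 0 and len(node_weights) != n_nodes:
        raise ValueError("one node weight per BOLD node required")
    if kp == 0 and ko == 0:
        return bold
    out = values.copy()
    bold_sd = values.std(axis=1, keepdims=True)
    if kp > 0:
        s = slfo - slfo.mean()
        s_sd = s.std() or 1.0
        out = out + kp * node_weights[:, None] * bold_sd * (s / s_sd)[None, :]
    if ko > 0:
        rng = np.random.default_rng(seed)
        out = out + ko * bold_sd * rng.standard_normal((n_nodes, n_times))
    return BOLDTimeseries(values=out, fs=bold.fs)


# ---------------------------------------------------------------------------
# serialisation: one TSV per band plus a JSON manifest
# ---------------------------------------------------------------------------


def write_amplitude_tensor(tensor: AmplitudeTensor, out_dir):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "shape": list(tensor.shape),
        "fs": tensor.fs,
        "bands": [list(b) for b in tensor.band_spec.bands],
        "node_names": tensor.node_names,
        "source_fs": tensor.source_fs,
        "source_n": tensor.source_n,
        "t_trunc": tensor.t_trunc,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    for b, (name, *_rest) in enumerate(tensor.band_spec.bands):
        header = "\t".join(tensor.node_names)
        np.savetxt(out_dir / f"band_{b:02d}_{name}.tsv", tensor.values[:, b, :].T,
                   delimiter="\t", header=header, comments="", fmt="%.8g")


def read_amplitude_tensor(out_dir) -> AmplitudeTensor:
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    bands = BandSpec(bands=tuple(tuple(b) for b in manifest["bands"]))
    mats = []
    for b, (name, *_rest) in enumerate(bands.bands):
        mat = np.loadtxt(out_dir / f"band_{b:02d}_{name}.tsv", delimiter="\t",
                         skiprows=1)
        mats.append(np.atleast_2d(mat).T if mat.ndim == 1 else mat.T)
    values = np.stack(mats, axis=1)
    return AmplitudeTensor(values=values, fs=manifest["fs"], band_spec=bands,
                           node_names=manifest["node_names"],
                           source_fs=manifest.get("source_fs"),
                           source_n=manifest.get("source_n"),
                           t_trunc=manifest.get("t_trunc", 0.0))
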