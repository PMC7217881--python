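"""Morlet time-frequency decomposition and the 146 x 48 feature space.

An epoch (768 samples, 512 Hz, -500..1000 ms) is convolved with a bank of
complex Morlet wavelets at 146 integer center frequencies, 4..149 Hz.  The
wavelet at f0 has Gaussian envelopes in time (sigma_t) and frequency
(sigma_f = 1 / (2 pi sigma_t)) with a band-dependent cycle count
f0 / sigma_f: 3 in theta (4-8 Hz), 4 in alpha (9-14 Hz), 5 in beta
(15-30 Hz) and 6 in both gamma ranges (31-60, 61-150 Hz).  Squared
magnitude gives power; each frequency row is divided by its own mean
baseline power (-500..-100 ms) and averaged over 48 consecutive bins of 16
samples (31.25 ms), yielding the 146 x 48 matrix of dimensionless
modulation ratios that all later stages consume.

Wavelets are L2 (unit-energy) normalized; since only post/baseline power
ratios are used downstream, the normalization convention cancels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import fftconvolve
from scipy.stats import wilcoxon
from statsmodels.stats.multitest import multipletests

from .synthdata import FS, N_SAMPLES, epoch_times_ms

FREQS = np.arange(4, 150)
"""146 integer center frequencies, 4..149 Hz (1-Hz rows)."""

N_FREQS = FREQS.size
N_BINS = 48
BIN_SAMPLES = N_SAMPLES // N_BINS  # 16 samples = 31.25 ms
N_FEATURES = N_FREQS * N_BINS  # 7008

BASELINE_MS = (-500.0, -100.0)
POST_MS = (0.0, 1000.0)

_CYCLE_BANDS = ((4, 8, 3), (9, 14, 4), (15, 30, 5), (31, 60, 6), (61, 150, 6))


def n_cycles_for(f0: float) -> int:
    """Band-dependent wavelet cycle count f0/sigma_f."""
    for lo, hi, c in _CYCLE_BANDS:
        if lo <= f0 <= hi:
            return c
    raise ValueError(f"frequency {f0} Hz outside the 4-150 Hz analysis range")


def morlet_wavelet(f0: float, n_cycles: float, fs: float = FS) -> np.ndarray:
    """Complex Morlet wavelet, zero-mean and unit-energy, support +-5 sigma_t.

    The admissibility (zero-mean) correction subtracts the carrier's
    Gaussian-weighted mean; at 3 cycles this is what keeps a DC offset from
    leaking into the theta rows.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    sigma_t = n_cycles / (2.0 * np.pi * f0)
    half = int(np.ceil(5.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    gauss = np.exp(-(t**2) / (2.0 * sigma_t**2))
    carrier = np.exp(2j * np.pi * f0 * t)
    dc = np.sum(gauss * carrier) / np.sum(gauss)
    w = gauss * (carrier - dc)
    return w / np.sqrt(np.sum(np.abs(w) ** 2))


@dataclass(frozen=True)
class WaveletBank:
    """Precomputed Morlet filters for the full frequency grid."""

    freqs: np.ndarray
    n_cycles: np.ndarray
    fs: float
    wavelets: tuple

    @classmethod
    def default(cls, fs: float = FS) -> "WaveletBank":
        return _default_bank(fs)

    @property
    def sigma_t(self) -> np.ndarray:
        return self.n_cycles / (2.0 * np.pi * self.freqs)

    @property
    def sigma_f(self) -> np.ndarray:
        return self.freqs / self.n_cycles


@lru_cache(maxsize=4)
def _default_bank(fs: float) -> WaveletBank:
    cycles = np.array([n_cycles_for(f) for f in FREQS])
    wavelets = tuple(morlet_wavelet(f, c, fs) for f, c in zip(FREQS, cycles))
    return WaveletBank(FREQS.copy(), cycles, fs, wavelets)


def _convolve_power(traces: np.ndarray, wavelet: np.ndarray) -> np.ndarray:
    """|wavelet * trace|^2 with reflection padding against edge artifacts."""
    pad = wavelet.size // 2
    pad = min(pad, traces.shape[-1] - 1)
    padded = np.pad(traces, [(0, 0)] * (traces.ndim - 1) + [(pad, pad)], mode="reflect")
    conv = fftconvolve(padded, wavelet[(None,) * (traces.ndim - 1) + (slice(None),)], mode="same", axes=-1)
    power = np.abs(conv[..., pad : pad + traces.shape[-1]]) ** 2
    return power


def _bank_power_batch(epochs: np.ndarray, bank: "WaveletBank") -> np.ndarray:
    """All-frequency power for a batch of epochs via one shared forward FFT.

    Equivalent to per-frequency ``_convolve_power`` (reflection padding at
    the widest wavelet's half-support, FFT-domain products, centered crop)
    but the padded epochs are transformed once instead of once per row.
    """
    from scipy.fft import irfft, next_fast_len, rfft

    n = epochs.shape[-1]
    pad = min(max(w.size // 2 for w in bank.wavelets), n - 1)
    padded = np.pad(epochs, [(0, 0), (pad, pad)], mode="reflect")
    m = padded.shape[-1]
    wmax = max(w.size for w in bank.wavelets)
    nfft = next_fast_len(m + wmax - 1)
    # real & imaginary parts transformed separately so rfft applies
    spec = rfft(padded, nfft, axis=-1)
    out = np.empty((epochs.shape[0], len(bank.wavelets), n), dtype=np.float32)
    for i, w in enumerate(bank.wavelets):
        wf_r = rfft(np.real(w), nfft)
        wf_i = rfft(np.imag(w), nfft)
        # full convolution; 'same' crop start = (len(w) - 1) // 2
        start = (w.size - 1) // 2 + pad
        conv_r = irfft(spec * wf_r, nfft, axis=-1)[..., start : start + n]
        conv_i = irfft(spec * wf_i, nfft, axis=-1)[..., start : start + n]
        out[:, i, :] = conv_r**2 + conv_i**2
    return out


def morlet_power(trace: np.ndarray, f0: float, n_cycles: float, fs: float = FS) -> np.ndarray:
    """Time-varying spectral power P(t, f0) = |w(t, f0) * s(t)|^2."""
    trace = np.asarray(trace, dtype=float)
    if f0 >= fs / 2:
        raise ValueError("f0 must be below the Nyquist frequency")
    w = morlet_wavelet(f0, n_cycles, fs)
    return _convolve_power(trace[None, :], w)[0]


def tf_transform(epoch: np.ndarray, bank: WaveletBank | None = None) -> np.ndarray:
    """Full-rate power matrix (146 x n_samples) for one epoch."""
    return tf_transform_batch(np.asarray(epoch, float)[None, :], bank)[0]


def tf_transform_batch(epochs: np.ndarray, bank: WaveletBank | None = None) -> np.ndarray:
    """Power matrices (n_trials x 146 x n_samples) for a stack of epochs."""
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 2:
        raise ValueError("epochs must be (n_trials, n_samples)")
    bank = bank or WaveletBank.default()
    return _bank_power_batch(epochs, bank)


def _window_mask(window_ms: tuple[float, float], n_samples: int) -> np.ndarray:
    t = epoch_times_ms(n_samples)
    return (t >= window_ms[0]) & (t < window_ms[1])


def baseline_normalize(
    power: np.ndarray, baseline_ms: tuple[float, float] = BASELINE_MS
) -> np.ndarray:
    """Divide each frequency row by its mean power in the baseline window."""
    power = np.asarray(power, dtype=float)
    mask = _window_mask(baseline_ms, power.shape[-1])
    base = power[..., mask].mean(axis=-1, keepdims=True)
    bad = np.flatnonzero(np.ravel(base) == 0)
    if bad.size:
        raise ValueError(f"zero baseline power in frequency row(s) {bad.tolist()}")
    return power / base


def bin_time(normalized: np.ndarray, n_bins: int = N_BINS) -> np.ndarray:
    """Average consecutive samples into n_bins contiguous time bins."""
    normalized = np.asarray(normalized, dtype=float)
    n = normalized.shape[-1]
    if n % n_bins:
        raise ValueError(f"{n} columns not divisible into {n_bins} bins")
    shape = normalized.shape[:-1] + (n_bins, n // n_bins)
    return normalized.reshape(shape).mean(axis=-1)


@dataclass
class TFMap:
    """Baseline-normalized 146 x 48 power-ratio matrix (the feature space)."""

    values: np.ndarray
    freqs: np.ndarray = None
    bin_ms: float = 1000.0 * BIN_SAMPLES / FS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FREQS, N_BINS):
            raise ValueError(f"a TFMap is exactly {N_FREQS} x {N_BINS}")
        if np.any(self.values < 0):
            raise ValueError("power ratios are nonnegative")
        if self.freqs is None:
            self.freqs = FREQS.copy()

    def flatten(self) -> np.ndarray:
        """Row-major (frequency-major) feature vector of length 7008."""
        return self.values.reshape(-1)

    @classmethod
    def from_flat(cls, flat: np.ndarray) -> "TFMap":
        return cls(np.asarray(flat, float).reshape(N_FREQS, N_BINS))


def epoch_tf_map(epoch: np.ndarray, bank: WaveletBank | None = None) -> TFMap:
    """Epoch -> baseline-normalized, binned 146 x 48 map."""
    power = tf_transform(epoch, bank)
    return TFMap(bin_time(baseline_normalize(power)))


def probe_tf_features(
    epochs: np.ndarray,
    bank: WaveletBank | None = None,
    batch: int = 64,
):
    """TF features for all epochs of a probe.

    Returns ``(tfmaps, post_power, base_power)`` where ``tfmaps`` is
    (n_trials, 146, 48) of baseline-normalized binned ratios and
    ``post_power`` / ``base_power`` are (n_trials, 146) per-trial mean raw
    power in the post-stimulus (0..1000 ms) and baseline (-500..-100 ms)
    windows — the matched pairs of the responsiveness test.  Epochs are
    processed in batches to bound memory.
    """
    epochs = np.asarray(epochs, dtype=float)
    n = epochs.shape[0]
    tfmaps = np.empty((n, N_FREQS, N_BINS), dtype=np.float32)
    post = np.empty((n, N_FREQS))
    base = np.empty((n, N_FREQS))
    post_mask = _window_mask(POST_MS, epochs.shape[1])
    base_mask = _window_mask(BASELINE_MS, epochs.shape[1])
    for lo in range(0, n, batch):
        hi = min(lo + batch, n)
        power = tf_transform_batch(epochs[lo:hi], bank)
        post[lo:hi] = power[..., post_mask].mean(axis=-1)
        base[lo:hi] = power[..., base_mask].mean(axis=-1)
        tfmaps[lo:hi] = bin_time(power / base[lo:hi, :, None])
    return tfmaps, post, base


@dataclass
class ResponsivenessResult:
    """Per-frequency Wilcoxon screen of post-stimulus vs baseline power."""

    probe_id: str
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    responsive: bool
    n_significant_frequencies: int
    alpha: float


def responsiveness_test(
    post_power: np.ndarray,
    base_power: np.ndarray,
    alpha: float = 0.005,
    probe_id: str = "",
) -> ResponsivenessResult:
    """Wilcoxon signed-rank screen across the 146 frequency rows.

    For each frequency the matched pairs are one trial's mean post-stimulus
    power against the same trial's mean baseline power.  P-values are
    Benjamini-Hochberg adjusted across frequencies; a probe is responsive
    when at least two adjusted p-values are <= alpha.  A frequency whose
    pairs are all tied gets p = 1.
    """
    post_power = np.asarray(post_power, float)
    base_power = np.asarray(base_power, float)
    if post_power.shape != base_power.shape or post_power.ndim != 2:
        raise ValueError("post_power and base_power must both be (n_trials, n_freqs)")
    if post_power.shape[0] < 6:
        raise ValueError("the signed-rank screen needs at least 6 trials")
    n_freqs = post_power.shape[1]
    p_raw = np.ones(n_freqs)
    diff = post_power - base_power
    nonzero = ~np.all(diff == 0, axis=0)
    if nonzero.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = wilcoxon(diff[:, nonzero], zero_method="wilcox", axis=0)
        p_raw[nonzero] = np.atleast_1d(res.pvalue)
    _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    n_sig = int(np.sum(p_adj <= alpha))
    return ResponsivenessResult(
        probe_id=probe_id,
        p_raw=p_raw,
        p_adjusted=p_adj,
        responsive=n_sig >= 2,
        n_significant_frequencies=n_sig,
        alpha=alpha,
    )
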