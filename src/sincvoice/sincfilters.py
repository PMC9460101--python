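"""Parametrized sinc band-pass filterbank.

Each channel of the filterbank is an ideal band-pass impulse response
expressed as the difference of two scaled sinc low-pass kernels,

    g[n] = 2 f2 sinc(2 pi f2 n) - 2 f1 sinc(2 pi f1 n),

where ``f1 < f2`` are the band edges in normalized frequency (cycles per
sample), ``sinc(x) = sin(x)/x`` with ``sinc(0) = 1``, and ``n`` runs over
symmetric integer offsets.  Only the two cutoffs per channel are learnable,
so an 80-channel bank carries 160 scalars; every kernel is even-symmetric
by construction.

Cutoff validity under unconstrained optimization is enforced by a total
reparameterization: ``f1 = min_low + |raw_low|`` and
``f2 = min(f1 + min_band + |raw_band|, nyquist)``, so any pair of real
parameters maps to a valid band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy.signal.windows import hamming

__all__ = [
    "SincFilterBank",
    "make_sinc_kernel",
    "constrain_cutoffs",
    "init_filterbank",
    "apply_filterbank",
    "filterbank_response",
    "save_filterbank_csv",
    "load_filterbank_csv",
]

_WINDOWS = {
    "hamming": lambda L: hamming(L, sym=True),
    "none": lambda L: np.ones(L),
}


def _window(name: str, length: int) -> np.ndarray:
    try:
        return _WINDOWS[name](length)
    except KeyError:
        raise ValueError(f"unknown window {name!r}; choose from {sorted(_WINDOWS)}")


def make_sinc_kernel(
    f1: float,
    f2: float,
    filter_len: int = 251,
    sample_rate: float = 16000.0,
    window: str = "hamming",
) -> np.ndarray:
    """Band-pass kernel for cutoffs ``f1 < f2`` (Hz), tapered by ``window``.

    The center tap equals ``2 (f2 - f1) / sample_rate`` times the window
    center value; the kernel is even-symmetric about its center.
    """
    if filter_len % 2 == 0:
        raise ValueError(f"filter_len must be odd, got {filter_len}")
    if not 0.0 <= f1 < f2:
        raise ValueError(f"need 0 <= f1 < f2, got f1={f1}, f2={f2}")
    if f2 > sample_rate / 2:
        raise ValueError(f"f2={f2} exceeds Nyquist {sample_rate / 2}")
    half = (filter_len - 1) // 2
    n = np.arange(-half, half + 1)
    lo, hi = f1 / sample_rate, f2 / sample_rate
    g = _scaled_sinc(hi, n) - _scaled_sinc(lo, n)
    return g * _window(window, filter_len)


def _scaled_sinc(f: float, n: np.ndarray) -> np.ndarray:
    """2 f sinc(2 pi f n) at integer offsets n, with normalized frequency f."""
    x = 2.0 * np.pi * f * n
    out = np.full(n.shape, 2.0 * f, dtype=float)
    nz = n != 0
    out[nz] = np.sin(x[nz]) / (np.pi * n[nz])
    return out


def sinc_kernel_grads(
    f1: float,
    f2: float,
    filter_len: int,
    sample_rate: float,
    window: str = "hamming",
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic (d g / d f1, d g / d f2) in per-Hz units.

    d/df [2 f sinc(2 pi f n)] = 2 cos(2 pi f n) for every n (including 0),
    so the gradients are plain cosines under the same taper.
    """
    half = (filter_len - 1) // 2
    n = np.arange(-half, half + 1)
    w = _window(window, filter_len)
    d_hi = 2.0 * np.cos(2.0 * np.pi * (f2 / sample_rate) * n) * w / sample_rate
    d_lo = -2.0 * np.cos(2.0 * np.pi * (f1 / sample_rate) * n) * w / sample_rate
    return d_lo, d_hi


def constrain_cutoffs(
    raw_low: float | np.ndarray,
    raw_band: float | np.ndarray,
    min_low_hz: float = 50.0,
    min_band_hz: float = 50.0,
    sample_rate: float = 16000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Map unconstrained reals to a valid band ``0 < f1 < f2 <= Nyquist``.

    Total by design: absolute values impose the floors, and both edges are
    clipped so the band stays inside (0, Nyquist] for any input, which keeps
    gradient-based updates from ever producing a degenerate filter.
    """
    nyq = sample_rate / 2.0
    f1 = min_low_hz + np.abs(np.asarray(raw_low, dtype=float))
    f1 = np.minimum(f1, nyq - min_band_hz)
    f2 = np.minimum(f1 + min_band_hz + np.abs(np.asarray(raw_band, dtype=float)), nyq)
    return f1, f2


@dataclass
class SincFilterBank:
    """Learnable sinc band-pass filterbank front end.

    ``raw_low`` and ``raw_band`` are the 2 x n_filters unconstrained
    learnable scalars; effective cutoffs come from :func:`constrain_cutoffs`.
    """

    n_filters: int = 80
    filter_len: int = 251
    sample_rate: float = 16000.0
    raw_low: np.ndarray = field(default=None)  # type: ignore[assignment]
    raw_band: np.ndarray = field(default=None)  # type: ignore[assignment]
    window: str = "hamming"
    min_low_hz: float = 50.0
    min_band_hz: float = 50.0

    def __post_init__(self):
        if self.filter_len % 2 == 0:
            raise ValueError("filter_len must be odd")
        if self.raw_low is None:
            self.raw_low = np.zeros(self.n_filters)
        if self.raw_band is None:
            self.raw_band = np.zeros(self.n_filters)
        self.raw_low = np.asarray(self.raw_low, dtype=float)
        self.raw_band = np.asarray(self.raw_band, dtype=float)
        if self.raw_low.shape != (self.n_filters,) or self.raw_band.shape != (self.n_filters,):
            raise ValueError("raw parameter arrays must have shape (n_filters,)")

    @property
    def n_learnable(self) -> int:
        return 2 * self.n_filters

    def cutoffs_hz(self) -> tuple[np.ndarray, np.ndarray]:
        """Effective (f1, f2) per channel in Hz, always a valid band."""
        return constrain_cutoffs(
            self.raw_low, self.raw_band, self.min_low_hz, self.min_band_hz, self.sample_rate
        )

    def kernels(self) -> np.ndarray:
        """(n_filters, filter_len) tap matrix; rows even-symmetric."""
        f1, f2 = self.cutoffs_hz()
        taps = np.empty((self.n_filters, self.filter_len))
        for i in range(self.n_filters):
            taps[i] = make_sinc_kernel(
                f1[i], f2[i], self.filter_len, self.sample_rate, self.window
            )
        return taps


def _mel(f_hz: np.ndarray | float) -> np.ndarray:
    return 2595.0 * np.log10(1.0 + np.asarray(f_hz, dtype=float) / 700.0)


def _mel_inv(m: np.ndarray) -> np.ndarray:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def init_filterbank(
    n_filters: int = 80,
    sample_rate: float = 16000.0,
    scheme: str = "mel",
    filter_len: int = 251,
    window: str = "hamming",
    min_low_hz: float = 50.0,
    min_band_hz: float = 50.0,
) -> SincFilterBank:
    """Deterministically tile [min_low_hz, Nyquist) with band edges.

    ``mel`` spacing places bands densely at low frequency, matching how
    perceptually relevant detail concentrates below ~1 kHz in voice; bands
    are contiguous, ordered by rising lower edge.
    """
    if n_filters < 1:
        raise ValueError("n_filters must be >= 1")
    nyq = sample_rate / 2.0
    f_hi = nyq - min_band_hz
    if scheme == "mel":
        edges = _mel_inv(np.linspace(_mel(min_low_hz), _mel(f_hi), n_filters + 1))
    elif scheme == "linear":
        edges = np.linspace(min_low_hz, f_hi, n_filters + 1)
    else:
        raise ValueError(f"unknown init scheme {scheme!r}")
    f1 = edges[:-1]
    f2 = edges[1:]
    raw_low = f1 - min_low_hz
    raw_band = np.maximum(f2 - f1 - min_band_hz, 0.0)
    return SincFilterBank(
        n_filters=n_filters,
        filter_len=filter_len,
        sample_rate=sample_rate,
        raw_low=raw_low,
        raw_band=raw_band,
        window=window,
        min_low_hz=min_low_hz,
        min_band_hz=min_band_hz,
    )


def apply_filterbank(chunk: np.ndarray, bank: SincFilterBank) -> np.ndarray:
    """Convolve a 1-D chunk with every channel; 'valid' extent, no padding.

    Returns an (n_filters, len(chunk) - filter_len + 1) feature matrix.
    """
    chunk = np.asarray(chunk, dtype=float)
    if chunk.ndim != 1:
        raise ValueError("chunk must be 1-D")
    if chunk.size < bank.filter_len:
        raise ValueError(
            f"chunk length {chunk.size} shorter than filter_len {bank.filter_len}"
        )
    return fftconvolve(chunk[None, :], bank.kernels(), mode="valid", axes=-1)


def filterbank_response(bank: SincFilterBank, n_fft: int = 4096) -> tuple[np.ndarray, np.ndarray]:
    """One-sided DFT magnitude of each kernel.

    Returns ``(freqs_hz, mags)`` with ``mags`` of shape
    (n_filters, n_fft // 2 + 1).  The peak of channel i lies inside its
    configured band to within one bin.
    """
    if n_fft < bank.filter_len:
        raise ValueError("n_fft must be >= filter_len")
    mags = np.abs(np.fft.rfft(bank.kernels(), n=n_fft, axis=-1))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / bank.sample_rate)
    return freqs, mags


def save_filterbank_csv(bank: SincFilterBank, path) -> None:
    """Write learned bands as a diffable CSV: channel, f1_hz, f2_hz."""
    f1, f2 = bank.cutoffs_hz()
    with open(path, "w") as fh:
        fh.write("channel,f1_hz,f2_hz\n")
        for i in range(bank.n_filters):
            fh.write(f"{i},{f1[i]:.6f},{f2[i]:.6f}\n")


def load_filterbank_csv(path, sample_rate: float = 16000.0, **kwargs) -> SincFilterBank:
    """Rebuild a bank from a band table written by :func:`save_filterbank_csv`."""
    rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    f1, f2 = rows[:, 1], rows[:, 2]
    min_low = kwargs.pop("min_low_hz", 50.0)
    min_band = kwargs.pop("min_band_hz", 50.0)
    return SincFilterBank(
        n_filters=len(f1),
        sample_rate=sample_rate,
        raw_low=f1 - min_low,
        raw_band=np.maximum(f2 - f1 - min_band, 0.0),
        min_low_hz=min_low,
        min_band_hz=min_band,
        **kwargs,
    )
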