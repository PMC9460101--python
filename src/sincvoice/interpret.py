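"""Filter-level interpretability analyses.

Two views of what the first layer learned:

* per-channel portraits — a channel's time-domain taps next to its
  one-sided DFT magnitude (band-pass by construction for the sinc front
  end, unconstrained for the 1-D baseline);
* averaged power spectral density — pass a vowel through the full
  filterbank, estimate a 256-point Welch PSD per channel (an 80 x 256
  matrix at the reference width), then average across channels to a
  single 256-bin profile.  Comparing the profiles of two front ends on
  the same utterance shows which acoustic structure (notably the first
  formant of /a/) each preserves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .networks import VoiceNet
from .sincfilters import SincFilterBank, apply_filterbank
from .vowelsynth import LabeledWaveform

__all__ = ["PSDProfile", "channel_portrait", "psd_profile", "compare_profiles"]

N_PSD = 256


@dataclass
class PSDProfile:
    bins: np.ndarray  # 256 two-sided power values
    bin_frequencies: np.ndarray  # Hz, fftfreq ordering
    source: str = ""

    def __post_init__(self):
        self.bins = np.asarray(self.bins, dtype=float)
        if self.bins.shape != (N_PSD,):
            raise ValueError(f"profile must have exactly {N_PSD} bins")
        if (self.bins < -1e-12).any():
            raise ValueError("power values must be nonnegative")

    def one_sided(self) -> tuple[np.ndarray, np.ndarray]:
        half = N_PSD // 2 + 1
        return self.bin_frequencies[:half], self.bins[:half]

    def peak_hz(self) -> float:
        freqs, power = self.one_sided()
        return float(freqs[int(np.argmax(power))])

    def band_energy(self, lo_hz: float, hi_hz: float) -> float:
        freqs, power = self.one_sided()
        m = (freqs >= lo_hz) & (freqs <= hi_hz)
        return float(power[m].sum())


def channel_portrait(model: VoiceNet, channel_index: int,
                     n_fft: int = 4096) -> dict:
    """Time taps and one-sided magnitude response of one front-end channel."""
    kernels = model.front_kernels()
    if not 0 <= channel_index < kernels.shape[0]:
        raise IndexError(
            f"channel {channel_index} out of range [0, {kernels.shape[0]})"
        )
    taps = kernels[channel_index]
    mag = np.abs(np.fft.rfft(taps, n=n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / model.spec.sample_rate)
    out = {"channel": channel_index, "taps": taps, "freqs_hz": freqs,
           "magnitude": mag}
    try:
        f1, f2 = model.front_bank().cutoffs_hz()
        out["band_hz"] = (float(f1[channel_index]), float(f2[channel_index]))
    except ValueError:
        pass  # free-form front end has no parametric band
    return out


def _front_features(waveform: np.ndarray, front_end) -> tuple[np.ndarray, float]:
    if isinstance(front_end, SincFilterBank):
        return apply_filterbank(waveform, front_end), front_end.sample_rate
    if isinstance(front_end, VoiceNet):
        kernels = front_end.front_kernels()
        from scipy.signal import fftconvolve

        return (fftconvolve(waveform[None, :], kernels, mode="valid", axes=-1),
                front_end.spec.sample_rate)
    raise TypeError("front_end must be a SincFilterBank or a VoiceNet")


def psd_profile(waveform: LabeledWaveform | np.ndarray, front_end,
                n_psd: int = N_PSD, source: str = "") -> PSDProfile:
    """Channel-averaged Welch PSD of the filterbank-processed waveform.

    Welch settings: ``n_psd``-point segments, 50% overlap, Hamming taper,
    all two-sided bins retained so the per-channel matrix is
    (n_filters, n_psd) before averaging.
    """
    if isinstance(waveform, LabeledWaveform):
        samples, sr = waveform.samples, waveform.sample_rate
    else:
        samples = np.asarray(waveform, dtype=float)
        sr = None
    feats, fe_sr = _front_features(samples, front_end)
    sr = sr or fe_sr
    if feats.shape[1] < n_psd:
        raise ValueError(
            f"filtered signal length {feats.shape[1]} shorter than one "
            f"{n_psd}-point PSD segment"
        )
    freqs, psd = welch(feats, fs=sr, window="hamming", nperseg=n_psd,
                       noverlap=n_psd // 2, return_onesided=False,
                       detrend=False, scaling="density", axis=-1)
    return PSDProfile(psd.mean(axis=0), freqs, source=source)


def compare_profiles(profile_a: PSDProfile, profile_b: PSDProfile,
                     bands: list[tuple[float, float]] | None = None,
                     labels: tuple[str, str] = ("A", "B"),
                     out_png=None) -> dict:
    """Peak positions and band energies of two profiles on one bin grid."""
    if not np.allclose(profile_a.bin_frequencies, profile_b.bin_frequencies):
        raise ValueError("profiles must share one frequency grid")
    bands = bands or [(600.0, 1000.0)]  # first-formant region of /a/
    report = {
        "peak_hz": {labels[0]: profile_a.peak_hz(), labels[1]: profile_b.peak_hz()},
        "peak_separation_hz": abs(profile_a.peak_hz() - profile_b.peak_hz()),
        "band_energy": {},
        "band_energy_ratio": {},
    }
    for lo, hi in bands:
        ea = profile_a.band_energy(lo, hi)
        eb = profile_b.band_energy(lo, hi)
        key = f"{lo:.0f}-{hi:.0f}Hz"
        report["band_energy"][key] = {labels[0]: ea, labels[1]: eb}
        report["band_energy_ratio"][key] = ea / eb if eb > 0 else float("inf")
    if out_png is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for prof, lbl in ((profile_a, labels[0]), (profile_b, labels[1])):
            freqs, power = prof.one_sided()
            ax.semilogy(freqs, power + 1e-20, label=lbl)
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("power spectral density")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out_png, dpi=120)
        plt.close(fig)
    return report
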