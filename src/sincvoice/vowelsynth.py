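"""Synthetic sustained /a/ vowels with disorder-like acoustic signatures.

Source-filter synthesis: a Rosenberg-style glottal pulse train with
per-cycle jitter (period perturbation) and shimmer (amplitude
perturbation) drives a cascade of second-order formant resonators tuned
to /a/ (800, 1200, 2800 Hz by default).  Class presets then shape the
qualitative signatures of the five clinical categories:

* ``Normal`` — low jitter/shimmer, negligible high-frequency noise,
  stationary envelope;
* ``FD`` (functional dysphonia) — elevated jitter/shimmer but a
  stationary envelope;
* ``Neo`` (neoplasm) — strong high-frequency (> 2.5 kHz) noise;
* ``Pho`` (phonotrauma) — intermediate high-frequency noise;
* ``VP`` (vocal palsy) — deep slow amplitude modulation, i.e. a
  nonstationary energy trajectory.

These are qualitative emulations for exercising the classifier end to
end, not perceptually validated simulations of pathology.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.io import wavfile
from scipy.signal import butter, lfilter, sosfilt

__all__ = [
    "SynthParams",
    "LabeledWaveform",
    "CLASS_PRESETS",
    "LABELS",
    "glottal_source",
    "formant_filter",
    "synth_vowel",
    "make_dataset",
    "load_manifest",
    "read_wav",
    "save_presets_yaml",
]

LABELS = ("Normal", "FD", "Neo", "Pho", "VP")

DEFAULT_FORMANTS = ((800.0, 80.0), (1200.0, 90.0), (2800.0, 120.0))


@dataclass
class SynthParams:
    """Knobs of the source-filter vowel generator (units in names)."""

    f0_hz: float = 140.0
    jitter_pct: float = 0.5
    shimmer_pct: float = 2.0
    formants: tuple = DEFAULT_FORMANTS
    hf_noise_db: float = -50.0  # >2.5 kHz noise level rel. voiced RMS
    noise_band_hz: tuple | None = None  # (lo, hi) band-pass; None = high-pass 2.5 kHz
    am_depth: float = 0.0  # slow AM depth in [0, 1]
    am_rate_hz: float = 4.0
    duration_s: float = 3.0
    sample_rate: float = 16000.0

    def __post_init__(self):
        if self.f0_hz <= 0:
            raise ValueError("f0_hz must be positive")
        if self.jitter_pct < 0 or self.shimmer_pct < 0:
            raise ValueError("jitter/shimmer percentages must be >= 0")
        if not 0.0 <= self.am_depth <= 1.0:
            raise ValueError("am_depth must lie in [0, 1]")
        nyq = self.sample_rate / 2.0
        if any(f >= nyq for f, _bw in self.formants):
            raise ValueError("formant centers must be below Nyquist")


@dataclass
class LabeledWaveform:
    samples: np.ndarray
    sample_rate: float
    label: str
    utterance_id: str

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if np.max(np.abs(self.samples), initial=0.0) > 1.0 + 1e-9:
            raise ValueError("samples must lie in [-1, 1]")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate


# Class presets are explicit, inspectable configuration: the clinical
# descriptions are qualitative, so the exact levels are generator choices.
CLASS_PRESETS: dict[str, dict] = {
    "Normal": dict(jitter_pct=0.3, shimmer_pct=1.5, hf_noise_db=-50.0, am_depth=0.0),
    "FD": dict(jitter_pct=3.0, shimmer_pct=8.0, hf_noise_db=-40.0, am_depth=0.0),
    "Neo": dict(jitter_pct=1.5, shimmer_pct=4.0, hf_noise_db=-10.0, am_depth=0.0),
    "Pho": dict(jitter_pct=1.5, shimmer_pct=4.0, hf_noise_db=-22.0, am_depth=0.0),
    "VP": dict(jitter_pct=1.0, shimmer_pct=3.0, hf_noise_db=-40.0,
               am_depth=0.8, am_rate_hz=4.0),
}


def _rosenberg_pulse(n_samples: int, open_quotient: float = 0.6,
                     speed_quotient: float = 2.5) -> np.ndarray:
    """One smooth glottal flow pulse over ``n_samples`` points.

    Rising phase 0..Tp, falling phase Tp..Tp+Tn, closed for the rest of the
    cycle; smooth shape gives a realistic spectral tilt.
    """
    t_open = open_quotient * n_samples
    tp = int(round(t_open * speed_quotient / (1.0 + speed_quotient)))
    tn = max(int(round(t_open)) - tp, 1)
    pulse = np.zeros(n_samples)
    up = np.arange(tp)
    pulse[:tp] = 0.5 * (1.0 - np.cos(np.pi * up / max(tp, 1)))
    down = np.arange(tn)
    seg = np.cos(np.pi * down / (2.0 * tn))
    pulse[tp : tp + tn] = seg[: max(n_samples - tp, 0)]
    return pulse


def glottal_source(params: SynthParams, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Quasi-periodic glottal pulse train with jitter and shimmer.

    Each cycle's period is ``T0 (1 + jitter e)`` and its amplitude
    ``(1 + shimmer e')`` with independent standard-normal draws, so the
    measured coefficient of variation of cycle lengths tracks
    ``jitter_pct``.  Deterministic for a given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sr = params.sample_rate
    n_total = int(round(params.duration_s * sr))
    t0 = sr / params.f0_hz
    out = np.zeros(n_total)
    pos = 0
    while pos < n_total:
        period = t0 * (1.0 + (params.jitter_pct / 100.0) * rng.standard_normal())
        period_n = max(int(round(period)), 8)
        amp = max(1.0 + (params.shimmer_pct / 100.0) * rng.standard_normal(), 0.05)
        pulse = amp * _rosenberg_pulse(period_n)
        end = min(pos + period_n, n_total)
        out[pos:end] = pulse[: end - pos]
        pos += period_n
    return out


def formant_filter(excitation: np.ndarray, formants=DEFAULT_FORMANTS,
                   sample_rate: float = 16000.0) -> np.ndarray:
    """Cascade of second-order resonators (one per formant).

    Each resonator has poles at radius ``exp(-pi B / fs)`` and angle
    ``2 pi F / fs``, normalized to unit gain at its center frequency.
    """
    y = np.asarray(excitation, dtype=float)
    for f_hz, bw_hz in formants:
        if bw_hz <= 0:
            raise ValueError("formant bandwidth must be positive")
        if f_hz >= sample_rate / 2:
            raise ValueError("formant center above Nyquist")
        r = np.exp(-np.pi * bw_hz / sample_rate)
        theta = 2.0 * np.pi * f_hz / sample_rate
        a = [1.0, -2.0 * r * np.cos(theta), r * r]
        # unit gain at the resonance frequency
        w = np.exp(-1j * theta)
        gain = np.abs(1.0 / (1.0 + a[1] * w + a[2] * w**2))
        y = lfilter([1.0 / gain], a, y)
    return y


_sos_cache: dict[tuple, np.ndarray] = {}


def _filtered_noise(n: int, sample_rate: float, rng: np.random.Generator,
                    band_hz: tuple | None = None) -> np.ndarray:
    if band_hz is None:
        key = (round(sample_rate), "hp2500")
        if key not in _sos_cache:
            _sos_cache[key] = butter(4, 2500.0, btype="highpass",
                                     fs=sample_rate, output="sos")
    else:
        key = (round(sample_rate), round(band_hz[0]), round(band_hz[1]))
        if key not in _sos_cache:
            _sos_cache[key] = butter(4, band_hz, btype="bandpass",
                                     fs=sample_rate, output="sos")
    return sosfilt(_sos_cache[key], rng.standard_normal(n))


def synth_vowel(label: str, params: SynthParams | None = None,
                seed: int = 0, **overrides) -> LabeledWaveform:
    """Generate one labeled sustained /a/ vowel for a class preset.

    Pipeline: preset -> glottal source -> formant cascade -> additive
    high-passed noise at ``hf_noise_db`` below the voiced RMS -> slow
    amplitude modulation of depth ``am_depth`` -> peak normalization
    to 0.9 (clip-free by construction).
    """
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}; expected one of {LABELS}")
    base = params if params is not None else SynthParams()
    p = replace(base, **{**CLASS_PRESETS[label], **overrides})
    rng = np.random.default_rng(seed)

    # lip-radiation effect: excite the tract with the flow derivative, which
    # removes the DC of the pulse train and flattens its spectral tilt
    flow = glottal_source(p, rng)
    excitation = np.diff(flow, prepend=flow[0])
    voiced = formant_filter(excitation, p.formants, p.sample_rate)
    n = len(voiced)
    voiced_rms = np.sqrt(np.mean(voiced**2)) + 1e-12
    noise = _filtered_noise(n, p.sample_rate, rng, p.noise_band_hz)
    noise *= voiced_rms * 10.0 ** (p.hf_noise_db / 20.0) / (np.sqrt(np.mean(noise**2)) + 1e-12)
    x = voiced + noise

    if p.am_depth > 0:
        t = np.arange(n) / p.sample_rate
        phase = rng.uniform(0, 2 * np.pi)
        env = 1.0 - p.am_depth * 0.5 * (1.0 + np.sin(2 * np.pi * p.am_rate_hz * t + phase))
        x = x * env

    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.9 * x / peak
    return LabeledWaveform(x, p.sample_rate, label, f"{label.lower()}_{seed:06d}")


def write_wav(path, w: LabeledWaveform) -> None:
    """PCM 16-bit mono WAV."""
    pcm = np.clip(np.round(w.samples * 32767.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), int(w.sample_rate), pcm)


def read_wav(path, label: str = "", utterance_id: str | None = None) -> LabeledWaveform:
    sr, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data.astype(float) / 32768.0
    else:
        samples = np.asarray(data, dtype=float)
    return LabeledWaveform(samples, float(sr), label,
                           utterance_id or Path(path).stem)


def make_dataset(n_per_class: dict[str, int], seed: int = 0,
                 out_dir=None, params: SynthParams | None = None) -> "pd.DataFrame":
    """Generate a labeled vowel corpus and (optionally) write WAVs + manifest.

    Returns the manifest as a DataFrame with columns
    ``utterance_id, path, label``; when ``out_dir`` is None the waveforms
    are kept in memory in the ``waveform`` column and ``path`` is empty.
    Reproducible: utterance seeds derive from ``seed`` deterministically.
    """
    import pandas as pd

    for lbl, cnt in n_per_class.items():
        if lbl not in LABELS:
            raise ValueError(f"unknown label {lbl!r}")
        if cnt < 0:
            raise ValueError("counts must be >= 0")
    rows = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    for lbl in LABELS:  # fixed label order for reproducibility
        cnt = n_per_class.get(lbl, 0)
        child_seeds = ss.spawn(1)[0].generate_state(cnt) if cnt else []
        for i in range(cnt):
            utt_seed = int(child_seeds[i] % (2**31))
            w = synth_vowel(lbl, params=params, seed=utt_seed)
            uid = f"{lbl.lower()}_{i:04d}"
            w.utterance_id = uid
            if out_dir is not None:
                path = out_dir / f"{uid}.wav"
                write_wav(path, w)
                rows.append({"utterance_id": uid, "path": str(path), "label": lbl})
            else:
                rows.append({"utterance_id": uid, "path": "", "label": lbl,
                             "waveform": w})
    cols = ["utterance_id", "path", "label"]
    if out_dir is None:
        cols.append("waveform")
    manifest = pd.DataFrame(rows, columns=cols)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False,
                        columns=["utterance_id", "path", "label"],
                        quoting=csv.QUOTE_MINIMAL)
    return manifest


def load_manifest(path) -> "pd.DataFrame":
    """Read a ``utterance_id,path,label`` manifest and attach waveforms."""
    import pandas as pd

    df = pd.read_csv(path)
    df["waveform"] = [
        read_wav(row.path, label=row.label, utterance_id=row.utterance_id)
        for row in df.itertuples()
    ]
    return df


def save_presets_yaml(path) -> None:
    """Dump the class presets so experiments are config-driven."""
    with open(path, "w") as fh:
        yaml.safe_dump(CLASS_PRESETS, fh, sort_keys=True)
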