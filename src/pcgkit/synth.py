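"""Synthetic newborn phonocardiogram generator with ground-truth annotations.

The generator renders quasi-periodic cardiac cycles at newborn heart rates
(~120-160 bpm).  S1 and S2 are short Gaussian-windowed tones inside the
20-100 Hz analysis band (defaults: S1 40 Hz / 80 ms, S2 65 Hz / 60 ms, the
standard PCG-phantom choice), with systole shorter than diastole.  Murmurs
are band-limited noise bursts placed in the systolic or diastolic interval;
their band is 90-180 Hz, reflecting that turbulent-flow murmurs are
higher-pitched than the valve-closure sounds.  Additive noise is a mixture
of broadband white noise and low-frequency baseline wander at a configured
SNR.  Output is a pure function of the configuration, including its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .audio_io import AudioRecording, write_wav
from .errors import ValidationError

MURMUR_KINDS = (
    "none",
    "innocent_systolic",
    "pathological_systolic",
    "pathological_diastolic",
)

#: Innocent murmurs are rendered quieter (this factor times the configured
#: murmur amplitude) and over only the early half of systole; pathological
#: murmurs use the full configured amplitude over the whole interval.
INNOCENT_AMPLITUDE_FACTOR = 0.4

_MURMUR_BAND_HZ = (90.0, 180.0)
_S2_RELATIVE_AMPLITUDE = 0.7
_FIRST_S1_OFFSET_S = 0.2


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic PCG recording."""

    duration_s: float = 8.0
    sample_rate_hz: float = 4000.0
    heart_rate_bpm: float = 140.0
    systole_fraction: float = 0.4
    s1_center_freq_hz: float = 40.0
    s2_center_freq_hz: float = 65.0
    s1_duration_s: float = 0.08
    s2_duration_s: float = 0.06
    murmur_kind: str = "none"
    murmur_relative_amplitude: float = 0.0
    noise_snr_db: float = 20.0
    hr_jitter_pct: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValidationError("duration_s: must be positive")
        if not 0 < self.systole_fraction < 1:
            raise ValidationError("systole_fraction: must lie in (0, 1)")
        if not self.heart_rate_bpm > 0:
            raise ValidationError("heart_rate_bpm: must be positive")
        fmax = max(self.s1_center_freq_hz, self.s2_center_freq_hz)
        if self.sample_rate_hz < 2 * fmax:
            raise ValidationError(
                "sample_rate_hz: must be at least twice the larger center frequency"
            )
        if self.murmur_kind not in MURMUR_KINDS:
            raise ValidationError(f"murmur_kind: unknown kind {self.murmur_kind!r}")
        if self.murmur_relative_amplitude < 0:
            raise ValidationError("murmur_relative_amplitude: must be >= 0")
        if not self.s1_duration_s > 0 or not self.s2_duration_s > 0:
            raise ValidationError("s1_duration_s/s2_duration_s: must be positive")
        if math.isnan(self.noise_snr_db):
            raise ValidationError("noise_snr_db: must be a number (or +inf for noise-free)")
        if self.hr_jitter_pct < 0:
            raise ValidationError("hr_jitter_pct: must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """True event times and class label of a synthetic recording."""

    s1_times_s: np.ndarray
    s2_times_s: np.ndarray
    label: str
    murmur_kind: str

    def __post_init__(self) -> None:
        s1 = np.asarray(self.s1_times_s, dtype=np.float64)
        s2 = np.asarray(self.s2_times_s, dtype=np.float64)
        object.__setattr__(self, "s1_times_s", s1)
        object.__setattr__(self, "s2_times_s", s2)


def _gaussian_tone(t: np.ndarray, center: float, duration: float, freq: float) -> np.ndarray:
    # +-3 sigma spans the nominal duration; cosine so the energy peak sits
    # exactly at the annotated center.
    sigma = duration / 6.0
    env = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return env * np.cos(2 * np.pi * freq * (t - center))


def _murmur_burst(
    rng: np.random.Generator,
    n_total: int,
    fs: float,
    start_s: float,
    end_s: float,
    amplitude: float,
) -> np.ndarray:
    i0 = max(0, int(round(start_s * fs)))
    i1 = min(n_total, int(round(end_s * fs)))
    if i1 - i0 < 8 or amplitude <= 0:
        return np.zeros(n_total)
    noise = rng.standard_normal(n_total)
    lo, hi = _MURMUR_BAND_HZ
    hi = min(hi, 0.45 * fs)
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    shaped = sosfiltfilt(sos, noise)
    burst = np.zeros(n_total)
    window = np.hanning(i1 - i0)
    seg = shaped[i0:i1] * window
    peak = np.max(np.abs(seg))
    if peak > 0:
        burst[i0:i1] = seg * (amplitude / peak)
    return burst


def generate_recording(config: SynthConfig) -> tuple[AudioRecording, GroundTruth]:
    """Render one synthetic PCG and its ground truth.

    The clean signal (S1/S2 tones plus any murmur) is peak-normalized to 1
    before noise is added, so ``murmur_relative_amplitude`` and the SNR are
    both referenced to the S1 peak.  Identical configurations produce
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate_hz
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs

    base_cycle = 60.0 / config.heart_rate_bpm
    jitter = config.hr_jitter_pct / 100.0

    s1_times: list[float] = []
    s2_times: list[float] = []
    cycle_bounds: list[tuple[float, float, float]] = []  # (s1, s2, next_s1)
    t_cursor = _FIRST_S1_OFFSET_S
    while t_cursor < config.duration_s:
        cycle_len = base_cycle * (1.0 + jitter * rng.uniform(-1.0, 1.0))
        s1 = t_cursor
        s2 = s1 + config.systole_fraction * cycle_len
        s1_times.append(s1)
        if s2 < config.duration_s:
            s2_times.append(s2)
        cycle_bounds.append((s1, s2, s1 + cycle_len))
        t_cursor = s1 + cycle_len

    clean = np.zeros(n)
    for s1 in s1_times:
        clean += _gaussian_tone(t, s1, config.s1_duration_s, config.s1_center_freq_hz)
    for s2 in s2_times:
        clean += _S2_RELATIVE_AMPLITUDE * _gaussian_tone(
            t, s2, config.s2_duration_s, config.s2_center_freq_hz
        )

    if config.murmur_kind != "none" and config.murmur_relative_amplitude > 0:
        for s1, s2, next_s1 in cycle_bounds:
            if config.murmur_kind == "pathological_diastolic":
                start = s2 + config.s2_duration_s / 2
                end = next_s1 - config.s1_duration_s / 2
                amp = config.murmur_relative_amplitude
            else:
                start = s1 + config.s1_duration_s / 2
                end = s2 - config.s2_duration_s / 2
                amp = config.murmur_relative_amplitude
                if config.murmur_kind == "innocent_systolic":
                    end = start + (end - start) / 2
                    amp *= INNOCENT_AMPLITUDE_FACTOR
            clean += _murmur_burst(rng, n, fs, start, end, amp)

    peak = np.max(np.abs(clean))
    if peak > 0:
        clean = clean / peak

    signal = clean
    if np.isfinite(config.noise_snr_db):
        sig_power = float(np.mean(clean**2))
        noise_power = sig_power / 10.0 ** (config.noise_snr_db / 10.0)
        white = rng.standard_normal(n)
        wander = sosfiltfilt(
            butter(2, 10.0, btype="lowpass", fs=fs, output="sos"),
            rng.standard_normal(n),
        )

        def _scaled(x: np.ndarray, power: float) -> np.ndarray:
            p = float(np.mean(x**2))
            return x * math.sqrt(power / p) if p > 0 else x

        signal = clean + _scaled(white, 0.7 * noise_power) + _scaled(wander, 0.3 * noise_power)

    label = "pathological" if config.murmur_kind.startswith("pathological") else "normal"
    recording = AudioRecording(
        samples=signal,
        sample_rate_hz=fs,
        subject_id=f"synth-{config.seed}",
        label=label,
    )
    truth = GroundTruth(
        s1_times_s=np.array(s1_times),
        s2_times_s=np.array(s2_times),
        label=label,
        murmur_kind=config.murmur_kind,
    )
    return recording, truth


def generate_dataset(
    n_normal: int,
    n_pathological: int,
    base_config: SynthConfig = SynthConfig(),
    seed: int = 0,
) -> list[tuple[AudioRecording, GroundTruth]]:
    """Generate a labeled collection of synthetic recordings.

    Per-recording seeds are derived deterministically from ``seed``; the
    heart rate and SNR are mildly randomized around the base configuration
    (+-8% and +-3 dB).  Normal recordings alternate between no murmur and an
    innocent systolic murmur; pathological recordings alternate between
    systolic and diastolic murmurs.
    """
    if n_normal < 0 or n_pathological < 0:
        raise ValidationError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    total = n_normal + n_pathological
    rec_seeds = rng.integers(0, 2**31 - 1, size=total)
    hr_factors = 1.0 + rng.uniform(-0.08, 0.08, size=total)
    snr_offsets = rng.uniform(-3.0, 3.0, size=total)

    kinds = ["none", "innocent_systolic"] * (n_normal // 2 + 1)
    kinds = kinds[:n_normal]
    kinds += (["pathological_systolic", "pathological_diastolic"] * (n_pathological // 2 + 1))[
        :n_pathological
    ]

    out = []
    for i, kind in enumerate(kinds):
        snr = base_config.noise_snr_db
        if np.isfinite(snr):
            snr = snr + float(snr_offsets[i])
        cfg = replace(
            base_config,
            murmur_kind=kind,
            heart_rate_bpm=base_config.heart_rate_bpm * float(hr_factors[i]),
            noise_snr_db=snr,
            seed=int(rec_seeds[i]),
        )
        rec, truth = generate_recording(cfg)
        rec = replace(rec, subject_id=f"synth-{i:04d}")
        out.append((rec, truth))
    return out


def write_dataset(
    dataset: list[tuple[AudioRecording, GroundTruth]], out_dir: str | Path
) -> None:
    """Persist a dataset as WAV files plus ground-truth and label sidecars.

    Each recording ``<id>.wav`` gets an events CSV ``<id>.events.csv``
    (columns ``time_s, event``); ``labels.csv`` maps file to class label.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, truth in dataset:
        name = f"{rec.subject_id}.wav"
        write_wav(rec, out_dir / name)
        events = pd.DataFrame(
            {
                "time_s": np.concatenate([truth.s1_times_s, truth.s2_times_s]),
                "event": ["S1"] * truth.s1_times_s.size + ["S2"] * truth.s2_times_s.size,
            }
        ).sort_values("time_s")
        events.to_csv(out_dir / f"{rec.subject_id}.events.csv", index=False)
        rows.append({"file": name, "label": truth.label})
    pd.DataFrame(rows).to_csv(out_dir / "labels.csv", index=False)
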