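"""Reading, writing and resampling mono PCG audio.

Conventions used throughout the package: 0-based sample indexing, times in
seconds, half-open intervals [onset, offset). Amplitudes are dimensionless
with nominal range [-1, 1]. Stereo input is collapsed to mono by channel
averaging, since a single stethoscope channel is assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import FormatError, ParameterError, ValidationError

#: Default internal analysis rate.  The analysis band is 20-100 Hz, so
#: 44 kHz acquisition-rate audio is decimated on ingestion for speed.
DEFAULT_ANALYSIS_RATE_HZ = 4000

_INT_SCALES = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31}


@dataclass(frozen=True)
class AudioRecording:
    """A uniformly sampled mono pressure signal.

    Parameters
    ----------
    samples : ndarray
        Amplitude series, dimensionless, nominal range [-1, 1].
    sample_rate_hz : float
        Sampling rate in Hz; must be positive.
    subject_id : str
        Opaque identifier for the recording.
    label : str or None
        Optional class label, ``"normal"`` or ``"pathological"``.
    """

    samples: np.ndarray
    sample_rate_hz: float
    subject_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 1:
            raise ValidationError("samples: must be a non-empty 1-D series")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("samples: amplitudes must be finite")
        if not self.sample_rate_hz > 0:
            raise ValidationError("sample_rate_hz: must be positive")
        if self.label is not None and self.label not in ("normal", "pathological"):
            raise ValidationError(f"label: unknown label {self.label!r}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate_hz

    def with_samples(self, samples: np.ndarray) -> "AudioRecording":
        return replace(self, samples=samples)


def read_wav(path: str | Path) -> AudioRecording:
    """Read a WAV file (PCM 16/32-bit, 8-bit unsigned, or IEEE float).

    Samples are scaled to [-1, 1]; stereo is collapsed to mono by channel
    mean; the rate is taken from the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rate, data = wavfile.read(str(path))
    if data.dtype in _INT_SCALES:
        samples = data.astype(np.float64) / _INT_SCALES[data.dtype]
    elif data.dtype == np.dtype("uint8"):
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype.kind == "f":
        samples = data.astype(np.float64)
    else:
        raise FormatError(f"unsupported WAV encoding: {data.dtype}")
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioRecording(samples=samples, sample_rate_hz=float(rate), subject_id=path.stem)


def write_wav(recording: AudioRecording, path: str | Path) -> None:
    """Write a recording as 16-bit PCM WAV.

    Amplitudes outside [-1, 1] are clipped with a warning.  Round-trip
    read-back reproduces the samples within the 16-bit quantization step.
    """
    samples = recording.samples
    if samples.size == 0:
        raise ParameterError("cannot write an empty recording")
    peak = np.max(np.abs(samples))
    if peak > 1.0:
        warnings.warn(
            f"amplitudes up to {peak:.3g} exceed [-1, 1]; clipping", stacklevel=2
        )
        samples = np.clip(samples, -1.0, 1.0)
    quantized = np.round(samples * (2**15 - 1)).astype(np.int16)
    wavfile.write(str(path), int(round(recording.sample_rate_hz)), quantized)


def resample(recording: AudioRecording, target_rate_hz: float) -> AudioRecording:
    """Resample to ``target_rate_hz`` with a polyphase anti-aliasing filter.

    Duration is preserved within one sample period and the new sample count
    is ``round(old_count * ratio)``.  Tones below both Nyquist limits keep
    their amplitude within 1%.
    """
    if not target_rate_hz > 0:
        raise ParameterError("target_rate_hz must be positive")
    if target_rate_hz == recording.sample_rate_hz:
        return recording
    ratio = Fraction(target_rate_hz / recording.sample_rate_hz).limit_denominator(10000)
    out = resample_poly(recording.samples, ratio.numerator, ratio.denominator)
    n_target = int(round(recording.samples.size * target_rate_hz / recording.sample_rate_hz))
    n_target = max(n_target, 1)
    if out.size > n_target:
        out = out[:n_target]
    elif out.size < n_target:
        out = np.pad(out, (0, n_target - out.size))
    return replace(recording, samples=out, sample_rate_hz=float(target_rate_hz))


def read_labels_csv(path: str | Path) -> dict[str, str]:
    """Read a labels sidecar CSV with columns ``file, label``."""
    import pandas as pd

    df = pd.read_csv(path)
    if not {"file", "label"} <= set(df.columns):
        raise FormatError("labels CSV must have columns 'file' and 'label'")
    return dict(zip(df["file"].astype(str), df["label"].astype(str)))
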