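"""S1/S2 segmentation of a denoised PCG.

Peak detection uses the complex Gaussian (Gabor) wavelet

    psi(t) = C * exp(-j*omega*t) * exp(-t**2),

dilated by a scale factor and convolved with the signal; the coefficient
magnitude acts as a band-selective envelope.  Peaks are local maxima of the
max-normalized envelope above a threshold (default 0.1), localized at
zero-crossings of the first difference.  Since systole is shorter than
diastole, the alternating short/long pattern of inter-peak intervals
assigns S1 (opens the short interval) and S2 (closes it); the phase is
chosen by majority vote over intervals so one noisy interval cannot flip
the whole labeling.  Cardiac cycles are then cut from one S1 to the next.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .audio_io import AudioRecording
from .errors import AmbiguityError, SegmentationError, ValidationError

logger = logging.getLogger(__name__)

#: Default peak-detection threshold on max-normalized coefficient magnitudes.
DEFAULT_THRESHOLD = 0.1
#: Default minimum peak separation; shorter than any plausible newborn systole.
DEFAULT_MIN_SEPARATION_S = 0.06
#: Relative spread below which inter-peak intervals are considered
#: non-alternating and labeling is refused.
_AMBIGUITY_TOLERANCE = 0.05


@dataclass(frozen=True)
class GaborWaveletSpec:
    """Complex Gaussian wavelet: carrier ``omega`` (rad per unit of the
    dimensionless argument t/scale), normalizing constant and dilation.

    The wavelet's passband center in Hz is ``omega / (2*pi*scale)``; the
    default (omega=5, scale ~15.9 ms) centers near 50 Hz, the midpoint of
    the 20-100 Hz analysis band.
    """

    omega: float = 5.0
    normalizing_constant: float = 1.0
    scale: float = 5.0 / (2 * math.pi * 50.0)

    def __post_init__(self) -> None:
        if not self.omega > 0:
            raise ValidationError("omega: must be positive")
        if not self.normalizing_constant > 0:
            raise ValidationError("normalizing_constant: must be positive")
        if not self.scale > 0:
            raise ValidationError("scale: must be positive")

    @classmethod
    def from_center_frequency(cls, center_freq_hz: float, omega: float = 5.0) -> "GaborWaveletSpec":
        """Choose the dilation so the passband centers at ``center_freq_hz``."""
        return cls(omega=omega, scale=omega / (2 * math.pi * center_freq_hz))

    @property
    def center_frequency_hz(self) -> float:
        return self.omega / (2 * math.pi * self.scale)

    def evaluate(self, t: np.ndarray | float) -> np.ndarray:
        """The mother wavelet C * exp(-j*omega*u) * exp(-u^2) at u = t/scale."""
        u = np.asarray(t, dtype=np.float64) / self.scale
        return self.normalizing_constant * np.exp(-1j * self.omega * u) * np.exp(-(u**2))


@dataclass(frozen=True)
class WaveletPeak:
    time_s: float
    magnitude: float


@dataclass(frozen=True)
class HeartSoundEvent:
    time_s: float
    kind: str  # "S1" or "S2"


@dataclass(frozen=True)
class CardiacCycle:
    """One S1-to-S1 span of the signal with its internal S2 landmark."""

    samples: np.ndarray
    sample_rate_hz: float
    start_s: float
    end_s: float
    s2_offset_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def systole(self) -> tuple[float, float]:
        """Half-open [S1, S2) interval, in absolute seconds."""
        return (self.start_s, self.start_s + self.s2_offset_s)

    @property
    def diastole(self) -> tuple[float, float]:
        """Half-open [S2, next S1) interval, in absolute seconds."""
        return (self.start_s + self.s2_offset_s, self.end_s)


def gabor_wavelet_transform(
    recording: AudioRecording, spec: GaborWaveletSpec = GaborWaveletSpec()
) -> np.ndarray:
    """Magnitude of the signal's convolution with the dilated wavelet.

    Returns a series time-aligned with the input (same length), normalized
    to max 1.  A zero signal yields all zeros (no normalization) and a
    logged warning.
    """
    if recording.samples.size == 0:
        raise ValidationError("empty recording")
    fs = recording.sample_rate_hz
    half = int(math.ceil(4.0 * spec.scale * fs))
    tk = np.arange(-half, half + 1) / fs
    kernel = np.conj(spec.evaluate(tk))[::-1]  # correlation with the wavelet
    coeff = fftconvolve(recording.samples, kernel, mode="same")
    mag = np.abs(coeff)
    peak = mag.max()
    if peak == 0:
        logger.warning("gabor_wavelet_transform: zero signal, returning zeros")
        return mag
    return mag / peak


def detect_peaks(
    coefficients: np.ndarray,
    sample_rate_hz: float,
    threshold: float = DEFAULT_THRESHOLD,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
) -> list[WaveletPeak]:
    """Local maxima of a normalized envelope above ``threshold``.

    Maxima are localized at zero-crossings of the first difference; peaks
    closer than ``min_separation_s`` are merged keeping the larger.
    """
    c = np.asarray(coefficients, dtype=np.float64)
    if c.size < 3:
        return []
    d = np.diff(c)
    # zero-crossing of the first difference: rising before, non-rising after
    idx = np.nonzero((d[:-1] > 0) & (d[1:] <= 0))[0] + 1
    idx = idx[c[idx] >= threshold]
    if idx.size == 0:
        return []
    # non-maximum suppression by magnitude, deterministic (ties: earlier wins)
    order = np.lexsort((idx, -c[idx]))
    min_sep = int(round(min_separation_s * sample_rate_hz))
    kept: list[int] = []
    for k in order:
        i = idx[k]
        if all(abs(i - j) >= min_sep for j in kept):
            kept.append(i)
    kept.sort()
    return [WaveletPeak(time_s=i / sample_rate_hz, magnitude=float(c[i])) for i in kept]


def label_events(peaks: list[WaveletPeak]) -> list[HeartSoundEvent]:
    """Assign S1/S2 by the alternating short/long interval rule.

    The peak opening each short (systolic) interval is S1 and the peak
    closing it is S2.  The phase (whether the first interval is systolic)
    is decided by majority vote: the alternation with the smaller mean
    "short" interval wins.  Intervals that do not alternate — all equal
    within 5% — raise :class:`AmbiguityError`.
    """
    if len(peaks) < 3:
        raise SegmentationError(f"need at least 3 peaks, got {len(peaks)}")
    times = np.array([p.time_s for p in peaks])
    if np.any(np.diff(times) <= 0):
        raise SegmentationError("peak times must be strictly increasing")
    intervals = np.diff(times)
    even = intervals[0::2]
    odd = intervals[1::2]
    mean_even, mean_odd = float(even.mean()), float(odd.mean())
    if abs(mean_even - mean_odd) / float(intervals.mean()) < _AMBIGUITY_TOLERANCE:
        raise AmbiguityError(
            "inter-peak intervals do not alternate; cannot assign systole/diastole"
        )
    # if even-position intervals are the short ones, peak 0 opens a systole -> S1
    first_is_s1 = mean_even < mean_odd
    events = []
    for i, p in enumerate(peaks):
        s1 = (i % 2 == 0) == first_is_s1
        events.append(HeartSoundEvent(time_s=p.time_s, kind="S1" if s1 else "S2"))
    return events


def extract_cycles(
    recording: AudioRecording, events: list[HeartSoundEvent]
) -> list[CardiacCycle]:
    """Cut S1-to-S1 cardiac cycles from labeled events.

    A leading S2 and any trailing partial cycle are dropped.  Cycles whose
    systole is not shorter than their diastole (a labeling artifact on
    noisy spans) are skipped with a warning.
    """
    evs = list(events)
    while evs and evs[0].kind != "S1":
        evs.pop(0)
    fs = recording.sample_rate_hz
    cycles: list[CardiacCycle] = []
    i = 0
    while i + 2 < len(evs):
        a, b, c = evs[i], evs[i + 1], evs[i + 2]
        if not (a.kind == "S1" and b.kind == "S2" and c.kind == "S1"):
            i += 1
            continue
        s2_offset = b.time_s - a.time_s
        duration = c.time_s - a.time_s
        if not 0 < s2_offset < duration:
            i += 2
            continue
        if s2_offset >= duration - s2_offset:
            logger.warning(
                "cycle at %.3f s has systole >= diastole; skipping", a.time_s
            )
            i += 2
            continue
        i0, i1 = int(round(a.time_s * fs)), int(round(c.time_s * fs))
        cycles.append(
            CardiacCycle(
                samples=recording.samples[i0:i1].copy(),
                sample_rate_hz=fs,
                start_s=a.time_s,
                end_s=c.time_s,
                s2_offset_s=s2_offset,
            )
        )
        i += 2
    if not cycles:
        logger.warning("no complete S1-to-S1 cycle found")
    return cycles


def segment_recording(
    recording: AudioRecording,
    spec: GaborWaveletSpec = GaborWaveletSpec(),
    threshold: float = DEFAULT_THRESHOLD,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
) -> tuple[list[HeartSoundEvent], list[CardiacCycle]]:
    """Full segmentation chain: wavelet envelope -> peaks -> labels -> cycles."""
    coeff = gabor_wavelet_transform(recording, spec)
    peaks = detect_peaks(coeff, recording.sample_rate_hz, threshold, min_separation_s)
    events = label_events(peaks)
    cycles = extract_cycles(recording, events)
    return events, cycles
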