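"""De-noising of PCG recordings.

The denoising step is a 3rd-order Butterworth band-pass with 20 and 100 Hz
cutoffs, retaining the main spectral components of S1 and S2.  Filtering is
applied forward-backward (zero-phase) so that event times are not shifted
before segmentation; a single-pass Butterworth would delay the envelope.
A short-time spectrogram is provided for visual QC of the band content, and
peak-amplitude normalization makes the downstream wavelet detection
threshold scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .audio_io import AudioRecording
from .errors import ParameterError, ValidationError


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification (order, cutoffs in Hz)."""

    order: int = 3
    low_cutoff_hz: float = 20.0
    high_cutoff_hz: float = 100.0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValidationError("order: must be >= 1")
        if not 0 < self.low_cutoff_hz < self.high_cutoff_hz:
            raise ValidationError("cutoffs: need 0 < low < high")

    def design_sos(self, sample_rate_hz: float) -> np.ndarray:
        if self.high_cutoff_hz >= sample_rate_hz / 2:
            raise ParameterError(
                f"high_cutoff_hz={self.high_cutoff_hz} must be below the "
                f"Nyquist frequency {sample_rate_hz / 2}"
            )
        return signal.butter(
            self.order,
            [self.low_cutoff_hz, self.high_cutoff_hz],
            btype="bandpass",
            fs=sample_rate_hz,
            output="sos",
        )

    def magnitude_response_db(
        self, freqs_hz: np.ndarray, sample_rate_hz: float
    ) -> np.ndarray:
        """Single-pass magnitude response in dB at the given frequencies."""
        sos = self.design_sos(sample_rate_hz)
        _, h = signal.sosfreqz(sos, worN=np.atleast_1d(freqs_hz), fs=sample_rate_hz)
        return 20.0 * np.log10(np.maximum(np.abs(h), 1e-300))


@dataclass(frozen=True)
class Spectrogram:
    times_s: np.ndarray
    freqs_hz: np.ndarray
    power: np.ndarray  # time x frequency, nonnegative


def bandpass_filter(recording: AudioRecording, spec: FilterSpec = FilterSpec()) -> AudioRecording:
    """Zero-phase Butterworth band-pass; output has the input's length."""
    sos = spec.design_sos(recording.sample_rate_hz)
    filtered = signal.sosfiltfilt(sos, recording.samples)
    return recording.with_samples(filtered)


def compute_spectrogram(
    recording: AudioRecording,
    window_s: float = 0.5,
    overlap_fraction: float = 0.5,
) -> Spectrogram:
    """Short-time power spectrum (Hann window) for band-content QC."""
    nperseg = int(round(window_s * recording.sample_rate_hz))
    if nperseg > recording.samples.size:
        raise ParameterError("window_s is longer than the recording")
    if not 0 <= overlap_fraction < 1:
        raise ParameterError("overlap_fraction must lie in [0, 1)")
    freqs, times, sxx = signal.spectrogram(
        recording.samples,
        fs=recording.sample_rate_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=int(nperseg * overlap_fraction),
        scaling="density",
        mode="psd",
    )
    return Spectrogram(times_s=times, freqs_hz=freqs, power=sxx.T)


def normalize_amplitude(recording: AudioRecording) -> AudioRecording:
    """Scale so that max |amplitude| = 1 (sign-preserving)."""
    peak = np.max(np.abs(recording.samples))
    if peak == 0:
        raise ParameterError("cannot normalize an all-zero signal")
    return recording.with_samples(recording.samples / peak)


def denoise(recording: AudioRecording, spec: FilterSpec = FilterSpec()) -> AudioRecording:
    """Band-pass filter then peak-normalize — the standard pre-segmentation chain."""
    return normalize_amplitude(bandpass_filter(recording, spec))
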