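"""Per-cycle feature extraction for murmur classification.

Six feature families are computed on each representative cardiac cycle:
maximum amplitude, sum of positive area, variance, Shannon energy, and two
higher-order spectral transforms — the bispectrum and a third-order
(Wigner) time-frequency distribution.  Each polyspectrum is reduced to
four summary scalars (mean magnitude, max magnitude, normalized entropy,
log-magnitude sum), giving a 12-dimensional vector.  Per-recording vectors
are the coverage-weighted average over the representative cycles chosen by
the DTW selection step.

The bispectrum uses the direct FFT estimator: segments are Hann-windowed,
Fourier-transformed and averaged as B(f1, f2) = <X(f1) X(f2) X*(f1+f2)>.
Quadratic phase coupling between f1, f2 and f1+f2 survives the averaging;
independent phases cancel.  The third-order Wigner distribution is
evaluated on its diagonal frequency slice with a sliding Hann lag window
(a pseudo form, for stability), on the analytic signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .cycle_selection import CycleSelection
from .errors import ParameterError
from .segmentation import CardiacCycle

FEATURE_NAMES = (
    "max_amplitude",
    "sum_positive_area",
    "variance",
    "shannon_energy",
    "bis_mean",
    "bis_max",
    "bis_entropy",
    "bis_logsum",
    "wig_mean",
    "wig_max",
    "wig_entropy",
    "wig_logsum",
)


@dataclass(frozen=True)
class FeatureVector:
    """The fixed 12-dimensional per-recording descriptor."""

    max_amplitude: float
    sum_positive_area: float
    variance: float
    shannon_energy: float
    bispectrum_features: tuple[float, float, float, float]
    wigner_bispectrum_features: tuple[float, float, float, float]

    def to_array(self) -> np.ndarray:
        return np.array(
            [
                self.max_amplitude,
                self.sum_positive_area,
                self.variance,
                self.shannon_energy,
                *self.bispectrum_features,
                *self.wigner_bispectrum_features,
            ]
        )

    @classmethod
    def from_array(cls, v: np.ndarray) -> "FeatureVector":
        v = np.asarray(v, dtype=np.float64)
        if v.shape != (len(FEATURE_NAMES),):
            raise ParameterError(f"expected {len(FEATURE_NAMES)} features, got {v.shape}")
        return cls(
            max_amplitude=float(v[0]),
            sum_positive_area=float(v[1]),
            variance=float(v[2]),
            shannon_energy=float(v[3]),
            bispectrum_features=tuple(float(x) for x in v[4:8]),
            wigner_bispectrum_features=tuple(float(x) for x in v[8:12]),
        )


def _samples(cycle: CardiacCycle | np.ndarray) -> np.ndarray:
    x = cycle.samples if isinstance(cycle, CardiacCycle) else np.asarray(cycle, dtype=np.float64)
    return np.asarray(x, dtype=np.float64)


def time_domain_features(cycle: CardiacCycle | np.ndarray) -> tuple[float, float, float]:
    """(max |amplitude|, sum of positive samples, population variance)."""
    x = _samples(cycle)
    if x.size == 0:
        raise ParameterError("empty cycle")
    return (
        float(np.max(np.abs(x))),
        float(x[x > 0].sum()),
        float(np.var(x)),
    )


def shannon_energy(cycle: CardiacCycle | np.ndarray) -> float:
    """SE = -(1/N) sum x_i^2 ln(x_i^2), with 0*ln(0) := 0.

    For amplitudes in [-1, 1] the result is nonnegative and emphasizes
    medium-intensity components over both the loudest and the quietest.
    """
    x = _samples(cycle)
    if x.size == 0:
        return 0.0
    x2 = x**2
    terms = np.where(x2 > 0, -x2 * np.log(x2, where=x2 > 0, out=np.zeros_like(x2)), 0.0)
    return float(terms.mean())


def bispectrum(
    cycle: CardiacCycle | np.ndarray,
    segment_length: int = 256,
    overlap_fraction: float = 0.5,
) -> np.ndarray:
    """Direct (segment-averaged FFT) bispectrum estimate.

    Returns the complex matrix B[f1, f2] on the grid 0..segment_length//2
    in both axes; B is symmetric in (f1, f2) by construction.  Segments
    are mean-removed and Hann-windowed.
    """
    x = _samples(cycle)
    if x.size < segment_length:
        raise ParameterError(
            f"cycle of {x.size} samples shorter than segment_length={segment_length}"
        )
    if not 0 <= overlap_fraction < 1:
        raise ParameterError("overlap_fraction must lie in [0, 1)")
    hop = max(1, int(round(segment_length * (1 - overlap_fraction))))
    window = np.hanning(segment_length)
    k = segment_length // 2 + 1
    idx = np.add.outer(np.arange(k), np.arange(k)) % segment_length
    acc = np.zeros((k, k), dtype=np.complex128)
    n_seg = 0
    for start in range(0, x.size - segment_length + 1, hop):
        seg = x[start : start + segment_length]
        seg = (seg - seg.mean()) * window
        spec = np.fft.fft(seg)
        xf = spec[:k]
        acc += np.multiply.outer(xf, xf) * np.conj(spec[idx])
        n_seg += 1
    return acc / n_seg


def wigner_bispectrum(
    cycle: CardiacCycle | np.ndarray,
    sample_rate_hz: float | None = None,
    n_lags: int = 128,
    hop: int = 16,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Diagonal slice of the third-order Wigner distribution.

    For the analytic signal z, the lag kernel k(t, tau) = z(t+tau)^2 *
    conj(z(t-2*tau)) is Hann-windowed over tau and Fourier-transformed,
    which for a tone at f0 concentrates at 4*f0; the frequency axis is
    rescaled accordingly so a tone appears at its own frequency.  Returns
    (times_s, freqs_hz, magnitude map of shape time x frequency).  Time
    shifts of the signal shift the map along the time axis.
    """
    x = _samples(cycle)
    if x.size == 0:
        return np.array([]), np.array([]), np.zeros((0, 0))
    if sample_rate_hz is None:
        sample_rate_hz = cycle.sample_rate_hz if isinstance(cycle, CardiacCycle) else 1.0
    if np.all(x == 0):
        z = np.zeros(x.size, dtype=np.complex128)
    else:
        z = hilbert(x)
    half = n_lags // 2
    # zero-pad so t+tau and t-2*tau always index inside the buffer
    pad = 2 * n_lags
    zp = np.concatenate([np.zeros(pad, np.complex128), z, np.zeros(pad, np.complex128)])
    taus = np.arange(-half, half)
    window = np.hanning(n_lags)
    frames = np.arange(0, x.size, hop)
    kernel = np.empty((frames.size, n_lags), dtype=np.complex128)
    for r, t0 in enumerate(frames):
        tc = t0 + pad
        kernel[r] = zp[tc + taus] ** 2 * np.conj(zp[tc - 2 * taus]) * window
    spec = np.fft.fft(np.fft.ifftshift(kernel, axes=1), axis=1)
    mag = np.abs(spec[:, :half])  # keep nonnegative-frequency half
    freqs = np.arange(half) * sample_rate_hz / n_lags / 4.0
    times = frames / sample_rate_hz
    return times, freqs, mag


def summarize_polyspectrum(values: np.ndarray) -> tuple[float, float, float, float]:
    """(mean |.|, max |.|, normalized entropy, sum log(1+|.|)) of a spectrum.

    The entropy is -sum p_i ln p_i / ln K with p_i = |.|_i / sum |.|; an
    all-zero input yields (0, 0, 0, 0) and a single non-zero bin yields
    entropy 0.
    """
    v = np.abs(np.asarray(values)).ravel()
    if v.size == 0 or not np.all(np.isfinite(v)):
        raise ParameterError("polyspectrum summary requires finite input")
    total = v.sum()
    if total == 0:
        return (0.0, 0.0, 0.0, 0.0)
    p = v / total
    with np.errstate(divide="ignore", invalid="ignore"):
        h = float(-np.sum(np.where(p > 0, p * np.log(p, where=p > 0, out=np.zeros_like(p)), 0.0)))
    norm = np.log(v.size) if v.size > 1 else 1.0
    return (
        float(v.mean()),
        float(v.max()),
        h / norm,
        float(np.log1p(v).sum()),
    )


def cycle_features(
    cycle: CardiacCycle | np.ndarray,
    sample_rate_hz: float | None = None,
    segment_length: int = 256,
    overlap_fraction: float = 0.5,
) -> FeatureVector:
    """All six feature families for a single cycle."""
    max_amp, pos_area, var = time_domain_features(cycle)
    se = shannon_energy(cycle)
    x = _samples(cycle)
    seg_len = min(segment_length, x.size)
    bis = bispectrum(cycle, segment_length=seg_len, overlap_fraction=overlap_fraction)
    _, _, wig = wigner_bispectrum(cycle, sample_rate_hz=sample_rate_hz)
    return FeatureVector(
        max_amplitude=max_amp,
        sum_positive_area=pos_area,
        variance=var,
        shannon_energy=se,
        bispectrum_features=summarize_polyspectrum(bis),
        wigner_bispectrum_features=summarize_polyspectrum(wig),
    )


def extract_features(
    recording,
    selection: CycleSelection,
    cycles: list[CardiacCycle],
    segment_length: int = 256,
    overlap_fraction: float = 0.5,
) -> FeatureVector:
    """Coverage-weighted average of representative-cycle features.

    Weights are the number of cycles each representative covers, so the
    result is invariant to permutations of the cycle order.
    """
    if not selection.representative_indices:
        raise ParameterError("empty selection")
    counts: dict[int, int] = {}
    for rep in selection.assignment.values():
        counts[rep] = counts.get(rep, 0) + 1
    total = sum(counts.values())
    acc = np.zeros(len(FEATURE_NAMES))
    for rep in selection.representative_indices:
        fv = cycle_features(
            cycles[rep],
            segment_length=segment_length,
            overlap_fraction=overlap_fraction,
        )
        acc += fv.to_array() * (counts.get(rep, 0) / total)
    return FeatureVector.from_array(acc)
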