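import math
from dataclasses import replace

import numpy as np
import pytest

from pcgkit import (
    FEATURE_NAMES,
    ParameterError,
    SynthConfig,
    bandpass_filter,
    bispectrum,
    extract_features,
    generate_recording,
    select_representatives,
    shannon_energy,
    summarize_polyspectrum,
    time_domain_features,
    wigner_bispectrum,
)
from pcgkit.features import cycle_features

FS = 4000.0


class TestTimeDomainFeatures:
    def test_constant_series(self):
        m, pa, v = time_domain_features(np.full(4, 0.5))
        assert (m, pa, v) == (0.5, 2.0, 0.0)

    def test_plus_minus_one(self):
        m, pa, v = time_domain_features(np.array([-1.0, 1.0]))
        assert (m, pa, v) == (1.0, 1.0, 1.0)

    def test_negation_symmetry(self):
        x = np.random.default_rng(0).normal(size=50)
        m1, _, v1 = time_domain_features(x)
        m2, _, v2 = time_domain_features(-x)
        assert m1 == m2 and v1 == pytest.approx(v2)

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            time_domain_features(np.array([]))

    def test_scaling_linear_and_quadratic(self):
        x = np.random.default_rng(1).normal(size=100)
        m1, _, v1 = time_domain_features(x)
        m2, _, v2 = time_domain_features(3.0 * x)
        assert m2 == pytest.approx(3.0 * m1, rel=1e-6)
        assert v2 == pytest.approx(9.0 * v1, rel=1e-6)


class TestShannonEnergy:
    def test_zero_signal(self):
        assert shannon_energy(np.zeros(10)) == 0.0

    def test_unit_amplitudes(self):
        assert shannon_energy(np.array([1.0, -1.0, 1.0])) == pytest.approx(0.0)

    def test_exp_minus_half(self):
        x = np.full(8, math.exp(-0.5))
        assert shannon_energy(x) == pytest.approx(math.exp(-1.0))

    def test_nonnegative_on_unit_range(self):
        x = np.random.default_rng(2).uniform(-1, 1, size=500)
        assert shannon_energy(x) >= 0.0


class TestBispectrum:
    def test_zero_signal(self):
        assert np.all(bispectrum(np.zeros(1024), 256) == 0)

    def test_symmetry_in_f1_f2(self):
        x = np.random.default_rng(3).normal(size=2048)
        b = bispectrum(x, 256)
        assert np.allclose(b, b.T, rtol=1e-10, atol=1e-12)

    def test_phase_coupled_triad_peak(self):
        fs, seg, nseg = 256, 256, 256
        n = seg * nseg
        t = np.arange(n) / fs
        coupled = (
            np.cos(2 * np.pi * 30 * t) + np.cos(2 * np.pi * 40 * t) + np.cos(2 * np.pi * 70 * t)
        )
        bc = np.abs(bispectrum(coupled, seg, 0.0))
        assert bc[30, 40] >= 10 * np.median(bc)
        # per-segment random phase on the third tone destroys the coupling
        rng = np.random.default_rng(7)
        x = np.cos(2 * np.pi * 30 * t) + np.cos(2 * np.pi * 40 * t)
        third = np.concatenate(
            [
                np.cos(2 * np.pi * 70 * t[i * seg : (i + 1) * seg] + p)
                for i, p in enumerate(rng.uniform(0, 2 * np.pi, nseg))
            ]
        )
        bu = np.abs(bispectrum(x + third, seg, 0.0))
        assert bu[30, 40] < bc[30, 40] / 10

    def test_cubic_amplitude_scaling(self):
        x = np.random.default_rng(4).normal(size=1024)
        b1 = np.abs(bispectrum(x, 256))
        b2 = np.abs(bispectrum(2.0 * x, 256))
        assert np.allclose(b2, 8.0 * b1, rtol=1e-6, atol=1e-12)

    def test_short_cycle_rejected(self):
        with pytest.raises(ParameterError):
            bispectrum(np.zeros(100), 256)


class TestWignerBispectrum:
    def test_zero_signal_zero_map(self):
        _, _, w = wigner_bispectrum(np.zeros(512), 1000.0)
        assert np.all(w == 0)

    def test_shift_covariance(self):
        fs, hop = 1000.0, 16
        t = np.arange(1024) / fs
        sig = np.exp(-0.5 * ((t - 0.35) / 0.02) ** 2) * np.cos(2 * np.pi * 60 * (t - 0.35))
        shifted = np.roll(sig, 4 * hop)
        _, _, w1 = wigner_bispectrum(sig, fs, hop=hop)
        _, _, w2 = wigner_bispectrum(shifted, fs, hop=hop)
        err = np.max(np.abs(w2[4:34] - w1[:30])) / w1.max()
        assert err < 1e-6

    def test_chirp_ridge_increases(self):
        fs = 1000.0
        t = np.arange(1024) / fs
        sig = np.cos(2 * np.pi * (30 * t + 15 * t**2))  # 30 -> ~60 Hz
        _, freqs, w = wigner_bispectrum(sig, fs, hop=16)
        ridge = freqs[np.argmax(w, axis=1)][5:-5]
        assert np.all(np.diff(ridge) >= 0)
        assert ridge[-1] > ridge[0]


class TestSummarizePolyspectrum:
    def test_all_zero(self):
        assert summarize_polyspectrum(np.zeros((4, 4))) == (0.0, 0.0, 0.0, 0.0)

    def test_single_nonzero_entry_entropy_zero(self):
        m = np.zeros(16)
        m[3] = 2.0
        mean, mx, h, ls = summarize_polyspectrum(m)
        assert h == 0.0 and mx == 2.0 and mean == pytest.approx(0.125)

    def test_uniform_entropy_one(self):
        _, _, h, _ = summarize_polyspectrum(np.full(32, 0.7))
        assert h == pytest.approx(1.0)


class TestExtractFeatures:
    def test_single_representative_equals_cycle_features(self, segmented):
        rec, _, _, cycles = segmented
        sel = select_representatives(cycles[:1])
        fv = extract_features(rec, sel, cycles[:1])
        direct = cycle_features(cycles[0])
        assert np.allclose(fv.to_array(), direct.to_array())

    def test_weighted_mean_arithmetic(self, segmented):
        from pcgkit.cycle_selection import CycleSelection

        rec, _, _, cycles = segmented
        sel = CycleSelection(
            representative_indices=[0, 1],
            assignment={0: 0, 1: 1, 2: 0, 3: 0},
            distances={0: 0.0, 1: 0.0, 2: 0.001, 3: 0.001},
            coverage_threshold=0.005,
            max_assigned_distance=0.001,
        )
        fv = extract_features(rec, sel, cycles)
        a = cycle_features(cycles[0]).to_array()
        b = cycle_features(cycles[1]).to_array()
        assert np.allclose(fv.to_array(), (3 * a + b) / 4)

    def test_permutation_invariance(self, segmented):
        rec, _, _, cycles = segmented
        perm = list(reversed(range(len(cycles))))
        sel_a = select_representatives(cycles, threshold=0.005)
        sel_b = select_representatives([cycles[i] for i in perm], threshold=0.005)
        fa = extract_features(rec, sel_a, cycles)
        fb = extract_features(rec, sel_b, [cycles[i] for i in perm])
        assert np.allclose(fa.to_array(), fb.to_array(), rtol=1e-9)

    def test_dimensionality_and_finiteness_on_simulator(self):
        from pcgkit.pipeline import PipelineConfig, process_recording

        cfg = PipelineConfig()
        for seed in (21, 22, 23):
            rec, _ = generate_recording(replace(SynthConfig(), seed=seed, murmur_kind="pathological_systolic", murmur_relative_amplitude=0.5))
            _, _, _, fv = process_recording(rec, cfg)
            v = fv.to_array()
            assert v.shape == (len(FEATURE_NAMES),)
            assert np.all(np.isfinite(v))


class TestClassEffectSize:
    def test_systolic_shannon_energy_separates_classes(self):
        """Cohen's |d| > 1 between murmur-free and murmur-bearing recordings
        on the Shannon energy of filtered systolic intervals."""
        base = SynthConfig(noise_snr_db=20.0, murmur_relative_amplitude=0.5)
        groups = {"none": [], "pathological_systolic": []}
        for kind, vals in groups.items():
            for i in range(15):
                cfg = replace(base, murmur_kind=kind, seed=4000 + i)
                rec, truth = generate_recording(cfg)
                filt = bandpass_filter(rec)
                fs = rec.sample_rate_hz
                ses = []
                for s1, s2 in zip(truth.s1_times_s, truth.s2_times_s):
                    i0 = int((s1 + cfg.s1_duration_s / 2) * fs)
                    i1 = int((s2 - cfg.s2_duration_s / 2) * fs)
                    if i1 > i0:
                        ses.append(shannon_energy(filt.samples[i0:i1]))
                vals.append(float(np.mean(ses)))
        a = np.array(groups["none"])
        b = np.array(groups["pathological_systolic"])
        pooled = math.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        d = abs(a.mean() - b.mean()) / pooled
        assert d > 1.0
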