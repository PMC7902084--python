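"""Simulator: geometry, particle model, photon statistics, dataset assembly."""

import numpy as np
import pytest

from gmlsort.errors import ConfigError, DataError
from gmlsort.preprocess import annulus_mask, nphsh_of
from gmlsort.simulate import (
    SimulationConfig,
    add_background,
    compute_alpha,
    generate_dataset,
    make_qgrid,
    multiple_particle_intensity,
    sample_particle_count,
    single_particle_intensity,
)


class TestQGrid:
    def test_corner_and_center_q(self):
        qg = make_qgrid(128, 128, 0.11, gap_rows=4, particle_diameter=70.0)
        assert qg.q[0, 0] == pytest.approx(0.11)
        assert qg.q[-1, -1] == pytest.approx(0.11)
        assert qg.q.max() == pytest.approx(0.11)
        # center falls between the four central pixels
        assert qg.q[63:65, 63:65].max() < 2 * qg.dq

    def test_radial_monotonicity_along_axes(self):
        qg = make_qgrid(64, 64, 0.11, gap_rows=0, particle_diameter=70.0)
        row = qg.q[32, 32:]
        assert np.all(np.diff(row) > 0)

    def test_shannon_side_definition(self):
        qg = make_qgrid(128, 128, 0.11, gap_rows=4, particle_diameter=70.0)
        assert qg.shannon_side == pytest.approx(1.0 / 140.0)
        assert qg.shannon_side > qg.dq  # Shannon pixels span several detector pixels

    def test_gap_rows_contiguous_and_horizontal(self):
        qg = make_qgrid(64, 64, 0.11, gap_rows=4, particle_diameter=70.0)
        bad_rows = np.flatnonzero(~qg.gap_mask.all(axis=1))
        assert len(bad_rows) == 4
        assert np.all(np.diff(bad_rows) == 1)
        assert not qg.gap_mask[bad_rows].any()

    def test_zero_gap_all_usable(self):
        qg = make_qgrid(64, 64, 0.11, gap_rows=0, particle_diameter=70.0)
        assert qg.gap_mask.all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_rows=8),
            dict(q_corner=0.0),
            dict(q_corner=-1.0),
            dict(particle_diameter=0.0),
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        base = dict(n_rows=64, n_cols=64, q_corner=0.11, gap_rows=0, particle_diameter=70.0)
        base.update(kwargs)
        with pytest.raises(ConfigError):
            make_qgrid(**base)


class TestSingleParticle:
    def test_forward_scattering_maximum(self, qgrid_nogap, rng):
        frame = single_particle_intensity(qgrid_nogap, rng, size_jitter=0.0, modulation=False)
        assert frame.ravel().argmax() in np.flatnonzero(
            qgrid_nogap.q.ravel() == qgrid_nogap.q.min()
        )
        assert (frame >= 0).all()

    def test_deterministic_given_rng_state(self, qgrid):
        a = single_particle_intensity(qgrid, np.random.default_rng(5), size_jitter=0.0)
        b = single_particle_intensity(qgrid, np.random.default_rng(5), size_jitter=0.0)
        np.testing.assert_array_equal(a, b)

    def test_first_ring_zero_matches_form_factor_root(self):
        # independent oracle: brute-force sign change of the radial
        # amplitude 3(sin x - x cos x)/x^3 with x = 2 pi q R
        R = 35.0
        q_fine = np.linspace(1e-5, 0.05, 200001)
        x = 2 * np.pi * q_fine * R
        amp = 3 * (np.sin(x) - x * np.cos(x)) / x**3
        sign_change = np.flatnonzero(np.diff(np.sign(amp)))[0]
        q_zero_oracle = q_fine[sign_change]
        # the model's radial profile must dip at that q
        qg = make_qgrid(256, 256, 0.05, gap_rows=0, particle_diameter=70.0)
        frame = single_particle_intensity(qg, np.random.default_rng(0), size_jitter=0.0, modulation=False)
        near = np.abs(qg.q - q_zero_oracle) < qg.dq
        far = np.abs(qg.q - 0.8 * q_zero_oracle) < qg.dq
        assert frame[near].mean() < 1e-3 * frame[far].mean()
        # and the root itself sits at x ~ 4.4934 in q = 1/d units
        assert q_zero_oracle == pytest.approx(4.4934 / (2 * np.pi * R), rel=1e-3)


class TestParticleCounts:
    def test_conditional_poisson_fraction(self):
        rng = np.random.default_rng(0)
        n = 10000
        counts = np.array([sample_particle_count(1.0, rng) for _ in range(n)])
        assert counts.min() >= 1
        p_single = np.exp(-1) / (1 - np.exp(-1))  # ~0.582
        frac = (counts == 1).mean()
        se = np.sqrt(p_single * (1 - p_single) / n)
        assert abs(frac - p_single) < 3 * se

    def test_small_lambda_limit_all_singles(self):
        rng = np.random.default_rng(0)
        counts = [sample_particle_count(1e-4, rng) for _ in range(200)]
        assert all(c == 1 for c in counts)

    def test_invalid_lambda(self, rng):
        with pytest.raises(ConfigError):
            sample_particle_count(0.0, rng)


class TestMultipleParticle:
    def test_sum_matches_elementwise_oracle(self, qgrid):
        seed = 77
        K = 7
        frame = multiple_particle_intensity(qgrid, K, np.random.default_rng(seed))
        rng2 = np.random.default_rng(seed)
        expected = np.zeros(qgrid.shape)
        for _ in range(K):
            expected = expected + single_particle_intensity(qgrid, rng2)
        np.testing.assert_allclose(frame, expected, rtol=1e-12)
        assert (frame >= 0).all()

    def test_rejects_k_below_two(self, qgrid, rng):
        with pytest.raises(DataError):
            multiple_particle_intensity(qgrid, 1, rng)


class TestScaling:
    def test_alpha_identity_and_linearity(self, qgrid):
        # a frame already at the target needs alpha = 1; linearity in target
        frame = np.ones(qgrid.shape)
        base = nphsh_of(frame, qgrid)
        scaled = frame / base  # now nphsh = 1 exactly
        assert compute_alpha(scaled, qgrid, (0.06, 0.08), 1.0) == pytest.approx(1.0)
        assert compute_alpha(scaled, qgrid, (0.06, 0.08), 0.1) == pytest.approx(0.1)

    def test_alpha_calibrates_arbitrary_frame_vs_tally_oracle(self, qgrid, rng):
        frame = rng.random(qgrid.shape)
        target = 0.37
        alpha = compute_alpha(frame, qgrid, (0.06, 0.08), target)
        # independent pixel-by-pixel tally of the scaled frame
        mask = annulus_mask(qgrid, 0.06, 0.08)
        total = 0.0
        npix = 0
        scaled = alpha * frame
        for i in range(qgrid.n_rows):
            for j in range(qgrid.n_cols):
                if mask[i, j]:
                    total += scaled[i, j]
                    npix += 1
        n_shannon = npix * (qgrid.dq / qgrid.shannon_side) ** 2
        assert total / n_shannon == pytest.approx(target, rel=1e-9)

    def test_zero_signal_cannot_scale(self, qgrid):
        with pytest.raises(DataError):
            compute_alpha(np.zeros(qgrid.shape), qgrid, (0.06, 0.08), 1.0)


class TestBackground:
    def test_b_zero_is_identity(self, qgrid, rng):
        frame = rng.random(qgrid.shape)
        np.testing.assert_array_equal(add_background(frame, qgrid, 0.0, 1.0), frame)

    @pytest.mark.parametrize("b", [1.0, 10.0])
    def test_background_disk_tally(self, qgrid, b):
        target = 0.5
        bg = add_background(np.zeros(qgrid.shape), qgrid, b, target)
        assert nphsh_of(bg, qgrid) == pytest.approx(b * target, rel=1e-9)

    def test_negative_b_rejected(self, qgrid):
        with pytest.raises(ConfigError):
            add_background(np.zeros(qgrid.shape), qgrid, -1.0, 1.0)


class TestGenerateDataset:
    def test_noise_free_labels_match_counts(self, tiny_noise_free_sets):
        train, _ = tiny_noise_free_sets
        np.testing.assert_array_equal(train.labels, (train.meta["K"] == 1).astype(np.uint8))
        assert (train.frames >= 0).all()
        # gap pixels zeroed
        gap = ~train.geometry.gap_mask.ravel()
        assert np.abs(train.frames[:, gap]).max() == 0

    def test_seed_determinism_bit_identical(self):
        cfg = SimulationConfig(n_rows=64, n_cols=64, nphsh_target=0.5, b=1.0, seed=9)
        a = generate_dataset(cfg, n=20)
        b = generate_dataset(cfg, n=20)
        np.testing.assert_array_equal(a.frames, b.frames)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.meta["K"], b.meta["K"])

    def test_poisson_frames_are_integer_counts(self):
        cfg = SimulationConfig(n_rows=64, n_cols=64, nphsh_target=1.0, b=1.0, seed=3)
        sset = generate_dataset(cfg, n=10)
        np.testing.assert_array_equal(sset.frames, np.round(sset.frames))

    def test_nphsh_calibration_monte_carlo(self):
        # b=0, w=1: measured photons per Shannon pixel match the target
        # within 3 sigma of the Poisson counting error
        cfg = SimulationConfig(
            n_rows=64, n_cols=64, nphsh_target=1.0, b=0.0, w_range=(1.0, 1.0), seed=42
        )
        n = 2000
        sset = generate_dataset(cfg, n=n)
        qg = sset.geometry
        mask = annulus_mask(qg, 0.06, 0.08).ravel()
        n_shannon = mask.sum() * (qg.dq / qg.shannon_side) ** 2
        total = sset.frames[:, mask].sum()
        expected = n * n_shannon * cfg.nphsh_target
        assert abs(total - expected) < 3 * np.sqrt(expected)

    def test_background_additivity_in_expectation(self):
        # disk tally difference between b=10 and b=0 runs of the same seed
        # equals b * target * n_shannon per frame, within Poisson error
        n = 400
        base = dict(n_rows=64, n_cols=64, nphsh_target=0.5, w_range=(1.0, 1.0), seed=5)
        with_bg = generate_dataset(SimulationConfig(b=10.0, **base), n=n)
        without = generate_dataset(SimulationConfig(b=0.0, **base), n=n)
        qg = with_bg.geometry
        mask = annulus_mask(qg, 0.06, 0.08).ravel()
        n_shannon = mask.sum() * (qg.dq / qg.shannon_side) ** 2
        diff = with_bg.frames[:, mask].sum() - without.frames[:, mask].sum()
        expected = 10.0 * 0.5 * n_shannon * n
        assert abs(diff - expected) < 4 * np.sqrt(with_bg.frames[:, mask].sum())

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(nphsh_target=-1.0)
        with pytest.raises(ConfigError):
            SimulationConfig(w_range=(0.0, 1.0))
        with pytest.raises(ConfigError):
            SimulationConfig(b=-0.5)
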