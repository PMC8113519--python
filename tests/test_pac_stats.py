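"""Surrogate null, z-scores/prevalence, circular tests, phase conversion,
robust regression and source selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tempopac import pac_stats as pst
from tempopac import synthetic as syn
from tempopac import tpac as tp

FS = 300.0
TWO_PI = 2 * np.pi


def _env_phase(truth, window=slice(300, 600)):
    _, x = syn.generate_pac_epoch(truth, 4.0, FS)
    kern = tp.design_bandpass(48.0, 72.0, FS)
    env = np.abs(stats_hilbert(tp._zero_phase_filter(x, kern)))
    ph = tp.fp_phase(x, truth.fP_hz, FS, tp.TpacConfig())
    return env[window], ph[window]


def stats_hilbert(x):
    from scipy.signal import hilbert

    return hilbert(x)


class TestBlockSurrogates:
    def test_constant_envelope_degenerate_z_floored(self):
        env = np.ones(150)
        ph = np.linspace(0, 10 * np.pi, 150, endpoint=False) % TWO_PI
        surr = pst.block_surrogates(env, ph, n_surr=200, seed=0)
        task, _ = tp.coupling_vector(env, ph)
        with pytest.warns(UserWarning, match="degenerate"):
            res = pst.z_and_prevalence(
                np.array([task]), surr[None, :] * 0 + task,
            )
        assert res.z_scores[0] == 0.0

    def test_coupled_signal_exceeds_surrogate_97_5(self):
        """Strong noiseless coupling beats the 97.5th surrogate percentile.

        fP is chosen incommensurate with the 5-block split (at 10 Hz a
        block is exactly one alpha cycle and permutation is a no-op for
        a perfectly periodic signal)."""
        truth = syn.PacGroundTruth(fP_hz=9.17, snr_db=None, seed=1)
        env, ph = _env_phase(truth)
        task, _ = tp.coupling_vector(env, ph)
        surr = pst.block_surrogates(env, ph, n_surr=500, seed=1)
        assert task > np.percentile(surr, 97.5)

    def test_null_mean_z_near_zero(self):
        """200 uncoupled-noise trials: mean z within 0.2 of 0."""
        rng = np.random.default_rng(42)
        kern = tp.design_bandpass(48.0, 72.0, FS)
        cfg = tp.TpacConfig()
        task, surr = [], []
        for i in range(200):
            truth = syn.PacGroundTruth(
                modulation_depth=0.0, fast_amplitude=0.0, snr_db=-20.0, seed=5000 + i
            )
            _, x = syn.generate_pac_epoch(truth, 4.0, FS)
            env = np.abs(stats_hilbert(tp._zero_phase_filter(x, kern)))[450:600]
            ph = tp.fp_phase(x, 10.0, FS, cfg)[450:600]
            s, _ = tp.coupling_vector(env, ph)
            task.append(s)
            surr.append(pst.block_surrogates(env, ph, n_surr=200, seed=rng))
        res = pst.z_and_prevalence(np.array(task), np.vstack(surr))
        assert abs(res.mean_z) < 0.2

    def test_identity_permutation_excluded(self):
        rng = np.random.default_rng(0)
        env = rng.uniform(0.5, 1.5, 100)
        ph = rng.uniform(0, TWO_PI, 100)
        task, _ = tp.coupling_vector(env, ph)
        surr = pst.block_surrogates(env, ph, n_surr=300, seed=1)
        assert not np.any(np.isclose(surr, task, atol=1e-15))

    def test_surrogate_of_surrogate_same_distribution(self):
        """Re-permuting a surrogate leaves the null unchanged (KS p > 0.01)."""
        rng = np.random.default_rng(3)
        env = rng.uniform(0.5, 1.5, 500)
        ph = rng.uniform(0, TWO_PI, 500)
        s1 = pst.block_surrogates(env, ph, n_surr=800, seed=10)
        # permute once, then surrogate the permuted series
        base = np.concatenate([np.array_split(env, 5)[j] for j in (2, 0, 4, 1, 3)])
        s2 = pst.block_surrogates(base, ph, n_surr=800, seed=11)
        assert stats.ks_2samp(s1, s2).pvalue > 0.01

    def test_too_few_blocks(self):
        with pytest.raises(ValueError):
            pst.block_surrogates(np.ones(10), np.ones(10), n_blocks=1)


class TestZAndPrevalence:
    def test_shifted_by_two_sd_gives_z2_and_full_prevalence(self):
        rng = np.random.default_rng(0)
        surr = rng.normal(1.0, 0.1, size=(20, 500))
        task = surr.mean(axis=1) + 2 * surr.std(axis=1, ddof=1)
        res = pst.z_and_prevalence(task, surr)
        assert np.allclose(res.z_scores, 2.0)
        assert res.prevalence_pct == 100.0
        assert res.mean_z == pytest.approx(2.0)

    def test_symmetric_null_prevalence_half(self):
        rng = np.random.default_rng(1)
        surr = rng.normal(0.5, 0.1, size=(400, 300))
        task = rng.normal(0.5, 0.1 / np.sqrt(300), size=400) * 0 + surr.mean(axis=1)
        task = surr.mean(axis=1) + rng.normal(0, 1e-3, 400)
        res = pst.z_and_prevalence(task, surr)
        assert 40.0 < res.prevalence_pct < 60.0

    def test_requires_100_surrogates(self):
        with pytest.raises(ValueError):
            pst.z_and_prevalence(np.ones(3), np.ones((3, 50)))

    def test_critical_value_is_upper_tail_quantile(self):
        assert pst.critical_z(0.0125) == pytest.approx(
            stats.norm.ppf(1 - 0.0125)
        )


class TestKuiper:
    def test_identical_samples_minimal_statistic(self):
        a = np.random.default_rng(0).uniform(0, TWO_PI, 50)
        v, p = pst.kuiper_two_sample(a, a)
        assert v == pytest.approx(0.0, abs=1e-12)  # ECDFs coincide
        assert p > 0.99

    def test_joint_rotation_invariance_exact(self):
        rng = np.random.default_rng(1)
        a = rng.vonmises(0, 1, 40) % TWO_PI
        b = rng.vonmises(1, 2, 60) % TWO_PI
        v0 = pst.kuiper_statistic(a, b)
        for rot in (0.5, 2.0, 4.5):
            v = pst.kuiper_statistic((a + rot) % TWO_PI, (b + rot) % TWO_PI)
            assert v == pytest.approx(v0, abs=1e-12)

    def test_power_against_opposite_von_mises(self):
        """Two von Mises 180 deg apart, kappa=2, n=100: rejected in >=99% of 200 runs."""
        rng = np.random.default_rng(2)
        rejects = 0
        for _ in range(200):
            a = rng.vonmises(0, 2, 100) % TWO_PI
            b = rng.vonmises(np.pi, 2, 100) % TWO_PI
            _, p = pst.kuiper_two_sample(a, b)
            rejects += p < 0.05
        assert rejects >= 198

    def test_rotated_copy_not_significant_under_null_shape(self):
        """Uniform null: a rotated independent sample rejects at ~alpha."""
        rng = np.random.default_rng(3)
        rejects = 0
        n_sim = 500
        for _ in range(n_sim):
            a = rng.uniform(0, TWO_PI, 60)
            b = (rng.uniform(0, TWO_PI, 60) + 1.0) % TWO_PI  # rotation, same shape
            _, p = pst.kuiper_two_sample(a, b)
            rejects += p < 0.05
        assert rejects <= 0.06 * n_sim + 3 * np.sqrt(n_sim * 0.05 * 0.95)

    def test_permutation_matches_asymptotic(self):
        rng = np.random.default_rng(4)
        a = rng.vonmises(0, 1, 30) % TWO_PI
        b = rng.vonmises(0.8, 1, 30) % TWO_PI
        v1, p_asym = pst.kuiper_two_sample(a, b, method="asymptotic")
        v2, p_perm = pst.kuiper_two_sample(a, b, method="permutation", n_perm=4000)
        assert v1 == v2
        assert p_perm == pytest.approx(p_asym, abs=0.05)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            pst.kuiper_two_sample(np.ones(5), np.ones(20))


class TestRayleigh:
    def test_concentrated_sample_minimal_p(self):
        z, p, mean = pst.rayleigh_test(np.full(20, 1.3))
        assert p < 1e-6
        assert mean == pytest.approx(1.3)

    def test_type_one_error_calibrated(self):
        """Uniform draws, n=16: rejection rate at alpha=0.0125 within binomial CI."""
        rng = np.random.default_rng(5)
        n_sim = 2000
        rejects = 0
        for _ in range(n_sim):
            _, p, _ = pst.rayleigh_test(rng.uniform(0, TWO_PI, 16))
            rejects += p < 0.0125
        se = np.sqrt(0.0125 * (1 - 0.0125) / n_sim)
        assert abs(rejects / n_sim - 0.0125) < 1.96 * se + 1e-9

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            pst.rayleigh_test(np.ones(4))


class TestCircularShift:
    @pytest.mark.parametrize(
        "m1,m2,expected",
        [(351.0, 136.0, 145.0), (276.0, 55.0, 139.0), (10.0, 350.0, 20.0)],
    )
    def test_worked_examples(self, m1, m2, expected):
        assert pst.circular_shift_deg(m1, m2) == pytest.approx(expected)

    @given(st.floats(0, 360), st.floats(0, 360))
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_range(self, a, b):
        d = pst.circular_shift_deg(a, b)
        assert 0.0 <= d <= 180.0
        assert d == pytest.approx(pst.circular_shift_deg(b, a))

    @given(st.floats(0, 360))
    @settings(max_examples=50, deadline=None)
    def test_self_shift_zero(self, a):
        assert pst.circular_shift_deg(a, a) == 0.0


class TestPhaseToMs:
    def test_full_cycle_at_10hz_is_100ms(self):
        assert pst.phase_to_ms(TWO_PI, 10.0) == pytest.approx(100.0)
        assert pst.phase_to_ms(np.pi, 10.0) == pytest.approx(50.0)

    def test_126_deg_at_10hz_is_35ms(self):
        assert pst.phase_to_ms(np.deg2rad(126.0), 10.0) == pytest.approx(35.0)

    @given(st.floats(0.01, 10), st.floats(1, 100), st.floats(1.01, 3))
    @settings(max_examples=100, deadline=None)
    def test_linear_in_phase_inverse_in_frequency(self, phi, fp, c):
        assert pst.phase_to_ms(c * phi, fp) == pytest.approx(
            c * pst.phase_to_ms(phi, fp), rel=1e-12
        )
        assert pst.phase_to_ms(phi, c * fp) == pytest.approx(
            pst.phase_to_ms(phi, fp) / c, rel=1e-12
        )

    def test_nonpositive_frequency(self):
        with pytest.raises(ValueError):
            pst.phase_to_ms(1.0, 0.0)


class TestRobustRegression:
    def test_exact_line(self):
        x = np.linspace(20, 50, 12)
        res = pst.robust_regression_tr_vs_period(1.5 * x, x)
        assert res["slope"] == pytest.approx(1.5, abs=1e-8)
        assert res["r_squared"] == pytest.approx(1.0, abs=1e-10)

    def test_slope_recovery_with_noise(self):
        """True slope 1.5, noise SD 5 ms, n=16: mean estimate within 0.15."""
        rng = np.random.default_rng(6)
        slopes = []
        for _ in range(200):
            x = rng.uniform(20, 45, 16)
            y = 1.5 * x + rng.normal(0, 5, 16)
            slopes.append(pst.robust_regression_tr_vs_period(y, x)["slope"])
        assert abs(np.mean(slopes) - 1.5) < 0.15

    def test_corrected_threshold(self):
        res = pst.robust_regression_tr_vs_period(
            1.5 * np.arange(5, 11), np.arange(5, 11, dtype=float)
        )
        assert res["alpha"] == pytest.approx(0.05 / 12)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            pst.robust_regression_tr_vs_period(np.ones(6), np.ones(6))
        with pytest.raises(ValueError):
            pst.robust_regression_tr_vs_period(np.ones(3), np.arange(3.0))


class TestMaxShiftSourceSelection:
    @staticmethod
    def _sample(rng, mu, kappa=2.0, n=60):
        return rng.vonmises(mu, kappa, n) % TWO_PI

    def test_single_source_selected_iff_significant(self):
        rng = np.random.default_rng(7)
        shifted = {"s0": (self._sample(rng, 0), self._sample(rng, np.pi))}
        out = pst.max_shift_source_selection(shifted)
        assert out["selected"] == "s0"
        null = {"s0": (self._sample(rng, 0), self._sample(rng, 0))}
        out = pst.max_shift_source_selection(null)
        assert out["selected"] is None

    def test_truly_shifted_source_found(self):
        """One shifted source among 5: selected in >= 90% of 100 runs."""
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(100):
            sources = {
                f"s{i}": (self._sample(rng, 0), self._sample(rng, 0))
                for i in range(4)
            }
            sources["shifted"] = (self._sample(rng, 0), self._sample(rng, np.pi))
            out = pst.max_shift_source_selection(sources)
            hits += out["selected"] == "shifted"
        assert hits >= 90

    def test_all_null_flag_rate_matches_type_one(self):
        """All-null sources: per-subject flag rate tracks the Kuiper alpha."""
        rng = np.random.default_rng(9)
        n_sim = 100
        n_sources = 5
        selected = 0
        for _ in range(n_sim):
            sources = {
                f"s{i}": (
                    rng.uniform(0, TWO_PI, 60), rng.uniform(0, TWO_PI, 60)
                )
                for i in range(n_sources)
            }
            out = pst.max_shift_source_selection(sources)
            selected += out["selected"] is not None
        # family-wise: 1 - (1-alpha)^5 ~ 0.23; allow generous binomial slack
        expect = 1 - (1 - 0.05) ** n_sources
        assert abs(selected / n_sim - expect) < 0.15


class TestBonferroni:
    def test_region_and_regression_families(self):
        assert pst.bonferroni_alpha(0.05, 4) == pytest.approx(0.0125)
        assert pst.bonferroni_alpha(0.05, 12) == pytest.approx(0.0042, abs=5e-5)
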