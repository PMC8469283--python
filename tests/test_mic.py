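"""MIC: plug-in grid MI, exhaustive vs DP search, statistic properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cortemg.mic import (
    DataError,
    PairedSample,
    bootstrap_mic,
    grid_mutual_information,
    grid_resolution_bound,
    max_grid_mi,
    mic,
    mic_value,
)


class TestGridMutualInformation:
    def test_perfect_2x2_association_is_one_bit(self):
        x = np.array([0] * 5 + [1] * 5)
        sample = PairedSample(x, x)
        got = grid_mutual_information(sample, [-0.5, 0.5, 1.5],
                                      [-0.5, 0.5, 1.5])
        assert got == pytest.approx(1.0, abs=1e-12)

    def test_independence_is_zero_bits(self):
        x = np.repeat([0, 0, 1, 1], 25)
        y = np.tile([0, 1], 50)
        got = grid_mutual_information(PairedSample(x, y),
                                      [-0.5, 0.5, 1.5], [-0.5, 0.5, 1.5])
        assert got == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_3113_table(self):
        # counts [[3,1],[1,3]]: I = 0.75*log2(1.5) + 0.25*log2(0.5)
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        y = np.array([0, 0, 0, 1, 0, 1, 1, 1])
        got = grid_mutual_information(PairedSample(x, y),
                                      [-0.5, 0.5, 1.5], [-0.5, 0.5, 1.5])
        expect = 0.75 * np.log2(1.5) + 0.25 * np.log2(0.5)
        assert got == pytest.approx(expect, abs=1e-12)
        assert got == pytest.approx(0.18872, abs=5e-6)

    def test_degenerate_edges_rejected(self):
        sample = PairedSample(np.arange(4.0), np.arange(4.0))
        with pytest.raises(ValueError):
            grid_mutual_information(sample, [0.0, 0.0, 3.0], [0.0, 1.5, 3.0])


class TestMaxGridMI:
    def test_monotone_data_2x2_reaches_one_bit(self):
        x = np.arange(10.0)
        assert max_grid_mi(PairedSample(x, x ** 2), 2, 2,
                           "exhaustive") == pytest.approx(1.0)
        assert max_grid_mi(PairedSample(x, x ** 2), 2, 2,
                           "heuristic") == pytest.approx(1.0)

    @pytest.mark.parametrize("shape", [(2, 2), (2, 3), (3, 2), (3, 3)])
    def test_heuristic_never_exceeds_and_matches_exhaustive(self, shape):
        r, m = shape
        for seed in range(25):
            rng = np.random.default_rng(seed)
            sample = PairedSample(rng.normal(size=14), rng.normal(size=14))
            exact = max_grid_mi(sample, r, m, "exhaustive")
            fast = max_grid_mi(sample, r, m, "heuristic")
            assert fast <= exact + 1e-9
            assert fast == pytest.approx(exact, abs=1e-9)

    def test_tied_values_well_defined(self):
        # six points with heavy ties: cuts fall between distinct values
        sample = PairedSample(np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0]),
                              np.array([0.0, 0.0, 1.0, 1.0, 1.0, 1.0]))
        exact = max_grid_mi(sample, 2, 2, "exhaustive")
        fast = max_grid_mi(sample, 2, 2, "heuristic")
        assert np.isfinite(exact) and exact >= 0
        assert fast == pytest.approx(exact, abs=1e-12)

    def test_tiny_grid_rejected(self):
        sample = PairedSample(np.arange(6.0), np.arange(6.0))
        with pytest.raises(ValueError):
            max_grid_mi(sample, 1, 3)


class TestMICStatistic:
    def test_noiseless_monotone_relationship_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(size=100)
        for y in (x, np.exp(3 * x), -x ** 3):
            assert mic_value(x, y) == 1.0

    def test_constant_variable_gives_zero(self):
        x = np.random.default_rng(1).uniform(size=50)
        assert mic_value(x, np.zeros(50)) == 0.0

    def test_symmetry_exact(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=60), rng.normal(size=60)
        a = mic(PairedSample(x, y))
        b = mic(PairedSample(y, x))
        assert a.mic == b.mic

    def test_invariant_under_strictly_monotone_transforms(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=80)
        y = x + rng.normal(size=80)
        base = mic_value(x, y)
        assert mic_value(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert mic_value(x, -1.0 / (1 + np.exp(-y))) == pytest.approx(
            base, abs=1e-12)

    def test_small_sample_matches_exhaustive_search(self):
        # independent uniforms: the fast search equals the full grid
        # enumeration at the same B(n) bound on small subsamples
        rng = np.random.default_rng(4)
        for _ in range(10):
            x, y = rng.uniform(size=16), rng.uniform(size=16)
            fast = mic(PairedSample(x, y), mode="heuristic")
            full = mic(PairedSample(x, y), mode="exhaustive")
            assert fast.mic == pytest.approx(full.mic, abs=1e-9)

    def test_characteristic_matrix_respects_bound(self):
        result = mic(PairedSample(np.arange(30.0),
                                  np.random.default_rng(5).normal(size=30)))
        B = grid_resolution_bound(30)
        for (r, m), value in result.characteristic_matrix.items():
            assert r * m < B
            assert 0.0 <= value <= 1.0

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_mic_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        x = rng.normal(size=n)
        y = rng.normal(size=n) + rng.integers(0, 2) * x
        assert 0.0 <= mic_value(x, y) <= 1.0

    def test_expected_mic_nonincreasing_in_noise(self):
        rng = np.random.default_rng(6)
        means = []
        for eps in (0.1, 0.7, 3.0):
            vals = []
            for _ in range(8):
                x = rng.uniform(size=120)
                vals.append(mic_value(x, x + eps * rng.normal(size=120)))
            means.append(np.mean(vals))
        assert means[0] > means[1] - 0.02
        assert means[1] > means[2] - 0.02

    def test_underestimation_bias_shrinks_with_sample_size(self):
        # a deterministic nonmonotone relationship needs grid resolution the
        # B(n) cap denies at small n, so small samples underestimate it and
        # the estimate climbs back toward 1 as n grows
        rng = np.random.default_rng(7)
        means = []
        for n in (30, 100, 300):
            vals = []
            for _ in range(6):
                x = rng.uniform(size=n)
                vals.append(mic_value(x, np.sin(4 * np.pi * x)))
            means.append(np.mean(vals))
        assert means[0] < means[1] and means[0] < means[2]
        assert means[2] > 0.9

    def test_input_validation(self):
        with pytest.raises(DataError):
            mic(PairedSample(np.arange(3.0), np.arange(3.0)))
        with pytest.raises(ValueError):
            mic(PairedSample(np.arange(10.0), np.arange(10.0)), alpha=1.5)
        with pytest.raises(DataError):
            PairedSample(np.array([np.nan, 1.0]), np.array([0.0, 1.0]))


class TestBootstrap:
    @staticmethod
    def _trials(rng, n_trials=12, n_per=20):
        out = []
        for _ in range(n_trials):
            x = rng.uniform(size=n_per)
            out.append(PairedSample(x, x + 0.3 * rng.normal(size=n_per)))
        return out

    def test_single_trial_single_rep_equals_plain_mic(self, rng):
        trial = self._trials(rng, n_trials=1, n_per=40)[0]
        boot = bootstrap_mic([trial], k=1, reps=1, rng=0)
        assert boot.values[0] == mic(trial).mic
        assert boot.mean == boot.values[0] and boot.sd == 0.0

    def test_resampling_defaults_are_30_trials_100_reps(self, rng):
        trials = self._trials(rng, n_trials=5, n_per=10)
        boot = bootstrap_mic(trials, rng=1)
        assert boot.k == 30 and boot.reps == 100
        assert boot.values.shape == (100,)
        assert 0.0 <= boot.values.min() and boot.values.max() <= 1.0

    def test_empty_trial_list_rejected(self):
        with pytest.raises(DataError):
            bootstrap_mic([], k=3, reps=2)


class TestNullBehaviour:
    def test_zero_coupling_mic_indistinguishable_from_permutation_null(self):
        # generator with all-zero coupling: unit rates and EMG share no
        # drive, so the observed MIC should sit inside the permutation null
        from cortemg.synthetic import GeneratorConfig, simulate_session
        from cortemg.pipeline import RunConfig, analyze_session

        n_units = 3
        cfg = GeneratorConfig(
            seed=21, n_sessions=1, lesion_session=1, session_duration=40.0,
            n_units_initial=n_units, muscles=("LS", "RS"), artifact_rate=0.0,
            baseline_coupling=np.zeros((n_units, 2)))
        analysis = analyze_session(simulate_session(cfg, 0),
                                   RunConfig(generator=cfg, mic_max_n=150))
        r = analysis.rates_steps[:150, 0]
        m = analysis.emg_steps[:150, 0]
        observed = mic_value(r, m)
        rng = np.random.default_rng(99)
        null = [mic_value(r, rng.permutation(m)) for _ in range(39)]
        # observed should not be an extreme outlier of the null (alpha 2.5%)
        assert observed <= max(null)
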