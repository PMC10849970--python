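"""Switching-LDS fitting, simulation, taxonomy, decoding and alignment."""

import warnings

import numpy as np
import pytest

from respdyn import rslds as R
from respdyn import synthetic as syn


@pytest.fixture(scope="module")
def node_fit(node_small):
    model = R.RecurrentSwitchingLDS.from_spikes(
        node_small.spikes, node_small.config.duration
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(seed=0, max_iter=10)
    return model, res


class TestEigenTaxonomy:
    @pytest.mark.parametrize(
        "a,expected",
        [
            (0.9 * np.eye(2), "stable node"),
            (1.1 * np.eye(2), "unstable node"),
            (np.diag([1.1, 0.8]), "saddle"),
            (1.02 * np.array([[np.cos(0.3), -np.sin(0.3)],
                              [np.sin(0.3), np.cos(0.3)]]), "unstable spiral"),
            (0.95 * np.array([[np.cos(0.3), -np.sin(0.3)],
                              [np.sin(0.3), np.cos(0.3)]]), "stable spiral"),
        ],
    )
    def test_categories(self, a, expected):
        assert R.classify_eigenvalues(a) == expected

    def test_invariant_to_orthogonal_basis_change(self, rng):
        a = 1.03 * np.array([[np.cos(0.4), -np.sin(0.4)],
                             [np.sin(0.4), np.cos(0.4)]])
        q, _ = np.linalg.qr(rng.normal(size=(2, 2)))
        assert R.classify_eigenvalues(q @ a @ q.T) == R.classify_eigenvalues(a)


class TestFit:
    def test_objective_non_decreasing(self, node_fit):
        _, res = node_fit
        obj = res.log_objective
        drops = np.diff(obj) < -1e-6 * np.abs(obj[:-1])
        assert not drops.any()

    def test_transition_probabilities_normalize(self, node_fit, rng):
        _, res = node_fit
        p = res.transition_probabilities(rng.normal(size=(200, 2)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert p.min() >= 0

    def test_states_align_with_true_inspiration(self, node_small, node_fit):
        _, res = node_fit
        zt = node_small.state_true[: len(res.states)]
        agree = np.mean(res.states == zt)
        assert max(agree, 1 - agree) > 0.9

    def test_constant_rate_unit_emission(self, node_fit):
        _, res = node_fit
        x = np.zeros((10, 2))
        rates = res.emission_rates(x)
        assert np.allclose(rates, rates[0], atol=1e-9)

    def test_too_little_data_raises(self):
        with pytest.raises(ValueError, match="60 s"):
            R.RecurrentSwitchingLDS(np.zeros((12, 100)), bin_width=0.01)

    def test_too_few_units_raises(self):
        with pytest.raises(ValueError, match="10 units"):
            R.RecurrentSwitchingLDS(np.zeros((3, 10_000)), bin_width=0.01)


class TestSimulate:
    def test_single_stable_state_converges_to_fixed_point(self, node_fit):
        _, res = node_fit
        import copy

        r = copy.deepcopy(res)
        a = 0.9 * np.eye(2)
        b = np.array([0.2, -0.1])
        r.A = a[None]
        r.b = b[None]
        r.trans_w = np.zeros((1, 2))
        r.trans_b = np.zeros(1)
        x, _ = r.simulate(2000, x0=np.array([3.0, 3.0]))
        assert np.allclose(x[-1], np.linalg.solve(np.eye(2) - a, b), atol=1e-6)

    def test_same_start_is_deterministic(self, node_fit):
        _, res = node_fit
        x1, z1 = res.simulate(500, x0=np.array([1.0, 0.5]))
        x2, z2 = res.simulate(500, x0=np.array([1.0, 0.5]))
        assert np.array_equal(x1, x2) and np.array_equal(z1, z2)

    def test_overflow_truncates_with_flag(self, node_fit):
        import copy

        _, res = node_fit
        r = copy.deepcopy(res)
        r.A = (2.0 * np.eye(2))[None].repeat(r.n_states, axis=0)
        r.b = np.zeros_like(r.b)
        r.simulate(200, x0=np.array([1.0, 1.0]))
        assert r.simulation_truncated


class TestRegenerativeRule:
    def test_constant_trace_is_not_regenerative(self):
        assert not R.classify_regenerative(np.ones(5000), 100.0)

    def test_sustained_bursting_is_regenerative(self):
        t = np.arange(6000) / 100.0
        trace = np.maximum(np.sin(2 * np.pi * 2.5 * t), 0.0) ** 2
        assert R.classify_regenerative(trace, 100.0)

    def test_decaying_oscillation_is_not(self):
        t = np.arange(6000) / 100.0
        trace = np.exp(-t * np.log(2) / 5.0) * np.maximum(
            np.sin(2 * np.pi * 2.5 * t), 0.0
        )
        assert not R.classify_regenerative(trace, 100.0)

    def test_breath_stats_count_bursts(self):
        t = np.arange(4000) / 100.0
        trace = np.maximum(np.sin(2 * np.pi * 2.0 * t), 0.0)
        stats = R.simulated_breath_stats(trace, 100.0)
        assert abs(stats["frequency_hz"] - 2.0) < 0.1
        assert stats["n_bursts"] >= 70


class TestDecoder:
    def test_realizable_target_fits_tightly(self, rng):
        x = rng.normal(size=(3000, 2))
        y = np.maximum(0.0, x[:, 0] + 0.5 * x[:, 1])
        dec = R.fit_diaphragm_decoder(x, y, seed=0)
        pred = dec.decode(x)
        ss = 1 - ((pred - y) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert ss > 0.99

    def test_constant_latent_gives_constant_prediction(self, rng):
        x = rng.normal(size=(2000, 2))
        dec = R.fit_diaphragm_decoder(x, x[:, 0], seed=0)
        pred = dec.decode(np.tile([0.3, -0.2], (50, 1)))
        assert np.ptp(pred) < 1e-9


class TestAlignment:
    def test_identity_when_target_equals_source(self, rng):
        x = rng.normal(size=(100, 2))
        assert np.allclose(R.align_latents(x, x), np.eye(2), atol=1e-10)

    def test_known_mixing_matrix_recovered(self, rng):
        x = rng.normal(size=(100, 2))
        mix = np.array([[0.3, -1.2], [0.8, 0.4]])
        w = R.align_latents(x, x @ mix)
        assert np.allclose(w, mix, atol=1e-6)

    def test_rank_deficient_source_raises(self, rng):
        x = np.zeros((100, 2))
        x[:, 0] = rng.normal(size=100)
        with pytest.raises(ValueError, match="rank"):
            R.align_latents(x, x)

    def test_phase_binned_latent_shape(self, node_small, node_fit):
        _, res = node_fit
        from respdyn import breath as B

        trace = B.DiaphragmTrace(node_small.diaphragm, 1000.0)
        table = B.detect_breaths(trace)
        phase = B.compute_phase(table, 1000.0, node_small.config.duration)
        phi = phase.phi[::10][: len(res.latent)]
        binned = R.phase_binned_latent(res.latent, phi)
        assert binned.shape == (100, 2)
        assert np.isfinite(binned).mean() >= 0.85


class TestDropoutRule:
    def test_step_function_matches_oracle(self):
        # regenerative up to 20 removals, never after: the rule takes
        # the greater of the logistic boundary and the last success
        counts = np.arange(0, 41, 5)
        flags = counts <= 20
        utf, boundary = R.units_to_failure_rule(counts, flags)
        assert utf == max(boundary, 20)
        assert 20 <= utf <= 25

    def test_all_regenerative_returns_max(self):
        counts = np.arange(0, 31, 5)
        utf, _ = R.units_to_failure_rule(counts, np.ones(len(counts), bool))
        assert utf == 30

    def test_subset_of_all_units_matches_full_model(self, node_small, node_fit):
        model, res = node_fit
        step = 10
        n_bins = model.n_bins
        dia = node_small.diaphragm[: n_bins * step].reshape(n_bins, step).mean(1)
        out = R.subset_refit(
            model.counts, dia, {"all": np.ones(model.n_units, bool)},
            seed=0, fit_kwargs={"max_iter": 8},
        )
        assert len(out) == 1 and bool(out.regenerative.iloc[0])

    def test_small_subset_skipped(self, node_small, node_fit):
        model, _ = node_fit
        dia = np.zeros(model.n_bins)
        out = R.subset_refit(
            model.counts, dia, {"tiny": np.arange(4)}, seed=0
        )
        assert out.empty


class TestBreathAlignedComparison:
    def test_self_comparison_is_perfect(self, rng):
        aligned = rng.gamma(2.0, 1.0, (20, 60))
        out = R.breath_aligned_r2(aligned, aligned, seed=0, n_shuffles=20)
        assert out["median_r2"] == pytest.approx(1.0)
        assert out["median_r2"] > out["shuffle_cells_median"]
        assert out["median_r2"] > out["shuffle_time_median"]
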