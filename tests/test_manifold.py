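"""Rate preprocessing, population PCA, trajectory statistics, subspace
angles and pairwise correlation structure."""

import numpy as np
import pytest

from respdyn import breath as B
from respdyn import manifold as M


class TestRateMatrix:
    def test_unit_without_spikes_is_zero(self):
        rm = M.build_rate_matrix([np.array([]), np.array([1.0])], 2.0)
        assert np.all(rm.rates[0] == 0.0)
        assert rm.rates[1].sum() > 0

    def test_single_spike_kernel_integral_is_one(self):
        rm = M.build_rate_matrix([np.array([1.0])], 2.0)
        assert (rm.rates[0] ** 2).sum() == pytest.approx(1.0, abs=1e-6)

    def test_sqrt_transform_scaling_law(self, rng):
        # doubling spike density doubles pre-sqrt values, so the stored
        # (post-sqrt) matrix scales by sqrt(2)
        spikes = np.sort(rng.uniform(0, 10, 400))
        both = np.sort(np.concatenate([spikes, spikes]))
        r1 = M.build_rate_matrix([spikes], 10.0).rates[0]
        r2 = M.build_rate_matrix([both], 10.0).rates[0]
        dense = r1 > 0.2
        assert np.allclose(r2[dense] / r1[dense], np.sqrt(2), atol=0.02)


class TestPCA:
    def test_rank_two_data_needs_two_components(self, rng):
        t = np.arange(4000) * 0.005
        lat = np.stack([np.sin(t), np.cos(2 * t)])
        rates = np.abs(rng.normal(1, 0.2, (30, 1)) @ lat[:1]
                       + rng.normal(1, 0.2, (30, 1)) @ lat[1:]) + 1.0
        rm = M.RateMatrix(rates)
        res = M.fit_population_pca(rm)
        frac = res.explained_variance[:2].sum() / res.explained_variance.sum()
        assert frac > 0.99

    def test_fit_epoch_projections_are_centred(self, rng):
        rm = M.RateMatrix(rng.gamma(2.0, 1.0, (20, 8000)))
        res = M.fit_population_pca(rm, fit_epoch=(0.0, 20.0))
        n_fit = int(20.0 / rm.bin_width)
        assert np.allclose(res.projections[:, :n_fit].mean(axis=1), 0, atol=1e-9)

    def test_loadings_orthonormal(self, rng):
        rm = M.RateMatrix(rng.gamma(2.0, 1.0, (20, 4000)))
        res = M.fit_population_pca(rm)
        gram = res.loadings.T @ res.loadings
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_variance_conservation(self, rng):
        rm = M.RateMatrix(rng.gamma(2.0, 1.0, (15, 6000)))
        res = M.fit_population_pca(rm)
        total = ((rm.rates - rm.rates.mean(1, keepdims=True)) ** 2).sum() / (
            rm.rates.shape[1] - 1
        )
        assert res.explained_variance.sum() == pytest.approx(total, rel=1e-6)

    def test_short_epoch_raises(self, rng):
        rm = M.RateMatrix(rng.gamma(2.0, 1.0, (15, 6000)))
        with pytest.raises(ValueError, match="10 s"):
            M.fit_population_pca(rm, fit_epoch=(0.0, 5.0))


class TestReorder:
    def _result_with_projections(self, proj):
        n_comp = proj.shape[0]
        return M.ManifoldResult(
            loadings=np.eye(n_comp),
            projections=proj,
            explained_variance=np.ones(n_comp),
            mean=np.zeros(n_comp),
            bin_width=0.005,
            fit_epoch=(0.0, proj.shape[1] * 0.005),
        )

    def test_breathing_component_ordered_first(self, rng):
        t = np.arange(24_000) * 0.005
        rhythm = np.sin(2 * np.pi * 1.0 * t)
        proj = np.stack([rng.normal(size=len(t)),
                         rhythm + 0.1 * rng.normal(size=len(t)),
                         rng.normal(size=len(t))])
        trace = B.DiaphragmTrace(
            np.interp(np.arange(len(t) * 5) / 1000.0, t, np.maximum(rhythm, 0)),
            1000.0,
        )
        res = M.reorder_by_coherence(self._result_with_projections(proj), trace)
        assert res.coherence_order[0] == 1
        assert sorted(res.coherence_order.tolist()) == [0, 1, 2]
        # white-noise components rank behind the rhythmic one
        assert res.component_coherence[1] > res.component_coherence[0]
        assert res.component_coherence[1] > res.component_coherence[2]


class TestTrajectoryStats:
    def _phase(self, period_s, duration_s, rate=200.0, duty=0.4):
        n = int(duration_s * rate)
        t = np.arange(n) / rate
        tb = t % period_s
        phi = np.where(
            tb < duty * period_s,
            np.pi * tb / (duty * period_s),
            -np.pi + np.pi * (tb - duty * period_s) / ((1 - duty) * period_s),
        )
        return B.PhaseSignal(phi, rate)

    def test_uniform_rotation_has_constant_speed(self):
        rate, duration, period = 200.0, 60.0, 1.0
        t = np.arange(int(duration * rate)) / rate
        # one rotation per breath, synchronized with the phase signal
        ang = 2 * np.pi * t / period
        proj = np.stack([2 * np.cos(ang), 2 * np.sin(ang)])
        res = M.ManifoldResult(
            loadings=np.eye(2), projections=proj,
            explained_variance=np.ones(2), mean=np.zeros(2),
            bin_width=1 / rate, fit_epoch=(0, duration),
        )
        ts = M.trajectory_stats(res, self._phase(period, duration, rate),
                                n_components=2)
        expected = 2 * 2 * np.pi / (period * rate)
        assert np.nanmax(np.abs(ts.speed - expected)) < 0.05 * expected

    def test_identical_breaths_have_zero_distance(self):
        rate, duration, period = 200.0, 30.0, 1.0
        t = np.arange(int(duration * rate)) / rate
        ang = 2 * np.pi * (t % period)
        proj = np.stack([np.cos(ang), np.sin(ang)])
        res = M.ManifoldResult(
            loadings=np.eye(2), projections=proj,
            explained_variance=np.ones(2), mean=np.zeros(2),
            bin_width=1 / rate, fit_epoch=(0, duration),
        )
        ts = M.trajectory_stats(res, self._phase(period, duration, rate),
                                n_components=2)
        assert np.nanmax(ts.distance_to_mean) < 0.05

    def test_designed_speed_profile_is_recovered(self):
        # phase-dependent angular velocity injected as projections: the
        # recovered phase-binned speed correlates with the design
        rate, duration, period = 200.0, 120.0, 1.0
        t = np.arange(int(duration * rate)) / rate
        frac = (t % period) / period
        # radius modulation gives a designed phase-dependent speed
        r = 1.0 + 0.5 * np.sin(2 * np.pi * frac)
        proj = np.stack([r * np.cos(2 * np.pi * frac),
                         r * np.sin(2 * np.pi * frac)])
        res = M.ManifoldResult(
            loadings=np.eye(2), projections=proj,
            explained_variance=np.ones(2), mean=np.zeros(2),
            bin_width=1 / rate, fit_epoch=(0, duration),
        )
        ts = M.trajectory_stats(res, self._phase(period, duration, rate),
                                n_components=2)
        designed = np.linalg.norm(np.diff(proj[:, :int(rate * period)]), axis=0)
        # bin the designed per-step speed the same way
        phi = self._phase(period, period, rate).phi[:-1]
        bins = B.bin_phase(phi)
        d_binned = np.bincount(bins, weights=designed, minlength=100) / np.maximum(
            np.bincount(bins, minlength=100), 1
        )
        ok = ~np.isnan(ts.speed)
        corr = np.corrcoef(ts.speed[ok], d_binned[ok])[0, 1]
        assert corr > 0.9

    def test_empty_bins_are_nan(self):
        rate, duration = 200.0, 20.0
        proj = np.zeros((2, int(duration * rate)))
        phase = self._phase(1.0, duration, rate)
        phase.phi[B.bin_phase(phase.phi) == 10] = np.nan
        ts = M.trajectory_stats(
            M.ManifoldResult(
                loadings=np.eye(2), projections=proj,
                explained_variance=np.ones(2), mean=np.zeros(2),
                bin_width=1 / rate, fit_epoch=(0, duration),
            ),
            phase, n_components=2,
        )
        assert np.isnan(ts.speed[10])


class TestPrincipalAngles:
    def test_identical_subspaces_give_unit_cosines(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(20, 3)))
        assert np.allclose(M.principal_angles(q, q), 1.0, atol=1e-10)

    def test_orthogonal_subspaces_give_zero(self):
        a = np.eye(6)[:, :2]
        b = np.eye(6)[:, 2:4]
        assert np.allclose(M.principal_angles(a, b), 0.0, atol=1e-12)

    @pytest.mark.parametrize("theta", [0.3, 1.0, np.pi / 2 - 0.1])
    def test_planar_angle_construction(self, theta):
        # two planes in R^3 sharing one axis, tilted by theta about it:
        # cosines are {1, cos theta}
        a = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        b = np.array([[1.0, 0.0], [0.0, np.cos(theta)], [0.0, np.sin(theta)]])
        cos = M.principal_angles(a, b)
        assert cos[0] == pytest.approx(1.0, abs=1e-8)
        assert cos[1] == pytest.approx(np.cos(theta), abs=1e-8)

    def test_mismatched_unit_dimension_raises(self):
        with pytest.raises(ValueError, match="unit"):
            M.principal_angles(np.eye(4)[:, :2], np.eye(5)[:, :2])


class TestCorrelationStructure:
    def test_identical_conditions_give_unit_fit(self, rng):
        rm = M.RateMatrix(rng.gamma(2.0, 1.0, (12, 4000)))
        _, _, _, r = M.correlation_structure(rm, rm)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_matrices_symmetric_with_unit_diagonal(self, rng):
        rm = M.RateMatrix(rng.gamma(2.0, 1.0, (10, 3000)))
        ca, cb, _, _ = M.correlation_structure(rm, rm)
        assert np.allclose(ca, ca.T)
        assert np.allclose(np.diag(ca), 1.0)

    def test_unitwise_permutation_decorrelates(self, rng):
        shared = rng.normal(size=(1, 6000))
        rates = np.abs(rng.normal(1, 0.1, (16, 1)) @ shared
                       + 0.8 * rng.normal(size=(16, 6000))) + 0.5
        rm_a = M.RateMatrix(rates)
        rm_b = M.RateMatrix(rates[rng.permutation(16)])
        _, _, _, r = M.correlation_structure(rm_a, rm_b)
        assert abs(r) < 0.3

    def test_constant_unit_pairs_are_missing(self, rng):
        rates = rng.gamma(2.0, 1.0, (8, 2000))
        rates[3] = 1.0
        ca, _, pairs, _ = M.correlation_structure(
            M.RateMatrix(rates), M.RateMatrix(rates)
        )
        assert np.isnan(ca[3, 4])
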