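"""Per-unit metrics: QC gate, tuning, coherence, selectivity, categories."""

import numpy as np
import pytest

from respdyn import breath as B
from respdyn import coherence as C
from respdyn import units as U


@pytest.fixture(scope="module")
def eupnea_phase(eupnea_small):
    trace = B.DiaphragmTrace(eupnea_small.diaphragm, 1000.0)
    table = B.detect_breaths(trace)
    phase = B.compute_phase(table, 1000.0, eupnea_small.config.duration)
    return trace, phase


class TestQC:
    @pytest.mark.parametrize(
        "isi,amp,presence,label,morphine,kept",
        [
            (0.1, 0.05, 0.95, "good", False, True),
            (0.6, 0.05, 0.95, "good", False, False),   # ISI violations
            (0.1, 0.2, 0.95, "good", False, False),    # amplitude cutoff
            (0.1, 0.05, 0.30, "good", False, False),   # presence ratio
            (0.1, 0.05, 0.30, "good", True, True),     # relaxed to 0.25
            (0.1, 0.05, 0.95, "noise", False, False),  # sorter label
        ],
    )
    def test_quality_gate(self, isi, amp, presence, label, morphine, kept):
        unit = U.UnitQC(0, isi, amp, presence, label)
        assert (0 in U.qc_filter([unit], morphine_mode=morphine)) == kept

    def test_fraction_bounds_validated(self):
        with pytest.raises(ValueError):
            U.UnitQC(0, 1.5, 0.0, 0.9)


class TestPhaseTuning:
    def test_uniform_spikes_give_flat_ratio(self, eupnea_phase, rng):
        _, phase = eupnea_phase
        spikes = rng.uniform(0, 60.0, size=100_000)
        tuning = U.phase_tuning(spikes, phase)
        assert np.all(np.abs(tuning.value - 1.0) < 0.15)
        # occupancy-weighted mean is one by construction
        assert np.sum(tuning.value * tuning.phase_occupancy) == pytest.approx(1.0)

    def test_point_mass_occupies_single_bin(self, eupnea_phase):
        _, phase = eupnea_phase
        from respdyn.breath import bin_phase

        target_bin = 75
        ok = ~np.isnan(phase.phi)
        cand = np.flatnonzero(ok)
        cand = cand[bin_phase(phase.phi[cand]) == target_bin]
        spikes = cand[:50] / 1000.0
        tuning = U.phase_tuning(spikes, phase)
        assert np.count_nonzero(tuning.value) == 1
        assert abs(tuning.preferred_phase - np.pi / 2) < 2 * np.pi / 50

    def test_coherent_unit_peaks_match_designed_phase(self):
        # sharply tuned units over a long record: the typical (median)
        # tuning argmax lands within two phase bins of the designed
        # preferred phase.  Units whose preferred direction points where
        # the latent barely moves have flat-topped curves with an
        # ill-defined argmax, so the median is the robust summary.
        from respdyn import synthetic as syn

        cfg = syn.GroundTruthConfig(
            duration=120.0, n_units=8, seed=13, frac_coherent=1.0,
            emission_gain_range=(1.2, 1.5), baseline_rate_range=(5.0, 15.0),
        )
        ds = syn.generate_dataset(cfg)
        trace = B.DiaphragmTrace(ds.diaphragm, 1000.0)
        table = B.detect_breaths(trace)
        phase = B.compute_phase(table, 1000.0, cfg.duration)
        designed = ds.model_true["designed_preferred_phase"]
        dists = []
        for u in range(8):
            tuning = U.phase_tuning(ds.spikes[u], phase)
            d = abs(tuning.preferred_phase - designed[u])
            dists.append(min(d, 2 * np.pi - d))
        assert np.median(dists) <= 2 * (2 * np.pi / 100) + 1e-9

    def test_zero_spikes_raise_distinct_error(self, eupnea_phase):
        _, phase = eupnea_phase
        with pytest.raises(ValueError, match="no spikes"):
            U.phase_tuning(np.array([]), phase)


class TestCoherence:
    def test_bounds_are_ordered(self, eupnea_small, eupnea_phase):
        trace, _ = eupnea_phase
        res = U.multitaper_coherence_unit(
            eupnea_small.spikes[0], trace, window_s=60.0
        )
        assert 0.0 <= res.c_lb <= res.c <= res.c_ub <= 1.0
        assert np.all(res.lower <= res.coherence + 1e-12)
        assert np.all(res.coherence <= res.upper + 1e-12)

    def test_trace_with_itself_is_coherent(self):
        rng = np.random.default_rng(1)
        t = np.arange(120_000) / 1000.0
        x = np.cos(2 * np.pi * 2.0 * t) + 0.05 * rng.normal(size=len(t))
        res = C.multitaper_coherence(x, x + 0.01 * rng.normal(size=len(t)), 1000.0)
        assert res.c > 0.99 and abs(res.peak_freq - 2.0) < 0.2

    def test_short_record_raises(self):
        with pytest.raises(ValueError, match="segments"):
            C.multitaper_coherence(np.zeros(5000), np.zeros(5000), 1000.0)

    def test_incoherent_generator_population_has_low_clb(self):
        """With no latent-coupled units, the coherence lower bound stays
        below the phasic threshold in nearly all seeds."""
        from respdyn import synthetic as syn

        low = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = syn.GroundTruthConfig(
                duration=300.0, n_units=1, seed=100 + seed, frac_coherent=0.0
            )
            ds = syn.generate_dataset(cfg)
            res = C.spike_field_coherence(ds.spikes[0], ds.diaphragm, 1000.0)
            low += res.c_lb < 0.1
        assert low >= 0.95 * n_seeds


class TestSelectivity:
    def test_uniform_tuning_has_zero_selectivity(self):
        tuning = U.PhasicTuning(np.ones(100), np.full(100, 0.01), 1.0, 1.0)
        assert U.selectivity_index(tuning) == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_has_unit_selectivity(self):
        v = np.zeros(100)
        v[30] = 5.0
        tuning = U.PhasicTuning(v, np.full(100, 0.01), 1.0, 1.0)
        assert U.selectivity_index(tuning) == pytest.approx(1.0, abs=1e-12)

    def test_cosine_tuning_matches_integral_oracle(self):
        # oracle: continuous integral of (1+cos phi) e^{i phi} over
        # (1+cos phi) gives resultant length 1/2
        phi_fine = np.linspace(-np.pi, np.pi, 200_001)
        r_fine = 1 + np.cos(phi_fine)
        oracle = abs(np.trapezoid(r_fine * np.exp(1j * phi_fine), phi_fine)
                     / np.trapezoid(r_fine, phi_fine))
        edges = np.linspace(-np.pi, np.pi, 101)
        centers = 0.5 * (edges[:-1] + edges[1:])
        tuning = U.PhasicTuning(1 + np.cos(centers), np.full(100, 0.01), 1.0, 1.0)
        assert U.selectivity_index(tuning) == pytest.approx(oracle, abs=0.01)
        assert oracle == pytest.approx(0.5, abs=1e-6)

    def test_invariant_to_uniform_rescaling(self, rng):
        v = rng.uniform(0.1, 2.0, size=100)
        t1 = U.PhasicTuning(v, np.full(100, 0.01), 1.0, 1.0)
        t2 = U.PhasicTuning(7.3 * v, np.full(100, 0.01), 1.0, 1.0)
        assert U.selectivity_index(t1) == pytest.approx(U.selectivity_index(t2))

    def test_all_zero_raises(self):
        tuning = U.PhasicTuning(np.zeros(100), np.full(100, 0.01), 0.0, 0.0)
        with pytest.raises(ValueError):
            U.selectivity_index(tuning)


class TestCategories:
    def _coh(self, c_lb, phase_lag=0.5):
        return C.CoherenceResult(
            freqs=np.array([1.0]), coherence=np.array([c_lb]),
            lower=np.array([c_lb]), upper=np.array([1.0]),
            phase=np.array([phase_lag]), c=c_lb + 0.05, c_lb=c_lb,
            c_ub=1.0, peak_freq=1.0, phase_lag=phase_lag,
        )

    def test_low_bound_is_tonic(self):
        cat = U.classify_unit(self._coh(0.05))
        assert not cat.phasic and cat.respiratory_class == "tonic"

    def test_inspiratory_window(self):
        assert U.classify_unit(self._coh(0.5, np.pi / 3)).respiratory_class == (
            "inspiratory"
        )

    def test_expiratory_window(self):
        assert U.classify_unit(self._coh(0.5, -np.pi / 2)).respiratory_class == (
            "expiratory"
        )

    def test_raising_threshold_never_increases_phasic_count(self, rng):
        clbs = rng.uniform(0, 1, 200)
        counts = [
            sum(U.classify_unit(self._coh(c), clb_threshold=t).phasic for c in clbs)
            for t in (0.1, 0.3, 0.5, 0.9)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    @pytest.mark.parametrize(
        "p,frac,tagged",
        [(1e-5, 0.5, True), (1e-5, 0.10, False), (0.01, 0.9, False)],
    )
    def test_opto_tag_rule(self, p, frac, tagged):
        assert U.classify_tagged(p, frac) is tagged
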