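"""Reusable study drivers: the end-to-end computations behind the
package's validation results.

Each driver generates its inputs with the synthetic module, runs the
analysis under study and returns plain-dict summaries.  They back both
the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import breath as B
from . import manifold as M
from . import synthetic as syn
from .coherence import spike_field_coherence
from .rslds import (
    RecurrentSwitchingLDS,
    breath_aligned_average,
    breath_aligned_r2,
    classify_regenerative,
    dropout_analysis,
    fit_diaphragm_decoder,
    simulated_breath_stats,
    state_roles,
)
from scipy.ndimage import gaussian_filter1d


def coherence_calibration(seed: int = 0, duration: float = 300.0,
                          n_null: int = 20) -> dict:
    """Phase-locked versus independent Poisson units.

    A unit firing at 20(1 + cos 2*pi*2.5t) spikes/s against a matched
    2.5-Hz trace must have a high coherence lower bound; homogeneous
    Poisson units independent of the trace must stay below the phasic
    threshold in nearly every seed.
    """
    rate = 1000.0
    t = np.arange(int(duration * rate)) / rate
    f = 2.5
    trace = 1 + np.cos(2 * np.pi * f * t)
    rng = np.random.default_rng(seed)
    lam = 20 * (1 + np.cos(2 * np.pi * f * t)) / rate
    locked_spikes = t[rng.random(len(t)) < lam]
    locked = spike_field_coherence(locked_spikes, trace, rate)
    below = 0
    for k in range(n_null):
        r = np.random.default_rng(seed + 1000 + k)
        sp = np.sort(r.uniform(0, duration, r.poisson(20 * duration)))
        below += spike_field_coherence(sp, trace, rate).c_lb < 0.1
    return {
        "locked_c_lb": float(locked.c_lb),
        "locked_peak_freq": float(locked.peak_freq),
        "null_frac_below_threshold": below / n_null,
    }


def eupnea_pipeline(seed: int, duration: float = 300.0, n_units: int = 150):
    """Detected breaths, phase and coherence-ordered manifold for one
    slow-eupnea recording (the phase-kinematics study conditions)."""
    cfg = syn.eupnea_kinematics_config(seed=seed, duration=duration,
                                       n_units=n_units)
    ds = syn.generate_dataset(cfg)
    trace = B.DiaphragmTrace(ds.diaphragm, ds.diaphragm_rate)
    table = B.detect_breaths(trace)
    phase = B.compute_phase(table, trace.rate, duration)
    rates = M.build_rate_matrix(ds.spikes, duration)
    res = M.fit_population_pca(rates, fit_epoch=(0.0, duration), n_components=10)
    res = M.reorder_by_coherence(res, trace)
    return ds, trace, table, phase, res


def kinematics_study(seed: int = 0, n_recordings: int = 5) -> dict:
    """Phase profiles of trajectory speed and breath-to-breath distance,
    averaged across recordings (as the population figures do), with the
    circular distance of each minimum from the inspiration-offset bin."""
    speeds, dists = [], []
    for k in range(n_recordings):
        _, _, _, phase, res = eupnea_pipeline(seed + 7 + k)
        ts = M.trajectory_stats(res, phase)
        speeds.append(ts.speed)
        dists.append(ts.distance_to_mean)
    speed = np.nanmean(speeds, axis=0)
    dist = np.nanmean(dists, axis=0)

    def circ_from_offset(b):
        # the offset sits on the bin-99/bin-0 boundary (phi = +-pi)
        return int(min((b - 99) % 100, (99 - b) % 100, (b - 0) % 100,
                       (0 - b) % 100))

    return {
        "speed_profile": speed,
        "distance_profile": dist,
        "speed_min_bin": int(np.nanargmin(speed)),
        "distance_min_bin": int(np.nanargmin(dist)),
        "speed_min_offset_distance_bins": circ_from_offset(
            int(np.nanargmin(speed))
        ),
        "distance_min_offset_distance_bins": circ_from_offset(
            int(np.nanargmin(dist))
        ),
        "speed_max_bin": int(np.nanargmax(speed)),
    }


def _fit_and_simulate(ds, duration, seed, n_states=2, max_iter=12,
                      sim_s=60.0):
    model = RecurrentSwitchingLDS.from_spikes(ds.spikes, duration,
                                              n_states=n_states)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(seed=seed, max_iter=max_iter)
    step = int(round(ds.diaphragm_rate * model.bin_width))
    n_bins = model.n_bins
    dia = ds.diaphragm[: n_bins * step].reshape(n_bins, step).mean(1)
    dec = fit_diaphragm_decoder(res.latent, dia, seed=seed)
    x_sim, _ = res.simulate(int(round(sim_s / model.bin_width)), seed=seed)
    sim_dia = dec.decode(x_sim)
    return model, res, dia, sim_dia


def recovery_study(seed: int = 0, n_seeds: int = 10,
                   duration: float = 300.0, n_units: int = 100) -> dict:
    """Parameter recovery of the unstable-spiral / stable-node system.

    Fits the two-state model to ``n_seeds`` generated recordings and
    summarizes eigenvalue-category recovery, inspiratory-modulus error,
    regeneration and simulated breathing rate; also fits the one-state
    control on the first recording (it can only decay).
    """
    per_seed = []
    r2_summary = None
    k1_regen = None
    for k in range(n_seeds):
        cfg = syn.spiral_node_config(seed=seed + 1 + k, duration=duration,
                                     n_units=n_units)
        ds = syn.generate_dataset(cfg)
        model, res, dia, sim_dia = _fit_and_simulate(ds, duration, seed=seed)
        roles = state_roles(res.states, ds.state_true == 1)
        cats = {}
        mods = {}
        for s in range(res.n_states):
            if s < len(roles):
                eig = np.linalg.eigvals(res.taxonomy_dynamics[s])
                cats[roles[s]] = res.state_categories()[s]
                mods[roles[s]] = float(np.abs(eig).max())
        stats = simulated_breath_stats(sim_dia, 1.0 / model.bin_width)
        true_period = float(np.diff(ds.breaths_true.onset.values).mean())
        regen = classify_regenerative(sim_dia, 1.0 / model.bin_width)
        per_seed.append(
            {
                "categories_correct": (
                    cats.get("inspiratory") == "unstable spiral"
                    and cats.get("expiratory") == "stable node"
                ),
                "insp_modulus": mods.get("inspiratory", np.nan),
                "regenerative": bool(regen),
                "rate_ratio": stats["frequency_hz"] * true_period,
            }
        )
        if k == 0:
            # breath-aligned simulated-vs-observed comparison with
            # shuffle controls, on the first recording
            obs_rates = gaussian_filter1d(model.counts, 2.0, axis=1) / 0.01
            obs_al = breath_aligned_average(
                obs_rates, ds.breaths_true.onset.values, 0.01,
                window=(-0.1, 0.25),
            )
            from scipy.signal import find_peaks, peak_widths

            thr = sim_dia.min() + 0.3 * np.ptp(sim_dia)
            pk, _ = find_peaks(sim_dia, height=thr, distance=10)
            sim_onsets = peak_widths(sim_dia, pk, rel_height=0.8)[2] * 0.01
            sim_rates = res.emission_rates(
                res.simulate(len(sim_dia), seed=seed)[0]
            ).T
            sim_al = breath_aligned_average(sim_rates, sim_onsets, 0.01,
                                            window=(-0.1, 0.25))
            r2_summary = breath_aligned_r2(obs_al, sim_al, seed=seed,
                                           n_shuffles=100)
            _, _, _, k1_sim = _fit_and_simulate(ds, duration, seed=seed,
                                                n_states=1)
            k1_regen = bool(classify_regenerative(k1_sim, 100.0))

    true_mod = syn.spiral_node_config().insp_spiral_radius_growth
    mods = [p["insp_modulus"] for p in per_seed]
    ratios = [p["rate_ratio"] for p in per_seed]
    return {
        "per_seed": per_seed,
        "n_categories_correct": int(sum(p["categories_correct"]
                                        for p in per_seed)),
        "n_seeds": n_seeds,
        "insp_modulus_median": float(np.median(mods)),
        "insp_modulus_true": float(true_mod),
        "insp_modulus_median_err_pct": float(
            100 * abs(np.median(mods) - true_mod) / true_mod
        ),
        "n_regenerative": int(sum(p["regenerative"] for p in per_seed)),
        "rate_ratio_median": float(np.median(ratios)),
        "k1_regenerative": k1_regen,
        "r2": r2_summary,
    }


def dropout_study(seed: int = 0, duration: float = 240.0,
                  n_units: int = 60) -> dict:
    """Coherence-ordered unit removal on a half-coherent population.

    Removing the most latent-coupled units first must break regeneration
    with strictly fewer removals than removing the tonic units first.
    The ordering metric is the ground-truth latent coupling strength
    (the generator's analogue of measured coherence).
    """
    cfg = syn.spiral_node_config(seed=seed + 11, duration=duration,
                                 n_units=n_units, frac_coherent=0.5)
    ds = syn.generate_dataset(cfg)
    model = RecurrentSwitchingLDS.from_spikes(ds.spikes, duration)
    step = int(round(ds.diaphragm_rate * model.bin_width))
    dia = ds.diaphragm[: model.n_bins * step].reshape(model.n_bins, step).mean(1)
    metric = np.linalg.norm(ds.model_true["emission_weights"], axis=1)
    schedule = np.arange(0, n_units - 14, 9)
    out = {}
    for order in ("coherence-descending", "coherence-ascending"):
        r = dropout_analysis(
            model.counts, dia, metric, order=order, schedule=schedule,
            seed=seed, fit_kwargs={"max_iter": 8},
        )
        out[order] = {
            "units_to_failure": float(r.units_to_failure),
            "fraction_of_population": float(r.fraction_of_population),
            "logistic_boundary": float(r.logistic_boundary),
            "flags": [bool(f) for f in r.regenerative],
        }
    out["asymmetry_strict"] = (
        out["coherence-descending"]["units_to_failure"]
        < out["coherence-ascending"]["units_to_failure"]
    )
    return out


def sigh_detection_study(seed: int = 0, duration: float = 300.0) -> dict:
    """Sensitivity and precision of the MAD sigh rule on implanted sighs."""
    cfg = syn.GroundTruthConfig(duration=duration, n_units=5, seed=seed + 3,
                                perturbation="sigh")
    ds = syn.generate_dataset(cfg)
    trace = B.DiaphragmTrace(ds.diaphragm, ds.diaphragm_rate)
    table = B.detect_sighs(B.detect_breaths(trace))
    true_on = ds.breaths_true[ds.breaths_true.is_sigh].onset.values
    det_on = table[table.is_sigh].onset.values
    tp = sum(bool(np.any(np.abs(det_on - t) < 0.2)) for t in true_on)
    sensitivity = tp / len(true_on) if len(true_on) else np.nan
    precision = (
        sum(bool(np.any(np.abs(true_on - t) < 0.2)) for t in det_on) / len(det_on)
        if len(det_on) else np.nan
    )
    return {
        "n_true": int(len(true_on)),
        "n_detected": int(len(det_on)),
        "sensitivity": float(sensitivity),
        "precision": float(precision),
    }
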