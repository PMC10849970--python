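"""End-to-end orchestration of the analysis stages.

A :class:`PipelineConfig` fully determines a run (inputs or synthetic
configuration, stage parameters, seeds); :func:`run_pipeline` executes
breath segmentation -> per-unit metrics -> activity clustering ->
manifold statistics -> rSLDS fitting, writes every artifact with
provenance (config hash, seed, package version), and returns a
:class:`RunReport`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from . import synthetic
from .breath import (
    DiaphragmTrace,
    compute_phase,
    detect_breaths,
    detect_gasp_epochs,
    detect_sighs,
    integrate_emg,
)
from .clustering import coherence_threshold_sweep
from .manifold import (
    build_rate_matrix,
    fit_population_pca,
    reorder_by_coherence,
    trajectory_stats,
)
from .rslds import (
    RecurrentSwitchingLDS,
    classify_dynamics,
    classify_regenerative,
    fit_diaphragm_decoder,
    simulated_breath_stats,
)
from .units import unit_metrics_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Complete, serializable description of a pipeline run."""

    # inputs: either file paths or a synthetic-generator configuration
    spikes_path: str | None = None
    emg_path: str | None = None
    emg_rate: float | None = None          # raw EMG rate; None = integrated
    synthetic: dict | None = None          # GroundTruthConfig fields
    out_dir: str = "respdyn_out"
    # stage switches
    run_units: bool = True
    run_clustering: bool = True
    run_manifold: bool = True
    run_rslds: bool = True
    # breath stage
    min_height: float = 0.5
    min_distance_s: float = 0.1
    offset_fraction: float = 0.1
    sigh_window: int = 51
    sigh_mad_factor: float = 7.0
    gasp_window: int = 7
    gasp_start_ibi_s: float = 1.0
    gasp_stop_ibi_s: float = 0.85
    # unit metrics
    coherence_window_s: float = 300.0
    clb_threshold: float = 0.1
    morphine_mode: bool = False            # relaxes QC presence ratio to 0.25
    # clustering
    coherence_thresholds: tuple = (0.0, 0.1, 0.3, 0.5, 0.7, 0.9, 0.99)
    k_min: int = 2
    k_max: int = 15
    n_shuffles: int = 5000
    # manifold
    fit_epoch: tuple | None = None
    # rslds
    rslds_states: int = 2
    rslds_latent: int = 2
    rslds_max_iter: int = 12
    sim_duration_s: float = 40.0
    # randomness
    seed: int = 0

    def to_yaml(self) -> str:
        d = asdict(self)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key in ("coherence_thresholds", "fit_epoch"):
            if isinstance(d.get(key), list):
                d[key] = tuple(d[key])
        return cls(**d)

    def digest(self) -> str:
        """Hash of the analysis parameters (the output path is not part
        of a run's scientific identity)."""
        d = asdict(self)
        d.pop("out_dir")
        text = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage status and headline outputs of a run."""

    config_digest: str
    seed: int
    stages: dict = field(default_factory=dict)
    warnings_: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config_digest": self.config_digest,
            "seed": self.seed,
            "stages": self.stages,
            "warnings": self.warnings_,
        }


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect configuration problems (empty list = valid)."""
    issues: list[str] = []
    if config.synthetic is None:
        if config.spikes_path is None or config.emg_path is None:
            issues.append("either synthetic config or input paths are required")
        else:
            for p in (config.spikes_path, config.emg_path):
                if p and not Path(p).exists():
                    issues.append(f"input file not found: {p}")
    else:
        try:
            synthetic.GroundTruthConfig(**config.synthetic).validate()
        except (TypeError, ValueError) as exc:
            issues.append(f"invalid synthetic config: {exc}")
    if not 0.0 <= config.clb_threshold <= 1.0:
        issues.append("clb_threshold must lie in [0, 1]")
    for thr in config.coherence_thresholds:
        if not 0.0 <= thr <= 1.0:
            issues.append(f"coherence threshold {thr} outside [0, 1]")
    if config.k_max < config.k_min:
        issues.append("k_max must be >= k_min")
    if config.k_min < 2:
        issues.append("k_min must be >= 2")
    for name in ("min_height", "min_distance_s", "sim_duration_s",
                 "coherence_window_s"):
        if getattr(config, name) <= 0:
            issues.append(f"{name} must be positive")
    if not 0 < config.offset_fraction < 1:
        issues.append("offset_fraction must lie in (0, 1)")
    if config.gasp_stop_ibi_s >= config.gasp_start_ibi_s:
        issues.append("gasp stop threshold must be below the start threshold")
    if config.rslds_states not in (1, 2, 3):
        issues.append("rslds_states must be 1, 2 or 3")
    return issues


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        scfg = synthetic.GroundTruthConfig(**config.synthetic)
        if scfg.seed == 0 and config.seed != 0:
            scfg = dataclasses.replace(scfg, seed=config.seed)
        ds = synthetic.generate_dataset(scfg)
        trace = DiaphragmTrace(ds.diaphragm, ds.diaphragm_rate)
        duration = scfg.duration
        return ds.spikes, trace, duration, ds
    spikes = rio.read_spikes(config.spikes_path)
    if config.emg_rate is not None and config.emg_rate >= 10_000:
        raw = pd.read_csv(config.emg_path)["value"].to_numpy(float)
        trace = integrate_emg(raw, config.emg_rate)
    else:
        trace = rio.read_trace(config.emg_path, rate=config.emg_rate)
    duration = trace.duration
    return spikes, trace, duration, None


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the configured stages and write all artifacts.

    A stage failure is recorded in the report (with the remaining
    stages skipped where they depend on it); the report is always
    written to ``<out_dir>/report.json``.
    """
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid configuration: " + "; ".join(issues))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_digest=config.digest(), seed=config.seed)
    (out / "config.yaml").write_text(config.to_yaml())

    spikes, trace, duration, ds = _load_inputs(config)
    rio.write_spikes(spikes, out / "spikes.tsv")
    rio.write_trace(trace, out / "diaphragm.csv")
    report.stages["inputs"] = {
        "n_units": len(spikes),
        "duration_s": duration,
        "synthetic": ds is not None,
    }

    # ---- breath segmentation, phase, event detection -----------------
    breaths = detect_breaths(
        trace,
        min_height=config.min_height,
        min_distance_s=config.min_distance_s,
        offset_fraction=config.offset_fraction,
    )
    if len(breaths) < 2:
        report.stages["breaths"] = {"status": "failed", "n_breaths": len(breaths)}
        rio.write_json(report.to_dict(), out / "report.json")
        return report
    breaths = detect_sighs(
        breaths, window=config.sigh_window, mad_factor=config.sigh_mad_factor
    )
    gasps = detect_gasp_epochs(
        breaths,
        window=config.gasp_window,
        start_ibi_s=config.gasp_start_ibi_s,
        stop_ibi_s=config.gasp_stop_ibi_s,
    )
    phase = compute_phase(breaths, trace.rate, duration, t0=trace.t0)
    breaths.to_csv(out / "breaths.csv", index=False)
    gasps.to_csv(out / "gasp_epochs.csv", index=False)
    report.stages["breaths"] = {
        "status": "ok",
        "n_breaths": int(len(breaths)),
        "n_sighs": int(breaths.is_sigh.sum()),
        "n_gasp_epochs": int(len(gasps)),
        "mean_ibi_s": float(np.nanmean(breaths.ibi.values)),
    }

    metrics = tunings = None
    if config.run_units:
        metrics, tunings = unit_metrics_table(
            spikes, trace, phase,
            window_s=config.coherence_window_s,
            clb_threshold=config.clb_threshold,
        )
        metrics.to_csv(out / "unit_metrics.csv", index=False)
        np.savetxt(out / "tunings.csv",
                   np.vstack([t.value for t in tunings]), delimiter=",")
        counts = metrics.unit_class.value_counts().to_dict()
        report.stages["unit_metrics"] = {
            "status": "ok",
            "n_phasic": int((metrics.c_lb > config.clb_threshold).sum()),
            "class_counts": {k: int(v) for k, v in counts.items()},
        }

    if config.run_clustering and metrics is not None:
        tuning_mat = np.vstack([t.value for t in tunings])
        sweep = coherence_threshold_sweep(
            tuning_mat,
            metrics.c_lb.to_numpy(),
            thresholds=config.coherence_thresholds,
            k_range=range(config.k_min, config.k_max + 1),
            seed=config.seed,
        )
        sweep.to_csv(out / "cluster_sweep.csv", index=False)
        report.stages["clustering"] = {
            "status": "ok" if len(sweep) else "skipped",
            "optimal_k": {
                f"{row.threshold:g}": int(row.optimal_k)
                for row in sweep.itertuples()
            },
        }

    manifold_res = None
    if config.run_manifold:
        rates = build_rate_matrix(spikes, duration)
        manifold_res = fit_population_pca(
            rates, fit_epoch=config.fit_epoch, n_components=10
        )
        manifold_res = reorder_by_coherence(manifold_res, trace)
        ts = trajectory_stats(manifold_res, phase)
        pd.DataFrame(
            {
                "phase_bin": np.arange(100),
                "speed": ts.speed,
                "distance_to_mean": ts.distance_to_mean,
            }
        ).to_csv(out / "trajectory_stats.csv", index=False)
        sp_min = int(np.nanargmin(ts.speed))
        report.stages["manifold"] = {
            "status": "ok",
            "n_components": int(ts.n_components),
            "component_coherence": [
                float(c) for c in manifold_res.component_coherence[:6]
            ],
            "speed_min_bin": sp_min,
            "distance_min_bin": int(np.nanargmin(ts.distance_to_mean)),
        }

    if config.run_rslds:
        model = RecurrentSwitchingLDS.from_spikes(
            spikes, duration,
            n_states=config.rslds_states, n_latent=config.rslds_latent,
        )
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            res = model.fit(seed=config.seed, max_iter=config.rslds_max_iter)
        report.warnings_.extend(str(w.message) for w in wlist)
        step = int(round(trace.rate * model.bin_width))
        n_bins = model.n_bins
        dia_binned = trace.samples[: n_bins * step].reshape(n_bins, step).mean(1)
        decoder = fit_diaphragm_decoder(res.latent, dia_binned, seed=config.seed)
        x_sim, _ = res.simulate(
            int(round(config.sim_duration_s / model.bin_width)), seed=config.seed
        )
        sim_dia = decoder.decode(x_sim)
        regen = classify_regenerative(sim_dia, 1.0 / model.bin_width)
        stats = simulated_breath_stats(sim_dia, 1.0 / model.bin_width)
        insp_mask = phase.phi[:: step][: n_bins] >= 0
        taxonomy = classify_dynamics(res, np.nan_to_num(insp_mask, nan=0) > 0)
        rio.write_rslds(res, out / "rslds_model.json")
        taxonomy.to_csv(out / "rslds_taxonomy.csv", index=False)
        report.stages["rslds"] = {
            "status": "ok",
            "converged": bool(res.converged),
            "regenerative": bool(regen),
            "simulated_rate_hz": stats["frequency_hz"],
            "taxonomy": {
                str(row.role): str(row.category) for row in taxonomy.itertuples()
            },
        }

    rio.write_json(report.to_dict(), out / "report.json")
    return report
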