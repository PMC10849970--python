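"""Reading and writing the pipeline's file formats.

Spike tables are tab-separated (columns ``unit_id, spike_time_s``);
traces are single-column CSV with a JSON sidecar holding the sampling
rate; tables are plain CSV; model parameters and run reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .breath import DiaphragmTrace


def write_spikes(spikes: list[np.ndarray], path: str | Path) -> None:
    rows = [(u, t) for u, st in enumerate(spikes) for t in st]
    pd.DataFrame(rows, columns=["unit_id", "spike_time_s"]).to_csv(
        path, sep="\t", index=False
    )


def read_spikes(path: str | Path) -> list[np.ndarray]:
    """Read a spike table; unit ids index the returned list."""
    df = pd.read_csv(path, sep="\t")
    n = int(df.unit_id.max()) + 1 if len(df) else 0
    return [
        np.sort(df.loc[df.unit_id == u, "spike_time_s"].to_numpy(float))
        for u in range(n)
    ]


def write_trace(trace: DiaphragmTrace, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"value": trace.samples}).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"rate_hz": trace.rate, "t0_s": trace.t0}))


def read_trace(path: str | Path, rate: float | None = None) -> DiaphragmTrace:
    path = Path(path)
    samples = pd.read_csv(path)["value"].to_numpy(float)
    t0 = 0.0
    if rate is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no sampling-rate sidecar {sidecar}; pass rate explicitly"
            )
        meta = json.loads(sidecar.read_text())
        rate = float(meta["rate_hz"])
        t0 = float(meta.get("t0_s", 0.0))
    return DiaphragmTrace(samples, rate, t0)


def write_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=default))


def write_rslds(results, path: str | Path) -> None:
    """Serialize a fitted rSLDS (parameters + metadata, not the paths)."""
    write_json(
        {
            "n_states": results.n_states,
            "n_latent": results.latent.shape[1],
            "bin_width_s": results.model.bin_width,
            "A": results.A,
            "A_identified": results.A_identified,
            "b": results.b,
            "noise_scale": results.noise_scale,
            "transition_weights": results.trans_w,
            "transition_bias": results.trans_b,
            "emission_weights": results.emission_weights,
            "emission_bias": results.emission_bias,
            "seed": results.seed,
            "algorithm": results.algorithm,
            "converged": results.converged,
            "log_objective": results.log_objective,
            "state_categories": results.state_categories(),
        },
        path,
    )
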