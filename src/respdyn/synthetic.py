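"""Synthetic ground-truth datasets for the respiratory-population pipeline.

The generator emulates the statistical structure the analysis assumes: a
two-dimensional latent state that alternates between two linear regimes
(an unstable spiral during inspiration, and an expiratory regime that
contracts onto the inspiratory-off target and then drifts slowly back
toward breath onset), a population of units spiking as inhomogeneous
Poisson processes driven by the latent through an exponential link, and
an integrated diaphragm trace read out from the latent during the
inspiratory regime.

Perturbation modes reshape the latent: ``sigh`` scales designated breath
excursions, ``gasp`` collapses the rotation to a rest point with brief
ballistic efforts, and ``opioid`` time-dilates the dynamics.

All randomness derives from a single seed; per-unit spike streams use
child seed sequences so that unit ``i`` is reproducible independently of
``n_units``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

INSPIRATION = 1
EXPIRATION = 0

_PERTURBATIONS = ("none", "sigh", "gasp", "opioid")


class DivergenceError(RuntimeError):
    """Raised when the latent leaves the guard radius without switching."""


@dataclass
class GroundTruthConfig:
    """Parameters of the generative model.

    The default configuration produces slow eupnea-like breathing with a
    1.5-s period (0.4 s inspiration), chosen so that each of the 100
    respiratory phase bins spans several samples of the 5-ms rate grid
    used downstream.

    Parameters
    ----------
    duration : float
        Recording length, seconds.
    latent_dt : float
        Latent integration step, seconds.
    n_units : int
        Number of simulated units.
    frac_coherent : float
        Fraction of units whose emission weights couple to the latent;
        the remainder are tonic (rate independent of the latent).
    insp_duration_s, exp_duration_s : float
        Designed durations of the inspiratory and expiratory regimes.
    insp_spiral_radius_growth : float
        Per-step eigenvalue modulus of the inspiratory spiral (>1 for an
        unstable spiral).
    exp_mode : {"saddle", "node"}
        Expiratory regime geometry.  ``saddle`` (default eupnea)
        contracts onto the inspiratory-off target along one direction
        while a weakly expanding direction carries the pre-inspiratory
        drift back to onset.  ``node`` is a stable node whose fixed
        point lies across the onset boundary, so the latent decays
        through the boundary and re-enters the spiral.
    exp_eigenvalues : tuple of float or None
        Real eigenvalue pair of the expiratory dynamics.  ``None``
        derives the slow eigenvalue from ``exp_duration_s`` (saddle
        mode) or uses ``(0.92, 0.78)`` (node mode).
    emission_gain_range : tuple of float
        Range of per-unit latent coupling norms (log-rate units per unit
        latent amplitude).
    baseline_rate_range : tuple of float
        Range of per-unit baseline rates, spikes/s.
    dynamics_noise_sd : float
        Isotropic dynamics noise per latent step.
    diaphragm_noise_sd : float
        Additive Gaussian noise on the diaphragm readout, as a fraction
        of the noise-free trace standard deviation.
    perturbation : {"none", "sigh", "gasp", "opioid"}
    sigh_every : int
        In sigh mode, every ``sigh_every``-th breath is a sigh.
    sigh_scale : float
        Latent amplitude scale of sigh breaths.
    sigh_gain : float
        Extra diaphragm readout gain on sigh breaths (total amplitude
        scaling is ``sigh_scale * sigh_gain``).
    gasp_interval_range : tuple of float
        Range of inter-gasp intervals, seconds (all > 1 s).
    opioid_dilation : float
        Time-dilation factor of the latent update in opioid mode.
    seed : int
        Seed determining every random draw.
    """

    duration: float = 300.0
    latent_dt: float = 0.01
    n_units: int = 150
    frac_coherent: float = 0.6
    insp_duration_s: float = 0.65
    exp_duration_s: float = 1.15
    insp_spiral_radius_growth: float | None = None
    exp_mode: str = "saddle"
    exp_eigenvalues: tuple[float, float] | None = None
    exp_node_p1: float = 1.5
    exp_node_coupling: float = 0.1
    exp_node_fast: float = 0.5
    saddle_x1: float = -2.6
    onset_radius: float = 1.0
    onset_jitter_sd: float = 0.0
    offset_radius_factor: float = 2.0
    emission_center: tuple[float, float] = (0.0, 0.0)
    emission_gain_range: tuple[float, float] = (0.45, 0.8)
    baseline_rate_range: tuple[float, float] = (8.0, 25.0)
    dynamics_noise_sd: float = 0.002
    diaphragm_noise_sd: float = 0.05
    diaphragm_rate: float = 1000.0
    readout_angle: float = np.pi / 2.0
    readout_bias: float = 0.2
    perturbation: str = "none"
    sigh_every: int = 20
    sigh_scale: float = 2.0
    sigh_gain: float = 6.0
    gasp_interval_range: tuple[float, float] = (1.5, 3.0)
    gasp_amplitude: float = 2.5
    gasp_effort_s: float = 0.16
    opioid_dilation: float = 1.5
    max_rate_hz: float = 1000.0
    guard_radius_factor: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.latent_dt <= 0:
            raise ValueError("latent_dt must be > 0")
        if not 0.0 <= self.frac_coherent <= 1.0:
            raise ValueError("frac_coherent must lie in [0, 1]")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.perturbation not in _PERTURBATIONS:
            raise ValueError(
                f"unknown perturbation {self.perturbation!r}; "
                f"expected one of {_PERTURBATIONS}"
            )
        if self.exp_mode not in ("saddle", "node"):
            raise ValueError("exp_mode must be 'saddle' or 'node'")
        if self.gasp_interval_range[0] <= 1.0 + self.gasp_effort_s:
            raise ValueError("gasp intervals must exceed 1 s plus the effort")

    # -- derived design quantities -------------------------------------
    @property
    def n_insp_steps(self) -> int:
        return max(2, int(round(self.insp_duration_s / self.latent_dt)))

    @property
    def n_exp_steps(self) -> int:
        return max(2, int(round(self.exp_duration_s / self.latent_dt)))

    @property
    def spiral_omega(self) -> float:
        """Rotation per step: half a turn over the designed inspiration."""
        return np.pi / self.n_insp_steps

    @property
    def offset_radius(self) -> float:
        if self.exp_mode == "node" or self.insp_spiral_radius_growth is not None:
            log_r = self.n_insp_steps * np.log(self.spiral_rho)
            if log_r > 700:
                return np.inf
            return self.onset_radius * np.exp(log_r)
        return self.onset_radius * self.offset_radius_factor

    @property
    def exp_travel_eigenvalue(self) -> float:
        """Slowly expanding saddle eigenvalue carrying the drift from the
        offset radius back to the onset half-plane over exp_duration_s."""
        d0 = self.offset_radius + self.saddle_x1
        travel = (self.onset_radius - self.saddle_x1) / max(-d0, 1e-12)
        return float(travel) ** (1.0 / self.n_exp_steps)

    @property
    def spiral_rho(self) -> float:
        """Per-step modulus of the inspiratory spiral.

        By default (saddle eupnea) the modulus is set so the *mean*
        onset radius -- onset threshold plus half the expected crossing
        overshoot -- grows to the designed offset radius in exactly half
        a rotation, keeping the offset aligned with the spiral's half
        turn.
        """
        if self.insp_spiral_radius_growth is not None:
            return self.insp_spiral_radius_growth
        if self.exp_mode == "node":
            return 1.04
        lam_u = self.exp_travel_eigenvalue
        onset_mean = self.onset_radius + 0.5 * (lam_u - 1.0) * (
            self.onset_radius - self.saddle_x1
        )
        return (self.offset_radius / onset_mean) ** (1.0 / self.n_insp_steps)

    @property
    def designed_period_s(self) -> float:
        base = (self.n_insp_steps + self.n_exp_steps) * self.latent_dt
        if self.perturbation == "opioid":
            return base * self.opioid_dilation
        return base

    def insp_dynamics(self) -> tuple[np.ndarray, np.ndarray]:
        rho, om = self.spiral_rho, self.spiral_omega
        a = rho * np.array([[np.cos(om), -np.sin(om)], [np.sin(om), np.cos(om)]])
        return a, np.zeros(2)

    def exp_dynamics(self) -> tuple[np.ndarray, np.ndarray]:
        """Expiratory regime (A, b).

        In node mode the regime is a shear-coupled stable node
        A = [[lam_slow, 0], [kappa, lam_fast]] whose fixed point sits on
        the inspiratory side of the half-plane boundary x2 > 0.  Its
        slow manifold x2*(x1) dips below the boundary at breath offset
        and re-crosses it at the onset radius, so the cycle regenerates
        under a purely linear, memoryless switching rule -- exactly the
        recurrent rule a fitted switching model expresses.  The slow
        eigenvalue is derived from ``exp_duration_s``; the fast one is
        ``exp_node_fast``.
        """
        if self.exp_mode == "node":
            p1, kap = self.exp_node_p1, self.exp_node_coupling
            if self.exp_eigenvalues is not None:
                lam_slow, lam_fast = self.exp_eigenvalues
            else:
                lam_fast = self.exp_node_fast
                frac = (p1 - self.onset_radius) / (p1 + self.offset_radius)
                lam_slow = float(frac) ** (1.0 / self.n_exp_steps)
            # fixed point placed so the slow manifold crosses x2 = 0 at
            # the onset radius
            p2 = kap * (p1 - self.onset_radius) / (1.0 - lam_fast)
            a = np.array([[lam_slow, 0.0], [kap, lam_fast]])
            p = np.array([p1, p2])
        else:
            if self.exp_eigenvalues is not None:
                lam = self.exp_eigenvalues
            else:
                lam = (self.exp_travel_eigenvalue, 0.01)
            a = np.diag(lam).astype(float)
            p = np.array([self.saddle_x1, 0.0])
        b = (np.eye(2) - a) @ p
        return a, b


@dataclass
class SyntheticDataset:
    """A generated recording with full ground truth."""

    config: GroundTruthConfig
    latent_true: np.ndarray          # (T, 2)
    state_true: np.ndarray           # (T,) in {INSPIRATION, EXPIRATION}
    spikes: list[np.ndarray]         # per-unit spike times, s
    diaphragm: np.ndarray            # integrated trace at diaphragm_rate
    diaphragm_rate: float
    breaths_true: pd.DataFrame       # columns onset, offset (+ is_sigh / is_gasp)
    model_true: dict                 # generating parameters

    @property
    def latent_times(self) -> np.ndarray:
        return np.arange(len(self.latent_true)) * self.config.latent_dt

    def write(self, outdir: str | Path) -> None:
        """Write spikes (TSV), diaphragm (CSV + sidecar) and ground truth."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = [
            (u, t) for u, st in enumerate(self.spikes) for t in st
        ]
        pd.DataFrame(rows, columns=["unit_id", "spike_time_s"]).to_csv(
            outdir / "spikes.tsv", sep="\t", index=False
        )
        pd.DataFrame({"value": self.diaphragm}).to_csv(
            outdir / "diaphragm.csv", index=False
        )
        (outdir / "diaphragm.csv.json").write_text(
            json.dumps({"rate_hz": self.diaphragm_rate, "t0_s": 0.0})
        )
        self.breaths_true.to_csv(outdir / "breaths_true.csv", index=False)
        meta = {
            "diaphragm_rate": self.diaphragm_rate,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.config).items()
            },
            "model_true": {
                k: np.asarray(v).tolist() if isinstance(v, (np.ndarray, list)) else v
                for k, v in self.model_true.items()
                if k != "template_cycle"
            },
        }
        (outdir / "ground_truth.json").write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# latent dynamics
# ---------------------------------------------------------------------------

def generate_latent(
    config: GroundTruthConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the two-regime latent and its discrete state sequence.

    The discrete state at step ``t`` is a recurrent function of the
    latent at ``t - 1``.  In the default (saddle) eupnea it is
    hysteretic: inspiration ends when the spiral, after at least half a
    rotation, crosses the designed offset radius, and expiration ends
    when the drift axis crosses the onset half-plane
    ``x1 >= onset_radius``.  In node mode the rule is memoryless --
    inspiration is simply the half-plane ``x2 > 0`` -- so the true
    switching rule lies inside the model class a recurrent switching
    fit can express.

    Returns ``(latent, state)`` with shapes ``(T, 2)`` and ``(T,)``.
    """
    x, z, _ = _generate_latent_full(config, rng)
    return x, z


def _generate_latent_full(
    config: GroundTruthConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    if config.perturbation == "gasp":
        x, z = _generate_gasp_latent(config, rng)
        return x, z, None

    n_steps = int(round(config.duration / config.latent_dt))
    a_i, b_i = config.insp_dynamics()
    a_e, b_e = config.exp_dynamics()
    guard = config.guard_radius_factor * config.onset_radius
    sigh_mode = config.perturbation == "sigh"
    dilation = config.opioid_dilation if config.perturbation == "opioid" else 1.0

    x = np.empty((n_steps, 2))
    z = np.empty(n_steps, dtype=np.int8)
    xi = np.array([config.onset_radius, 0.0])
    r_on_cur = config.onset_radius
    state = INSPIRATION
    armed = False            # inspiration: past half rotation
    breath_index = 0
    scale = 1.0              # sigh amplitude scale of the current breath
    acc = 1.0                # time-dilation accumulator
    noise = rng.normal(0.0, config.dynamics_noise_sd, size=(n_steps, 2))

    if sigh_mode:
        scale = config.sigh_scale if breath_index % config.sigh_every == 0 else 1.0
        xi = xi * scale
    sigh_flags: list[bool] = []

    node_mode = config.exp_mode == "node"
    for t in range(n_steps):
        # recurrent switch: state chosen from the previous latent
        r = float(np.hypot(*xi))
        if node_mode:
            new_state = INSPIRATION if xi[1] > 0 else EXPIRATION
            if new_state == INSPIRATION and state == EXPIRATION:
                breath_index += 1
            state = new_state
        elif state == INSPIRATION:
            if not armed and np.arctan2(xi[1], xi[0]) > np.pi / 2:
                armed = True
            if armed and r >= config.offset_radius * scale:
                state, armed = EXPIRATION, False
        else:
            if xi[0] >= r_on_cur:
                state = INSPIRATION
                breath_index += 1
                if config.onset_jitter_sd > 0:
                    r_on_cur = config.onset_radius * (
                        1.0 + rng.normal(0.0, config.onset_jitter_sd)
                    )
                if sigh_mode:
                    new_scale = (
                        config.sigh_scale
                        if breath_index % config.sigh_every == 0
                        else 1.0
                    )
                    xi = xi * (new_scale / 1.0)
                    scale = new_scale
        acc += 1.0 / dilation
        if acc >= 1.0:
            acc -= 1.0
            if state == INSPIRATION:
                xi = a_i @ xi + b_i * scale + noise[t]
            else:
                if sigh_mode and scale != 1.0:
                    # saddle scaled with the breath so the return path matches
                    p = np.linalg.solve(np.eye(2) - a_e, b_e) * scale
                    xi = a_e @ (xi - p) + p + noise[t]
                    if xi[0] >= 0:
                        scale = 1.0  # sigh excursion has returned
                else:
                    xi = a_e @ xi + b_e + noise[t]
        x[t] = xi
        z[t] = state
        if sigh_mode:
            sigh_flags.append(scale != 1.0)
        if np.hypot(*xi) > guard:
            raise DivergenceError(
                f"latent exceeded guard radius {guard:.1f} at step {t} "
                f"({t * config.latent_dt:.2f} s) without reaching the switch "
                "boundary"
            )
    return x, z, (np.asarray(sigh_flags) if sigh_mode else None)


def _generate_gasp_latent(
    config: GroundTruthConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Rest point plus brief, symmetric ballistic excursions."""
    n_steps = int(round(config.duration / config.latent_dt))
    x = rng.normal(0.0, config.dynamics_noise_sd, size=(n_steps, 2))
    z = np.full(n_steps, EXPIRATION, dtype=np.int8)
    u = np.array([np.cos(1.2), np.sin(1.2)])
    n_half = max(2, int(round(config.gasp_effort_s / 2 / config.latent_dt)))
    ramp = np.concatenate(
        [np.linspace(0, 1, n_half, endpoint=False), np.linspace(1, 0, n_half + 1)]
    )
    t = int(round(1.0 / config.latent_dt))  # settle before the first gasp
    while t + len(ramp) < n_steps:
        seg = slice(t, t + len(ramp))
        x[seg] += np.outer(ramp * config.gasp_amplitude, u)
        z[seg][ramp > 0] = INSPIRATION
        gap = rng.uniform(*config.gasp_interval_range)
        t += len(ramp) + int(round(gap / config.latent_dt))
    return x, z


def breaths_from_state(
    state: np.ndarray,
    dt: float,
    sigh_flags: np.ndarray | None = None,
    min_duration_s: float = 0.03,
) -> pd.DataFrame:
    """Extract true breath onset/offset times from the state sequence.

    Episodes shorter than ``min_duration_s`` (either state) are merged
    into their neighbours: near a memoryless switching boundary the
    dynamics noise can produce brief chatter that is not a breath.
    """
    s = np.asarray(state) == INSPIRATION
    min_len = max(1, int(round(min_duration_s / dt)))
    s = s.copy()
    for target in (True, False):
        edges = np.flatnonzero(np.diff(s.astype(int)) != 0) + 1
        bounds = np.concatenate([[0], edges, [len(s)]])
        for a, bnd in zip(bounds[:-1], bounds[1:]):
            if s[a] == target and bnd - a < min_len:
                s[a:bnd] = not target
    edges = np.diff(s.astype(int))
    onsets = np.flatnonzero(edges == 1) + 1
    offsets = np.flatnonzero(edges == -1) + 1
    if s[0]:
        onsets = np.insert(onsets, 0, 0)
    # keep only complete breaths
    pairs = []
    for on in onsets:
        nxt = offsets[offsets > on]
        if len(nxt):
            pairs.append((on, nxt[0]))
    df = pd.DataFrame(pairs, columns=["onset_step", "offset_step"])
    df["onset"] = df.onset_step * dt
    df["offset"] = df.offset_step * dt
    if sigh_flags is not None:
        df["is_sigh"] = [bool(sigh_flags[on]) for on in df.onset_step]
    return df


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def generate_spikes(
    latent_true: np.ndarray,
    config: GroundTruthConfig,
    seed_seq: np.random.SeedSequence | None = None,
) -> tuple[list[np.ndarray], dict]:
    """Draw per-unit spike trains from an inhomogeneous Poisson model.

    Each unit fires with rate ``baseline * exp(c . x_t)`` held constant
    within each latent step; the count in a bin is Poisson with that
    mean and spike times are placed uniformly within the bin (exact for
    piecewise-constant rates).  Coherent units have ``|c| > 0`` with a
    random preferred direction; tonic units have ``c = 0``.

    Returns the spike-time lists and the true emission parameters.
    """
    config.validate()
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(config.seed).spawn(2)[1]
    param_rng = np.random.default_rng(seed_seq)
    child_seqs = seed_seq.spawn(config.n_units)

    n = config.n_units
    n_coh = int(round(config.frac_coherent * n))
    coherent = np.zeros(n, dtype=bool)
    coherent[param_rng.permutation(n)[:n_coh]] = True
    gains = param_rng.uniform(*config.emission_gain_range, size=n)
    angles = param_rng.uniform(-np.pi, np.pi, size=n)
    baselines = param_rng.uniform(*config.baseline_rate_range, size=n)
    c = np.where(
        coherent[:, None],
        gains[:, None] * np.stack([np.cos(angles), np.sin(angles)], axis=1),
        0.0,
    )

    dt = config.latent_dt
    center = np.asarray(config.emission_center, float)
    log_rate = (latent_true - center) @ c.T  # (T, n)
    rates_hz = baselines[None, :] * np.exp(log_rate)
    too_fast = rates_hz.max(axis=0) > config.max_rate_hz
    if too_fast.any():
        bad = int(np.flatnonzero(too_fast)[0])
        raise ValueError(
            f"emission rate overflow: unit {bad} reaches "
            f"{rates_hz[:, bad].max():.0f} spikes/s "
            f"(limit {config.max_rate_hz:.0f}); reduce its gain"
        )
    spikes: list[np.ndarray] = []
    for u in range(n):
        rng_u = np.random.default_rng(child_seqs[u])
        counts = rng_u.poisson(rates_hz[:, u] * dt)
        idx = np.repeat(np.arange(len(counts)), counts)
        times = (idx + rng_u.uniform(size=idx.size)) * dt
        spikes.append(np.sort(times))
    model_true = {
        "coherent": coherent,
        "emission_weights": c,
        "emission_gain": gains,
        "preferred_direction": angles,
        "baseline_rate_hz": baselines,
    }
    return spikes, model_true


# ---------------------------------------------------------------------------
# diaphragm
# ---------------------------------------------------------------------------

def generate_diaphragm(
    latent_true: np.ndarray,
    state_true: np.ndarray,
    config: GroundTruthConfig,
    rng: np.random.Generator | None = None,
    sigh_flags: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Integrated diaphragm trace: rectified latent readout, gated by state.

    The readout is ``max(0, w . x)`` with ``w`` a fixed unit vector,
    active only during the inspiratory state, linearly upsampled to
    ``diaphragm_rate``, with additive Gaussian noise of standard
    deviation ``diaphragm_noise_sd`` (relative to the noise-free trace
    s.d.), and finally normalized to unit standard deviation.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    dt = config.latent_dt
    w = np.array([np.cos(config.readout_angle), np.sin(config.readout_angle)])
    # affine readout with a positive bias: the diaphragm is recruited
    # abruptly at breath onset, so the gated trace steps up at the state
    # switch rather than rising from zero
    raw = np.maximum(0.0, latent_true @ w + config.readout_bias)
    raw = raw * (state_true == INSPIRATION)
    if sigh_flags is not None:
        raw = raw * np.where(sigh_flags, config.sigh_gain, 1.0)

    n_out = int(round(config.duration * config.diaphragm_rate))
    t_out = np.arange(n_out) / config.diaphragm_rate
    t_lat = np.arange(len(raw)) * dt
    trace = np.interp(t_out, t_lat, raw)
    # re-impose the state gate at full resolution so expiration is exactly 0
    state_hi = np.asarray(state_true)[
        np.minimum((t_out / dt).astype(int), len(raw) - 1)
    ]
    trace = trace * (state_hi == INSPIRATION)

    clean_sd = trace.std()
    if clean_sd == 0:
        clean_sd = 1.0
    if config.diaphragm_noise_sd > 0:
        trace = trace + rng.normal(
            0.0, config.diaphragm_noise_sd * clean_sd, size=trace.shape
        )
    sd = trace.std()
    if sd > 0:
        trace = trace / sd
    breaths = breaths_from_state(state_true, dt, sigh_flags)
    return trace, breaths


# ---------------------------------------------------------------------------
# dataset assembly and perturbations
# ---------------------------------------------------------------------------

def _template_cycle(config: GroundTruthConfig) -> tuple[np.ndarray, np.ndarray]:
    """One noise-free breath cycle of the designed dynamics (for ground
    truth such as per-unit designed preferred phase)."""
    quiet = GroundTruthConfig(**{**asdict(config), "dynamics_noise_sd": 0.0,
                                 "perturbation": "none",
                                 "duration": 6 * config.designed_period_s})
    x, z = generate_latent(quiet, np.random.default_rng(0))
    br = breaths_from_state(z, quiet.latent_dt)
    if len(br) < 3:
        return x, z
    on, nxt = int(br.onset_step.iloc[-2]), int(br.onset_step.iloc[-1])
    return x[on:nxt], z[on:nxt]


def designed_preferred_phase(
    config: GroundTruthConfig,
    model_true: dict,
    latent: np.ndarray,
    state: np.ndarray,
) -> np.ndarray:
    """Per-unit phase of maximal expected rate over the generated latent.

    The expectation is over the generator's own latent noise (the
    phase-binned mean of the true, spike-free rates), so it is exactly
    the quantity a tuning-curve estimate converges to.  Phase is 0 at
    onset, +pi at offset and (-pi, 0) during expiration.
    """
    br = breaths_from_state(state, config.latent_dt)
    t = len(latent)
    phi = np.full(t, np.nan)
    ons, offs = br.onset_step.values, br.offset_step.values
    for i in range(len(br) - 1):
        a, b, c = int(ons[i]), int(offs[i]), int(ons[i + 1])
        phi[a:b] = np.linspace(0, np.pi, b - a, endpoint=False)
        phi[b:c] = np.linspace(-np.pi, 0, c - b, endpoint=False)
    ok = ~np.isnan(phi)
    bins = np.clip(((phi[ok] + np.pi) / (2 * np.pi) * 100).astype(int), 0, 99)
    center = np.asarray(config.emission_center, float)
    rates = np.exp((latent[ok] - center) @
                   np.asarray(model_true["emission_weights"]).T)
    counts = np.bincount(bins, minlength=100).astype(float)
    counts[counts == 0] = np.nan
    binned = np.empty((100, rates.shape[1]))
    for u in range(rates.shape[1]):
        binned[:, u] = np.bincount(bins, weights=rates[:, u],
                                   minlength=100) / counts
    centers = np.linspace(-np.pi, np.pi, 101)[:-1] + np.pi / 100
    return centers[np.nanargmax(binned, axis=0)]


def generate_dataset(config: GroundTruthConfig) -> SyntheticDataset:
    """Generate a complete synthetic recording from a single seed."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    seq_latent, seq_units, seq_diaphragm = root.spawn(3)
    x, z, sigh_flags = _generate_latent_full(config, np.random.default_rng(seq_latent))
    spikes, model_true = generate_spikes(x, config, seq_units)
    trace, breaths = generate_diaphragm(
        x, z, config, np.random.default_rng(seq_diaphragm), sigh_flags
    )
    model_true = dict(model_true)
    model_true["A_insp"], model_true["b_insp"] = config.insp_dynamics()
    model_true["A_exp"], model_true["b_exp"] = config.exp_dynamics()
    model_true["designed_period_s"] = config.designed_period_s
    model_true["designed_preferred_phase"] = designed_preferred_phase(
        config, model_true, x, z
    )
    if config.perturbation == "gasp":
        breaths["is_gasp"] = True
    return SyntheticDataset(
        config=config,
        latent_true=x,
        state_true=z,
        spikes=spikes,
        diaphragm=trace,
        diaphragm_rate=config.diaphragm_rate,
        breaths_true=breaths,
        model_true=model_true,
    )


def apply_perturbation(dataset: SyntheticDataset, mode: str) -> SyntheticDataset:
    """Regenerate ``dataset`` under a perturbation mode.

    Perturbations are generative (they reshape the latent dynamics), so
    this re-runs the generator with the same seed and configuration but
    ``perturbation=mode``.
    """
    if mode not in ("sigh", "gasp", "opioid"):
        raise ValueError(f"unknown perturbation mode {mode!r}")
    cfg = GroundTruthConfig(**{**asdict(dataset.config), "perturbation": mode})
    return generate_dataset(cfg)


def eupnea_kinematics_config(
    seed: int = 0, duration: float = 300.0, n_units: int = 150, **overrides
) -> GroundTruthConfig:
    """Slow-eupnea study configuration for phase-resolved manifold
    statistics.

    The default (saddle) breath geometry with a strongly driven, mostly
    coherent population: per-bin firing is high enough that the
    deterministic trajectory speed clears the Poisson noise floor of
    the 5-ms rate estimates, so the designed phase profile of speed and
    breath-to-breath variability is measurable.
    """
    base = dict(
        duration=duration,
        n_units=n_units,
        seed=seed,
        frac_coherent=0.75,
        baseline_rate_range=(20.0, 60.0),
        emission_gain_range=(0.6, 1.0),
    )
    base.update(overrides)
    return GroundTruthConfig(**base)


def spiral_node_config(
    seed: int = 0,
    duration: float = 300.0,
    n_units: int = 100,
    frac_coherent: float = 0.8,
    **overrides,
) -> GroundTruthConfig:
    """Unstable-spiral / stable-node study configuration.

    Breathing at ~2.9 Hz with a 0.12-s inspiratory half-rotation
    (per-step spiral modulus 1.06) and a shear-coupled stable-node
    expiration whose switching rule is a memoryless half-plane, so the
    generating system lies inside the recurrent switching model class.
    Used for the dynamics-recovery, regeneration and dropout studies.
    """
    base = dict(
        duration=duration,
        n_units=n_units,
        seed=seed,
        exp_mode="node",
        insp_duration_s=0.12,
        exp_duration_s=0.2,
        insp_spiral_radius_growth=1.06,
        frac_coherent=frac_coherent,
        baseline_rate_range=(15.0, 35.0),
        emission_gain_range=(0.75, 1.0),
        dynamics_noise_sd=0.02,
    )
    base.update(overrides)
    return GroundTruthConfig(**base)


# ---------------------------------------------------------------------------
# tuning-curve archetype family (for clustering studies)
# ---------------------------------------------------------------------------

def make_archetype_tunings(
    n_per_class: int = 30,
    noise_sd: float = 0.05,
    clb_values: tuple[float, float, float] = (0.95, 0.95, 0.3),
    kappa: float = 4.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthetic phase-tuning curves from three archetypes.

    Archetypes are an inspiratory bump (von Mises centred at +pi/2), an
    expiratory bump (centred at -pi/2) and a flat weakly-modulated
    profile.  Each unit carries a nominal coherence lower bound
    (``clb_values`` per class; strong for the phasic archetypes, weak
    for the flat one) standing in for the measured value, so that
    coherence-threshold sweeps can be exercised on a known family.

    Returns ``(tunings, c_lb, labels)`` with ``tunings`` of shape
    ``(3 * n_per_class, 100)``.
    """
    rng = np.random.default_rng(seed)
    phi = (np.arange(100) + 0.5) / 100 * 2 * np.pi - np.pi
    shapes = [
        np.exp(kappa * np.cos(phi - np.pi / 2)),
        np.exp(kappa * np.cos(phi + np.pi / 2)),
        np.ones_like(phi),
    ]
    rows, clbs, labels = [], [], []
    for k, shape in enumerate(shapes):
        base = shape / shape.max()
        for _ in range(n_per_class):
            rows.append(np.maximum(base + rng.normal(0, noise_sd, size=100), 0.0))
            clbs.append(clb_values[k] + rng.normal(0, 0.01))
            labels.append(k)
    return np.asarray(rows), np.clip(np.asarray(clbs), 0, 1), np.asarray(labels)
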