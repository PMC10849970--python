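"""Population-manifold analysis: rate preprocessing, PCA, trajectory
statistics, subspace comparison and pairwise-correlation structure.

Spike trains are binned at 5 ms, smoothed with a 10-ms Gaussian kernel
and square-root transformed; PCA is fitted on a designated epoch
(typically the 100% O2 baseline) and applied to the whole recording.
Components are reordered by their multitaper coherence with the
integrated diaphragm -- the leading reordered component is the most
respiratory one regardless of variance -- and trajectory statistics
(speed and distance to the mean trajectory) are accumulated in the 100
standard respiratory phase bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .breath import DiaphragmTrace, PhaseSignal, bin_phase
from .coherence import multitaper_coherence


@dataclass
class RateMatrix:
    """Units x time-bins matrix of transformed rates."""

    rates: np.ndarray
    bin_width: float = 0.005
    kernel_sd: float = 0.010

    @property
    def n_units(self) -> int:
        return self.rates.shape[0]

    @property
    def times(self) -> np.ndarray:
        return (np.arange(self.rates.shape[1]) + 0.5) * self.bin_width


@dataclass
class ManifoldResult:
    """A fitted population PCA and its projections."""

    loadings: np.ndarray            # (units, components), orthonormal columns
    projections: np.ndarray         # (components, time)
    explained_variance: np.ndarray  # per component
    mean: np.ndarray                # fit-epoch mean, per unit
    bin_width: float
    fit_epoch: tuple[float, float]
    coherence_order: np.ndarray | None = None
    component_coherence: np.ndarray | None = None

    def reordered_projections(self, n_components: int | None = None) -> np.ndarray:
        order = (
            self.coherence_order
            if self.coherence_order is not None
            else np.arange(self.projections.shape[0])
        )
        out = self.projections[order]
        return out if n_components is None else out[:n_components]


@dataclass
class TrajectoryStats:
    """Phase-binned trajectory statistics (100 bins of width pi/50)."""

    mean_trajectory: np.ndarray     # (100, d)
    speed: np.ndarray               # (100,) NaN where unsampled
    distance_to_mean: np.ndarray    # (100,)
    n_components: int


def build_rate_matrix(
    spikes: list[np.ndarray],
    duration: float,
    bin_width: float = 0.005,
    kernel_sd: float = 0.010,
) -> RateMatrix:
    """Bin, smooth and square-root transform the population spike trains.

    5-ms bins, Gaussian kernel of 10-ms standard deviation, then an
    element-wise square root (a variance-stabilizing transform for
    Poisson counts).
    """
    n_bins = int(round(duration / bin_width))
    rates = np.zeros((len(spikes), n_bins))
    for i, st in enumerate(spikes):
        idx = np.floor(np.asarray(st) / bin_width).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        np.add.at(rates[i], idx, 1.0)
    rates = gaussian_filter1d(rates, kernel_sd / bin_width, axis=1)
    return RateMatrix(np.sqrt(np.maximum(rates, 0.0)), bin_width, kernel_sd)


def fit_population_pca(
    rates: RateMatrix,
    fit_epoch: tuple[float, float] | None = None,
    n_components: int | None = None,
) -> ManifoldResult:
    """PCA fitted on ``fit_epoch`` and applied to the whole recording.

    Centering uses the fit-epoch mean throughout, so shifts of the
    population state in other epochs remain visible in the projections.
    """
    x = rates.rates
    total_s = x.shape[1] * rates.bin_width
    if fit_epoch is None:
        fit_epoch = (0.0, total_s)
    a = int(round(fit_epoch[0] / rates.bin_width))
    b = int(round(fit_epoch[1] / rates.bin_width))
    if (b - a) * rates.bin_width < 10.0:
        raise ValueError("fit epoch must be at least 10 s long")
    fit = x[:, a:b]
    mean = fit.mean(axis=1)
    centred = fit - mean[:, None]
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    var = s**2 / (fit.shape[1] - 1)
    if n_components is not None:
        u, var = u[:, :n_components], var[:n_components]
    projections = u.T @ (x - mean[:, None])
    return ManifoldResult(
        loadings=u,
        projections=projections,
        explained_variance=var,
        mean=mean,
        bin_width=rates.bin_width,
        fit_epoch=fit_epoch,
    )


def reorder_by_coherence(
    result: ManifoldResult,
    trace: DiaphragmTrace,
    segment_s: float = 10.0,
    freq_range: tuple[float, float] = (0.5, 8.0),
    max_components: int | None = 20,
) -> ManifoldResult:
    """Score each component's respiratory coherence and sort descending.

    Uses the continuous-continuous multitaper estimator (NW = 3, 5
    tapers) between each component time course and the integrated
    diaphragm resampled onto the component timebase.  The permutation is
    stored on the result (``coherence_order``); projections themselves
    are left untouched.
    """
    step = int(round(trace.rate * result.bin_width))
    dia = trace.samples[:: step]
    n = min(dia.shape[0], result.projections.shape[1])
    rate = 1.0 / result.bin_width
    n_comp = result.projections.shape[0]
    scored = n_comp if max_components is None else min(n_comp, max_components)
    coh = np.zeros(n_comp)
    for i in range(scored):
        res = multitaper_coherence(
            result.projections[i, :n], dia[:n], rate,
            segment_s=segment_s, freq_range=freq_range,
        )
        coh[i] = res.c
    order = np.argsort(-coh, kind="stable")
    result.coherence_order = order
    result.component_coherence = coh
    return result


def trajectory_stats(
    result: ManifoldResult,
    phase: PhaseSignal,
    n_components: int | None = None,
    coherence_floor: float = 0.3,
    max_default_components: int = 4,
    n_bins: int = 100,
) -> TrajectoryStats:
    """Phase-binned speed, mean trajectory and distance-to-mean.

    Speed uses first differences of the leading (coherence-ordered)
    components at the native time step, assigned to the phase bin of
    the earlier sample; the per-bin speed is the norm of the binned
    mean displacement (the deterministic velocity profile).  The mean trajectory is the
    phase-binned mean of the projections; distance-to-mean is each
    sample's Euclidean distance to the mean-trajectory point of its
    phase bin, averaged per bin.  Bins without samples are NaN.

    ``n_components`` defaults to the number of components whose
    respiratory coherence exceeds ``coherence_floor`` (capped at 4, and
    at least 2).
    """
    if n_components is None:
        if result.component_coherence is not None:
            n_above = int(np.sum(result.component_coherence > coherence_floor))
            n_components = int(np.clip(n_above, 2, max_default_components))
        else:
            n_components = min(max_default_components, result.projections.shape[0])
    proj = result.reordered_projections(n_components).T  # (time, d)

    step = int(round(1.0 / (phase.rate * result.bin_width)))
    if step >= 1:
        phi = phase.phi[:: step][: len(proj)]
    else:
        idx = np.round(np.arange(len(proj)) * result.bin_width * phase.rate).astype(int)
        phi = np.full(len(proj), np.nan)
        ok = idx < len(phase.phi)
        phi[ok] = phase.phi[idx[ok]]
    n = min(len(phi), len(proj))
    phi, proj = phi[:n], proj[:n]
    valid = ~np.isnan(phi)
    bins = bin_phase(phi[valid], n_bins)
    counts = np.bincount(bins, minlength=n_bins).astype(float)
    empty = counts == 0
    counts[empty] = np.nan

    mean_traj = np.empty((n_bins, proj.shape[1]))
    for d in range(proj.shape[1]):
        mean_traj[:, d] = (
            np.bincount(bins, weights=proj[valid, d], minlength=n_bins) / counts
        )

    # per-bin speed: norm of the phase-binned mean displacement.
    # Binning the sample-wise norms instead folds the isotropic
    # estimation noise of the projections into a rate-dependent floor
    # that buries the kinematic profile; the mean displacement averages
    # that noise out and estimates the deterministic velocity.
    diffs = np.diff(proj, axis=0)
    dvalid = valid[:-1] & valid[1:]
    dbins = bin_phase(phi[:-1][dvalid], n_bins)
    dcounts = np.bincount(dbins, minlength=n_bins).astype(float)
    dcounts[dcounts == 0] = np.nan
    mean_disp = np.empty((n_bins, proj.shape[1]))
    for dd in range(proj.shape[1]):
        mean_disp[:, dd] = (
            np.bincount(dbins, weights=diffs[dvalid, dd], minlength=n_bins)
            / dcounts
        )
    speed = np.linalg.norm(mean_disp, axis=1)

    # distance-to-mean is a per-breath statistic: each breath
    # contributes its mean position per phase bin, and its Euclidean
    # distance to the mean trajectory is then averaged across breaths
    phi_v = phi[valid]
    onset_marks = np.zeros(valid.sum(), dtype=int)
    onset_marks[1:] = (phi_v[1:] >= 0) & (phi_v[:-1] < 0)
    breath_id = np.cumsum(onset_marks)
    combo = breath_id * n_bins + bins
    ncombo = (breath_id.max() + 1) * n_bins
    ccounts = np.bincount(combo, minlength=ncombo).astype(float)
    pos = np.empty((ncombo, proj.shape[1]))
    with np.errstate(invalid="ignore"):
        for d in range(proj.shape[1]):
            pos[:, d] = (
                np.bincount(combo, weights=proj[valid, d], minlength=ncombo)
                / ccounts
            )
    have = ccounts > 0
    bin_of = np.arange(ncombo) % n_bins
    dvals = np.linalg.norm(pos[have] - mean_traj[bin_of[have]], axis=1)
    dcounts2 = np.bincount(bin_of[have], minlength=n_bins).astype(float)
    dcounts2[dcounts2 == 0] = np.nan
    distance = (
        np.bincount(bin_of[have], weights=dvals, minlength=n_bins) / dcounts2
    )
    return TrajectoryStats(
        mean_trajectory=mean_traj,
        speed=speed,
        distance_to_mean=distance,
        n_components=proj.shape[1],
    )


def principal_angles(
    loadings_a: np.ndarray, loadings_b: np.ndarray, d: int | None = None
) -> np.ndarray:
    """Cosines of the principal angles between two loading subspaces.

    The singular values of ``A^T B`` (for orthonormal bases A, B) are
    cos(theta) in decreasing order; 1 for shared directions, 0 for
    orthogonal ones.
    """
    a = np.asarray(loadings_a, float)
    b = np.asarray(loadings_b, float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("loading matrices must share the unit dimension")
    if d is not None:
        a, b = a[:, :d], b[:, :d]
    # orthonormalize defensively; no-op for PCA loadings
    qa, _ = np.linalg.qr(a)
    qb, _ = np.linalg.qr(b)
    s = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return np.clip(s, 0.0, 1.0)


def correlation_structure(
    rates_a: RateMatrix, rates_b: RateMatrix
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, float]:
    """Pairwise zero-lag rate correlations in two conditions.

    Returns the two correlation matrices, a long-format table of unit
    pairs with their correlation in each condition, and the linear-fit
    correlation R between the conditions' pair values.  Pairs involving
    a constant-rate unit are NaN.
    """
    xa, xb = rates_a.rates, rates_b.rates
    if xa.shape[0] != xb.shape[0]:
        raise ValueError("conditions must contain the same unit set")
    with np.errstate(invalid="ignore", divide="ignore"):
        ca = np.corrcoef(xa)
        cb = np.corrcoef(xb)
    iu = np.triu_indices(xa.shape[0], k=1)
    va, vb = ca[iu], cb[iu]
    ok = np.isfinite(va) & np.isfinite(vb)
    r = float(np.corrcoef(va[ok], vb[ok])[0, 1]) if ok.sum() > 2 else np.nan
    pairs = pd.DataFrame(
        {"unit_i": iu[0], "unit_j": iu[1], "r_a": va, "r_b": vb}
    )
    return ca, cb, pairs, r


def correlation_fit_ci(r: float, n_pairs: int) -> tuple[float, float]:
    """95% confidence interval of a correlation via the Fisher transform."""
    if not np.isfinite(r) or n_pairs < 4:
        return (np.nan, np.nan)
    z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    se = 1.0 / np.sqrt(n_pairs - 3)
    return (float(np.tanh(z - 1.96 * se)), float(np.tanh(z + 1.96 * se)))
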