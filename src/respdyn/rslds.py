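"""Recurrent switching linear dynamical system (rSLDS) for population
spike counts.

Model.  A D-dimensional continuous latent x_t evolves under one of K
linear regimes,

    x_t = A_k x_{t-1} + b_k + w_t,      w_t ~ N(0, w^2 I),

where the active regime z_t depends on the previous continuous state
through a softmax ("recurrent" switching),

    p(z_t = k | x_{t-1}) ∝ exp(W_k . x_{t-1} + r_k),

and each unit emits spike counts through a Poisson generalized linear
model on the latent,

    y_{t,n} ~ Poisson( exp(c_n . x_t + d_n) ).

With K = 2 and D = 2 this captures alternating inspiratory/expiratory
regimes: an unstable spiral drives the inspiratory excursion, and a
contracting expiratory regime returns the state toward breath onset.

Fitting.  Parameters and the latent path are estimated by joint-MAP
coordinate ascent: (i) discrete states by exact per-bin maximization of
the dynamics-plus-transition terms, (ii) per-state dynamics by least
squares, (iii) recurrent weights by multinomial logistic regression,
(iv) emissions by a vectorized Newton Poisson GLM, and (v) the latent
path by a block-tridiagonal (banded) Newton step on the Poisson
likelihood with the Gaussian dynamics prior, with backtracking so the
joint objective never decreases.  The objective trace is stored and is
non-decreasing up to the stated tolerance.

Simulation sets the dynamics noise to zero and iterates the fitted
regimes deterministically (the discrete state is the argmax of the
recurrent logits).  A fitted model whose simulated, decoded diaphragm
sustains rhythmic bursting is called *regenerative*.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.linalg import solve_banded
from scipy.ndimage import gaussian_filter1d
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVR

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# small numerical helpers
# ---------------------------------------------------------------------------

def _fit_poisson_glm(
    x: np.ndarray, y: np.ndarray, beta0: np.ndarray | None = None,
    n_iter: int = 25, tol: float = 1e-8,
) -> np.ndarray:
    """Vectorized Newton fit of independent Poisson GLMs sharing a design.

    ``x`` is (T, D); ``y`` is (T, N) counts.  Returns (D + 1, N)
    coefficients, intercept last.  Each unit's problem is convex; Newton
    steps are damped by halving until the per-unit log-likelihood does
    not decrease.
    """
    t, d = x.shape
    xd = np.column_stack([x, np.ones(t)])
    n = y.shape[1]
    if beta0 is None:
        beta = np.zeros((d + 1, n))
        beta[-1] = np.log(np.maximum(y.mean(axis=0), 1e-10))
    else:
        beta = beta0.copy()

    def ll(b):
        eta = np.clip(xd @ b, -30, 30)
        return (y * eta - np.exp(eta)).sum(axis=0)

    cur = ll(beta)
    for _ in range(n_iter):
        eta = np.clip(xd @ beta, -30, 30)
        mu = np.exp(eta)
        grad = xd.T @ (y - mu)                       # (D+1, N)
        h = np.einsum("tn,ti,tj->nij", mu, xd, xd)   # (N, D+1, D+1)
        h += 1e-9 * np.eye(d + 1)
        step = np.linalg.solve(h, grad.T[:, :, None])[:, :, 0].T
        new_beta = beta + step
        new = ll(new_beta)
        bad = new < cur - 1e-10
        scale = 1.0
        while bad.any() and scale > 1e-4:
            scale *= 0.5
            new_beta[:, bad] = beta[:, bad] + scale * step[:, bad]
            new = ll(new_beta)
            bad = new < cur - 1e-10
        if np.max(np.abs(new_beta - beta)) < tol:
            beta = new_beta
            break
        beta, cur = new_beta, np.maximum(new, cur)
    return beta


def _fit_transition(
    x: np.ndarray, z: np.ndarray, k: int, d: int, balanced: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Multinomial logistic fit of z_t on x_{t-1} (recurrent weights).

    ``balanced`` reweights classes so the majority regime (expiration
    occupies most of the cycle) does not bias the switching surface;
    used for the final reported/simulated transition model.
    """
    lr = LogisticRegression(
        C=1e6, max_iter=300, class_weight="balanced" if balanced else None
    )
    lr.fit(x[:-1], z[1:])
    trans_w = np.zeros((k, d))
    trans_b = np.zeros(k)
    if lr.coef_.shape[0] == 1:  # binary: sklearn stores a single row
        trans_w[lr.classes_[1]] = lr.coef_[0]
        trans_b[lr.classes_[1]] = lr.intercept_[0]
    else:
        trans_w[lr.classes_] = lr.coef_
        trans_b[lr.classes_] = lr.intercept_
    return trans_w, trans_b


def classify_eigenvalues(a: np.ndarray, imag_tol: float = 1e-6) -> str:
    """Discrete-time taxonomy of a 2x2 dynamics matrix.

    Complex eigenvalues give a spiral (unstable if the modulus exceeds
    1, the unit circle); real pairs give stable/unstable nodes or, when
    the moduli straddle 1, a saddle.
    """
    eig = np.linalg.eigvals(np.asarray(a, float))
    mod = np.abs(eig)
    if np.max(np.abs(eig.imag)) > imag_tol:
        return "unstable spiral" if mod.max() > 1.0 else "stable spiral"
    above = mod > 1.0
    if above.all():
        return "unstable node"
    if (~above).all():
        return "stable node"
    return "saddle"


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class RecurrentSwitchingLDS:
    """rSLDS model of binned population spike counts.

    Parameters
    ----------
    counts : array (n_units, n_bins)
        Spike counts in ``bin_width`` bins (10 ms by default).
    bin_width : float
        Bin width in seconds.
    n_states : int
        Number of discrete regimes K (1-3 supported; 2 is the standard
        inspiration/expiration model; K = 1 is the non-switching
        control).
    n_latent : int
        Continuous latent dimension D.
    """

    def __init__(
        self,
        counts: np.ndarray,
        bin_width: float = 0.01,
        n_states: int = 2,
        n_latent: int = 2,
    ) -> None:
        counts = np.asarray(counts, float)
        if counts.ndim != 2:
            raise ValueError("counts must be (n_units, n_bins)")
        if not 1 <= n_states <= 3:
            raise ValueError("n_states must be 1, 2 or 3")
        self.counts = counts
        self.bin_width = bin_width
        self.n_states = n_states
        self.n_latent = n_latent
        self.n_units, self.n_bins = counts.shape
        if self.n_bins * bin_width < 60.0:
            raise ValueError("need at least 60 s of data to fit the rSLDS")
        if self.n_units < 10:
            raise ValueError("need at least 10 units to fit the rSLDS")

    @classmethod
    def from_spikes(
        cls,
        spikes: list[np.ndarray],
        duration: float,
        bin_width: float = 0.01,
        **kwargs,
    ) -> "RecurrentSwitchingLDS":
        n_bins = int(round(duration / bin_width))
        counts = np.zeros((len(spikes), n_bins))
        for i, st in enumerate(spikes):
            idx = np.floor(np.asarray(st) / bin_width).astype(int)
            idx = idx[(idx >= 0) & (idx < n_bins)]
            np.add.at(counts[i], idx, 1.0)
        return cls(counts, bin_width=bin_width, **kwargs)

    # -- fitting -------------------------------------------------------

    def _init_latent(self) -> np.ndarray:
        """PCA of smoothed square-root rates, standardized per dimension.

"""
        sm = np.sqrt(gaussian_filter1d(self.counts, 2.0, axis=1))
        means = sm.mean(axis=1, keepdims=True)
        sm -= means
        u, s, vt = np.linalg.svd(sm, full_matrices=False)
        x = (s[: self.n_latent, None] * vt[: self.n_latent]).T  # (T, D)
        scale = np.maximum(x.std(axis=0), 1e-12)
        x /= scale
        return x

    def _hessian_blocks(
        self, x, z, a, wvar, beta
    ) -> tuple[np.ndarray, np.ndarray]:
        """Block-tridiagonal negative Hessian of the joint log posterior
        in the latent path: diagonal blocks (T, D, D) and sub-diagonal
        blocks (T-1, D, D) coupling x_{t+1} with x_t."""
        t, d = x.shape
        c = beta[:-1].T
        az = a[z[1:]]
        eta = np.clip(x @ c.T + beta[-1], -30, 30)
        mu = np.exp(eta)
        diag = np.einsum("tn,ni,nj->tij", mu, c, c)
        diag[1:] += np.eye(d) / wvar
        diag[:-1] += np.einsum("tij,tik->tjk", az, az) / wvar
        sub = -az / wvar
        return diag, sub

    def _latent_newton(
        self, x, z, a, b, wvar, beta, n_steps: int = 2
    ) -> np.ndarray:
        """Banded Newton ascent on the latent path given everything else."""
        t, d = x.shape
        c = beta[:-1].T          # (N, D)
        d0 = beta[-1]            # (N,)
        y = self.counts.T        # (T, N)
        az = a[z[1:]]            # (T-1, D, D) dynamics into each t >= 1

        def objective(xx):
            eta = np.clip(xx @ c.T + d0, -30, 30)
            obs = (y * eta - np.exp(eta)).sum()
            resid = xx[1:] - np.einsum("tij,tj->ti", az, xx[:-1]) - b[z[1:]]
            dyn = -0.5 * (resid**2).sum() / wvar
            return obs + dyn

        cur = objective(x)
        for _ in range(n_steps):
            eta = np.clip(x @ c.T + d0, -30, 30)
            mu = np.exp(eta)
            grad = (y - mu) @ c                       # (T, D)
            resid = x[1:] - np.einsum("tij,tj->ti", az, x[:-1]) - b[z[1:]]
            grad[1:] -= resid / wvar
            grad[:-1] += np.einsum("tij,ti->tj", az, resid) / wvar

            diag, sub = self._hessian_blocks(x, z, a, wvar, beta)
            nvar = t * d
            bw = 2 * d - 1
            ab = np.zeros((2 * bw + 1, nvar))
            rows = np.arange(t)
            for i in range(d):
                for j in range(d):
                    cix = rows * d + j
                    ab[bw + (i - j), cix] += diag[:, i, j]
                    c2 = rows[:-1] * d + j            # x_t cols
                    ab[bw + (d + i - j), c2] += sub[:, i, j]
                    ab[bw + (j - d - i), rows[:-1] * d + d + i] += sub[:, i, j]

            step = solve_banded((bw, bw), ab, grad.reshape(-1)).reshape(t, d)
            scale = 1.0
            for _ in range(12):
                new = objective(x + scale * step)
                if new >= cur:
                    x = x + scale * step
                    cur = new
                    break
                scale *= 0.5
        return x

    def fit(
        self,
        seed: int = 0,
        max_iter: int = 25,
        tol: float = 1e-6,
        latent_refinement: bool = True,
        verbose: bool = False,
    ) -> "RSLDSResults":
        """Fit by joint-MAP coordinate ascent.

        Returns an :class:`RSLDSResults`.  The objective (joint log
        posterior of latent path, states and parameters, up to
        constants) is recorded per iteration and is non-decreasing up to
        ``tol`` (relative); non-convergence raises a warning but still
        returns the best model.
        """
        rng = np.random.default_rng(seed)
        k, d, t = self.n_states, self.n_latent, self.n_bins
        x = self._init_latent()
        x0 = x.copy()                  # fixed reference for the noise scale
        y = self.counts.T

        # initial discrete states: k-means on standardized (x, dx)
        if k > 1:
            dx = np.vstack([np.zeros((1, d)), np.diff(x, axis=0)])
            feats = np.column_stack([x, dx / np.maximum(dx.std(axis=0), 1e-12)])
            from sklearn.cluster import KMeans

            z = KMeans(n_clusters=k, n_init=5, random_state=seed).fit_predict(feats)
        else:
            z = np.zeros(t, dtype=int)

        beta = _fit_poisson_glm(x, y)
        a = np.tile(np.eye(d), (k, 1, 1))
        b = np.zeros((k, d))
        wvar = 1e-2
        trans_w = np.zeros((k, d))
        trans_b = np.zeros(k)
        degenerate: list[int] = []

        def transition_ll(xprev, zz, w_mat, b_vec):
            logits = xprev @ w_mat.T + b_vec
            logits -= logits.max(axis=1, keepdims=True)
            logp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
            return logp[np.arange(len(zz)), zz].sum(), logp

        def objective(x, z, a, b, wvar, beta, trans_w, trans_b):
            eta = np.clip(np.column_stack([x, np.ones(t)]) @ beta, -30, 30)
            obs = (y * eta - np.exp(eta)).sum()
            resid = x[1:] - np.einsum("tij,tj->ti", a[z[1:]], x[:-1]) - b[z[1:]]
            dyn = -0.5 * (resid**2).sum() / wvar - 0.5 * (t - 1) * d * np.log(
                2 * np.pi * wvar
            )
            tr = 0.0
            if k > 1:
                tr, _ = transition_ll(x[:-1], z[1:], trans_w, trans_b)
            return obs + dyn + tr

        history: list[float] = []
        converged = False
        for it in range(max_iter):
            # (i) per-state dynamics by least squares on the regime
            # interiors: bins within 3 steps of a state switch are
            # excluded, because the smoothed latent rounds the regime
            # corners and marked switches can lag the true ones, which
            # would blend the two regimes' dynamics.
            degenerate = []
            interior = np.ones(t, dtype=bool)
            if k > 1:
                sw = np.flatnonzero(np.diff(z) != 0) + 1
                for off in range(-3, 4):
                    idx = np.clip(sw + off, 0, t - 1)
                    interior[idx] = False
            for s in range(k):
                sel = np.flatnonzero((z[1:] == s) & interior[1:]) + 1
                if len(sel) < 5 * d:
                    degenerate.append(s)
                    continue
                xp = np.column_stack([x[sel - 1], np.ones(len(sel))])
                sol, *_ = np.linalg.lstsq(xp, x[sel], rcond=None)
                a[s] = sol[:d].T
                b[s] = sol[d]
            # noise scale from the interior residuals of the initial
            # (data-driven) latent, then frozen: re-estimating it on the
            # MAP-refined path would feed back (refined paths shrink
            # residuals, overweighting the prior until the variance
            # collapses)
            if it == 0:
                az = a[z[1:]]
                resid = x0[1:] - np.einsum("tij,tj->ti", az, x0[:-1]) - b[z[1:]]
                msk = interior[1:]
                wvar = max((resid[msk] ** 2).mean(), 1e-8)

            # (ii) recurrent transition weights
            if k > 1 and len(np.unique(z[1:])) == k:
                trans_w, trans_b = _fit_transition(x, z, k, d)

            # (iii) exact discrete-state update
            if k > 1:
                pred = np.einsum("kij,tj->tki", a, x[:-1]) + b[None]
                err = ((x[1:, None, :] - pred) ** 2).sum(-1)
                loglik = -0.5 * err / wvar
                _, logp = transition_ll(x[:-1], z[1:], trans_w, trans_b)
                z[1:] = np.argmax(loglik + logp, axis=1)

            # (iv) emissions
            beta = _fit_poisson_glm(x, y, beta0=beta, n_iter=4)

            # (v) MAP latent path refinement (Poisson likelihood with
            # the Gaussian dynamics prior, banded Newton)
            if latent_refinement:
                x = self._latent_newton(x, z, a, b, wvar, beta)

            obj = objective(x, z, a, b, wvar, beta, trans_w, trans_b)
            if verbose:
                logger.info("iter %d objective %.2f", it, obj)
            if history and obj < history[-1] - tol * abs(history[-1]):
                logger.warning("objective decreased at iteration %d", it)
            if history and abs(obj - history[-1]) < tol * abs(history[-1]):
                history.append(obj)
                converged = True
                break
            history.append(obj)
        if not converged:
            warnings.warn("rSLDS fit did not converge; returning best model")
        for s in degenerate:
            logger.warning("discrete state %d is (nearly) unvisited", s)

        # identifiability-guarded dynamics for the eigenvalue taxonomy:
        # a state-conditional regressor direction whose variance sits
        # near the latent noise floor is not identified by the
        # regression (e.g. a fast-contracting direction that is spent
        # within the excluded corner bins) and, fit naively, its
        # eigenvalue reflects the autocorrelation of the smoothed latent
        # noise rather than the dynamics.  For classification such a
        # direction is treated as contracting (its response annihilated;
        # the regime demonstrably collapses it faster than the bin
        # width, else its variance would not sit at the noise floor).
        # Simulation uses the raw regression dynamics, whose on-manifold
        # flow carries the observed timing.
        a_tax = a.copy()
        interior = np.ones(t, dtype=bool)
        if k > 1:
            sw = np.flatnonzero(np.diff(z) != 0) + 1
            for off in range(-3, 4):
                interior[np.clip(sw + off, 0, t - 1)] = False
        for s in range(k):
            sel = np.flatnonzero((z[1:] == s) & interior[1:]) + 1
            if len(sel) < 5 * d:
                continue
            xc = x[sel - 1]
            evals, evecs = np.linalg.eigh(np.cov(xc.T))
            for j in range(d):
                if evals[j] <= 3.0 * wvar and evals[j] < evals.max():
                    u = evecs[:, j]
                    a_tax[s] = a_tax[s] - np.outer(a_tax[s] @ u, u)

        # final reported transition model: class-balanced, so the
        # switching surface is centred on the transitions rather than
        # pulled toward the majority regime
        if k > 1 and len(np.unique(z[1:])) == k:
            trans_w, trans_b = _fit_transition(x, z, k, d, balanced=True)

        return RSLDSResults(
            model=self,
            A=a.copy(),
            A_identified=a_tax,
            b=b.copy(),
            noise_scale=float(np.sqrt(wvar)),
            trans_w=trans_w.copy(),
            trans_b=trans_b.copy(),
            emission_weights=beta[:-1].T.copy(),
            emission_bias=beta[-1].copy(),
            latent=x,
            states=z,
            log_objective=np.asarray(history),
            converged=converged,
            degenerate_states=tuple(degenerate),
            seed=seed,
            algorithm="MAP coordinate ascent (banded-Newton latent refinement)",
        )


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class RSLDSResults:
    """Fitted rSLDS: parameters, posterior paths and diagnostics.

    ``A`` holds the raw per-state regression dynamics used for
    simulation.  ``A_identified`` holds the same matrices with
    unidentified (noise-floor) regressor directions treated as
    contracting; the eigenvalue taxonomy
    (:meth:`eigenvalues`/:meth:`state_categories`) is computed on these.
    """

    model: RecurrentSwitchingLDS
    A: np.ndarray                  # (K, D, D) simulation dynamics
    b: np.ndarray                  # (K, D)
    noise_scale: float             # w (s.d. of isotropic dynamics noise)
    trans_w: np.ndarray            # (K, D) recurrent weights
    trans_b: np.ndarray            # (K,)
    emission_weights: np.ndarray   # (N, D)
    emission_bias: np.ndarray      # (N,)
    latent: np.ndarray             # (T, D) MAP latent path
    states: np.ndarray             # (T,) discrete state path
    log_objective: np.ndarray
    converged: bool
    degenerate_states: tuple = ()
    seed: int = 0
    algorithm: str = ""
    A_identified: np.ndarray | None = None

    # -- basic quantities ---------------------------------------------

    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    def transition_probabilities(self, x: np.ndarray) -> np.ndarray:
        """softmax(W x + r) rows; each row sums to one."""
        logits = np.atleast_2d(x) @ self.trans_w.T + self.trans_b
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def emission_rates(self, x: np.ndarray) -> np.ndarray:
        """Per-unit rates (spikes/s) along a latent path: exp(Cx+d)/dt."""
        eta = np.clip(np.atleast_2d(x) @ self.emission_weights.T
                      + self.emission_bias, -30, 30)
        return np.exp(eta) / self.model.bin_width

    @property
    def taxonomy_dynamics(self) -> np.ndarray:
        return self.A if self.A_identified is None else self.A_identified

    def eigenvalues(self) -> list[np.ndarray]:
        """Per-state eigenvalues of the identifiability-guarded dynamics."""
        return [
            np.linalg.eigvals(self.taxonomy_dynamics[s])
            for s in range(self.n_states)
        ]

    def state_categories(self) -> list[str]:
        return [
            classify_eigenvalues(self.taxonomy_dynamics[s])
            for s in range(self.n_states)
        ]

    # -- simulation ----------------------------------------------------

    def simulate(
        self,
        n_steps: int,
        x0: np.ndarray | None = None,
        seed: int | None = None,
        overflow: float = 1e6,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Noise-free forward simulation of the fitted dynamics.

        The discrete state is chosen deterministically as the argmax of
        the recurrent transition logits at the previous latent; the
        noise term is identically zero.  ``x0`` defaults to the
        posterior latent at a random observed time (seed-controlled).
        Numeric overflow truncates the simulation with a flag
        (``self.simulation_truncated``).
        """
        if x0 is None:
            rng = np.random.default_rng(self.seed if seed is None else seed)
            x0 = self.latent[rng.integers(len(self.latent))]
        x = np.empty((n_steps, len(x0)))
        z = np.empty(n_steps, dtype=int)
        xi = np.asarray(x0, float)
        self.simulation_truncated = False
        for t in range(n_steps):
            if self.n_states > 1:
                logits = self.trans_w @ xi + self.trans_b
                s = int(np.argmax(logits))
            else:
                s = 0
            xi = self.A[s] @ xi + self.b[s]
            if not np.all(np.isfinite(xi)) or np.linalg.norm(xi) > overflow:
                self.simulation_truncated = True
                x[t:] = x[t - 1] if t else 0.0
                z[t:] = s
                logger.warning("simulation truncated at step %d (overflow)", t)
                break
            x[t] = xi
            z[t] = s
        return x, z

    # -- summaries -----------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Recurrent switching LDS results",
            "=" * 40,
            f"states K={self.n_states}  latent D={self.latent.shape[1]}  "
            f"units N={self.model.n_units}  bins T={self.model.n_bins} "
            f"({self.model.n_bins * self.model.bin_width:.0f} s at "
            f"{1e3 * self.model.bin_width:.0f} ms)",
            f"algorithm: {self.algorithm}",
            f"converged: {self.converged}  iterations: {len(self.log_objective)}",
            f"dynamics noise scale w = {self.noise_scale:.4f}",
        ]
        occ = [float(np.mean(self.states == s)) for s in range(self.n_states)]
        for s in range(self.n_states):
            eig = np.linalg.eigvals(self.taxonomy_dynamics[s])
            lines.append(
                f"state {s}: occupancy {occ[s]:.2f}  "
                f"eigenvalues {np.round(eig, 4)}  -> "
                f"{classify_eigenvalues(self.taxonomy_dynamics[s])}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# diaphragm decoder and the regenerative criterion
# ---------------------------------------------------------------------------

@dataclass
class DiaphragmDecoder:
    """Nonlinear (RBF support-vector) regression from latent to diaphragm."""

    svr: SVR
    x_scale: np.ndarray
    x_mean: np.ndarray

    def decode(self, x: np.ndarray) -> np.ndarray:
        return self.svr.predict((np.atleast_2d(x) - self.x_mean) / self.x_scale)


def fit_diaphragm_decoder(
    x_observed: np.ndarray,
    diaphragm: np.ndarray,
    max_train: int = 4000,
    seed: int = 0,
    **svr_kwargs,
) -> DiaphragmDecoder:
    """Train the latent-to-diaphragm readout on observed data.

    ``diaphragm`` must be on the same timebase as ``x_observed`` (the
    model's count bins).  Training subsamples at most ``max_train``
    points for tractability of the kernel regression.
    """
    x = np.asarray(x_observed, float)
    yv = np.asarray(diaphragm, float)
    n = min(len(x), len(yv))
    x, yv = x[:n], yv[:n]
    rng = np.random.default_rng(seed)
    idx = (
        rng.choice(n, size=max_train, replace=False) if n > max_train
        else np.arange(n)
    )
    mean, scale = x.mean(0), np.maximum(x.std(0), 1e-12)
    svr = SVR(C=10.0, epsilon=0.05, **svr_kwargs)
    svr.fit((x[idx] - mean) / scale, yv[idx])
    return DiaphragmDecoder(svr=svr, x_scale=scale, x_mean=mean)


def classify_regenerative(
    simulated: np.ndarray,
    rate: float,
    reference: np.ndarray | None = None,
    freq_range: tuple[float, float] = (0.5, 8.0),
    peak_factor: float = 5.0,
    decay_ratio: float = 0.5,
) -> bool:
    """Does a simulated diaphragm trace sustain rhythmic bursting?

    Regenerative iff (i) the periodogram has a dominant peak inside
    ``freq_range`` at least ``peak_factor`` times the median spectral
    power over that band, and (ii) the burst amplitude (5th-95th
    percentile range) of the last third of the simulation is at least
    ``decay_ratio`` of the first third (no decay).  ``reference`` is
    accepted for signature compatibility but the rule is absolute.
    """
    x = np.asarray(simulated, float)
    if len(x) < rate:
        return False
    if np.ptp(x) < 1e-12:
        return False
    freqs, pxx = signal.welch(x - x.mean(), fs=rate, nperseg=min(len(x), int(20 * rate)))
    band = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
    if not band.any() or pxx[band].max() <= 0:
        return False
    med = np.median(pxx[band])
    if med <= 0 or pxx[band].max() < peak_factor * med:
        return False
    third = len(x) // 3
    amp_first = np.percentile(x[:third], 95) - np.percentile(x[:third], 5)
    amp_last = np.percentile(x[-third:], 95) - np.percentile(x[-third:], 5)
    return bool(amp_last >= decay_ratio * amp_first and amp_first > 1e-9)


def simulated_breath_stats(
    simulated: np.ndarray, rate: float, min_height_frac: float = 0.3
) -> dict:
    """Breath frequency and mean burst (inspiratory) duration of a
    simulated diaphragm trace, via peak detection with width at half
    prominence."""
    x = np.asarray(simulated, float)
    span = np.ptp(x)
    if span < 1e-12:
        return {"frequency_hz": 0.0, "insp_duration_s": 0.0, "n_bursts": 0}
    thr = x.min() + min_height_frac * span
    peaks, props = signal.find_peaks(x, height=thr, distance=max(1, int(0.1 * rate)))
    if len(peaks) < 2:
        return {"frequency_hz": 0.0, "insp_duration_s": 0.0, "n_bursts": len(peaks)}
    widths = signal.peak_widths(x, peaks, rel_height=0.8)[0] / rate
    freq = (len(peaks) - 1) / ((peaks[-1] - peaks[0]) / rate)
    return {
        "frequency_hz": float(freq),
        "insp_duration_s": float(np.mean(widths)),
        "n_bursts": int(len(peaks)),
    }


# ---------------------------------------------------------------------------
# state-to-phase roles and breath-aligned comparison
# ---------------------------------------------------------------------------

def state_roles(
    states: np.ndarray,
    insp_mask: np.ndarray,
    min_occupancy: float = 0.05,
) -> list[str]:
    """Label each discrete state inspiratory/expiratory by majority
    overlap of its occupancy with inspiration intervals; states with
    under ``min_occupancy`` total occupancy are 'mixed'."""
    states = np.asarray(states)
    insp = np.asarray(insp_mask, bool)
    n = min(len(states), len(insp))
    states, insp = states[:n], insp[:n]
    roles = []
    for s in np.unique(states):
        sel = states == s
        if sel.mean() < min_occupancy:
            roles.append("mixed")
        else:
            roles.append("inspiratory" if insp[sel].mean() > 0.5 else "expiratory")
    return roles


def classify_dynamics(
    results: RSLDSResults, insp_mask: np.ndarray
) -> pd.DataFrame:
    """Eigenvalue taxonomy of each state with its breath-phase role."""
    roles = state_roles(results.states, insp_mask)
    rows = []
    for s in range(results.n_states):
        eig = np.linalg.eigvals(results.taxonomy_dynamics[s])
        rows.append(
            {
                "state": s,
                "role": roles[s] if s < len(roles) else "mixed",
                "category": classify_eigenvalues(results.taxonomy_dynamics[s]),
                "modulus_max": float(np.abs(eig).max()),
                "eig_real": eig.real.tolist(),
                "eig_imag": eig.imag.tolist(),
                "occupancy": float(np.mean(results.states == s)),
            }
        )
    return pd.DataFrame(rows)


def breath_aligned_average(
    rates: np.ndarray,
    onsets_s: np.ndarray,
    bin_width: float,
    window: tuple[float, float] = (-0.2, 0.6),
) -> np.ndarray:
    """Average (units, lags) of per-unit rates around breath onsets."""
    lo = int(round(window[0] / bin_width))
    hi = int(round(window[1] / bin_width))
    t = rates.shape[1] if rates.ndim == 2 else len(rates)
    segs = []
    for on in np.asarray(onsets_s) / bin_width:
        i = int(round(on))
        if i + lo < 0 or i + hi >= t:
            continue
        segs.append(rates[:, i + lo: i + hi])
    if not segs:
        raise ValueError("no complete breath windows inside the recording")
    return np.mean(segs, axis=0)


def breath_aligned_r2(
    observed_aligned: np.ndarray,
    simulated_aligned: np.ndarray,
    seed: int = 0,
    n_shuffles: int = 200,
) -> dict:
    """Per-unit squared correlation between observed and simulated
    breath-aligned rate averages, with two shuffle controls (unit
    identity permutation; time-bin permutation)."""
    obs, sim = np.asarray(observed_aligned), np.asarray(simulated_aligned)
    if obs.shape != sim.shape:
        raise ValueError("aligned averages must have matching shapes")
    rng = np.random.default_rng(seed)

    def r2(a_mat, b_mat):
        out = np.full(len(a_mat), np.nan)
        for i in range(len(a_mat)):
            if a_mat[i].std() > 0 and b_mat[i].std() > 0:
                out[i] = np.corrcoef(a_mat[i], b_mat[i])[0, 1] ** 2
        return out

    true_r2 = r2(obs, sim)
    cell_meds, time_meds = [], []
    for _ in range(n_shuffles):
        perm = rng.permutation(len(obs))
        cell_meds.append(np.nanmedian(r2(obs, sim[perm])))
        tperm = rng.permutation(obs.shape[1])
        time_meds.append(np.nanmedian(r2(obs, sim[:, tperm])))
    return {
        "r2": true_r2,
        "median_r2": float(np.nanmedian(true_r2)),
        "shuffle_cells_median": float(np.mean(cell_meds)),
        "shuffle_time_median": float(np.mean(time_meds)),
    }


# ---------------------------------------------------------------------------
# latent alignment across recordings
# ---------------------------------------------------------------------------

def phase_binned_latent(
    latent: np.ndarray, phi: np.ndarray, n_bins: int = 100
) -> np.ndarray:
    """Mean latent per respiratory phase bin (bins of width pi/50)."""
    from .breath import bin_phase

    latent = np.asarray(latent)
    phi = np.asarray(phi)
    n = min(len(latent), len(phi))
    latent, phi = latent[:n], phi[:n]
    ok = ~np.isnan(phi)
    bins = bin_phase(phi[ok], n_bins)
    counts = np.bincount(bins, minlength=n_bins).astype(float)
    counts[counts == 0] = np.nan
    out = np.empty((n_bins, latent.shape[1]))
    for d in range(latent.shape[1]):
        out[:, d] = np.bincount(bins, weights=latent[ok, d], minlength=n_bins) / counts
    return out


def align_latents(x_binned: np.ndarray, z_binned: np.ndarray) -> np.ndarray:
    """Least-squares alignment W with X W ~= Z for phase-binned latents.

    ``X`` and ``Z`` are (100, D) phase-binned mean latents of a source
    and a target recording; the aligned source latent is ``x @ W``.
    Raises on rank-deficient X.
    """
    x = np.asarray(x_binned, float)
    z = np.asarray(z_binned, float)
    ok = ~(np.isnan(x).any(axis=1) | np.isnan(z).any(axis=1))
    x, z = x[ok], z[ok]
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient phase-binned latent; cannot align")
    w, *_ = np.linalg.lstsq(x, z, rcond=None)
    return w


# ---------------------------------------------------------------------------
# dropout and subset analyses
# ---------------------------------------------------------------------------

@dataclass
class DropoutResult:
    order: str
    removal_counts: np.ndarray
    regenerative: np.ndarray
    units_to_failure: float
    fraction_of_population: float
    logistic_boundary: float
    full_stats: dict
    step_stats: list


def _regen_vs_full(step: dict, full: dict) -> bool:
    if full["frequency_hz"] <= 0:
        return False
    fr = step["frequency_hz"] / full["frequency_hz"]
    if not 0.75 <= fr <= 1.5:
        return False
    if full["insp_duration_s"] <= 0:
        return False
    dr = step["insp_duration_s"] / full["insp_duration_s"]
    return 0.75 <= dr <= 1.25


def units_to_failure_rule(
    removal_counts: np.ndarray, flags: np.ndarray
) -> tuple[float, float]:
    """Combine the logistic decision boundary with the first failure.

    Fits a logistic regression of the regenerative flag on the removal
    count; the decision boundary is where the predicted probability
    crosses 0.5.  The number of units to failure is the larger of that
    boundary and the last removal count that still regenerated before
    the first failure.  Returns (units_to_failure, boundary).
    """
    counts = np.asarray(removal_counts, float)
    flags = np.asarray(flags, bool)
    if flags.all():
        return float(counts.max()), float(counts.max())
    if not flags.any():
        return 0.0, 0.0
    first_fail = np.flatnonzero(~flags)[0]
    last_ok = counts[first_fail - 1] if first_fail > 0 else 0.0
    lr = LogisticRegression(C=1e6, max_iter=500)
    lr.fit(counts[:, None], flags.astype(int))
    coef = float(lr.coef_[0, 0])
    boundary = -float(lr.intercept_[0]) / coef if abs(coef) > 1e-12 else 0.0
    boundary = float(np.clip(boundary, 0.0, counts.max()))
    return float(max(boundary, last_ok)), boundary


def refit_and_simulate(
    counts: np.ndarray,
    dia_binned: np.ndarray,
    bin_width: float = 0.01,
    n_states: int = 2,
    seed: int = 0,
    sim_duration_s: float = 40.0,
    fit_kwargs: dict | None = None,
) -> tuple[RSLDSResults, np.ndarray, dict]:
    """Fit an rSLDS on ``counts``, decode the simulated diaphragm and
    summarize its rhythm.  The workhorse of dropout/subset analyses."""
    model = RecurrentSwitchingLDS(counts, bin_width=bin_width, n_states=n_states)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(seed=seed, **(fit_kwargs or {}))
    dec = fit_diaphragm_decoder(res.latent, dia_binned, seed=seed)
    x_sim, _ = res.simulate(int(round(sim_duration_s / bin_width)), seed=seed)
    sim_dia = dec.decode(x_sim)
    stats = simulated_breath_stats(sim_dia, 1.0 / bin_width)
    return res, sim_dia, stats


def dropout_analysis(
    counts: np.ndarray,
    dia_binned: np.ndarray,
    metric: np.ndarray,
    order: str = "coherence-descending",
    schedule: np.ndarray | None = None,
    bin_width: float = 0.01,
    seed: int = 0,
    fit_kwargs: dict | None = None,
) -> DropoutResult:
    """Sequential unit-removal analysis of model regeneration.

    Units are removed in the requested order -- by descending or
    ascending coherence, by descending firing rate, or randomly -- and
    the model plus diaphragm decoder are refit (cold start) at each
    removal count in ``schedule``.  A step is regenerative when its
    simulated diaphragm keeps 75-150% of the full model's simulated
    frequency and 75-125% of its inspiratory duration.  The number of
    units to failure combines a logistic-regression decision boundary
    with the first observed failure (whichever is greater).
    """
    counts = np.asarray(counts, float)
    n_units = counts.shape[0]
    metric = np.asarray(metric, float)
    rng = np.random.default_rng(seed)
    if order == "coherence-descending" or order == "rate-descending":
        removal = np.argsort(-metric)
    elif order == "coherence-ascending":
        removal = np.argsort(metric)
    elif order == "random":
        removal = rng.permutation(n_units)
    else:
        raise ValueError(f"unknown removal order {order!r}")

    if schedule is None:
        step = max(1, (n_units - 12) // 10)
        schedule = np.arange(0, n_units - 11, step)
    schedule = np.asarray(sorted(set(int(s) for s in schedule)))

    full_res, _, full_stats = refit_and_simulate(
        counts, dia_binned, bin_width=bin_width, seed=seed, fit_kwargs=fit_kwargs
    )
    if not _regen_vs_full(full_stats, full_stats) or full_stats["n_bursts"] < 5:
        raise ValueError("full model is not regenerative; dropout undefined")

    flags, stats_list = [], []
    for n_rm in schedule:
        if n_rm == 0:
            flags.append(True)  # removing nothing is regenerative by definition
            stats_list.append(full_stats)
            continue
        keep = np.setdiff1d(np.arange(n_units), removal[:n_rm])
        if len(keep) < 10:
            break
        _, _, st = refit_and_simulate(
            counts[keep], dia_binned, bin_width=bin_width, seed=seed,
            fit_kwargs=fit_kwargs,
        )
        flags.append(_regen_vs_full(st, full_stats))
        stats_list.append(st)
    schedule = schedule[: len(flags)]
    utf, boundary = units_to_failure_rule(schedule, np.asarray(flags))
    return DropoutResult(
        order=order,
        removal_counts=schedule,
        regenerative=np.asarray(flags),
        units_to_failure=utf,
        fraction_of_population=utf / n_units,
        logistic_boundary=boundary,
        full_stats=full_stats,
        step_stats=stats_list,
    )


def subset_refit(
    counts: np.ndarray,
    dia_binned: np.ndarray,
    subsets: dict[str, np.ndarray],
    bin_width: float = 0.01,
    seed: int = 0,
    min_units: int = 10,
    fit_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Refit the model on arbitrary unit subsets and classify
    regeneration (absolute spectral rule) for each.

    ``subsets`` maps a name to a boolean mask or index array over units
    (e.g. rostrocaudal windows).  Subsets below ``min_units`` are
    skipped.
    """
    counts = np.asarray(counts, float)
    rows = []
    for name, sel in subsets.items():
        sel = np.asarray(sel)
        idx = np.flatnonzero(sel) if sel.dtype == bool else sel
        if len(idx) < min_units:
            logger.warning("subset %s has %d units (<%d); skipped",
                           name, len(idx), min_units)
            continue
        _, sim_dia, st = refit_and_simulate(
            counts[idx], dia_binned, bin_width=bin_width, seed=seed,
            fit_kwargs=fit_kwargs,
        )
        flag = classify_regenerative(sim_dia, 1.0 / bin_width)
        rows.append(
            {"subset": name, "n_units": len(idx), "regenerative": flag, **st}
        )
    return pd.DataFrame(rows)
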