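"""Activity-pattern clustering with silhouette model selection.

Phase tuning curves are smoothed (circular 3-sample Savitzky-Golay),
max-normalized, and clustered in three feature spaces -- the raw
100-bin matrix R, its leading four principal components P, and twenty
nonnegative matrix factorization scores N -- with both k-means and Ward
agglomerative clustering, for 2..15 clusters.  The optimal cluster
number maximizes the silhouette score; shuffle controls recompute the
silhouette under random label permutations; a coherence-threshold sweep
repeats the whole analysis on increasingly coherent subpopulations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import NMF, PCA
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

FEATURE_SETS = ("raw", "pca", "nmf")
METHODS = ("kmeans", "ward")


@dataclass
class FeatureSets:
    """The three clustering feature spaces derived from tuning curves."""

    R: np.ndarray                  # (n, 100) smoothed, max-normalized
    P: np.ndarray                  # (n, 4) principal-component scores
    N: np.ndarray                  # (n, 20) nonnegative factor scores
    pca_explained: float           # variance fraction captured by P
    kept: np.ndarray               # indices of retained units

    def get(self, name: str) -> np.ndarray:
        return {"raw": self.R, "pca": self.P, "nmf": self.N}[name]


def prepare_feature_sets(
    tunings: np.ndarray,
    n_pcs: int = 4,
    n_nmf: int = 20,
    min_units: int = 25,
    seed: int = 0,
) -> FeatureSets:
    """Build the raw/PCA/NMF feature sets from a tuning matrix.

    Each row is smoothed with a circular (wrap-around) 3-sample
    Savitzky-Golay filter of polynomial order 1 and divided by its
    maximum.  Rows with zero maximum are dropped with a warning.
    """
    x = np.asarray(tunings, dtype=float)
    if x.ndim != 2:
        raise ValueError("tunings must be a (units, bins) matrix")
    if len(x) < min_units:
        raise ValueError(
            f"need >= {min_units} units for a well-posed factorization, got {len(x)}"
        )
    pad = 2
    wrapped = np.concatenate([x[:, -pad:], x, x[:, :pad]], axis=1)
    smooth = savgol_filter(wrapped, 3, 1, axis=1)[:, pad:-pad]
    maxima = smooth.max(axis=1)
    kept = np.flatnonzero(maxima > 0)
    if len(kept) < len(x):
        logger.warning("dropping %d units with zero tuning maximum", len(x) - len(kept))
    r = smooth[kept] / maxima[kept, None]
    r = np.clip(r, 0.0, None)

    pca = PCA(n_components=min(n_pcs, len(kept) - 1, r.shape[1]))
    p = pca.fit_transform(r)
    explained = float(pca.explained_variance_ratio_.sum())
    if explained < 0.95:
        logger.warning("leading %d PCs explain only %.1f%% of variance",
                       n_pcs, 100 * explained)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nmf = NMF(
            n_components=min(n_nmf, len(kept) - 1),
            init="nndsvda",
            random_state=seed,
            max_iter=500,
        )
        n = nmf.fit_transform(r)
    return FeatureSets(R=r, P=p, N=n, pca_explained=explained, kept=kept)


def _cluster(features: np.ndarray, method: str, k: int, seed: int) -> np.ndarray:
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        return km.fit_predict(features)
    if method == "ward":
        return AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(
            features
        )
    raise ValueError(f"unknown clustering method {method!r}")


def cluster_sweep(
    features: FeatureSets,
    k_range: range = range(2, 16),
    methods: tuple[str, ...] = METHODS,
    feature_sets: tuple[str, ...] = FEATURE_SETS,
    seed: int = 0,
) -> pd.DataFrame:
    """Cluster every (feature set, method, k) combination.

    Returns a tidy frame with columns ``feature_set, method, k,
    silhouette, labels``.  The silhouette is Euclidean, computed in the
    same feature space that was clustered.  Degenerate configurations
    (k >= n, or a single distinct point) are skipped with a warning.
    """
    rows = []
    for fs in feature_sets:
        x = features.get(fs)
        if np.ptp(x, axis=0).max() < 1e-12:
            logger.warning("feature set %s has no variance; skipped", fs)
            continue
        for method in methods:
            for k in k_range:
                if k >= len(x):
                    logger.warning("skipping k=%d >= n=%d", k, len(x))
                    continue
                labels = _cluster(x, method, k, seed)
                if len(np.unique(labels)) < 2:
                    logger.warning("degenerate clustering (%s/%s/k=%d)", fs, method, k)
                    continue
                try:
                    sil = float(silhouette_score(x, labels))
                except ValueError:
                    sil = np.nan
                if not np.isfinite(sil):
                    logger.warning("silhouette undefined (%s/%s/k=%d)", fs, method, k)
                    continue
                rows.append(
                    {
                        "feature_set": fs,
                        "method": method,
                        "k": k,
                        "silhouette": sil,
                        "labels": labels,
                    }
                )
    return pd.DataFrame(rows)


def optimal_k(sweep: pd.DataFrame) -> int:
    """Cluster number maximizing the mean silhouette across techniques.

    Ties break toward the smaller k.
    """
    if sweep.empty:
        raise ValueError("empty sweep")
    mean_sil = sweep.groupby("k")["silhouette"].mean().sort_index()
    return int(mean_sil.idxmax())


def shuffle_control(
    features: np.ndarray,
    labels: np.ndarray,
    n_shuffles: int = 5000,
    percentile: float = 99.0,
    seed: int = 0,
) -> float:
    """Silhouette of label-shuffled controls.

    Recomputes the silhouette after randomly permuting the cluster
    labels ``n_shuffles`` times and reports the requested percentile
    (the 99th by default) of the null distribution.
    """
    rng = np.random.default_rng(seed)
    scores = np.empty(n_shuffles)
    labels = np.asarray(labels)
    for i in range(n_shuffles):
        scores[i] = silhouette_score(features, rng.permutation(labels))
    return float(np.percentile(scores, percentile))


def coherence_threshold_sweep(
    tunings: np.ndarray,
    c_lb: np.ndarray,
    thresholds: tuple[float, ...] = (0.0, 0.1, 0.3, 0.5, 0.7, 0.9, 0.99),
    k_range: range = range(2, 16),
    min_units: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeat the clustering sweep on increasingly coherent subsets.

    For each threshold T the analysis keeps units with coherence lower
    bound above T, rebuilds the feature sets and reruns the sweep.
    Returns one row per threshold with the optimal k, the mean
    silhouette at that k and its 95% confidence interval across the six
    technique combinations (3 feature sets x 2 clusterers).  Subsets
    with fewer than ``min_units`` units are skipped with a warning.
    """
    c_lb = np.asarray(c_lb, float)
    rows = []
    for thr in thresholds:
        mask = c_lb > thr
        if mask.sum() < min_units:
            logger.warning(
                "threshold %.2f keeps %d units (< %d); skipped", thr, mask.sum(),
                min_units,
            )
            continue
        feats = prepare_feature_sets(
            np.asarray(tunings)[mask], min_units=min_units, seed=seed
        )
        sweep = cluster_sweep(feats, k_range=k_range, seed=seed)
        if sweep.empty:
            continue
        k_opt = optimal_k(sweep)
        at_k = sweep[sweep.k == k_opt]["silhouette"].to_numpy()
        sem = at_k.std(ddof=1) / np.sqrt(len(at_k)) if len(at_k) > 1 else 0.0
        rows.append(
            {
                "threshold": thr,
                "n_units": int(mask.sum()),
                "optimal_k": k_opt,
                "mean_silhouette": float(at_k.mean()),
                "ci95_halfwidth": float(1.96 * sem),
            }
        )
    return pd.DataFrame(rows)
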