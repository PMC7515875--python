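"""Co-expression profiling of exon-only vs exon:intron-ratio features.

Each gene becomes a feature vector across samples: min-rescaled counts
(or the ratio of min-rescaled exon to min-rescaled intron counts), log2
transformed and z-scored per gene.  Genes are clustered with K-means
under the Pearson-correlation distance d(x, y) = 1 - r(x, y); because
rows are z-scored, 1 - r = ||x - y||^2 / (2 d), so Lloyd's mean-update
step remains the correct centroid under this distance.  The number of
clusters is chosen by a Gaussian-sphere AIC, and partitions are compared
with the adjusted Rand index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .genemodel import MatchedCounts
from .stats import rescale_by_min

__all__ = [
    "FeatureMatrix",
    "ClusterModel",
    "build_features",
    "kmeans_corr",
    "select_k_aic",
    "adjusted_rand_index",
    "rank_overlap",
]

FEATURE_MODES = ("exon_only", "exon_intron_ratio")


@dataclass
class FeatureMatrix:
    """Genes x samples z-scored log2 feature profiles."""

    values: pd.DataFrame
    mode: str
    dropped: list[str]

    @property
    def genes(self) -> pd.Index:
        return self.values.index


def _zscore_rows(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    z = np.where(sd > 0, (mat - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return z, ok


def build_features(mc: MatchedCounts, mode: str) -> FeatureMatrix:
    """Per-gene min-rescale -> log2 -> z-score feature construction.

    ``exon_only`` uses the exon counts alone; ``exon_intron_ratio``
    divides min-rescaled exon by min-rescaled intron counts (with the +1
    guard when a minimum is zero).  Genes whose profile has zero variance
    after the transform are dropped and reported.
    """
    if mode not in FEATURE_MODES:
        raise ValueError(f"mode must be one of {FEATURE_MODES}")
    if mc.exon.shape[1] < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    exon = mc.exon.to_numpy(dtype=float)
    rescaled_e = np.vstack([rescale_by_min(row, zero_guard=True) for row in exon])
    if mode == "exon_only":
        feats = np.log2(rescaled_e)
    else:
        intron = mc.intron.to_numpy(dtype=float)
        rescaled_i = np.vstack([rescale_by_min(row, zero_guard=True) for row in intron])
        feats = np.log2(rescaled_e / rescaled_i)
    z, ok = _zscore_rows(feats)
    dropped = mc.genes[~ok].tolist()
    values = pd.DataFrame(z[ok], index=mc.genes[ok], columns=mc.samples)
    return FeatureMatrix(values=values, mode=mode, dropped=dropped)


@dataclass
class ClusterModel:
    k: int
    assignment: pd.Series  # gene -> cluster id
    centroids: np.ndarray  # k x samples, z-scored
    wcss: float  # total within-cluster correlation distance
    wcss_eucl: float  # Euclidean WCSS of the z-scored data
    aic: float


def _zscore_vec(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def _corr_to_centroids(z: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # rows and centroids are z-scored (population sd) so r = x.c / d
    return z @ centroids.T / z.shape[1]


def _lloyd(z: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100):
    n = z.shape[0]
    centroids = z[rng.choice(n, size=k, replace=False)].copy()
    assign = np.full(n, -1)
    for _ in range(max_iter):
        corr = _corr_to_centroids(z, centroids)
        new_assign = corr.argmax(axis=1)
        dist_to_own = 1.0 - corr[np.arange(n), new_assign]
        for c in range(k):  # re-seed empty clusters from the farthest point
            if not (new_assign == c).any():
                far = int(np.argmax(dist_to_own))
                new_assign[far] = c
                dist_to_own[far] = 0.0
        if (new_assign == assign).all():
            break
        assign = new_assign
        for c in range(k):
            centroids[c] = _zscore_vec(z[assign == c].mean(axis=0))
    corr = _corr_to_centroids(z, centroids)
    wcss = float(np.sum(1.0 - corr[np.arange(n), assign]))
    return assign, centroids, wcss


def kmeans_corr(
    fm: FeatureMatrix, k: int, restarts: int = 50, seed: int = 0
) -> ClusterModel:
    """K-means under correlation distance, best of ``restarts`` random starts."""
    z = fm.values.to_numpy(dtype=float)
    n, d = z.shape
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} genes")
    root = np.random.default_rng(seed)
    best = None
    for sub in root.spawn(restarts):
        assign, centroids, wcss = _lloyd(z, k, sub)
        if best is None or wcss < best[2]:
            best = (assign, centroids, wcss)
    assign, centroids, wcss = best
    means = np.vstack([z[assign == c].mean(axis=0) for c in range(k)])
    wcss_eucl = float(sum(np.sum((z[assign == c] - means[c]) ** 2) for c in range(k)))
    aic = _kmeans_aic(wcss_eucl, n, d, k)
    return ClusterModel(
        k=k,
        assignment=pd.Series(assign, index=fm.genes, name="cluster"),
        centroids=centroids,
        wcss=wcss,
        wcss_eucl=wcss_eucl,
        aic=aic,
    )


def _kmeans_aic(wcss_eucl: float, n: int, d: int, k: int) -> float:
    # Gaussian-sphere information criterion: n*d*ln(WCSS/(n*d)) + ln(n*d)*k*d.
    # The Schwarz (sample-size-aware) weight on the k*d centroid parameters is
    # required here: a constant weight of 2 is smaller than the chance WCSS
    # reduction an extra centroid buys on pure noise at these matrix sizes,
    # so it would keep splitting unstructured data.
    return n * d * np.log(max(wcss_eucl, 1e-12) / (n * d)) + np.log(n * d) * k * d


def select_k_aic(
    fm: FeatureMatrix, k_range: list[int], restarts: int = 50, seed: int = 0
) -> ClusterModel:
    """Fit K-means for each candidate k and return the AIC minimiser.

    Ties break toward the smallest k.
    """
    if not k_range:
        raise ValueError("k_range must be non-empty")
    best: ClusterModel | None = None
    for k in sorted(k_range):
        model = kmeans_corr(fm, k, restarts=restarts, seed=seed)
        if best is None or model.aic < best.aic:
            best = model
    return best


def adjusted_rand_index(a, b) -> float:
    """Hubert-Arabie adjusted Rand index between two labelings.

    Both arguments are label sequences over the same elements (same
    length, same order); 1 for identical partitions (up to relabeling),
    ~0 under independent random labelings.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("partitions must label the same element set")
    return float(adjusted_rand_score(a, b))


def rank_overlap(list_a, list_b, top_n: int) -> int:
    """Size of the intersection of the two top-``top_n`` prefixes."""
    la, lb = list(list_a), list(list_b)
    if set(la) != set(lb):
        raise ValueError("ranked lists must cover the same gene universe")
    if top_n > len(la):
        raise ValueError(f"top_n={top_n} exceeds universe size {len(la)}")
    return len(set(la[:top_n]) & set(lb[:top_n]))
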