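"""Quantitative analyses of FC profiles and their latent embeddings.

Covers the full battery run on embedded connectivity profiles: silhouette-
index network segregation (with bootstrap confidence intervals), inter- and
intra-subject dispersion and their ratio, connectome fingerprinting from
"barcode" vectors, k-means subclustering of a network's embeddings,
trait-embedding correlations with Benjamini-Hochberg (linear step-up) FDR
correction, ridge-regularized covariate prediction, and smoothed 2-D latent
density maps for cohort comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold
from sklearn.svm import SVR
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SilhouetteResult",
    "FingerprintResult",
    "silhouette",
    "bootstrap_network_si",
    "dispersion",
    "dispersion_snr",
    "connectome_barcode",
    "latent_barcode",
    "fingerprint",
    "subcluster",
    "trait_correlation",
    "predict_covariate",
    "density_map",
    "density_difference",
    "default_lambda_grid",
]


class DegenerateInputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# silhouette
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SilhouetteResult:
    """Per-sample silhouette values with their components.

    si = (b - a) / max(a, b), where ``a`` is the mean distance to the other
    members of the sample's own network and ``b`` the smallest mean distance
    to any other network.  Samples in singleton networks have undefined si
    (NaN) and are excluded from all means.
    """

    si: np.ndarray
    a: np.ndarray
    b: np.ndarray
    labels: np.ndarray
    network_mean: dict
    overall_mean: float
    network_ci: dict | None = None


def _pairwise(points: np.ndarray, metric: str) -> np.ndarray:
    if metric == "correlation":
        d = cdist(points, points, metric="correlation")
    elif metric == "euclidean":
        d = cdist(points, points, metric="euclidean")
    else:
        raise ValueError("metric must be 'correlation' or 'euclidean'")
    np.fill_diagonal(d, 0.0)
    return d


def silhouette(points: np.ndarray, labels, metric: str = "euclidean") -> SilhouetteResult:
    """Silhouette index of each sample against its network labels.

    Correlation distance (1 - Pearson r) is the convention for vertex-space
    FC profiles; Euclidean distance for latent embeddings.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if points.shape[0] != labels.shape[0]:
        raise ValueError("points and labels disagree in length")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least two networks")
    d = _pairwise(points, metric)
    n = points.shape[0]
    a = np.full(n, np.nan)
    b = np.full(n, np.nan)
    members = {u: np.flatnonzero(labels == u) for u in uniq}
    for i in range(n):
        own = members[labels[i]]
        if own.size > 1:
            a[i] = d[i, own].sum() / (own.size - 1)   # excludes self (d_ii = 0)
        b[i] = min(d[i, members[u]].mean() for u in uniq if u != labels[i])
    with np.errstate(invalid="ignore"):
        si = (b - a) / np.maximum(a, b)
    net_mean = {
        u: float(np.nanmean(si[members[u]])) if np.isfinite(si[members[u]]).any() else np.nan
        for u in uniq
    }
    return SilhouetteResult(
        si=si, a=a, b=b, labels=labels,
        network_mean=net_mean,
        overall_mean=float(np.nanmean(si)),
    )


def bootstrap_network_si(
    embeddings: np.ndarray,
    labels,
    metric: str = "euclidean",
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """95% CI of per-network mean silhouette by bootstrapping subjects.

    ``embeddings`` is (n_subjects, n_samples, n_dims); each bootstrap draw
    resamples subjects with replacement, averages embeddings across the
    resampled subjects, and recomputes the per-network mean silhouette.
    Returns {network: (lo, hi)} percentile (2.5/97.5) intervals.
    """
    embeddings = np.asarray(embeddings, dtype=float)
    if embeddings.ndim != 3 or embeddings.shape[0] < 2:
        raise ValueError("need (n_subjects >= 2, n_samples, n_dims) embeddings")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_subj = embeddings.shape[0]
    uniq = np.unique(np.asarray(labels))
    draws = {u: [] for u in uniq}
    for _ in range(n_boot):
        pick = rng.integers(n_subj, size=n_subj)
        res = silhouette(embeddings[pick].mean(axis=0), labels, metric=metric)
        for u in uniq:
            draws[u].append(res.network_mean[u])
    return {
        u: (float(np.nanpercentile(v, 2.5)), float(np.nanpercentile(v, 97.5)))
        for u, v in draws.items()
    }


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def dispersion(points: np.ndarray) -> float:
    """Mean squared Euclidean distance to the centroid (mean, not sum, so
    inter- and intra-subject values are comparable across sample counts)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise ValueError("dispersion of an empty point set is undefined")
    centroid = points.mean(axis=0)
    return float(((points - centroid) ** 2).sum(axis=1).mean())


def dispersion_snr(inter: float, intra: float) -> float:
    """Ratio of inter-subject to intra-subject dispersion."""
    if intra <= 0:
        raise ZeroDivisionError("intra-subject dispersion must be positive")
    return inter / intra


# ---------------------------------------------------------------------------
# fingerprinting
# ---------------------------------------------------------------------------

def connectome_barcode(connectome: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Strictly-lower-triangle entries of a symmetric connectome, row-major."""
    c = np.asarray(connectome, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("connectome must be square")
    if not np.allclose(c, c.T, atol=atol):
        raise ValueError("connectome is not symmetric within tolerance")
    i, j = np.tril_indices(c.shape[0], k=-1)
    return c[i, j]


def latent_barcode(embeddings: np.ndarray) -> np.ndarray:
    """Concatenate each parcel's latent values into one session vector.

    ``embeddings`` is (n_parcels, n_dims) in a fixed parcel order; the
    barcode has length n_parcels * n_dims.
    """
    e = np.asarray(embeddings, dtype=float)
    if e.ndim != 2:
        raise ValueError("embeddings must be a parcel x dim table")
    return e.reshape(-1)


@dataclass(frozen=True)
class FingerprintResult:
    similarity: np.ndarray      # (S, S) Pearson r, rows = session-1 subjects
    hits_1: int                 # correct identifications from session 1
    hits_2: int
    accuracy: float             # (hits_1/S + hits_2/S) / 2
    ties: int


def fingerprint(barcodes_s1: np.ndarray, barcodes_s2: np.ndarray) -> FingerprintResult:
    """Subject identification across two sessions via barcode correlation.

    similarity[i, j] = Pearson r(session-1 barcode of subject i, session-2
    barcode of subject j).  Direction 1 predicts each session-1 subject as
    the argmax over session-2 barcodes; direction 2 is symmetric.  Exact
    ties resolve to the lowest index and are counted.
    """
    b1 = np.atleast_2d(np.asarray(barcodes_s1, dtype=float))
    b2 = np.atleast_2d(np.asarray(barcodes_s2, dtype=float))
    if b1.shape != b2.shape or b1.shape[0] < 2:
        raise ValueError("need matching barcode sets for >= 2 subjects")
    if (b1.std(axis=1) == 0).any() or (b2.std(axis=1) == 0).any():
        raise DegenerateInputError("constant barcode has undefined correlation")
    z1 = (b1 - b1.mean(axis=1, keepdims=True))
    z1 /= np.linalg.norm(z1, axis=1, keepdims=True)
    z2 = (b2 - b2.mean(axis=1, keepdims=True))
    z2 /= np.linalg.norm(z2, axis=1, keepdims=True)
    sim = z1 @ z2.T
    s = sim.shape[0]
    pred1 = sim.argmax(axis=1)          # ties: argmax takes the lowest index
    pred2 = sim.argmax(axis=0)
    ties = int(
        sum((sim[i] == sim[i].max()).sum() > 1 for i in range(s))
        + sum((sim[:, j] == sim[:, j].max()).sum() > 1 for j in range(s))
    )
    hits_1 = int((pred1 == np.arange(s)).sum())
    hits_2 = int((pred2 == np.arange(s)).sum())
    return FingerprintResult(
        similarity=sim, hits_1=hits_1, hits_2=hits_2,
        accuracy=(hits_1 / s + hits_2 / s) / 2.0, ties=ties,
    )


# ---------------------------------------------------------------------------
# subclustering
# ---------------------------------------------------------------------------

def subcluster(
    embeddings: np.ndarray,
    k: int = 2,
    n_restarts: int = 10,
    seed: int = 0,
    parcel_ids: np.ndarray | None = None,
):
    """k-means over embedded samples (e.g. one network's parcels x subjects).

    Returns (labels, centroids, probability_table); the table gives, per
    parcel, the fraction of its samples assigned to each cluster (a
    percentage of the population when samples are one-per-subject).
    Centroids can be pushed through the decoder to visualize subnetworks.
    """
    x = np.asarray(embeddings, dtype=float)
    if x.ndim != 2 or x.shape[0] < k:
        raise ValueError("need a (samples >= k) x dim matrix")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(x)
    labels, centroids = km.labels_, km.cluster_centers_
    table = None
    if parcel_ids is not None:
        df = pd.DataFrame({"parcel": np.asarray(parcel_ids), "cluster": labels})
        table = (
            df.groupby("parcel")["cluster"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
            .reindex(columns=range(k), fill_value=0.0)
        )
    return labels, centroids, table


# ---------------------------------------------------------------------------
# trait correlation with FDR
# ---------------------------------------------------------------------------

def trait_correlation(
    embeddings: np.ndarray,
    scores: dict,
    q: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of each (parcel, latent dim) with each trait score.

    ``embeddings`` is (n_subjects, n_parcels, n_dims); ``scores`` maps trait
    name -> (n_subjects,) values, NaN marking missing subjects (dropped
    pairwise).  p-values are adjusted by the Benjamini-Hochberg linear
    step-up procedure within each (dim, trait) family across parcels.
    """
    e = np.asarray(embeddings, dtype=float)
    if e.ndim != 3:
        raise ValueError("embeddings must be subject x parcel x dim")
    n_subj, n_parcel, n_dim = e.shape
    rows = []
    for trait, vals in scores.items():
        vals = np.asarray(vals, dtype=float)
        keep_all = np.isfinite(vals)
        if keep_all.sum() < 3:
            raise ValueError(f"trait {trait!r} has fewer than 3 scored subjects")
        if np.nanstd(vals) == 0:
            raise DegenerateInputError(f"trait {trait!r} has zero variance")
        for dim in range(n_dim):
            fam = []
            for p in range(n_parcel):
                x = e[keep_all, p, dim]
                y = vals[keep_all]
                r, pval = stats.pearsonr(x, y)
                fam.append((trait, dim, p, r, pval))
            praw = np.array([f[4] for f in fam])
            flag, padj, _, _ = multipletests(praw, alpha=q, method="fdr_bh")
            for (trait_, dim_, parc, r, pval), fl, pa in zip(fam, flag, padj):
                rows.append((trait_, dim_, parc, r, pval, pa, bool(fl)))
    return pd.DataFrame(
        rows,
        columns=["trait", "dim", "parcel", "r", "p", "p_adj", "significant"],
    )


# ---------------------------------------------------------------------------
# covariate prediction
# ---------------------------------------------------------------------------

def default_lambda_grid() -> np.ndarray:
    """15 regularization strengths log-evenly spaced over [1e-8, 1e3]."""
    return np.logspace(-8, 3, 15)


def predict_covariate(
    features: np.ndarray,
    target: np.ndarray,
    split_fraction: float = 0.8,
    lambda_grid: np.ndarray | None = None,
    n_repeats: int = 100,
    seed: int = 0,
    model: str = "ridge",
) -> dict:
    """Predict a session covariate (e.g. age) from embedding features.

    Each repeat draws a seeded ``split_fraction`` train split, picks the
    regularization strength by 5-fold cross-validation on the training
    portion, refits, and scores Pearson r between predicted and held-out
    targets.  The default estimator is an L2-regularized linear model
    (ridge); ``model="svr"`` switches to epsilon-insensitive SVR with the
    same grid interpreted as 1/C.
    Returns mean, sd, 95% percentile CI, and the per-repeat r values.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    if x.shape[0] != y.shape[0] or x.shape[0] < 10:
        raise ValueError("need >= 10 sessions with matching features/targets")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid)
    n = x.shape[0]
    n_train = int(round(split_fraction * n))
    if not (0 < n_train < n):
        raise ValueError("split leaves an empty train or test set")

    def make(lam):
        if model == "ridge":
            return Ridge(alpha=lam)
        if model == "svr":
            return SVR(kernel="linear", C=1.0 / lam)
        raise ValueError("model must be 'ridge' or 'svr'")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rs = []
    for _ in range(n_repeats):
        order = rng.permutation(n)
        tr, te = order[:n_train], order[n_train:]
        cv = KFold(n_splits=5, shuffle=True, random_state=int(rng.integers(2**31)))
        cv_scores = np.zeros(grid.size)
        for itr, iva in cv.split(tr):
            a, b = tr[itr], tr[iva]
            for gi, lam in enumerate(grid):
                est = make(lam).fit(x[a], y[a])
                cv_scores[gi] += ((est.predict(x[b]) - y[b]) ** 2).mean()
        best = make(grid[int(np.argmin(cv_scores))]).fit(x[tr], y[tr])
        pred = best.predict(x[te])
        if np.std(pred) == 0 or np.std(y[te]) == 0:
            rs.append(0.0)
        else:
            rs.append(float(stats.pearsonr(pred, y[te])[0]))
    rs = np.asarray(rs)
    return {
        "mean": float(rs.mean()),
        "sd": float(rs.std(ddof=1)) if rs.size > 1 else 0.0,
        "ci": (float(np.percentile(rs, 2.5)), float(np.percentile(rs, 97.5))),
        "values": rs,
    }


# ---------------------------------------------------------------------------
# density maps
# ---------------------------------------------------------------------------

def density_map(
    embeddings: np.ndarray,
    grid_spec: tuple[float, float, float, float, int],
    bandwidth: float = 0.0,
) -> np.ndarray:
    """Gaussian-smoothed 2-D probability density of latent points.

    ``grid_spec`` is (xmin, xmax, ymin, ymax, bins); ``bandwidth`` is the
    smoothing sigma in bins.  The result sums to 1 over the grid so that
    densities from different cohorts on the same grid subtract cleanly.
    """
    e = np.asarray(embeddings, dtype=float)
    if e.ndim != 2 or e.shape[1] != 2:
        raise ValueError("density maps need 2-D embeddings")
    xmin, xmax, ymin, ymax, bins = grid_spec
    h, _, _ = np.histogram2d(
        e[:, 0], e[:, 1], bins=bins, range=[[xmin, xmax], [ymin, ymax]]
    )
    if bandwidth > 0:
        h = gaussian_filter(h, sigma=bandwidth)
    total = h.sum()
    return h / total if total > 0 else h


def density_difference(d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """Signed elementwise difference of two density maps on a shared grid."""
    d1, d2 = np.asarray(d1), np.asarray(d2)
    if d1.shape != d2.shape:
        raise ValueError("density maps must share one grid")
    return d1 - d2
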