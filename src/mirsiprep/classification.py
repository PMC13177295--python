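"""Spectral classification: correlation, PCA, UMAP, feature importance.

This stage asks whether tissue (kidney vs liver) and preparation (FF vs
FFPE) labels are recoverable from pixel spectra.  ROI-mean spectra are
compared by Pearson correlation; Z-scored spectra go through PCA and a
2-D UMAP embedding for cluster visualisation, and an L2-regularised
logistic regression on the Z-scored spectra ranks wavenumbers by
|coefficient| (fitting on spectra rather than embedding coordinates so
the importances map back to wavenumbers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import silhouette_score

__all__ = [
    "EmbeddingResult",
    "roi_correlation_matrix",
    "pca_reduce",
    "umap_embed",
    "cluster_separation_metrics",
    "logistic_feature_importance",
]

PCA_COMPONENTS = 20
UMAP_N_NEIGHBORS = 15
UMAP_MIN_DIST = 0.1
TOP_N_WAVENUMBERS = 40


@dataclass(frozen=True)
class EmbeddingResult:
    """2-D embedding coordinates with their labels."""

    coords: np.ndarray  # (n, 2)
    labels: pd.DataFrame  # one row per spectrum (e.g. tissue, preparation)
    pca_components: int
    seed: int | None


def roi_correlation_matrix(
    roi_mean_spectra: pd.DataFrame | np.ndarray,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation matrix of ROI-mean spectra.

    Rows are ROIs (index = ROI labels when a DataFrame is given).  The
    result is exactly symmetric with a unit diagonal.
    """
    if isinstance(roi_mean_spectra, pd.DataFrame):
        data = roi_mean_spectra.to_numpy(dtype=float)
        idx = [str(i) for i in roi_mean_spectra.index]
    else:
        data = np.asarray(roi_mean_spectra, dtype=float)
        idx = labels if labels is not None else [str(i) for i in range(len(data))]
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need at least 2 ROI spectra")
    if np.any(data.std(axis=1) == 0):
        raise ValueError("constant ROI spectrum has undefined correlation")
    r = np.corrcoef(data)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=idx, columns=idx)


def pca_reduce(
    spectra: np.ndarray, n_components: int = PCA_COMPONENTS
) -> tuple[np.ndarray, np.ndarray]:
    """PCA scores and explained-variance fractions.

    Component signs are fixed so the largest-magnitude loading of each
    component is positive, making the scores deterministic.  If the data
    rank is below ``n_components`` the decomposition is reduced with a
    warning rather than failing.
    """
    x = np.asarray(spectra, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected (n_spectra, n_wavenumbers)")
    max_comp = min(x.shape)
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds min(n_spectra, n_wavenumbers)"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    rank = int(np.sum(pca.explained_variance_ > 1e-12 * pca.explained_variance_[0]))
    if rank < n_components:
        import warnings

        warnings.warn(
            f"data rank {rank} < n_components {n_components}; "
            "trailing components carry no variance",
            RuntimeWarning,
            stacklevel=2,
        )
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(
        pca.components_[np.arange(n_components),
                        np.abs(pca.components_).argmax(axis=1)]
    )
    flip[flip == 0] = 1.0
    scores = scores * flip[None, :]
    return scores, pca.explained_variance_ratio_.copy()


def umap_embed(
    scores: np.ndarray,
    n_neighbors: int = UMAP_N_NEIGHBORS,
    min_dist: float = UMAP_MIN_DIST,
    seed: int | None = 0,
    labels: pd.DataFrame | None = None,
    pca_components: int | None = None,
) -> EmbeddingResult:
    """2-D UMAP embedding of (typically PCA-reduced) spectra.

    Seed-reproducible: a fixed ``seed`` pins the embedding exactly for a
    given umap-learn version.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2 or x.shape[0] < 10:
        raise ValueError("need at least 10 spectra for a UMAP embedding")
    import umap  # deferred: numba compilation is slow at import time

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, x.shape[0] - 1),
        min_dist=min_dist,
        random_state=seed,
    )
    coords = np.asarray(reducer.fit_transform(x), dtype=float)
    if labels is None:
        labels = pd.DataFrame(index=range(x.shape[0]))
    return EmbeddingResult(
        coords=coords,
        labels=labels.reset_index(drop=True),
        pca_components=pca_components if pca_components is not None else x.shape[1],
        seed=seed,
    )


def cluster_separation_metrics(
    embedding: EmbeddingResult | np.ndarray,
    labels: np.ndarray | pd.Series,
) -> pd.DataFrame:
    """Pairwise silhouette and centroid distance between label groups.

    For every unordered label pair, the silhouette score restricted to
    the points of those two groups and the Euclidean distance between
    their centroids on the embedding coordinates.
    """
    coords = embedding.coords if isinstance(embedding, EmbeddingResult) else np.asarray(embedding)
    labels = np.asarray(labels)
    if labels.shape[0] != coords.shape[0]:
        raise ValueError("labels length does not match embedding")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 distinct labels")
    rows = []
    for i in range(uniq.size):
        for j in range(i + 1, uniq.size):
            sel = (labels == uniq[i]) | (labels == uniq[j])
            sub = coords[sel]
            sub_labels = labels[sel]
            if np.sum(labels == uniq[i]) < 2 or np.sum(labels == uniq[j]) < 2:
                raise ValueError(
                    f"labels {uniq[i]!r}/{uniq[j]!r} need >= 2 points each"
                )
            sil = float(silhouette_score(sub, sub_labels))
            ci = coords[labels == uniq[i]].mean(axis=0)
            cj = coords[labels == uniq[j]].mean(axis=0)
            rows.append(
                {
                    "label_a": uniq[i],
                    "label_b": uniq[j],
                    "silhouette": sil,
                    "centroid_distance": float(np.linalg.norm(ci - cj)),
                }
            )
    return pd.DataFrame(rows)


def logistic_feature_importance(
    spectra: np.ndarray,
    labels: np.ndarray | pd.Series,
    wavenumbers: np.ndarray,
    top_n: int = TOP_N_WAVENUMBERS,
    seed: int | None = 0,
    C: float = 1.0,
) -> pd.DataFrame:
    """Top discriminative wavenumbers from L2 logistic regression.

    Fits a binary L2-regularised logistic regression on Z-scored spectra
    (wavenumbers as features) and ranks wavenumbers by |coefficient|.
    Returns ``top_n`` rows (wavenumber, importance, rank) in descending
    importance; regularisation keeps perfectly separable classes stable.
    """
    x = np.asarray(spectra, dtype=float)
    y = np.asarray(labels)
    wns = np.asarray(wavenumbers, dtype=float)
    if x.shape[1] != wns.size:
        raise ValueError("wavenumbers length does not match spectra")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    if counts.min() < 50:
        raise ValueError(
            f"need >= 50 spectra per class, got {dict(zip(classes, counts))}"
        )
    if top_n > wns.size:
        raise ValueError("top_n exceeds the number of wavenumbers")
    # default penalty is L2; C=1 keeps separable classes well-posed
    model = LogisticRegression(C=C, solver="lbfgs", max_iter=2000, random_state=seed)
    model.fit(x, y)
    importance = np.abs(model.coef_[0])
    # stable tie-break on wavenumber so the ranking is order-invariant
    order = np.lexsort((wns, -importance))[:top_n]
    return pd.DataFrame(
        {
            "wavenumber": wns[order],
            "importance": importance[order],
            "rank": np.arange(1, top_n + 1),
        }
    )
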