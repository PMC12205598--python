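"""Redistribution scoring: centroids, Euclidean score, ROC threshold, PCA view.

A protein's redistribution score is the Euclidean distance between the
arithmetic-mean 128-d feature centroid of its cells in the wild-type
background (pooled over replicates) and the centroid in the paralog-deletion
background.  No feature scaling is applied before the distance; Z-scoring is
used only for the PCA visualization.  The classification threshold is chosen
by ROC analysis on visually confirmed true cases against random-pair
controls, taking the smallest candidate threshold that achieves the minimal
false-positive rate (ties broken toward maximal true-positive rate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Operating threshold reported for the original full-scale screen
#: (annotation/reference only; synthetic screens recompute their own).
REFERENCE_THRESHOLD = 4.73


@dataclass(frozen=True)
class ConditionCentroid:
    protein: str
    background: str
    mean: np.ndarray  # 128 per-feature arithmetic means over pooled cells
    n_cells: int


@dataclass(frozen=True)
class RedistributionRecord:
    protein: str
    score: float
    threshold: float
    flag_redistributed: bool


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    fpr: float
    fnr: float
    tpr: float


def condition_centroid(
    embeddings: np.ndarray, protein: str = "", background: str = ""
) -> ConditionCentroid:
    """Arithmetic mean of each feature over all cells pooled across replicates."""
    embeddings = np.asarray(embeddings, dtype=float)
    if embeddings.ndim != 2 or embeddings.shape[0] == 0:
        raise ValueError("centroid requires at least one cell (2-D array)")
    return ConditionCentroid(
        protein=protein,
        background=background,
        mean=embeddings.mean(axis=0),
        n_cells=embeddings.shape[0],
    )


def redistribution_score(c_wt: ConditionCentroid, c_del: ConditionCentroid) -> float:
    """Euclidean distance between a protein's WT and deletion centroids."""
    if c_wt.protein != c_del.protein:
        raise ValueError(f"centroid proteins differ: {c_wt.protein!r} vs {c_del.protein!r}")
    return float(np.linalg.norm(c_wt.mean - c_del.mean))


def select_threshold(scores_true, scores_false) -> ThresholdResult:
    """ROC threshold: minimal FPR on the false set, then maximal TPR.

    Candidate thresholds are midpoints between consecutive sorted unique
    pooled scores; a score is classified positive when it exceeds the
    threshold.  Among candidates achieving the minimal FPR, the smallest
    threshold is returned (which also maximizes TPR at that FPR).
    """
    st = np.asarray(scores_true, dtype=float)
    sf = np.asarray(scores_false, dtype=float)
    if st.size == 0 or sf.size == 0:
        raise ValueError("both score sets must be nonempty")
    pooled = np.unique(np.concatenate([st, sf]))
    if pooled.size < 2:
        candidates = np.array([pooled[0]])  # degenerate: all scores equal
    else:
        candidates = (pooled[:-1] + pooled[1:]) / 2.0
    fprs = np.array([(sf > t).mean() for t in candidates])
    tprs = np.array([(st > t).mean() for t in candidates])
    min_fpr = fprs.min()
    at_min = np.flatnonzero(fprs == min_fpr)
    best = at_min[np.argmax(tprs[at_min])]  # candidates sorted asc; argmax takes first max
    return ThresholdResult(
        threshold=float(candidates[best]),
        fpr=float(fprs[best]),
        fnr=float(1.0 - tprs[best]),
        tpr=float(tprs[best]),
    )


def classify_redistribution(
    scores: dict[str, float], threshold: float
) -> list[RedistributionRecord]:
    """Flag proteins whose score exceeds the threshold (strict)."""
    return [
        RedistributionRecord(
            protein=p, score=s, threshold=threshold, flag_redistributed=bool(s > threshold)
        )
        for p, s in scores.items()
    ]


@dataclass(frozen=True)
class PCAView:
    coordinates: np.ndarray  # (n_cells, 2)
    variance_explained: tuple[float, float]  # percent of total variance
    centroids: dict[tuple[str, str], np.ndarray]  # (protein, background) -> PC coords
    arrows: dict[str, tuple[np.ndarray, np.ndarray]]  # protein -> (WT centroid, DEL centroid)


def pca_view(
    embeddings: np.ndarray,
    proteins: list[str],
    backgrounds: list[str],
) -> PCAView:
    """Two-component PCA of Z-scored features for one pair's four conditions.

    Used for visualization only; scores are always computed in the raw
    feature space.  PC signs follow the convention that each component's
    largest-magnitude loading is positive, making reruns identical.
    """
    from sklearn.decomposition import PCA

    X = np.asarray(embeddings, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("PCA view requires at least 3 cells")
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("degenerate input: all features are constant")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(Z)
    # deterministic sign convention
    for j in range(2):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            pca.components_[j] = -load
            coords[:, j] = -coords[:, j]
    var = tuple(100.0 * v for v in pca.explained_variance_ratio_[:2])
    proteins = np.asarray(proteins)
    backgrounds = np.asarray(backgrounds)
    centroids: dict[tuple[str, str], np.ndarray] = {}
    for p in np.unique(proteins):
        for b in np.unique(backgrounds[proteins == p]):
            sel = (proteins == p) & (backgrounds == b)
            centroids[(str(p), str(b))] = coords[sel].mean(axis=0)
    arrows = {
        str(p): (centroids[(str(p), "WT")], centroids[(str(p), "DELETION")])
        for p in np.unique(proteins)
        if (str(p), "WT") in centroids and (str(p), "DELETION") in centroids
    }
    return PCAView(coordinates=coords, variance_explained=var, centroids=centroids, arrows=arrows)
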