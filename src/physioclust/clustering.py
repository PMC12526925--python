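"""Silhouette-gated staged clustering of embedded trials.

Rather than cutting one dendrogram at ``k``, the procedure refines the
partition in stages.  At each stage the active trials are re-normalized
(per-channel min–max over the active subset's pairs), re-embedded in 3D
and tentatively split in two by hierarchical agglomerative clustering
(HAC).  If the silhouette coefficient of that 2-split exceeds the
threshold (0.5 by default), the smaller cluster is peeled off as final
and the larger one proceeds to the next stage; otherwise the remainder
is partitioned directly into however many clusters are still needed.
The procedure therefore always produces exactly ``target_k`` clusters.

Cluster/class correspondence for evaluation is established with the
Hungarian algorithm on the contingency table (maximum total overlap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_score

from .cohort import Trial
from .dissimilarity import (
    DissimilarityMatrix,
    DissimilarityParams,
    build_matrix,
    subset_matrix,
)
from .embedding import LayoutParams, layout


@dataclass(frozen=True)
class StagedParams:
    target_k: int = 6
    sc_threshold: float = 0.5
    linkage: str = "ward"
    min_stage_size: int = 4

    def __post_init__(self) -> None:
        if self.target_k < 2:
            raise ValueError("target_k must be >= 2")
        if not 0.0 <= self.sc_threshold <= 1.0:
            raise ValueError("sc_threshold must be in [0, 1]")
        if self.linkage not in ("ward", "average", "complete"):
            raise ValueError("linkage must be one of ward/average/complete")


@dataclass(frozen=True)
class StageRecord:
    stage_index: int
    member_trial_ids: tuple[str, ...]
    sc_at_2: float
    action: str  # "peel" | "final_partition"
    peeled_trial_ids: tuple[str, ...]


@dataclass(frozen=True)
class ClusteringResult:
    labels: dict[str, int]
    stages: tuple[StageRecord, ...]

    def labels_for(self, trial_ids) -> np.ndarray:
        return np.array([self.labels[t] for t in trial_ids])


def hac_labels(coords: np.ndarray, k: int, linkage: str = "ward") -> np.ndarray:
    """Agglomerative clustering of points under Euclidean distances,
    cut at ``k`` clusters; labels are integers in ``{0..k-1}``."""
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k = {k} outside [1, {n}]")
    if k == n:
        return np.arange(n)
    if k == 1:
        return np.zeros(n, int)
    Z = hierarchy.linkage(coords, method=linkage)
    return hierarchy.fcluster(Z, k, criterion="maxclust") - 1


def silhouette_coefficient(coords: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette (b - a) / max(a, b) over points; singleton
    clusters contribute 0."""
    labels = np.asarray(labels)
    n_clusters = len(np.unique(labels))
    if n_clusters < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    if n_clusters == len(labels):
        return 0.0  # every cluster is a singleton; each contributes 0
    return float(silhouette_score(np.asarray(coords, float), labels))


@dataclass(frozen=True)
class LabelMapping:
    mapping: dict[int, int]  # predicted cluster -> true class
    overlap: int  # total items on the matched diagonal


def hungarian_map(pred_labels, true_labels) -> LabelMapping:
    """One-to-one cluster/class assignment maximizing total overlap.

    Rectangular contingency tables are handled by the rectangular
    assignment itself (unmatched clusters stay unmapped).
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if len(pred) == 0 or len(pred) != len(true):
        raise ValueError("label lists must be non-empty and of equal length")
    pred_ids = np.unique(pred)
    true_ids = np.unique(true)
    table = np.zeros((len(pred_ids), len(true_ids)), int)
    p_index = {p: i for i, p in enumerate(pred_ids)}
    t_index = {t: i for i, t in enumerate(true_ids)}
    for p, t in zip(pred, true):
        table[p_index[p], t_index[t]] += 1
    rows, cols = linear_sum_assignment(table, maximize=True)

    def _native(v):
        return v.item() if isinstance(v, np.generic) else v

    mapping = {_native(pred_ids[r]): _native(true_ids[c]) for r, c in zip(rows, cols)}
    overlap = int(table[rows, cols].sum())
    return LabelMapping(mapping=mapping, overlap=overlap)


def _smaller_cluster(two_labels: np.ndarray, active: np.ndarray) -> np.ndarray:
    """Boolean mask (over the active subset) of the cluster to peel.

    Size decides; a tie peels the cluster whose smallest global trial
    index is larger (deterministic rule).
    """
    mask0 = two_labels == two_labels[0]
    n0, n1 = int(mask0.sum()), int((~mask0).sum())
    if n0 < n1:
        return mask0
    if n1 < n0:
        return ~mask0
    min0 = active[mask0].min()
    min1 = active[~mask0].min()
    return mask0 if min0 > min1 else ~mask0


def staged_cluster(
    trials: list[Trial],
    modality: str = "both",
    target_k: int = 6,
    dissim_params: DissimilarityParams | None = None,
    layout_params: LayoutParams | None = None,
    staged_params: StagedParams | None = None,
    matrix: DissimilarityMatrix | None = None,
) -> ClusteringResult:
    """Run the staged refinement until exactly ``target_k`` clusters exist.

    ``matrix`` may supply a precomputed dissimilarity matrix carrying the
    raw per-channel tensor; per-stage "re-computation" then amounts to
    re-normalizing the active subset's raw distances (alignment, trimming
    and DTW are pairwise-local, so raw distances are stage-invariant).
    """
    layout_params = layout_params or LayoutParams()
    sp = staged_params or StagedParams(target_k=target_k)
    if sp.target_k != target_k:
        sp = StagedParams(target_k=target_k, sc_threshold=sp.sc_threshold,
                          linkage=sp.linkage, min_stage_size=sp.min_stage_size)
    n = len(trials)
    if target_k < 2:
        raise ValueError("target_k must be >= 2")
    if n < target_k:
        raise ValueError(f"{n} trials cannot form {target_k} clusters")
    if matrix is None:
        matrix = build_matrix(trials, modality, dissim_params)
    ids = matrix.trial_ids

    labels: dict[str, int] = {}
    stages: list[StageRecord] = []
    active = np.arange(n)
    remaining_k = target_k
    next_label = 0
    stage_index = 0
    while True:
        sub = subset_matrix(matrix, active)
        lp = LayoutParams(**{**layout_params.__dict__, "seed": layout_params.seed + stage_index})
        lay = layout(sub, lp)
        two = hac_labels(lay.coords, 2, sp.linkage)
        sc2 = silhouette_coefficient(lay.coords, two)
        peel_mask = _smaller_cluster(two, active)
        can_peel = (
            sc2 > sp.sc_threshold
            and remaining_k >= 2
            and len(active) >= sp.min_stage_size
            and len(active) - int(peel_mask.sum()) >= remaining_k - 1
        )
        members = tuple(ids[i] for i in active)
        if can_peel:
            peeled = active[peel_mask]
            stages.append(
                StageRecord(
                    stage_index=stage_index,
                    member_trial_ids=members,
                    sc_at_2=sc2,
                    action="peel",
                    peeled_trial_ids=tuple(ids[i] for i in peeled),
                )
            )
            for i in peeled:
                labels[ids[i]] = next_label
            next_label += 1
            active = active[~peel_mask]
            remaining_k -= 1
            stage_index += 1
            if remaining_k == 1:
                for i in active:
                    labels[ids[i]] = next_label
                break
        else:
            final = hac_labels(lay.coords, remaining_k, sp.linkage)
            stages.append(
                StageRecord(
                    stage_index=stage_index,
                    member_trial_ids=members,
                    sc_at_2=sc2,
                    action="final_partition",
                    peeled_trial_ids=(),
                )
            )
            for i, lab in zip(active, final):
                labels[ids[i]] = next_label + int(lab)
            break
    return ClusteringResult(labels=labels, stages=tuple(stages))


def save_result(result: ClusteringResult, path, params: dict | None = None) -> None:
    import json
    from pathlib import Path

    payload = {
        "labels": result.labels,
        "stages": [
            {
                "stage_index": s.stage_index,
                "members": list(s.member_trial_ids),
                "sc_at_2": s.sc_at_2,
                "action": s.action,
                "peeled": list(s.peeled_trial_ids),
            }
            for s in result.stages
        ],
        "params": params or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


class StagedClusterer(ClusterMixin, BaseEstimator):
    """Scikit-learn style estimator running the full staged procedure.

    ``fit(trials)`` computes (or reuses, via the ``matrix`` keyword) the
    DTW dissimilarity matrix, then runs the staged refinement; fitted
    attributes are ``labels_`` (aligned with the input trial order),
    ``result_`` and ``matrix_``.
    """

    def __init__(self, target_k: int = 6, modality: str = "both",
                 sc_threshold: float = 0.5, linkage: str = "ward",
                 min_stage_size: int = 4, max_lag_frac: float = 0.25,
                 trim_frac: float = 0.05, stride: int = 1,
                 layout_params: LayoutParams | None = None, seed: int = 0):
        self.target_k = target_k
        self.modality = modality
        self.sc_threshold = sc_threshold
        self.linkage = linkage
        self.min_stage_size = min_stage_size
        self.max_lag_frac = max_lag_frac
        self.trim_frac = trim_frac
        self.stride = stride
        self.layout_params = layout_params
        self.seed = seed

    def fit(self, X: list[Trial], y=None, matrix: DissimilarityMatrix | None = None):
        lp = self.layout_params or LayoutParams(seed=self.seed)
        dp = DissimilarityParams(
            max_lag_frac=self.max_lag_frac, trim_frac=self.trim_frac, stride=self.stride
        )
        sp = StagedParams(
            target_k=self.target_k, sc_threshold=self.sc_threshold,
            linkage=self.linkage, min_stage_size=self.min_stage_size,
        )
        self.matrix_ = matrix if matrix is not None else build_matrix(X, self.modality, dp)
        self.result_ = staged_cluster(
            X, self.modality, self.target_k, dp, lp, sp, matrix=self.matrix_
        )
        self.labels_ = self.result_.labels_for([tr.trial_id for tr in X])
        return self

    def fit_predict(self, X: list[Trial], y=None, **kwargs) -> np.ndarray:
        return self.fit(X, y, **kwargs).labels_
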