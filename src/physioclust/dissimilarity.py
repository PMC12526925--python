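"""Pairwise trial dissimilarity.

For every unordered pair of trials and every homologous channel the
pipeline (i) finds the lag maximizing the normalized cross-correlation,
(ii) aligns the two sequences and greedily trims up to 5% of the overlap
from the ends where the pointwise discrepancy is largest, (iii) computes
the classic un-windowed DTW distance with absolute-difference local
cost.  Per-channel distances are min–max normalized over all pairs
(globally, per channel) and aggregated into a single dissimilarity
``D(i, j)`` as the Euclidean norm of the normalized vector, yielding a
symmetric matrix with zero diagonal bounded by ``sqrt(m)`` for ``m``
channels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import ACC_KINDS, ECG_KINDS, ChannelKind, Trial

logger = logging.getLogger(__name__)

#: channel order per modality: (ACCx, ACCy, ACCz, ECG1, ECG2) restricted
MODALITY_CHANNELS: dict[str, tuple[ChannelKind, ...]] = {
    "acc": ACC_KINDS,
    "ecg": ECG_KINDS,
    "both": ACC_KINDS + ECG_KINDS,
}


@dataclass(frozen=True)
class DissimilarityParams:
    #: lag search bound as a fraction of the shorter sequence length
    max_lag_frac: float = 0.25
    #: fraction of the aligned overlap that may be trimmed from the ends
    trim_frac: float = 0.05
    #: optional subsampling stride applied just before the DTW recursion
    stride: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.max_lag_frac <= 1:
            raise ValueError("max_lag_frac must be in [0, 1]")
        if not 0 <= self.trim_frac < 0.5:
            raise ValueError("trim_frac must be in [0, 0.5)")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass(frozen=True)
class AlignmentResult:
    lag_samples: int
    x_trimmed: np.ndarray
    y_trimmed: np.ndarray


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Aggregate dissimilarities plus the raw per-channel tensor.

    ``values[i, j]`` is the Euclidean norm of the per-channel normalized
    DTW distances; ``raw[i, j, k]`` keeps the un-normalized distance of
    channel ``channels[k]`` so sub-cohorts can be re-normalized without
    recomputing any DTW.
    """

    trial_ids: tuple[str, ...]
    values: np.ndarray
    channel_stats: dict[str, tuple[float, float]]
    modality: str
    channels: tuple[str, ...]
    raw: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.trial_ids)


def optimal_lag(x: np.ndarray, y: np.ndarray, max_lag: int) -> int:
    """Lag maximizing the normalized cross-correlation of the overlap.

    A positive lag means the second sequence is advanced: samples
    ``x[t]`` are matched with ``y[t + lag]``.  The correlation at each
    candidate lag is computed on the overlapping parts only, each
    mean-removed and scaled by the overlap norms.  Exact ties resolve to
    the smallest ``|lag|``, negative before positive.  Constant inputs
    yield lag 0 with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("sequences must have length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant sequence: optimal lag defaults to 0", RuntimeWarning, stacklevel=2)
        return 0
    nx, ny = len(x), len(y)
    max_lag = int(max_lag)
    lags = np.arange(-max_lag, max_lag + 1)
    a = np.maximum(0, -lags)
    b = np.minimum(nx, ny - lags)
    n_ov = b - a
    valid = n_ov >= 2

    cx = np.concatenate(([0.0], np.cumsum(x)))
    cxx = np.concatenate(([0.0], np.cumsum(x * x)))
    cy = np.concatenate(([0.0], np.cumsum(y)))
    cyy = np.concatenate(([0.0], np.cumsum(y * y)))
    # full cross-correlation: corr[idx] = sum_t x[t] * y[t - (idx - (ny-1))]
    corr = sps.correlate(x, y, mode="full", method="auto")

    ncc = np.full(len(lags), -np.inf)
    av, bv, lv = a[valid], b[valid], lags[valid]
    nv = (bv - av).astype(float)
    sx = cx[bv] - cx[av]
    sxx = cxx[bv] - cxx[av]
    sy = cy[bv + lv] - cy[av + lv]
    syy = cyy[bv + lv] - cyy[av + lv]
    sxy = corr[ny - 1 - lv]
    num = sxy - sx * sy / nv
    varx = sxx - sx * sx / nv
    vary = syy - sy * sy / nv
    den = np.sqrt(np.maximum(varx, 0.0) * np.maximum(vary, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(den > 0, num / den, -np.inf)
    ncc[valid] = vals
    if not np.any(np.isfinite(ncc)):
        warnings.warn("degenerate overlaps: optimal lag defaults to 0", RuntimeWarning, stacklevel=2)
        return 0
    # tie-break: smallest |lag| first, then negative before positive
    priority = np.lexsort((lags > 0, np.abs(lags)))
    best = priority[int(np.argmax(ncc[priority]))]
    return int(lags[best])


def align_and_trim(
    x: np.ndarray, y: np.ndarray, lag: int, trim_frac: float = 0.05
) -> AlignmentResult:
    """Shift ``y`` by ``lag``, cut to the overlap, greedily trim the ends.

    Up to ``floor(trim_frac * overlap)`` samples are removed one at a
    time, always from the end whose current boundary pointwise absolute
    difference is larger (left end wins ties), stopping early once both
    boundary differences are zero.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    lag = int(lag)
    if abs(lag) >= min(len(x), len(y)):
        raise ValueError(f"|lag| = {abs(lag)} too large for sequence lengths")
    a = max(0, -lag)
    b = min(len(x), len(y) - lag)
    overlap = b - a
    if overlap < 10:
        raise ValueError(f"aligned overlap of {overlap} samples is too short (< 10)")
    xa = x[a:b]
    ya = y[a + lag : b + lag]
    budget = int(np.floor(trim_frac * overlap))
    i, j = 0, overlap
    for _ in range(budget):
        dl = abs(xa[i] - ya[i])
        dr = abs(xa[j - 1] - ya[j - 1])
        if dl == 0.0 and dr == 0.0:
            break
        if dl >= dr:
            i += 1
        else:
            j -= 1
    return AlignmentResult(lag_samples=lag, x_trimmed=xa[i:j], y_trimmed=ya[i:j])


@njit(cache=True, fastmath=True)
def _dtw_cost(x: np.ndarray, y: np.ndarray) -> float:  # pragma: no cover - jit
    n = x.shape[0]
    m = y.shape[0]
    prev = np.empty(m + 1)
    cur = np.empty(m + 1)
    for j in range(m + 1):
        prev[j] = np.inf
    prev[0] = 0.0
    for i in range(n):
        cur[0] = np.inf
        xi = x[i]
        for j in range(1, m + 1):
            c = xi - y[j - 1]
            if c < 0.0:
                c = -c
            best = prev[j]
            if prev[j - 1] < best:
                best = prev[j - 1]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = c + best
        tmp = prev
        prev = cur
        cur = tmp
    return prev[m]


def dtw_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Classic DTW cost: full dynamic program, no window, |x - y| local
    cost, symmetric {match, insert, delete} steps, un-normalized."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("dtw_distance requires non-empty sequences")
    return float(_dtw_cost(x, y))


def channel_pair_distance(
    x: np.ndarray, y: np.ndarray, params: DissimilarityParams
) -> float:
    """Lag-align, trim and DTW one homologous channel pair."""
    max_lag = int(np.floor(params.max_lag_frac * min(len(x), len(y))))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lag = optimal_lag(x, y, max_lag)
    ar = align_and_trim(x, y, lag, params.trim_frac)
    xs = ar.x_trimmed[:: params.stride]
    ys = ar.y_trimmed[:: params.stride]
    return dtw_distance(xs, ys)


def pair_distance_vector(
    trial_i: Trial,
    trial_j: Trial,
    modality: str = "both",
    params: DissimilarityParams | None = None,
) -> np.ndarray:
    """Raw DTW distance vector over the modality's channels, ordered
    (ACCx, ACCy, ACCz, ECG1, ECG2) restricted to the modality."""
    params = params or DissimilarityParams()
    kinds = MODALITY_CHANNELS[modality]
    out = np.empty(len(kinds))
    for k, kind in enumerate(kinds):
        ci, cj = trial_i.channels[kind], trial_j.channels[kind]
        if ci.rate != cj.rate:
            raise ValueError(
                f"rate mismatch on {kind.value}: {ci.rate} vs {cj.rate}"
            )
        out[k] = channel_pair_distance(ci.samples, cj.samples, params)
    return out


def compute_raw_tensor(
    trials: list[Trial],
    modality: str = "both",
    params: DissimilarityParams | None = None,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Raw per-channel DTW distances for all C(n, 2) unordered pairs.

    Returns an ``(n, n, m)`` tensor (symmetric in the first two axes,
    zero diagonal) and the channel names.
    """
    params = params or DissimilarityParams()
    n = len(trials)
    if n < 2:
        raise ValueError("need at least 2 trials")
    kinds = MODALITY_CHANNELS[modality]
    raw = np.zeros((n, n, len(kinds)))
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            vec = pair_distance_vector(trials[i], trials[j], modality, params)
            raw[i, j] = vec
            raw[j, i] = vec
            n_pairs += 1
    logger.info("evaluated %d unique trial pairs (%s modality)", n_pairs, modality)
    return raw, tuple(k.value for k in kinds)


def normalize_and_aggregate(
    raw: np.ndarray,
    channels: tuple[str, ...],
    trial_ids: tuple[str, ...],
    modality: str,
) -> DissimilarityMatrix:
    """Global per-channel min–max normalization and Euclidean aggregation.

    The min/max of each channel are taken over the off-diagonal pairs of
    the given tensor; a channel with zero spread contributes 0 to every
    pair (with a warning).
    """
    n = raw.shape[0]
    iu = np.triu_indices(n, k=1)
    stats: dict[str, tuple[float, float]] = {}
    normalized = np.zeros_like(raw)
    for k, name in enumerate(channels):
        vals = raw[iu[0], iu[1], k]
        dmin, dmax = float(vals.min()), float(vals.max())
        stats[name] = (dmin, dmax)
        if dmax == dmin:
            warnings.warn(
                f"channel {name} has zero distance spread; normalized values set to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        normalized[:, :, k] = (raw[:, :, k] - dmin) / (dmax - dmin)
    values = np.sqrt(np.sum(normalized**2, axis=2))
    np.fill_diagonal(values, 0.0)
    return DissimilarityMatrix(
        trial_ids=tuple(trial_ids),
        values=values,
        channel_stats=stats,
        modality=modality,
        channels=tuple(channels),
        raw=raw,
    )


def subset_matrix(matrix: DissimilarityMatrix, indices: np.ndarray) -> DissimilarityMatrix:
    """Re-normalize a sub-cohort's raw distances over its own pairs."""
    if matrix.raw is None:
        raise ValueError("matrix carries no raw tensor; cannot re-normalize a subset")
    idx = np.asarray(indices, int)
    raw = matrix.raw[np.ix_(idx, idx)]
    ids = tuple(matrix.trial_ids[i] for i in idx)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return normalize_and_aggregate(raw, matrix.channels, ids, matrix.modality)


def build_matrix(
    trials: list[Trial],
    modality: str = "both",
    params: DissimilarityParams | None = None,
) -> DissimilarityMatrix:
    """Full pipeline over all unordered trial pairs."""
    raw, channels = compute_raw_tensor(trials, modality, params)
    ids = tuple(tr.trial_id for tr in trials)
    return normalize_and_aggregate(raw, channels, ids, modality)


def save_matrix(matrix: DissimilarityMatrix, path) -> None:
    """TSV (header = trial ids) plus a JSON sidecar with the stats."""
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    df = pd.DataFrame(matrix.values, index=matrix.trial_ids, columns=matrix.trial_ids)
    df.to_csv(path, sep="\t")
    sidecar = {
        "modality": matrix.modality,
        "channels": list(matrix.channels),
        "channel_stats": {k: list(v) for k, v in matrix.channel_stats.items()},
        "n_trials": matrix.n,
        "n_pairs": matrix.n * (matrix.n - 1) // 2,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_matrix(path) -> DissimilarityMatrix:
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return DissimilarityMatrix(
        trial_ids=tuple(df.index),
        values=df.to_numpy(),
        channel_stats={k: tuple(v) for k, v in sidecar["channel_stats"].items()},
        modality=sidecar["modality"],
        channels=tuple(sidecar["channels"]),
        raw=None,
    )


class DTWDissimilarity(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer from trials to a dissimilarity matrix.

    ``fit_transform`` returns the aggregate ``(n, n)`` matrix; the fitted
    object retains ``matrix_`` (with the raw per-channel tensor),
    ``channel_stats_`` and ``trial_ids_``.
    """

    def __init__(self, modality: str = "both", max_lag_frac: float = 0.25,
                 trim_frac: float = 0.05, stride: int = 1):
        self.modality = modality
        self.max_lag_frac = max_lag_frac
        self.trim_frac = trim_frac
        self.stride = stride

    def _params(self) -> DissimilarityParams:
        return DissimilarityParams(
            max_lag_frac=self.max_lag_frac, trim_frac=self.trim_frac, stride=self.stride
        )

    def fit(self, X: list[Trial], y=None):
        self.matrix_ = build_matrix(X, self.modality, self._params())
        self.channel_stats_ = self.matrix_.channel_stats
        self.trial_ids_ = self.matrix_.trial_ids
        return self

    def transform(self, X: list[Trial]) -> np.ndarray:
        ids = tuple(tr.trial_id for tr in X)
        if not hasattr(self, "matrix_") or ids != self.trial_ids_:
            self.fit(X)
        return self.matrix_.values

    def fit_transform(self, X: list[Trial], y=None) -> np.ndarray:
        return self.fit(X).matrix_.values
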