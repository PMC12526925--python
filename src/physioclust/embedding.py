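"""Force-directed 3D embedding of a trial dissimilarity matrix.

Each trial is a node of a fully connected graph.  A pair at Euclidean
distance ``r`` with dissimilarity ``D`` exchanges a repulsive force
``fr = -C K^2 / r * exp(alpha * |D|)`` and an attractive force
``fa = r^2 / K * exp(gamma * |D|)``; the combined force ``fc = fr + fa``
(positive pulls the pair together) vanishes at the equilibrium distance

    r* = K * C^(1/3) * exp((alpha - gamma) * |D| / 3),

which with ``alpha > 0 > gamma`` grows strictly with dissimilarity —
similar trials end up close, dissimilar ones far apart.  The combined
force is the negative gradient of the pair potential
``U(r) = -C K^2 e^{alpha |D|} ln r + r^3 e^{gamma |D|} / (3K)``, so the
layout iteration — every node moves along its net force with a damped
adaptive step, a step that would raise the total potential is rejected
and the step size halved — is gradient descent on the system energy,
whose trace is non-increasing over accepted steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .dissimilarity import DissimilarityMatrix


@dataclass(frozen=True)
class LayoutParams:
    K: float = 1.0  # spring length (layout length unit)
    C: float = 0.2  # relative repulsion strength
    alpha: float = 1.5  # repulsion exponent scale (per dissimilarity unit)
    gamma: float = -1.5  # attraction exponent scale (per dissimilarity unit)
    step0: float = 0.05  # initial step size, in units of K
    n_iter: int = 500
    tol: float = 1e-4  # mean-displacement stop threshold, in units of K
    seed: int = 0
    n_components: int = 3

    def __post_init__(self) -> None:
        if self.K <= 0 or self.C <= 0:
            raise ValueError("K and C must be positive")
        if self.n_iter < 1 or self.tol < 0:
            raise ValueError("n_iter must be >= 1 and tol >= 0")


@dataclass(frozen=True)
class EmbeddingLayout:
    coords: np.ndarray  # (n, 3), centered at the origin
    energy_trace: np.ndarray  # energy proxy at each accepted step
    converged: bool


def pair_force(
    y_i: np.ndarray, y_j: np.ndarray, d_ij: float, params: LayoutParams | None = None
) -> float:
    """Signed combined force magnitude along the i→j direction.

    Positive values pull ``i`` toward ``j``; negative push apart.
    Coincident nodes receive a deterministic jitter of ``1e-6 K`` before
    evaluation.
    """
    params = params or LayoutParams()
    y_i = np.asarray(y_i, float)
    y_j = np.asarray(y_j, float)
    r = float(np.linalg.norm(y_i - y_j))
    if r == 0.0:
        r = 1e-6 * params.K
    d = abs(float(d_ij))
    fr = -params.C * params.K**2 / r * np.exp(params.alpha * d)
    fa = r**2 / params.K * np.exp(params.gamma * d)
    return float(fr + fa)


def equilibrium_distance(d: float, params: LayoutParams | None = None) -> float:
    """Closed-form root of the combined force for dissimilarity ``d``."""
    params = params or LayoutParams()
    return params.K * params.C ** (1.0 / 3.0) * np.exp((params.alpha - params.gamma) * abs(d) / 3.0)


def _forces_and_energy(
    coords: np.ndarray, D: np.ndarray, params: LayoutParams, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Net force on each node and the total pair potential.

    The potential ``U(r) = -C K^2 e^{alpha D} ln r + r^3 e^{gamma D} / (3K)``
    satisfies ``-dU/dr = -fc``: moving every node along its net force is
    exact gradient descent on ``sum_{i<j} U(r_ij)``, which is the energy
    the iteration minimizes.
    """
    n = coords.shape[0]
    diff = coords[None, :, :] - coords[:, None, :]  # diff[i, j] = y_j - y_i
    r = np.linalg.norm(diff, axis=2)
    coincident = (r == 0.0) & ~np.eye(n, dtype=bool)
    if np.any(coincident):
        jitter = 1e-6 * params.K * rng.standard_normal(coords.shape)
        return _forces_and_energy(coords + jitter, D, params, rng)
    r_safe = np.where(r == 0.0, 1.0, r)
    expd_r = np.exp(params.alpha * np.abs(D))
    expd_a = np.exp(params.gamma * np.abs(D))
    fc = -params.C * params.K**2 / r_safe * expd_r + r_safe**2 / params.K * expd_a
    np.fill_diagonal(fc, 0.0)
    unit = diff / r_safe[:, :, None]
    forces = np.sum(fc[:, :, None] * unit, axis=1)
    pot = -params.C * params.K**2 * expd_r * np.log(r_safe) + r_safe**3 * expd_a / (3 * params.K)
    iu = np.triu_indices(n, k=1)
    return forces, float(np.sum(pot[iu]))


def layout(
    matrix: DissimilarityMatrix | np.ndarray,
    params: LayoutParams | None = None,
    init: np.ndarray | None = None,
) -> EmbeddingLayout:
    """Iterate the force model to a low-energy 3D configuration.

    Nodes start uniformly in the unit cube (seeded) unless ``init`` is
    given.  Each iteration moves every node along its net force with an
    adaptive global step (displacements capped at ``0.1 K``); a step
    that would increase the total pair potential is rejected and the
    step size halved.  Stops at ``n_iter`` accepted/rejected iterations, when the
    mean accepted displacement falls below ``tol * K``, or when the step
    size underflows.  The returned coordinates are centered at the
    origin.
    """
    params = params or LayoutParams()
    D = matrix.values if isinstance(matrix, DissimilarityMatrix) else np.asarray(matrix, float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("layout requires at least 2 nodes")
    if D.shape != (n, n):
        raise ValueError("dissimilarity matrix must be square")
    rng = np.random.default_rng(params.seed)
    coords = rng.uniform(0.0, 1.0, (n, params.n_components)) if init is None else np.array(init, float)
    step = params.step0 * params.K
    cap = 0.1 * params.K

    forces, energy = _forces_and_energy(coords, D, params, rng)
    trace = [energy]
    converged = False
    for _ in range(params.n_iter):
        disp = step * forces
        norms = np.linalg.norm(disp, axis=1, keepdims=True)
        scale = np.where(norms > cap, cap / np.where(norms == 0, 1.0, norms), 1.0)
        disp = disp * scale
        new_coords = coords + disp
        new_forces, new_energy = _forces_and_energy(new_coords, D, params, rng)
        if new_energy <= energy:
            coords, forces, energy = new_coords, new_forces, new_energy
            trace.append(energy)
            step *= 1.1
            if float(np.mean(np.linalg.norm(disp, axis=1))) < params.tol * params.K:
                converged = True
                break
        else:
            step *= 0.5
            if step < 1e-12 * params.K:
                converged = True
                break
    coords = coords - coords.mean(axis=0)
    return EmbeddingLayout(coords=coords, energy_trace=np.asarray(trace), converged=converged)


def save_layout(result: EmbeddingLayout, trial_ids, path, params: LayoutParams | None = None) -> None:
    """CSV (trial_id, x, y, z) + JSON sidecar with params and the trace."""
    import dataclasses
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    cols = ["x", "y", "z"][: result.coords.shape[1]]
    df = pd.DataFrame(result.coords, columns=cols)
    df.insert(0, "trial_id", list(trial_ids))
    df.to_csv(path, index=False)
    sidecar = {
        "params": dataclasses.asdict(params) if params else None,
        "energy_trace": result.energy_trace.tolist(),
        "converged": bool(result.converged),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


class ForceDirectedEmbedding(BaseEstimator):
    """Scikit-learn style wrapper around :func:`layout`.

    ``fit_transform(D)`` takes a precomputed square dissimilarity matrix
    and returns the ``(n, 3)`` embedded coordinates; fitted attributes
    are ``embedding_``, ``energy_trace_`` and ``converged_``.
    """

    def __init__(self, K: float = 1.0, C: float = 0.2, alpha: float = 1.5,
                 gamma: float = -1.5, step0: float = 0.05, n_iter: int = 500,
                 tol: float = 1e-4, seed: int = 0, n_components: int = 3):
        self.K = K
        self.C = C
        self.alpha = alpha
        self.gamma = gamma
        self.step0 = step0
        self.n_iter = n_iter
        self.tol = tol
        self.seed = seed
        self.n_components = n_components

    def _params(self) -> LayoutParams:
        return LayoutParams(K=self.K, C=self.C, alpha=self.alpha, gamma=self.gamma,
                            step0=self.step0, n_iter=self.n_iter, tol=self.tol,
                            seed=self.seed, n_components=self.n_components)

    def fit(self, X, y=None):
        result = layout(X, self._params())
        self.embedding_ = result.coords
        self.energy_trace_ = result.energy_trace
        self.converged_ = result.converged
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).embedding_
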