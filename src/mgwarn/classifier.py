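"""Effect-size-maximizing linear combination of similarity series.

The daily model output is a weighted mean of the K per-signal
similarities, output(t) = (1/K) * sum_i w_i * s_i(t), with weights
constrained to w_i >= 0 and mean(w) = 1. Because every similarity lies in
[0, 1] and the weighted mean is a convex combination under these
constraints, the output is itself in [0, 1] and is read as a probability
of impending deterioration. The weights are the model's only parameters
and are fitted to maximize Cohen's d of the output between pre-event and
other days of the training set.

The objective is scale-invariant in w and, after pre-computing class
means and pooled scatter of the similarity matrix, evaluating d(w) is
O(K^2); fitting uses multi-start SLSQP over the (scaled) simplex with the
uniform vector and all one-hot corners always among the starts, followed
by an exact feasibility projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

EPS_SD = 1e-12
FEAS_TOL = 1e-9


@dataclass
class ModelWeights:
    """Per-signal nonnegative coefficients with mean exactly 1."""

    signal_order: tuple[str, ...]
    coefficients: np.ndarray
    objective: float = float("nan")  # Cohen's d on the training days
    lookback: int | None = None
    fold_id: str | None = None
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        K = len(self.signal_order)
        if self.coefficients.shape != (K,):
            raise ValueError("one coefficient per signal required")
        if (self.coefficients < -FEAS_TOL).any():
            raise ValueError("coefficients must be nonnegative")
        if abs(self.coefficients.mean() - 1.0) > FEAS_TOL:
            raise ValueError("coefficients must have mean exactly 1")

    def as_dict(self) -> dict:
        return {
            "signal_order": list(self.signal_order),
            "coefficients": self.coefficients.tolist(),
            "objective": self.objective,
            "lookback": self.lookback,
            "fold_id": self.fold_id,
            "seed": self.seed,
        }


def model_output(similarities: np.ndarray, weights: ModelWeights) -> np.ndarray:
    """Daily probability series from a (n_days, K) similarity matrix whose
    columns follow ``weights.signal_order``."""
    X = np.asarray(similarities, dtype=float)
    K = len(weights.signal_order)
    if X.ndim != 2 or X.shape[1] != K:
        raise ValueError(
            f"similarity matrix has {X.shape[1] if X.ndim == 2 else '?'} columns "
            f"but weights cover {K} signals"
        )
    return X @ weights.coefficients / K


def cohens_d(values: np.ndarray, labels: np.ndarray, eps: float = EPS_SD) -> float:
    """Pooled-SD Cohen's d of ``values`` between label-1 and label-0 days.

    d = (mean1 - mean0) / s_pooled with
    s_pooled^2 = ((n1-1) s1^2 + (n0-1) s0^2) / (n1 + n0 - 2).
    A zero pooled SD is floored at ``eps`` (signed-infinity sentinel).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    x1, x0 = values[labels == 1], values[labels == 0]
    if len(x1) == 0 or len(x0) == 0:
        raise ValueError("both classes must be non-empty")
    ssd = ((x1 - x1.mean()) ** 2).sum() + ((x0 - x0.mean()) ** 2).sum()
    dof = len(x1) + len(x0) - 2
    s_pooled = np.sqrt(ssd / dof) if dof > 0 else 0.0
    return float((x1.mean() - x0.mean()) / max(s_pooled, eps))


def project_to_feasible(w: np.ndarray, K: int | None = None) -> np.ndarray:
    """Exact feasibility: clip to >= 0, rescale to mean 1 (uniform if the
    clipped vector is all-zero)."""
    w = np.maximum(np.asarray(w, dtype=float), 0.0)
    K = len(w) if K is None else K
    s = w.sum()
    if s <= 0:
        return np.ones(K)
    return w * (K / s)


def _moments(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class mean difference and pooled scatter of the similarity columns;
    d(w) = (w @ a) / sqrt(w @ Cp @ w) up to the (cancelling) 1/K factor."""
    X1, X0 = X[y == 1], X[y == 0]
    a = X1.mean(axis=0) - X0.mean(axis=0)
    dof = len(X1) + len(X0) - 2

    def scatter(M):
        if len(M) < 2:
            return np.zeros((X.shape[1], X.shape[1]))
        C = M - M.mean(axis=0)
        return C.T @ C

    Cp = (scatter(X1) + scatter(X0)) / max(dof, 1)
    return a, Cp


def fit_weights(
    X: np.ndarray,
    y: np.ndarray,
    signal_order: tuple[str, ...],
    seed: int = 0,
    n_random_starts: int = 8,
    max_iter: int = 500,
    lookback: int | None = None,
    fold_id: str | None = None,
) -> ModelWeights:
    """Fit nonnegative unit-mean weights maximizing Cohen's d.

    Deterministic given ``seed``. The returned weights are feasible to
    1e-9 and their objective is >= that of uniform weights and of every
    one-hot corner (all of which are among the optimizer starts). Ties
    within numerical precision break toward the smallest Euclidean norm.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    K = len(signal_order)
    if X.ndim != 2 or X.shape[1] != K:
        raise ValueError("X must be (n_days, K) matching signal_order")
    if (y == 1).sum() == 0:
        raise ValueError("untrainable: no positive-labeled days in training data")
    if (y == 0).sum() == 0:
        raise ValueError("untrainable: no negative-labeled days in training data")
    if K == 1:
        w = np.ones(1)
        d = cohens_d(model_output(X, _bare(signal_order, w)), y)
        return ModelWeights(signal_order, w, objective=d, lookback=lookback,
                            fold_id=fold_id, seed=seed)

    a, Cp = _moments(X, y)

    def d_of(w: np.ndarray) -> float:
        q = float(w @ Cp @ w)
        return float(w @ a) / max(np.sqrt(max(q, 0.0)), EPS_SD)

    def neg_d(w):
        return -d_of(w)

    def neg_grad(w):
        q = float(w @ Cp @ w)
        s = max(np.sqrt(max(q, 0.0)), EPS_SD)
        return -(a / s - float(w @ a) / s**3 * (Cp @ w))

    rng = np.random.default_rng(np.random.SeedSequence([seed, K]))
    starts = [np.ones(K)]
    starts += [K * np.eye(K)[i] for i in range(K)]
    starts += [K * rng.dirichlet(np.ones(K)) for _ in range(n_random_starts)]
    # scale-invariance: the unconstrained maximizer direction, if feasible
    try:
        ridge = Cp + 1e-10 * np.trace(Cp) * np.eye(K) + 1e-18 * np.eye(K)
        w_lda = np.linalg.solve(ridge, a)
        if (w_lda >= 0).any() and w_lda.max() > 0:
            starts.append(project_to_feasible(w_lda))
    except np.linalg.LinAlgError:
        pass

    constraints = [{"type": "eq", "fun": lambda w: w.sum() - K,
                    "jac": lambda w: np.ones_like(w)}]
    bounds = [(0.0, float(K))] * K
    candidates: list[np.ndarray] = []
    for w0 in starts:
        candidates.append(project_to_feasible(w0))
        res = minimize(
            neg_d, w0, jac=neg_grad, method="SLSQP", bounds=bounds,
            constraints=constraints, options={"maxiter": max_iter, "ftol": 1e-12},
        )
        if np.all(np.isfinite(res.x)):
            candidates.append(project_to_feasible(res.x))
    scores = np.array([d_of(w) for w in candidates])
    best_score = scores.max()
    near = [w for w, s in zip(candidates, scores) if s >= best_score - 1e-12]
    w_best = min(near, key=lambda w: float(w @ w))
    d_train = cohens_d(model_output(X, _bare(signal_order, w_best)), y)
    return ModelWeights(
        signal_order, w_best, objective=d_train, lookback=lookback,
        fold_id=fold_id, seed=seed,
    )


def _bare(signal_order: tuple[str, ...], w: np.ndarray) -> ModelWeights:
    return ModelWeights(tuple(signal_order), w)
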