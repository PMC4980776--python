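"""Linear support vector regression by dual coordinate descent.

The trainer minimizes the L2-regularized squared epsilon-insensitive loss

    min_w  1/2 ||w||^2 + C * sum_i max(|w.x_i - y_i| - eps, 0)^2

in its dual formulation: with beta_i the (signed) dual variable of sample
i, the dual objective

    f(beta) = 1/2 beta' Q beta - y'beta + eps ||beta||_1 + ||beta||^2 / (4C)

(Q = X X') is minimized one coordinate at a time, each coordinate solved
exactly by a soft-thresholded Newton step, visiting the samples in a
freshly randomized order every sweep.  The primal weights w = X'beta are
maintained incrementally so each update costs one sparse row product.
Iteration stops when the largest projected-gradient violation over a sweep
drops below a tolerance.  With eps = 0 the objective is exactly ridge
regression with penalty 1/(2C), which the tests use as a closed-form
oracle.

The bias is handled as an appended, regularized constant feature of value
one (disable with ``fit_bias=False``).  Cost selection uses k-fold
cross-validation with a shared fold partition across the cost grid; costs
whose mean fold RMSD agree within a small relative tolerance are treated
as ties and the lowest such cost is returned, an optimistic choice that
favours the least complex model.

The inner sweep is compiled with numba; results are deterministic for a
given seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
from numba import njit

from .featurize import SignatureDictionary, read_signature_list, write_signature_list

_SOLVER_TAG = "dual-cd-l2l2-svr"
_FORMAT_TAG = "sigqsar-model"

#: costs whose CV mean RMSDs differ by less than this relative amount are ties
COST_TIE_RTOL = 1e-6

DEFAULT_COST_GRID = (0.005, 0.05, 0.1, 0.5, 1.0, 10.0, 100.0)


class BackendContractError(RuntimeError):
    """A kernel backend violated the trainer contract."""


@dataclass(frozen=True)
class RbfParams:
    """Hyperparameters of a kernelized (RBF) backend: cost C and width gamma."""

    cost: float
    gamma: float

    def __post_init__(self) -> None:
        if self.cost <= 0 or self.gamma <= 0:
            raise ValueError("cost and gamma must be strictly positive")


@dataclass
class SvrModel:
    """A trained linear SVR: weight vector, bias and provenance."""

    weights: np.ndarray
    bias: float
    cost: float
    epsilon: float
    heights: tuple[int, ...] | None = None
    tolerance: float = 0.0
    sweeps: int = 0
    seed: int = 0
    solver: str = _SOLVER_TAG

    @property
    def n_features(self) -> int:
        return int(self.weights.shape[0])

    def predict(self, matrix) -> np.ndarray:
        return predict(self, matrix)


@njit(cache=True)
def _cd_sweep(data, indices, indptr, y, qii, w, beta, inv2c, eps, sweep_seed):
    n = y.shape[0]
    np.random.seed(sweep_seed)
    perm = np.arange(n)
    for k in range(n - 1, 0, -1):
        j = np.random.randint(0, k + 1)
        tmp = perm[k]
        perm[k] = perm[j]
        perm[j] = tmp
    max_violation = 0.0
    for t in range(n):
        i = perm[t]
        lo, hi = indptr[i], indptr[i + 1]
        xw = 0.0
        for k in range(lo, hi):
            xw += data[k] * w[indices[k]]
        g = xw - y[i] + beta[i] * inv2c
        if beta[i] > 0.0:
            violation = abs(g + eps)
        elif beta[i] < 0.0:
            violation = abs(g - eps)
        else:
            violation = max(0.0, abs(g) - eps)
        if violation > max_violation:
            max_violation = violation
        h = qii[i]
        gp = g + eps
        gm = g - eps
        if h * beta[i] > gp:
            d = -gp / h
        elif h * beta[i] < gm:
            d = -gm / h
        else:
            d = -beta[i]
        if d != 0.0:
            beta[i] += d
            for k in range(lo, hi):
                w[indices[k]] += d * data[k]
    return max_violation


def _as_solver_csr(matrix) -> sp.csr_matrix:
    m = sp.csr_matrix(matrix, dtype=np.float64)
    m.indices = m.indices.astype(np.int64)
    m.indptr = m.indptr.astype(np.int64)
    return m


def _dual_objective(w, beta, y, cost, eps) -> float:
    return float(
        0.5 * w @ w - y @ beta + eps * np.abs(beta).sum() + (beta @ beta) / (4.0 * cost)
    )


def train_linear_svr(
    matrix,
    labels,
    cost: float,
    epsilon: float = 0.1,
    *,
    tolerance: float = 1e-5,
    max_sweeps: int = 2000,
    seed: int = 0,
    fit_bias: bool = True,
    heights: Sequence[int] | None = None,
    debug: bool = False,
) -> SvrModel:
    """Train a linear SVR model.

    Parameters
    ----------
    matrix, labels
        Sparse (or dense) n-by-p feature matrix and length-n targets.
    cost
        Regularization parameter C > 0; larger C fits the data harder.
    epsilon
        Half-width of the insensitivity tube (residuals below it are free).
    tolerance, max_sweeps
        Stop when the largest projected-gradient violation in a sweep is
        at most ``tolerance``, or after ``max_sweeps`` sweeps.
    seed
        Seeds the per-sweep coordinate order; training is deterministic
        given the seed.
    fit_bias
        Model an intercept via an appended constant feature (regularized).
    debug
        Additionally assert that the dual objective never increases
        between sweeps.
    """
    if cost <= 0:
        raise ValueError("cost must be strictly positive")
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    y = np.asarray(labels, dtype=np.float64).ravel()
    X = _as_solver_csr(matrix)
    if X.shape[0] != y.shape[0]:
        raise ValueError(
            f"matrix has {X.shape[0]} rows but labels has {y.shape[0]} entries"
        )
    n_features = X.shape[1]
    if fit_bias:
        X = _as_solver_csr(sp.hstack([X, np.ones((X.shape[0], 1))], format="csr"))

    inv2c = 1.0 / (2.0 * cost)
    row_sq = np.asarray(X.multiply(X).sum(axis=1)).ravel()
    qii = row_sq + inv2c
    w = np.zeros(X.shape[1])
    beta = np.zeros(X.shape[0])

    prev_obj = _dual_objective(w, beta, y, cost, epsilon) if debug else 0.0
    sweeps = 0
    max_violation = np.inf
    for sweep in range(max_sweeps):
        sweep_seed = (seed * 1_000_003 + sweep) % (2**31 - 1)
        max_violation = _cd_sweep(
            X.data, X.indices, X.indptr, y, qii, w, beta, inv2c, epsilon, sweep_seed
        )
        sweeps = sweep + 1
        if debug:
            obj = _dual_objective(w, beta, y, cost, epsilon)
            if obj > prev_obj + 1e-9 * max(1.0, abs(prev_obj)):
                raise AssertionError(
                    f"dual objective increased: {prev_obj} -> {obj} on sweep {sweeps}"
                )
            prev_obj = obj
        if max_violation <= tolerance:
            break

    bias = float(w[-1]) if fit_bias else 0.0
    weights = w[:-1].copy() if fit_bias else w.copy()
    return SvrModel(
        weights=weights,
        bias=bias,
        cost=float(cost),
        epsilon=float(epsilon),
        heights=tuple(int(h) for h in heights) if heights is not None else None,
        tolerance=float(tolerance),
        sweeps=sweeps,
        seed=int(seed),
    )


def predict(model: SvrModel, matrix) -> np.ndarray:
    """Predictions ``X w + b``; features beyond the model's width must be absent."""
    X = sp.csr_matrix(matrix, dtype=np.float64)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"matrix has {X.shape[1]} features but model expects {model.n_features}"
        )
    return np.asarray(X @ model.weights).ravel() + model.bias


def rmsd(observed, predicted) -> float:
    """Root-mean-square deviation between two equal-length vectors."""
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape[0]} vs {pred.shape[0]}")
    if obs.size == 0:
        raise ValueError("RMSD of empty vectors is undefined")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def kfold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic k-fold partition of ``range(n)``."""
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if folds > n:
        raise ValueError(f"cannot split {n} records into {folds} folds")
    rng = np.random.default_rng(seed)
    return [np.sort(part) for part in np.array_split(rng.permutation(n), folds)]


def cross_validate_cost(
    matrix,
    labels,
    cost_grid: Sequence[float] = DEFAULT_COST_GRID,
    folds: int = 5,
    seed: int = 0,
    *,
    epsilon: float = 0.1,
    tolerance: float = 1e-5,
    max_sweeps: int = 2000,
    fit_bias: bool = True,
):
    """Choose C by k-fold cross-validation, favouring lower cost on ties.

    The fold partition is fixed by ``seed`` and shared across the whole
    cost grid, so every cost is scored on identical splits.  The chosen
    cost minimizes the mean fold RMSD; costs within ``COST_TIE_RTOL``
    relative of the minimum count as the same performance and the lowest
    of them wins.

    Returns ``(chosen_cost, table)`` where ``table`` is a DataFrame with
    one row per cost (columns ``cost``, ``mean_rmsd``, ``fold_rmsds``).
    """
    import pandas as pd

    grid = sorted(set(float(c) for c in cost_grid))
    if not grid:
        raise ValueError("cost grid must be non-empty")
    y = np.asarray(labels, dtype=float).ravel()
    X = sp.csr_matrix(matrix, dtype=np.float64)
    fold_idx = kfold_indices(X.shape[0], folds, seed)
    all_idx = np.arange(X.shape[0])

    rows = []
    for cost in grid:
        fold_rmsds = []
        for held in fold_idx:
            train = np.setdiff1d(all_idx, held, assume_unique=False)
            model = train_linear_svr(
                X[train], y[train], cost, epsilon,
                tolerance=tolerance, max_sweeps=max_sweeps, seed=seed, fit_bias=fit_bias,
            )
            fold_rmsds.append(rmsd(y[held], predict(model, X[held])))
        rows.append(
            {"cost": cost, "mean_rmsd": float(np.mean(fold_rmsds)), "fold_rmsds": fold_rmsds}
        )
    table = pd.DataFrame(rows)
    best = table["mean_rmsd"].min()
    threshold = best * (1.0 + COST_TIE_RTOL) + 1e-15
    chosen = float(table.loc[table["mean_rmsd"] <= threshold, "cost"].min())
    return chosen, table


# -- persistence ------------------------------------------------------------


def save_model(
    model: SvrModel,
    dictionary: SignatureDictionary,
    model_path,
    signatures_path,
) -> tuple[int, int]:
    """Write the model file and its paired signature list.

    The model file is self-describing text: a header (solver tag, feature
    count, bias, hyperparameters, solver metadata) followed by one weight
    per line in feature-index order.  Returns both file sizes in bytes.
    """
    if model.n_features != len(dictionary):
        raise ValueError(
            f"model has {model.n_features} weights but dictionary has {len(dictionary)} entries"
        )
    heights_text = ",".join(str(h) for h in model.heights) if model.heights else "-"
    with open(model_path, "w") as fh:
        fh.write(f"{_FORMAT_TAG} 1\n")
        fh.write(f"solver {model.solver}\n")
        fh.write(f"features {model.n_features}\n")
        fh.write(f"bias_term true\n")
        fh.write(f"bias {model.bias!r}\n")
        fh.write(f"cost {model.cost!r}\n")
        fh.write(f"epsilon {model.epsilon!r}\n")
        fh.write(f"heights {heights_text}\n")
        fh.write(f"tolerance {model.tolerance!r}\n")
        fh.write(f"sweeps {model.sweeps}\n")
        fh.write(f"seed {model.seed}\n")
        fh.write("weights\n")
        for value in model.weights:
            fh.write(f"{float(value)!r}\n")
    sig_size = write_signature_list(dictionary, signatures_path)
    return os.path.getsize(model_path), sig_size


def load_model(model_path, signatures_path) -> tuple[SvrModel, SignatureDictionary]:
    """Load a model file together with its signature list.

    Raises
    ------
    ValueError
        If the files are inconsistent (feature count != signature count)
        or the model file is malformed.
    """
    with open(model_path) as fh:
        lines = [line.rstrip("\n") for line in fh]
    if not lines or not lines[0].startswith(_FORMAT_TAG):
        raise ValueError(f"{model_path}: not a {_FORMAT_TAG} file")
    header: dict[str, str] = {}
    body_at = None
    for k, line in enumerate(lines[1:], start=1):
        if line == "weights":
            body_at = k + 1
            break
        key, _, value = line.partition(" ")
        header[key] = value
    if body_at is None:
        raise ValueError(f"{model_path}: missing weights section")
    n_features = int(header["features"])
    weight_lines = [line for line in lines[body_at:] if line]
    if len(weight_lines) != n_features:
        raise ValueError(
            f"{model_path}: expected {n_features} weights, found {len(weight_lines)}"
        )
    heights_text = header.get("heights", "-")
    heights = (
        tuple(int(h) for h in heights_text.split(",")) if heights_text != "-" else None
    )
    model = SvrModel(
        weights=np.array([float(v) for v in weight_lines]),
        bias=float(header["bias"]),
        cost=float(header["cost"]),
        epsilon=float(header["epsilon"]),
        heights=heights,
        tolerance=float(header.get("tolerance", "0")),
        sweeps=int(header.get("sweeps", "0")),
        seed=int(header.get("seed", "0")),
        solver=header.get("solver", _SOLVER_TAG),
    )
    dictionary = read_signature_list(signatures_path)
    if len(dictionary) != model.n_features:
        raise ValueError(
            f"signature list {signatures_path} has {len(dictionary)} entries "
            f"but model expects {model.n_features}"
        )
    return model, dictionary


# -- kernel backend contract ------------------------------------------------

#: a backend trainer maps (matrix, labels, RbfParams) to a predictor
BackendTrainer = Callable[[object, object, RbfParams], object]


def linear_backend(matrix, labels, params: RbfParams, *, seed: int = 0):
    """The in-repo linear trainer wrapped in the kernel-backend contract.

    Uses ``params.cost`` only; the kernel width does not apply to a linear
    model and is ignored.
    """
    return train_linear_svr(matrix, labels, params.cost, seed=seed)


def sklearn_rbf_backend(matrix, labels, params: RbfParams, *, epsilon: float = 0.1):
    """RBF-kernel SVR backend backed by scikit-learn's solver."""
    from sklearn.svm import SVR

    est = SVR(kernel="rbf", C=params.cost, gamma=params.gamma, epsilon=epsilon)
    est.fit(sp.csr_matrix(matrix, dtype=np.float64), np.asarray(labels, dtype=float))

    class _Adapter:
        def predict(self, m):
            return est.predict(sp.csr_matrix(m, dtype=np.float64))

    return _Adapter()


def check_backend(trainer: BackendTrainer, *, n: int = 40, p: int = 8, seed: int = 0) -> None:
    """Verify a backend trainer satisfies the harness contract.

    Checks that training on a small random problem returns an object whose
    ``predict`` gives a finite vector of the right length, that repeated
    training is deterministic, and that an RMSD can be computed from the
    predictions.  Raises :class:`BackendContractError` on any violation.
    """
    rng = np.random.default_rng(seed)
    X = sp.csr_matrix(rng.normal(size=(n, p)))
    y = rng.normal(size=n)
    params = RbfParams(cost=1.0, gamma=0.1)
    preds = []
    for _ in range(2):
        model = trainer(X, y, params)
        if not hasattr(model, "predict"):
            raise BackendContractError("backend result lacks a predict method")
        pred = np.asarray(model.predict(X), dtype=float).ravel()
        if pred.shape != (n,):
            raise BackendContractError(
                f"backend predictions have shape {pred.shape}, expected ({n},)"
            )
        if not np.all(np.isfinite(pred)):
            raise BackendContractError("backend predictions are not finite")
        preds.append(pred)
    if not np.array_equal(preds[0], preds[1]):
        raise BackendContractError("backend is not deterministic across retrains")
    rmsd(y, preds[0])
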