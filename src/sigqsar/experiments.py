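"""Study harnesses: learning curves and cost/gamma grid search.

The learning-curve harness varies the training-set size at fixed method:
a held-out test set is drawn once per seed, then for every (size,
replicate) pair an independent training subsample is drawn without
replacement from the remaining records, a model is trained from scratch
(its signature dictionary rebuilt from the subsample, exactly as a real
training run would) and scored on the fixed test set by RMSD.  Per-size
medians summarize the replicates.

The grid search scores every (cost, gamma) cell of a kernel backend on a
fixed train/test split and reports the full RMSD table plus the best
cell, breaking ties toward lower cost and then lower gamma.
"""

from __future__ import annotations

import os
import time
from dataclasses import dataclass
from itertools import product
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .chemio import PropertyRecord
from .featurize import (
    SignatureDictionary,
    build_dictionary,
    vectorize_multiset,
    vectors_to_csr,
)
from .signatures import molecule_signatures
from .svr import RbfParams, predict, rmsd, train_linear_svr

DEFAULT_HEIGHTS = (1, 2, 3)
DEFAULT_REPLICATES = 3
DEFAULT_TEST_FRACTION = 0.2
MAX_TEST_SIZE = 50_000

DEFAULT_COSTS = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)
DEFAULT_GAMMAS = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0)


@dataclass
class LearningCurvePoint:
    """One trained model in a learning-curve sweep."""

    size: int
    replicate: int
    method: str
    test_rmsd: float
    build_seconds: float
    observed: np.ndarray | None = None
    predicted: np.ndarray | None = None


@dataclass(frozen=True)
class GridCell:
    """RMSD of one (cost, gamma) combination."""

    cost: float
    gamma: float
    test_rmsd: float


def _signature_multisets(records: Sequence[PropertyRecord], heights) -> list:
    return [molecule_signatures(r.molecule, heights) for r in records]


def _featurize_split(
    train_multisets, test_multisets
) -> tuple[SignatureDictionary, "object", "object"]:
    dictionary = build_dictionary(train_multisets)
    train_vecs = [vectorize_multiset(ms, dictionary) for ms in train_multisets]
    test_vecs = [vectorize_multiset(ms, dictionary) for ms in test_multisets]
    return (
        dictionary,
        vectors_to_csr(train_vecs, len(dictionary)),
        vectors_to_csr(test_vecs, len(dictionary)),
    )


def learning_curve(
    records: Sequence[PropertyRecord],
    sizes: Sequence[int],
    *,
    replicates: int = DEFAULT_REPLICATES,
    method: str = "linear",
    backend: Callable | None = None,
    backend_params: RbfParams | None = None,
    cost: float = 1.0,
    epsilon: float = 0.1,
    heights: Sequence[int] = DEFAULT_HEIGHTS,
    seed: int = 0,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    keep_predictions: bool = False,
) -> tuple[list[LearningCurvePoint], pd.DataFrame]:
    """Replicated learning curve over training-set sizes.

    Returns the individual points and a per-size median summary
    (DataFrame with columns ``size`` and ``median_rmsd``).
    """
    if replicates < 1:
        raise ValueError("replicates must be at least 1")
    sizes = sorted(int(s) for s in sizes)
    n = len(records)
    n_test = min(int(round(test_fraction * n)), MAX_TEST_SIZE)
    too_big = [s for s in sizes if s + n_test > n]
    if too_big:
        raise ValueError(
            f"training sizes {too_big} exceed the {n - n_test} records left "
            f"after the {n_test}-record test set"
        )

    rng = np.random.default_rng(seed)
    test_idx = np.sort(rng.choice(n, size=n_test, replace=False))
    pool = np.setdiff1d(np.arange(n), test_idx)

    multisets = _signature_multisets(records, heights)
    y = np.array([r.value for r in records])
    test_multisets = [multisets[i] for i in test_idx]
    y_test = y[test_idx]

    points: list[LearningCurvePoint] = []
    for size, rep in product(sizes, range(replicates)):
        sub_rng = np.random.default_rng([seed, size, rep])
        train_idx = sub_rng.choice(pool, size=size, replace=False)
        train_multisets = [multisets[i] for i in train_idx]
        t0 = time.perf_counter()
        _, X_train, X_test = _featurize_split(train_multisets, test_multisets)
        if method == "linear":
            model = train_linear_svr(
                X_train, y[train_idx], cost, epsilon, seed=seed, heights=heights
            )
            pred = predict(model, X_test)
        else:
            if backend is None or backend_params is None:
                raise ValueError("a backend and its params are required for non-linear methods")
            pred = np.asarray(
                backend(X_train, y[train_idx], backend_params).predict(X_test)
            ).ravel()
        elapsed = time.perf_counter() - t0
        points.append(
            LearningCurvePoint(
                size=size,
                replicate=rep,
                method=method,
                test_rmsd=rmsd(y_test, pred),
                build_seconds=elapsed,
                observed=y_test.copy() if keep_predictions else None,
                predicted=pred if keep_predictions else None,
            )
        )

    summary = (
        pd.DataFrame({"size": [p.size for p in points], "rmsd": [p.test_rmsd for p in points]})
        .groupby("size", as_index=False)["rmsd"]
        .median()
        .rename(columns={"rmsd": "median_rmsd"})
    )
    return points, summary


def grid_search(
    train_records: Sequence[PropertyRecord],
    test_records: Sequence[PropertyRecord],
    cost_grid: Sequence[float] = DEFAULT_COSTS,
    gamma_grid: Sequence[float] = DEFAULT_GAMMAS,
    backend: Callable = None,
    *,
    heights: Sequence[int] = DEFAULT_HEIGHTS,
) -> tuple[list[GridCell], GridCell]:
    """Evaluate every (cost, gamma) cell of a kernel backend on a fixed split.

    Returns all cells plus the argmin cell; exact RMSD ties are broken
    toward the lower cost and then the lower gamma, so the result does not
    depend on grid enumeration order.
    """
    if backend is None:
        from .svr import sklearn_rbf_backend as backend  # noqa: F811
    costs = sorted(set(float(c) for c in cost_grid))
    gammas = sorted(set(float(g) for g in gamma_grid))
    if not costs or not gammas:
        raise ValueError("cost and gamma grids must be non-empty")

    train_multisets = _signature_multisets(train_records, heights)
    test_multisets = _signature_multisets(test_records, heights)
    _, X_train, X_test = _featurize_split(train_multisets, test_multisets)
    y_train = np.array([r.value for r in train_records])
    y_test = np.array([r.value for r in test_records])

    cells = [
        GridCell(c, g, rmsd(y_test, np.asarray(
            backend(X_train, y_train, RbfParams(cost=c, gamma=g)).predict(X_test)
        ).ravel()))
        for c, g in product(costs, gammas)
    ]
    best = min(cells, key=lambda cell: (cell.test_rmsd, cell.cost, cell.gamma))
    return cells, best


def coefficient_recovery(
    records: Sequence[PropertyRecord],
    truth,
    *,
    seed: int = 0,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    cost_grid: Sequence[float] | None = None,
    folds: int = 5,
    min_prevalence: float = 0.03,
) -> dict:
    """Fit the synthetic ground-truth model back from noisy data.

    Features are computed on the ground truth's own dictionary and height
    set so the fitted weights are directly comparable to the true
    coefficients.  Signature count matrices carry exact structural
    collinearity among their rarest columns (substructures co-occurring
    in a single molecule, conservation identities between bond counts
    seen from either end), so features present in less than
    ``min_prevalence`` of the training molecules are pruned before
    fitting — the standard rare-feature cut that makes the remaining
    design full rank; their weights stay at zero, which is also the true
    value since the generator places its coefficients on prevalent
    features.  The fit uses epsilon = 0 — the ridge limit of the solver —
    because recovery is an estimation problem, not a prediction-tube
    problem; cost is chosen by cross-validation on the training split.
    Returns the held-out RMSD, its ratio to the noise level, the
    worst-case coefficient error over the *full* dictionary and the
    chosen cost.
    """
    from .svr import DEFAULT_COST_GRID, cross_validate_cost

    if cost_grid is None:
        cost_grid = DEFAULT_COST_GRID
    multisets = [molecule_signatures(r.molecule, truth.heights) for r in records]
    X = vectors_to_csr(
        [vectorize_multiset(ms, truth.dictionary) for ms in multisets], len(truth.dictionary)
    )
    y = np.array([r.value for r in records])
    rng = np.random.default_rng(seed)
    n = len(records)
    test_idx = np.sort(rng.choice(n, size=int(round(test_fraction * n)), replace=False))
    train_idx = np.setdiff1d(np.arange(n), test_idx)

    train_prevalence = np.asarray((X[train_idx] > 0).sum(axis=0)).ravel() / train_idx.size
    kept = np.flatnonzero(train_prevalence >= min_prevalence)
    X_kept = X[:, kept]

    chosen_cost, _ = cross_validate_cost(
        X_kept[train_idx], y[train_idx], cost_grid, folds=folds, seed=seed, epsilon=0.0
    )
    model = train_linear_svr(
        X_kept[train_idx], y[train_idx], chosen_cost, 0.0, seed=seed, heights=truth.heights
    )
    heldout = rmsd(y[test_idx], predict(model, X_kept[test_idx]))
    weights_full = np.zeros(len(truth.dictionary))
    weights_full[kept] = model.weights
    coef_err = float(np.max(np.abs(weights_full - truth.beta)))
    return {
        "heldout_rmsd": heldout,
        "rmsd_to_noise": heldout / truth.noise_sigma if truth.noise_sigma > 0 else float("inf"),
        "coef_max_err": coef_err,
        "chosen_cost": chosen_cost,
        "model": model,
        "n_train": int(train_idx.size),
        "n_test": int(test_idx.size),
    }


# -- reporting --------------------------------------------------------------


def report(results, out_dir, *, model_files: Iterable[tuple[str, str, str]] = ()) -> None:
    """Write machine-readable TSV tables for a harness run.

    ``results`` is either a list of :class:`LearningCurvePoint` (written
    as ``learning_curve.tsv`` plus per-point predicted-vs-observed pair
    files) or of :class:`GridCell` (written as ``grid_search.tsv``, one
    row per cell, heatmap-ready).  ``model_files`` is an optional list of
    ``(tag, model_path, signatures_path)`` whose byte sizes are recorded
    in ``file_sizes.tsv``.
    """
    import logging

    os.makedirs(out_dir, exist_ok=True)
    results = list(results)
    if not results:
        logging.getLogger("sigqsar").warning("report: empty result list")
    if all(isinstance(r, GridCell) for r in results) and results:
        frame = pd.DataFrame(
            [{"cost": c.cost, "gamma": c.gamma, "test_rmsd": c.test_rmsd} for c in results]
        )
        frame.to_csv(os.path.join(out_dir, "grid_search.tsv"), sep="\t", index=False)
    else:
        frame = pd.DataFrame(
            [
                {
                    "size": p.size,
                    "replicate": p.replicate,
                    "method": p.method,
                    "test_rmsd": p.test_rmsd,
                    "build_seconds": p.build_seconds,
                }
                for p in results
            ],
            columns=["size", "replicate", "method", "test_rmsd", "build_seconds"],
        )
        frame.to_csv(os.path.join(out_dir, "learning_curve.tsv"), sep="\t", index=False)
        for p in results:
            if p.observed is not None and p.predicted is not None:
                pd.DataFrame({"observed": p.observed, "predicted": p.predicted}).to_csv(
                    os.path.join(
                        out_dir, f"pred_vs_obs_{p.method}_n{p.size}_rep{p.replicate}.tsv"
                    ),
                    sep="\t",
                    index=False,
                )
    if model_files:
        rows = [
            {
                "tag": tag,
                "model_bytes": os.path.getsize(model_path),
                "signatures_bytes": os.path.getsize(signatures_path),
            }
            for tag, model_path, signatures_path in model_files
        ]
        pd.DataFrame(rows).to_csv(os.path.join(out_dir, "file_sizes.tsv"), sep="\t", index=False)
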