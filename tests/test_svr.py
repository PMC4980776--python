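import numpy as np
import pytest
import scipy.sparse as sp

from sigqsar import (
    BackendContractError,
    RbfParams,
    build_dictionary,
    check_backend,
    cross_validate_cost,
    linear_backend,
    load_model,
    molecule_signatures,
    parse_smiles,
    predict,
    rmsd,
    save_model,
    sklearn_rbf_backend,
    train_linear_svr,
)
from sigqsar.featurize import SignatureDictionary
from sigqsar.svr import kfold_indices


def ridge_solution(X, y, cost):
    p = X.shape[1]
    return np.linalg.solve(X.T @ X + np.eye(p) / (2 * cost), X.T @ y)


class TestTrainLinearSvr:
    def test_all_zero_labels_give_zero_model(self):
        rng = np.random.default_rng(0)
        model = train_linear_svr(rng.normal(size=(10, 4)), np.zeros(10), cost=1.0)
        assert np.all(model.weights == 0.0) and model.bias == 0.0

    @pytest.mark.parametrize("trial", range(5))
    def test_epsilon_zero_matches_ridge(self, trial):
        """With eps=0 the objective is ridge; compare to the direct solve."""
        rng = np.random.default_rng(100 + trial)
        X, y = rng.normal(size=(50, 20)), rng.normal(size=50)
        model = train_linear_svr(
            X, y, cost=1.0, epsilon=0.0, tolerance=1e-12, max_sweeps=200_000,
            seed=trial, fit_bias=False,
        )
        assert np.max(np.abs(model.weights - ridge_solution(X, y, 1.0))) <= 1e-6

    def test_single_sample_large_cost_limit(self):
        model = train_linear_svr(
            np.array([[1.0]]), [2.0], cost=1e6, epsilon=0.0,
            tolerance=1e-10, max_sweeps=100_000, fit_bias=False,
        )
        assert abs(model.weights[0] - 2.0) <= 1e-4

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X, y = rng.normal(size=(40, 6)), rng.normal(size=40)
        m1 = train_linear_svr(X, y, 1.0, seed=7)
        m2 = train_linear_svr(X, y, 1.0, seed=7)
        assert np.array_equal(m1.weights, m2.weights) and m1.bias == m2.bias

    def test_dual_objective_never_increases(self):
        rng = np.random.default_rng(2)
        X, y = rng.normal(size=(100, 30)), rng.normal(size=100)
        train_linear_svr(X, y, 2.0, 0.1, debug=True, tolerance=1e-8, max_sweeps=3000)

    def test_training_rmsd_monotone_in_cost(self):
        """More cost means a harder fit: training RMSD is non-increasing in C."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(120, 10))
        y = X @ rng.normal(size=10) + rng.normal(scale=0.5, size=120)
        errors = [
            rmsd(y, predict(train_linear_svr(X, y, c, 0.0, tolerance=1e-9,
                                             max_sweeps=50_000), sp.csr_matrix(X)))
            for c in (0.01, 0.1, 1.0, 10.0, 100.0)
        ]
        assert all(b <= a + 1e-9 for a, b in zip(errors, errors[1:]))

    def test_sparse_parameter_recovery(self):
        """y = beta.x + b + noise with sparse beta is recovered at well-chosen C."""
        rng = np.random.default_rng(4)
        n, p, sigma = 2000, 100, 0.1
        beta = np.zeros(p)
        support = rng.choice(p, size=10, replace=False)
        beta[support] = rng.uniform(0.5, 1.5, size=10) * rng.choice([-1, 1], size=10)
        X = rng.normal(size=(n, p))
        y = X @ beta + 0.3 + rng.normal(scale=sigma, size=n)
        model = train_linear_svr(X[:1600], y[:1600], cost=10.0, epsilon=0.0,
                                 tolerance=1e-8, max_sweeps=20_000)
        assert np.max(np.abs(model.weights - beta)) <= 0.05
        assert rmsd(y[1600:], predict(model, sp.csr_matrix(X[1600:]))) <= 1.2 * sigma

    def test_invalid_inputs(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="cost"):
            train_linear_svr(X, np.zeros(10), cost=0.0)
        with pytest.raises(ValueError, match="epsilon"):
            train_linear_svr(X, np.zeros(10), cost=1.0, epsilon=-0.1)
        with pytest.raises(ValueError, match="rows"):
            train_linear_svr(X, np.zeros(7), cost=1.0)


class TestPredict:
    def test_zero_model_predicts_bias(self):
        model = train_linear_svr(np.zeros((5, 3)), np.full(5, 2.5), cost=100.0, epsilon=0.0)
        pred = predict(model, sp.csr_matrix(np.eye(3)))
        assert np.allclose(pred, model.bias)
        assert abs(model.bias - 2.5) < 0.05

    def test_exact_interpolation_of_consistent_data(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(80, 10))
        w = rng.normal(size=10)
        y = X @ w  # noiseless, overdetermined but consistent
        model = train_linear_svr(X, y, cost=1e5, epsilon=0.0, tolerance=1e-10,
                                 max_sweeps=100_000, fit_bias=False)
        assert np.max(np.abs(predict(model, sp.csr_matrix(X)) - y)) <= 1e-3

    def test_record_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        X, y = rng.normal(size=(30, 5)), rng.normal(size=30)
        model = train_linear_svr(X, y, 1.0)
        perm = rng.permutation(30)
        assert np.array_equal(predict(model, sp.csr_matrix(X[perm])),
                              predict(model, sp.csr_matrix(X))[perm])

    def test_feature_width_mismatch(self):
        model = train_linear_svr(np.zeros((4, 3)), np.zeros(4), 1.0)
        with pytest.raises(ValueError, match="features"):
            predict(model, sp.csr_matrix(np.zeros((2, 5))))


class TestRmsd:
    def test_identical_vectors(self):
        assert rmsd([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_arithmetic_example(self):
        assert rmsd([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_constant_offset(self):
        v = np.array([1.0, -2.0, 0.5])
        assert rmsd(v, v + 0.7) == pytest.approx(0.7)

    def test_errors(self):
        with pytest.raises(ValueError):
            rmsd([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            rmsd([], [])


class TestCrossValidateCost:
    def test_singleton_grid(self):
        rng = np.random.default_rng(8)
        X, y = rng.normal(size=(30, 4)), rng.normal(size=30)
        chosen, table = cross_validate_cost(X, y, [0.5], folds=3)
        assert chosen == 0.5 and len(table) == 1

    def test_exact_tie_returns_lowest_cost(self):
        # all-zero labels: every cost fits perfectly, fold RMSDs all zero
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 5))
        chosen, table = cross_validate_cost(X, np.zeros(40), [0.01, 1.0, 100.0], folds=4)
        assert table["mean_rmsd"].nunique() == 1
        assert chosen == 0.01

    def test_heavy_noise_avoids_grid_maximum(self):
        """On pure noise the exhaustive CV table itself is the oracle."""
        rng = np.random.default_rng(10)
        X = rng.normal(size=(200, 40))
        y = rng.normal(size=200)  # no signal at all
        grid = [0.005, 0.05, 0.5, 5.0, 50.0]
        chosen, table = cross_validate_cost(X, y, grid, folds=5, seed=3, epsilon=0.0)
        assert chosen < max(grid)
        best = table["mean_rmsd"].min()
        eligible = table.loc[table["mean_rmsd"] <= best * (1 + 1e-6) + 1e-15, "cost"]
        assert chosen == eligible.min()

    def test_folds_shared_across_costs_and_errors(self):
        assert [len(f) for f in kfold_indices(10, 5, seed=1)] == [2] * 5
        with pytest.raises(ValueError):
            kfold_indices(3, 5, seed=1)
        rng = np.random.default_rng(11)
        with pytest.raises(ValueError):
            cross_validate_cost(rng.normal(size=(3, 2)), np.zeros(3), [1.0], folds=5)
        with pytest.raises(ValueError):
            cross_validate_cost(rng.normal(size=(10, 2)), np.zeros(10), [], folds=2)


@pytest.fixture()
def trained_signature_model():
    graphs = [parse_smiles(s) for s in ("CCO", "CO", "CCC", "CCN", "c1ccccc1O")]
    multisets = [molecule_signatures(g, (1, 2)) for g in graphs]
    dictionary = build_dictionary(multisets)
    from sigqsar.featurize import vectorize_multiset, vectors_to_csr

    X = vectors_to_csr([vectorize_multiset(m, dictionary) for m in multisets], len(dictionary))
    y = np.array([0.5, 1.0, -0.2, 0.3, 2.0])
    model = train_linear_svr(X, y, 10.0, 0.1, heights=(1, 2), seed=5)
    return model, dictionary, X


class TestPersistence:
    def test_round_trip_reproduces_predictions(self, tmp_path, trained_signature_model):
        model, dictionary, X = trained_signature_model
        mp, sp_ = tmp_path / "model.txt", tmp_path / "signatures.txt"
        model_bytes, sig_bytes = save_model(model, dictionary, mp, sp_)
        assert model_bytes == len(mp.read_bytes()) and sig_bytes > 0
        loaded, loaded_dict = load_model(mp, sp_)
        assert loaded_dict == dictionary
        assert loaded.heights == model.heights
        assert np.max(np.abs(predict(loaded, X) - predict(model, X))) <= 1e-12

    def test_model_file_line_count(self, tmp_path, trained_signature_model):
        model, dictionary, _ = trained_signature_model
        mp, sp_ = tmp_path / "model.txt", tmp_path / "signatures.txt"
        save_model(model, dictionary, mp, sp_)
        lines = mp.read_text().splitlines()
        header = lines.index("weights") + 1
        assert len(lines) == header + model.n_features

    def test_tampered_signature_list_detected(self, tmp_path, trained_signature_model):
        model, dictionary, _ = trained_signature_model
        mp, sp_ = tmp_path / "model.txt", tmp_path / "signatures.txt"
        save_model(model, dictionary, mp, sp_)
        lines = sp_.read_text().splitlines()
        sp_.write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(ValueError, match="entries"):
            load_model(mp, sp_)

    def test_feature_count_mismatch_on_save(self, trained_signature_model, tmp_path):
        model, _, _ = trained_signature_model
        wrong = SignatureDictionary(("[C]",))
        with pytest.raises(ValueError, match="entries"):
            save_model(model, wrong, tmp_path / "m.txt", tmp_path / "s.txt")


class TestBackendContract:
    def test_linear_trainer_satisfies_contract(self):
        check_backend(linear_backend)

    def test_sklearn_rbf_satisfies_contract(self):
        check_backend(sklearn_rbf_backend)

    def test_wrong_length_predictions_rejected(self):
        def broken(matrix, labels, params):
            class Bad:
                def predict(self, m):
                    return np.zeros(3)

            return Bad()

        with pytest.raises(BackendContractError, match="shape"):
            check_backend(broken)

    def test_rbf_params_validation(self):
        with pytest.raises(ValueError):
            RbfParams(cost=-1.0, gamma=0.1)
        with pytest.raises(ValueError):
            RbfParams(cost=1.0, gamma=0.0)
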