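"""Imputer families: closed-form oracles, recovery on synthetic data,
determinism, and the iterative autoencoder contract."""

import numpy as np
import pandas as pd
import pytest

import mtimpute as mt
from mtimpute.models import (
    AE_HIDDEN,
    ImputerSpec,
    iterative_impute,
    train_autoencoder,
    train_linear,
    train_null,
    train_trees,
)


def _frame(rng, n, cols):
    return pd.DataFrame(rng.uniform(0, 1, size=(n, len(cols))), columns=cols)


class TestNull:
    def test_stores_train_mean_and_imputes_constant(self):
        train = pd.DataFrame({"A": [0.2, 0.4, 0.6], "T": [0.2, 0.4, 0.6]})
        imp = train_null(train, "T")
        assert imp.mean_ == pytest.approx(0.4)
        out = imp.predict(train)
        np.testing.assert_allclose(out["T"].to_numpy(), 0.4)

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            train_null(pd.DataFrame({"T": []}), "T")

    def test_mae_identity_and_uniform_closed_form(self):
        """Null MAE equals mean absolute deviation about the train mean; on
        Uniform[0,1] with mean 0.5 this converges to E|U-1/2| = 1/4."""
        rng = np.random.default_rng(0)
        train = pd.DataFrame({"T": [0.5, 0.5]})
        imp = train_null(train, "T")
        test = pd.DataFrame({"T": rng.uniform(0, 1, 50_000)})
        pred = imp.predict(test)["T"].to_numpy()
        mae = np.abs(test["T"].to_numpy() - pred).mean()
        # exact identity with the mean-absolute-deviation formula
        assert mae == pytest.approx(np.abs(test["T"] - 0.5).mean(), abs=1e-15)
        assert mae == pytest.approx(0.25, abs=0.01)


class TestLinear:
    def test_exact_linear_combination_recovered(self):
        rng = np.random.default_rng(1)
        X = _frame(rng, 3000, ["A", "B", "C"])
        X["T"] = 0.5 * X.A + 0.3 * X.B + 0.2 * X.C
        train, test = X.iloc[:2000], X.iloc[2000:]
        imp = train_linear(train, "T")
        mae = np.abs(imp.predict(test)["T"].to_numpy() - test["T"].to_numpy()).mean()
        assert mae <= 0.01

    def test_gaussian_noise_floor(self):
        """With N(0, 0.05) residual noise the best attainable MAE is
        sigma*sqrt(2/pi) ~ 0.040."""
        rng = np.random.default_rng(2)
        X = _frame(rng, 6000, ["A", "B", "C"])
        X["T"] = np.clip(
            0.5 * X.A + 0.3 * X.B + 0.2 * X.C + rng.normal(0, 0.05, 6000), 0, 1
        )
        train, test = X.iloc[:4000], X.iloc[4000:]
        imp = train_linear(train, "T")
        mae = np.abs(imp.predict(test)["T"].to_numpy() - test["T"].to_numpy()).mean()
        expected = 0.05 * np.sqrt(2 / np.pi)
        assert mae == pytest.approx(expected, rel=0.30)

    def test_independent_target_matches_null(self):
        rng = np.random.default_rng(3)
        X = _frame(rng, 4000, ["A", "B"])
        X["T"] = rng.uniform(0, 1, 4000)
        train, test = X.iloc[:3000], X.iloc[3000:]
        lin = train_linear(train, "T")
        nul = train_null(train, "T")
        mae_lin = np.abs(lin.predict(test)["T"].to_numpy() - test["T"].to_numpy()).mean()
        mae_nul = np.abs(nul.predict(test)["T"].to_numpy() - test["T"].to_numpy()).mean()
        assert mae_lin <= 1.10 * mae_nul

    def test_too_few_rows_for_cv_rejected(self):
        X = pd.DataFrame({"A": [0.1, 0.2, 0.3], "T": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="fold"):
            train_linear(X, "T")


class TestTrees:
    def test_step_function_recovered(self):
        rng = np.random.default_rng(4)
        X = _frame(rng, 4000, ["A", "B"])
        X["T"] = np.where(X.A < 0.5, 0.2, 0.8)
        train, test = X.iloc[:3000], X.iloc[3000:]
        imp = train_trees(train, "T")
        mae = np.abs(imp.predict(test)["T"].to_numpy() - test["T"].to_numpy()).mean()
        assert mae <= 0.02

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        X = _frame(rng, 500, ["A", "B", "T"])
        spec = ImputerSpec("boosted_trees", ("T",), seed=9)
        a = train_trees(X, "T", spec).predict(X)["T"]
        b = train_trees(X, "T", spec).predict(X)["T"]
        pd.testing.assert_series_equal(a, b)

    def test_trees_match_or_beat_linear_on_nonlinear_targets(self, prepared_fold):
        """pRB and AR carry (clipped, niche-modulated) dependencies; trees
        should never trail the linear model by more than 0.01 MAE."""
        split, (_, _, _, test_s, X_train, X_test) = prepared_fold
        for target in ("pRB", "AR"):
            truth = test_s.data[target].to_numpy()
            m_lin = np.abs(
                train_linear(X_train, target).predict(X_test)[target] - truth
            ).mean()
            m_tree = np.abs(
                train_trees(X_train, target).predict(X_test)[target] - truth
            ).mean()
            assert m_tree <= m_lin + 0.01


class TestPredictContract:
    def test_predictions_clipped_and_permutation_invariant(self):
        rng = np.random.default_rng(6)
        X = _frame(rng, 1000, ["A", "T"])
        X["T"] = 2.0 * X.A  # forces predictions above 1 pre-clip
        imp = train_linear(X, "T")
        out = imp.predict(X)["T"]
        assert out.between(0, 1).all()
        perm = rng.permutation(len(X))
        out_p = imp.predict(X.iloc[perm].reset_index(drop=True))["T"]
        np.testing.assert_allclose(out_p.to_numpy(), out.to_numpy()[perm])

    def test_schema_mismatch_rejected(self):
        rng = np.random.default_rng(7)
        X = _frame(rng, 300, ["A", "B", "T"])
        imp = train_trees(X, "T")
        with pytest.raises(ValueError, match="schema"):
            imp.predict(X[["A", "T"]])


def test_bundle_round_trip_preserves_predictions(tmp_path):
    rng = np.random.default_rng(8)
    X = _frame(rng, 400, ["A", "B", "T"])
    imp = train_trees(X, "T", ImputerSpec("boosted_trees", ("T",), seed=11))
    mt.save_imputer(imp, tmp_path / "bundle")
    back = mt.load_imputer(tmp_path / "bundle")
    assert back.spec == imp.spec
    pd.testing.assert_frame_equal(back.predict(X), imp.predict(X))


class _IdentityAE:
    """Degenerate reconstructor that copies its protein inputs through."""

    def __init__(self, panel, train_means):
        self.panel = panel
        self.train_means = train_means
        self.input_columns = list(panel.names)

    def reconstruct(self, X):
        return X[self.panel.names].copy().reset_index(drop=True)


@pytest.fixture(scope="module")
def trained_ae(prepared_fold):
    _, (_, _, _, _, X_train, _) = prepared_fold
    panel = mt.ProteinPanel.default()
    return train_autoencoder(
        X_train, panel, ImputerSpec("autoencoder", tuple(panel.names), seed=1)
    )


class TestAutoencoder:
    def test_latent_dimension_below_panel_size(self, trained_ae):
        assert trained_ae.latent_dim < len(trained_ae.panel)
        assert trained_ae.model.hidden_layer_sizes == AE_HIDDEN

    def test_reconstruction_beats_null_on_training_data(self, prepared_fold, trained_ae):
        _, (_, _, _, _, X_train, _) = prepared_fold
        recon = trained_ae.reconstruct(X_train)
        for p in trained_ae.panel.names:
            truth = X_train[p].to_numpy()
            mae_ae = np.abs(recon[p].to_numpy() - truth).mean()
            mae_null = np.abs(truth.mean() - truth).mean()
            assert mae_ae < mae_null, p

    def test_same_seed_gives_identical_weights(self, prepared_fold):
        _, (_, _, _, _, X_train, _) = prepared_fold
        panel = mt.ProteinPanel.default()
        spec = ImputerSpec("autoencoder", tuple(panel.names), seed=5)
        a = train_autoencoder(X_train, panel, spec)
        b = train_autoencoder(X_train, panel, spec)
        for wa, wb in zip(a.model.coefs_, b.model.coefs_):
            np.testing.assert_array_equal(wa, wb)

    def test_latent_must_compress(self, prepared_fold):
        _, (_, _, _, _, X_train, _) = prepared_fold
        panel = mt.ProteinPanel.default()
        spec = ImputerSpec(
            "autoencoder", tuple(panel.names),
            hyperparameters={"hidden_layer_sizes": (32, 32)},
        )
        with pytest.raises(ValueError, match="latent"):
            train_autoencoder(X_train, panel, spec)


class TestIterativeImpute:
    def _toy(self, n=50, seed=0):
        panel = mt.ProteinPanel.from_entries(
            [("A", "lineage", 1), ("B", "lineage", 1), ("T", "functional", 2)]
        )
        rng = np.random.default_rng(seed)
        X = _frame(rng, n, list(panel.names))
        means = X.mean()
        return panel, X, means

    def test_identity_ae_fixed_point_at_init(self):
        panel, X, means = self._toy()
        ae = _IdentityAE(panel, means)
        final, traj = iterative_impute(ae, X, ["T"], init="mean")
        assert traj.n_iter == 10
        for it in traj.iterations:
            np.testing.assert_allclose(it["T"].to_numpy(), means["T"])
        np.testing.assert_allclose(final["T"].to_numpy(), means["T"])
        final0, _ = iterative_impute(ae, X, ["T"], init="zero")
        assert (final0["T"] == 0.0).all()

    def test_single_iteration_reduces_to_one_decode(self, prepared_fold, ):
        _, (_, _, _, _, X_train, X_test) = prepared_fold
        panel = mt.ProteinPanel.default()
        ae = train_autoencoder(
            X_train, panel, ImputerSpec("autoencoder", tuple(panel.names), seed=2)
        )
        final, traj = iterative_impute(ae, X_test, ["CK7"], n_iter=1, window=1)
        X0 = X_test.copy()
        X0["CK7"] = float(ae.train_means["CK7"])
        single = ae.reconstruct(X0)["CK7"]
        np.testing.assert_allclose(final["CK7"].to_numpy(), single.to_numpy())

    def test_window_is_mean_of_last_iterations(self):
        panel, X, means = self._toy()

        class Shifter(_IdentityAE):
            def __init__(self, panel, means):
                super().__init__(panel, means)
                self.step = 0.0

            def reconstruct(self, X):
                out = X[self.panel.names].copy().reset_index(drop=True)
                self.step += 0.01
                out["T"] = self.step
                return out

        ae = Shifter(panel, means)
        final, traj = iterative_impute(ae, X, ["T"], n_iter=10, window=5)
        # iterations 6..10 carry values 0.06..0.10 -> mean 0.08
        np.testing.assert_allclose(final["T"].to_numpy(), 0.08)

    def test_non_target_columns_never_modified(self):
        panel, X, means = self._toy()
        ae = _IdentityAE(panel, means)
        _, traj = iterative_impute(ae, X, ["T"])
        # run again and inspect the inputs indirectly: A and B in every
        # iteration's source equal the originals (identity AE echoes inputs)
        final, _ = iterative_impute(ae, X, ["T"])
        assert "A" not in traj.iterations[0].columns

    def test_parameter_validation(self):
        panel, X, means = self._toy()
        ae = _IdentityAE(panel, means)
        with pytest.raises(ValueError, match="window"):
            iterative_impute(ae, X, ["T"], n_iter=3, window=5)
        with pytest.raises(ValueError, match="panel"):
            iterative_impute(ae, X, ["nope"])
        with pytest.raises(ValueError, match="init"):
            iterative_impute(ae, X, ["T"], init="median")

    def test_stabilizes_within_window(self, prepared_fold):
        """The windowed estimate differs from the last iteration by less
        than the iteration-to-iteration spread of the window."""
        _, (_, _, _, test_s, X_train, X_test) = prepared_fold
        panel = mt.ProteinPanel.default()
        ae = train_autoencoder(
            X_train, panel, ImputerSpec("autoencoder", tuple(panel.names), seed=3)
        )
        truth = test_s.data["pRB"].to_numpy()
        final, traj = iterative_impute(ae, X_test, ["pRB"])
        maes = [
            np.abs(it["pRB"].to_numpy() - truth).mean()
            for it in traj.iterations[-traj.window :]
        ]
        mae_final = np.abs(final["pRB"].to_numpy() - truth).mean()
        spread = max(np.std(maes), 1e-4)
        assert abs(mae_final - maes[-1]) < max(3 * spread, 0.01)
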