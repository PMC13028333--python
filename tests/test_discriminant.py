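"""Stepwise canonical discriminant analysis: assumption checks, selection,
canonical structure, classification and the territorial map."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

import kinanthro as ka
from kinanthro.cli import DEFAULT_CANDIDATES
from kinanthro.discriminant import RankError, wilks_lambda


def _clusters(rng, means, n=40, sd=1.0, p=3):
    """Gaussian groups with common spherical covariance."""
    X, y = [], []
    for i, mu in enumerate(means):
        X.append(rng.normal(0, sd, (n, p)) + np.asarray(mu))
        y += [f"g{i}"] * n
    return pd.DataFrame(np.vstack(X), columns=[f"x{j}" for j in range(p)]), np.array(y)


def cca_canonical_correlations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent oracle: canonical correlations between the features and the
    one-hot group coding via QR/SVD (no scatter matrices involved)."""
    Xc = X - X.mean(axis=0)
    groups = np.unique(y)
    Y = np.column_stack([(y == g).astype(float) for g in groups[:-1]])
    Yc = Y - Y.mean(axis=0)
    qx, _ = np.linalg.qr(Xc)
    qy, _ = np.linalg.qr(Yc)
    s = np.linalg.svd(qx.T @ qy, compute_uv=False)
    return np.sort(s)[::-1]


class TestAssumptions:
    def test_box_m_accepts_common_covariance(self):
        rng = np.random.default_rng(21)
        X, y = _clusters(rng, [(0, 0, 0), (1, 0, 0), (0, 1, 0)], n=120)
        rep = ka.check_assumptions(X, y)
        assert rep.box_p > 0.05
        assert not any("Box" in f for f in rep.flags)

    def test_duplicated_column_blows_up_vif(self):
        rng = np.random.default_rng(21)
        X, y = _clusters(rng, [(0, 0, 0), (2, 0, 0)], n=50)
        X["x3"] = X["x0"] + rng.normal(0, 1e-6, len(X))
        rep = ka.check_assumptions(X, y)
        assert rep.vif["x3"] > 1e3
        assert any("x3" in f for f in rep.flags)

    def test_orthogonal_columns_have_unit_vif(self):
        rng = np.random.default_rng(21)
        X, y = _clusters(rng, [(0, 0, 0), (1, 1, 1)], n=200)
        rep = ka.check_assumptions(X, y)
        assert all(v < 1.2 for v in rep.vif.values())


class TestStepwise:
    def test_single_informative_variable_enters_first(self):
        rng = np.random.default_rng(31)
        X, y = _clusters(rng, [(0, 0, 0), (4, 0, 0)], n=40)
        path = ka.stepwise_select(X, y)
        assert path.selected[0] == "x0"

    def test_infinite_entry_threshold_selects_nothing(self):
        rng = np.random.default_rng(31)
        X, y = _clusters(rng, [(0, 0, 0), (4, 0, 0)], n=40)
        path = ka.stepwise_select(X, y, f_enter=np.inf)
        assert path.selected == []
        assert path.lambda_path == []  # Lambda stays at 1

    def test_arm_girth_leads_selection_on_synthetic_cohorts(self):
        """Arm relaxed girth is among the first two entrants in most
        replicates of the synthetic study cohort."""
        hits = 0
        reps = 40
        for seed in range(reps):
            coh = ka.generate(ka.default_spec(seed=seed))
            df = coh.to_dataframe()
            path = ka.stepwise_select(df[list(DEFAULT_CANDIDATES)], df["position"])
            if "arm_relaxed" in path.selected[:2]:
                hits += 1
        assert hits > reps / 2

    def test_lambda_path_is_monotone_on_entries(self, cohort189):
        df = cohort189.to_dataframe()
        path = ka.stepwise_select(df[list(DEFAULT_CANDIDATES)], df["position"])
        entries = [l for l, msg in zip(path.lambda_path, path.log)
                   if msg.startswith("enter")]
        assert all(b < a for a, b in zip(entries, entries[1:]))


class TestCanonical:
    def test_eigenvalue_canonical_correlation_identity(self, cohort189):
        df = cohort189.to_dataframe()
        model = ka.fit_canonical(df[list(DEFAULT_CANDIDATES)], df["position"])
        assert np.allclose(
            model.canonical_correlations,
            np.sqrt(model.eigenvalues / (1 + model.eigenvalues)),
        )
        assert model.variance_explained_pct.sum() == pytest.approx(100.0)
        assert 0 < model.wilks_lambda <= 1
        assert (np.diff(model.eigenvalues) <= 1e-12).all()

    def test_two_group_centroid_separation_is_standardized_difference(self):
        rng = np.random.default_rng(41)
        n, delta, sd = 500, 1.5, 1.0
        x = np.concatenate([rng.normal(0, sd, n), rng.normal(delta, sd, n)])
        X = pd.DataFrame({"x": x})
        y = np.array(["a"] * n + ["b"] * n)
        model = ka.fit_canonical(X, y)
        d_mean = x[n:].mean() - x[:n].mean()
        s_pooled = np.sqrt(
            ((n - 1) * x[:n].var(ddof=1) + (n - 1) * x[n:].var(ddof=1)) / (2 * n - 2))
        gap = model.centroids.loc["b", "DF1"] - model.centroids.loc["a", "DF1"]
        assert abs(gap) == pytest.approx(abs(d_mean) / s_pooled, rel=1e-9)

    def test_identical_group_means_give_null_structure(self):
        rng = np.random.default_rng(41)
        X = pd.DataFrame(rng.normal(0, 1, (90, 3)), columns=["a", "b", "c"])
        y = np.repeat(["g1", "g2", "g3"], 30)
        X.iloc[:] -= np.vstack([X[y == g].mean() for g in ("g1", "g2", "g3")]
                               ).repeat(30, axis=0)
        model = ka.fit_canonical(X, y)
        assert model.eigenvalues.max() < 1e-10
        assert model.wilks_lambda == pytest.approx(1.0)

    def test_lambda_product_equals_determinant_ratio(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            X, y = _clusters(rng, rng.normal(0, 1, (3, 4)), n=25, p=4)
            model = ka.fit_canonical(X, y)
            # eigenvalue route must match det(W)/det(T) on the same data
            assert model.wilks_lambda == pytest.approx(
                wilks_lambda(X.to_numpy(), y), rel=1e-10)

    def test_agrees_with_independent_cca_oracle_and_sklearn(self):
        """Canonical correlations match a QR/SVD canonical-correlation oracle
        to 1e-8 and classification matches scikit-learn's LDA."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(43)
        for _ in range(5):
            X, y = _clusters(rng, rng.normal(0, 2, (3, 4)), n=40, p=4)
            model = ka.fit_canonical(X, y, priors="proportional")
            oracle = cca_canonical_correlations(X.to_numpy(), y)
            assert np.allclose(model.canonical_correlations, oracle[:2], atol=1e-8)
            lda = LinearDiscriminantAnalysis().fit(X, y)
            agree = np.mean(lda.predict(X) == ka.predict(model, X))
            assert agree >= 0.99

    def test_rank_error_when_underdetermined(self):
        rng = np.random.default_rng(44)
        X = pd.DataFrame(rng.normal(0, 1, (5, 4)))
        y = np.array(["a", "a", "b", "b", "c"])
        with pytest.raises(RankError):
            ka.fit_canonical(X, y)


class TestClassification:
    def test_accuracy_from_confusion_trace(self, cohort189):
        df = cohort189.to_dataframe()
        model = ka.fit_canonical(df[list(DEFAULT_CANDIDATES)], df["position"])
        rep = ka.classify(model, df[list(DEFAULT_CANDIDATES)], df["position"])
        total = rep.confusion.to_numpy().sum()
        assert total == len(df)
        assert rep.accuracy_pct == pytest.approx(
            100.0 * np.trace(rep.confusion.to_numpy()) / total)
        # row sums equal the per-position sample sizes
        counts = df["position"].value_counts()
        for pos in model.groups:
            assert rep.confusion.loc[pos].sum() == counts[pos]

    def test_printed_accuracy_arithmetic(self):
        assert round(100.0 * 109 / 189, 1) == 57.7

    def test_perfectly_separated_clusters_classify_fully(self):
        rng = np.random.default_rng(51)
        X, y = _clusters(rng, [(0, 0, 0), (30, 0, 0), (0, 30, 0)], n=30, sd=0.5)
        model = ka.fit_canonical(X, y)
        rep = ka.classify(model, X, y)
        assert rep.accuracy_pct == 100.0

    def test_null_features_accuracy_near_max_prior(self):
        rng = np.random.default_rng(52)
        sizes = {"a": 40, "b": 25, "c": 15}
        accs = []
        for _ in range(100):
            y = np.repeat(list(sizes), list(sizes.values()))
            X = pd.DataFrame(rng.normal(0, 1, (sum(sizes.values()), 3)))
            model = ka.fit_canonical(X, y, priors="proportional")
            accs.append(ka.classify(model, X, y).accuracy_pct / 100.0)
        max_prior = max(sizes.values()) / sum(sizes.values())
        assert abs(np.mean(accs) - max_prior) < 0.07

    def test_separation_monotonically_improves_model(self):
        rng = np.random.default_rng(53)
        eig1, acc = [], []
        for delta in (0.5, 1.5, 3.0):
            X, y = _clusters(rng, [(0, 0, 0), (delta, 0, 0), (0, delta, 0)], n=60)
            model = ka.fit_canonical(X, y)
            eig1.append(model.eigenvalues[0])
            acc.append(ka.classify(model, X, y).accuracy_pct)
        assert eig1[0] < eig1[1] < eig1[2]
        assert acc[0] < acc[1] < acc[2]


class TestTerritorialMap:
    @pytest.fixture()
    def model(self, cohort189):
        df = cohort189.to_dataframe()
        return ka.fit_canonical(df[list(DEFAULT_CANDIDATES)], df["position"])

    def test_centroid_cells_classify_as_their_group(self, model):
        tm = ka.territorial_map(model)
        cent = tm["centroids"]
        log_priors = {g: np.log(model.priors[g]) for g in model.groups}
        for pos in model.groups:
            z = cent.loc[pos].to_numpy()
            scores = {g: -0.5 * np.sum((z - cent.loc[g].to_numpy())**2)
                      + log_priors[g] for g in model.groups}
            assert max(scores, key=scores.get) == pos

    def test_partition_invariant_under_grid_refinement(self, model):
        coarse = ka.territorial_map(model, bounds=(-5, 5, -5, 5), resolution=21)
        fine = ka.territorial_map(model, bounds=(-5, 5, -5, 5), resolution=41)
        cg, fg = coarse["grid"], fine["grid"]
        merged = cg.merge(fg, on=["df1", "df2"], suffixes=("_c", "_f"))
        assert len(merged) == len(cg)  # coarse lattice is a sub-lattice
        assert (merged["position_c"] == merged["position_f"]).all()

    def test_linemen_and_skill_positions_split_on_df1(self, model):
        cent = model.centroids["DF1"]
        assert cent["OL"] > 0 and cent["DL"] > 0
        for pos in ("DB", "QB", "RB", "WR"):
            assert cent[pos] < 0

    def test_model_json_round_trip(self, model, tmp_path):
        import json
        text = model.to_json(tmp_path / "model.json")
        payload = json.loads(text)
        assert payload["selected_variables"] == model.selected_variables
        assert payload["wilks_lambda"] == pytest.approx(model.wilks_lambda)
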