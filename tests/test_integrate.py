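import numpy as np
import pandas as pd
import pytest
from scipy.linalg import eigh

from metabaxes.integrate import (
    AgingAxes,
    IntegrationError,
    assemble_coefficients,
    compute_scores,
    fit_lasso_phenotype,
    LassoFit,
    orient_and_label,
    pca_on_coefficients,
    prune_correlated,
    select_components,
    CoefficientMatrix,
)


def prune_reference(X, threshold):
    """Brute-force re-implementation of the iterative pruning rule."""
    cols = list(X.columns)
    data = {c: X[c].to_numpy(dtype=float) for c in cols}
    removed = []
    while True:
        active = [c for c in cols if c not in removed]
        corr = {}
        for a in active:
            for b in active:
                if a < b:
                    r = abs(np.corrcoef(data[a], data[b])[0, 1])
                    corr[(a, b)] = corr[(b, a)] = r
        violating = {
            c for c in active
            if any(corr[(c, o)] > threshold for o in active if o != c)
        }
        if not violating:
            return [c for c in cols if c not in removed], removed
        means = {
            c: np.mean([corr[(c, o)] for o in active if o != c]) for c in active
        }
        best = None
        for c in active:  # column order = tie-break order
            if c in violating and (best is None or means[c] > means[best] + 1e-15):
                best = c
        removed.append(best)


def exact_corr_frame(R, n=60, seed=0):
    """Columns with *exact* sample correlation matrix R."""
    rng = np.random.default_rng(seed)
    k = R.shape[0]
    raw = np.column_stack([np.ones(n), rng.standard_normal((n, k))])
    q, _ = np.linalg.qr(raw)
    basis = q[:, 1:]  # orthonormal, each orthogonal to the ones vector
    evals, evecs = np.linalg.eigh(R)
    evals = np.clip(evals, 1e-6, None)  # nearest-PSD projection
    root = evecs @ np.diag(np.sqrt(evals)) @ evecs.T
    X = basis @ root
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    return pd.DataFrame(X, columns=[f"m{i}" for i in range(k)])


class TestPruneCorrelated:
    def test_hand_trace(self):
        # r(A,B)=0.9 and r(A,C)=0.85 force r(B,C) >= 0.535, so a valid
        # correlation matrix needs r(B,C)=0.6; mean |r| is then
        # A 0.875 > B 0.75 > C 0.725 -> remove A, and {B, C} (0.6) stay
        R = np.array([[1.0, 0.9, 0.85], [0.9, 1.0, 0.6], [0.85, 0.6, 1.0]])
        X = exact_corr_frame(R)
        corr = X.corr().abs()
        assert corr.loc["m0", "m1"] == pytest.approx(0.9, abs=1e-9)
        assert corr.loc["m0", "m2"] == pytest.approx(0.85, abs=1e-9)
        kept, log = prune_correlated(X, 0.8)
        assert log.removed == ["m0"]
        assert log.mean_abs_corr[0] == pytest.approx(0.875, abs=1e-9)
        assert kept == ["m1", "m2"]

    def test_identity_when_below_threshold(self):
        R = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.3], [0.2, 0.3, 1.0]])
        X = exact_corr_frame(R)
        kept, log = prune_correlated(X, 0.8)
        assert kept == list(X.columns)
        assert log.removed == []

    def test_duplicate_column_one_removed(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(50)
        X = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.standard_normal(50)})
        kept, log = prune_correlated(X, 0.8)
        assert len(kept) == 2
        assert "c" in kept
        assert len(log.removed) == 1

    def test_constant_column_errors(self):
        X = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(IntegrationError, match="a"):
            prune_correlated(X, 0.8)

    def test_postcondition_max_corr(self, small_cohort):
        from metabaxes.preprocess import impute_half_min, log_standardize

        Z, _ = log_standardize(impute_half_min(small_cohort.metabolites))
        kept, _ = prune_correlated(Z, 0.8)
        corr = np.abs(Z[kept].corr().to_numpy())
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.8 + 1e-12

    def test_matches_brute_force_reference(self):
        rng = np.random.default_rng(2)
        for rep in range(200):
            n, m = 40, 15
            # draw correlated columns from a random factor model
            F = rng.standard_normal((n, 3))
            W = rng.standard_normal((3, m))
            X = pd.DataFrame(
                F @ W + 0.3 * rng.standard_normal((n, m)),
                columns=[f"c{j:02d}" for j in range(m)],
            )
            kept, log = prune_correlated(X, 0.8)
            kept_ref, removed_ref = prune_reference(X, 0.8)
            assert log.removed == removed_ref, f"rep {rep}"
            assert kept == kept_ref


class TestLasso:
    def test_strong_signal_selected(self):
        rng = np.random.default_rng(3)
        n, m = 400, 20
        X = pd.DataFrame(
            rng.standard_normal((n, m)), columns=[f"m{j}" for j in range(m)]
        )
        X = (X - X.mean()) / X.std(ddof=1)
        y = X["m0"].copy()
        y.name = "ph"
        fit = fit_lasso_phenotype(y, X, folds=5, cv_seed=0)
        assert fit.coefficients["m0"] > 0.9
        assert (fit.coefficients.drop("m0").abs() < 0.02).all()

    def test_full_shrinkage_limit(self):
        rng = np.random.default_rng(4)
        n, m = 100, 5
        X = pd.DataFrame(
            rng.standard_normal((n, m)), columns=[f"m{j}" for j in range(m)]
        )
        y = pd.Series(rng.standard_normal(n), name="ph")
        from sklearn.linear_model import Lasso

        big = Lasso(alpha=1e6).fit(X.to_numpy(), y.to_numpy())
        assert (big.coef_ == 0).all()

    def test_null_support_small(self):
        rng = np.random.default_rng(5)
        n, m = 1000, 100
        small_support = 0
        reps = 10
        for _ in range(reps):
            X = pd.DataFrame(
                rng.standard_normal((n, m)), columns=[f"m{j}" for j in range(m)]
            )
            y = pd.Series(rng.standard_normal(n), name="ph")
            fit = fit_lasso_phenotype(y, X, folds=5, cv_seed=1)
            small_support += (fit.coefficients != 0).sum() <= 5
        assert small_support >= reps * 0.9

    def test_constant_y_errors(self):
        X = pd.DataFrame({"m0": np.arange(20, dtype=float)})
        y = pd.Series(np.ones(20), name="ph")
        with pytest.raises(IntegrationError, match="constant"):
            fit_lasso_phenotype(y, X, folds=5)

    def test_too_few_rows_errors(self):
        X = pd.DataFrame({"m0": [1.0, 2.0, 3.0]})
        y = pd.Series([1.0, 2.0, 1.5], name="ph")
        with pytest.raises(IntegrationError, match="fold"):
            fit_lasso_phenotype(y, X, folds=5)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(
            rng.standard_normal((200, 30)), columns=[f"m{j}" for j in range(30)]
        )
        y = pd.Series(
            X["m1"] * 0.5 + rng.standard_normal(200) * 0.5, name="ph"
        )
        a = fit_lasso_phenotype(y, X, folds=5, cv_seed=42)
        b = fit_lasso_phenotype(y, X, folds=5, cv_seed=42)
        assert (a.coefficients == b.coefficients).all()
        assert a.alpha == b.alpha

    def test_1se_rule_penalizes_harder(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(
            rng.standard_normal((300, 40)), columns=[f"m{j}" for j in range(40)]
        )
        y = pd.Series(
            X.iloc[:, :5].sum(axis=1) * 0.3 + rng.standard_normal(300), name="ph"
        )
        fit_min = fit_lasso_phenotype(y, X, folds=5, cv_seed=0, rule="min")
        fit_1se = fit_lasso_phenotype(y, X, folds=5, cv_seed=0, rule="1se")
        assert fit_1se.alpha >= fit_min.alpha
        assert (fit_1se.coefficients != 0).sum() <= (fit_min.coefficients != 0).sum()


class TestAssemble:
    def _fit(self, values, ids, name):
        return LassoFit(
            coefficients=pd.Series(values, index=ids, name=name),
            alpha=0.1,
            cv_rule="min",
        )

    def test_construction(self):
        ids = ["m1", "m2", "m3"]
        fits = {
            "ph1": self._fit([1.0, 0.0, 0.0], ids, "ph1"),
            "ph2": self._fit([0.0, 2.0, 0.0], ids, "ph2"),
        }
        cm = assemble_coefficients(fits)
        assert cm.B.to_numpy().tolist() == [[1.0, 0.0], [0.0, 2.0], [0.0, 0.0]]

    def test_zero_column_warns(self):
        ids = ["m1", "m2"]
        fits = {
            "ph1": self._fit([1.0, 0.0], ids, "ph1"),
            "ph2": self._fit([0.0, 0.0], ids, "ph2"),
        }
        with pytest.warns(UserWarning, match="ph2"):
            cm = assemble_coefficients(fits)
        assert "ph2" in cm.phenotype_ids

    def test_mismatched_ids_error(self):
        fits = {
            "ph1": self._fit([1.0], ["m1"], "ph1"),
            "ph2": self._fit([1.0], ["mX"], "ph2"),
        }
        with pytest.raises(IntegrationError, match="ph2"):
            assemble_coefficients(fits)


def pca_oracle(B, center=True):
    """Independent route: eigendecomposition of the covariance of B."""
    Bc = B - B.mean(axis=0) if center else B.copy()
    evals, evecs = eigh(Bc.T @ Bc)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    weights = Bc @ evecs
    return evecs, weights, evals / evals.sum()


class TestPCA:
    def _cm(self, B):
        m, p = B.shape
        return CoefficientMatrix(
            B=pd.DataFrame(
                B,
                index=[f"m{i}" for i in range(m)],
                columns=[f"ph{j}" for j in range(p)],
            ),
            lambda_per_phenotype=pd.Series(0.1, index=[f"ph{j}" for j in range(p)]),
            cv_seed=0,
        )

    def test_rank_one(self):
        u = np.array([1.0, 2.0, -1.0, 0.5])
        v = np.array([1.0, -1.0, 0.5])
        B = np.outer(u, v)
        axes = pca_on_coefficients(self._cm(B), center=False)
        assert axes.variance_proportion.iloc[0] == pytest.approx(1.0)
        w = axes.weights.iloc[:, 0].to_numpy()
        l = axes.loadings.iloc[:, 0].to_numpy()
        assert abs(np.corrcoef(w, u)[0, 1]) == pytest.approx(1.0)
        assert abs(np.corrcoef(l, v)[0, 1]) == pytest.approx(1.0)

    def test_matches_eigh_oracle(self):
        rng = np.random.default_rng(8)
        for rep in range(100):
            B = rng.standard_normal((50, 8))
            axes = pca_on_coefficients(self._cm(B))
            evecs, wts, props = pca_oracle(B)
            k = axes.k
            for j in range(k):
                a = axes.loadings.iloc[:, j].to_numpy()
                b = evecs[:, j]
                sign = np.sign(a @ b)
                assert np.abs(a - sign * b).max() < 1e-8, f"rep {rep} comp {j}"
                aw = axes.weights.iloc[:, j].to_numpy()
                bw = wts[:, j] * sign
                assert np.abs(aw - bw).max() < 1e-8
            assert np.abs(
                axes.variance_proportion.to_numpy() - props[:k]
            ).max() < 1e-10

    def test_variance_proportions_sum_to_one(self):
        rng = np.random.default_rng(9)
        axes = pca_on_coefficients(self._cm(rng.standard_normal((30, 6))))
        assert axes.variance_proportion.sum() == pytest.approx(1.0, abs=1e-12)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(10)
        axes = pca_on_coefficients(self._cm(rng.standard_normal((40, 7))))
        G = axes.loadings.to_numpy().T @ axes.loadings.to_numpy()
        assert np.abs(G - np.eye(axes.k)).max() < 1e-10

    def test_rank_deficient_components_dropped(self):
        B = np.zeros((10, 4))
        B[:, 0] = np.arange(10, dtype=float)
        B[:, 1] = 2 * np.arange(10, dtype=float)
        axes = pca_on_coefficients(self._cm(B), center=False)
        assert axes.k == 1


class TestSelectComponents:
    def test_paper_shape_four(self):
        vp = pd.Series([0.18, 0.16, 0.12, 0.10, 0.05, 0.04])
        assert select_components(vp, 0.10) == 4

    def test_two(self):
        assert select_components(pd.Series([0.5, 0.3, 0.09]), 0.10) == 2

    def test_floor_with_warning(self):
        with pytest.warns(UserWarning, match="keeping the first"):
            k = select_components(pd.Series([0.09, 0.08]), 0.10)
        assert k == 1

    def test_empty_errors(self):
        with pytest.raises(IntegrationError):
            select_components(pd.Series([], dtype=float))

    def test_rule_counts_leading_run_only(self):
        # a later component above threshold does not count
        vp = pd.Series([0.5, 0.08, 0.2, 0.12])
        with pytest.raises(IntegrationError):
            select_components(vp)  # non-increasing is a precondition


class TestScores:
    def test_unit_weight_construction(self):
        Z = pd.DataFrame(
            {"m1": [0.5, -0.5, 1.5, -1.5], "m2": [1.0, -1.0, 2.0, -2.0]},
            index=list("abcd"),
        )
        w = pd.DataFrame({"axis_0": [1.0, 0.0]}, index=["m1", "m2"])
        raw = Z.to_numpy() @ w.to_numpy()
        assert raw[0, 0] == 0.5  # before final standardization
        sc = compute_scores(w, Z)
        assert sc.scores["axis_0"].mean() == pytest.approx(0.0, abs=1e-12)
        assert sc.scores["axis_0"].std(ddof=1) == pytest.approx(1.0)

    def test_replay_identical(self, small_cohort):
        from metabaxes.preprocess import impute_half_min, log_standardize

        Z, _ = log_standardize(impute_half_min(small_cohort.metabolites))
        rng = np.random.default_rng(11)
        w = pd.DataFrame(
            rng.standard_normal((Z.shape[1], 2)),
            index=Z.columns,
            columns=["axis_0", "axis_1"],
        )
        a = compute_scores(w, Z)
        b = compute_scores(w, Z)
        assert (a.scores.to_numpy() == b.scores.to_numpy()).all()

    def test_scale_invariance_through_pipeline(self, small_cohort):
        from metabaxes.preprocess import (
            MetaboliteMatrix,
            impute_half_min,
            log_standardize,
        )

        m = small_cohort.metabolites
        Z1, _ = log_standardize(impute_half_min(m))
        scaled = MetaboliteMatrix(values=m.values * 3.0, qc=m.qc, cv=m.cv)
        Z3, _ = log_standardize(impute_half_min(scaled))
        rng = np.random.default_rng(12)
        w = pd.DataFrame(
            rng.standard_normal((Z1.shape[1], 1)), index=Z1.columns,
            columns=["axis_0"],
        )
        s1 = compute_scores(w, Z1).scores
        s3 = compute_scores(w, Z3).scores
        assert np.abs(s1.to_numpy() - s3.to_numpy()).max() < 1e-10

    def test_missing_metabolites_error_and_zero_fill(self):
        Z = pd.DataFrame({"m1": [0.1, -0.1, 0.3]})
        w = pd.DataFrame({"axis_0": [1.0, 2.0]}, index=["m1", "m2"])
        with pytest.raises(IntegrationError, match="m2"):
            compute_scores(w, Z)
        with pytest.warns(UserWarning, match="zero-fill"):
            sc = compute_scores(w, Z, zero_fill=True)
        assert sc.scores.shape == (3, 1)


class TestOrientAndLabel:
    def _axes_scores(self, flip_sign):
        rng = np.random.default_rng(13)
        n = 300
        phen = pd.DataFrame(
            {"top": rng.standard_normal(n), "other": rng.standard_normal(n)},
            index=[f"p{i}" for i in range(n)],
        )
        score_vals = flip_sign * (
            0.6 * phen["top"] + 0.8 * rng.standard_normal(n)
        )
        scores_df = pd.DataFrame({"axis_0": score_vals}, index=phen.index)
        scores_df = (scores_df - scores_df.mean()) / scores_df.std(ddof=1)
        from metabaxes.integrate import MetabolicScores

        axes = AgingAxes(
            loadings=pd.DataFrame({"axis_0": [0.9, 0.1]}, index=["top", "other"]),
            weights=pd.DataFrame({"axis_0": [1.0, -1.0]}, index=["m1", "m2"]),
            variance_proportion=pd.Series({"axis_0": 1.0}),
            center=pd.Series({"top": 0.0, "other": 0.0}),
        )
        scores = MetabolicScores(scores=scores_df, cohort="train")
        return axes, scores, phen

    def test_negative_correlation_flipped(self):
        axes, scores, phen = self._axes_scores(flip_sign=-1.0)
        oriented, new_scores = orient_and_label(
            axes, scores, phen, {"top": "adiposity_sarcopenia"}
        )
        r = np.corrcoef(new_scores.scores["axis_0"], phen["top"])[0, 1]
        assert r > 0
        assert oriented.signs["axis_0"] == -1.0
        assert oriented.labels["axis_0"] == "adiposity_sarcopenia:top"

    def test_positive_correlation_unchanged(self):
        axes, scores, phen = self._axes_scores(flip_sign=1.0)
        oriented, new_scores = orient_and_label(axes, scores, phen)
        assert oriented.signs["axis_0"] == 1.0
        assert (new_scores.scores["axis_0"] == scores.scores["axis_0"]).all()

    def test_label_ties_break_to_lower_index(self):
        from metabaxes.integrate import MetabolicScores

        rng = np.random.default_rng(14)
        n = 100
        phen = pd.DataFrame(
            rng.standard_normal((n, 2)), columns=["first", "second"]
        )
        axes = AgingAxes(
            loadings=pd.DataFrame(
                {"axis_0": [0.5, 0.5]}, index=["first", "second"]
            ),
            weights=pd.DataFrame({"axis_0": [1.0]}, index=["m1"]),
            variance_proportion=pd.Series({"axis_0": 1.0}),
            center=pd.Series({"first": 0.0, "second": 0.0}),
        )
        scores = MetabolicScores(
            scores=pd.DataFrame({"axis_0": phen["first"]}, index=phen.index),
            cohort="train",
        )
        oriented, _ = orient_and_label(axes, scores, phen, {"first": "d"})
        assert oriented.labels["axis_0"] == "d:first"
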