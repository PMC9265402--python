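"""PCA index construction: fits, the high-loading rule, threshold reduction,
supervised direction, and index application."""

import numpy as np
import pandas as pd
import pytest

import aceindex as ai
from aceindex.pca import IndexDefinition, PCASolution

from conftest import two_block_matrix


def oracle_eig(X: pd.DataFrame):
    """Dense eigendecomposition of the explicitly formed correlation matrix."""
    R = np.corrcoef(X.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eig(R)
    order = np.argsort(evals.real)[::-1]
    return evals.real[order], evecs.real[:, order]


class TestFitPca:
    def test_rank_one_pair_explains_everything(self):
        x = np.arange(10.0)
        Z = ai.standardize(pd.DataFrame({"a": x, "b": 3 * x + 1}))
        sol = ai.fit_pca(Z, 1)
        assert sol.prop_variance[0] == pytest.approx(1.0, abs=1e-8)

    def test_loadings_orthonormal(self, standardized_matrix):
        sol = ai.fit_pca(standardized_matrix, 4)
        L = sol.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(4), atol=1e-8)

    def test_matches_dense_eigendecomposition(self, rng):
        X = pd.DataFrame(rng.standard_normal((6, 4)), columns=list("abcd"))
        Z = ai.standardize(X)
        sol = ai.fit_pca(Z, 3)
        evals, evecs = oracle_eig(X)
        np.testing.assert_allclose(sol.eigenvalues, evals[:3], atol=1e-8)
        for j in range(3):  # eigenvectors equal up to sign
            v = sol.loadings.iloc[:, j].to_numpy()
            assert min(
                np.abs(v - evecs[:, j]).max(), np.abs(v + evecs[:, j]).max()
            ) < 1e-8

    def test_eigenvalues_nonincreasing(self, standardized_matrix):
        sol = ai.fit_pca(standardized_matrix, 6)
        assert (np.diff(sol.eigenvalues) <= 1e-12).all()
        assert (np.diff(sol.prop_variance) <= 1e-12).all()

    def test_invalid_k_rejected(self, standardized_matrix):
        with pytest.raises(ValueError):
            ai.fit_pca(standardized_matrix, 0)
        with pytest.raises(ValueError):
            ai.fit_pca(standardized_matrix, 7)

    def test_unstandardized_input_rejected(self, rng):
        X = pd.DataFrame(rng.uniform(10, 20, size=(30, 3)))
        with pytest.raises(ValueError, match="centered"):
            ai.fit_pca(X, 1)


def make_solution(loadings: np.ndarray) -> PCASolution:
    names = [f"v{i}" for i in range(loadings.shape[0])]
    cols = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    return PCASolution(
        loadings=pd.DataFrame(loadings, index=names, columns=cols),
        eigenvalues=np.ones(loadings.shape[1]),
        prop_variance=np.full(loadings.shape[1], 0.1),
        variable_names=names,
    )


class TestHighLoadingRule:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ((0.20, 0.05), (True, False)),   # magnitude and margin on PC1
            ((0.20, 0.18), (False, False)),  # margin 0.02 < 0.10
            ((0.14, 0.01), (False, False)),  # 0.14 below the 0.15 floor
        ],
    )
    def test_two_component_rule(self, row, expected):
        sol = make_solution(np.array([row]))
        high = ai.classify_high_loading(sol, ai.HighLoadingRule())
        assert tuple(high.iloc[0]) == expected

    def test_single_component_margin_is_vacuous(self):
        sol = make_solution(np.array([[0.16], [0.10]]))
        high = ai.classify_high_loading(sol, ai.HighLoadingRule())
        assert high["PC1"].tolist() == [True, False]


class TestThresholdPca:
    def test_two_block_fixture_drops_off_block_variables(self):
        Z = two_block_matrix(seed=42)
        defn, trace = ai.threshold_pca_index(Z)
        assert defn.n_score_columns == 2
        assert sorted(defn.variable_names) == sorted(
            [f"b1_{i}" for i in range(6)] + [f"b2_{i}" for i in range(6)]
        )
        dropped = [v for it in trace.iterations for v in it.dropped]
        assert sorted(dropped) == [f"noise_{i}" for i in range(4)]
        assert trace.stop_reason == "no variables merited dropping"

    def test_invariant_under_variable_reordering(self, rng):
        Z = two_block_matrix(seed=42)
        perm = list(np.array(Z.columns)[rng.permutation(Z.shape[1])])
        defn_a, _ = ai.threshold_pca_index(Z)
        defn_b, _ = ai.threshold_pca_index(Z[perm])
        assert sorted(defn_a.variable_names) == sorted(defn_b.variable_names)
        sa = ai.apply_index(defn_a, Z[defn_a.variable_names])
        sb = ai.apply_index(defn_b, Z[defn_b.variable_names])
        for c in sa.columns:
            assert abs(np.corrcoef(sa[c], sb[c])[0, 1]) == pytest.approx(1.0, abs=1e-10)

    def test_failing_first_fit_terminates_without_drops(self):
        # one dominant factor plus a two-variable pair: PC2 concentrates on
        # the pair (2 < 4 high loadings) while the other four variables are
        # high on PC1, so the very first fit fails and the pass stops with
        # nothing dropped
        r = np.random.default_rng(8)
        n = 1000
        f = r.standard_normal(n)
        u = r.standard_normal(n)
        cols = {f"v{i}": f + 0.3 * r.standard_normal(n) for i in range(4)}
        cols["p0"] = f + 0.9 * u + 0.3 * r.standard_normal(n)
        cols["p1"] = f + 0.9 * u + 0.3 * r.standard_normal(n)
        Z = ai.standardize(pd.DataFrame(cols))
        defn, trace = ai.threshold_pca_index(Z)
        assert len(trace.iterations) == 1
        assert trace.iterations[0].dropped == []
        assert "initial 2-PC fit" in trace.iterations[0].note
        assert len(defn.variable_names) == 6

    def test_too_few_variables_rejected(self, rng):
        Z = ai.standardize(pd.DataFrame(rng.standard_normal((30, 3))))
        with pytest.raises(ValueError, match="at least"):
            ai.threshold_pca_index(Z)


class TestFirstPc:
    def test_rank_one_data_recovers_latent(self, rng):
        latent = rng.standard_normal(200)
        Z = ai.standardize(
            pd.DataFrame({f"v{i}": (i + 1) * latent for i in range(4)})
        )
        defn = ai.first_pc_index(Z)
        scores = ai.apply_index(defn, Z).iloc[:, 0]
        assert abs(np.corrcoef(scores, latent)[0, 1]) == pytest.approx(1.0, abs=1e-10)

    def test_score_variance_equals_leading_eigenvalue(self, standardized_matrix):
        sol = ai.fit_pca(standardized_matrix, 1)
        defn = ai.first_pc_index(standardized_matrix)
        scores = ai.apply_index(defn, standardized_matrix).iloc[:, 0]
        assert scores.var(ddof=1) == pytest.approx(sol.eigenvalues[0], abs=1e-8)


class TestSupervisedPca:
    def test_linear_kernel_closed_form(self, rng):
        Z = ai.standardize(pd.DataFrame(rng.standard_normal((60, 5)),
                                        columns=list("abcde")))
        y = rng.integers(0, 2, 60)
        defn = ai.supervised_pca_index(Z, y)
        yc = y - y.mean()
        v = Z.to_numpy().T @ yc / (len(y) - 1)
        v = v / np.linalg.norm(v)
        got = defn.loadings.iloc[:, 0].to_numpy()
        assert min(np.abs(got - v).max(), np.abs(got + v).max()) < 1e-10

    def test_informative_column_dominates(self, rng):
        n = 2000
        signal = rng.standard_normal(n)
        y = (signal + 0.5 * rng.standard_normal(n) > 0).astype(int)
        df = pd.DataFrame({"signal": signal})
        for i in range(4):
            df[f"junk{i}"] = rng.standard_normal(n)
        defn = ai.supervised_pca_index(ai.standardize(df), y)
        assert defn.loadings.iloc[:, 0].abs().idxmax() == "signal"

    def test_constant_outcome_rejected(self, standardized_matrix):
        with pytest.raises(ValueError, match="constant"):
            ai.supervised_pca_index(standardized_matrix, np.ones(len(standardized_matrix)))


class TestApplyIndex:
    def make_defn(self):
        return IndexDefinition(
            method="first_pc",
            variable_names=["a", "b", "c"],
            loadings=pd.DataFrame({"PC1": [0.5, 0.3, 0.2]}, index=["a", "b", "c"]),
        )

    def test_dot_product(self):
        Z = pd.DataFrame({"a": [2.0, 0.0], "b": [0.0, 0.0], "c": [5.0, 0.0]})
        scores = ai.apply_index(self.make_defn(), Z)
        assert scores.iloc[:, 0].tolist() == [2.0, 0.0]

    def test_linearity(self, rng):
        Z = pd.DataFrame(rng.standard_normal((10, 3)), columns=["a", "b", "c"])
        defn = self.make_defn()
        np.testing.assert_allclose(
            ai.apply_index(defn, 3.0 * Z), 3.0 * ai.apply_index(defn, Z), atol=1e-12
        )

    def test_column_mismatch_lists_variables(self):
        Z = pd.DataFrame({"a": [1.0], "d": [1.0]})
        with pytest.raises(ValueError) as err:
            ai.apply_index(self.make_defn(), Z)
        assert "'b'" in str(err.value) and "'d'" in str(err.value)


def test_all_methods_agree_on_rank_one_data(rng):
    """With a single latent factor driving both data and outcome, the three
    PCA constructions reduce to the same direction up to sign."""
    latent = rng.standard_normal(500)
    Z = ai.standardize(
        pd.DataFrame({f"v{i}": (1 + 0.5 * i) * latent for i in range(5)})
    )
    y = (latent > 0).astype(int)
    s1 = ai.apply_index(ai.first_pc_index(Z), Z).iloc[:, 0]
    s2 = ai.apply_index(ai.supervised_pca_index(Z, y), Z).iloc[:, 0]
    defn_t, _ = ai.threshold_pca_index(Z)
    st_ = ai.apply_index(defn_t, Z[defn_t.variable_names]).iloc[:, 0]
    for other in (s2, st_):
        assert abs(np.corrcoef(s1, other)[0, 1]) == pytest.approx(1.0, abs=1e-8)


def test_index_definition_yaml_round_trip(standardized_matrix):
    defn = ai.first_pc_index(standardized_matrix)
    clone = IndexDefinition.from_yaml(defn.to_yaml())
    before = ai.apply_index(defn, standardized_matrix)
    after = ai.apply_index(clone, standardized_matrix)
    assert (before.to_numpy() == after.to_numpy()).all()
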