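"""Autoscaling, PCA, UPGMA clustering and Tukey HSD."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hilipid.errors import DataError
from hilipid.stats_chemometrics import (
    autoscale,
    ellipses_disjoint,
    run_hca,
    run_pca,
    significance_stars,
    tukey_hsd,
)


def frame(array, prefix="s"):
    array = np.asarray(array, float)
    return pd.DataFrame(
        array,
        index=[f"{prefix}{i}" for i in range(array.shape[0])],
        columns=[f"v{j}" for j in range(array.shape[1])],
    )


class TestAutoscale:
    def test_z_scores_with_sample_sd(self):
        scaled = autoscale(frame([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(scaled["v0"], [-1.0, 0.0, 1.0])

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        scaled = autoscale(frame(rng.normal(size=(6, 4))))
        again = autoscale(scaled)
        np.testing.assert_allclose(again.to_numpy(), scaled.to_numpy(), atol=1e-12)

    def test_constant_column_dropped(self, caplog):
        import logging

        data = frame([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with caplog.at_level(logging.WARNING, logger="hilipid.stats_chemometrics"):
            scaled = autoscale(data)
        assert list(scaled.columns) == ["v0"]
        assert any("constant" in r.message for r in caplog.records)

    def test_too_few_rows_rejected(self):
        with pytest.raises(DataError):
            autoscale(frame([[1.0, 2.0]]))


class TestPca:
    def test_single_varying_column(self):
        data = autoscale(frame([[1.0, 3.0], [2.0, 3.0], [3.0, 3.0]]))
        result = run_pca(data)
        assert result.variance_fractions[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        result = run_pca(autoscale(frame(rng.normal(size=(8, 5)))))
        assert result.variance_fractions.sum() == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        """Scores/loadings of a 4x2 matrix equal a covariance eigen-solver's."""
        x = np.array([[2.0, 1.0], [0.5, 3.0], [-1.0, 0.0], [4.0, -2.0]])
        data = frame(x)
        result = run_pca(data)
        centered = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(centered.T @ centered)
        order = np.argsort(evals)[::-1]
        evecs = evecs[:, order]
        for k in range(2):
            ours = result.loadings[f"PC{k + 1}"].to_numpy()
            ref = evecs[:, k]
            if np.sign(ours[np.argmax(np.abs(ours))]) != np.sign(ref[np.argmax(np.abs(ref))]):
                ref = -ref
            np.testing.assert_allclose(ours, ref, atol=1e-10)
            np.testing.assert_allclose(
                result.scores[f"PC{k + 1}"].to_numpy(), centered @ ref, atol=1e-10)

    def test_reconstruction_with_all_components(self):
        rng = np.random.default_rng(2)
        data = autoscale(frame(rng.normal(size=(6, 4))))
        result = run_pca(data)
        recon = result.scores.to_numpy() @ result.loadings.to_numpy().T
        centered = data.to_numpy() - data.to_numpy().mean(axis=0)
        np.testing.assert_allclose(recon, centered, atol=1e-9)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(3)
        data = autoscale(frame(rng.normal(size=(7, 3))))
        result = run_pca(data)
        for name in result.loadings.columns:
            col = result.loadings[name].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_group_ellipses_and_disjointness(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 0.3, size=(5, 2)) + [0, 0]
        b = rng.normal(0, 0.3, size=(5, 2)) + [8, 0]
        data = frame(np.vstack([a, b]))
        groups = pd.Series(["A"] * 5 + ["B"] * 5, index=data.index)
        result = run_pca(data, groups=groups)
        assert set(result.ellipses) == {"A", "B"}
        assert ellipses_disjoint(result.ellipses["A"], result.ellipses["B"])

    def test_overlapping_groups_not_disjoint(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1.0, size=(6, 2))
        b = rng.normal(0.2, 1.0, size=(6, 2))
        data = frame(np.vstack([a, b]))
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=data.index)
        result = run_pca(data, groups=groups)
        assert not ellipses_disjoint(result.ellipses["A"], result.ellipses["B"])


class TestHca:
    def test_identical_samples_merge_at_zero(self):
        data = frame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        result = run_hca(data)
        assert result.linkage[0, 2] == pytest.approx(0.0)

    def test_average_linkage_arithmetic(self):
        """d(A,B)=1, d(A,C)=d(B,C)=2: AB merge at 1, C joins at (2+2)/2."""
        data = frame([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(4 - 0.25)]])
        result = run_hca(data)
        assert result.linkage[0, 2] == pytest.approx(1.0)
        assert result.linkage[1, 2] == pytest.approx(2.0)

    def test_cophenetic_is_ultrametric(self):
        rng = np.random.default_rng(6)
        result = run_hca(frame(rng.normal(size=(6, 4))))
        c = result.cophenetic.to_numpy()
        n = c.shape[0]
        for i, j, k in itertools.permutations(range(n), 3):
            assert c[i, j] <= max(c[i, k], c[j, k]) + 1e-12

    def test_variable_axis_clusters_columns(self):
        rng = np.random.default_rng(7)
        data = frame(rng.normal(size=(5, 3)))
        result = run_hca(data, axis="variables")
        assert sorted(result.labels) == ["v0", "v1", "v2"]

    def test_newick_renders_all_leaves(self):
        rng = np.random.default_rng(8)
        data = frame(rng.normal(size=(5, 3)))
        text = run_hca(data).newick()
        assert text.endswith(";")
        for label in data.index:
            assert label in text

    def test_cut_returns_requested_cluster_count(self):
        rng = np.random.default_rng(9)
        data = frame(np.vstack([rng.normal(0, 0.1, (3, 2)),
                                rng.normal(5, 0.1, (3, 2))]))
        cut = run_hca(data).cut(2)
        assert cut.nunique() == 2


class TestTukeyHsd:
    def test_identical_groups_not_significant(self):
        out = tukey_hsd({"a": [1, 1, 1.01], "b": [1, 1.01, 1], "c": [1.01, 1, 1]})
        assert (out["p_value"] > 0.9).all()
        assert (out["stars"] == "").all()

    def test_extreme_separation_heavily_starred(self):
        out = tukey_hsd({"a": [0, 0, 0], "b": [0, 0, 0], "c": [10, 10, 10.0001]})
        starred = out[(out["group_a"] == "c") | (out["group_b"] == "c")]
        assert (starred["stars"] == "***").all()
        flat = out[(out["group_a"] == "a") & (out["group_b"] == "b")]
        assert (flat["stars"] == "").all()

    def test_matches_reference_implementation(self):
        """Three shifted triplets: p-values agree with statsmodels to 3 s.f."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        groups = {"g1": [1.1, 1.2, 1.3], "g2": [2.1, 2.2, 2.3], "g3": [3.1, 3.2, 3.3]}
        ours = tukey_hsd(groups)
        values = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), 3)
        ref = pairwise_tukeyhsd(values, labels)
        ref_p = {frozenset(pair): p for pair, p in
                 zip(itertools.combinations(groups, 2), ref.pvalues)}
        for _, row in ours.iterrows():
            expected = ref_p[frozenset((row["group_a"], row["group_b"]))]
            assert row["p_value"] == pytest.approx(expected, rel=1e-3, abs=1e-6)

    def test_zero_variance_guard(self):
        out = tukey_hsd({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert (out["p_value"] < 1e-10).all()

    def test_group_size_validation(self):
        with pytest.raises(DataError):
            tukey_hsd({"a": [1.0], "b": [1.0, 2.0]})


def test_significance_star_thresholds():
    assert significance_stars(0.02) == ""
    assert significance_stars(0.009) == "*"
    assert significance_stars(0.004) == "**"
    assert significance_stars(0.0009) == "***"
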