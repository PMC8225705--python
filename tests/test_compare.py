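"""Presence matrices, Jaccard, PCA, factor-variance attribution, t-SNE."""

import itertools

import numpy as np
import pandas as pd
import pytest

import contextgem as cg
from contextgem.model import build_model


@pytest.fixture
def four_reaction_reference():
    return build_model([(f"r{i}", {}, 0.0, 1.0) for i in range(1, 5)])


class TestPresenceMatrix:
    def test_constant_rows_filtered_and_centered(self, four_reaction_reference):
        sets = {"m1": {"r1", "r2"}, "m2": {"r1", "r3"},
                "m3": {"r1", "r2", "r3"}}
        pm = cg.presence_matrix(sets, four_reaction_reference)
        # r1 present everywhere, r4 absent everywhere → filtered
        assert set(pm.filtered_reactions) == {"r1", "r4"}
        assert pm.reaction_ids == ["r2", "r3"]
        assert np.allclose(pm.matrix.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(pm.matrix.sum(axis=1), 0.0, atol=1e-12)

    def test_identical_models_leave_nothing(self, four_reaction_reference):
        sets = {"m1": {"r1"}, "m2": {"r1"}}
        pm = cg.presence_matrix(sets, four_reaction_reference)
        assert pm.matrix.empty and set(pm.filtered_reactions) == \
            {"r1", "r2", "r3", "r4"}

    def test_mismatched_reference_rejected(self, four_reaction_reference):
        sets = {"m1": {"r1"}, "m2": {"r9"}}
        with pytest.raises(ValueError, match="r9"):
            cg.presence_matrix(sets, four_reaction_reference)

    def test_needs_two_models(self, four_reaction_reference):
        with pytest.raises(ValueError, match="2 models"):
            cg.presence_matrix({"m1": {"r1"}}, four_reaction_reference)


class TestJaccard:
    def test_identity_disjoint_and_half(self):
        sets = {"a": {"r1", "r2", "r3"}, "b": {"r2", "r3", "r4"},
                "c": {"r9"}}
        jac = cg.jaccard_matrix(sets)
        assert jac.loc["a", "a"] == 1.0
        assert jac.loc["a", "b"] == pytest.approx(0.5)  # |∩|=2, |∪|=4
        assert jac.loc["a", "c"] == 0.0

    def test_empty_sets_identical(self, caplog):
        jac = cg.jaccard_matrix({"a": set(), "b": set()})
        assert jac.loc["a", "b"] == 1.0

    def test_matrix_properties(self):
        rng = np.random.default_rng(0)
        universe = [f"r{i}" for i in range(12)]
        sets = {f"m{k}": set(rng.choice(universe, rng.integers(0, 12),
                                        replace=False))
                for k in range(5)}
        jac = cg.jaccard_matrix(sets)
        assert np.allclose(jac, jac.T)
        assert np.allclose(np.diag(jac), 1.0)
        assert ((jac >= 0) & (jac <= 1)).all().all()
        dist = cg.jaccard_matrix(sets, distance=True)
        assert np.allclose(dist, 1.0 - jac)


class TestPCA:
    def test_two_models_rank_one(self, four_reaction_reference):
        pm = cg.presence_matrix({"m1": {"r1"}, "m2": {"r2"}},
                                four_reaction_reference)
        _, fractions = cg.pca_reactions(pm)
        assert fractions[0] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self, four_reaction_reference):
        sets = {"m1": {"r1", "r2"}, "m2": {"r1", "r3"},
                "m3": {"r2", "r4"}, "m4": {"r3", "r4"}}
        pm = cg.presence_matrix(sets, four_reaction_reference)
        _, fractions = cg.pca_reactions(pm)
        assert fractions.sum() == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self, four_reaction_reference):
        sets = {"m1": {"r1", "r2"}, "m2": {"r1", "r3"},
                "m3": {"r2", "r4"}, "m4": {"r3", "r4"}}
        pm = cg.presence_matrix(sets, four_reaction_reference)
        _, fractions = cg.pca_reactions(pm)
        X = pm.matrix.to_numpy()
        eigvals = np.linalg.eigvalsh(X @ X.T)[::-1]
        eigvals = eigvals[eigvals > 1e-12]
        expected = eigvals / eigvals.sum()
        assert np.allclose(np.sort(fractions[fractions > 1e-12])[::-1],
                           expected)

    def test_empty_matrix_errors(self, four_reaction_reference):
        pm = cg.presence_matrix({"m1": {"r1"}, "m2": {"r1"}},
                                four_reaction_reference)
        with pytest.raises(ValueError, match="empty"):
            cg.pca_reactions(pm)


class TestVarianceByFactor:
    def test_perfect_separation_is_100(self):
        assert cg.variance_by_factor([1, 1, 2, 2], ["a", "a", "b", "b"]) == \
            pytest.approx(100.0)

    def test_binary_factor_invariant_to_level_order(self):
        scores = [0.3, 1.1, 0.2, 2.0]
        one = cg.variance_by_factor(scores, ["a", "a", "b", "b"])
        other = cg.variance_by_factor(scores, ["b", "b", "a", "a"])
        assert one == pytest.approx(other)

    def test_three_levels_match_exhaustive_orderings(self):
        scores = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = ["x", "y", "z", "x", "y", "z"]
        result = cg.variance_by_factor(scores, labels)
        best = 0.0
        for order in itertools.permutations([1, 2, 3]):
            enc = np.array([order["xyz".index(l)] for l in labels], float)
            r = np.corrcoef(enc, scores)[0, 1]
            best = max(best, r ** 2)
        assert result == pytest.approx(100.0 * best)
        assert result == pytest.approx(100.0)  # exact affine encoding exists

    def test_constant_inputs_warn_and_return_zero(self):
        with pytest.warns(UserWarning):
            assert cg.variance_by_factor([1.0, 1.0, 1.0],
                                         ["a", "b", "a"]) == 0.0
        with pytest.warns(UserWarning):
            assert cg.variance_by_factor([1.0, 2.0, 3.0],
                                         ["a", "a", "a"]) == 0.0

    def test_bounded_in_0_100(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            scores = rng.normal(size=9)
            labels = rng.choice(list("abc"), size=9)
            if len(set(labels)) < 2:
                continue
            v = cg.variance_by_factor(scores, labels)
            assert 0.0 <= v <= 100.0

    def test_planted_block_beats_random_factor(self, four_reaction_reference):
        """A factor that drives a presence block explains more PC1 variance
        than a random relabelling, for most seeds."""
        rng = np.random.default_rng(0)
        wins = 0
        n_models, block = 12, 6
        universe = [f"r{i}" for i in range(1, 5)]
        reference = build_model([(f"r{i}", {}, 0.0, 1.0)
                                 for i in range(block + 6)])
        for trial in range(10):
            planted = np.array(["A"] * 6 + ["B"] * 6)
            sets = {}
            for m in range(n_models):
                kept = {f"r{i}" for i in range(block)
                        if planted[m] == "B"}
                kept |= {f"r{block + i}" for i in range(6)
                         if rng.random() < 0.5}
                sets[f"m{m}"] = kept
            pm = cg.presence_matrix(sets, reference)
            scores, _ = cg.pca_reactions(pm)
            v_planted = cg.variance_by_factor(scores["PC1"], planted)
            v_random = cg.variance_by_factor(scores["PC1"],
                                             rng.permutation(planted))
            wins += v_planted > v_random
        assert wins >= 9


class TestTsne:
    def _pm(self, n):
        rng = np.random.default_rng(1)
        reference = build_model([(f"r{i}", {}, 0.0, 1.0) for i in range(30)])
        sets = {f"m{k}": {f"r{i}" for i in range(30) if rng.random() < 0.5}
                for k in range(n)}
        return cg.presence_matrix(sets, reference)

    def test_shape_and_determinism(self):
        pm = self._pm(20)
        one = cg.tsne_embed(pm, perplexity=15, seed=7)
        two = cg.tsne_embed(pm, perplexity=15, seed=7)
        assert one.shape == (20, 2)
        assert np.array_equal(one.to_numpy(), two.to_numpy())

    def test_perplexity_must_be_below_n(self):
        pm = self._pm(20)
        with pytest.raises(ValueError, match="perplexity"):
            cg.tsne_embed(pm, perplexity=25)
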