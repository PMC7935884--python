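"""Differential-expression filters, BH correction, correlation, overlaps."""

import itertools

import numpy as np
import pandas as pd
import pytest

from wormtrauma.errors import DataError
from wormtrauma.transcriptomics import (
    age_response_trend,
    benjamini_hochberg,
    cross_correlate,
    differential_expression,
    overlap_sets,
    screen_candidate_filter,
    zscore_normalize,
)


def _bh_stepup(p):
    """Independent step-up oracle for Benjamini-Hochberg q-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


def _bh_from_package(p):
    return benjamini_hochberg(p)


class TestDifferentialExpression:
    def _planted_matrix(self, rng, n_genes=20, n_shifted=4, fold=4.0):
        base = rng.lognormal(np.log(100.0), 0.05, size=(n_genes, 6))
        genes = [f"g{i:02d}" for i in range(n_genes)]
        expr = pd.DataFrame(base, index=genes, columns=[f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)])
        shifted = genes[:n_shifted]
        expr.loc[shifted, ["a0", "a1", "a2"]] *= fold
        return expr, shifted

    def test_identical_groups_yield_no_significant_genes(self, rng):
        expr, _ = self._planted_matrix(rng, n_shifted=0)
        de = differential_expression(expr, ["a0", "a1", "a2"], ["b0", "b1", "b2"])
        assert not de["significant"].any()

    @pytest.mark.parametrize("fdr", [False, True])
    def test_exactly_the_planted_genes_are_significant(self, rng, fdr):
        expr, shifted = self._planted_matrix(rng)
        de = differential_expression(
            expr, ["a0", "a1", "a2"], ["b0", "b1", "b2"], fdr=fdr
        )
        assert sorted(de.index[de["significant"]]) == sorted(shifted)
        assert (de.loc[shifted, "direction"] == "up").all()

    def test_zero_variance_gene_gets_p_one(self):
        expr = pd.DataFrame(
            {"a0": [5.0], "a1": [5.0], "b0": [5.0], "b1": [5.0]}, index=["flat"]
        )
        de = differential_expression(expr, ["a0", "a1"], ["b0", "b1"])
        assert de.loc["flat", "p"] == 1.0

    def test_significance_is_monotone_in_thresholds(self, rng):
        expr = pd.DataFrame(
            rng.lognormal(np.log(50.0), 0.6, size=(60, 6)),
            index=[f"g{i}" for i in range(60)],
            columns=["a0", "a1", "a2", "b0", "b1", "b2"],
        )
        strict = differential_expression(expr, ["a0", "a1", "a2"], ["b0", "b1", "b2"],
                                         fc_threshold=2.0, p_threshold=0.05)
        loose = differential_expression(expr, ["a0", "a1", "a2"], ["b0", "b1", "b2"],
                                        fc_threshold=1.5, p_threshold=0.20)
        assert set(strict.index[strict["significant"]]) <= set(loose.index[loose["significant"]])

    def test_fold_change_exactly_at_threshold_is_significant(self):
        # group means exactly 2-fold apart: the >= threshold is inclusive
        expr = pd.DataFrame(
            [[200.0, 199.0, 201.0, 100.0, 100.0, 100.0]],
            index=["edge"],
            columns=["a0", "a1", "a2", "b0", "b1", "b2"],
        )
        de = differential_expression(expr, ["a0", "a1", "a2"], ["b0", "b1", "b2"])
        assert de.loc["edge", "log2fc"] == pytest.approx(1.0, abs=1e-12)
        assert bool(de.loc["edge", "significant"])

    def test_small_group_rejected(self):
        expr = pd.DataFrame(np.ones((3, 3)), columns=["a0", "b0", "b1"])
        with pytest.raises(DataError):
            differential_expression(expr, ["a0"], ["b0", "b1"])


class TestBenjaminiHochberg:
    def test_hand_computed_example(self):
        q = _bh_from_package([0.01, 0.02, 0.03, 0.5])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_matches_stepup_oracle_exhaustively_on_sorted_grid(self):
        """All nondecreasing p-vectors of length <= 5 on a 0.1 grid (BH is
        permutation-equivariant, so sorted vectors cover all cases)."""
        grid = np.round(np.arange(0.0, 1.01, 0.1), 10)
        for k in range(1, 6):
            for combo in itertools.combinations_with_replacement(grid, k):
                np.testing.assert_allclose(
                    _bh_from_package(list(combo)), _bh_stepup(list(combo)), atol=1e-12
                )

    def test_matches_stepup_oracle_on_random_fine_grid_vectors(self, rng):
        for _ in range(300):
            p = rng.integers(0, 101, size=rng.integers(1, 6)) / 100.0
            np.testing.assert_allclose(_bh_from_package(p), _bh_stepup(p), atol=1e-12)

    def test_permutation_equivariance(self, rng):
        p = np.array([0.03, 0.8, 0.001, 0.2, 0.05])
        q = _bh_from_package(p)
        perm = rng.permutation(5)
        np.testing.assert_allclose(_bh_from_package(p[perm]), q[perm], atol=1e-12)


class TestZscoreNormalize:
    def test_hand_arithmetic_with_n_minus_one_convention(self):
        np.testing.assert_allclose(zscore_normalize([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_constant_vector_rejected(self):
        with pytest.raises(DataError, match="constant"):
            zscore_normalize([2.0, 2.0, 2.0])

    def test_nan_positions_preserved_and_symmetric(self):
        out = zscore_normalize([1.0, np.nan, 3.0])
        assert np.isnan(out[1])
        assert out[0] == pytest.approx(-out[2])


class TestCrossCorrelate:
    def _matrix(self, rng, n=200):
        x = rng.normal(size=n)
        return pd.DataFrame(
            {"self": x, "copy": x.copy(), "neg": -x, "noise": rng.normal(size=n)},
            index=[f"g{i}" for i in range(n)],
        )

    def test_dataset_against_itself_and_negation(self, rng):
        m = self._matrix(rng)
        cm = cross_correlate(m, m.index)
        assert cm.r.loc["self", "copy"] == pytest.approx(1.0)
        assert cm.r.loc["self", "neg"] == pytest.approx(-1.0)

    def test_matches_brute_force_complete_case_pearson(self, rng):
        m = self._matrix(rng, n=300)
        mask = rng.random(m.shape) < 0.1
        m = m.mask(mask)
        cm = cross_correlate(m, m.index)
        complete = m.dropna(axis=0, how="any")
        assert cm.n_genes_used == len(complete)
        oracle = np.corrcoef(complete.to_numpy(), rowvar=False)
        np.testing.assert_allclose(cm.r.to_numpy(), oracle, atol=1e-12)

    def test_invariant_to_positive_affine_rescaling_of_one_dataset(self, rng):
        m = self._matrix(rng)
        scaled = m.copy()
        scaled["noise"] = 3.7 * scaled["noise"] + 11.0
        a = cross_correlate(m, m.index).r.to_numpy()
        b = cross_correlate(scaled, m.index).r.to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_restricts_to_reference_set(self, rng):
        m = self._matrix(rng)
        subset = list(m.index[:50])
        cm = cross_correlate(m, subset)
        assert cm.n_genes_used == 50

    def test_too_few_complete_cases_rejected(self):
        m = pd.DataFrame(
            {"a": [1.0, np.nan, 2.0, 4.0], "b": [np.nan, 1.0, 2.0, 5.0]},
            index=list("wxyz"),
        )
        with pytest.raises(DataError, match="complete"):
            cross_correlate(m, m.index)

    def test_symmetric_unit_diagonal(self, rng):
        cm = cross_correlate(self._matrix(rng), [f"g{i}" for i in range(200)])
        r = cm.r.to_numpy()
        np.testing.assert_allclose(r, r.T, atol=1e-14)
        np.testing.assert_allclose(np.diag(r), 1.0)
        assert (np.abs(r) <= 1 + 1e-12).all()


class TestOverlapSets:
    def test_identical_sets(self):
        out = overlap_sets(["a", "b"], ["a", "b"])
        assert (out["a_only"], out["shared"], out["b_only"]) == (0, 2, 0)

    def test_disjoint_sets(self):
        out = overlap_sets(["a"], ["b"])
        assert out["shared"] == 0 and out["a_only"] == 1 and out["b_only"] == 1

    def test_partial_overlap_counts(self):
        a = [f"g{i}" for i in range(1, 11)]
        b = [f"g{i}" for i in range(6, 16)]
        out = overlap_sets(a, b)
        assert (out["a_only"], out["shared"], out["b_only"]) == (5, 5, 5)
        assert out["a_only"] + out["shared"] + out["b_only"] == len(set(a) | set(b))


class TestAgeResponseTrend:
    def test_identical_vectors(self):
        fc = np.full(10, 4.0)
        out = age_response_trend(fc, fc)
        assert out["mean_diff"] == 0.0 and out["p"] == 1.0

    def test_planted_uniform_attenuation(self, rng):
        l1 = rng.normal(3.0, 0.1, size=100)
        l4 = l1 - 1.0 + rng.normal(0, 0.1, size=100)
        out = age_response_trend(l1, l4, data_kind="log2")
        assert out["mean_diff"] == pytest.approx(1.0, abs=0.05)
        assert out["p"] < 1e-10
        assert out["n_above_threshold_both"] == 100  # all stay above 2-fold

    def test_swapping_days_flips_the_difference(self, rng):
        d1 = rng.lognormal(1.0, 0.3, size=20)
        d4 = rng.lognormal(0.5, 0.3, size=20)
        fwd = age_response_trend(d1, d4)
        rev = age_response_trend(d4, d1)
        assert fwd["mean_diff"] == pytest.approx(-rev["mean_diff"])


class TestScreenCandidateFilter:
    @staticmethod
    def _de(genes, significant):
        return pd.DataFrame(
            {"log2fc": 2.0, "p": 0.01, "q": 0.02, "significant": significant},
            index=genes,
        )

    def test_all_flags_true_returns_every_significant_gene(self):
        genes = [f"g{i}" for i in range(10)]
        de = self._de(genes, [True] * 10)
        ann = pd.DataFrame(
            {"expression_level": 2.0, "neuronal": True, "homolog": True, "rnai_available": True},
            index=genes,
        )
        assert screen_candidate_filter(de, ann) == genes

    def test_no_rnai_clones_means_no_candidates(self):
        genes = ["g1", "g2"]
        de = self._de(genes, [True, True])
        ann = pd.DataFrame(
            {"expression_level": 2.0, "neuronal": True, "homolog": True, "rnai_available": False},
            index=genes,
        )
        assert screen_candidate_filter(de, ann) == []

    def test_funnel_sizes_on_constructed_cohort(self):
        """120 significant genes; 89 pass the expression/neuronal/homolog
        criteria and 51 of those also have an RNAi clone."""
        genes = [f"g{i:03d}" for i in range(120)]
        de = self._de(genes, [True] * 120)
        ann = pd.DataFrame(
            {
                "expression_level": [2.0 if i < 89 else 0.5 for i in range(120)],
                "neuronal": True,
                "homolog": True,
                "rnai_available": [i < 51 for i in range(120)],
            },
            index=genes,
        )
        assert len(screen_candidate_filter(de, ann, require_rnai=False)) == 89
        assert len(screen_candidate_filter(de, ann, require_rnai=True)) == 51

    def test_genes_missing_annotations_fail_closed(self):
        de = self._de(["known", "unknown"], [True, True])
        ann = pd.DataFrame(
            {"expression_level": [2.0], "neuronal": [True], "homolog": [True],
             "rnai_available": [True]},
            index=["known"],
        )
        assert screen_candidate_filter(de, ann) == ["known"]
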