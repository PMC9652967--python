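import math

import numpy as np
import pandas as pd
import pytest

from brcaness import GeneSet, GsvaParams, enrichment_walk, gsva_scores, kernel_cdf_transform, rank_weights
from oracles import oracle_gsva, oracle_kcdf


class TestKernelCdf:
    def test_ecdf_is_rank_fraction(self, matrix_factory):
        m = matrix_factory([[1.0, 2.0, 3.0]])
        z = kernel_cdf_transform(m, kcdf="ecdf")
        assert z.iloc[0].tolist() == pytest.approx([1 / 3, 2 / 3, 1.0])

    def test_gaussian_symmetric_center_is_half(self, matrix_factory):
        # values symmetric about 5; by symmetry of Phi the central sample gets 0.5
        m = matrix_factory([[3.0, 5.0, 7.0]])
        z = kernel_cdf_transform(m, kcdf="gaussian")
        assert z.iloc[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_gaussian_matches_term_by_term_summation(self, matrix_factory):
        row = [0.0, 1.0, 2.0, 3.0]
        z = kernel_cdf_transform(matrix_factory([row]), kcdf="gaussian")
        expected = oracle_kcdf([row], "gaussian")[0]
        assert z.iloc[0].tolist() == pytest.approx(expected, abs=1e-12)

    def test_single_sample_rejected(self, matrix_factory):
        with pytest.raises(ValueError, match="2 samples"):
            kernel_cdf_transform(matrix_factory([[1.0]]), kcdf="ecdf")

    def test_zero_variance_genes_dropped_with_warning(self, matrix_factory, caplog):
        m = matrix_factory([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        with caplog.at_level("WARNING"):
            z = kernel_cdf_transform(m, kcdf="gaussian")
        assert list(z.index) == ["g0"]
        assert "zero-variance" in caplog.text

    def test_all_zero_variance_is_error(self, matrix_factory):
        with pytest.raises(ValueError, match="zero variance"):
            kernel_cdf_transform(matrix_factory([[1.0, 1.0], [2.0, 2.0]]), kcdf="gaussian")


class TestRankWeights:
    @pytest.mark.parametrize(
        "p,expected",
        [(4, [1.0, 0.0, 1.0, 2.0]), (5, [1.5, 0.5, 0.5, 1.5, 2.5])],
    )
    def test_symmetric_weights(self, p, expected):
        _, w = rank_weights(np.linspace(1, 0, p))
        assert w.tolist() == expected

    def test_ordering_descending_with_index_tie_break(self):
        ordering, _ = rank_weights(np.array([0.5, 0.9, 0.5, 0.1]))
        assert ordering.tolist() == [1, 0, 2, 3]

    def test_tied_ordering_stable_under_permutation(self):
        # permuting the input permutes the ordering consistently: the gene with
        # the lower original index still precedes its tie partner
        z = np.array([0.3, 0.3, 0.8])
        o1, _ = rank_weights(z)
        assert o1.tolist() == [2, 0, 1]


class TestEnrichmentWalk:
    def test_set_at_top_walks_to_plus_one(self):
        ordering = np.array([0, 1, 2, 3])
        _, w = rank_weights(np.linspace(1, 0, 4))
        member = np.array([True, False, False, False])
        es = enrichment_walk(ordering, w, member, es_mode="max_deviation")
        assert es == pytest.approx(1.0)

    def test_set_at_bottom_walks_to_minus_one(self):
        ordering = np.array([0, 1, 2, 3])
        _, w = rank_weights(np.linspace(1, 0, 4))
        member = np.array([False, False, False, True])
        es = enrichment_walk(ordering, w, member, es_mode="max_deviation")
        assert es == pytest.approx(-1.0)

    def test_walk_vector_hand_enumeration(self):
        # set gene at rank 1 of 4: nu = [1, 2/3, 1/3, 0]; mirrored at rank 4:
        # nu = [-1/3, -2/3, -1, 0] (antisymmetric complement)
        _, w = rank_weights(np.linspace(1, 0, 4))
        up = enrichment_walk(np.arange(4), w, np.array([True, False, False, False]))
        down = enrichment_walk(np.arange(4), w, np.array([False, False, False, True]))
        assert up == pytest.approx(1.0)
        assert down == pytest.approx(-1.0)

    def test_degenerate_sets_rejected(self):
        _, w = rank_weights(np.linspace(1, 0, 4))
        with pytest.raises(ValueError):
            enrichment_walk(np.arange(4), w, np.ones(4, dtype=bool))
        with pytest.raises(ValueError):
            enrichment_walk(np.arange(4), w, np.zeros(4, dtype=bool))

    def test_es_bounded_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            p = rng.integers(3, 25)
            m = rng.integers(1, p)
            member = np.zeros(p, dtype=bool)
            member[rng.choice(p, size=m, replace=False)] = True
            z = rng.random(p)
            ordering, w = rank_weights(z)
            tau = rng.choice([0.0, 0.5, 1.0, 2.0])
            for mode in ("mx_diff", "max_deviation"):
                try:
                    es = enrichment_walk(ordering, w, member, tau=tau, es_mode=mode)
                except ValueError:
                    # defined degenerate case: a singleton set whose gene sits
                    # at the zero-weight middle rank
                    assert member.sum() == 1
                    continue
                assert -1.0 <= es <= 1.0


class TestGsvaScores:
    def test_set_topping_one_sample_scores_it_highest(self, matrix_factory):
        # two set genes are the strongest in sample 0 only
        vals = np.full((6, 4), 5.0) + np.random.default_rng(2).normal(0, 0.1, (6, 4))
        vals[0, 0] += 4.0
        vals[1, 0] += 4.0
        m = matrix_factory(vals)
        scores = gsva_scores(m, GeneSet("S", "d", ("g0", "g1")),
                             GsvaParams(min_set_genes_present=2))
        assert scores["S"].idxmax() == "s0"

    def test_sample_permutation_equivariance(self, random_log2_matrix, matrix_factory):
        m = random_log2_matrix
        s = GeneSet("S", "d", tuple(m.gene_ids[:6]))
        base = gsva_scores(m, s)
        perm = list(reversed(m.sample_ids))
        m2 = matrix_factory(m.values[perm].to_numpy(), genes=m.gene_ids, samples=perm)
        again = gsva_scores(m2, s)
        assert np.allclose(base["S"].loc[perm].to_numpy(), again["S"].to_numpy())

    def test_ecdf_invariant_to_monotone_transform_of_one_gene(self, random_log2_matrix, matrix_factory):
        m = random_log2_matrix
        s = GeneSet("S", "d", tuple(m.gene_ids[:6]))
        p = GsvaParams(kcdf="ecdf")
        base = gsva_scores(m, s, p)
        vals = m.values.to_numpy().copy()
        vals[3] = np.exp(vals[3] / 2.0)  # strictly increasing transform
        again = gsva_scores(matrix_factory(vals, genes=m.gene_ids, samples=m.sample_ids), s, p)
        assert np.allclose(base.to_numpy(), again.to_numpy())

    def test_missing_set_genes_dropped_and_small_sets_rejected(self, random_log2_matrix):
        m = random_log2_matrix
        s = GeneSet("S", "d", (*m.gene_ids[:5], "NOT_A_GENE"))
        scores = gsva_scores(m, s, GsvaParams(min_set_genes_present=5))
        assert scores.shape == (12, 1)
        with pytest.raises(ValueError, match="'S'"):
            gsva_scores(m, s, GsvaParams(min_set_genes_present=6))

    def test_gaussian_requires_log2_scale(self, matrix_factory):
        m = matrix_factory(np.random.default_rng(1).gamma(2, 10, (8, 5)), scale="tpm")
        with pytest.raises(ValueError, match="log2"):
            gsva_scores(m, GeneSet("S", "d", ("g0", "g1", "g2", "g3", "g4")))

    def test_case_insensitive_gene_matching(self, random_log2_matrix):
        m = random_log2_matrix
        upper = GeneSet("S", "d", tuple(g.upper() for g in m.gene_ids[:6]))
        lower = GeneSet("S", "d", tuple(m.gene_ids[:6]))
        assert gsva_scores(m, upper).equals(gsva_scores(m, lower))

    def test_constant_gene_does_not_change_other_scores(self, matrix_factory):
        rng = np.random.default_rng(5)
        vals = rng.normal(6, 1, (10, 6))
        m = matrix_factory(vals)
        s = GeneSet("S", "d", tuple(f"g{i}" for i in range(5)))
        base = gsva_scores(m, s)
        with_const = matrix_factory(
            np.vstack([vals, np.full((1, 6), 3.0)]),
            genes=[f"g{i}" for i in range(10)] + ["flat"],
        )
        again = gsva_scores(with_const, s)  # flat gene dropped under gaussian
        assert np.allclose(base.to_numpy(), again.to_numpy())

    def test_matches_brute_force_oracle_small(self, matrix_factory):
        rng = np.random.default_rng(23)
        for kcdf, tol in (("ecdf", 1e-12), ("gaussian", 1e-9)):
            vals = rng.normal(5, 2, (7, 5))
            genes = [f"g{i}" for i in range(7)]
            samples = [f"s{j}" for j in range(5)]
            m = matrix_factory(vals, genes=genes, samples=samples)
            set_genes = ("g1", "g4", "g6")
            mine = gsva_scores(m, GeneSet("S", "d", set_genes),
                               GsvaParams(kcdf=kcdf, min_set_genes_present=2))
            ref = oracle_gsva(vals.tolist(), genes, samples, set_genes, kcdf=kcdf)
            for s in samples:
                assert mine.loc[s, "S"] == pytest.approx(ref[s], abs=tol)
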