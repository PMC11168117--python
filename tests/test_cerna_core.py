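import math
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from cernet.cerna_core import (
    CorrEdge,
    assemble_triplets,
    candidate_pairs,
    pearson_r,
    sponge_pvalue,
    spearman_rho,
)


def textbook_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    dx, dy = x - x.mean(), y - y.mean()
    return float(np.sum(dx * dy) / math.sqrt(np.sum(dx**2) * np.sum(dy**2)))


def textbook_spearman(x, y):
    rank = lambda v: pd.Series(v).rank(method="average").values
    return textbook_pearson(rank(x), rank(y))


def exact_upper_tail(x, M, N, U):
    """Exhaustive-enumeration hypergeometric tail as an exact rational."""
    total = Fraction(0)
    for k in range(x, min(M, N) + 1):
        if k <= M and N - k <= U - M and N - k >= 0:
            total += Fraction(comb(M, k) * comb(U - M, N - k), comb(U, N))
    return total


class TestSpearman:
    def test_perfect_antitone(self):
        assert spearman_rho([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_perfect_monotone(self):
        assert spearman_rho([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_tied_ranks_hand_value(self):
        # ranks of x: [1.5, 1.5, 3]; Pearson of ranks = 1.5 / sqrt(3)
        assert spearman_rho([1, 1, 2], [1, 2, 3]) == pytest.approx(1.5 / math.sqrt(3))

    def test_zero_variance_is_nan(self):
        assert math.isnan(spearman_rho([2, 2, 2], [1, 2, 3]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3], [1, 2])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [3, 4])

    def test_random_vectors_match_textbook_formula(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            x, y = rng.normal(size=(2, 25))
            assert abs(spearman_rho(x, y) - textbook_spearman(x, y)) < 1e-12

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 15))
        assert spearman_rho(np.exp(x), y) == pytest.approx(spearman_rho(x, y))
        assert spearman_rho(x, y**3) == pytest.approx(spearman_rho(x, y))


class TestPearson:
    def test_affine_invariance(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)

    def test_negation(self):
        x = np.array([1.0, 5.0, 2.0, 8.0])
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_random_vectors_match_textbook_formula(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            x, y = rng.normal(size=(2, 25))
            assert abs(pearson_r(x, y) - textbook_pearson(x, y)) < 1e-12


class TestSpongePvalue:
    def test_zero_overlap_is_certain(self):
        assert sponge_pvalue(0, 3, 4, 10) == 1.0

    def test_minimal_exact_case(self):
        assert sponge_pvalue(1, 1, 1, 2) == pytest.approx(0.5)

    def test_hand_enumerated_case(self):
        assert sponge_pvalue(3, 4, 5, 10) == pytest.approx(66 / 252)

    def test_full_sweep_small_universe_matches_exact_enumeration(self):
        for U in range(1, 13):
            for M in range(U + 1):
                for N in range(U + 1):
                    for x in range(min(M, N) + 1):
                        expected = float(exact_upper_tail(x, M, N, U))
                        assert sponge_pvalue(x, M, N, U) == pytest.approx(
                            expected, abs=1e-12
                        )

    def test_matches_scipy_survival_function(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            U = int(rng.integers(2, 500))
            M = int(rng.integers(0, U + 1))
            N = int(rng.integers(0, U + 1))
            x = int(rng.integers(0, min(M, N) + 1))
            assert sponge_pvalue(x, M, N, U) == pytest.approx(
                float(hypergeom.sf(x - 1, U, M, N)), rel=1e-9, abs=1e-12
            )

    def test_non_increasing_in_overlap(self):
        values = [sponge_pvalue(x, 8, 9, 30) for x in range(9)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize(
        "args",
        [(4, 3, 5, 10), (1, 11, 5, 10), (1, 5, 11, 10), (-1, 3, 5, 10)],
    )
    def test_inadmissible_arguments_rejected(self, args):
        with pytest.raises(ValueError):
            sponge_pvalue(*args)


def _frame(data, samples):
    return pd.DataFrame(data, columns=samples)


class TestFilters:
    def test_threshold_is_strict(self):
        from cernet.target_prediction import TargetMap

        samples = [f"s{i}" for i in range(5)]
        x = np.arange(5.0)
        # permutation [4,3,0,2,1] of ranks 0..4 has sum d^2 = 34, hence
        # Spearman rho = 1 - 6*34/120 = -0.7 exactly
        y_exact = np.array([4, 3, 0, 2, 1], float)
        assert spearman_rho(x, y_exact) == pytest.approx(-0.7, abs=1e-12)
        expr = pd.DataFrame(
            {"mir": x, "t_exact": y_exact, "t_below": -x},
            index=samples,
        ).T
        tmap = TargetMap(targets_of={"mir": {"t_exact", "t_below"}})
        de = pd.DataFrame(
            {"rna_class": ["miRNA", "mRNA", "mRNA"], "status": ["up", "down", "down"]},
            index=["mir", "t_exact", "t_below"],
        )
        edges = candidate_pairs(tmap, de, expr)
        assert [e.node_b for e in edges] == ["t_below"]

    def test_non_de_members_excluded(self):
        from cernet.target_prediction import TargetMap

        samples = [f"s{i}" for i in range(6)]
        x = np.arange(6.0)
        expr = pd.DataFrame({"mir": x, "t0": -x}, index=samples).T
        tmap = TargetMap(targets_of={"mir": {"t0"}})
        de = pd.DataFrame(
            {"rna_class": ["miRNA", "mRNA"], "status": ["up", "ns"]},
            index=["mir", "t0"],
        )
        assert candidate_pairs(tmap, de, expr) == []


class TestAssembleTriplets:
    def _inputs(self, pcc_target=0.95, universe=30):
        """Minimal ce/mRNA pair sharing one passing miRNA."""
        rng = np.random.default_rng(1)
        n = 12
        samples = [f"s{i}" for i in range(n)]
        z = np.linspace(-1, 1, n)
        ce = z + rng.normal(0, 0.05, n)
        mrna_perfect = z + rng.normal(0, 0.05, n)
        # blend noise until the ce-mRNA Pearson is close to the requested value
        mir = -z + rng.normal(0, 0.05, n)
        expr = pd.DataFrame(
            {"mir": mir, "ce": ce, "mrna": mrna_perfect}, index=samples
        ).T
        de = pd.DataFrame(
            {
                "rna_class": ["miRNA", "lncRNA", "mRNA"],
                "status": ["up", "down", "down"],
            },
            index=["mir", "ce", "mrna"],
        )
        edges = [
            CorrEdge("mir", "ce", "spearman", spearman_rho(mir, ce)),
            CorrEdge("mir", "mrna", "spearman", spearman_rho(mir, mrna_perfect)),
        ]
        assert all(e.passes for e in edges)
        return edges, expr, de

    def test_triplet_emitted_when_all_filters_pass(self):
        edges, expr, de = self._inputs()
        triplets = assemble_triplets(edges, expr, de, universe_u=30)
        assert len(triplets) == 1
        t = triplets[0]
        assert (t.ce_id, t.mirna_id, t.mrna_id) == ("ce", "mir", "mrna")
        assert t.sponge.pvalue == pytest.approx(1 / 30)

    def test_sponge_threshold_strict(self):
        edges, expr, de = self._inputs()
        # with U = 20 the single-shared-miRNA tail is exactly 0.05: excluded
        assert assemble_triplets(edges, expr, de, universe_u=20) == []
        assert len(assemble_triplets(edges, expr, de, universe_u=21)) == 1

    def test_pcc_threshold_strict(self):
        edges, expr, de = self._inputs()
        assert (
            assemble_triplets(edges, expr, de, universe_u=30, pcc_threshold=1.0)
            == []
        )

    def test_emitted_triplets_satisfy_all_thresholds(self, strong_scenario):
        from cernet.network_pipeline import analyze_counts

        sc = strong_scenario
        _, _, _, triplets = analyze_counts(sc.counts, sc.sequences)
        assert triplets
        for t in triplets:
            assert t.scc_ce_mirna < -0.7
            assert t.scc_mrna_mirna < -0.7
            assert t.pcc_ce_mrna > 0.9
            assert t.sponge.pvalue < 0.05
            assert 0 <= t.sponge.x <= min(t.sponge.M, t.sponge.N)

    def test_output_order_deterministic_and_input_order_invariant(self):
        edges, expr, de = self._inputs()
        fwd = assemble_triplets(edges, expr, de, universe_u=30)
        rev = assemble_triplets(list(reversed(edges)), expr, de, universe_u=30)
        assert fwd == rev

    def test_universe_smaller_than_set_rejected(self):
        edges, expr, de = self._inputs()
        with pytest.raises(ValueError):
            assemble_triplets(edges, expr, de, universe_u=0)
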