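from fractions import Fraction

import numpy as np
import pytest

import oracles
from conftest import make_expression
from coldnet.expression import average_replicates, combine_genotypes
from coldnet.simulate import generate_expression
from coldnet.tricluster import (
    OrderPreservingTricluster,
    TriConfig,
    Tricluster,
    discretize_series,
    find_conserved,
    find_divergent,
    genotype_overlap_summary,
    pattern_pvalue,
)


class TestDiscretize:
    @pytest.mark.parametrize(
        "profile, delta, expected",
        [
            ([1.0, 2.0, 1.8], 0.5, "UN"),
            ([3.0, 3.0, 3.0], 0.5, "NN"),
            ([0.0, 0.1, 0.3], 0.0, "UU"),   # delta=0: any strict increase is U
            ([5.0, 3.0, 1.0], 0.5, "DD"),
            ([0.0, 0.5], 0.4999, "U"),
        ],
    )
    def test_examples(self, profile, delta, expected):
        assert discretize_series(profile, delta) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            discretize_series([1.0, np.nan], 0.5)


class TestConserved:
    def test_identical_genotypes_give_full_cluster(self):
        vals = np.tile([[0, 1, 2.5], [5, 3, 1]], (1, 3))
        x = make_expression(vals, ["a", "b", "c"], [0, 1, 2])
        found = find_conserved(x, TriConfig(min_genes=1))
        full = [c for c in found if set(c.genotypes) == {"a", "b", "c"}]
        covered = set().union(*(c.genes for c in full))
        assert covered == {"g1", "g2"}

    def test_small_known_cluster(self):
        # genes 1-2 share "UU" in both genotypes; genes 3-4 do not
        block = np.array(
            [
                [0, 1, 2, 0, 1, 2],
                [5, 6, 7, 3, 4, 5],
                [0, -1, -2, 0, 1, 2],
                [1, 1, 1, 1, 1, 1],
            ],
            dtype=float,
        )
        x = make_expression(block, ["s1", "s2"], [0, 1, 2])
        found = find_conserved(x, TriConfig(min_genes=1))
        match = [
            c
            for c in found
            if c.pattern == "UU" and set(c.genotypes) == {"s1", "s2"}
        ]
        assert len(match) == 1 and set(match[0].genes) == {"g1", "g2"}

    def test_single_genotype_warns_empty(self):
        x = make_expression([[0, 1, 2.0]], ["a"], [0, 1, 2])
        with pytest.warns(UserWarning):
            assert find_conserved(x, TriConfig(min_genes=1)) == []

    @pytest.mark.parametrize("trial", range(25))
    def test_oracle_equivalence_on_random_instances(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(3, 16))
        l = int(rng.integers(2, 4))
        m = int(rng.integers(3, 6))
        vals = np.round(rng.normal(0, 1, (n, l * m)), 1)
        x = make_expression(vals, [f"s{i}" for i in range(l)], list(range(m)))
        cfg = TriConfig(delta=0.5, min_genes=1, min_window=2)
        mine = {
            (frozenset(c.genes), frozenset(c.genotypes), c.window, c.pattern)
            for c in find_conserved(x, cfg)
        }
        assert mine == oracles.brute_force_conserved(x, cfg)

    def test_anti_monotonicity_on_planted_instance(self):
        # any conserved (genes, S', W) stays conserved on sub-subsets/windows
        rng = np.random.default_rng(7)
        vals = np.round(rng.normal(0, 1, (8, 12)), 1)
        x = make_expression(vals, ["s0", "s1", "s2"], [0, 1, 2, 3])
        cfg = TriConfig(min_genes=1, min_window=2)
        for c in find_conserved(x, cfg):
            pats = set()
            for geno in c.genotypes:
                cols = [f"{geno}:{t}" for t in range(c.window[0], c.window[1] + 1)]
                for gene in c.genes:
                    pats.add(discretize_series(x.values.loc[gene, cols].to_numpy(), cfg.delta))
            assert pats == {c.pattern}


class TestDivergent:
    def test_unique_pattern_flagged(self):
        vals = np.array(
            [[0, 1, 2, 5, 4, 3, 5, 4, 3, 5, 4, 3]], dtype=float
        )  # "UU" in s1, "DD" elsewhere
        x = make_expression(vals, ["s1", "s2", "s3", "s4"], [0, 1, 2])
        found = find_divergent(x, TriConfig(min_genes=1))
        assert len(found) == 1
        c = found[0]
        assert c.genotypes == ("s1",) and c.pattern == "UU" and c.other_pattern == "DD"

    def test_identical_data_has_no_divergence(self):
        vals = np.tile([[0, 1, 2.0]], (1, 3))
        x = make_expression(vals, ["a", "b", "c"], [0, 1, 2])
        assert find_divergent(x, TriConfig(min_genes=1)) == []

    def test_planted_delay_detected_with_shift_annotation(self, small_truth):
        x = generate_expression(small_truth)
        comb = combine_genotypes(average_replicates(x))
        found = find_divergent(comb, TriConfig(min_genes=2))
        delayed = [s for s in small_truth.divergent_sets if s.kind == "delay"]
        assert delayed
        for ps in delayed:
            match = [
                c
                for c in found
                if set(c.genotypes) == set(ps.genotypes) and set(ps.genes) <= set(c.genes)
            ]
            assert match and match[0].shift == 1


class TestPatternPvalue:
    def test_matches_exact_binomial_sum(self):
        cl = Tricluster(
            genes=tuple(f"g{i}" for i in range(5)),
            genotypes=("a", "b"),
            window=(0, 1),
            pattern="U",
            kind="conserved",
        )
        # uniform null: q = (1/3)^(1*2) = 1/9, n=10, observed 5
        p = pattern_pvalue(cl, n_genes=10)
        exact = oracles.binom_sf_exact(5, 10, Fraction(1, 9))
        assert p == pytest.approx(float(exact), rel=1e-12)

    def test_empty_cluster_p_one(self):
        cl = Tricluster((), ("a", "b"), (0, 1), "U", "conserved")
        assert pattern_pvalue(cl, n_genes=10) == 1.0

    def test_certain_pattern_p_one(self):
        cl = Tricluster(("g1",), ("a",), (0, 1), "N", "conserved")
        assert pattern_pvalue(cl, n_genes=5, background={"N": 1.0, "U": 0.0, "D": 0.0}) == 1.0

    def test_decreasing_in_cluster_size(self):
        def cl(size):
            return Tricluster(
                tuple(f"g{i}" for i in range(size)), ("a", "b"), (0, 2), "UU", "conserved"
            )

        ps = [pattern_pvalue(cl(s), n_genes=50) for s in (1, 3, 5, 8)]
        assert all(ps[i + 1] < ps[i] for i in range(len(ps) - 1))

    def test_empirical_background_used(self):
        cl = Tricluster(("g1", "g2"), ("a", "b"), (0, 1), "U", "conserved")
        p_unif = pattern_pvalue(cl, n_genes=10)
        p_emp = pattern_pvalue(cl, n_genes=10, background={"U": 0.8, "D": 0.1, "N": 0.1})
        assert p_emp > p_unif  # common symbol: larger null probability


class TestSummaryAndInvariants:
    def test_identical_data_fully_shared(self):
        vals = np.tile([[0, 1, 2.5], [3, 1, 0]], (1, 3))
        x = make_expression(vals, ["a", "b", "c"], [0, 1, 2])
        cons = find_conserved(x, TriConfig(min_genes=1))
        summary = genotype_overlap_summary(cons, x.genes)
        full = summary[summary["combination"] == "a+b+c"]
        assert full["percent"].iloc[0] == 100.0
        others = summary[(summary["size"] > 1) & (summary["combination"] != "a+b+c")]
        assert (others["percent"] == 0).all()

    def test_planted_subset_fraction(self):
        rng = np.random.default_rng(5)
        n, m = 100, 4
        vals = np.round(rng.normal(0, 0.1, (n, 3 * m)), 2)
        # 10 genes share a strong pattern in genotypes s0+s1 only
        planted = np.array([0, 2, 4, 6.0])
        for g in range(10):
            vals[g, 0:4] = planted
            vals[g, 4:8] = planted
        x = make_expression(vals, ["s0", "s1", "s2"], [0, 1, 2, 3])
        cons = find_conserved(x, TriConfig(min_genes=2))
        summary = genotype_overlap_summary(cons, x.genes)
        row = summary[summary["combination"] == "s0+s1"]
        assert row["percent"].iloc[0] == pytest.approx(10.0)

    def test_empty_cluster_list_all_zero(self):
        summary = genotype_overlap_summary([], ["g1", "g2"])
        assert len(summary) == 0 or (summary["n_genes"] == 0).all()

    def test_no_gene_conserved_everywhere_and_divergent(self):
        rng = np.random.default_rng(9)
        vals = np.round(rng.normal(0, 1, (12, 12)), 1)
        x = make_expression(vals, ["a", "b", "c"], [0, 1, 2, 3])
        cfg = TriConfig(min_genes=1)
        cons = find_conserved(x, cfg)
        div = find_divergent(x, cfg)
        fully_conserved = set().union(
            *(set(c.genes) for c in cons if set(c.genotypes) == {"a", "b", "c"}),
            set(),
        )
        divergent_genes = set().union(*(set(c.genes) for c in div), set())
        assert not (fully_conserved & divergent_genes)


class TestEstimator:
    def test_fit_recovers_planted_sets(self, small_truth):
        x = generate_expression(small_truth)
        comb = combine_genotypes(average_replicates(x))
        model = OrderPreservingTricluster(min_genes=3).fit(comb)
        for ps in small_truth.conserved_sets:
            match = [
                c
                for c in model.conserved_
                if c.pattern == ps.pattern and set(c.genotypes) == set(ps.genotypes)
            ]
            assert match and set(match[0].genes) == set(ps.genes)
            assert match[0].pvalue < 1e-4

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TriConfig(delta=-1.0)
        with pytest.raises(ValueError):
            TriConfig(min_genes=0)
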