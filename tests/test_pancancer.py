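import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ihas import pancancer as pc
from ihas.supermodules import SuperModuleSet


def make_sms(cohort, assignments, targets_per_sm):
    """SuperModuleSet stub from explicit module->SM assignment."""
    module_ids = list(assignments)
    boundaries = []
    ordered = sorted(module_ids, key=lambda m: assignments[m])
    groups = [assignments[m] for m in ordered]
    for i in range(1, len(ordered)):
        if groups[i] != groups[i - 1]:
            boundaries.append(i)
    n_sm = len(set(groups))
    return SuperModuleSet(
        cohort=cohort,
        module_ids=ordered,
        sample_ids=["s0"],
        module_boundaries=boundaries,
        sample_boundaries=[],
        supermodule_targets=[set() for _ in range(n_sm)],
    )


class TestMembershipMatrix:
    def test_counts_match_bruteforce(self, rng):
        modules = {f"c0:E{i}:+": set(rng.choice([f"g{j}" for j in range(12)],
                                                 size=4, replace=False))
                   for i in range(6)}
        assignments = {mid: i % 2 for i, mid in enumerate(modules)}
        sms = make_sms("c0", assignments, modules)
        M = pc.build_membership_matrix([sms], modules)
        for gene in M.index:
            for sm_idx in (0, 1):
                expected = sum(
                    gene in t for mid, t in modules.items() if assignments[mid] == sm_idx
                )
                assert M.loc[gene, f"c0:SM{sm_idx}"] == expected

    def test_gene_in_two_modules_counts_twice(self):
        modules = {"c0:A:+": {"g"}, "c0:B:+": {"g"}}
        sms = make_sms("c0", {"c0:A:+": 0, "c0:B:+": 0}, modules)
        M = pc.build_membership_matrix([sms], modules)
        assert M.loc["g", "c0:SM0"] == 2

    def test_requires_cohorts(self):
        with pytest.raises(ValueError):
            pc.build_membership_matrix([])


class TestSuperModuleGrouping:
    def test_identical_columns_single_group(self):
        genes = [f"g{i}" for i in range(30)]
        col = [1 if i < 10 else 0 for i in range(30)]
        M = pd.DataFrame({f"c:SM{j}": col for j in range(4)}, index=genes)
        sets = {name: set(genes[:10]) for name in pc.STOPPING_CATEGORIES}
        groups = pc.cluster_supermodule_groups(M, sets)
        assert len(groups) == 1

    def test_two_enrichment_families_two_groups(self):
        genes = [f"g{i}" for i in range(200)]
        fam_a = set(genes[:50])
        fam_b = set(genes[50:100])
        cols = {}
        for j in range(3):
            cols[f"c:A{j}"] = [1 if g in fam_a else 0 for g in genes]
        for j in range(3):
            cols[f"c:B{j}"] = [1 if g in fam_b else 0 for g in genes]
        M = pd.DataFrame(cols, index=genes)
        sets = dict.fromkeys(pc.STOPPING_CATEGORIES, set())
        sets = {name: (fam_a if i % 2 == 0 else fam_b)
                for i, name in enumerate(pc.STOPPING_CATEGORIES)}
        groups = pc.cluster_supermodule_groups(M, sets)
        assert len(groups) == 2
        families = {frozenset(g) for g in groups}
        assert families == {
            frozenset(f"c:A{j}" for j in range(3)),
            frozenset(f"c:B{j}" for j in range(3)),
        }

    def test_planted_jaccard_families_recovered(self, rng):
        """Three Super-Module families with high within-family and low
        between-family gene overlap are recovered as three groups."""
        genes = [f"g{i}" for i in range(300)]
        cores = [set(genes[k * 100:(k + 1) * 100]) for k in range(3)]
        cols = {}
        for k, core in enumerate(cores):
            for j in range(4):
                member = {g for g in core if rng.random() < 0.9}
                member |= {g for g in genes if rng.random() < 0.01}
                cols[f"c:F{k}_{j}"] = [1 if g in member else 0 for g in genes]
        M = pd.DataFrame(cols, index=genes)
        sets = {name: cores[i % 3] for i, name in enumerate(pc.STOPPING_CATEGORIES)}
        groups = pc.cluster_supermodule_groups(M, sets)
        assert len(groups) == 3
        for group in groups:
            families = {c.split("_")[0] for c in group}
            assert len(families) == 1


class TestGeneGroups:
    def test_binomial_tail_matches_direct_summation(self):
        for c, n, p in [(3, 40, 0.02), (1, 10, 0.5), (7, 20, 0.3)]:
            direct = sum(
                stats.binom.pmf(k, n, p) for k in range(c, n + 1)
            )
            assert pc.binomial_membership_tail(c, n, p) == pytest.approx(direct, abs=1e-12)

    def test_concentrated_gene_gets_unit_vector(self):
        genes = [f"g{i}" for i in range(100)]
        M = pd.DataFrame(0, index=genes, columns=["c:SM0", "c:SM1"])
        M.loc["g0", "c:SM0"] = 8  # g0 in every module of group 0
        for g in genes[1:]:
            M.loc[g, "c:SM1"] = 1
        groups = [["c:SM0"], ["c:SM1"]]
        gg = pc.assign_gene_groups(M, groups, min_gg_size=1)
        patterns = {tuple(p): set(g) for p, g in gg}
        assert {"g0"} == patterns.get((1, 0), set())

    def test_planted_gene_groups_recovered(self, rng):
        """Genes planted to occur repeatedly in one Super-Module-Group each
        are bucketed back into their groups (Jaccard >= 0.9)."""
        genes = [f"g{i}" for i in range(150)]
        truth = {g: i // 50 for i, g in enumerate(genes)}
        cols = {}
        for k in range(3):
            for j in range(15):
                cols[f"c:F{k}_{j}"] = [
                    int(rng.random() < (0.8 if truth[g] == k else 0.01)) for g in genes
                ]
        M = pd.DataFrame(cols, index=genes)
        groups = [[f"c:F{k}_{j}" for j in range(15)] for k in range(3)]
        gg = pc.assign_gene_groups(M, groups, min_gg_size=10)
        assert len(gg) == 3
        for pat, members in gg:
            k = int(np.argmax(pat))
            true_set = {g for g in genes if truth[g] == k}
            jac = len(set(members) & true_set) / len(set(members) | true_set)
            assert jac >= 0.9


class TestEnrichment:
    def test_matches_exact_tail_summation(self):
        universe = {f"g{i}" for i in range(1000)}
        gene_set = {f"g{i}" for i in range(10)}
        group = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(100, 115)}
        rec = pc.hypergeom_enrichment(gene_set, group, universe)
        N, K, n, k = 1000, 10, 20, 5
        exact = sum(
            stats.hypergeom.pmf(x, N, K, n) for x in range(k, min(K, n) + 1)
        )
        assert rec.p == pytest.approx(exact, rel=1e-10)

    def test_zero_overlap_p_one(self):
        universe = {f"g{i}" for i in range(50)}
        rec = pc.hypergeom_enrichment(set(list(universe)[:5]), set(list(universe)[40:]), universe)
        assert rec.p == 1.0

    def test_group_equal_universe_saturates(self):
        universe = {f"g{i}" for i in range(30)}
        rec = pc.hypergeom_enrichment(set(list(universe)[:7]), universe, universe)
        assert rec.p == 1.0

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            pc.hypergeom_enrichment(set(), set(), set())

    def test_bh_q_monotone_in_p_rank(self, rng):
        recs = [
            pc.EnrichmentRecord("s", f"grp{i}", 1, 5, 5, 100, float(p))
            for i, p in enumerate(rng.uniform(size=20))
        ]
        pc.adjust_fdr(recs)
        by_p = sorted(recs, key=lambda r: r.p)
        qs = [r.q for r in by_p]
        assert all(b >= a - 1e-12 for a, b in zip(qs, qs[1:]))
        assert all(r.q >= r.p for r in recs)


class TestMetaGeneGroups:
    def test_dominant_seed_category_wins(self):
        universe = {f"g{i}" for i in range(500)}
        immune = {f"g{i}" for i in range(60)}
        cycle = {f"g{i}" for i in range(400, 460)}
        gene_groups = [((1, 0), sorted(immune)), ((0, 1), sorted(cycle))]
        seeds = {1: {"immune_like": immune}, 3: {"cycle_like": cycle}}
        meta = pc.define_meta_gene_groups(gene_groups, seeds, universe)
        assert meta == {0: 1, 1: 3}

    def test_no_significant_seed_unassigned(self, rng):
        universe = {f"g{i}" for i in range(500)}
        random_group = set(rng.choice(sorted(universe), 40, replace=False))
        seeds = {1: {"immune_like": set(rng.choice(sorted(universe), 40, replace=False))}}
        meta = pc.define_meta_gene_groups([((1,), sorted(random_group))], seeds, universe)
        assert meta[0] is None


class TestRecurrentEffectors:
    def test_rare_effector_not_reported(self):
        group = [{"E:+"}] + [set() for _ in range(19)]
        out = pc.find_recurrent_effectors(group, group, n_permutations=50)
        assert out == []

    def test_permutation_p_matches_exhaustive_enumeration(self):
        """On a 6-Super-Module toy with a 3-SM group, the permutation p of
        an effector present in k group members matches exact enumeration
        over all C(6,3) subsets."""
        all_sms = [{"E:+"}, {"E:+"}, {"E:+"}, set(), set(), set()]
        group = all_sms[:3]  # effector in all 3
        obs = 3
        combos = list(itertools.combinations(range(6), 3))
        exact = sum(
            1 for c in combos if sum("E:+" in all_sms[i] for i in c) >= obs
        ) / len(combos)
        out = pc.find_recurrent_effectors(
            group, all_sms, min_count=3, alpha=1.0, n_permutations=20000,
            rng=np.random.default_rng(0),
        )
        assert len(out) == 1
        _, count, p = out[0]
        assert count == 3
        assert p == pytest.approx(exact, abs=0.01)

    def test_exclusive_effector_hits_resolution_floor(self):
        group = [{"E:+"} for _ in range(5)]
        others = [set() for _ in range(15)]
        out = pc.find_recurrent_effectors(group, group + others,
                                          n_permutations=999,
                                          rng=np.random.default_rng(1))
        assert out[0][2] <= 1 / 1000 + 1e-12

    def test_null_p_roughly_uniform_under_shuffled_labels(self, rng):
        """When the 'group' is itself a random subset, permutation p-values
        spread over (0, 1)."""
        all_sms = [
            {f"E{j}:+" for j in rng.choice(8, size=3, replace=False)}
            for _ in range(24)
        ]
        ps = []
        for rep in range(60):
            idx = rng.choice(24, size=8, replace=False)
            group = [all_sms[i] for i in idx]
            out = pc.find_recurrent_effectors(
                group, all_sms, min_count=1, alpha=1.0, n_permutations=200, rng=rng
            )
            ps.extend(p for _, _, p in out)
        assert np.mean(ps) == pytest.approx(0.5, abs=0.12)


class TestIntegratedView:
    def test_identity_factors_recover_middle(self, rng):
        M2 = rng.integers(0, 5, (4, 6)).astype(float)
        out = pc.build_integrated_view(np.eye(4), M2, np.eye(6))
        np.testing.assert_allclose(out, M2)

    def test_zero_occurrences_zero_view(self, rng):
        out = pc.build_integrated_view(
            rng.random((3, 4)), np.zeros((4, 5)), rng.random((5, 2))
        )
        np.testing.assert_allclose(out, 0.0)

    def test_matches_triple_loop(self, rng):
        M1, M2, M3 = rng.random((3, 4)), rng.random((4, 5)), rng.random((5, 2))
        out = pc.build_integrated_view(M1, M2, M3)
        brute = np.zeros((3, 2))
        for i in range(3):
            for l in range(2):
                brute[i, l] = sum(
                    M1[i, j] * M2[j, k] * M3[k, l]
                    for j in range(4) for k in range(5)
                )
        np.testing.assert_allclose(out, brute, atol=1e-12)

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            pc.build_integrated_view(np.ones((2, 3)), np.ones((4, 4)), np.ones((4, 2)))
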