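"""Amplicon genotyping, panel filters, clone identity and relatedness."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conifersnp import simgen
from conifersnp.genoclone import (
    EmptyPanelError,
    call_amplicon_genotypes,
    filter_panel,
    flag_nonvariable_loci,
    grm,
    het_ci_filter,
    identity_analysis,
    mismatch_gap,
    mismatch_percent,
    mismatch_profile,
    polymorphism_test,
)


def _counts(rows, loci=None):
    rows = np.asarray(rows)
    idx = [f"I{i}" for i in range(rows.shape[0])]
    cols = loci or [f"L{i}" for i in range(rows.shape[1])]
    return pd.DataFrame(rows, index=idx, columns=cols)


class TestCallGenotypes:
    def test_clean_homozygote(self):
        gm = call_amplicon_genotypes(_counts([[50]]), _counts([[0]]), err=0.01)
        assert gm.iloc[0, 0] == 0

    def test_depth_two_ambiguous_is_missing(self):
        # one read of each allele in a panel of otherwise-homozygous calls:
        # far too little data to clear the 0.95 posterior bar
        ref = _counts([[30]] * 19 + [[1]])
        alt = _counts([[0]] * 19 + [[1]])
        gm = call_amplicon_genotypes(ref, alt, err=0.01)
        assert np.isnan(gm.iloc[-1, 0])

    def test_zero_depth_missing(self):
        gm = call_amplicon_genotypes(_counts([[0]]), _counts([[0]]), err=0.01)
        assert np.isnan(gm.iloc[0, 0])

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            call_amplicon_genotypes(_counts([[-1]]), _counts([[1]]))

    def test_concordance_at_study_depth(self, clone_panel):
        """At ~21x mean amplicon depth the called genotypes agree with the
        generating dosages >= 99% of the time."""
        pop, ref_c, alt_c, _ = clone_panel
        gm = call_amplicon_genotypes(ref_c, alt_c)
        called = ~np.isnan(gm.to_numpy())
        conc = (gm.to_numpy() == pop.genotypes.to_numpy())[called].mean()
        assert conc >= 0.99


class TestPolymorphismTest:
    def test_clean_monomorphic_locus_flagged(self):
        ref = np.full(50, 30)
        alt = np.zeros(50)
        p = polymorphism_test(ref, alt)
        assert p > 0.5

    def test_balanced_split_strongly_variable(self):
        ref = np.array([30] * 25 + [0] * 25)
        alt = np.array([0] * 25 + [30] * 25)
        assert polymorphism_test(ref, alt) < 1e-10

    def test_undercovered_locus_untestable(self):
        assert np.isnan(polymorphism_test(np.array([10] * 5), np.zeros(5)))

    def test_truth_monomorphic_loci_flagged(self):
        """Loci monomorphic in the generating population are flagged
        non-variable >= 95% of the time."""
        pop = simgen.build_clone_population(0, 0, 100, 0, seed=51, n_loci=50)
        pop.genotypes.iloc[:, :25] = 0.0  # force 25 monomorphic loci
        ref_c, alt_c = simgen.simulate_amplicons(pop, seed=52)
        keep = flag_nonvariable_loci(ref_c, alt_c)
        mono = keep.iloc[:25]
        assert (~mono).mean() >= 0.95


class TestFilterPanel:
    def test_locus_missing_boundary_inclusive(self):
        gm = _counts(np.zeros((20, 2)))
        gm.iloc[:, 0] = [1, 0] * 10
        gm.iloc[:3, 1] = np.nan  # exactly 15% missing
        gm.iloc[1, 0] = 1.0
        out = filter_panel(gm)
        assert "L1" not in out.gm.columns
        assert out.attrition["locus_missing"] == 1

    def test_maf_boundary_inclusive(self):
        # 20 individuals; L0 has MAF exactly 0.05 -> dropped, L1 stays
        col0 = np.zeros(20)
        col0[0] = 2.0  # p = 0.05
        col1 = np.array([0, 1] * 10, dtype=float)
        out = filter_panel(_counts(np.column_stack([col0, col1])))
        assert list(out.gm.columns) == ["L1"]
        assert out.attrition["maf"] == 1

    def test_individual_missing_rule(self):
        gm = _counts(np.tile([0.0, 1.0], (10, 5))[:, :5])
        gm.iloc[0, :2] = np.nan  # 40% missing for I0
        out = filter_panel(gm)
        assert "I0" not in out.gm.index
        assert out.attrition["indiv_missing"] == 1

    def test_attrition_conserved(self, clone_panel):
        pop, ref_c, alt_c, _ = clone_panel
        gm = call_amplicon_genotypes(ref_c, alt_c)
        out = filter_panel(gm)
        assert gm.shape[1] == out.gm.shape[1] + out.attrition["locus_missing"] + out.attrition["maf"]
        assert gm.shape[0] == out.gm.shape[0] + out.attrition["indiv_missing"]

    def test_empty_result_names_rule(self):
        gm = _counts(np.full((20, 3), np.nan))
        with pytest.raises(EmptyPanelError, match="locus_missing"):
            filter_panel(gm)


class TestHetCiFilter:
    def test_all_het_excluded(self):
        gm = _counts(np.ones((342, 1)))
        kept, excluded = het_ci_filter(gm)
        assert excluded == ["L0"]

    def test_exact_half_het_kept(self):
        gm = _counts(np.array([[1.0], [0.0]] * 171))
        kept, excluded = het_ci_filter(gm)
        assert kept == ["L0"]

    def test_type_i_error_rate_under_hwe(self):
        """Under Hardy-Weinberg (true heterozygosity <= 0.5) the exclusion
        rate over 1000 simulated loci stays within alpha."""
        rng = np.random.default_rng(53)
        n, m = 342, 1000
        p = rng.uniform(0.2, 0.8, m)
        geno = (rng.random((n, m)) < p).astype(float) + (rng.random((n, m)) < p)
        gm = _counts(geno)
        _, excluded = het_ci_filter(gm, alpha=0.05)
        assert len(excluded) / m <= 0.05


class TestMismatch:
    def test_identical_vectors_zero(self):
        v = pd.Series([0.0, 1, 2, 1])
        assert mismatch_percent(v, v) == 0.0

    def test_five_of_hundred(self):
        a = pd.Series(np.zeros(100))
        b = a.copy()
        b.iloc[:5] = 1.0
        assert mismatch_percent(a, b) == pytest.approx(0.05)

    def test_no_shared_loci_raises(self):
        a = pd.Series([np.nan, 1.0])
        b = pd.Series([1.0, np.nan])
        with pytest.raises(ValueError):
            mismatch_percent(a, b)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_trio_mismatch_at_least_max_pairwise(self, seed):
        rng = np.random.default_rng(seed)
        trio = rng.integers(0, 3, size=(3, 40)).astype(float)
        trio[rng.random((3, 40)) < 0.1] = np.nan
        ok = ~np.isnan(trio).any(axis=0)
        if not ok.any():
            return
        tm = mismatch_percent(*trio)
        pairs = [
            mismatch_percent(
                np.where(ok, trio[i], np.nan), np.where(ok, trio[j], np.nan)
            )
            for i, j in itertools.combinations(range(3), 2)
        ]
        assert tm >= max(pairs) - 1e-12

    def test_gap_statistic_arithmetic(self):
        assert mismatch_gap(8.8, 46.6) == pytest.approx(37.8)


class TestMismatchProfile:
    def test_single_genet_clean_ramets_zero(self):
        geno = np.tile(np.array([0.0, 1, 2, 1, 0] * 8), (3, 1))
        gm = pd.DataFrame(geno, index=["a", "b", "c"])
        labels = pd.Series({"a": "G1", "b": "G1", "c": "G1"})
        prof = mismatch_profile(gm, labels, n_groups=0, seed=0)
        assert (prof.table.mismatch_pct == 0).all()

    def test_distributions_disjoint_on_study_panel(self, clone_panel):
        pop, _rc, _ac, gm = clone_panel
        ident = identity_analysis(gm, pop.labels)
        prof = mismatch_profile(gm, ident.assignments, n_groups=83, seed=54)
        s = prof.summary
        assert s["ramet_pair_max"] < s["unrelated_pair_min"]
        assert s["ramet_trio_max"] < s["unrelated_trio_min"]
        assert s["pair_gap"] > 0 and s["trio_gap"] > 0

    def test_too_few_genets_raise(self):
        gm = pd.DataFrame(np.zeros((2, 10)), index=["a", "b"])
        labels = pd.Series({"a": "G1", "b": "G2"})
        with pytest.raises(ValueError):
            mismatch_profile(gm, labels, n_groups=5)


class TestIdentity:
    def test_clean_population_recovers_truth_exactly(self):
        pop = simgen.build_clone_population(10, 5, 5, 0, seed=55)
        ident = identity_analysis(pop.genotypes, pop.labels)
        assert len(ident.mislabels) == 0
        for g, members in pop.labels.groupby(pop.labels).groups.items():
            assert len({ident.assignments[m] for m in members}) == 1

    def test_planted_mislabels_reported_with_classes(self, clone_panel):
        pop, _rc, _ac, gm = clone_panel
        ident = identity_analysis(gm, pop.labels)
        found = ident.mislabels.set_index("individual")
        planted = {m[0]: m for m in pop.mislabels}
        assert set(found.index) == set(planted)
        for ind, (_, true_g, _lab, kind) in planted.items():
            assert found.loc[ind, "class"] == kind
            if kind == "reassigned":
                assert found.loc[ind, "inferred_genet"] == true_g

    def test_identical_genet_pair_reported_as_conflict(self):
        pop = simgen.build_clone_population(4, 0, 0, 0, seed=56)
        # make two trio genets genetically identical
        g1 = pop.labels[pop.labels == "G001"].index
        g2 = pop.labels[pop.labels == "G002"].index
        pop.genotypes.loc[g2] = pop.genotypes.loc[g1].to_numpy()
        ident = identity_analysis(pop.genotypes, pop.labels)
        assert ident.conflicts


class TestGrm:
    def test_identical_individuals_equal_entries(self):
        gm = pd.DataFrame(
            [[0.0, 1, 2, 1], [0.0, 1, 2, 1], [2.0, 1, 0, 0]],
            index=["a", "b", "c"],
        )
        rel = grm(gm)
        assert rel.G.loc["a", "b"] == pytest.approx(rel.G.loc["a", "a"])
        assert rel.G.loc["a", "b"] == pytest.approx(rel.G.loc["b", "b"])

    def test_three_by_four_toy_matches_hand_oracle(self):
        gm = pd.DataFrame(
            [[0.0, 1, 2, 0], [1.0, 1, 0, 2], [2.0, 0, 1, 1]],
            index=["a", "b", "c"],
        )
        # independent elementwise computation
        mat = gm.to_numpy()
        p = mat.mean(axis=0) / 2
        Z = mat - 2 * p
        denom = 2 * np.sum(p * (1 - p))
        expect = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                expect[i, j] = sum(Z[i, k] * Z[j, k] for k in range(4)) / denom
        rel = grm(gm)
        assert np.allclose(rel.G.to_numpy(), expect, atol=1e-12)

    def test_all_monomorphic_raises(self):
        gm = pd.DataFrame(np.zeros((3, 4)))
        with pytest.raises(ValueError):
            grm(gm)

    def test_invariant_to_locus_and_individual_order(self):
        rng = np.random.default_rng(57)
        gm = pd.DataFrame(
            rng.integers(0, 3, (8, 12)).astype(float),
            index=[f"I{i}" for i in range(8)],
        )
        rel = grm(gm)
        perm_loci = list(rng.permutation(gm.columns))
        perm_inds = list(rng.permutation(gm.index))
        rel2 = grm(gm.loc[perm_inds, perm_loci])
        assert np.allclose(
            rel2.G.loc[gm.index, gm.index].to_numpy(), rel.G.to_numpy()
        )

    def test_within_genet_blocks_exceed_between(self, clone_panel):
        """Ramets of a genet form high-relatedness diagonal blocks above
        every unrelated pair."""
        pop, _rc, _ac, gm = clone_panel
        kept, _ = het_ci_filter(gm)
        rel = grm(gm[kept])
        tg = pop.true_genet
        G = rel.G.to_numpy()
        inds = list(rel.G.index)
        same = np.equal.outer(tg[inds].to_numpy(), tg[inds].to_numpy())
        off = ~np.eye(len(inds), dtype=bool)
        within = G[same & off]
        between = G[~same]
        assert within.min() > between.max()

    def test_fifty_locus_subset_reproduces_identity_assignments(self, clone_panel):
        pop, _rc, _ac, gm = clone_panel
        rng = np.random.default_rng(58)
        sub = gm[list(rng.choice(gm.columns, 50, replace=False))]
        full_ident = identity_analysis(gm, pop.labels)
        sub_ident = identity_analysis(sub, pop.labels)
        # identical grouping: same partition of individuals
        full_groups = full_ident.assignments.groupby(full_ident.assignments).groups
        sub_groups = sub_ident.assignments.groupby(sub_ident.assignments).groups
        assert {frozenset(v) for v in full_groups.values()} == {
            frozenset(v) for v in sub_groups.values()
        }

    def test_half_sib_relatedness_near_quarter(self):
        """Simulated half-sib families at 113 loci average r ~ 0.25."""
        rng = np.random.default_rng(59)
        m = 113
        p = rng.uniform(0.1, 0.9, m)
        n_fam, per_fam, n_bg = 30, 2, 60
        rows, fam_of = [], []
        for f in range(n_fam):
            shared_parent = (rng.random((2, m)) < p).astype(int)
            for _ in range(per_fam):
                from_shared = shared_parent[rng.integers(0, 2, m), np.arange(m)]
                other = (rng.random(m) < p).astype(int)
                rows.append(from_shared + other)
                fam_of.append(f)
        for _ in range(n_bg):
            rows.append(
                (rng.random(m) < p).astype(int) + (rng.random(m) < p).astype(int)
            )
            fam_of.append(-1)
        gm = pd.DataFrame(np.array(rows, dtype=float))
        rel = grm(gm)
        G = rel.G.to_numpy()
        vals = [
            G[i, j]
            for i in range(len(fam_of))
            for j in range(i + 1, len(fam_of))
            if fam_of[i] == fam_of[j] and fam_of[i] >= 0
        ]
        assert abs(float(np.mean(vals)) - 0.25) <= 0.08
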