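"""TDT bookkeeping, logistic association, meta-analysis, LD and clumping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methmr import assoc, simdata
from methmr.assoc import AssociationError
from tests.conftest import make_summary


def trio_set(families, father_observed=None):
    """families: list of (father, mother, child) dosages at one SNP."""
    f, m, c = (np.array(x, dtype=float).reshape(-1, 1) for x in zip(*families))
    n = len(families)
    snps = pd.DataFrame(
        {"snp_id": ["rs1"], "chrom": "1", "pos": [100], "effect_allele": ["A"],
         "other_allele": ["G"], "maf": [0.3]}
    )
    return simdata.TrioSet(
        father=f, mother=m, child=c,
        father_observed=np.array(father_observed if father_observed is not None
                                 else [True] * n),
        mother_observed=np.ones(n, dtype=bool),
        child_affected=np.ones(n, dtype=bool),
        snps=snps,
    )


class TestTdtCounts:
    def test_het_by_hom_family_bookkeeping(self):
        # Aa x aa -> child Aa: the A was transmitted
        assert assoc.tdt_counts(trio_set([(1, 0, 1)]), "rs1") == (1, 0)
        # Aa x aa -> child aa: the A was not transmitted
        assert assoc.tdt_counts(trio_set([(1, 0, 0)]), "rs1") == (0, 1)
        # AA x Aa -> child AA: het mother transmitted A
        assert assoc.tdt_counts(trio_set([(2, 1, 2)]), "rs1") == (1, 0)

    def test_double_heterozygote_counts_child_dosage(self):
        assert assoc.tdt_counts(trio_set([(1, 1, 2)]), "rs1") == (2, 0)
        assert assoc.tdt_counts(trio_set([(1, 1, 1)]), "rs1") == (1, 1)
        assert assoc.tdt_counts(trio_set([(1, 1, 0)]), "rs1") == (0, 2)

    def test_homozygous_parents_uninformative(self):
        trios = trio_set([(0, 0, 0), (2, 2, 2), (2, 0, 1)])
        assert assoc.tdt_counts(trios, "rs1") == (0, 0)
        scan = assoc.tdt_scan(trios)
        assert scan["excluded"].iloc[0]

    def test_masked_parent_families_contribute_nothing(self):
        trios = trio_set([(1, 0, 1), (1, 0, 1)], father_observed=[True, False])
        assert assoc.tdt_counts(trios, "rs1") == (1, 0)

    def test_unknown_snp_raises(self):
        with pytest.raises(AssociationError):
            assoc.tdt_counts(trio_set([(1, 0, 1)]), "rs99")


class TestTdtTest:
    def test_balanced_counts_give_null(self):
        rec = assoc.tdt_test(40, 40)
        assert rec["chisq"] == 0 and rec["beta"] == 0

    def test_mcnemar_chi_square_and_p(self):
        rec = assoc.tdt_test(50, 30)
        assert rec["chisq"] == pytest.approx(5.0)
        assert rec["p_chisq"] == pytest.approx(stats.chi2.sf(5.0, 1), rel=1e-12)
        assert rec["p_chisq"] == pytest.approx(0.02535, abs=1e-4)
        assert rec["beta"] == pytest.approx(np.log(50 / 30))
        assert rec["se"] == pytest.approx(np.sqrt(1 / 50 + 1 / 30))

    def test_haldane_correction_for_zero_cell(self):
        rec = assoc.tdt_test(10, 0)
        assert rec["beta"] == pytest.approx(np.log(10.5 / 0.5))
        assert rec["se"] == pytest.approx(np.sqrt(1 / 10.5 + 1 / 0.5))

    def test_no_transmissions_raises(self):
        with pytest.raises(AssociationError):
            assoc.tdt_test(0, 0)


class TestCaseControl:
    def test_monomorphic_snp_flagged(self, small_panel):
        panel = simdata.GenotypePanel(
            dosages=np.column_stack([np.ones(100), np.random.default_rng(0).integers(0, 3, 100)]).astype(float),
            snps=pd.DataFrame(
                {"snp_id": ["mono", "ok"], "chrom": "1", "pos": [1, 2],
                 "effect_allele": ["A", "A"], "other_allele": ["G", "G"]}
            ),
        )
        phen = np.random.default_rng(1).binomial(1, 0.5, 100)
        st = assoc.case_control_assoc(panel, phen)
        row = st.set_index("snp_id").loc["mono"]
        assert row["excluded"] and row["exclusion_reason"] == "monomorphic"
        assert np.isinf(row["se"])

    def test_requires_both_classes(self, small_panel):
        with pytest.raises(AssociationError):
            assoc.case_control_assoc(small_panel, np.ones(small_panel.n_individuals))

    def test_strong_effect_power(self):
        # OR = 2 per allele, n = 2000, maf 0.3: genome-wide signal nearly always
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(900 + rep)
            g = rng.binomial(2, 0.3, size=2000).astype(float)
            p = 1 / (1 + np.exp(-(-1.0 + np.log(2.0) * g)))
            phen = rng.binomial(1, p)
            panel = simdata.GenotypePanel(
                dosages=g[:, None],
                snps=pd.DataFrame({"snp_id": ["rs1"], "chrom": "1", "pos": [1],
                                   "effect_allele": ["A"], "other_allele": ["G"]}),
            )
            st = assoc.case_control_assoc(panel, phen)
            hits += st["p"].iloc[0] < 1e-8
        assert hits >= 90

    def test_covariate_adjustment_runs(self, small_panel):
        rng = np.random.default_rng(5)
        cov = simdata.make_covariates(small_panel.n_individuals, seed=6)
        phen = rng.binomial(1, 0.4, small_panel.n_individuals)
        st = assoc.case_control_assoc(small_panel, phen, covariates=cov)
        assert (~st["excluded"]).all()
        assert (st.loc[~st["excluded"], "se"] > 0).all()


class TestMeta:
    def test_two_equal_studies_symmetric(self):
        a = make_summary(["rs1"], [1.0], [1.0])
        out = assoc.fixed_effect_meta([a, a.copy()])
        assert out["beta"].iloc[0] == pytest.approx(1.0)
        assert out["se"].iloc[0] == pytest.approx(1 / np.sqrt(2))

    def test_meta_with_itself_halves_variance(self):
        a = make_summary(["rs1", "rs2"], [0.3, -0.2], [0.1, 0.05])
        out = assoc.fixed_effect_meta([a, a.copy()]).set_index("snp_id")
        for snp in ("rs1", "rs2"):
            se0 = a.set_index("snp_id").loc[snp, "se"]
            assert out.loc[snp, "se"] ** 2 == pytest.approx(se0**2 / 2, rel=1e-12)

    def test_hand_computed_weighted_mean(self):
        a = make_summary(["rs1"], [0.4], [0.1])
        b = make_summary(["rs1"], [0.0], [0.2])
        out = assoc.fixed_effect_meta([a, b])
        assert out["beta"].iloc[0] == pytest.approx(0.32, rel=1e-12)

    def test_swapped_alleles_harmonized_by_sign_flip(self):
        a = make_summary(["rs1"], [0.4], [0.1])
        b = make_summary(["rs1"], [-0.4], [0.2], ea=["G"], oa=["A"], eaf=0.7)
        out_swapped = assoc.fixed_effect_meta([a, b])
        out_plain = assoc.fixed_effect_meta(
            [a, make_summary(["rs1"], [0.4], [0.2])]
        )
        assert out_swapped["beta"].iloc[0] == pytest.approx(out_plain["beta"].iloc[0])

    def test_irreconcilable_and_palindromic_snps_dropped(self):
        a = make_summary(["rs1", "rs2"], [0.4, 0.4], [0.1, 0.1],
                         ea=["A", "A"], oa=["G", "T"], eaf=0.5)
        b = make_summary(["rs1", "rs2"], [0.4, 0.4], [0.1, 0.1],
                         ea=["A", "A"], oa=["C", "T"], eaf=0.5)
        harm, drops = assoc.harmonize_alleles(a, b)
        assert harm.empty
        reasons = dict(zip(drops["snp_id"], drops["reason"]))
        assert reasons["rs1"] == "irreconcilable-alleles"
        assert reasons["rs2"] == "palindromic-ambiguous"

    def test_palindromic_kept_outside_ambiguity_band(self):
        a = make_summary(["rs1"], [0.4], [0.1], ea=["A"], oa=["T"], eaf=0.1)
        b = make_summary(["rs1"], [0.4], [0.1], ea=["A"], oa=["T"], eaf=0.1)
        harm, drops = assoc.harmonize_alleles(a, b)
        assert len(harm) == 1 and drops.empty

    def test_strand_flip_resolved_via_complement(self):
        a = make_summary(["rs1"], [0.4], [0.1], ea=["A"], oa=["G"])
        b = make_summary(["rs1"], [0.4], [0.2], ea=["T"], oa=["C"])
        harm, _ = assoc.harmonize_alleles(a, b)
        assert harm["beta"].iloc[0] == pytest.approx(0.4)


class TestLd:
    def test_self_and_duplicate_correlation(self, small_panel):
        ids = small_panel.snp_ids[:2]
        ld = assoc.compute_ld(small_panel, ids)
        assert ld.loc[ids[0], ids[0]] == pytest.approx(1.0)
        dup = simdata.GenotypePanel(
            dosages=np.column_stack([small_panel.dosages[:, 0]] * 2),
            snps=pd.DataFrame({"snp_id": ["a", "b"], "chrom": "1", "pos": [1, 2],
                               "effect_allele": ["A", "A"], "other_allele": ["G", "G"]}),
        )
        assert assoc.compute_ld(dup).loc["a", "b"] == pytest.approx(1.0)

    def test_cross_block_ld_near_zero(self):
        pool = simdata.make_haplotype_pool(
            n_snps=8, maf_low=0.2, maf_high=0.4, block_sizes=[3, 3, 1, 1],
            within_block_rho=0.8, pool_size=5000, seed=42,
        )
        big = simdata.draw_genotypes(pool, 5000, seed=77)
        ld = assoc.compute_ld(big)
        blocks = pool.blocks
        small_pool = pool
        for i in range(small_pool.n_snps):
            for j in range(small_pool.n_snps):
                if blocks[i] != blocks[j]:
                    assert abs(ld.iloc[i, j]) < 0.05

    def test_monomorphic_error_names_snp(self):
        panel = simdata.GenotypePanel(
            dosages=np.column_stack([np.ones(50), np.arange(50) % 3]).astype(float),
            snps=pd.DataFrame({"snp_id": ["flat", "ok"], "chrom": "1", "pos": [1, 2],
                               "effect_allele": ["A", "A"], "other_allele": ["G", "G"]}),
        )
        with pytest.raises(AssociationError, match="flat"):
            assoc.compute_ld(panel)


def naive_clump(stats_df, ld, r2_threshold, window_kb):
    """Independent reference: explicit loop over sorted candidates checking
    every kept index SNP."""
    df = stats_df.sort_values(["p", "snp_id"], kind="mergesort")
    df = df[df["snp_id"].isin(ld.index)]
    kept = []
    for _, row in df.iterrows():
        conflict = False
        for k in kept:
            kpos = stats_df.set_index("snp_id").loc[k, "pos"]
            if (
                abs(row["pos"] - kpos) <= window_kb * 1000
                and ld.loc[row["snp_id"], k] ** 2 >= r2_threshold
            ):
                conflict = True
                break
        if not conflict:
            kept.append(row["snp_id"])
    return kept


class TestClump:
    def test_uncorrelated_snps_all_retained(self):
        st = make_summary(["rs1", "rs2", "rs3"], [0.1, 0.2, 0.3], [0.1, 0.1, 0.1])
        ld = pd.DataFrame(np.eye(3), index=st["snp_id"], columns=st["snp_id"])
        assert set(assoc.clump(st, ld, 0.001, 250)) == {"rs1", "rs2", "rs3"}

    def test_stronger_snp_dominates_correlated_pair(self):
        st = make_summary(["weak", "strong"], [0.2, 0.6], [0.1, 0.1],
                          pos=[1_000_000, 1_010_000])
        ld = pd.DataFrame([[1.0, 0.95], [0.95, 1.0]],
                          index=st["snp_id"], columns=st["snp_id"])
        assert assoc.clump(st, ld, 0.001, 250) == ["strong"]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_naive_reference_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        m = 20
        pool = simdata.make_haplotype_pool(
            n_snps=m, maf_low=0.2, maf_high=0.4, block_sizes=[5, 5, 5, 5],
            within_block_rho=0.7, pool_size=300, seed=seed,
            positions=np.sort(rng.choice(np.arange(1, 2_000_001), m, replace=False)),
        )
        panel = simdata.draw_genotypes(pool, 200, seed=seed + 100)
        ld = assoc.compute_ld(panel)
        st = make_summary(
            pool.snp_ids, rng.normal(0, 0.3, m), rng.uniform(0.05, 0.2, m),
            pos=pool.positions,
        )
        ours = assoc.clump(st, ld, 0.1, 100)
        ref = naive_clump(st, ld, 0.1, 100)
        assert ours == ref
        # post-condition: surviving index SNPs pairwise independent or distant
        pos = st.set_index("snp_id")["pos"]
        for a in ours:
            for b in ours:
                if a != b:
                    assert (abs(pos[a] - pos[b]) > 100_000) or (ld.loc[a, b] ** 2 < 0.1)

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(9)
        m = 12
        pool = simdata.make_haplotype_pool(
            n_snps=m, maf_low=0.2, maf_high=0.4, block_sizes=[6, 6],
            within_block_rho=0.8, pool_size=300, seed=9,
        )
        panel = simdata.draw_genotypes(pool, 300, seed=10)
        ld = assoc.compute_ld(panel)
        st = make_summary(pool.snp_ids, rng.normal(0, 0.3, m),
                          rng.uniform(0.05, 0.2, m), pos=pool.positions)
        shuffled = st.sample(frac=1, random_state=4).reset_index(drop=True)
        assert assoc.clump(st, ld, 0.05, 250) == assoc.clump(shuffled, ld, 0.05, 250)
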