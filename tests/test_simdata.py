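"""Generator correctness: LD structure, Hardy-Weinberg, liability model,
trio transmission and scenario determinism."""

import numpy as np
import pytest
from scipy import stats

from methmr import simdata
from methmr.experiments import scenario_preset
from methmr.simdata import ParameterError


class TestHaplotypePool:
    def test_deterministic_given_seed(self):
        kw = dict(n_snps=6, maf_low=0.1, maf_high=0.5, block_sizes=[3, 3],
                  within_block_rho=0.5, pool_size=300, seed=3)
        a = simdata.make_haplotype_pool(**kw)
        b = simdata.make_haplotype_pool(**kw)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.positions, b.positions)

    def test_allele_frequencies_and_positions(self):
        pool = simdata.make_haplotype_pool(
            n_snps=10, maf_low=0.1, maf_high=0.5, block_sizes=[5, 5],
            within_block_rho=0.6, pool_size=5000, seed=11,
        )
        emp = pool.haplotypes.mean(axis=0)
        assert np.all(np.abs(emp - pool.mafs) < 0.05)
        assert np.all(np.diff(pool.positions) > 0)

    def test_independent_snps_uncorrelated(self):
        pool = simdata.make_haplotype_pool(
            n_snps=8, maf_low=0.2, maf_high=0.4, block_sizes=[1] * 8,
            within_block_rho=0.0, pool_size=10_000, seed=5,
        )
        r = np.corrcoef(pool.haplotypes, rowvar=False)
        off = r[~np.eye(8, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_high_ld_pair_matches_latent_gaussian_oracle(self):
        # Monte-Carlo oracle on the latent-Gaussian threshold model itself
        rho, maf = 0.95, 0.3
        rng = np.random.default_rng(123)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=100_000)
        alleles = z < stats.norm.ppf(maf)
        oracle_r2 = np.corrcoef(alleles, rowvar=False)[0, 1] ** 2

        pool = simdata.make_haplotype_pool(
            n_snps=2, maf_low=maf, maf_high=maf, block_sizes=[2],
            within_block_rho=rho, pool_size=10_000, seed=9,
            mafs=np.array([maf, maf]),
        )
        panel = simdata.draw_genotypes(pool, 10_000, seed=10)
        r2 = np.corrcoef(panel.dosages, rowvar=False)[0, 1] ** 2
        assert r2 > 0.6
        assert abs(r2 - oracle_r2) < 0.06

    def test_tetrachoric_solver_hits_target_genotype_r2(self):
        target_r = np.sqrt(0.5)
        rho = simdata.latent_rho_for_allele_corr(float(target_r), 0.3, 0.3)
        pool = simdata.make_haplotype_pool(
            n_snps=2, maf_low=0.3, maf_high=0.3, block_sizes=[2],
            within_block_rho=rho, pool_size=20_000, seed=21,
            mafs=np.array([0.3, 0.3]),
        )
        r = np.corrcoef(pool.haplotypes, rowvar=False)[0, 1]
        assert abs(r - target_r) < 0.02

    @pytest.mark.parametrize(
        "kw",
        [
            dict(maf_low=0.0),
            dict(maf_low=0.4, maf_high=0.2),
            dict(block_sizes=[3, 2]),
            dict(pool_size=50),
            dict(within_block_rho=1.1),
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        base = dict(n_snps=4, maf_low=0.1, maf_high=0.4, block_sizes=[2, 2],
                    within_block_rho=0.5, pool_size=200, seed=0)
        base.update(kw)
        with pytest.raises(ParameterError):
            simdata.make_haplotype_pool(**base)


class TestGenotypes:
    def test_hardy_weinberg_heterozygosity(self):
        pool = simdata.make_haplotype_pool(
            n_snps=1, maf_low=0.5, maf_high=0.5, block_sizes=[1],
            within_block_rho=0.0, pool_size=10_000, seed=2,
            mafs=np.array([0.5]),
        )
        panel = simdata.draw_genotypes(pool, 10_000, seed=3)
        het = np.mean(panel.dosages[:, 0] == 1)
        assert abs(het - 0.5) < 0.02

    def test_single_individual_shape_and_range(self, small_pool):
        panel = simdata.draw_genotypes(small_pool, 1, seed=0)
        assert panel.dosages.shape == (1, small_pool.n_snps)
        assert set(np.unique(panel.dosages)) <= {0.0, 1.0, 2.0}

    def test_invalid_n_rejected(self, small_pool):
        with pytest.raises(ParameterError):
            simdata.draw_genotypes(small_pool, 0, seed=0)


class TestMethylation:
    def test_beta_values_in_unit_interval(self, small_panel):
        meth = simdata.simulate_methylation(
            small_panel, 0, 0.5, None, None, 1.0, seed=4, n_null_cpgs=3
        )
        vals = meth.beta_values.to_numpy()
        assert np.all((vals > 0) & (vals < 1))

    def test_null_effect_gives_null_slope(self, small_panel):
        meth = simdata.simulate_methylation(
            small_panel, 0, 0.0, None, None, 1.0, seed=5
        )
        g = small_panel.dosages[:, 0]
        y = meth.latent["cg_causal"].to_numpy()
        slope, intercept, *_ = stats.linregress(g, y)
        se = np.sqrt(np.var(y) / (len(y) * np.var(g)))
        assert abs(slope) < 3 * se

    def test_latent_slope_recovery_over_replicates(self):
        # parameter-recovery oracle: mean latent-scale slope near the truth
        effect = 0.5
        slopes = []
        for rep in range(100):
            rng_seed = 100 + rep
            pool = simdata.make_haplotype_pool(
                n_snps=1, maf_low=0.3, maf_high=0.3, block_sizes=[1],
                within_block_rho=0.0, pool_size=500, seed=rng_seed,
                mafs=np.array([0.3]),
            )
            panel = simdata.draw_genotypes(pool, 1000, seed=rng_seed + 1)
            meth = simdata.simulate_methylation(
                panel, 0, effect, None, None, 1.0, seed=rng_seed + 2
            )
            g = panel.dosages[:, 0]
            y = meth.latent["cg_causal"].to_numpy()
            slopes.append(stats.linregress(g, y).slope)
        assert abs(np.mean(slopes) - effect) < 0.1


class TestDisease:
    def test_null_case_fraction_matches_prevalence(self):
        pool = simdata.make_haplotype_pool(
            n_snps=2, maf_low=0.3, maf_high=0.3, block_sizes=[1, 1],
            within_block_rho=0.0, pool_size=1000, seed=6,
        )
        panel = simdata.draw_genotypes(pool, 10_000, seed=7)
        cfg = scenario_preset("null", mqtl_effect=0.0, prevalence=0.1)
        phen = simdata.simulate_disease(panel, None, cfg, seed=8)
        assert abs(phen.mean() - 0.10) < 0.01

    def test_zero_mediation_effect_means_disease_independent_of_methylation(self):
        pool = simdata.make_haplotype_pool(
            n_snps=8, maf_low=0.3, maf_high=0.3, block_sizes=[1] * 8,
            within_block_rho=0.0, pool_size=1000, seed=9,
        )
        panel = simdata.draw_genotypes(pool, 5000, seed=10)
        cfg = scenario_preset("mediation", methylation_to_liability=1e-12)
        rng = np.random.default_rng(11)
        m = cfg.mqtl_effect * panel.dosages[:, 0] + rng.standard_normal(5000)
        phen = simdata.simulate_disease(
            panel, m, cfg, seed=12, causal_snp_index=0, background_indices=[6, 7]
        )
        import statsmodels.api as sm

        fit = sm.Logit(phen, sm.add_constant(m)).fit(disp=0)
        assert abs(fit.tvalues[1]) < 3

    @pytest.mark.parametrize(
        "kw",
        [
            dict(model="mediation", direct_snp_to_liability=0.3),
            dict(model="null", methylation_to_liability=0.5),
            dict(model="linkage", methylation_to_liability=0.0,
                 direct_snp_to_liability=0.0, linkage_r2=0.5),
            dict(model="reverse_causation", mqtl_effect=0.5,
                 methylation_to_liability=0.0, liability_to_methylation=0.7),
            dict(model="mediation", prevalence=0.0),
        ],
    )
    def test_model_inconsistent_configs_rejected(self, kw):
        with pytest.raises(ParameterError):
            simdata.ScenarioConfig(**kw)

    def test_linkage_r2_realized_between_causal_loci(self):
        cfg = scenario_preset("linkage", seed=13, pool_size=8000)
        bundle = simdata.generate_scenario(cfg)
        roles = bundle.snp_truth["role"]
        i = int(np.flatnonzero(roles == "mqtl_causal")[0])
        j = int(np.flatnonzero(roles == "disease_causal")[0])
        g = bundle.mqtl_cohort.genotypes.dosages
        r2 = np.corrcoef(g[:, i], g[:, j])[0, 1] ** 2
        assert abs(r2 - cfg.linkage_r2) < 0.1


class TestTrios:
    def test_mendelian_consistency_and_ascertainment(self):
        cfg = scenario_preset("mediation", n_trios=100, seed=14)
        bundle = simdata.generate_scenario(cfg)
        trios = bundle.trios
        lo = (trios.father == 2).astype(int) + (trios.mother == 2).astype(int)
        hi = (trios.father > 0).astype(int) + (trios.mother > 0).astype(int)
        assert np.all(trios.child >= lo) and np.all(trios.child <= hi)
        assert trios.child_affected.all()

    def test_null_transmission_ratio_balanced(self):
        pool = simdata.make_haplotype_pool(
            n_snps=1, maf_low=0.3, maf_high=0.3, block_sizes=[1],
            within_block_rho=0.0, pool_size=500, seed=15,
        )
        cfg = scenario_preset("null", mqtl_effect=0.0)
        trios = simdata.simulate_trios(pool, cfg, 3000, seed=16)
        from methmr.assoc import tdt_counts

        b, c = tdt_counts(trios, pool.snp_ids[0])
        assert abs(b / (b + c) - 0.5) < 0.02

    def test_ascertainment_cap_raises(self, monkeypatch):
        monkeypatch.setattr(simdata, "_ASCERTAINMENT_CAP", 5000)
        pool = simdata.make_haplotype_pool(
            n_snps=1, maf_low=0.3, maf_high=0.3, block_sizes=[1],
            within_block_rho=0.0, pool_size=200, seed=17,
        )
        cfg = scenario_preset("null", mqtl_effect=0.0, prevalence=1e-4)
        with pytest.raises(RuntimeError, match="ascertainment cap"):
            simdata.simulate_trios(pool, cfg, 100, seed=18)


class TestScenarioFactory:
    def test_identical_configs_give_bit_identical_bundles(self):
        cfg = scenario_preset("mediation", seed=19, n_trios=20)
        a = simdata.generate_scenario(cfg)
        b = simdata.generate_scenario(cfg)
        assert np.array_equal(a.gwas.genotypes.dosages, b.gwas.genotypes.dosages)
        assert np.array_equal(a.gwas.phenotype, b.gwas.phenotype)
        assert a.mqtl_cohort.methylation.beta_values.equals(
            b.mqtl_cohort.methylation.beta_values
        )
        assert np.array_equal(a.trios.child, b.trios.child)

    def test_truth_table_roles_per_model(self):
        null_bundle = simdata.generate_scenario(
            scenario_preset("null", mqtl_effect=0.0, seed=20, n_trios=2)
        )
        assert (null_bundle.snp_truth["role"] == "none").all()
        assert not null_bundle.cpg_truth["causal"].any()

        med = simdata.generate_scenario(scenario_preset("mediation", seed=21, n_trios=2))
        assert (med.snp_truth["role"] == "mqtl_causal").sum() == 1
        assert med.cpg_truth.set_index("cpg_id").loc["cg_causal", "causal"]

    def test_cell_proportions_sum_to_one(self):
        cov = simdata.make_covariates(200, seed=22)
        cells = cov[[c for c in cov.columns if c.startswith("cell_")]]
        assert np.allclose(cells.sum(axis=1), 1.0, atol=1e-9)

    def test_case_control_logodds_reference_matches_simulation(self):
        # the closed-form liability->log-odds oracle vs a large ascertained fit
        cfg = scenario_preset("mediation", seed=23)
        ref = simdata.expected_case_control_logodds(cfg)
        betas = []
        for s in range(4):
            rng = np.random.default_rng(400 + s)
            pool, ci, di, bg = simdata._scenario_layout(cfg, rng)
            cohort = simdata.simulate_case_control_cohort(
                pool, cfg, 6000, 18000, seed=500 + s,
                causal_snp_index=ci, disease_snp_index=di, background_indices=bg,
            )
            from methmr.assoc import case_control_assoc

            st = case_control_assoc(
                cohort.genotypes, cohort.phenotype, snp_ids=[pool.snp_ids[ci]]
            )
            betas.append(st["beta"].iloc[0])
        assert abs(np.mean(betas) - ref) < 0.03
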