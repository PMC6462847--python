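"""Calibration and recovery experiments over the synthetic scenarios.

These are the repeatable Monte-Carlo experiments the analysis rests on:
type-I-error calibration of every test in the pipeline under null data,
parameter recovery of the forward-MR estimand under mediation,
colocalization specificity under linkage, and end-to-end classification
accuracy across the four causal models. Each function is a pure function
of its seed and returns plain numbers; the acceptance script and the test
suite both run them.

Replicate counts and cohort sizes are arguments with defaults matching the
experiment definitions in the package documentation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import assoc, coloc, mqtl, mr, pipeline, simdata, triangulate

__all__ = [
    "scenario_preset",
    "tdt_null_rejection",
    "case_control_null_rejection",
    "anova_null_rejection",
    "reverse_mr_rejection",
    "forward_mr_recovery",
    "measured_exposure_slope",
    "forward_mr_estimand",
    "jlim_linkage_rejection",
    "classification_accuracy",
    "replication_concordance",
]

# The study conditions: strong-effect settings per causal model. Effects are
# chosen so the focal association is clearly detectable at the default
# cohort sizes (GWAS 500 cases / 1500 controls, methylation cohort 900),
# mirroring the regime where per-locus triangulation is meaningful.
_PRESETS = {
    "mediation": {},
    "pleiotropy": dict(methylation_to_liability=0.0, direct_snp_to_liability=0.3),
    "linkage": dict(
        methylation_to_liability=0.0, direct_snp_to_liability=0.3, linkage_r2=0.5
    ),
    "reverse_causation": dict(
        mqtl_effect=0.0, methylation_to_liability=0.0, liability_to_methylation=0.7
    ),
    "null": dict(methylation_to_liability=0.0),
}


def scenario_preset(model: str, seed: int = 0, **overrides) -> simdata.ScenarioConfig:
    """Model-consistent scenario defaults (the study conditions)."""
    kw = dict(_PRESETS[model])
    kw.update(overrides)
    return simdata.ScenarioConfig(model=model, seed=seed, **kw)


def _seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


# ---------------------------------------------------------------------------
# type-I-error calibration
# ---------------------------------------------------------------------------


def tdt_null_rejection(
    n_reps: int = 800, n_trios: int = 100, alpha: float = 0.05, seed: int = 0
) -> float:
    """Rejection rate of the TDT chi-square at ``alpha`` over null trios
    (disease independent of genotype)."""
    cfg = scenario_preset("null", mqtl_effect=0.0, n_trios=n_trios)
    rej = 0
    for s in _seeds(seed, n_reps):
        rng = np.random.default_rng(s)
        pool = simdata.make_haplotype_pool(
            n_snps=2, maf_low=0.3, maf_high=0.3, block_sizes=[1, 1],
            within_block_rho=0.0, pool_size=400, seed=int(rng.integers(2**31)),
        )
        trios = simdata.simulate_trios(
            pool, cfg, n_trios, int(rng.integers(2**31)), duo_fraction=0.2
        )
        b, c = assoc.tdt_counts(trios, pool.snp_ids[0])
        if b + c == 0:
            continue
        rej += assoc.tdt_test(b, c)["p_chisq"] < alpha
    return rej / n_reps


def case_control_null_rejection(
    n_reps: int = 800, n: int = 300, alpha: float = 0.05, seed: int = 0
) -> float:
    """Rejection rate of the per-SNP logistic Wald test when the phenotype
    is independent of genotype."""
    rej = 0
    used = 0
    for s in _seeds(seed, n_reps):
        rng = np.random.default_rng(s)
        pool = simdata.make_haplotype_pool(
            n_snps=1, maf_low=0.3, maf_high=0.3, block_sizes=[1],
            within_block_rho=0.0, pool_size=400, seed=int(rng.integers(2**31)),
        )
        panel = simdata.draw_genotypes(pool, n, int(rng.integers(2**31)))
        phen = rng.binomial(1, 0.3, size=n)
        if phen.sum() in (0, n):
            continue
        st = assoc.case_control_assoc(panel, phen)
        if st["excluded"].iloc[0]:
            continue
        used += 1
        rej += st["p"].iloc[0] < alpha
    return rej / max(used, 1)


def anova_null_rejection(
    n_reps: int = 1000, n_per_group: int = 20, alpha: float = 0.05, seed: int = 0
) -> float:
    """Rejection rate of the covariate-adjusted subtype ANOVA when all
    groups share one mean."""
    rej = 0
    labels = np.repeat(["CLO", "CLP", "CPO"], n_per_group)
    n = len(labels)
    for s in _seeds(seed, n_reps):
        rng = np.random.default_rng(s)
        cov = simdata.make_covariates(n, int(rng.integers(2**31)), n_pcs=2)
        y = rng.standard_normal(n) + 0.3 * cov["sex"].to_numpy()
        _, p = triangulate.subtype_anova(y, labels, cov)
        rej += p < alpha
    return rej / n_reps


def _reverse_mr_once(bundle: simdata.ScenarioBundle) -> mr.MRResult | None:
    """Reverse MR for the causal CpG using the background disease SNPs
    outside its cis region (the pipeline's instrument rule)."""
    bg_ids = list(
        bundle.snp_truth.loc[bundle.snp_truth["role"] == "background_disease", "snp_id"]
    )
    cpg_pos = int(bundle.mqtl_cohort.methylation.cpg_positions["cg_causal"])
    snp_pos = bundle.pool.snp_table().set_index("snp_id")["pos"]
    bg_ids = [s for s in bg_ids if abs(int(snp_pos[s]) - cpg_pos) > 1_000_000]
    if not bg_ids:
        return None
    disease = assoc.case_control_assoc(
        bundle.gwas.genotypes, bundle.gwas.phenotype, snp_ids=bg_ids
    )
    disease = disease[~disease["excluded"]]
    resid = mqtl.prepare_methylation(
        bundle.mqtl_cohort.methylation.beta_values[["cg_causal"]],
        bundle.mqtl_cohort.covariates,
    )
    outcome = mqtl.snp_cpg_assoc(
        bundle.mqtl_cohort.genotypes, resid["cg_causal"].to_numpy(),
        "cg_causal", cpg_pos, list(disease["snp_id"]),
    )
    meta = bundle.pool.snp_table()[
        ["snp_id", "chrom", "pos", "effect_allele", "other_allele", "maf"]
    ].rename(columns={"maf": "eaf"})
    outcome = outcome.merge(meta, on="snp_id")
    outcome["n"] = bundle.mqtl_cohort.genotypes.n_individuals
    return mr.reverse_mr(disease, outcome)


def reverse_mr_rejection(
    model: str = "mediation",
    n_reps: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    *,
    n_individuals: int = 1200,
    n_mqtl: int = 600,
    pool_size: int = 1500,
) -> float:
    """Rejection rate of the reverse MR (disease liability -> methylation).

    Under mediation this is a type-I error (liability does not feed back on
    methylation); under reverse causation it is power.
    """
    rej = 0
    used = 0
    for s in _seeds(seed, n_reps):
        cfg = scenario_preset(
            model, seed=int(s), n_individuals=n_individuals, n_mqtl=n_mqtl,
            pool_size=pool_size, n_trios=1, n_null_cpgs=0,
        )
        bundle = simdata.generate_scenario(cfg)
        res = _reverse_mr_once(bundle)
        if res is None:
            continue
        used += 1
        rej += res.p < alpha
    return rej / max(used, 1)


# ---------------------------------------------------------------------------
# forward-MR parameter recovery
# ---------------------------------------------------------------------------


def measured_exposure_slope(
    cfg: simdata.ScenarioConfig, n: int = 100_000, n_seeds: int = 3, seed: int = 0
) -> float:
    """Asymptotic slope of the prepared (rank-normalized, residualized)
    methylation on the causal dosage, measured at large n and averaged over
    pools. This is the empirically documented normalization factor between
    the generative mqtl_effect and what the cis scan estimates."""
    slopes = []
    for s in _seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        pool, ci, _, _ = simdata._scenario_layout(cfg, rng)
        panel = simdata.draw_genotypes(pool, n, int(rng.integers(2**31)))
        cov = simdata.make_covariates(n, int(rng.integers(2**31)))
        meth = simdata.simulate_methylation(
            panel, ci, cfg.mqtl_effect, cov, simdata.DEFAULT_COVARIATE_EFFECTS,
            cfg.noise_sd, int(rng.integers(2**31)),
        )
        resid = mqtl.prepare_methylation(meth.beta_values[["cg_causal"]], cov)
        rec = mqtl.snp_cpg_assoc(
            panel, resid["cg_causal"].to_numpy(), "cg_causal", 0, [pool.snp_ids[ci]]
        )
        slopes.append(float(rec["beta"].iloc[0]))
    return float(np.mean(slopes))


def forward_mr_estimand(cfg: simdata.ScenarioConfig, seed: int = 0) -> float:
    """Reference value the forward-MR estimator converges to under
    mediation: the exact asymptotic case-control log-OR per allele divided
    by the measured asymptotic exposure slope. The ratio of this value to
    ``methylation_to_liability`` is the liability -> log-odds attenuation
    factor the pipeline documents."""
    logor = simdata.expected_case_control_logodds(cfg)
    slope = measured_exposure_slope(cfg, seed=seed)
    return logor / slope


def forward_mr_recovery(
    n_reps: int = 200, seed: int = 0, *, n_individuals: int = 2000, n_mqtl: int = 900
) -> dict:
    """Wald-ratio recovery of the attenuated methylation -> liability effect
    over replicated mediation studies, relative to the asymptotic estimand.
    Returns the per-replicate estimates, the reference and the median
    recovery ratio."""
    cfg0 = scenario_preset("mediation", n_individuals=n_individuals, n_mqtl=n_mqtl)
    reference = forward_mr_estimand(cfg0, seed=seed + 1)
    ests = []
    for s in _seeds(seed, n_reps):
        cfg = scenario_preset(
            "mediation", seed=int(s), n_individuals=n_individuals, n_mqtl=n_mqtl,
            n_trios=1, n_null_cpgs=0,
        )
        bundle = simdata.generate_scenario(cfg)
        ci = int(np.flatnonzero(bundle.snp_truth["role"] == "mqtl_causal")[0])
        snp = bundle.pool.snp_ids[ci]
        out = assoc.case_control_assoc(
            bundle.gwas.genotypes, bundle.gwas.phenotype, snp_ids=[snp]
        )
        resid = mqtl.prepare_methylation(
            bundle.mqtl_cohort.methylation.beta_values[["cg_causal"]],
            bundle.mqtl_cohort.covariates,
        )
        exp_rec = mqtl.snp_cpg_assoc(
            bundle.mqtl_cohort.genotypes, resid["cg_causal"].to_numpy(),
            "cg_causal", 0, [snp],
        )
        ests.append(float(out["beta"].iloc[0] / exp_rec["beta"].iloc[0]))
    median = float(np.median(ests))
    return {
        "estimates": ests,
        "reference": float(reference),
        "median": median,
        "median_ratio": median / reference,
        "attenuation_factor": float(reference / cfg0.methylation_to_liability),
    }


# ---------------------------------------------------------------------------
# colocalization specificity under linkage
# ---------------------------------------------------------------------------


def jlim_linkage_rejection(
    n_reps: int = 500,
    n_permutations: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    *,
    linkage_r2: float = 0.5,
    n_individuals: int = 1200,
    n_mqtl: int = 600,
    pool_size: int = 1500,
) -> float:
    """Rejection rate of the permutation colocalization test under the
    linkage scenario (distinct causal variants at the stated cross-locus
    r^2): the type-I error of calling a shared causal variant."""
    rej = 0
    used = 0
    for s in _seeds(seed, n_reps):
        cfg = scenario_preset(
            "linkage", seed=int(s), linkage_r2=linkage_r2,
            n_individuals=n_individuals, n_mqtl=n_mqtl, pool_size=pool_size,
            n_trios=1, n_null_cpgs=0,
        )
        bundle = simdata.generate_scenario(cfg)
        res = _coloc_causal_cpg(bundle, n_permutations, int(s) // 2 + 7)
        if res is None or res.status == coloc.UNDEFINED_STATISTIC:
            continue
        used += 1
        rej += res.p_permutation < alpha
    return rej / max(used, 1)


def _coloc_causal_cpg(
    bundle: simdata.ScenarioBundle, n_permutations: int, seed: int
) -> coloc.ColocResult | None:
    """Colocalization for the causal CpG, windowed around its mQTL SNP."""
    ci = int(np.flatnonzero(bundle.snp_truth["role"].str.startswith("mqtl"))[0]) \
        if (bundle.snp_truth["role"].str.startswith("mqtl")).any() else None
    if ci is None:
        return None
    snp_table = bundle.pool.snp_table()
    center = int(snp_table["pos"].iloc[ci])
    ids = list(
        snp_table.loc[(snp_table["pos"] - center).abs() <= 100_000, "snp_id"]
    )
    disease = assoc.case_control_assoc(
        bundle.gwas.genotypes, bundle.gwas.phenotype, snp_ids=ids
    )
    disease = disease[~disease["excluded"]]
    ids = list(disease["snp_id"])
    panel = bundle.mqtl_cohort.genotypes
    resid = mqtl.prepare_methylation(
        bundle.mqtl_cohort.methylation.beta_values[["cg_causal"]],
        bundle.mqtl_cohort.covariates,
    )["cg_causal"].to_numpy()
    G = panel.dosages[:, [panel.index_of(s) for s in ids]]
    r = assoc.compute_ld(panel, ids).to_numpy()
    z1 = (disease["beta"] / disease["se"]).to_numpy()
    z2 = coloc._bulk_z(G, resid[:, None])[:, 0]
    window = coloc.ColocWindow(snp_ids=ids, z1=z1, z2=z2, r=r)
    return coloc.jlim_permutation_p(window, G, resid, n_permutations, seed)


# ---------------------------------------------------------------------------
# end-to-end classification and replication
# ---------------------------------------------------------------------------


def classification_accuracy(
    n_per_model: int = 50,
    seed: int = 0,
    *,
    models: tuple[str, ...] = ("mediation", "linkage", "reverse_causation", "pleiotropy"),
    n_permutations: int = 200,
) -> dict[str, float]:
    """Fraction of simulated loci the triangulation classifier labels with
    the causal model that generated them, per model, at the preset
    strong-effect study conditions."""
    params = pipeline.PipelineParams(n_permutations=n_permutations)
    out = {}
    rng = np.random.default_rng(seed)
    for model in models:
        correct = 0
        for s in _seeds(int(rng.integers(2**31)), n_per_model):
            cfg = scenario_preset(model, seed=int(s), n_trios=1)
            bundle = simdata.generate_scenario(cfg)
            run = pipeline.run_triangulation(bundle, params, seed=int(s) // 3 + 1)
            sub = run.report[run.report["cpg_id"] == "cg_causal"]
            label = sub["label"].iloc[0] if len(sub) else "no_signal"
            correct += label == pipeline.expected_label[model]
        out[model] = correct / n_per_model
    return out


def replication_concordance(
    n_reps: int = 50, seed: int = 0, *, n_mqtl: int = 800
) -> float:
    """Two-cohort mQTL replication: fraction of discovery mQTL (p < 1e-7)
    whose effect replicates in an independent cohort in the same direction
    with p < 0.05, under one shared truth."""
    n_conc = 0
    n_disc = 0
    for s in _seeds(seed, n_reps):
        rng = np.random.default_rng(s)
        cfg = scenario_preset(
            "null", seed=int(s), mqtl_effect=0.5, n_mqtl=n_mqtl, n_trios=1,
            n_null_cpgs=2,
        )
        pool, ci, _, _ = simdata._scenario_layout(cfg, rng)
        tables = []
        for cohort_seed in rng.integers(0, 2**31, size=2):
            crng = np.random.default_rng(cohort_seed)
            panel = simdata.draw_genotypes(pool, n_mqtl, int(crng.integers(2**31)))
            cov = simdata.make_covariates(n_mqtl, int(crng.integers(2**31)))
            meth = simdata.simulate_methylation(
                panel, ci, cfg.mqtl_effect, cov, simdata.DEFAULT_COVARIATE_EFFECTS,
                cfg.noise_sd, int(crng.integers(2**31)), n_null_cpgs=2,
            )
            resid = mqtl.prepare_methylation(meth.beta_values, cov)
            tables.append(
                mqtl.cis_scan(panel, resid, meth.cpg_positions, p_threshold=1.0)
            )
        discovery = tables[0][tables[0]["p"] < mqtl.MQTL_P_THRESHOLD]
        if discovery.empty:
            continue
        rep = triangulate.replication_check(discovery, tables[1])
        n_disc += len(rep)
        n_conc += int(rep["concordant"].sum())
    return n_conc / max(n_disc, 1)
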