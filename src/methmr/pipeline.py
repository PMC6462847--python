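"""End-to-end triangulation over a simulated study.

Chains the stages: methylation preprocessing -> cis-mQTL scan -> instrument
selection by LD clumping -> case-control disease GWAS -> forward MR
(Wald / IVW / LD-aware GLS re-test) -> reverse MR (independent
genome-wide-significant disease SNPs, excluding any instrument in the cis
region of the CpG under test) -> colocalization with permutation p-values
-> per-locus classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assoc, coloc, mqtl, mr, triangulate
from .simdata import ScenarioBundle

__all__ = ["PipelineParams", "run_triangulation", "expected_label"]

# truth mapping used when scoring classifier output against the generator
expected_label = {
    "mediation": "putative_mediation_or_pleiotropy",
    "pleiotropy": "putative_mediation_or_pleiotropy",
    "linkage": "linkage",
    "reverse_causation": "reverse_causation",
    "null": "no_signal",
}


@dataclass(frozen=True)
class PipelineParams:
    cis_window_bp: int = 1_000_000
    mqtl_p_threshold: float = 1e-7
    clump_r2: float = 0.001
    clump_window_kb: float = 250.0
    gwas_significance: float = 5e-8      # reverse-MR instrument selection
    coloc_window_bp: int = 100_000
    r2_resolution: float = 0.8
    n_permutations: int = 200
    coloc_score: str = "max"
    alpha: float = 0.05
    reverse_exclusion_bp: int = 1_000_000


@dataclass
class TriangulationRun:
    calls: list
    report: pd.DataFrame
    mqtl_records: pd.DataFrame
    disease_stats: pd.DataFrame
    thresholds: triangulate.Thresholds
    reverse_instruments: list[str] = field(default_factory=list)


def _mqtl_as_summary(records: pd.DataFrame, snp_table: pd.DataFrame) -> pd.DataFrame:
    """mQTL records joined with SNP metadata into the summary-stat layout."""
    meta = snp_table[["snp_id", "chrom", "pos", "effect_allele", "other_allele", "maf"]]
    out = records.merge(meta, on="snp_id")
    out = out.rename(columns={"maf": "eaf"})
    out["n"] = np.nan
    return out[assoc.SUMMARY_COLUMNS + ["cpg_id", "cpg_pos"]]


def run_triangulation(
    bundle: ScenarioBundle,
    params: PipelineParams = PipelineParams(),
    seed: int = 0,
    *,
    flagged_probes: list[str] | None = None,
) -> TriangulationRun:
    """Run the full triangulation pipeline on one simulated study."""
    rng = np.random.default_rng(seed)
    cohort = bundle.mqtl_cohort
    panel = cohort.genotypes
    snp_table = bundle.pool.snp_table()

    # --- methylation side ----------------------------------------------
    residuals = mqtl.prepare_methylation(cohort.methylation.beta_values, cohort.covariates)
    records = mqtl.cis_scan(
        panel, residuals, cohort.methylation.cpg_positions,
        window_bp=params.cis_window_bp, p_threshold=params.mqtl_p_threshold,
    )
    records = mqtl.filter_probes(records, flagged_probes or [])

    # --- disease side ---------------------------------------------------
    disease_stats = assoc.case_control_assoc(bundle.gwas.genotypes, bundle.gwas.phenotype)
    usable = disease_stats[~disease_stats["excluded"]].copy()

    # reverse-MR instrument pool: genome-wide-significant, LD-clumped
    gw = usable[usable["p"] < params.gwas_significance]
    reverse_pool: list[str] = []
    if not gw.empty:
        ld_all = assoc.compute_ld(panel, list(gw["snp_id"]))
        reverse_pool = assoc.clump(gw, ld_all, params.clump_r2, params.clump_window_kb)

    # --- per-CpG loop ----------------------------------------------------
    cpg_ids = list(records["cpg_id"].unique())
    n_cpgs = max(len(cpg_ids), 1)
    thresholds = triangulate.Thresholds.with_bonferroni(n_cpgs, params.alpha)
    calls = []
    for cpg_id in cpg_ids:
        sub = records[records["cpg_id"] == cpg_id]
        cpg_pos = int(sub["cpg_pos"].iloc[0])
        exp_stats = _mqtl_as_summary(sub, snp_table)

        # independent instruments for this CpG
        ld = assoc.compute_ld(panel, list(exp_stats["snp_id"]))
        instruments = assoc.clump(exp_stats, ld, params.clump_r2, params.clump_window_kb)
        exp_stats = exp_stats[exp_stats["snp_id"].isin(instruments)].reset_index(drop=True)

        # forward MR
        try:
            iset, _ = mr.harmonize(
                exp_stats, usable, exposure_name=cpg_id, outcome_name="disease",
                ld=ld.loc[instruments, instruments] if len(instruments) > 1 else None,
            )
        except mr.MRError:
            continue
        if iset.n_instruments == 1:
            forward = mr.wald_ratio(iset)
        else:
            forward = mr.ivw_correlated(iset)  # LD-aware re-test is the headline
        lead_instrument = iset.table.loc[
            (iset.table["beta_exposure"].abs() / iset.table["se_exposure"]).idxmax(),
            "snp_id",
        ]

        # reverse MR: disease instruments outside this CpG's cis region
        reverse = None
        rev_ids = [
            s for s in reverse_pool
            if abs(int(snp_table.loc[snp_table["snp_id"] == s, "pos"].iloc[0]) - cpg_pos)
            > params.reverse_exclusion_bp
        ]
        if rev_ids:
            outcome_stats = mqtl.snp_cpg_assoc(
                panel, residuals[cpg_id].to_numpy(), cpg_id, cpg_pos, rev_ids,
            )
            outcome_summary = _mqtl_as_summary(outcome_stats, snp_table)
            try:
                reverse = mr.reverse_mr(
                    usable[usable["snp_id"].isin(rev_ids)], outcome_summary,
                    outcome_name=cpg_id,
                )
            except mr.MRError:
                reverse = None

        # colocalization around the disease lead SNP near the instrument
        coloc_result = None
        if forward.p < thresholds.forward:
            coloc_result = _colocalize(
                bundle, params, usable, residuals[cpg_id].to_numpy(),
                lead_instrument, int(rng.integers(2**31)),
            )

        calls.append(
            triangulate.classify_locus(
                cpg_id, lead_instrument, forward, reverse, coloc_result, thresholds
            )
        )

    report = triangulate.build_report(calls)
    return TriangulationRun(
        calls=calls, report=report, mqtl_records=records,
        disease_stats=disease_stats, thresholds=thresholds,
        reverse_instruments=reverse_pool,
    )


def _colocalize(
    bundle: ScenarioBundle,
    params: PipelineParams,
    disease_stats: pd.DataFrame,
    cpg_residuals: np.ndarray,
    instrument_snp: str,
    seed: int,
) -> coloc.ColocResult:
    """Build the window around the instrument, take z1 from the disease
    GWAS and z2 from the methylation cohort, and run the permutation test."""
    panel = bundle.mqtl_cohort.genotypes
    snp_table = bundle.pool.snp_table()
    center = int(snp_table.loc[snp_table["snp_id"] == instrument_snp, "pos"].iloc[0])
    in_window = snp_table["pos"].sub(center).abs() <= params.coloc_window_bp
    ids = [
        s for s in snp_table.loc[in_window, "snp_id"]
        if s in set(disease_stats["snp_id"])
    ]
    sub = disease_stats.set_index("snp_id").loc[ids]
    z1 = (sub["beta"] / sub["se"]).to_numpy()
    cols = [panel.index_of(s) for s in ids]
    G = panel.dosages[:, cols]
    r = assoc.compute_ld(panel, ids)
    z2 = coloc._bulk_z(G, cpg_residuals[:, None])[:, 0]
    window = coloc.ColocWindow(
        snp_ids=ids, z1=z1, z2=z2, r=r.to_numpy(), r2_resolution=params.r2_resolution
    )
    return coloc.jlim_permutation_p(
        window, G, cpg_residuals, params.n_permutations, seed, score=params.coloc_score
    )
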