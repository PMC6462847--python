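"""Synthetic cohorts with known causal structure.

Everything downstream of this module (TDT, case-control GWAS, cis-mQTL
scanning, Mendelian randomization, colocalization, triangulation) is
exercised on data generated here, under one of five causal models for the
relationship between a genetic variant G, DNA methylation M at a CpG, and a
binary trait D with liability L:

``mediation``
    G -> M -> L -> D. The variant's entire effect on disease runs through
    methylation.
``reverse_causation``
    G -> L -> M. Disease liability is purely (poly)genic; liability feeds
    back on methylation.
``linkage``
    G1 -> M, G2 -> L, with corr(G1, G2) set by a target r^2. Two distinct
    causal variants in linkage disequilibrium.
``pleiotropy``
    G -> M and G -> L through independent pathways (horizontal pleiotropy).
``null``
    G may be an mQTL but nothing connects methylation and disease.

Genotypes come from a haplotype pool with block LD built from a
latent-Gaussian threshold model: within a block, standard normals share an
exchangeable correlation and are dichotomized at the allele-frequency
quantile. Methylation beta-values are the logistic transform of a latent
Gaussian trait (so a rank-based inverse-normal transform downstream exactly
recovers the latent scale). Disease follows a liability-threshold model:
``D = 1`` iff ``predictor + N(0,1) > Phi^-1(1 - prevalence)``.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HaplotypePool",
    "GenotypePanel",
    "TrioSet",
    "MethylationSet",
    "ScenarioConfig",
    "CohortBundle",
    "ScenarioBundle",
    "make_haplotype_pool",
    "draw_genotypes",
    "make_covariates",
    "covariate_design",
    "simulate_methylation",
    "simulate_disease",
    "simulate_trios",
    "simulate_case_control_cohort",
    "generate_scenario",
    "latent_rho_for_allele_corr",
    "expected_case_control_logodds",
]

MODELS = ("mediation", "reverse_causation", "linkage", "pleiotropy", "null")

# Non-palindromic allele pairs (effect, other); palindromic A/T, C/G pairs are
# deliberately absent so simulated panels survive harmonization by default.
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))


class ParameterError(ValueError):
    """Invalid generator parameters."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HaplotypePool:
    """2N x m binary haplotype matrix with SNP metadata and block labels."""

    haplotypes: np.ndarray          # (2 * pool_size, n_snps) uint8
    positions: np.ndarray           # 1-based bp, strictly increasing
    mafs: np.ndarray                # target allele frequencies of the coded allele
    blocks: np.ndarray              # block index per SNP
    snp_ids: list[str]
    chrom: str = "1"
    a1: tuple[str, ...] = ()        # coded / effect allele per SNP
    a2: tuple[str, ...] = ()

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def pool_size(self) -> int:
        return self.haplotypes.shape[0] // 2

    def snp_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "chrom": self.chrom,
                "pos": self.positions,
                "effect_allele": list(self.a1),
                "other_allele": list(self.a2),
                "maf": self.mafs,
            }
        )


@dataclass
class GenotypePanel:
    """Individuals x SNPs additive dosages; doubles as an LD reference."""

    dosages: np.ndarray             # (n, m) float64, values in [0, 2]
    snps: pd.DataFrame              # snp_id, chrom, pos, effect_allele, other_allele

    def __post_init__(self) -> None:
        if self.dosages.ndim != 2:
            raise ParameterError("dosage matrix must be 2-dimensional")
        if self.dosages.shape[1] != len(self.snps):
            raise ParameterError("dosage columns must match SNP table rows")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps["snp_id"])

    def index_of(self, snp_id: str) -> int:
        idx = self.snps.index[self.snps["snp_id"] == snp_id]
        if len(idx) == 0:
            raise KeyError(f"SNP {snp_id!r} not in panel")
        return int(idx[0])

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.index_of(snp_id)]

    def subset(self, snp_ids: Sequence[str]) -> "GenotypePanel":
        cols = [self.index_of(s) for s in snp_ids]
        return GenotypePanel(
            dosages=self.dosages[:, cols].copy(),
            snps=self.snps.iloc[cols].reset_index(drop=True),
        )


@dataclass
class TrioSet:
    """Affected-offspring trios (duos are trios with one parent masked)."""

    father: np.ndarray              # (n_trios, m) dosages
    mother: np.ndarray
    child: np.ndarray
    father_observed: np.ndarray     # bool per family
    mother_observed: np.ndarray
    child_affected: np.ndarray      # all True under ascertainment
    snps: pd.DataFrame

    @property
    def n_trios(self) -> int:
        return self.child.shape[0]


@dataclass
class MethylationSet:
    """Beta-values in [0,1] plus the latent Gaussian scale they came from."""

    beta_values: pd.DataFrame       # individuals x CpGs
    latent: pd.DataFrame
    cpg_positions: pd.Series        # bp position per CpG (shared chromosome)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.beta_values.columns)


@dataclass
class CohortBundle:
    genotypes: GenotypePanel
    methylation: MethylationSet
    covariates: pd.DataFrame | None
    phenotype: np.ndarray | None    # 0/1 disease status
    truth: "ScenarioConfig"


@dataclass
class ScenarioBundle:
    """One simulated study: GWAS cohort, mQTL cohort, trios, truth tables."""

    pool: HaplotypePool
    gwas: CohortBundle
    mqtl_cohort: CohortBundle
    trios: TrioSet
    snp_truth: pd.DataFrame         # snp_id, role
    cpg_truth: pd.DataFrame         # cpg_id, pos, causal flag
    config: "ScenarioConfig"


# ---------------------------------------------------------------------------
# scenario configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioConfig:
    """Causal-model parameters plus cohort sizes and layout for one scenario.

    Effect-size conventions: ``mqtl_effect`` is the change in latent
    methylation (in residual-SD-comparable units, noise_sd defaults to 1) per
    coded allele; ``methylation_to_liability`` is liability units per
    population SD of methylation; ``direct_snp_to_liability`` is liability
    units per allele at the disease SNP (linkage / pleiotropy path);
    ``liability_to_methylation`` is latent-methylation units per SD of
    genetic liability (reverse model); ``background_snp_effect`` is the
    liability effect per allele at each of the independent background disease
    SNPs that make disease heritable in every non-null model (these are the
    reverse-MR instruments).
    """

    model: str = "mediation"
    n_individuals: int = 2000       # GWAS case-control total (1:3 cases:controls)
    n_mqtl: int = 900               # methylation cohort size
    n_trios: int = 200
    duo_fraction: float = 0.2       # fraction of trios with the father masked
    mqtl_effect: float = 0.5
    methylation_to_liability: float = 0.5
    direct_snp_to_liability: float = 0.0
    liability_to_methylation: float = 0.0
    prevalence: float = 0.05
    linkage_r2: float = 0.0
    background_snp_effect: float = 0.3
    n_background_snps: int = 6
    covariate_effect_sizes: Mapping[str, float] | None = None
    noise_sd: float = 1.0
    seed: int = 0
    # layout / pool parameters (the LD-reference surrogate)
    maf: float = 0.3
    pool_size: int = 4000
    focal_block_size: int = 8
    focal_block_r2: float = 0.9     # genotype r^2 within blocks A and B: tag
                                    # SNPs above the colocalization resolution
    focal_block_r2_c: float = 0.3   # moderate-LD block C
    n_null_cpgs: int = 12

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ParameterError(f"unknown model {self.model!r}")
        if not 0 < self.prevalence < 1:
            raise ParameterError("prevalence must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")
        self.validate()

    def validate(self) -> None:
        """Enforce that exactly the parameters consistent with `model` are set."""
        m = self.model
        msgs = []
        if m == "mediation":
            if self.direct_snp_to_liability != 0:
                msgs.append("direct_snp_to_liability must be 0 under mediation")
            if self.liability_to_methylation != 0:
                msgs.append("liability_to_methylation must be 0 under mediation")
            if self.linkage_r2 != 0:
                msgs.append("linkage_r2 must be 0 under mediation")
        elif m == "reverse_causation":
            if self.methylation_to_liability != 0:
                msgs.append("methylation_to_liability must be 0 under reverse_causation")
            if self.direct_snp_to_liability != 0:
                msgs.append("direct_snp_to_liability must be 0 under reverse_causation")
            if self.mqtl_effect != 0:
                msgs.append("mqtl_effect must be 0 under reverse_causation")
            if self.liability_to_methylation == 0:
                msgs.append("liability_to_methylation must be non-zero under reverse_causation")
            if self.background_snp_effect == 0:
                msgs.append("background_snp_effect must be non-zero under reverse_causation")
        elif m == "linkage":
            if not 0 <= self.linkage_r2 < 1:
                msgs.append("linkage_r2 must lie in [0, 1)")
            if self.methylation_to_liability != 0:
                msgs.append("methylation_to_liability must be 0 under linkage")
            if self.liability_to_methylation != 0:
                msgs.append("liability_to_methylation must be 0 under linkage")
            if self.direct_snp_to_liability == 0:
                msgs.append("direct_snp_to_liability must be non-zero under linkage")
        elif m == "pleiotropy":
            if self.methylation_to_liability != 0:
                msgs.append("methylation_to_liability must be 0 under pleiotropy")
            if self.liability_to_methylation != 0:
                msgs.append("liability_to_methylation must be 0 under pleiotropy")
            if self.linkage_r2 != 0:
                msgs.append("linkage_r2 must be 0 under pleiotropy")
            if self.direct_snp_to_liability == 0:
                msgs.append("direct_snp_to_liability must be non-zero under pleiotropy")
        elif m == "null":
            for name in (
                "methylation_to_liability",
                "direct_snp_to_liability",
                "liability_to_methylation",
                "linkage_r2",
            ):
                if getattr(self, name) != 0:
                    msgs.append(f"{name} must be 0 under the null model")
        if msgs:
            raise ParameterError("; ".join(msgs))


def null_config(**kwargs) -> ScenarioConfig:
    """A null-model config with all cross-trait paths zeroed."""
    base = dict(
        model="null",
        methylation_to_liability=0.0,
        direct_snp_to_liability=0.0,
        liability_to_methylation=0.0,
        linkage_r2=0.0,
    )
    base.update(kwargs)
    return ScenarioConfig(**base)


# ---------------------------------------------------------------------------
# haplotype pool and genotypes
# ---------------------------------------------------------------------------


from functools import lru_cache


@lru_cache(maxsize=256)
def latent_rho_for_allele_corr(target_r: float, maf1: float, maf2: float) -> float:
    """Latent-Gaussian correlation giving a target allele (phi) correlation.

    Solves the tetrachoric relation corr(B1, B2) = (P11 - p1 p2) /
    sqrt(p1 q1 p2 q2) with P11 the lower orthant probability of a bivariate
    normal at the MAF quantiles. Because genotypes are sums of two
    independent haplotypes, the genotype correlation equals this allele
    correlation.
    """
    if not 0 <= target_r < 1:
        raise ParameterError("target allele correlation must lie in [0, 1)")
    if target_r == 0:
        return 0.0
    t1, t2 = stats.norm.ppf(maf1), stats.norm.ppf(maf2)
    denom = np.sqrt(maf1 * (1 - maf1) * maf2 * (1 - maf2))

    def phi_corr(rho: float) -> float:
        p11 = stats.multivariate_normal.cdf(
            [t1, t2], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        )
        return (p11 - maf1 * maf2) / denom

    from scipy.optimize import brentq

    return float(brentq(lambda r: phi_corr(r) - target_r, 0.0, 0.999999, xtol=1e-10))


def make_haplotype_pool(
    n_snps: int,
    maf_low: float,
    maf_high: float,
    block_sizes: Sequence[int],
    within_block_rho: float | Sequence[float],
    pool_size: int,
    seed: int,
    *,
    positions: np.ndarray | None = None,
    mafs: np.ndarray | None = None,
    cross_block_rho: Mapping[tuple[int, int], float] | None = None,
    chrom: str = "1",
) -> HaplotypePool:
    """Build a block-LD haplotype pool via a latent-Gaussian threshold model.

    Per LD block, 2*pool_size latent standard normals share an exchangeable
    correlation and are dichotomized at Phi^-1(maf): the coded allele has
    frequency maf by construction. Blocks are independent unless an explicit
    ``cross_block_rho[(i, j)]`` latent coupling is requested (used to build
    linkage scenarios with a controlled cross-locus r^2).
    """
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ParameterError("require 0 < maf_low <= maf_high <= 0.5")
    block_sizes = list(block_sizes)
    if any(b < 1 for b in block_sizes) or sum(block_sizes) != n_snps:
        raise ParameterError("block_sizes must be positive and sum to n_snps")
    if pool_size < 100:
        raise ParameterError("pool_size must be at least 100")
    rhos = (
        [float(within_block_rho)] * len(block_sizes)
        if np.isscalar(within_block_rho)
        else list(within_block_rho)
    )
    if len(rhos) != len(block_sizes):
        raise ParameterError("within_block_rho must be scalar or one value per block")
    if any(not 0 <= r < 1 for r in rhos):
        raise ParameterError("within_block_rho values must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    if mafs is None:
        mafs = rng.uniform(maf_low, maf_high, size=n_snps)
    else:
        mafs = np.asarray(mafs, dtype=float)
        if mafs.shape != (n_snps,) or (mafs <= 0).any() or (mafs > 0.5).any():
            raise ParameterError("explicit mafs must be n_snps values in (0, 0.5]")
    if positions is None:
        positions = 1_000_000 + np.cumsum(rng.integers(1000, 5000, size=n_snps))
    positions = np.asarray(positions, dtype=np.int64)
    if positions.shape != (n_snps,) or (np.diff(positions) <= 0).any():
        raise ParameterError("positions must be n_snps strictly increasing integers")

    blocks = np.repeat(np.arange(len(block_sizes)), block_sizes)
    # Latent correlation matrix: exchangeable within blocks, optional uniform
    # coupling between named block pairs, zero elsewhere.
    sigma = np.zeros((n_snps, n_snps))
    for b, rho in enumerate(rhos):
        mask = blocks == b
        sigma[np.ix_(mask, mask)] = rho
    if cross_block_rho:
        for (bi, bj), rho in cross_block_rho.items():
            mi, mj = blocks == bi, blocks == bj
            sigma[np.ix_(mi, mj)] = rho
            sigma[np.ix_(mj, mi)] = rho
    np.fill_diagonal(sigma, 1.0)
    try:
        chol = np.linalg.cholesky(sigma + 1e-9 * np.eye(n_snps))
    except np.linalg.LinAlgError as exc:
        raise ParameterError("latent LD correlation matrix is not PSD") from exc

    latent = rng.standard_normal((2 * pool_size, n_snps)) @ chol.T
    thresholds = stats.norm.ppf(mafs)
    haplotypes = (latent < thresholds).astype(np.uint8)

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_snps)
    a1 = tuple(_ALLELE_PAIRS[i][0] for i in pair_idx)
    a2 = tuple(_ALLELE_PAIRS[i][1] for i in pair_idx)
    snp_ids = [f"rs{chrom}_{p}" for p in positions]
    return HaplotypePool(
        haplotypes=haplotypes,
        positions=positions,
        mafs=mafs,
        blocks=blocks,
        snp_ids=snp_ids,
        chrom=chrom,
        a1=a1,
        a2=a2,
    )


def _panel_from_haplotype_draws(pool: HaplotypePool, idx1, idx2) -> GenotypePanel:
    dosages = (
        pool.haplotypes[idx1].astype(np.float64) + pool.haplotypes[idx2].astype(np.float64)
    )
    return GenotypePanel(dosages=dosages, snps=pool.snp_table())


def draw_genotypes(pool: HaplotypePool, n_individuals: int, seed: int) -> GenotypePanel:
    """Sample individuals as sums of two haplotypes drawn with replacement."""
    if n_individuals < 1:
        raise ParameterError("n_individuals must be at least 1")
    if pool.haplotypes.shape[0] == 0:
        raise ParameterError("empty haplotype pool")
    rng = np.random.default_rng(seed)
    n_hap = pool.haplotypes.shape[0]
    idx = rng.integers(0, n_hap, size=(n_individuals, 2))
    return _panel_from_haplotype_draws(pool, idx[:, 0], idx[:, 1])


# ---------------------------------------------------------------------------
# covariates and methylation
# ---------------------------------------------------------------------------

DEFAULT_COVARIATE_EFFECTS = {
    "sex": 0.2,
    "pc1": 0.15,
    "pc2": -0.1,
    "batch_B": 0.3,
    "batch_C": -0.25,
    "cell_cd4t": 0.8,
    "cell_bcell": -0.6,
}


def make_covariates(
    n: int, seed: int, n_pcs: int = 10, batches: Sequence[str] = ("A", "B", "C")
) -> pd.DataFrame:
    """Sex, ancestry PCs, bisulfite batch and blood cell proportions.

    Cell proportions (four Houseman-style fractions) are Dirichlet and sum
    to one per individual; batch is categorical.
    """
    rng = np.random.default_rng(seed)
    cov = pd.DataFrame({"sex": rng.integers(0, 2, size=n)})
    for k in range(1, n_pcs + 1):
        cov[f"pc{k}"] = rng.standard_normal(n) * (0.5 / k)
    cov["batch"] = rng.choice(list(batches), size=n)
    cells = rng.dirichlet([12.0, 6.0, 4.0, 8.0], size=n)
    for j, name in enumerate(["cell_cd4t", "cell_cd8t", "cell_bcell", "cell_gran"]):
        cov[name] = cells[:, j]
    return cov


def covariate_design(
    covariates: pd.DataFrame,
    *,
    drop_first_batch: bool = True,
    drop_last_cell: bool = True,
    add_intercept: bool = False,
) -> pd.DataFrame:
    """Numeric design matrix: batch one-hot (first level dropped) and one
    cell-proportion column dropped (compositional)."""
    out = {}
    if add_intercept:
        out["intercept"] = np.ones(len(covariates))
    cell_cols = [c for c in covariates.columns if c.startswith("cell_")]
    drop_cells = cell_cols[-1:] if (drop_last_cell and cell_cols) else []
    for col in covariates.columns:
        if col == "batch":
            levels = sorted(covariates["batch"].unique())
            keep = levels[1:] if drop_first_batch else levels
            for lv in keep:
                out[f"batch_{lv}"] = (covariates["batch"] == lv).astype(float).to_numpy()
        elif col in drop_cells:
            continue
        else:
            out[col] = covariates[col].astype(float).to_numpy()
    return pd.DataFrame(out, index=covariates.index)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_methylation(
    panel: GenotypePanel,
    causal_snp_index: int | None,
    mqtl_effect: float,
    covariates: pd.DataFrame | None,
    covariate_effect_sizes: Mapping[str, float] | None,
    noise_sd: float,
    seed: int,
    *,
    n_null_cpgs: int = 0,
    causal_cpg_pos: int | None = None,
    null_cpg_positions: Sequence[int] | None = None,
    intercept: float = 0.0,
) -> MethylationSet:
    """Latent-Gaussian methylation with one (optional) cis-mQTL-driven CpG.

    latent = intercept + mqtl_effect * dosage + covariate terms + N(0, noise_sd);
    beta-values are the logistic transform of the latent trait, which keeps
    them in [0,1] while making the inverse-normal transform downstream an
    exact inverse on ranks. Null CpGs share the covariate and noise structure
    but have no genotype effect.
    """
    if noise_sd <= 0:
        raise ParameterError("noise_sd must be positive")
    if causal_snp_index is not None and not 0 <= causal_snp_index < panel.n_snps:
        raise ParameterError("causal_snp_index out of range")
    rng = np.random.default_rng(seed)
    n = panel.n_individuals

    cov_term = np.zeros(n)
    if covariates is not None and covariate_effect_sizes:
        design = covariate_design(covariates)
        for name, effect in covariate_effect_sizes.items():
            if name not in design.columns:
                raise ParameterError(f"covariate effect refers to unknown column {name!r}")
            cov_term = cov_term + effect * design[name].to_numpy()

    cpg_ids, positions, latents = [], [], []
    if causal_snp_index is not None:
        g = panel.dosages[:, causal_snp_index]
        pos = (
            int(causal_cpg_pos)
            if causal_cpg_pos is not None
            else int(panel.snps["pos"].iloc[causal_snp_index]) + 500
        )
        latents.append(
            intercept + mqtl_effect * g + cov_term + noise_sd * rng.standard_normal(n)
        )
        cpg_ids.append("cg_causal")
        positions.append(pos)
    if null_cpg_positions is not None:
        null_pos = [int(p) for p in null_cpg_positions]
    else:
        lo, hi = int(panel.snps["pos"].min()), int(panel.snps["pos"].max())
        null_pos = sorted(rng.integers(lo, hi + 1, size=n_null_cpgs).tolist())
    for k, pos in enumerate(null_pos):
        mu = rng.normal(0.0, 1.0)  # CpG-specific mean methylation level
        latents.append(mu + cov_term + noise_sd * rng.standard_normal(n))
        cpg_ids.append(f"cg_null_{k:03d}")
        positions.append(pos)

    if latents:
        latent = pd.DataFrame(np.column_stack(latents), columns=cpg_ids)
    else:
        latent = pd.DataFrame(index=range(n))
    beta = pd.DataFrame(
        _logistic(latent.to_numpy(dtype=float)) if latent.shape[1] else
        np.empty((n, 0)),
        columns=latent.columns, index=latent.index,
    )
    return MethylationSet(
        beta_values=beta,
        latent=latent,
        cpg_positions=pd.Series(positions, index=cpg_ids, name="pos"),
    )


# ---------------------------------------------------------------------------
# disease
# ---------------------------------------------------------------------------


def _background_score(
    panel_dosages: np.ndarray, bg_indices: Sequence[int], effect: float, mafs: np.ndarray
) -> tuple[np.ndarray, float]:
    """Centered polygenic liability over the background disease SNPs and its
    theoretical SD (centering keeps the realized prevalence at its nominal
    value; per-allele effects are unchanged)."""
    if len(bg_indices) == 0 or effect == 0:
        return np.zeros(panel_dosages.shape[0]), 0.0
    idx = list(bg_indices)
    g = panel_dosages[:, idx] - 2 * mafs[idx]
    score = effect * g.sum(axis=1)
    var = effect**2 * float(np.sum(2 * mafs[idx] * (1 - mafs[idx])))
    return score, float(np.sqrt(var))


def _methylation_pop_moments(cfg: ScenarioConfig) -> tuple[float, float]:
    """Theoretical mean and SD of the causal CpG's latent methylation
    (genotype term + noise; covariates enter only the mQTL cohort)."""
    pq2 = 2 * cfg.maf * (1 - cfg.maf)
    mean = cfg.mqtl_effect * 2 * cfg.maf
    sd = float(np.sqrt(cfg.mqtl_effect**2 * pq2 + cfg.noise_sd**2))
    return mean, sd


def simulate_disease(
    panel: GenotypePanel,
    methylation_latent: np.ndarray | None,
    scenario: ScenarioConfig,
    seed: int,
    *,
    causal_snp_index: int | None = None,
    disease_snp_index: int | None = None,
    background_indices: Sequence[int] = (),
    return_liability: bool = False,
):
    """Binary disease from a liability-threshold model under one causal model.

    Returns the phenotype vector; under the reverse-causation model also
    returns the updated latent methylation for the causal CpG (methylation is
    a consequence of standardized genetic liability there). With
    ``return_liability`` the latent liability is appended to the returned
    tuple.
    """
    scenario.validate()
    rng = np.random.default_rng(seed)
    n = panel.n_individuals
    t = stats.norm.ppf(1 - scenario.prevalence)

    bg_score, _ = _background_score(
        panel.dosages, background_indices, scenario.background_snp_effect
        if scenario.model != "null" else 0.0,
        panel.snps["maf"].to_numpy() if "maf" in panel.snps else np.full(panel.n_snps, scenario.maf),
    )

    predictor = bg_score.copy()
    new_methylation = None
    if scenario.model == "mediation":
        if methylation_latent is None:
            raise ParameterError("mediation model requires the latent methylation vector")
        mu, sd = _methylation_pop_moments(scenario)
        predictor += scenario.methylation_to_liability * (methylation_latent - mu) / sd
    elif scenario.model in ("pleiotropy", "linkage"):
        idx = disease_snp_index if scenario.model == "linkage" else causal_snp_index
        if idx is None:
            raise ParameterError(f"{scenario.model} model requires a disease SNP index")
        maf = float(panel.snps["maf"].iloc[idx]) if "maf" in panel.snps else scenario.maf
        predictor += scenario.direct_snp_to_liability * (panel.dosages[:, idx] - 2 * maf)
    elif scenario.model == "reverse_causation":
        # liability is purely genetic; methylation responds to it below
        pass

    liability = predictor + rng.standard_normal(n)
    phenotype = (liability > t).astype(np.int8)

    if scenario.model == "reverse_causation":
        _, bg_sd = _background_score(
            panel.dosages, background_indices, scenario.background_snp_effect,
            panel.snps["maf"].to_numpy() if "maf" in panel.snps else np.full(panel.n_snps, scenario.maf),
        )
        if bg_sd == 0:
            raise ParameterError("reverse_causation requires background disease SNPs")
        genetic_std = (bg_score - np.mean(bg_score)) / bg_sd
        new_methylation = (
            scenario.liability_to_methylation * genetic_std
            + scenario.noise_sd * rng.standard_normal(n)
        )

    out = [phenotype]
    if scenario.model == "reverse_causation":
        out.append(new_methylation)
    if return_liability:
        out.append(liability)
    return out[0] if len(out) == 1 else tuple(out)


# ---------------------------------------------------------------------------
# trios
# ---------------------------------------------------------------------------

_ASCERTAINMENT_CAP = 1_000_000


def simulate_trios(
    pool: HaplotypePool,
    scenario: ScenarioConfig,
    n_trios: int,
    seed: int,
    *,
    causal_snp_index: int | None = None,
    disease_snp_index: int | None = None,
    background_indices: Sequence[int] = (),
    duo_fraction: float | None = None,
) -> TrioSet:
    """Affected-offspring trios by rejection sampling.

    Parents are random pool individuals; each transmits one uniformly chosen
    haplotype. The child's disease status follows the scenario's liability
    model (using the child's own genotype-driven methylation under
    mediation); families are resampled until the child is affected, up to a
    cap of 10^6 candidate families. A ``duo_fraction`` of families has the
    father masked; the TDT counts transmissions only from observed
    heterozygous parents.
    """
    if n_trios < 1:
        raise ParameterError("n_trios must be at least 1")
    scenario.validate()
    rng = np.random.default_rng(seed)
    n_hap = pool.haplotypes.shape[0]
    t = stats.norm.ppf(1 - scenario.prevalence)
    mafs = pool.mafs
    mu_m, sd_m = _methylation_pop_moments(scenario)

    kept_f, kept_m, kept_c = [], [], []
    n_kept = 0
    n_drawn = 0
    while n_kept < n_trios:
        if n_drawn >= _ASCERTAINMENT_CAP:
            raise RuntimeError(
                f"ascertainment cap reached: {n_drawn} candidate families yielded "
                f"only {n_kept} affected children (prevalence too low?)"
            )
        batch = min(
            max(int(np.ceil((n_trios - n_kept) / max(scenario.prevalence, 1e-3))) * 2, 500),
            _ASCERTAINMENT_CAP - n_drawn,
        )
        n_drawn += batch
        hap_idx = rng.integers(0, n_hap, size=(batch, 4))  # father x2, mother x2
        transmit = rng.integers(0, 2, size=(batch, 2))     # which haplotype each parent gives
        f_hap1 = pool.haplotypes[hap_idx[:, 0]]
        f_hap2 = pool.haplotypes[hap_idx[:, 1]]
        m_hap1 = pool.haplotypes[hap_idx[:, 2]]
        m_hap2 = pool.haplotypes[hap_idx[:, 3]]
        father = (f_hap1 + f_hap2).astype(np.float64)
        mother = (m_hap1 + m_hap2).astype(np.float64)
        from_f = np.where(transmit[:, [0]] == 0, f_hap1, f_hap2)
        from_m = np.where(transmit[:, [1]] == 0, m_hap1, m_hap2)
        child = (from_f + from_m).astype(np.float64)

        bg_score, bg_sd = _background_score(
            child,
            background_indices,
            scenario.background_snp_effect if scenario.model != "null" else 0.0,
            mafs,
        )
        predictor = bg_score
        if scenario.model == "mediation":
            g = child[:, causal_snp_index]
            m_latent = scenario.mqtl_effect * g + scenario.noise_sd * rng.standard_normal(batch)
            predictor = predictor + scenario.methylation_to_liability * (m_latent - mu_m) / sd_m
        elif scenario.model == "pleiotropy":
            predictor = predictor + scenario.direct_snp_to_liability * (
                child[:, causal_snp_index] - 2 * mafs[causal_snp_index]
            )
        elif scenario.model == "linkage":
            predictor = predictor + scenario.direct_snp_to_liability * (
                child[:, disease_snp_index] - 2 * mafs[disease_snp_index]
            )
        liability = predictor + rng.standard_normal(batch)
        affected = liability > t
        kept_f.append(father[affected])
        kept_m.append(mother[affected])
        kept_c.append(child[affected])
        n_kept += int(affected.sum())

    father = np.concatenate(kept_f)[:n_trios]
    mother = np.concatenate(kept_m)[:n_trios]
    child = np.concatenate(kept_c)[:n_trios]

    frac = scenario.duo_fraction if duo_fraction is None else duo_fraction
    n_duo = int(round(frac * n_trios))
    father_observed = np.ones(n_trios, dtype=bool)
    if n_duo:
        father_observed[rng.choice(n_trios, size=n_duo, replace=False)] = False
    return TrioSet(
        father=father,
        mother=mother,
        child=child,
        father_observed=father_observed,
        mother_observed=np.ones(n_trios, dtype=bool),
        child_affected=np.ones(n_trios, dtype=bool),
        snps=pool.snp_table(),
    )


# ---------------------------------------------------------------------------
# case-control cohorts and the one-call scenario factory
# ---------------------------------------------------------------------------


def simulate_case_control_cohort(
    pool: HaplotypePool,
    scenario: ScenarioConfig,
    n_cases: int,
    n_controls: int,
    seed: int,
    *,
    causal_snp_index: int | None,
    disease_snp_index: int | None,
    background_indices: Sequence[int],
) -> CohortBundle:
    """Ascertained case-control GWAS cohort (quota sampling from the
    liability model). Methylation here is the latent biological trait only
    (no assay covariates); it exists so mediation can operate, not to be
    measured."""
    rng = np.random.default_rng(seed)
    t_cases: list[np.ndarray] = []
    t_controls: list[np.ndarray] = []
    m_cases: list[np.ndarray] = []
    m_controls: list[np.ndarray] = []
    have_cases = have_controls = 0
    n_drawn = 0
    while have_cases < n_cases or have_controls < n_controls:
        if n_drawn >= _ASCERTAINMENT_CAP:
            raise RuntimeError("case-control quota sampling exceeded the iteration cap")
        need_cases = n_cases - have_cases
        batch = int(min(
            max(2000, 2 * need_cases / max(scenario.prevalence, 1e-3)),
            _ASCERTAINMENT_CAP - n_drawn,
        ))
        n_drawn += batch
        panel = draw_genotypes(pool, batch, int(rng.integers(2**31)))
        if scenario.model == "reverse_causation" or scenario.mqtl_effect == 0:
            m_latent = scenario.noise_sd * rng.standard_normal(batch)
        else:
            m_latent = (
                scenario.mqtl_effect * panel.dosages[:, causal_snp_index]
                + scenario.noise_sd * rng.standard_normal(batch)
            )
        res = simulate_disease(
            panel,
            m_latent,
            scenario,
            int(rng.integers(2**31)),
            causal_snp_index=causal_snp_index,
            disease_snp_index=disease_snp_index,
            background_indices=background_indices,
        )
        if scenario.model == "reverse_causation":
            phen, m_latent = res
        else:
            phen = res
        case_mask = phen == 1
        t_cases.append(panel.dosages[case_mask])
        m_cases.append(m_latent[case_mask])
        t_controls.append(panel.dosages[~case_mask])
        m_controls.append(m_latent[~case_mask])
        have_cases += int(case_mask.sum())
        have_controls += int((~case_mask).sum())

    dos = np.vstack(
        [np.concatenate(t_cases)[:n_cases], np.concatenate(t_controls)[:n_controls]]
    )
    m_latent = np.concatenate(
        [np.concatenate(m_cases)[:n_cases], np.concatenate(m_controls)[:n_controls]]
    )
    phenotype = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    panel = GenotypePanel(dosages=dos, snps=pool.snp_table())
    meth = MethylationSet(
        beta_values=pd.DataFrame({"cg_causal": _logistic(m_latent)}),
        latent=pd.DataFrame({"cg_causal": m_latent}),
        cpg_positions=pd.Series(
            [int(pool.positions[causal_snp_index]) + 500 if causal_snp_index is not None else 0],
            index=["cg_causal"],
        ),
    )
    return CohortBundle(
        genotypes=panel, methylation=meth, covariates=None, phenotype=phenotype, truth=scenario
    )


def _scenario_layout(cfg: ScenarioConfig, rng: np.random.Generator):
    """Pool layout shared by all scenarios: three focal LD blocks (A: mQTL
    SNP, B: disease SNP for linkage, C: moderate LD) plus independent
    background disease SNPs far away."""
    k = cfg.focal_block_size
    n_focal = 3 * k
    n_snps = n_focal + cfg.n_background_snps
    spacing = 6000
    pos = []
    base = 10_000_000
    for b in range(3):
        pos.extend(base + b * 100_000 + spacing * np.arange(k))
    for j in range(cfg.n_background_snps):
        pos.append(20_000_000 + 3_000_000 * j)
    positions = np.asarray(pos, dtype=np.int64)
    block_sizes = [k, k, k] + [1] * cfg.n_background_snps
    rho_ab = latent_rho_for_allele_corr(float(np.sqrt(cfg.focal_block_r2)), cfg.maf, cfg.maf)
    rho_c = latent_rho_for_allele_corr(float(np.sqrt(cfg.focal_block_r2_c)), cfg.maf, cfg.maf)
    rhos = [rho_ab, rho_ab, rho_c] + [0.0] * cfg.n_background_snps
    cross = None
    if cfg.model == "linkage" and cfg.linkage_r2 > 0:
        target_allele_r = float(np.sqrt(cfg.linkage_r2))
        cross = {(0, 1): latent_rho_for_allele_corr(target_allele_r, cfg.maf, cfg.maf)}
    pool = make_haplotype_pool(
        n_snps=n_snps,
        maf_low=cfg.maf,
        maf_high=cfg.maf,
        block_sizes=block_sizes,
        within_block_rho=rhos,
        pool_size=cfg.pool_size,
        seed=int(rng.integers(2**31)),
        positions=positions,
        mafs=np.full(n_snps, cfg.maf),
        cross_block_rho=cross,
    )
    causal_idx = k // 2                   # middle of block A
    disease_idx = k + k // 2              # middle of block B
    background = list(range(n_focal, n_snps))
    return pool, causal_idx, disease_idx, background


def generate_scenario(config: ScenarioConfig) -> ScenarioBundle:
    """One-call factory: pool + GWAS cohort + mQTL cohort + trios + truth.

    Deterministic given ``config`` (two calls with the same config are
    bit-identical). The mQTL cohort carries measured methylation with
    covariate/batch/cell structure; the GWAS cohort carries case-control
    disease status; trios are ascertained on an affected child.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    pool, causal_idx, disease_idx, background = _scenario_layout(cfg, rng)

    cov_effects = (
        dict(cfg.covariate_effect_sizes)
        if cfg.covariate_effect_sizes is not None
        else dict(DEFAULT_COVARIATE_EFFECTS)
    )

    # --- mQTL (methylation) cohort -------------------------------------
    mqtl_panel = draw_genotypes(pool, cfg.n_mqtl, int(rng.integers(2**31)))
    covariates = make_covariates(cfg.n_mqtl, int(rng.integers(2**31)))
    if cfg.model == "reverse_causation":
        cpg_pos = int(pool.positions[background[0]]) + 500
        meth = simulate_methylation(
            mqtl_panel, None, 0.0, covariates, cov_effects, cfg.noise_sd,
            int(rng.integers(2**31)),
            n_null_cpgs=cfg.n_null_cpgs,
            causal_cpg_pos=None,
        )
        _, m_latent = simulate_disease(
            mqtl_panel, None, cfg, int(rng.integers(2**31)),
            background_indices=background,
        )
        # measured methylation = liability-driven biology + assay covariates
        design_term = np.zeros(cfg.n_mqtl)
        design = covariate_design(covariates)
        for name, eff in cov_effects.items():
            design_term += eff * design[name].to_numpy()
        latent = m_latent + design_term
        meth.latent.insert(0, "cg_causal", latent)
        meth.beta_values.insert(0, "cg_causal", _logistic(latent))
        pos_map = {"cg_causal": cpg_pos}
        pos_map.update(meth.cpg_positions.to_dict())
        meth.cpg_positions = pd.Series(pos_map, dtype=np.int64)
    else:
        meth = simulate_methylation(
            mqtl_panel,
            causal_idx,
            cfg.mqtl_effect,
            covariates,
            cov_effects,
            cfg.noise_sd,
            int(rng.integers(2**31)),
            n_null_cpgs=cfg.n_null_cpgs,
        )
    mqtl_cohort = CohortBundle(
        genotypes=mqtl_panel, methylation=meth, covariates=covariates,
        phenotype=None, truth=cfg,
    )

    # --- GWAS case-control cohort --------------------------------------
    n_cases = cfg.n_individuals // 4
    n_controls = cfg.n_individuals - n_cases
    gwas = simulate_case_control_cohort(
        pool, cfg, n_cases, n_controls, int(rng.integers(2**31)),
        causal_snp_index=causal_idx,
        disease_snp_index=disease_idx,
        background_indices=background,
    )

    # --- trios ----------------------------------------------------------
    trios = simulate_trios(
        pool, cfg, cfg.n_trios, int(rng.integers(2**31)),
        causal_snp_index=causal_idx,
        disease_snp_index=disease_idx,
        background_indices=background,
    )

    # --- truth tables ---------------------------------------------------
    roles = np.array(["none"] * pool.n_snps, dtype=object)
    if cfg.model in ("mediation", "linkage", "pleiotropy") or (
        cfg.model == "null" and cfg.mqtl_effect != 0
    ):
        roles[causal_idx] = "mqtl_causal"
    if cfg.model == "pleiotropy":
        roles[causal_idx] = "mqtl_and_disease_causal"
    if cfg.model == "linkage":
        roles[disease_idx] = "disease_causal"
    if cfg.model != "null":
        for j in background:
            roles[j] = "background_disease"
    snp_truth = pool.snp_table().assign(role=roles)
    cpg_truth = pd.DataFrame(
        {
            "cpg_id": meth.cpg_ids,
            "pos": meth.cpg_positions.loc[meth.cpg_ids].to_numpy(),
            "causal": [c == "cg_causal" and cfg.model != "null" for c in meth.cpg_ids],
        }
    )
    return ScenarioBundle(
        pool=pool, gwas=gwas, mqtl_cohort=mqtl_cohort, trios=trios,
        snp_truth=snp_truth, cpg_truth=cpg_truth, config=cfg,
    )


# ---------------------------------------------------------------------------
# liability -> log-odds reference (the measured attenuation/scale factor)
# ---------------------------------------------------------------------------


def expected_case_control_logodds(
    scenario: ScenarioConfig, case_fraction: float = 0.25
) -> float:
    """Asymptotic per-allele log-OR a case-control logistic regression of
    disease on the mQTL-SNP dosage converges to, under the mediation model.

    The liability-threshold model implies probit-scale cell risks: given
    genotype g and the (centered, discrete) background polygenic score, the
    residual liability is exactly normal, so P(D=1 | G=g) is a binomial
    mixture of probit terms over the background allele count. Case-control
    ascertainment re-weights the three genotype cells; the two-parameter
    logistic MLE on those exact cell probabilities is found by Newton
    iteration. Dividing by the normalized exposure effect e_G / s_M gives
    the reference value for the forward-MR estimand, i.e. the empirically
    measured liability->log-odds scale factor times the liability effect.
    """
    if scenario.model != "mediation":
        raise ParameterError("reference log-odds is defined for the mediation model")
    p = scenario.maf
    mu_m, sd_m = _methylation_pop_moments(scenario)
    t = stats.norm.ppf(1 - scenario.prevalence)
    s_resid = np.sqrt(
        1.0 + (scenario.methylation_to_liability * scenario.noise_sd / sd_m) ** 2
    )
    g = np.array([0.0, 1.0, 2.0])
    hwe = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    shift = scenario.methylation_to_liability * scenario.mqtl_effect * (g - 2 * p) / sd_m
    # exact distribution of the centered background score: allele count over
    # n_bg SNPs is Binomial(2 * n_bg, p)
    n_alleles = 2 * scenario.n_background_snps
    k = np.arange(n_alleles + 1)
    pmf = stats.binom.pmf(k, n_alleles, p)
    bg_vals = scenario.background_snp_effect * (k - n_alleles * p)
    risk = np.array(
        [
            float(np.sum(pmf * stats.norm.cdf((s + bg_vals - t) / s_resid)))
            for s in shift
        ]
    )
    # ascertained joint cell weights: cases re-weighted to case_fraction
    p_case = hwe * risk
    p_ctrl = hwe * (1 - risk)
    w_case = case_fraction * p_case / p_case.sum()
    w_ctrl = (1 - case_fraction) * p_ctrl / p_ctrl.sum()
    # two-parameter logistic MLE on exact cell probabilities (Newton)
    beta = np.zeros(2)
    X = np.column_stack([np.ones(3), g])
    for _ in range(100):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = w_case + w_ctrl
        grad = X.T @ (w_case - w * mu)
        hess = -(X * (w * mu * (1 - mu))[:, None]).T @ X
        step = np.linalg.solve(hess, grad)
        beta = beta - step
        if np.max(np.abs(step)) < 1e-12:
            break
    return float(beta[1])
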