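"""Bidirectional two-sample Mendelian randomization.

Forward direction: methylation (instrumented by its mQTL) -> disease
liability, via the Wald ratio for single-instrument CpGs, inverse-variance
weighting (IVW) for multi-instrument CpGs, and a correlated-instrument
generalized-least-squares re-test that accounts for LD between instruments.
Reverse direction: disease liability (instrumented by independent
genome-wide-significant disease SNPs) -> methylation, via IVW.

Conventions: first-order delta-method standard errors (no
exposure-uncertainty term), fixed-effect SEs, two-sided normal p-values.
The LD matrix enters as signed correlation r, not r^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import harmonize_alleles, normal_p, ridge_stabilize

__all__ = [
    "InstrumentSet",
    "MRResult",
    "harmonize",
    "wald_ratio",
    "ivw",
    "ivw_correlated",
    "reverse_mr",
    "bonferroni_threshold",
]


class MRError(ValueError):
    pass


@dataclass
class InstrumentSet:
    """Harmonized exposure/outcome effects for one MR test."""

    exposure_name: str
    outcome_name: str
    table: pd.DataFrame          # snp_id, beta_exposure, se_exposure,
                                 # beta_outcome, se_outcome, effect_allele
    ld: pd.DataFrame | None = None   # signed r over the instruments

    def __post_init__(self) -> None:
        required = {"snp_id", "beta_exposure", "se_exposure", "beta_outcome", "se_outcome"}
        missing = required - set(self.table.columns)
        if missing:
            raise MRError(f"instrument table missing columns: {sorted(missing)}")
        if len(self.table) < 1:
            raise MRError("instrument set must contain at least one instrument")
        if (self.table["se_exposure"] <= 0).any() or (self.table["se_outcome"] <= 0).any():
            raise MRError("instrument standard errors must be positive")

    @property
    def n_instruments(self) -> int:
        return len(self.table)


@dataclass
class MRResult:
    exposure: str
    outcome: str
    method: str                  # wald | ivw | ivw_ld
    n_instruments: int
    beta: float
    se: float
    p: float
    direction: str = "forward"   # forward | reverse

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "exposure": self.exposure, "outcome": self.outcome,
                "method": self.method, "n_instruments": self.n_instruments,
                "beta": self.beta, "se": self.se, "p": self.p,
                "direction": self.direction,
            }
        )


def harmonize(
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    *,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    ld: pd.DataFrame | None = None,
) -> tuple[InstrumentSet, pd.DataFrame]:
    """Build an instrument set on a shared effect-allele convention.

    Outcome betas are sign-flipped where effect alleles are swapped; strand
    flips resolved via complement; ambiguous palindromic SNPs dropped.
    Returns the instrument set and the drop log. Raises when no instruments
    survive.
    """
    harm, drop_log = harmonize_alleles(exposure_stats, outcome_stats)
    merged = exposure_stats.merge(
        harm[["snp_id", "beta", "se"]].rename(
            columns={"beta": "beta_outcome", "se": "se_outcome"}
        ),
        on="snp_id",
    )
    if merged.empty:
        raise MRError("no shared instruments after harmonization")
    table = merged.rename(columns={"beta": "beta_exposure", "se": "se_exposure"})[
        ["snp_id", "beta_exposure", "se_exposure", "beta_outcome", "se_outcome",
         "effect_allele"]
    ]
    sub_ld = None
    if ld is not None:
        ids = [s for s in table["snp_id"] if s in ld.index]
        table = table[table["snp_id"].isin(ids)].reset_index(drop=True)
        if table.empty:
            raise MRError("no shared instruments present in the LD matrix")
        sub_ld = ld.loc[list(table["snp_id"]), list(table["snp_id"])]
    return (
        InstrumentSet(exposure_name, outcome_name, table.reset_index(drop=True), sub_ld),
        drop_log,
    )


def wald_ratio(instruments: InstrumentSet, *, direction: str = "forward") -> MRResult:
    """Single-instrument MR: beta_outcome / beta_exposure with the
    first-order delta-method SE se_outcome / |beta_exposure|."""
    if instruments.n_instruments != 1:
        raise MRError("wald_ratio requires exactly one instrument")
    row = instruments.table.iloc[0]
    if row["beta_exposure"] == 0:
        raise MRError("exposure effect is zero: Wald ratio undefined")
    beta = float(row["beta_outcome"] / row["beta_exposure"])
    se = float(row["se_outcome"] / abs(row["beta_exposure"]))
    return MRResult(
        exposure=instruments.exposure_name, outcome=instruments.outcome_name,
        method="wald", n_instruments=1,
        beta=beta, se=se, p=float(normal_p(beta, se)), direction=direction,
    )


def ivw(instruments: InstrumentSet, *, direction: str = "forward") -> MRResult:
    """Inverse-variance-weighted MR: per-instrument Wald ratios combined
    with weights 1/se_j^2 (first-order SEs); algebraically a zero-intercept
    weighted regression of outcome betas on exposure betas with weights
    1/se_outcome^2, with the fixed-effect SE."""
    if instruments.n_instruments == 1:
        return wald_ratio(instruments, direction=direction)
    t = instruments.table
    if (t["beta_exposure"] == 0).any():
        raise MRError("zero exposure effect among instruments")
    x = t["beta_exposure"].to_numpy(dtype=float)
    y = t["beta_outcome"].to_numpy(dtype=float)
    w = 1.0 / t["se_outcome"].to_numpy(dtype=float) ** 2
    xwx = float(np.sum(w * x * x))
    beta = float(np.sum(w * x * y) / xwx)
    se = float(np.sqrt(1.0 / xwx))
    return MRResult(
        exposure=instruments.exposure_name, outcome=instruments.outcome_name,
        method="ivw", n_instruments=len(t),
        beta=beta, se=se, p=float(normal_p(beta, se)), direction=direction,
    )


def ivw_correlated(instruments: InstrumentSet, *, ridge: float = 1e-6,
                   direction: str = "forward") -> MRResult:
    """LD-aware MR re-test by generalized least squares.

    With x the exposure betas, y the outcome betas, S = diag(se_outcome) and
    rho the signed instrument LD matrix, Omega = S rho S and
    beta = (x' Omega^-1 x)^-1 x' Omega^-1 y, se = sqrt((x' Omega^-1 x)^-1).
    This is the maximizer of the multivariate-normal likelihood
    y ~ N(x beta, Omega), i.e. the closed form of the likelihood-based
    correlated-instrument method. rho is ridge-stabilized before inversion.
    """
    if instruments.ld is None:
        raise MRError("ivw_correlated requires an LD matrix over the instruments")
    t = instruments.table
    if list(instruments.ld.index) != list(t["snp_id"]):
        raise MRError("LD matrix rows must match the instrument order")
    x = t["beta_exposure"].to_numpy(dtype=float)
    y = t["beta_outcome"].to_numpy(dtype=float)
    s = t["se_outcome"].to_numpy(dtype=float)
    rho = ridge_stabilize(instruments.ld.to_numpy(), ridge)
    omega = rho * np.outer(s, s)
    try:
        omega_inv = np.linalg.inv(omega)
    except np.linalg.LinAlgError as exc:
        raise MRError("instrument covariance is singular even after ridge") from exc
    xox = float(x @ omega_inv @ x)
    if xox <= 0:
        raise MRError("degenerate exposure effects in GLS")
    beta = float(x @ omega_inv @ y / xox)
    se = float(np.sqrt(1.0 / xox))
    return MRResult(
        exposure=instruments.exposure_name, outcome=instruments.outcome_name,
        method="ivw_ld", n_instruments=len(t),
        beta=beta, se=se, p=float(normal_p(beta, se)), direction=direction,
    )


def reverse_mr(
    disease_instruments: pd.DataFrame,
    mqtl_outcome_stats: pd.DataFrame,
    *,
    exposure_name: str = "disease_liability",
    outcome_name: str = "methylation",
) -> MRResult:
    """Reverse-direction MR: disease liability as exposure (independent
    genome-wide-significant disease SNPs), methylation as outcome, combined
    by IVW (Wald ratio when a single instrument survives)."""
    instruments, _ = harmonize(
        disease_instruments, mqtl_outcome_stats,
        exposure_name=exposure_name, outcome_name=outcome_name,
    )
    return ivw(instruments, direction="reverse")


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise error control: per-test threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise MRError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise MRError("n_tests must be at least 1")
    return alpha / n_tests


def correlated_loglik(beta: float, instruments: InstrumentSet, ridge: float = 1e-6) -> float:
    """Log-likelihood of the correlated-instrument model y ~ N(x beta,
    S rho S) at a given causal effect; used as the numerical cross-check
    that `ivw_correlated`'s closed form maximizes it."""
    t = instruments.table
    x = t["beta_exposure"].to_numpy(dtype=float)
    y = t["beta_outcome"].to_numpy(dtype=float)
    s = t["se_outcome"].to_numpy(dtype=float)
    rho = ridge_stabilize(instruments.ld.to_numpy(), ridge)
    omega = rho * np.outer(s, s)
    return float(stats.multivariate_normal.logpdf(y, mean=x * beta, cov=omega))
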