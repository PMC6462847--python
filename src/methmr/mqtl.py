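"""cis-mQTL scanning: rank-based inverse-normal transform, covariate
residualization, windowed SNP-CpG regression and probe filtering.

The recipe is the standard two-stage one for array methylation: per CpG,
rank-normalize the beta-values, regress out sex, ancestry PCs, batch and
cell proportions, then regress the residuals on each SNP dosage within a
cis window (1 Mb by default, boundary inclusive) and keep associations
below the significance cutoff (1e-7 by default).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import GenotypePanel, covariate_design

__all__ = [
    "inverse_normal_transform",
    "residualize",
    "snp_cpg_assoc",
    "cis_scan",
    "filter_probes",
    "MQTL_COLUMNS",
]

MQTL_COLUMNS = ["cpg_id", "cpg_chrom", "cpg_pos", "snp_id", "snp_pos",
                "distance", "beta", "se", "p"]

CIS_WINDOW_BP = 1_000_000
MQTL_P_THRESHOLD = 1e-7


class MqtlError(ValueError):
    pass


def inverse_normal_transform(values: np.ndarray | pd.Series) -> np.ndarray:
    """Rank-based inverse normal: Phi^-1((rank - 0.5)/n), average ranks for
    ties. Invariant to any strictly monotone transform of the input; output
    has mean ~0 and SD ~1."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or np.sum(np.isfinite(x)) < 3:
        raise MqtlError("inverse-normal transform needs at least 3 finite values")
    if np.nanmax(x) == np.nanmin(x):
        raise MqtlError("all values identical: no rank information")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(x))


def residualize(y: np.ndarray, covariate_table: pd.DataFrame) -> np.ndarray:
    """OLS residuals of y on the covariate design (intercept always
    included; one batch level and one cell-proportion column dropped).

    Raises on rank deficiency, naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    design = covariate_design(covariate_table, add_intercept=True)
    X = design.to_numpy()
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy QR-style elimination
        bad = []
        keep: list[int] = []
        for j in range(X.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(X[:, trial]) < len(trial):
                bad.append(design.columns[j])
            else:
                keep.append(j)
        raise MqtlError(f"covariate design is rank deficient; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def _fast_simple_regression(y: np.ndarray, G: np.ndarray):
    """Vectorized simple linear regression of y on each column of G.

    Returns (slope, se, p) arrays; p is two-sided normal on slope/se.
    Columns with zero variance get NaN slope and infinite SE.
    """
    n = len(y)
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = gc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        ssr = np.einsum("i,i->", yc, yc) - slope * sxy
        sigma2 = np.maximum(ssr, 0.0) / max(n - 2, 1)
        se = np.sqrt(sigma2 / sxx)
    slope = np.where(sxx > 0, slope, np.nan)
    se = np.where(sxx > 0, se, np.inf)
    with np.errstate(invalid="ignore"):
        p = 2 * stats.norm.sf(np.abs(slope / se))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return slope, se, p


def snp_cpg_assoc(
    panel: GenotypePanel,
    residual_methylation: np.ndarray,
    cpg_id: str,
    cpg_pos: int,
    snp_ids: Sequence[str],
    *,
    cpg_chrom: str = "1",
) -> pd.DataFrame:
    """Association of one CpG's residualized methylation with named SNPs,
    regardless of distance (used e.g. for reverse-MR outcome statistics)."""
    cols = [panel.index_of(s) for s in snp_ids]
    G = panel.dosages[:, cols]
    slope, se, p = _fast_simple_regression(np.asarray(residual_methylation, float), G)
    pos = panel.snps["pos"].iloc[cols].to_numpy()
    return pd.DataFrame(
        {
            "cpg_id": cpg_id, "cpg_chrom": cpg_chrom, "cpg_pos": cpg_pos,
            "snp_id": list(snp_ids), "snp_pos": pos,
            "distance": np.abs(pos - cpg_pos),
            "beta": slope, "se": se, "p": p,
        }
    )


def cis_scan(
    panel: GenotypePanel,
    residual_methylation: pd.DataFrame,
    cpg_positions: pd.Series,
    window_bp: int = CIS_WINDOW_BP,
    p_threshold: float = MQTL_P_THRESHOLD,
    *,
    cpg_chrom: str = "1",
) -> pd.DataFrame:
    """cis-mQTL scan: for each CpG, regress its residualized methylation on
    every SNP within ``window_bp`` (inclusive at exactly the boundary) and
    emit records with p below ``p_threshold``.

    ``residual_methylation`` holds one column per CpG, already
    rank-normalized and residualized; trans pairs (distance > window) are
    never tested, mirroring a 1 Mb trans-exclusion rule.
    """
    if window_bp <= 0:
        raise MqtlError("window_bp must be positive")
    snp_pos = panel.snps["pos"].to_numpy()
    records = []
    for cpg_id in residual_methylation.columns:
        cpos = int(cpg_positions.loc[cpg_id])
        in_window = np.abs(snp_pos - cpos) <= window_bp
        if not in_window.any():
            continue
        G = panel.dosages[:, in_window]
        y = residual_methylation[cpg_id].to_numpy()
        slope, se, p = _fast_simple_regression(y, G)
        hit = p < p_threshold
        if not hit.any():
            continue
        ids = np.asarray(panel.snp_ids)[in_window][hit]
        pos = snp_pos[in_window][hit]
        records.append(
            pd.DataFrame(
                {
                    "cpg_id": cpg_id, "cpg_chrom": cpg_chrom, "cpg_pos": cpos,
                    "snp_id": ids, "snp_pos": pos,
                    "distance": np.abs(pos - cpos),
                    "beta": slope[hit], "se": se[hit], "p": p[hit],
                }
            )
        )
    if not records:
        return pd.DataFrame(columns=MQTL_COLUMNS)
    return pd.concat(records, ignore_index=True)[MQTL_COLUMNS]


def filter_probes(records: pd.DataFrame, flagged_probe_list: Sequence[str]) -> pd.DataFrame:
    """Remove records whose CpG is on the flagged-probe list (e.g.
    cross-hybridizing probes); returns the surviving records."""
    flagged = set(flagged_probe_list)
    if not flagged:
        return records.copy()
    keep = ~records["cpg_id"].isin(flagged)
    return records[keep].reset_index(drop=True)


def prepare_methylation(
    beta_values: pd.DataFrame, covariates: pd.DataFrame | None
) -> pd.DataFrame:
    """Rank-normalize each CpG column and residualize on covariates (when
    provided): the standard preprocessing before ``cis_scan``."""
    out = {}
    for cpg in beta_values.columns:
        y = inverse_normal_transform(beta_values[cpg].to_numpy())
        if covariates is not None:
            y = residualize(y, covariates)
        out[cpg] = y
    return pd.DataFrame(out, index=beta_values.index)
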