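"""Per-locus causal-model calls and follow-up statistics.

The classifier combines three pieces of evidence for each CpG-SNP locus —
forward MR (methylation -> disease), reverse MR (disease liability ->
methylation) and colocalization — into one of five labels via an explicit
decision table (gates evaluated in order):

1. forward MR not significant           -> ``no_signal``
2. reverse MR significant               -> ``reverse_causation``
3. colocalization undefined (sentinel)  -> ``indeterminate``
4. colocalization not significant       -> ``linkage``
5. otherwise                            -> ``putative_mediation_or_pleiotropy``

A "mediation" call is always labelled ``putative_mediation_or_pleiotropy``:
with mostly single-instrument CpGs, vertical mediation cannot be separated
from horizontal pleiotropy, and the label says so.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coloc import ColocResult, UNDEFINED_STATISTIC
from .mr import MRResult, bonferroni_threshold

__all__ = [
    "Thresholds",
    "TriangulationCall",
    "classify_locus",
    "replication_check",
    "cross_tissue_correlation",
    "subtype_anova",
    "build_report",
    "read_report",
]

LABELS = (
    "putative_mediation_or_pleiotropy",
    "reverse_causation",
    "linkage",
    "no_signal",
    "indeterminate",
)


class TriangulationError(ValueError):
    pass


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds. The forward threshold defaults to a Bonferroni
    correction over the number of CpGs tested; reverse and colocalization
    gates use nominal 0.05 (the conservative direction for mediation
    claims)."""

    forward: float = 0.05
    reverse: float = 0.05
    coloc: float = 0.05

    @classmethod
    def with_bonferroni(cls, n_cpgs: int, alpha: float = 0.05) -> "Thresholds":
        return cls(forward=bonferroni_threshold(alpha, n_cpgs))


@dataclass
class TriangulationCall:
    cpg_id: str
    snp_id: str
    forward: MRResult
    reverse: MRResult | None
    coloc: ColocResult | None
    label: str
    notes: str = ""


def classify_locus(
    cpg_id: str,
    snp_id: str,
    forward: MRResult,
    reverse: MRResult | None,
    coloc: ColocResult | None,
    thresholds: Thresholds,
) -> TriangulationCall:
    """Apply the decision table; see the module docstring for the gates."""
    notes = []
    if not np.isfinite(forward.p) or forward.p >= thresholds.forward:
        label = "no_signal"
    elif reverse is not None and np.isfinite(reverse.p) and reverse.p < thresholds.reverse:
        label = "reverse_causation"
        notes.append("reverse-MR gate is power-limited; interpret with caution")
    elif coloc is None or coloc.status == UNDEFINED_STATISTIC:
        label = "indeterminate"
        if coloc is not None and coloc.reason:
            notes.append(coloc.reason)
    elif coloc.p_permutation is None or coloc.p_permutation >= thresholds.coloc:
        label = "linkage"
    else:
        label = "putative_mediation_or_pleiotropy"
        notes.append("single-instrument MR cannot separate mediation from pleiotropy")
    return TriangulationCall(
        cpg_id=cpg_id, snp_id=snp_id, forward=forward, reverse=reverse,
        coloc=coloc, label=label, notes="; ".join(notes),
    )


def replication_check(
    discovery_records: pd.DataFrame, replication_records: pd.DataFrame
) -> pd.DataFrame:
    """Concordance between discovery and replication mQTL effects.

    Pairs are matched on (cpg_id, snp_id); a pair is concordant when the
    replication effect has the same sign as the discovery effect and a
    replication p-value below 0.05. Unmatched pairs are dropped.
    """
    merged = discovery_records.merge(
        replication_records, on=["cpg_id", "snp_id"], suffixes=("_disc", "_repl")
    )
    out = pd.DataFrame(
        {
            "cpg_id": merged["cpg_id"],
            "snp_id": merged["snp_id"],
            "discovery_beta": merged["beta_disc"],
            "replication_beta": merged["beta_repl"],
            "replication_p": merged["p_repl"],
        }
    )
    out["concordant"] = (
        np.sign(out["discovery_beta"]) == np.sign(out["replication_beta"])
    ) & (out["replication_p"] < 0.05)
    return out


def cross_tissue_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Pearson correlation with a 95% Fisher-z confidence interval:
    tanh(atanh(r) +- 1.96/sqrt(n-3))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise TriangulationError("need at least 4 paired finite values")
    if x.std() == 0 or y.std() == 0:
        raise TriangulationError("zero variance in one of the vectors")
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    if abs(r) >= 1.0 - 1e-12:
        r = float(np.sign(r))
        return r, r, r
    z = np.arctanh(r)
    half = 1.96 / np.sqrt(len(x) - 3)
    return r, float(np.tanh(z - half)), float(np.tanh(z + half))


def subtype_anova(
    methylation_vector: np.ndarray,
    subtype_labels: np.ndarray | pd.Series,
    covariate_table: pd.DataFrame | None = None,
) -> tuple[float, float]:
    """Covariate-adjusted one-way ANOVA across cleft subtypes.

    Extra-sum-of-squares F-test comparing the linear model
    covariates + subtype against covariates only, on (k-1, n - p_full)
    degrees of freedom. With no covariates this reduces to the textbook
    one-way ANOVA F.
    """
    y = np.asarray(methylation_vector, dtype=float)
    labels = pd.Series(np.asarray(subtype_labels)).astype(str)
    levels = sorted(labels.unique())
    if len(levels) < 2:
        raise TriangulationError("need at least 2 subtype groups")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise TriangulationError("every subtype group needs at least 2 members")
    n = len(y)
    base_cols = [np.ones(n)]
    if covariate_table is not None:
        from .simdata import covariate_design

        base_cols.append(covariate_design(covariate_table).to_numpy())
    X0 = np.column_stack(base_cols)
    dummies = np.column_stack([(labels == lv).to_numpy(float) for lv in levels[1:]])
    X1 = np.column_stack([X0, dummies])
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise TriangulationError("rank-deficient design (covariates confounded with subtype)")
    rss0 = float(np.sum((y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]) ** 2))
    rss1 = float(np.sum((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]) ** 2))
    df1 = len(levels) - 1
    df2 = n - X1.shape[1]
    f = ((rss0 - rss1) / df1) / (rss1 / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), p


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "snp_id", "cpg_id",
    "forward_beta", "forward_se", "forward_p", "forward_method", "forward_n_snps",
    "reverse_beta", "reverse_se", "reverse_p",
    "coloc_statistic", "coloc_p", "coloc_n_perm", "coloc_note",
    "label", "notes",
]


def build_report(
    calls: list[TriangulationCall],
    out_tsv: str | None = None,
    metadata: dict | None = None,
    out_meta: str | None = None,
) -> pd.DataFrame:
    """Results table shaped like a per-locus triangulation summary: one row
    per CpG-SNP call with forward/reverse MR effects, the colocalization
    statistic (``N/A`` plus a note code when the statistic was undefined)
    and the assigned label. Optionally written as TSV with a JSON metadata
    sidecar."""
    rows = []
    for c in calls:
        coloc_stat: object = "N/A"
        coloc_p: object = "N/A"
        n_perm = 0
        note = ""
        if c.coloc is not None and c.coloc.status != UNDEFINED_STATISTIC:
            coloc_stat = c.coloc.statistic
            coloc_p = c.coloc.p_permutation
            n_perm = c.coloc.n_permutations
        elif c.coloc is not None:
            note = c.coloc.reason or "undefined"
        rows.append(
            {
                "snp_id": c.snp_id, "cpg_id": c.cpg_id,
                "forward_beta": c.forward.beta, "forward_se": c.forward.se,
                "forward_p": c.forward.p, "forward_method": c.forward.method,
                "forward_n_snps": c.forward.n_instruments,
                "reverse_beta": c.reverse.beta if c.reverse else np.nan,
                "reverse_se": c.reverse.se if c.reverse else np.nan,
                "reverse_p": c.reverse.p if c.reverse else np.nan,
                "coloc_statistic": coloc_stat, "coloc_p": coloc_p,
                "coloc_n_perm": n_perm, "coloc_note": note,
                "label": c.label, "notes": c.notes,
            }
        )
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if out_tsv is not None:
        report.to_csv(out_tsv, sep="\t", index=False)
    if out_meta is not None:
        with open(out_meta, "w") as fh:
            json.dump(metadata or {}, fh, indent=2, sort_keys=True)
    return report


def read_report(path: str) -> pd.DataFrame:
    """Round-trip reader for the triangulation report TSV (the literal cell
    value ``N/A`` marks an undefined colocalization statistic and survives
    the round trip)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    numeric = ["forward_beta", "forward_se", "forward_p", "forward_n_snps",
               "reverse_beta", "reverse_se", "reverse_p", "coloc_n_perm"]
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("coloc_statistic", "coloc_p"):
        df[col] = df[col].apply(lambda v: v if v == "N/A" else float(v))
    return df
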