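"""GWAS-style summary statistics: TDT, case-control logistic association,
fixed-effects meta-analysis, LD matrices and greedy clumping.

Summary statistics live in pandas DataFrames with the column contract
``snp_id, chrom, pos, effect_allele, other_allele, beta, se, p, eaf, n``
(beta on the log-odds scale per effect allele). ``p`` is derived from
``beta/se`` under a two-sided normal so records stay self-consistent;
the TDT additionally carries the classic McNemar chi-square and its
chi-square p-value in ``chisq`` / ``p_chisq``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import GenotypePanel, TrioSet, covariate_design

__all__ = [
    "SUMMARY_COLUMNS",
    "normal_p",
    "validate_summary_stats",
    "tdt_counts",
    "tdt_test",
    "tdt_scan",
    "case_control_assoc",
    "harmonize_alleles",
    "fixed_effect_meta",
    "compute_ld",
    "clump",
]

SUMMARY_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "p", "eaf", "n",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


class AssociationError(ValueError):
    pass


def normal_p(beta: np.ndarray | float, se: np.ndarray | float) -> np.ndarray | float:
    """Two-sided normal p-value from an estimate and its standard error."""
    z = np.abs(np.asarray(beta, dtype=float) / np.asarray(se, dtype=float))
    p = 2 * stats.norm.sf(z)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def validate_summary_stats(df: pd.DataFrame, *, check_p: bool = True) -> None:
    """Raise on violated summary-statistic invariants."""
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise AssociationError(f"summary statistics missing columns: {missing}")
    if df["snp_id"].duplicated().any():
        dups = df.loc[df["snp_id"].duplicated(), "snp_id"].tolist()
        raise AssociationError(f"duplicate snp_id values: {dups[:5]}")
    if (df["se"] <= 0).any():
        raise AssociationError("all standard errors must be positive")
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        raise AssociationError("p-values must lie in (0, 1]")
    bad = ~df["effect_allele"].isin(list("ACGT")) | ~df["other_allele"].isin(list("ACGT"))
    if bad.any():
        raise AssociationError("alleles must be single bases A/C/G/T")
    if check_p:
        expected = normal_p(df["beta"].to_numpy(), df["se"].to_numpy())
        obs = df["p"].to_numpy()
        mask = (obs > np.finfo(float).tiny * 10) & (expected > np.finfo(float).tiny * 10)
        rel = np.abs(np.log(obs[mask]) - np.log(expected[mask]))
        if mask.any() and np.nanmax(rel) > 1e-6:
            raise AssociationError("p-values inconsistent with beta/se under the normal")


# ---------------------------------------------------------------------------
# transmission disequilibrium test
# ---------------------------------------------------------------------------


def tdt_counts(trios: TrioSet, snp_id: str) -> tuple[int, int]:
    """Transmission (b) and non-transmission (c) counts of the effect allele
    from heterozygous parents to affected children.

    Homozygous parents are uninformative. For trios with both parents
    observed the standard genotype bookkeeping applies (double-heterozygote
    families contribute via the child genotype). Duos (one parent masked)
    contribute nothing: with the second parent unknown, the observed
    heterozygous parent's transmission is only determined when the child is
    homozygous, and conditioning on that event is biased toward the major
    allele (P(child hom-alt) = p/2 vs P(child hom-ref) = q/2 under the
    null); an unbiased single-parent test needs the 1-TDT correction, which
    is out of scope here.
    """
    idx = trios.snps.index[trios.snps["snp_id"] == snp_id]
    if len(idx) == 0:
        raise AssociationError(f"SNP {snp_id!r} not present in trio set")
    j = int(idx[0])
    f = trios.father[:, j]
    m = trios.mother[:, j]
    c = trios.child[:, j]
    fo = trios.father_observed
    mo = trios.mother_observed

    b = 0.0
    cc = 0.0
    both = fo & mo
    f_het = f == 1
    m_het = m == 1
    # full trios: transmitted allele from each het parent is child dosage
    # minus the other parent's (determined) transmission
    t_from_f = np.where(m_het, np.nan, c - m / 2)   # defined when mother homozygous
    t_from_m = np.where(f_het, np.nan, c - f / 2)
    mask = both & f_het & ~m_het
    b += np.nansum(np.where(mask, t_from_f, 0.0))
    cc += np.nansum(np.where(mask, 1 - t_from_f, 0.0))
    mask = both & m_het & ~f_het
    b += np.nansum(np.where(mask, t_from_m, 0.0))
    cc += np.nansum(np.where(mask, 1 - t_from_m, 0.0))
    # double heterozygote: child dosage g implies g transmissions of the
    # effect allele and 2-g non-transmissions
    mask = both & f_het & m_het
    b += np.sum(np.where(mask, c, 0.0))
    cc += np.sum(np.where(mask, 2 - c, 0.0))
    return int(round(b)), int(round(cc))


def tdt_test(b: int, c: int) -> pd.Series:
    """TDT record from transmission counts.

    chi-square = (b-c)^2/(b+c) on 1 df; the meta-analysis-compatible effect
    is beta = ln(b/c) with se = sqrt(1/b + 1/c) (Haldane +0.5 applied to
    both counts when either is zero). ``p`` is the two-sided normal p-value
    from beta/se; the chi-square p-value is kept alongside in ``p_chisq``.
    """
    if b + c <= 0:
        raise AssociationError("TDT requires at least one informative transmission")
    chisq = (b - c) ** 2 / (b + c)
    p_chisq = float(stats.chi2.sf(chisq, df=1))
    bb, cc = (b + 0.5, c + 0.5) if (b == 0 or c == 0) else (float(b), float(c))
    beta = float(np.log(bb / cc))
    se = float(np.sqrt(1 / bb + 1 / cc))
    return pd.Series(
        {
            "b": b, "c": c,
            "chisq": float(chisq), "p_chisq": p_chisq,
            "beta": beta, "se": se, "p": float(normal_p(beta, se)),
        }
    )


def tdt_scan(trios: TrioSet, *, min_informative: int = 1, n: int | None = None) -> pd.DataFrame:
    """TDT across all SNPs in a trio set, as a summary-statistics table.

    SNPs with fewer informative transmissions than ``min_informative`` are
    flagged (``excluded=True``) and carry NaN statistics.
    """
    rows = []
    eff_n = n if n is not None else trios.n_trios
    for _, snp in trios.snps.iterrows():
        bb, cc = tdt_counts(trios, snp["snp_id"])
        rec = {
            "snp_id": snp["snp_id"], "chrom": snp["chrom"], "pos": snp["pos"],
            "effect_allele": snp["effect_allele"], "other_allele": snp["other_allele"],
            "eaf": snp.get("maf", np.nan), "n": eff_n,
        }
        if bb + cc < min_informative or bb + cc == 0:
            rec.update(beta=np.nan, se=np.nan, p=np.nan, chisq=np.nan,
                       p_chisq=np.nan, b=bb, c=cc, excluded=True)
        else:
            t = tdt_test(bb, cc)
            rec.update(beta=t["beta"], se=t["se"], p=t["p"], chisq=t["chisq"],
                       p_chisq=t["p_chisq"], b=bb, c=cc, excluded=False)
        rows.append(rec)
    df = pd.DataFrame(rows)
    return df[SUMMARY_COLUMNS + ["chisq", "p_chisq", "b", "c", "excluded"]]


# ---------------------------------------------------------------------------
# case-control logistic association
# ---------------------------------------------------------------------------


def case_control_assoc(
    panel: GenotypePanel,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | None = None,
    *,
    snp_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-SNP logistic regression of disease on dosage (+ covariates).

    Returns one summary-statistic row per SNP; monomorphic SNPs and fits
    with perfect separation are flagged ``excluded=True`` with an
    infinite-SE sentinel and must be dropped downstream.
    """
    import statsmodels.api as sm

    phenotype = np.asarray(phenotype)
    if phenotype.sum() == 0 or phenotype.sum() == len(phenotype):
        raise AssociationError("need at least one case and one control")
    if np.isnan(panel.dosages).any():
        raise AssociationError("missing dosages are not supported")

    cov = None
    if covariates is not None:
        cov = covariate_design(covariates).to_numpy()
    ids = snp_ids if snp_ids is not None else panel.snp_ids
    n = panel.n_individuals
    rows = []
    for snp_id in ids:
        j = panel.index_of(snp_id)
        g = panel.dosages[:, j]
        meta = panel.snps.iloc[j]
        rec = {
            "snp_id": snp_id, "chrom": meta["chrom"], "pos": meta["pos"],
            "effect_allele": meta["effect_allele"], "other_allele": meta["other_allele"],
            "eaf": float(g.mean() / 2), "n": n,
        }
        if np.ptp(g) == 0:
            rec.update(beta=np.nan, se=np.inf, p=np.nan, excluded=True,
                       exclusion_reason="monomorphic")
            rows.append(rec)
            continue
        X = np.column_stack([np.ones(n), g] if cov is None else [np.ones(n), g, cov])
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(phenotype, X).fit(disp=0, maxiter=100)
            beta, se = float(fit.params[1]), float(fit.bse[1])
            if not np.isfinite(se) or se > 50 or not fit.mle_retvals.get("converged", True):
                raise AssociationError("separation")
            rec.update(beta=beta, se=se, p=float(normal_p(beta, se)),
                       excluded=False, exclusion_reason="")
        except Exception:
            rec.update(beta=np.nan, se=np.inf, p=np.nan, excluded=True,
                       exclusion_reason="perfect_separation")
        rows.append(rec)
    df = pd.DataFrame(rows)
    return df[SUMMARY_COLUMNS + ["excluded", "exclusion_reason"]]


# ---------------------------------------------------------------------------
# allele harmonization and fixed-effects meta-analysis
# ---------------------------------------------------------------------------


def harmonize_alleles(
    ref: pd.DataFrame,
    other: pd.DataFrame,
    *,
    palindromic_eaf_band: tuple[float, float] = (0.42, 0.58),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align ``other`` onto ``ref``'s effect-allele convention.

    Resolution order per shared SNP: exact allele match (keep), swapped
    alleles (negate beta, flip eaf), strand flip via complement (keep),
    strand flip + swap (negate). Palindromic SNPs (A/T or C/G) are dropped
    when the reference EAF is missing or inside the ambiguity band;
    irreconcilable allele sets are dropped. Returns the harmonized table and
    a drop log (snp_id, reason).
    """
    merged = ref.merge(other, on="snp_id", suffixes=("_ref", "_oth"))
    out_rows, drops = [], []
    for _, r in merged.iterrows():
        ea_r, oa_r = r["effect_allele_ref"], r["other_allele_ref"]
        ea_o, oa_o = r["effect_allele_oth"], r["other_allele_oth"]
        if frozenset((ea_r, oa_r)) in _PALINDROMIC:
            eaf = r.get("eaf_ref", np.nan)
            lo, hi = palindromic_eaf_band
            if pd.isna(eaf) or lo <= eaf <= hi:
                drops.append((r["snp_id"], "palindromic-ambiguous"))
                continue
        flip = None
        if (ea_o, oa_o) == (ea_r, oa_r):
            flip = 1.0
        elif (ea_o, oa_o) == (oa_r, ea_r):
            flip = -1.0
        else:
            cea, coa = _COMPLEMENT.get(ea_o, "?"), _COMPLEMENT.get(oa_o, "?")
            if (cea, coa) == (ea_r, oa_r):
                flip = 1.0
            elif (cea, coa) == (oa_r, ea_r):
                flip = -1.0
        if flip is None:
            drops.append((r["snp_id"], "irreconcilable-alleles"))
            continue
        rec = {
            "snp_id": r["snp_id"],
            "chrom": r.get("chrom_ref", r.get("chrom", "")),
            "pos": r.get("pos_ref", r.get("pos", 0)),
            "effect_allele": ea_r, "other_allele": oa_r,
            "beta": flip * r["beta_oth"], "se": r["se_oth"],
            "eaf": r["eaf_oth"] if flip == 1.0 else 1 - r["eaf_oth"],
            "n": r["n_oth"],
        }
        rec["p"] = float(normal_p(rec["beta"], rec["se"]))
        out_rows.append(rec)
    harmonized = pd.DataFrame(out_rows, columns=SUMMARY_COLUMNS)
    drop_log = pd.DataFrame(drops, columns=["snp_id", "reason"])
    return harmonized, drop_log


def fixed_effect_meta(records_by_study: list[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effects inverse-variance-weighted meta-analysis.

    The first study defines the effect-allele convention; remaining studies
    are harmonized onto it (sign-flipping swapped alleles, dropping
    irreconcilable or ambiguous palindromic SNPs). Only SNPs present in at
    least two studies after harmonization are combined:
    beta = sum(b_i/se_i^2) / sum(1/se_i^2), se = sqrt(1/sum(1/se_i^2)).
    """
    if len(records_by_study) < 2:
        raise AssociationError("meta-analysis requires at least two studies")
    ref = records_by_study[0]
    aligned = [ref.copy()]
    for other in records_by_study[1:]:
        harm, _ = harmonize_alleles(ref, other)
        aligned.append(harm)
    rows = []
    for snp_id, grp0 in ref.groupby("snp_id", sort=False):
        contribs = []
        for tab in aligned:
            hit = tab[tab["snp_id"] == snp_id]
            if len(hit) and np.isfinite(hit["se"].iloc[0]) and hit["se"].iloc[0] > 0:
                contribs.append(hit.iloc[0])
        if len(contribs) < 2:
            continue
        w = np.array([1 / c["se"] ** 2 for c in contribs])
        b = np.array([c["beta"] for c in contribs])
        beta = float(np.sum(w * b) / np.sum(w))
        se = float(np.sqrt(1 / np.sum(w)))
        first = contribs[0]
        rows.append(
            {
                "snp_id": snp_id, "chrom": first["chrom"], "pos": first["pos"],
                "effect_allele": first["effect_allele"],
                "other_allele": first["other_allele"],
                "beta": beta, "se": se, "p": float(normal_p(beta, se)),
                "eaf": first["eaf"],
                "n": int(np.nansum([c["n"] for c in contribs])),
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


# ---------------------------------------------------------------------------
# LD and clumping
# ---------------------------------------------------------------------------


def compute_ld(panel: GenotypePanel, snp_subset: list[str] | None = None) -> pd.DataFrame:
    """Signed Pearson dosage-correlation matrix over a SNP subset.

    Raises on monomorphic SNPs (their correlation is undefined); the matrix
    is returned as a DataFrame indexed by snp_id.
    """
    ids = snp_subset if snp_subset is not None else panel.snp_ids
    if panel.n_individuals < 2:
        raise AssociationError("LD computation needs at least two individuals")
    cols = [panel.index_of(s) for s in ids]
    X = panel.dosages[:, cols]
    sds = X.std(axis=0)
    mono = [ids[k] for k in range(len(ids)) if sds[k] == 0]
    if mono:
        raise AssociationError(f"monomorphic SNP(s) in LD computation: {mono}")
    r = np.corrcoef(X, rowvar=False)
    r = np.atleast_2d(r)
    return pd.DataFrame(r, index=ids, columns=ids)


def ridge_stabilize(r: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    """Add a small ridge to the diagonal before inversion downstream."""
    return np.asarray(r, dtype=float) + ridge * np.eye(r.shape[0])


def clump(
    stats_df: pd.DataFrame,
    ld: pd.DataFrame,
    r2_threshold: float = 0.001,
    window_kb: float = 250.0,
) -> list[str]:
    """Greedy LD clumping: take the best remaining SNP by p-value as an
    index variant, remove everything within the window at r^2 >= threshold,
    repeat. Ties broken by (p, snp_id); SNPs absent from the LD panel are
    dropped. Returned index SNPs pairwise satisfy distance > window OR
    r^2 < threshold.
    """
    if stats_df.empty:
        raise AssociationError("cannot clump an empty summary-statistics table")
    df = stats_df.dropna(subset=["p"]).copy()
    in_panel = df["snp_id"].isin(ld.index)
    df = df[in_panel]
    df = df.sort_values(["p", "snp_id"], kind="mergesort").reset_index(drop=True)
    window_bp = window_kb * 1000
    alive = dict(zip(df["snp_id"], zip(df["pos"], df["p"])))
    order = list(df["snp_id"])
    kept: list[str] = []
    removed: set[str] = set()
    for snp in order:
        if snp in removed:
            continue
        kept.append(snp)
        pos = alive[snp][0]
        for other in order:
            if other == snp or other in removed:
                continue
            if abs(alive[other][0] - pos) <= window_bp and ld.loc[snp, other] ** 2 >= r2_threshold:
                removed.add(other)
        removed.add(snp)
    return kept
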