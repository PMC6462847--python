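"""Readers, writers, configuration and structured logging.

All on-disk formats are plain TSV/JSON with 1-based inclusive genomic
coordinates. Summary statistics use the exact column set
``snp_id, chrom, pos, effect_allele, other_allele, beta, se, p, eaf, n``
(column-name addressed, so header order is free). Genotype panels are a
dosage TSV (rows = individuals, header = SNP ids) with a SNP-map sidecar
(snp_id, chrom, pos, effect_allele, other_allele).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assoc import SUMMARY_COLUMNS, AssociationError, normal_p
from .simdata import GenotypePanel

__all__ = [
    "PipelineConfig",
    "load_config",
    "read_summary_stats",
    "write_summary_stats",
    "read_genotype_panel",
    "write_genotype_panel",
    "RunLogger",
]


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """Stage thresholds and paths for a full pipeline run; every threshold
    is validated against its documented domain and unknown keys are
    rejected."""

    clump_r2: float = 0.001
    clump_window_kb: float = 250.0
    cis_window_bp: int = 1_000_000
    mqtl_p_threshold: float = 1e-7
    r2_resolution: float = 0.8
    alpha: float = 0.05
    n_permutations: int = 200
    seed: int = 0
    scenario: dict = field(default_factory=dict)
    input_dir: str = ""
    output_dir: str = "results"
    cohort_labels: tuple[str, ...] = ("discovery", "replication")

    def __post_init__(self) -> None:
        checks = [
            (0 < self.clump_r2 <= 1, "clump_r2 must lie in (0, 1]"),
            (self.clump_window_kb > 0, "clump_window_kb must be positive"),
            (self.cis_window_bp > 0, "cis_window_bp must be positive"),
            (0 < self.mqtl_p_threshold < 1, "mqtl_p_threshold must lie in (0, 1)"),
            (0 < self.r2_resolution < 1, "r2_resolution must lie in (0, 1)"),
            (0 < self.alpha < 1, "alpha must lie in (0, 1)"),
            (self.n_permutations >= 100, "n_permutations must be at least 100"),
        ]
        bad = [msg for ok, msg in checks if not ok]
        if bad:
            raise FormatError("; ".join(bad))


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline configuration; unknown keys raise."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError("configuration must be a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"unknown configuration keys: {sorted(unknown)}")
    if "cohort_labels" in raw:
        raw["cohort_labels"] = tuple(raw["cohort_labels"])
    return PipelineConfig(**raw)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


def write_summary_stats(df: pd.DataFrame, path: str | Path) -> None:
    df[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_summary_stats(
    path: str | Path, logger: "RunLogger | None" = None
) -> pd.DataFrame:
    """Validated summary-statistic reader.

    Columns are matched by name (any order). Malformed numeric cells raise
    with the 1-based line number and column; rows with se <= 0 are rejected
    (and logged); p = 0 is clamped to the smallest positive float with a
    warning log.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = df.copy()
    for col in ("pos", "n"):
        out[col] = _numeric(df, col, path, integer=True)
    for col in ("beta", "se", "p", "eaf"):
        out[col] = _numeric(df, col, path)
    clamped = out["p"] == 0
    if clamped.any():
        out.loc[clamped, "p"] = np.finfo(float).tiny
        if logger:
            logger.log("read_summary_stats", "p_clamped", n=int(clamped.sum()))
    bad_se = out["se"] <= 0
    if bad_se.any():
        if logger:
            logger.log(
                "read_summary_stats", "rows_rejected",
                reason="nonpositive_se", n=int(bad_se.sum()),
            )
        out = out[~bad_se]
    if logger:
        logger.log("read_summary_stats", "loaded", n_in=len(df), n_out=len(out))
    return out[SUMMARY_COLUMNS].reset_index(drop=True)


def _numeric(df: pd.DataFrame, col: str, path, integer: bool = False) -> pd.Series:
    raw = df[col]
    converted = pd.to_numeric(raw, errors="coerce")
    bad = converted.isna() & raw.notna() & (raw.str.strip() != "") & (raw.str.upper() != "NA")
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise FormatError(f"{path}: malformed value in column {col!r} at line {line}")
    if integer:
        return converted.astype("Int64").astype(float)
    return converted.astype(float)


# ---------------------------------------------------------------------------
# genotype panels
# ---------------------------------------------------------------------------


def write_genotype_panel(panel: GenotypePanel, dosage_path: str | Path,
                         snpmap_path: str | Path) -> None:
    pd.DataFrame(panel.dosages, columns=panel.snp_ids).to_csv(
        dosage_path, sep="\t", index=False
    )
    cols = ["snp_id", "chrom", "pos", "effect_allele", "other_allele"]
    extra = [c for c in ("maf",) if c in panel.snps.columns]
    panel.snps[cols + extra].to_csv(snpmap_path, sep="\t", index=False)


def read_genotype_panel(dosage_path: str | Path, snpmap_path: str | Path) -> GenotypePanel:
    """Load a dosage TSV plus SNP-map sidecar; dosages outside [0, 2] or
    missing values raise, naming the offending cell."""
    dosage_path, snpmap_path = Path(dosage_path), Path(snpmap_path)
    if not snpmap_path.exists():
        raise FormatError(f"missing SNP map sidecar: {snpmap_path}")
    try:
        dos = pd.read_csv(dosage_path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{dosage_path}: empty genotype panel") from exc
    if dos.empty and dos.columns.size == 0:
        raise FormatError(f"{dosage_path}: empty genotype panel")
    snps = pd.read_csv(snpmap_path, sep="\t")
    if list(dos.columns) != list(snps["snp_id"]):
        raise FormatError("dosage columns do not match the SNP map")
    arr = dos.to_numpy(dtype=float)
    bad = ~np.isfinite(arr) | (arr < 0) | (arr > 2)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"{dosage_path}: invalid dosage {arr[i, j]!r} at row {i + 2}, "
            f"column {dos.columns[j]!r}"
        )
    return GenotypePanel(dosages=arr, snps=snps)


# ---------------------------------------------------------------------------
# structured logging
# ---------------------------------------------------------------------------


class RunLogger:
    """JSON-lines run log: every stage records inputs, parameters, seeds and
    record counts in/out plus drop reasons, machine-readably."""

    def __init__(self, path: str | Path | None = None, *, timestamps: bool = True):
        self.path = Path(path) if path is not None else None
        self.timestamps = timestamps
        self.entries: list[dict] = []
        if self.path is not None:
            self.path.parent.mkdir(parents=True, exist_ok=True)
            self.path.write_text("")

    def log(self, stage: str, event: str, **payload) -> dict:
        entry = {"stage": stage, "event": event, **payload}
        if self.timestamps:
            entry["time"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        self.entries.append(entry)
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(entry, sort_keys=True, default=str) + "\n")
        return entry

    def without_timestamps(self) -> list[dict]:
        return [{k: v for k, v in e.items() if k != "time"} for e in self.entries]
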