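#!/usr/bin/env python
"""Simulate one study per causal model.

Generates a full synthetic study (haplotype pool, case-control GWAS cohort,
methylation cohort with covariates, affected-offspring trios with duos, and
truth tables) under each of the five causal models, and writes the cohorts
as plain TSV/JSON under results/sim/<model>/.
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

from methmr import io, simdata
from methmr.experiments import scenario_preset

OUT = Path(__file__).resolve().parents[1] / "results" / "sim"
MODELS = ["mediation", "reverse_causation", "linkage", "pleiotropy", "null"]
BASE_SEED = 20260101


def main() -> None:
    for k, model in enumerate(MODELS):
        cfg = scenario_preset(model, seed=BASE_SEED + k, n_trios=638, duo_fraction=178 / 816)
        bundle = simdata.generate_scenario(cfg)
        out = OUT / model
        out.mkdir(parents=True, exist_ok=True)

        io.write_genotype_panel(bundle.mqtl_cohort.genotypes,
                                out / "mqtl_dosages.tsv", out / "snp_map.tsv")
        io.write_genotype_panel(bundle.gwas.genotypes,
                                out / "gwas_dosages.tsv", out / "snp_map_gwas.tsv")
        bundle.mqtl_cohort.methylation.beta_values.to_csv(
            out / "methylation.tsv", sep="\t", index=False)
        bundle.mqtl_cohort.methylation.cpg_positions.rename_axis(
            "cpg_id").reset_index().to_csv(out / "cpg_positions.tsv", sep="\t", index=False)
        bundle.mqtl_cohort.covariates.to_csv(out / "covariates.tsv", sep="\t", index=False)
        pd.DataFrame({"phenotype": bundle.gwas.phenotype}).to_csv(
            out / "phenotype.tsv", sep="\t", index=False)
        for name, arr in (("father", bundle.trios.father), ("mother", bundle.trios.mother),
                          ("child", bundle.trios.child)):
            pd.DataFrame(arr, columns=bundle.pool.snp_ids).to_csv(
                out / f"trio_{name}.tsv", sep="\t", index=False)
        pd.DataFrame({"father_observed": bundle.trios.father_observed}).to_csv(
            out / "trio_family_map.tsv", sep="\t", index=False)
        bundle.snp_truth.to_csv(out / "snp_truth.tsv", sep="\t", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(dataclasses.asdict(cfg), fh, indent=2, default=str)

        n_cases = int(bundle.gwas.phenotype.sum())
        print(f"{model}: GWAS {n_cases} cases / "
              f"{bundle.gwas.genotypes.n_individuals - n_cases} controls, "
              f"mQTL cohort n={bundle.mqtl_cohort.genotypes.n_individuals}, "
              f"{bundle.trios.n_trios} trios "
              f"({int((~bundle.trios.father_observed).sum())} duos) -> {out}")


if __name__ == "__main__":
    main()
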