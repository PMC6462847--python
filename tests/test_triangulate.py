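"""Decision table, replication concordance, tissue correlation, subtype
ANOVA and the report round trip."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methmr import simdata, triangulate
from methmr.coloc import ColocResult
from methmr.mr import MRResult
from methmr.triangulate import Thresholds, TriangulationError


def mrres(p, beta=0.5, direction="forward", method="wald"):
    return MRResult(
        exposure="cg", outcome="disease", method=method, n_instruments=1,
        beta=beta, se=0.1, p=p, direction=direction,
    )


def colocres(p, stat=10.0):
    return ColocResult(
        statistic=stat, p_permutation=p, n_permutations=200,
        n_snps_shared_support=4, n_snps_distinct_support=8,
    )


SENTINEL = ColocResult(
    statistic=None, p_permutation=None, n_permutations=0,
    n_snps_shared_support=0, n_snps_distinct_support=5,
    status="undefined", reason="shared support is empty",
)

THR = Thresholds.with_bonferroni(6425)


class TestClassifyLocus:
    @pytest.mark.parametrize(
        "forward_p,reverse_p,coloc_result,expected",
        [
            (1e-8, 0.6, colocres(0.001, 30.2), "putative_mediation_or_pleiotropy"),
            (1e-8, 0.6, colocres(1.0, -16.7), "linkage"),
            (0.5, 0.001, colocres(0.001), "no_signal"),
            (1e-8, 0.001, colocres(0.001), "reverse_causation"),
            (1e-8, 0.6, SENTINEL, "indeterminate"),
            (1e-8, 0.6, None, "indeterminate"),
        ],
    )
    def test_decision_table(self, forward_p, reverse_p, coloc_result, expected):
        call = triangulate.classify_locus(
            "cg1", "rs1", mrres(forward_p), mrres(reverse_p, direction="reverse"),
            coloc_result, THR,
        )
        assert call.label == expected

    def test_forward_threshold_is_bonferroni(self):
        assert THR.forward == pytest.approx(0.05 / 6425)
        call = triangulate.classify_locus(
            "cg1", "rs1", mrres(1e-5), mrres(0.6, direction="reverse"),
            colocres(0.001), THR,
        )
        assert call.label == "no_signal"  # 1e-5 > 0.05/6425


class TestReplicationCheck:
    def test_concordance_logic(self):
        disc = pd.DataFrame(
            {"cpg_id": ["a", "b", "c"], "snp_id": ["r1", "r2", "r3"],
             "beta": [0.5, -0.5, 0.5], "p": [1e-9] * 3}
        )
        repl = pd.DataFrame(
            {"cpg_id": ["a", "b", "c"], "snp_id": ["r1", "r2", "r3"],
             "beta": [0.4, 0.5, 0.4], "p": [0.01, 1e-9, 0.5]}
        )
        out = triangulate.replication_check(disc, repl).set_index("cpg_id")
        assert bool(out.loc["a", "concordant"])          # same sign, p<0.05
        assert not bool(out.loc["b", "concordant"])      # opposite sign
        assert not bool(out.loc["c", "concordant"])      # p too large

    def test_unmatched_pairs_dropped(self):
        disc = pd.DataFrame({"cpg_id": ["a"], "snp_id": ["r1"],
                             "beta": [0.5], "p": [1e-9]})
        repl = pd.DataFrame({"cpg_id": ["z"], "snp_id": ["r9"],
                             "beta": [0.5], "p": [1e-9]})
        assert triangulate.replication_check(disc, repl).empty


class TestCrossTissueCorrelation:
    def test_perfect_correlation_degenerate_ci(self):
        x = np.arange(10.0)
        r, lo, hi = triangulate.cross_tissue_correlation(x, x)
        assert r == lo == hi == 1.0

    def test_fisher_z_closed_form(self):
        # r=0.5 at n=30: CI = tanh(atanh(0.5) +- 1.96/sqrt(27))
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        e = rng.normal(size=30)
        y = x + e * np.sqrt(3)
        r, lo, hi = triangulate.cross_tissue_correlation(x, y)
        z = np.arctanh(r)
        assert lo == pytest.approx(np.tanh(z - 1.96 / np.sqrt(27)), abs=1e-12)
        assert hi == pytest.approx(np.tanh(z + 1.96 / np.sqrt(27)), abs=1e-12)
        r5, lo5, hi5 = 0.5, np.tanh(np.arctanh(0.5) - 1.96 / np.sqrt(27)), \
            np.tanh(np.arctanh(0.5) + 1.96 / np.sqrt(27))
        assert lo5 == pytest.approx(0.17, abs=0.005)
        assert hi5 == pytest.approx(0.73, abs=0.005)

    def test_null_correlation_mostly_small(self):
        big = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            r, *_ = triangulate.cross_tissue_correlation(
                rng.normal(size=100), rng.normal(size=100)
            )
            big += abs(r) >= 0.2
        assert big <= 10

    def test_zero_variance_raises(self):
        with pytest.raises(TriangulationError):
            triangulate.cross_tissue_correlation(np.ones(10), np.arange(10.0))


class TestSubtypeAnova:
    def test_matches_textbook_one_way_formula(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=45)
        labels = np.repeat(["CLO", "CLP", "CPO"], 15)
        f, p = triangulate.subtype_anova(y, labels)
        ref_f, ref_p = stats.f_oneway(y[:15], y[15:30], y[30:])
        assert f == pytest.approx(ref_f, abs=1e-10)
        assert p == pytest.approx(ref_p, abs=1e-10)

    def test_separated_groups_highly_significant(self):
        rng = np.random.default_rng(4)
        y = np.concatenate([rng.normal(0, 0.01, 10), rng.normal(0, 0.01, 10),
                            rng.normal(1, 0.01, 10)])
        labels = np.repeat(["CLO", "CLP", "CPO"], 10)
        _, p = triangulate.subtype_anova(y, labels)
        assert p < 1e-6

    def test_covariate_adjustment_removes_confounded_signal(self):
        rng = np.random.default_rng(5)
        cov = simdata.make_covariates(90, seed=6, n_pcs=2)
        labels = np.repeat(["CLO", "CLP", "CPO"], 30)
        y = rng.normal(size=90) + 0.8 * cov["sex"].to_numpy()
        _, p_adj = triangulate.subtype_anova(y, labels, cov)
        assert p_adj > 0.001  # no subtype effect once sex is adjusted

    def test_group_size_requirements(self):
        with pytest.raises(TriangulationError):
            triangulate.subtype_anova(np.arange(4.0), ["a", "a", "a", "b"])
        with pytest.raises(TriangulationError):
            triangulate.subtype_anova(np.arange(4.0), ["a"] * 4)


class TestReport:
    def make_calls(self):
        good = triangulate.classify_locus(
            "cg1", "rs1", mrres(1e-8), mrres(0.6, direction="reverse"),
            colocres(0.004, 30.2), THR,
        )
        und = triangulate.classify_locus(
            "cg2", "rs2", mrres(1e-8), mrres(0.6, direction="reverse"),
            SENTINEL, THR,
        )
        return [good, und]

    def test_empty_calls_give_header_only(self, tmp_path):
        path = tmp_path / "calls.tsv"
        triangulate.build_report([], out_tsv=str(path))
        text = path.read_text().strip().splitlines()
        assert len(text) == 1
        assert text[0].split("\t")[0] == "snp_id"

    def test_sentinel_renders_as_na_with_note(self):
        report = triangulate.build_report(self.make_calls())
        row = report.set_index("cpg_id").loc["cg2"]
        assert row["coloc_statistic"] == "N/A"
        assert row["coloc_p"] == "N/A"
        assert "empty" in row["coloc_note"]
        assert row["label"] == "indeterminate"

    def test_round_trip(self, tmp_path):
        path = tmp_path / "calls.tsv"
        report = triangulate.build_report(
            self.make_calls(), out_tsv=str(path),
            metadata={"seed": 3}, out_meta=str(tmp_path / "meta.json"),
        )
        back = triangulate.read_report(str(path))
        assert list(back["label"]) == list(report["label"])
        assert back.loc[0, "coloc_statistic"] == pytest.approx(30.2)
        assert back.loc[1, "coloc_statistic"] == "N/A"
        import json

        assert json.loads((tmp_path / "meta.json").read_text())["seed"] == 3
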