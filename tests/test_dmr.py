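"""Per-site chi-square testing, run binning, annotation, filters."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from conftest import single_site_matrices
from meddx.dmr import (
    annotate_dmrs,
    call_dmrs,
    class_tally,
    per_site_test,
    remove_sex_chromosomes,
)


class TestPerSiteTest:
    def test_matches_contingency_oracle(self):
        # independent brute-force 2x2 chi-square on random tables
        rng = np.random.default_rng(17)
        for _ in range(300):
            x1, x2 = rng.integers(1, 500, 2)
            n1 = x1 + rng.integers(100, 10_000)
            n2 = x2 + rng.integers(100, 10_000)
            case, control = single_site_matrices(x1, n1, x2, n2)
            res = per_site_test(case, control).iloc[0]
            stat, p, _, _ = chi2_contingency(
                [[x1, n1 - x1], [x2, n2 - x2]], correction=False
            )
            assert res.chi2 == pytest.approx(stat, rel=1e-9)
            assert res.p == pytest.approx(p, rel=1e-9)

    def test_textbook_table(self):
        case, control = single_site_matrices(30, 10_000, 10, 10_000)
        res = per_site_test(case, control).iloc[0]
        stat, p, _, _ = chi2_contingency([[30, 9970], [10, 9990]], correction=False)
        assert res.chi2 == pytest.approx(stat, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)

    def test_equal_proportions_give_p_one(self):
        case, control = single_site_matrices(50, 1000, 100, 2000)
        res = per_site_test(case, control).iloc[0]
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_zero_coverage_site(self):
        case, control = single_site_matrices(0, 1000, 0, 1000)
        res = per_site_test(case, control).iloc[0]
        assert res.p == 1.0 and res.direction == ""

    def test_label_swap_symmetry(self):
        case, control = single_site_matrices(30, 10_000, 10, 9_000)
        a = per_site_test(case, control).iloc[0]
        b = per_site_test(control, case).iloc[0]
        assert a.p == pytest.approx(b.p, rel=1e-12)
        assert {a.direction, b.direction} == {"hyper", "hypo"}


def make_results(rows):
    """rows: (pos, p, direction) on chr1 with unit coverage."""
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": [r[0] for r in rows],
            "case_pooled": 10.0,
            "control_pooled": 10.0,
            "case_rpm": [40.0 if r[2] == "hyper" else 10.0 for r in rows],
            "control_rpm": 20.0,
            "chi2": 30.0,
            "p": [r[1] for r in rows],
            "direction": [r[2] for r in rows],
        }
    )


class TestCallDmrs:
    def test_no_significant_sites(self):
        res = make_results([(100, 0.5, "hyper"), (200, 0.9, "hyper")])
        assert call_dmrs(res).empty

    def test_empty_input(self):
        assert call_dmrs(pd.DataFrame()).empty

    def test_gap_splits_runs(self):
        # 5 close significant sites, then a >max_gap jump, then 3 more
        sig = 1e-9
        rows = [(100 + 50 * i, sig, "hyper") for i in range(5)]
        rows += [(10_000 + 50 * i, sig, "hyper") for i in range(3)]
        dmrs = call_dmrs(make_results(rows), n_tests=8, max_gap=1000,
                         min_sites=1, min_size=1, min_fold=1)
        assert list(dmrs.n_sites) == [5, 3]
        assert dmrs.start.iloc[0] == 100 and dmrs.end.iloc[0] == 302

    def test_direction_change_splits_run(self):
        sig = 1e-9
        rows = [
            (100, sig, "hyper"), (150, sig, "hyper"),
            (200, sig, "hypo"),
            (250, sig, "hyper"), (300, sig, "hyper"),
        ]
        dmrs = call_dmrs(make_results(rows), n_tests=5, min_sites=1,
                         min_size=1, min_fold=1)
        assert list(dmrs.n_sites) == [2, 1, 2]
        assert list(dmrs.direction) == ["hyper", "hypo", "hyper"]

    def test_bonferroni_threshold(self):
        # p = 0.04: significant at n_tests=1, not at n_tests=2
        res = make_results([(100, 0.04, "hyper")])
        assert len(call_dmrs(res, n_tests=1, min_sites=1, min_size=1, min_fold=1)) == 1
        assert call_dmrs(res, n_tests=2, min_sites=1, min_size=1, min_fold=1).empty

    def test_threshold_monotonicity(self, planted_sim):
        ann, idx, planted, mats = planted_sim
        res = per_site_test(mats["tumor"], mats["control"])
        baseline = len(call_dmrs(res, min_sites=2, min_size=50, min_fold=1.5))
        for kwargs in ({"min_sites": 4}, {"min_size": 200}, {"min_fold": 3.0}):
            stricter = len(call_dmrs(res, **{"min_sites": 2, "min_size": 50,
                                             "min_fold": 1.5, **kwargs}))
            assert stricter <= baseline


class TestAnnotateDmrs:
    REGIONS = pd.DataFrame(
        [
            ("g:TSS", "chr1", 4000, 6000, "TSS"),
            ("cgi0", "chr1", 5500, 7000, "cpg_island"),
        ],
        columns=["region_id", "chrom", "start", "end", "cls"],
    )

    def dmr_at(self, start, end):
        return pd.DataFrame(
            [("chr1", start, end, 5, 3.0, "hyper", 1e-8)],
            columns=["chrom", "start", "end", "n_sites", "fold_change",
                     "direction", "min_p_corrected"],
        )

    def test_inside_tss(self):
        out = annotate_dmrs(self.dmr_at(4500, 4800), self.REGIONS)
        assert out.classes[0] == "TSS"

    def test_overlapping_two_classes(self):
        out = annotate_dmrs(self.dmr_at(5400, 5600), self.REGIONS)
        assert set(out.classes[0].split(",")) == {"TSS", "cpg_island"}
        assert class_tally(out) == {"TSS": 1, "cpg_island": 1}

    def test_intergenic(self):
        out = annotate_dmrs(self.dmr_at(10_000, 10_500), self.REGIONS)
        assert out.classes[0] == "intergenic"


class TestRemoveSexChromosomes:
    def test_removes_x_and_y(self):
        df = pd.DataFrame({"chrom": ["chr1", "chrX", "chrY"], "pos": [1, 2, 3]})
        out = remove_sex_chromosomes(df)
        assert list(out.chrom) == ["chr1"]

    def test_identity_without_sex_chroms(self):
        df = pd.DataFrame({"chrom": ["chr1", "chr2"], "pos": [1, 2]})
        pd.testing.assert_frame_equal(remove_sex_chromosomes(df), df)

    def test_empty_input(self):
        df = pd.DataFrame({"chrom": [], "pos": []})
        assert remove_sex_chromosomes(df).empty
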