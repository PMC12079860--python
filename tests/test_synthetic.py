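"""Generator contracts: determinism, planted effect sizes, mixtures."""
import numpy as np
import pandas as pd
import pytest

from meddx.containers import LpnPISiteIndex
from meddx.synthetic import (
    PlantedDmr,
    SimulationDesign,
    generate_genome,
    mean_profile,
    simulate_cfdna_counts,
    simulate_cohort,
    simulate_qmsp,
    simulate_site_counts,
)


class TestGenerateGenome:
    def test_feature_counts_near_densities(self):
        # 100 kb at 50 genes/Mb and 10 islands/Mb: Poisson means 5 and 1
        ann, idx = generate_genome(1, 100_000, 50, 10, seed=1)
        assert abs(len(ann.genes) - 5) <= 3 * np.sqrt(5)
        assert abs(len(ann.cpg_islands) - 1) <= 3 * np.sqrt(1) + 1
        assert idx.n_sites > 0

    def test_zero_gene_density_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(1, 10_000, 0, 5, seed=1)

    def test_short_chromosome_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(1, 5_000, 10, 5, seed=1)

    def test_same_seed_identical(self):
        a_ann, a_idx = generate_genome(1, 50_000, 30, 8, seed=42)
        b_ann, b_idx = generate_genome(1, 50_000, 30, 8, seed=42)
        pd.testing.assert_frame_equal(a_ann.genes, b_ann.genes)
        pd.testing.assert_frame_equal(a_ann.cpg_islands, b_ann.cpg_islands)
        for c in a_idx.positions:
            np.testing.assert_array_equal(a_idx.positions[c], b_idx.positions[c])

    def test_annotation_valid(self, toy_genome):
        ann, idx = toy_genome
        ann.validate()
        for chrom, pos in idx.positions.items():
            assert pos.max() < ann.chromosomes[chrom]


class TestSimulateSiteCounts:
    def test_null_design_groups_match(self, toy_genome):
        ann, idx = toy_genome
        design = SimulationDesign(n_per_group=20, planted_dmrs=[], seed=5)
        mats = simulate_site_counts(ann, idx, design)
        a = mats["tumor"].rpm().mean(axis=1)
        b = mats["control"].rpm().mean(axis=1)
        # site-level RPM difference averages to ~0 across the genome
        assert abs((a - b).mean()) < 0.05 * a.mean()

    def test_planted_hyper_fold_recovered(self, planted_sim):
        ann, idx, planted, mats = planted_sim
        sites = idx.sites_frame()
        d = planted[0]
        inside = (
            (sites.chrom == d.chrom) & (sites.pos >= d.start) & (sites.pos < d.end)
        ).to_numpy()
        ratio = (
            mats["tumor"].counts.loc[inside].to_numpy().mean()
            / mats["control"].counts.loc[inside].to_numpy().mean()
        )
        assert ratio == pytest.approx(4.0, rel=0.2)

    def test_fold_one_is_null(self, toy_genome):
        ann, idx = toy_genome
        chrom = idx.chroms[0]
        pos = idx.positions[chrom]
        dmr = PlantedDmr(chrom, int(pos[10]), int(pos[30]), "hyper", 1.0)
        design = SimulationDesign(n_per_group=10, planted_dmrs=[dmr], seed=6)
        mats = simulate_site_counts(ann, idx, design)
        inside = slice(10, 31)
        ratio = (
            mats["tumor"].counts.iloc[inside].to_numpy().mean()
            / mats["control"].counts.iloc[inside].to_numpy().mean()
        )
        assert ratio == pytest.approx(1.0, rel=0.1)

    def test_unplantable_dmr_warns(self, toy_genome):
        ann, idx = toy_genome
        chrom = idx.chroms[0]
        empty = PlantedDmr(chrom, 0, 5, "hyper", 4.0)  # below first site
        design = SimulationDesign(n_per_group=2, planted_dmrs=[empty], seed=7)
        with pytest.warns(UserWarning, match="cannot be planted"):
            simulate_site_counts(ann, idx, design)

    def test_determinism(self, toy_genome):
        ann, idx = toy_genome
        design = SimulationDesign(n_per_group=3, seed=8)
        a = simulate_site_counts(ann, idx, design)
        b = simulate_site_counts(ann, idx, design)
        pd.testing.assert_frame_equal(a["tumor"].counts, b["tumor"].counts)


@pytest.fixture(scope="module")
def profiles(planted_sim):
    ann, idx, planted, mats = planted_sim
    return idx, mean_profile(mats["tumor"]), mean_profile(mats["control"])


class TestSimulateCfdna:

    @pytest.mark.parametrize("tf,which", [(1.0, "tumor"), (0.0, "background")])
    def test_boundary_fractions(self, profiles, tf, which):
        idx, tumor, background = profiles
        m = simulate_cfdna_counts(idx, tumor, background, tf, n_samples=200, seed=9)
        observed = m.counts.mean(axis=1).to_numpy()
        expected = tumor if which == "tumor" else background
        # genome-averaged mean matches the chosen profile
        assert observed.mean() == pytest.approx(expected.mean(), rel=0.02)

    def test_mixture_is_convex_combination(self, profiles, planted_sim):
        idx, tumor, background = profiles
        _, _, planted, _ = planted_sim
        tf = 0.02
        m = simulate_cfdna_counts(idx, tumor, background, tf, n_samples=1000, seed=10)
        sites = idx.sites_frame()
        d = planted[0]
        inside = (
            (sites.chrom == d.chrom) & (sites.pos >= d.start) & (sites.pos < d.end)
        ).to_numpy()
        eff = m.counts.loc[inside].to_numpy().mean() / m.counts.loc[~inside].to_numpy().mean()
        # closed form: 0.02 * 4 + 0.98 * 1 = 1.06 at fold-4 DMR sites
        assert eff == pytest.approx(1.06, abs=0.03)

    def test_mismatched_profiles_rejected(self, profiles):
        idx, tumor, background = profiles
        with pytest.raises(ValueError):
            simulate_cfdna_counts(idx, tumor[:-1], background, 0.5)

    def test_bad_fraction_rejected(self, profiles):
        idx, tumor, background = profiles
        with pytest.raises(ValueError):
            simulate_cfdna_counts(idx, tumor, background, 1.5)


class TestSimulateQmsp:
    def test_noise_free_levels_exact(self):
        from meddx.qmsp import levels_matrix

        table = simulate_qmsp({"HCC": {"M1": 3.0}}, sd=0.0, n_per_group=5, seed=1, ref_ct_sd=0.3)
        levels, _ = levels_matrix(table)
        np.testing.assert_allclose(levels.loc["M1"], 2.0 ** -3.0)

    def test_two_cycle_shift_quadruples_level(self):
        from meddx.qmsp import levels_matrix

        table = simulate_qmsp(
            {"A": {"M": 3.0}, "B": {"M": 5.0}}, sd=0.4, n_per_group=100, seed=2
        )
        levels, groups = levels_matrix(table)
        ratio = (
            np.median(levels.loc["M", groups == "A"])
            / np.median(levels.loc["M", groups == "B"])
        )
        assert ratio == pytest.approx(4.0, rel=0.15)

    def test_determinism(self):
        a = simulate_qmsp({"g": {"m": 2.0}}, seed=3)
        b = simulate_qmsp({"g": {"m": 2.0}}, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateCohort:
    def test_group_medians_ordered(self):
        cohort = simulate_cohort({"HCC": 200, "cirrhosis": 200}, seed=4)
        med = cohort.groupby("group")[["afp", "pivka"]].median()
        assert med.loc["HCC", "afp"] > med.loc["cirrhosis", "afp"]
        assert med.loc["HCC", "pivka"] > med.loc["cirrhosis", "pivka"]

    def test_values_within_detection_limits(self):
        cohort = simulate_cohort({"HCC": 300}, seed=5)
        assert cohort.afp.between(0.5, 2000).all()
        assert cohort.pivka.between(5, 75000).all()

    def test_all_male(self):
        cohort = simulate_cohort({"HCC": 50}, male_fraction=1.0, seed=6)
        assert (cohort.sex == 1).all()

    def test_empty_cohort(self):
        cohort = simulate_cohort({"HCC": 0}, seed=7)
        assert cohort.empty

    def test_stage_only_for_hcc(self):
        cohort = simulate_cohort({"HCC": 20, "cirrhosis": 20}, seed=8)
        assert (cohort.loc[cohort.group == "HCC", "stage"].isin(["early", "late"])).all()
        assert (cohort.loc[cohort.group == "cirrhosis", "stage"] == "none").all()
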