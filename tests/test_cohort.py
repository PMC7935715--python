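import numpy as np
import pytest
from scipy import stats

from ffanips.cohort import (
    CohortError,
    SampleProfile,
    draw_sample_profile,
    karyotype_to_copy_map,
    parse_karyotype,
    simulate_cohort,
    simulate_from_profiles,
    tilt_pattern,
)
from ffanips.config import RunConfig
from tests.conftest import simulate_sample


class TestProfileDraws:
    def test_degenerate_model_gives_constant_ff(self, config):
        config.ff_bmi_slope = 0.0
        config.ff_noise_sd = 0.0
        config.ff_intercept = np.log(0.08)
        rng = np.random.default_rng(0)
        ffs = [draw_sample_profile(config, rng).true_ff for _ in range(20)]
        assert ffs == pytest.approx([0.08] * 20)

    def test_positive_bmi_slope_rejected(self, config):
        config.ff_bmi_slope = -0.01
        with pytest.raises(CohortError, match="slope"):
            draw_sample_profile(config, np.random.default_rng(0))

    def test_ff_negatively_correlated_with_bmi(self, config):
        rng = np.random.default_rng(1)
        profiles = [draw_sample_profile(config, rng) for _ in range(10_000)]
        bmi = np.array([p.bmi for p in profiles])
        ff = np.array([p.true_ff for p in profiles])
        r, p_val = stats.pearsonr(bmi, ff)
        assert r < 0
        assert p_val < 1e-10

    def test_low_ff_rates_match_calibration_targets(self, config):
        """Generator defaults reproduce ~3.7% low-FF overall and ~16% within
        the class-III obesity stratum, within Monte Carlo error at n=1e4."""
        rng = np.random.default_rng(2)
        profiles = [draw_sample_profile(config, rng) for _ in range(10_000)]
        bmi = np.array([p.bmi for p in profiles])
        ff = np.array([p.true_ff for p in profiles])
        low = ff < 0.04
        se_all = np.sqrt(0.037 * 0.963 / low.size)
        assert low.mean() == pytest.approx(0.037, abs=3 * se_all)
        stratum = bmi >= 40
        assert stratum.sum() > 100
        se_hi = np.sqrt(0.16 * 0.84 / stratum.sum())
        assert low[stratum].mean() == pytest.approx(0.16, abs=3 * se_hi)

    def test_ff_clipped_to_bounds(self, config):
        rng = np.random.default_rng(3)
        ffs = [draw_sample_profile(config, rng).true_ff for _ in range(2000)]
        assert min(ffs) >= config.ff_min
        assert max(ffs) <= config.ff_max

    def test_sca_karyotypes_imply_sex(self, config):
        config.karyotype_freqs = {"MX": 0.25, "TX": 0.25, "XXY": 0.25, "XYY": 0.25}
        rng = np.random.default_rng(4)
        for _ in range(40):
            p = draw_sample_profile(config, rng)
            kind, _ = parse_karyotype(p.karyotype)
            expected = "XX" if kind in ("MX", "TX") else "XY"
            assert p.fetal_sex == expected


class TestCopyMaps:
    @pytest.mark.parametrize("karyotype,sex,chrom,fetal,maternal", [
        ("euploid", "XY", "chrY", 1, 0),
        ("euploid", "XY", "chrX", 1, 2),
        ("euploid", "XX", "chrY", 0, 0),
        ("T21", "XX", "chr21", 3, 2),
        ("T13", "XY", "chr13", 3, 2),
        ("RAA(chr7)", "XX", "chr7", 3, 2),
        ("MX", "XX", "chrX", 1, 2),
        ("TX", "XX", "chrX", 3, 2),
        ("XXY", "XY", "chrX", 2, 2),
        ("XXY", "XY", "chrY", 1, 0),
        ("XYY", "XY", "chrY", 2, 0),
    ])
    def test_karyotype_copies(self, small_genome, karyotype, sex, chrom,
                              fetal, maternal):
        p = SampleProfile("s", "b", 25.0, 0.1, karyotype, sex)
        cmap = karyotype_to_copy_map(p, small_genome)
        mask = small_genome.chrom_mask(chrom)
        assert np.all(cmap.fetal[mask] == fetal)
        assert np.all(cmap.maternal[mask] == maternal)

    def test_microdeletion_hits_region_bins_only(self, small_genome):
        p = SampleProfile("s", "b", 25.0, 0.1, "microdeletion(22q11.2)", "XX")
        cmap = karyotype_to_copy_map(p, small_genome)
        region = small_genome.region_bins["22q11.2"]
        assert np.all(cmap.fetal[region] == 1)
        others = np.setdiff1d(
            np.flatnonzero(small_genome.chrom_mask("chr22")), region)
        assert np.all(cmap.fetal[others] == 2)

    @pytest.mark.parametrize("label", ["RAA(chr21)", "RAA(chrX)", "T22",
                                       "microdeletion(nowhere)"])
    def test_invalid_labels_rejected(self, small_genome, label):
        p = SampleProfile("s", "b", 25.0, 0.1, label, "XX")
        with pytest.raises(CohortError):
            karyotype_to_copy_map(p, small_genome)


class TestBinCountSimulation:
    def test_no_fetal_compartment_leaves_chry_empty(self, small_genome):
        config = RunConfig(chry_background=0.0)
        counts = simulate_sample(small_genome, config, np.random.default_rng(0),
                                 ff=0.005, sex="XX", depth=100_000)
        assert counts.total[small_genome.chrom_mask("chrY")].sum() == 0

    def test_chry_depth_ratio_is_half_ff(self, small_genome):
        """XY euploid: expected chrY share of depth equals FF/2 x length share."""
        config = RunConfig(chry_background=0.0, ff_tilt_amplitude=0.0)
        rng = np.random.default_rng(1)
        ff, reps = 0.10, 40
        y_mask = small_genome.chrom_mask("chrY")
        y_len = y_mask.sum() * small_genome.bin_width
        total_y = 0
        depth = 200_000
        for _ in range(reps):
            counts = simulate_sample(small_genome, config, rng, ff=ff,
                                     depth=depth)
            total_y += counts.total[y_mask, 0].sum()
        genome_len = np.sum(small_genome.bin_end - small_genome.bin_start)
        # weights: chrY ff/2, chrX 1-ff/2, autosomes 1
        x_len = small_genome.chrom_mask("chrX").sum() * small_genome.bin_width
        auto_len = genome_len - x_len - y_len
        w_tot = auto_len + x_len * (1 - ff / 2) + y_len * ff / 2
        expected = reps * depth * (y_len * ff / 2) / w_tot
        assert total_y == pytest.approx(expected, abs=3 * np.sqrt(expected))

    def test_t21_chr21_ratio_shift(self, small_genome, config):
        rng = np.random.default_rng(2)
        mask = small_genome.chrom_mask("chr21")
        other = small_genome.autosomal_mask & ~mask
        ratio_sum, exp_counts = 0.0, 0.0
        for _ in range(30):
            counts = simulate_sample(small_genome, config, rng, ff=0.10,
                                     karyotype="T21", depth=200_000)
            c21 = counts.total[mask, 0].sum() / mask.sum()
            rest = counts.total[other, 0].sum() / other.sum()
            ratio_sum += c21 / rest
            exp_counts += counts.total[mask, 0].sum()
        se = 1.05 / np.sqrt(exp_counts)
        assert ratio_sum / 30 == pytest.approx(1.05, abs=3 * se + 0.003)

    def test_multinomial_mode_conserves_depth_exactly(self, small_genome):
        config = RunConfig(noise_model="multinomial")
        counts = simulate_sample(small_genome, config, np.random.default_rng(3),
                                 depth=123_456)
        assert counts.total.sum() == 123_456
        assert np.array_equal(counts.total, counts.fetal + counts.maternal)

    def test_seed_determinism(self, small_genome, config):
        a = simulate_sample(small_genome, config, np.random.default_rng(42))
        b = simulate_sample(small_genome, config, np.random.default_rng(42))
        assert np.array_equal(a.total, b.total)
        assert np.array_equal(a.fetal, b.fetal)

    def test_tilt_is_zero_sum_per_chromosome(self, small_genome):
        t = tilt_pattern(small_genome, 0.3)
        for name in small_genome.chrom_names:
            mask = small_genome.chrom_mask(name)
            if name in ("chrX", "chrY"):
                assert np.all(t[mask] == 0)
            else:
                assert abs(t[mask].sum()) < 1e-9

    def test_depth_too_low_rejected(self, small_genome, config):
        with pytest.raises(CohortError, match="depth"):
            simulate_sample(small_genome, config, np.random.default_rng(0),
                            depth=5_000)


class TestCohortAssembly:
    def test_explicit_batch_composition_column_count(self, small_genome):
        config = RunConfig(depth=50_000)
        profiles = [
            SampleProfile(f"E{i}", "B0", 25.0, 0.1, "euploid",
                          "XY" if i % 2 else "XX")
            for i in range(20)
        ] + [
            SampleProfile("T", "B0", 25.0, 0.1, "T21", "XX"),
            SampleProfile("NTC", "B0", np.nan, 0.0, "euploid", "XX",
                          control_type="ntc"),
            SampleProfile("PXY", "B0", np.nan, 0.10, "euploid", "XY",
                          control_type="pooled_xy"),
        ]
        counts = simulate_from_profiles(
            profiles, config, small_genome, np.random.default_rng(0))
        assert len(counts.sample_ids) == 23

    def test_ntc_without_contamination_is_all_zero(self, small_genome):
        config = RunConfig(depth=50_000, ntc_contamination=0.0)
        profiles = [SampleProfile("NTC", "B0", np.nan, 0.0, "euploid", "XX",
                                  control_type="ntc")]
        counts = simulate_from_profiles(
            profiles, config, small_genome, np.random.default_rng(0))
        assert counts.total.sum() == 0

    def test_cohort_has_controls_and_truth(self, small_genome):
        config = RunConfig(cohort_size=12, n_batches=2, depth=50_000)
        manifest, counts, profiles = simulate_cohort(
            config, np.random.default_rng(5), small_genome)
        assert len(manifest) == len(counts.sample_ids) == 12 + 2 * 3
        ctl = manifest["control_type"].value_counts()
        assert ctl["ntc"] == 2 and ctl["pooled_xx"] == 2 and ctl["pooled_xy"] == 2
        patients = manifest[manifest["control_type"] == "none"]
        assert patients["true_ff"].notna().all()
        assert patients["karyotype"].notna().all()

    def test_replicates_share_latent_profile(self, small_genome):
        config = RunConfig(cohort_size=8, n_batches=2, depth=50_000)
        manifest, counts, profiles = simulate_cohort(
            config, np.random.default_rng(6), small_genome, replicate_every=2)
        reps = manifest[manifest["sample_id"].str.endswith("_rep")]
        assert len(reps) >= 1
        base = reps.iloc[0]["sample_id"].removesuffix("_rep")
        orig = manifest[manifest["sample_id"] == base].iloc[0]
        assert reps.iloc[0]["true_ff"] == orig["true_ff"]
        assert reps.iloc[0]["batch_id"] != orig["batch_id"]
        # independent counts
        a = counts.column(base)
        b = counts.column(reps.iloc[0]["sample_id"])
        assert not np.array_equal(a, b)

    def test_batch_without_euploid_raises(self, small_genome):
        config = RunConfig(cohort_size=3, karyotype_freqs={"T21": 1.0},
                           depth=50_000)
        with pytest.raises(CohortError, match="euploid"):
            simulate_cohort(config, np.random.default_rng(0), small_genome)


def test_euploid_xy_chry_estimator_converges(genome):
    """Mean over replicates of 2*(chrY depth ratio) approaches true FF."""
    from ffanips.ff import estimate_ff_chry, normalize_depth

    config = RunConfig(chry_background=0.0)
    rng = np.random.default_rng(7)
    ff, reps, depth = 0.08, 25, 500_000
    vals, y_counts = [], 0
    for _ in range(reps):
        counts = simulate_sample(genome, config, rng, ff=ff, depth=depth)
        ratios = normalize_depth(counts.total[:, 0], genome)
        vals.append(estimate_ff_chry(ratios, genome).raw)
        y_counts += counts.total[genome.chrom_mask("chrY"), 0].sum()
    se = ff / np.sqrt(y_counts)
    assert np.mean(vals) == pytest.approx(ff, abs=3 * se)
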