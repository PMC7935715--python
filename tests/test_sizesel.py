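import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ffanips.config import RunConfig
from ffanips.sizesel import (
    FragmentLengthMixture,
    SizeSelectionError,
    SizeSelectionSpec,
    apply_size_selection,
    bioinformatic_weighting,
    expected_ff_gain,
    retention_probabilities,
    simulate_fragment_lengths,
    solve_cutoff_for_target_mean,
)
from tests.conftest import simulate_sample


def default_mixture(ff=0.04):
    return FragmentLengthMixture.from_config(RunConfig(), ff)


class TestRetention:
    def test_infinite_cutoff_retains_everything(self):
        spec = SizeSelectionSpec(mode="hard", cutoff=np.inf)
        assert retention_probabilities(default_mixture(), spec) == (1.0, 1.0)

    def test_hard_cutoff_matches_gaussian_cdf(self):
        """Fetal ~ Normal(143, 10) truncated at 0, L=150: r_f = Phi(0.7)."""
        mix = FragmentLengthMixture(
            fetal=stats.truncnorm(-14.3, np.inf, loc=143, scale=10),
            maternal=stats.truncnorm(-8.35, np.inf, loc=167, scale=20),
            ff=0.04,
        )
        spec = SizeSelectionSpec(mode="hard", cutoff=150.0)
        r_f, r_m = retention_probabilities(mix, spec)
        assert r_f == pytest.approx(stats.norm.cdf(0.7), abs=1e-6)
        assert r_m == pytest.approx(stats.norm.cdf((150 - 167) / 20), abs=1e-6)
        assert r_f > r_m

    def test_point_mass_lengths_give_step_retention(self):
        mix = FragmentLengthMixture(
            fetal=stats.rv_discrete(values=([143], [1.0]))(),
            maternal=stats.rv_discrete(values=([167], [1.0]))(),
            ff=0.04,
        )
        spec = SizeSelectionSpec(mode="hard", cutoff=150.0)
        assert retention_probabilities(mix, spec) == (1.0, 0.0)

    def test_zero_retention_rejected(self):
        spec = SizeSelectionSpec(mode="hard", cutoff=1.0)
        with pytest.raises(SizeSelectionError, match="empty library"):  # numerically zero
            retention_probabilities(default_mixture(), spec)

    def test_logistic_mode_close_to_quadrature(self):
        mix = default_mixture()
        spec = SizeSelectionSpec(mode="logistic", cutoff=150.0, softness=4.0)
        r_f, r_m = retention_probabilities(mix, spec)
        grid = np.linspace(50, 300, 20_000)
        w = spec.retention(grid)
        oracle_f = np.trapezoid(w * mix.fetal.pdf(grid), grid)
        oracle_m = np.trapezoid(w * mix.maternal.pdf(grid), grid)
        assert r_f == pytest.approx(oracle_f, abs=1e-5)
        assert r_m == pytest.approx(oracle_m, abs=1e-5)
        assert r_f > r_m


class TestCutoffSolver:
    def test_target_at_pre_selection_mean_means_no_selection(self):
        mix = default_mixture()
        spec = solve_cutoff_for_target_mean(mix, mix.overall_mean())
        assert np.isinf(spec.cutoff)
        assert spec.r_f == spec.r_m == 1.0

    def test_solved_cutoff_reproduces_target_mean(self):
        """Self-consistency via independent numerical integration."""
        mix = default_mixture(0.04)
        spec = solve_cutoff_for_target_mean(mix, 140.0)
        grid = np.linspace(20, spec.cutoff, 400_000)
        num_f = np.trapezoid(grid * mix.fetal.pdf(grid), grid)
        num_m = np.trapezoid(grid * mix.maternal.pdf(grid), grid)
        den_f = np.trapezoid(mix.fetal.pdf(grid), grid)
        den_m = np.trapezoid(mix.maternal.pdf(grid), grid)
        realized = (mix.ff * num_f + (1 - mix.ff) * num_m) / (
            mix.ff * den_f + (1 - mix.ff) * den_m)
        assert realized == pytest.approx(140.0, abs=0.1)

    def test_logistic_mode_also_hits_target(self):
        mix = default_mixture(0.10)
        spec = solve_cutoff_for_target_mean(mix, 140.0, mode="logistic",
                                            softness=4.0)
        grid = np.linspace(20, 400, 200_000)
        w = spec.retention(grid)
        realized = (
            mix.ff * np.trapezoid(grid * w * mix.fetal.pdf(grid), grid)
            + (1 - mix.ff) * np.trapezoid(grid * w * mix.maternal.pdf(grid), grid)
        ) / (
            mix.ff * np.trapezoid(w * mix.fetal.pdf(grid), grid)
            + (1 - mix.ff) * np.trapezoid(w * mix.maternal.pdf(grid), grid)
        )
        assert realized == pytest.approx(140.0, abs=0.1)

    def test_unachievable_target_reports_range(self):
        with pytest.raises(SizeSelectionError, match="achievable range"):
            solve_cutoff_for_target_mean(default_mixture(), 10.0)


class TestGainLaw:
    def test_worked_example(self):
        ff_post, gain = expected_ff_gain(0.04, 0.6, 0.2)
        assert ff_post == pytest.approx(0.024 / 0.216, abs=1e-9)
        assert gain == pytest.approx(2.7778, abs=1e-3)

    def test_equal_retention_means_no_gain(self):
        for ff in (0.01, 0.1, 0.4):
            assert expected_ff_gain(ff, 0.5, 0.5)[1] == pytest.approx(1.0)

    def test_gain_decreases_with_ff(self):
        _, g_low = expected_ff_gain(0.04, 0.6, 0.2)
        _, g_high = expected_ff_gain(0.30, 0.6, 0.2)
        assert g_high == pytest.approx(0.6 / (0.3 * 0.6 + 0.7 * 0.2), abs=1e-9)
        assert g_high < g_low

    def test_boundary_ffs_are_limits_not_errors(self):
        assert expected_ff_gain(0.0, 0.6, 0.2) == (0.0, pytest.approx(3.0))
        assert expected_ff_gain(1.0, 0.6, 0.2) == (1.0, 1.0)

    @settings(max_examples=60, deadline=None)
    @given(
        ff=st.floats(0.01, 0.4),
        r_m=st.floats(0.05, 0.8),
        delta=st.floats(0.01, 0.19),
        step=st.floats(0.001, 0.05),
    )
    def test_gain_strictly_decreasing_property(self, ff, r_m, delta, step):
        r_f = min(r_m + delta, 1.0)
        ff2 = min(ff + step, 0.45)
        _, g1 = expected_ff_gain(ff, r_f, r_m)
        _, g2 = expected_ff_gain(ff2, r_f, r_m)
        assert g2 < g1
        assert g1 <= r_f / r_m + 1e-12


class TestApplySelection:
    def _counts(self, genome, config, rng, ff=0.10, depth=100_000):
        return simulate_sample(genome, config, rng, ff=ff, depth=depth)

    def test_identity_spec_changes_nothing(self, small_genome, config):
        counts = self._counts(small_genome, config, np.random.default_rng(0))
        spec = SizeSelectionSpec(mode="hard", cutoff=np.inf, r_f=1.0, r_m=1.0)
        out, share = apply_size_selection(counts, spec,
                                          np.random.default_rng(1),
                                          reamplify=False)
        assert np.array_equal(out.total, counts.total)

    def test_total_maternal_depletion(self, small_genome, config):
        counts = self._counts(small_genome, config, np.random.default_rng(2))
        spec = SizeSelectionSpec(mode="hard", cutoff=150, r_f=0.7, r_m=0.0)
        out, share = apply_size_selection(counts, spec,
                                          np.random.default_rng(3),
                                          reamplify=False)
        assert out.maternal.sum() == 0
        assert share[0] == pytest.approx(1.0)

    def test_requires_compartments(self, small_genome, config):
        counts = self._counts(small_genome, config, np.random.default_rng(4))
        counts.fetal = counts.maternal = None
        spec = SizeSelectionSpec(mode="hard", cutoff=150, r_f=0.7, r_m=0.2)
        with pytest.raises(SizeSelectionError, match="compartment"):
            apply_size_selection(counts, spec, np.random.default_rng(5))

    def test_realized_gain_matches_closed_form(self, small_genome, config):
        """Monte Carlo gain against the conditional-probability oracle.

        XX-fetus samples are used so the genome-wide fetal fragment share
        equals FF exactly (an XY fetal genome is slightly shorter than the
        maternal XX genome, offsetting the share by ~1.6%)."""
        rng = np.random.default_rng(6)
        for ff in (0.03, 0.10, 0.25):
            mix = default_mixture(ff)
            spec = solve_cutoff_for_target_mean(mix, 140.0)
            ff_post_exp, _ = expected_ff_gain(ff, spec.r_f, spec.r_m)
            shares = []
            for _ in range(12):
                counts = simulate_sample(small_genome, config, rng, ff=ff,
                                         sex="XX", depth=100_000)
                _, share = apply_size_selection(counts, spec, rng,
                                                reamplify=False)
                shares.append(share[0])
            n_retained = 100_000 * (ff * spec.r_f + (1 - ff) * spec.r_m)
            se = np.sqrt(ff_post_exp * (1 - ff_post_exp) / (12 * n_retained))
            assert np.mean(shares) == pytest.approx(ff_post_exp, abs=3 * se + 1e-4)

    def test_reamplification_restores_depth(self, small_genome, config):
        counts = self._counts(small_genome, config, np.random.default_rng(7))
        mix = default_mixture(0.10)
        spec = solve_cutoff_for_target_mean(mix, 140.0)
        out, _ = apply_size_selection(counts, spec, np.random.default_rng(8),
                                      reamplify=True)
        assert out.depths()[0] == counts.depths()[0]


class TestBioinformaticWeighting:
    @pytest.fixture()
    def fragments(self, small_genome, config):
        counts = simulate_sample(small_genome, config, np.random.default_rng(9),
                                 ff=0.15, depth=30_000)
        frags = simulate_fragment_lengths(counts, config,
                                          np.random.default_rng(10))
        return counts, frags

    def test_unit_weights_reproduce_raw_counts(self, small_genome, fragments):
        counts, frags = fragments
        weighted = bioinformatic_weighting(frags, lambda l: np.ones_like(l),
                                           small_genome)
        assert np.allclose(weighted.total[:, 0], counts.total[:, 0])

    def test_indicator_weight_equals_hard_selection(self, small_genome, fragments):
        """w = 1{length <= L} counts exactly the fragments a hard molecular
        cutoff at L would retain."""
        counts, frags = fragments
        L = 150.0
        weighted = bioinformatic_weighting(
            frags, lambda l: (l <= L).astype(float), small_genome)
        kept = frags[frags["length"] <= L]
        assert weighted.total.sum() == len(kept)
        fetal_share = (kept["compartment"] == "fetal").mean()
        spec = SizeSelectionSpec(mode="hard", cutoff=L)
        r_f, r_m = retention_probabilities(default_mixture(0.15), spec)
        expected_share, _ = expected_ff_gain(0.15, r_f, r_m)
        se = np.sqrt(expected_share * (1 - expected_share) / len(kept))
        assert fetal_share == pytest.approx(expected_share, abs=4 * se)

    def test_logistic_weights_boost_effective_ff(self, small_genome, fragments):
        counts, frags = fragments
        w = lambda l: 1.0 / (1.0 + np.exp((l - 150.0) / 4.0))
        weights = w(frags["length"].to_numpy())
        fetal_mass = weights[(frags["compartment"] == "fetal").to_numpy()].sum()
        eff_ff = fetal_mass / weights.sum()
        assert eff_ff / 0.15 > 1.0

    def test_negative_weights_rejected(self, small_genome, fragments):
        _, frags = fragments
        with pytest.raises(SizeSelectionError, match="negative"):
            bioinformatic_weighting(frags, lambda l: l - 200.0, small_genome)
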