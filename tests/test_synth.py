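import numpy as np
import pytest

from mivmsim import (
    MivmError,
    anova_dunnett,
    gen_fluorescence,
    gen_outcome_table,
    make_fixture,
)
from mivmsim.synth import (
    FluorescenceGeneratorSpec,
    OutcomeGeneratorSpec,
    default_fluorescence_spec,
    default_outcome_spec,
)


class TestOutcomeGenerator:
    def test_deterministic_under_seed(self):
        t1 = gen_outcome_table(default_outcome_spec(seed=5))
        t2 = gen_outcome_table(default_outcome_spec(seed=5))
        assert np.array_equal(t1.counts, t2.counts)

    def test_degenerate_simplex_puts_everything_in_one_category(self):
        spec = OutcomeGeneratorSpec(
            categories=["a", "b", "c", "d"],
            group_probs={"g": np.array([1.0, 0, 0, 0])},
            n_per_group={"g": 75}, seed=0,
        )
        t = gen_outcome_table(spec)
        assert t.counts.tolist() == [[75, 0, 0, 0]]

    def test_invalid_simplex_raises(self):
        spec = OutcomeGeneratorSpec(
            categories=["a", "b"], group_probs={"g": np.array([0.6, 0.6])},
            n_per_group={"g": 10}, seed=0,
        )
        with pytest.raises(MivmError):
            gen_outcome_table(spec)

    def test_per_arm_mii_recovery_matches_exact_power(self):
        """Empirical *** recovery per perfused arm vs exact binomial
        enumeration: 93.9% (50 uL/min arm) and 95.9% (100 uL/min arm)."""
        from mivmsim import chi_square_2x2

        hits50 = hits100 = 0
        for seed in range(200):
            t = gen_outcome_table(default_outcome_spec(seed=seed))
            mii = t.categories.index("MII")
            a = int(t.row("CTRL")[mii])
            c5 = int(t.row("native_50")[mii])
            c1 = int(t.row("native_100")[mii])
            hits50 += chi_square_2x2(a, 75 - a, c5, 75 - c5)[1] < 0.001
            hits100 += chi_square_2x2(a, 75 - a, c1, 72 - c1)[1] < 0.001
        for rate, exact in ((hits50 / 200, 0.9386), (hits100 / 200, 0.9590)):
            se = np.sqrt(exact * (1 - exact) / 200)
            assert abs(rate - exact) <= 3 * se

    def test_replicate_mean_matches_binomial_expectation(self):
        """Across 500 replicates the control MII count averages 49 (3 SE)."""
        p_mii = 49 / 75
        counts = []
        for s in range(500):
            t = gen_outcome_table(default_outcome_spec(seed=s))
            counts.append(t.row("CTRL")[t.categories.index("MII")])
        se = np.sqrt(75 * p_mii * (1 - p_mii) / 500)
        assert abs(np.mean(counts) - 49) < 3 * se


class TestFluorescenceGenerator:
    def test_zero_sd_collapses_to_mean(self):
        spec = FluorescenceGeneratorSpec(
            group_means={"g": 120.0}, group_sds={"g": 0.0},
            n_per_group={"g": 8}, seed=1,
        )
        (s,) = gen_fluorescence(spec)
        assert np.all(s.values == 120.0)

    def test_truncation_bounds_respected(self):
        spec = FluorescenceGeneratorSpec(
            group_means={"g": 10.0}, group_sds={"g": 50.0},
            n_per_group={"g": 500}, seed=2,
        )
        (s,) = gen_fluorescence(spec)
        assert s.values.min() >= 0.0 and s.values.max() <= 255.0

    def test_default_spec_reproduces_reported_significance_pattern(self):
        samples = gen_fluorescence(default_fluorescence_spec(seed=0))
        res = anova_dunnett(samples, "CTRL")
        assert res["dunnett"]["native_50"] < 0.001
        assert res["dunnett"]["native_100"] < 0.001

    def test_power_at_1p5_sd_separation(self):
        """Two groups 1.5 pooled SD apart, n = 20: detected in >= 80% of 200 seeds."""
        hits = 0
        for seed in range(200):
            spec = FluorescenceGeneratorSpec(
                group_means={"CTRL": 130.0, "treated": 130.0 - 1.5 * 25.0},
                group_sds={"CTRL": 25.0, "treated": 25.0},
                n_per_group={"CTRL": 20, "treated": 20}, seed=seed,
            )
            samples = gen_fluorescence(spec)
            res = anova_dunnett(samples, "CTRL")
            hits += res["dunnett"]["treated"] < 0.05
        assert hits / 200 >= 0.80


class TestFixtures:
    def test_unknown_fixture_raises(self):
        with pytest.raises(MivmError):
            make_fixture("nope")

    def test_uniform_box_closed_form_is_saturation(self):
        fx = make_fixture("uniform_box")
        assert np.all(fx.closed_form(np.linspace(0, 2e-3, 5)) == 0.21)

    def test_slab_closed_form_hand_values(self):
        fx = make_fixture("two_layer_slab")
        p = fx.params
        j = p["flux_out"]
        # top of oil at saturation; interface and bottom drop by J L / D per layer
        assert fx.closed_form(4.2e-3) == pytest.approx(0.21)
        assert fx.closed_form(2.1e-3) == pytest.approx(0.21 - j * 2.1e-3 / 2e-9)
        assert fx.closed_form(0.0) == pytest.approx(
            0.21 - j * 2.1e-3 / 2e-9 - j * 2.1e-3 / 3e-9
        )

    def test_poiseuille_shear_linear_in_flow_rate(self):
        fx = make_fixture("plane_poiseuille")
        assert fx.closed_form(2e-9) == pytest.approx(2 * fx.closed_form(1e-9))
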