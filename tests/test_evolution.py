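"""Fixation probabilities and rare-mutation Moran dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from friendlyrivals import (
    EvolutionConfig,
    PayoffMatrix,
    ReactiveStrategy,
    classify_reactive,
    fixation_probability,
    imitation_probability,
    make_named,
    reactive_grid,
    robustness_certificate,
    run_moran,
)
from friendlyrivals.evolution import (
    fixation_probability_values,
    partner_pd_threshold,
)


def _fixation_direct(s_xx, s_xy, s_yx, s_yy, N, sigma):
    """Literal product-form evaluation of the closed formula (oracle)."""
    total = 0.0
    for i in range(N):
        prod = 1.0
        for j in range(1, i + 1):
            prod *= np.exp(
                sigma * ((N - j - 1) * s_yy + j * s_yx - (N - j) * s_xy - (j - 1) * s_xx)
            )
        total += prod
    return 1.0 / total


class TestImitation:
    def test_neutral_selection_is_a_coin_flip(self):
        assert imitation_probability(3.0, 1.0, 0.0) == 0.5
        assert imitation_probability(2.5, 2.5, 4.0) == 0.5

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(-5, 5, allow_nan=False),
        st.floats(-5, 5, allow_nan=False),
        st.floats(0, 10, allow_nan=False),
    )
    def test_switch_probabilities_are_complementary(self, sx, sy, sigma):
        f = imitation_probability(sx, sy, sigma)
        g = imitation_probability(sy, sx, sigma)
        # mathematically f lies in (0, 1); strongly lopsided payoffs round
        # to the boundary in float64
        assert 0.0 < f <= 1.0
        assert f + g == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_payoff_difference(self):
        probs = [imitation_probability(s, 0.0, 1.0) for s in (-1.0, 0.0, 1.0)]
        assert probs[0] > probs[1] > probs[2]


class TestFixation:
    def test_neutral_mutant_fixes_at_one_over_n(self):
        for N in (2, 10, 50, 100):
            rho = fixation_probability_values(1.0, 1.0, 1.0, 1.0, N, 10.0 / N)
            assert rho == pytest.approx(1.0 / N, rel=1e-12)

    def test_log_space_matches_direct_product_form(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            s = rng.uniform(-1, 3, size=4)
            # sigma small enough that the literal product form cannot
            # overflow, so both routes are exact
            rho_log = fixation_probability_values(*s, 50, 0.02)
            rho_direct = _fixation_direct(*s, 50, 0.02)
            assert rho_log == pytest.approx(rho_direct, rel=1e-10)

    def test_two_player_population_closed_form(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            s_xx, s_xy, s_yx, s_yy = rng.uniform(-1, 3, size=4)
            sigma = 0.8
            rho = fixation_probability_values(s_xx, s_xy, s_yx, s_yy, 2, sigma)
            assert rho == pytest.approx(1.0 / (1.0 + np.exp(sigma * (s_yx - s_xy))), rel=1e-12)

    def test_wrapper_computes_payoffs(self):
        cfg = EvolutionConfig(N=10, seed=0)
        res = fixation_probability(make_named("AllD"), make_named("AllD"), cfg)
        assert res.rho == pytest.approx(0.1, rel=1e-12)

    def test_tiny_population_rejected(self):
        with pytest.raises(ValueError):
            fixation_probability_values(1, 1, 1, 1, 1, 0.1)


class TestReactiveClassification:
    def test_donation_threshold(self):
        assert partner_pd_threshold(PayoffMatrix.donation(3.0)) == pytest.approx(2 / 3)

    @pytest.mark.parametrize(
        "pc,pd,expected",
        [
            (1.0, 0.0, "rival"),  # tie-break: never forgiving wins
            (0.3, 0.0, "rival"),
            (1.0, 0.6, "partner"),
            (1.0, 0.7, "other"),  # forgives above the threshold
            (0.5, 0.5, "other"),
            (0.9, 0.2, "other"),
        ],
    )
    def test_partner_rival_other(self, pc, pd, expected):
        assert classify_reactive(ReactiveStrategy(pc, pd), PayoffMatrix.donation(3.0)) == expected

    def test_grid_has_121_strategies(self):
        grid = reactive_grid()
        assert len(grid) == 121
        assert len({(s.pc, s.pd) for s in grid}) == 121


class TestMoran:
    def test_neutral_pair_splits_residency(self):
        # two behaviourally identical strategies (AllD as a table and as a
        # reactive pair) have equal payoffs everywhere, so residency drifts
        # to half-and-half up to Monte-Carlo error
        cfg = EvolutionConfig(
            N=20,
            steps=20_000,
            runs=2,
            seed=5,
            grid=(make_named("AllD"), ReactiveStrategy(0.0, 0.0)),
        )
        report = run_moran(cfg)
        fractions = list(report.per_strategy.values())
        assert sum(fractions) == pytest.approx(1.0, abs=1e-9)
        assert abs(fractions[0] - 0.5) < 0.1

    def test_abundances_sum_to_one(self):
        cfg = EvolutionConfig(steps=5_000, runs=1, seed=2)
        report = run_moran(cfg)
        assert sum(report.per_strategy.values()) == pytest.approx(1.0, abs=1e-9)
        class_total = (
            report.per_class["partner"] + report.per_class["rival"] + report.per_class["other"]
        )
        assert class_total == pytest.approx(1.0, abs=1e-9)

    def test_reproducible_under_seed(self):
        cfg1 = EvolutionConfig(steps=3_000, runs=1, seed=11)
        cfg2 = EvolutionConfig(steps=3_000, runs=1, seed=11)
        r1, r2 = run_moran(cfg1), run_moran(cfg2)
        assert r1.per_strategy == r2.per_strategy

    def test_capri_abundance_not_hurt_by_stronger_selection(self, capri_strategy):
        # stochastic monotone trend over three selection strengths
        abundances = []
        for sigma in (0.1, 0.2, 0.4):
            cfg = EvolutionConfig(
                steps=30_000, runs=2, seed=23, sigma=sigma, special=(capri_strategy,)
            )
            abundances.append(run_moran(cfg).per_class["CAPRI"])
        assert abundances[-1] >= abundances[0] - 0.05


class TestSweep:
    def test_rivals_gain_as_benefit_shrinks(self):
        from friendlyrivals.evolution import sweep

        cfg = EvolutionConfig(steps=20_000, runs=1, seed=3)
        rows = sweep(cfg, "b", [1.5, 5.0])
        assert [r["b"] for r in rows] == [1.5, 5.0]
        # low benefit-to-cost favours rivals relative to partners
        assert rows[0]["rival"] > rows[1]["rival"]

    def test_unknown_parameter_rejected(self):
        from friendlyrivals.evolution import sweep

        with pytest.raises(ValueError):
            sweep(EvolutionConfig(), "sigma", [0.1])


class TestRobustness:
    def test_wsls_violated_by_alld(self):
        cfg = EvolutionConfig(N=50, seed=0)
        rep = robustness_certificate(make_named("WSLS"), [make_named("AllD")], cfg)
        assert not rep.ok
        assert any(v["inequality"] == "s_yx >= s_xy" for v in rep.violations)

    def test_self_mutant_sits_at_neutral_boundary(self, capri_strategy):
        cfg = EvolutionConfig(N=50, seed=0)
        rep = robustness_certificate(capri_strategy, [capri_strategy], cfg)
        assert rep.ok

    def test_capri_robust_against_grid_corner_mutants(self, capri_strategy):
        cfg = EvolutionConfig(N=50, seed=0)
        mutants = [ReactiveStrategy(pc, pd) for pc in (0.0, 1.0) for pd in (0.0, 1.0)]
        rep = robustness_certificate(capri_strategy, mutants, cfg, N_grid=(2, 10, 50))
        assert rep.ok, rep.violations
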