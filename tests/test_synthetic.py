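import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from biocombo.core_data import proportional_mortality
from biocombo.interaction import bliss_expected, schneider_orelli
from biocombo.synthetic import (
    SimulationConfig,
    combination_day_probability,
    default_paper_treatments,
    epf_day_probability,
    pyrethrum_day_probability,
    simulate_combination_experiment,
    simulate_dose_series,
    simulate_hyphae,
    simulate_radial_growth,
    treatment_day_probability,
)


class TestConfig:
    def test_default_design_matches_study_layout(self):
        cfg = SimulationConfig()
        assert cfg.n_replicates == 4
        assert cfg.larvae_per_replicate == 10
        assert cfg.observation_days == (1, 2, 4, 7, 10, 14)
        assert len(cfg.treatments) == 9
        assert sum(t.is_combination for t in cfg.treatments) == 4

    def test_invalid_psi_rejected(self):
        with pytest.raises(ValueError, match="psi"):
            SimulationConfig(bliss_psi=0.0)


class TestDayProbabilities:
    @given(
        p_pyr=st.floats(0, 1),
        p_epf=st.floats(0, 1),
    )
    def test_psi_one_is_exact_independence(self, p_pyr, p_epf):
        combined = combination_day_probability(p_pyr, p_epf, 1.0)
        assert combined == pytest.approx(bliss_expected(p_pyr, p_epf), abs=1e-12)

    @given(p_epf=st.floats(0.01, 0.99))
    def test_psi_below_one_attenuates_fungal_kill(self, p_epf):
        assert combination_day_probability(0.0, p_epf, 0.5) < p_epf
        assert combination_day_probability(0.0, p_epf, 2.0) > p_epf

    def test_knockdown_is_a_day_one_point_mass(self):
        cfg = SimulationConfig()
        day1 = pyrethrum_day_probability(100.0, 1, cfg)
        later = pyrethrum_day_probability(100.0, 5, cfg)
        assert day1 > 0.15  # ~20% knockdown at 100 ppm
        assert later == cfg.pyrethrum_residual_daily_hazard
        assert pyrethrum_day_probability(0.0, 1, cfg) == 0.0

    def test_fungal_kill_starts_at_onset(self):
        cfg = SimulationConfig()
        assert epf_day_probability(1e5, cfg.epf_onset_day - 1, cfg) == 0.0
        assert epf_day_probability(1e5, cfg.epf_onset_day, cfg) > 0.0
        assert epf_day_probability(0.0, 10, cfg) == 0.0

    def test_epf_hazard_reproduces_day14_target(self):
        cfg = SimulationConfig()
        h = epf_day_probability(1e5, 14, cfg)
        n_days = cfg.last_day - cfg.epf_onset_day + 1
        assert 1 - (1 - h) ** n_days == pytest.approx(0.44)

    def test_unlisted_dose_falls_back_to_curve(self):
        cfg = SimulationConfig()
        assert epf_day_probability(3e4, 14, cfg) > 0.0

    def test_control_composes_into_every_arm(self):
        cfg = SimulationConfig()
        ctl = cfg.treatments[0]
        assert treatment_day_probability(ctl, 5, cfg) == pytest.approx(
            cfg.control_daily_hazard
        )


class TestCombinationExperiment:
    def test_seed_determinism(self):
        t1 = simulate_combination_experiment(SimulationConfig(seed=7))
        t2 = simulate_combination_experiment(SimulationConfig(seed=7))
        assert t1.equals(t2)
        t3 = simulate_combination_experiment(SimulationConfig(seed=8))
        assert not t1.equals(t3)

    def test_zero_hazards_zero_deaths(self):
        cfg = SimulationConfig(
            control_daily_hazard=0.0,
            pyrethrum_residual_daily_hazard=0.0,
            epf_day14_mortality={1e4: 0.0, 1e5: 0.0},
            knockdown_lc50_ppm=1e12,
        )
        t = simulate_combination_experiment(cfg)
        assert (t.df["n_dead_cum"] == 0).all()

    def test_output_satisfies_table_invariants(self, nine_arm_table):
        # construction validates; spot-check the shape too
        assert len(nine_arm_table.df) == 9 * 4 * 6
        assert nine_arm_table.observation_days == (1, 2, 4, 7, 10, 14)

    def test_large_n_combination_matches_bliss_of_single_arms(self):
        cfg = SimulationConfig(n_replicates=1, larvae_per_replicate=100_000, seed=13)
        t = simulate_combination_experiment(cfg)
        props = proportional_mortality(t, 14).set_index("treatment_label")[
            "proportion_dead"
        ]
        k = props["control"]
        a = schneider_orelli(props["epf1e5"], k)
        b = schneider_orelli(props["pyr100"], k)
        observed = schneider_orelli(props["pyr100+epf1e5"], k)
        assert observed == pytest.approx(bliss_expected(a, b), abs=0.01)

    def test_control_mortality_near_twenty_percent_by_day_14(self):
        cfg = SimulationConfig(n_replicates=1, larvae_per_replicate=100_000, seed=14)
        t = simulate_combination_experiment(cfg)
        props = proportional_mortality(t, 14).set_index("treatment_label")[
            "proportion_dead"
        ]
        assert props["control"] == pytest.approx(0.20, abs=0.02)

    def test_control_decline_is_near_linear(self):
        cfg = SimulationConfig(n_replicates=1, larvae_per_replicate=100_000, seed=15)
        t = simulate_combination_experiment(cfg)
        ctl = t.df[t.df["treatment_label"] == "control"].sort_values("day")
        frac = ctl["n_dead_cum"].to_numpy() / ctl["n_start"].to_numpy()
        slope, intercept = np.polyfit(ctl["day"], frac, 1)
        assert abs(np.polyval([slope, intercept], ctl["day"]) - frac).max() < 0.02


class TestDoseSeries:
    def test_large_n_concentration(self):
        groups = simulate_dose_series(
            "LL2", -2.0, 100.0, [10, 100, 1000], 10**6, seed=3
        )
        from biocombo.dose_response import predict

        for g in groups:
            assert g.dead / g.n == pytest.approx(
                float(predict("LL2", -2.0, 100.0, g.dose)), abs=0.002
            )

    def test_location_dose_expects_half_mortality(self):
        from biocombo.dose_response import predict

        assert float(predict("LL2", -2.0, 100.0, 100.0)) == 0.5

    def test_seed_determinism(self):
        g1 = simulate_dose_series("W2_2", 2.0, 193.0, [50, 100, 200], 30, seed=5)
        g2 = simulate_dose_series("W2_2", 2.0, 193.0, [50, 100, 200], 30, seed=5)
        assert g1 == g2


class TestRadialGrowth:
    def test_zero_variance_exactly_linear(self):
        series = simulate_radial_growth(
            {0.0: 1.5}, plate_sd=0.0, replicate_sd=0.0, noise_sd=0.0, days=(0, 5, 10)
        )
        for s in series:
            assert np.allclose(s.radii, 5.0 + 1.5 * s.days)

    def test_rate_ordering_recovered(self):
        from biocombo.ancillary import growth_rates

        series = simulate_radial_growth(
            {0.0: 2.0, 400.0: 1.5, 800.0: 1.0},
            plate_sd=0.03,
            replicate_sd=0.0,
            noise_sd=0.1,
            days=(0, 3, 6, 9, 12),
            seed=8,
        )
        rates = growth_rates(series, temperature=20.0).rates["rate"]
        assert rates[0.0] > rates[400.0] > rates[800.0]

    def test_seed_determinism_and_dish_cap(self):
        kw = dict(rates={0.0: 5.0}, days=(0, 5, 10, 20), seed=4)
        s1 = simulate_radial_growth(**kw)
        s2 = simulate_radial_growth(**kw)
        assert all(np.allclose(a.radii, b.radii) for a, b in zip(s1, s2))
        assert max(s.radii.max() for s in s1) <= 45.0
        for s in s1:
            assert (np.diff(s.radii) >= 0).all()


class TestHyphaeGenerator:
    def test_degenerate_probabilities(self):
        counts = simulate_hyphae({"a": 0.0, "b": 1.0}, {"a": 15, "b": 12}, seed=2)
        by = {c.treatment: c for c in counts}
        assert by["a"].with_hyphae == 0
        assert by["b"].with_hyphae == 12

    def test_seed_determinism(self):
        args = ({"a": 0.6, "b": 0.4}, {"a": 20, "b": 25})
        assert simulate_hyphae(*args, seed=6) == simulate_hyphae(*args, seed=6)
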