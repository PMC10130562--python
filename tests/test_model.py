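"""Unit and property tests of the resistance scale and update kernel."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from irmsim import (
    CrossResistance,
    InsecticideProfile,
    ResistanceState,
    ScaleConstants,
    Scenario,
    bioassay_survival,
    dispersal_update,
    field_survival,
    intervention_update,
    population_averaged_survival,
    potential_response,
    refugia_update,
)
from irmsim.model import MIXTURE


class TestBioassaySurvival:
    @pytest.mark.parametrize(
        "z, expected",
        [
            (100.0, 0.10),          # scale anchor: z=100 is 10% survival
            (0.0, 0.0),             # no resistance, no survival
            (900.0, 0.50),          # half-survival point of the Hill curve
            (50.0, 50.0 / 950.0),   # ~5% survival, the pre-used start level
        ],
    )
    def test_anchor_points(self, z, expected):
        assert bioassay_survival(z) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    def test_strictly_increasing_and_bounded(self, a, b):
        ka, kb = bioassay_survival(a), bioassay_survival(b)
        assert 0.0 <= ka < 1.0
        if a < b:
            assert ka < kb

    def test_negative_prs_rejected(self):
        with pytest.raises(ValueError):
            bioassay_survival(-1.0)


class TestFieldSurvival:
    @pytest.mark.parametrize(
        "kb, expected", [(0.0, 0.15), (0.10, 0.198), (1.0, 0.63)]
    )
    def test_linear_map(self, kb, expected):
        assert field_survival(kb) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            field_survival(1.2)

    def test_scale_invariant_guards(self):
        with pytest.raises(ValueError):
            ScaleConstants(phi1=0.9, phi2=0.2)  # field survival would exceed 1
        with pytest.raises(ValueError):
            ScaleConstants(z50=-5.0)


class TestPotentialResponse:
    def test_sex_averaged_response(self):
        p = InsecticideProfile(h2=0.2, psi=0.0, x=0.5, m=1.0)
        assert potential_response(p, beta=10.0) == pytest.approx(1.0)

    def test_no_heritability_no_response(self):
        p = InsecticideProfile(h2=0.0, psi=0.1, x=0.9, m=0.5)
        assert potential_response(p, beta=10.0) == 0.0

    def test_worked_example_response(self, fig_profile):
        assert potential_response(fig_profile, beta=10.0) == pytest.approx(
            1.0964, abs=5e-4
        )


def _state(z_site, z_refugia=None):
    z_site = np.asarray(z_site, dtype=float)
    if z_refugia is None:
        z_refugia = z_site.copy()
    return ResistanceState(z_site, z_refugia)


class TestInterventionUpdate:
    def test_solo_deployment_net_response(self, fig_profile, no_cross):
        scn = Scenario()
        R = potential_response(fig_profile, scn.beta)
        z = intervention_update(
            _state([0.0, 0.0]), 0, [fig_profile, fig_profile], no_cross, scn
        )
        assert z[0] == pytest.approx(R * (1 - fig_profile.psi))
        assert z[0] == pytest.approx(0.9065, abs=1e-3)

    def test_idle_clamps_at_zero(self, fig_profile, no_cross):
        z = intervention_update(
            _state([0.0, 0.0]), None, [fig_profile, fig_profile], no_cross,
            Scenario()
        )
        assert np.all(z == 0.0)

    def test_mixture_from_susceptible_stays_susceptible(self, fig_profile, no_cross):
        # partner field survival at z=0 is 0.15 < psi, so the net change is
        # negative and clamps at zero
        z = intervention_update(
            _state([0.0, 0.0]), MIXTURE, [fig_profile, fig_profile], no_cross,
            Scenario()
        )
        assert np.all(z == 0.0)

    def test_correlated_response_on_idle_trait(self):
        # R_i = R_j = 1, psi = 0.1, alpha = 0.5:
        # idle trait gains -0.1 + 0.5 * 0.9 = +0.25
        p = InsecticideProfile(h2=0.2, psi=0.1, x=1.0, m=0.0)
        z = intervention_update(
            _state([10.0, 3.0]), 1, [p, p], CrossResistance.symmetric(0.5),
            Scenario()
        )
        assert z[0] == pytest.approx(10.35)

    def test_unknown_deployment_mode_rejected(self, fig_profile, no_cross):
        with pytest.raises(ValueError):
            intervention_update(
                _state([0.0, 0.0]), "both", [fig_profile, fig_profile],
                no_cross, Scenario()
            )

    @given(
        st.floats(0, 200), st.floats(0, 200),
        st.floats(0.05, 0.3), st.floats(0.01, 0.2), st.floats(0.4, 0.9),
        st.floats(0, 1),
    )
    def test_mixture_reduces_to_uncorrelated_form_at_alpha_zero(
        self, z1, z2, h2, psi, x, m
    ):
        # with alpha = 0 the mixture change per trait must equal
        # K_partner_field * R - psi * R, computed here independently
        p = InsecticideProfile(h2=h2, psi=psi, x=x, m=m)
        scn = Scenario()
        state = _state([z1, z2])
        got = intervention_update(
            state, MIXTURE, [p, p], CrossResistance.symmetric(0.0), scn
        )
        R = potential_response(p, scn.beta)
        kf = 0.48 * np.array([z1, z2]) / (900.0 + np.array([z1, z2])) + 0.15
        expected = np.maximum(
            np.array([z1, z2]) + kf[::-1] * R - psi * R, 0.0
        )
        np.testing.assert_allclose(got, expected, rtol=0, atol=1e-12)

    @given(st.floats(0, 200), st.floats(0.05, 0.3), st.floats(0.01, 0.2))
    def test_idle_reduces_to_pure_cost_at_alpha_zero(self, z, h2, psi):
        p = InsecticideProfile(h2=h2, psi=psi, x=0.7, m=0.3)
        scn = Scenario()
        got = intervention_update(
            _state([z, 0.0]), 1, [p, p], CrossResistance.symmetric(0.0), scn
        )
        R = potential_response(p, scn.beta)
        assert got[0] == pytest.approx(max(z - psi * R, 0.0), abs=1e-12)

    @given(st.floats(0, 5000), st.floats(0.05, 0.3), st.floats(0.01, 0.2))
    def test_mixture_gain_dampened_below_063_of_solo(self, z, h2, psi):
        # field survival never exceeds 0.63, so the selection gain of a
        # mixture component is at most 0.63 times the solo gain
        p = InsecticideProfile(h2=h2, psi=psi, x=0.7, m=0.3)
        scn = Scenario()
        state = _state([z, z])
        solo_gain = intervention_update(
            state, 0, [p, p], CrossResistance.symmetric(0.0), scn
        )[0] - z
        mix_gain = intervention_update(
            state, MIXTURE, [p, p], CrossResistance.symmetric(0.0), scn
        )[0] - z
        assert mix_gain <= 0.63 * solo_gain + 1e-9

    def test_grouped_mixture_cost_toggle(self):
        p = InsecticideProfile(h2=0.2, psi=0.1, x=1.0, m=0.0)  # R = 1
        state = _state([0.0, 0.0])
        scn = Scenario(mixture_cost_scaled=True)
        z = intervention_update(
            state, MIXTURE, [p, p], CrossResistance.symmetric(0.0), scn
        )
        # grouped reading: K_jF * R * (1 - psi) = 0.15 * 0.9 > 0
        assert z[0] == pytest.approx(0.15 * 0.9)


class TestRefugiaUpdate:
    @pytest.mark.parametrize(
        "z, psi, expected", [(5.0, 0.1, 4.9), (0.0, 0.1, 0.0), (5.0, 0.0, 5.0)]
    )
    def test_cost_decay_with_clamp(self, z, psi, expected):
        p = InsecticideProfile(h2=0.2, psi=psi, x=1.0, m=0.0)  # R = 1
        got = refugia_update(_state([1.0, 1.0], [z, z]), [p, p], Scenario())
        assert got[0] == pytest.approx(expected)


class TestDispersalUpdate:
    def test_worked_example_immigrant_fractions(self, fig_scenario):
        assert fig_scenario.r_into_site == pytest.approx(0.27545, abs=1e-5)
        assert fig_scenario.r_into_refugia == pytest.approx(0.60900, abs=1e-5)

    def test_no_dispersal_leaves_sites_independent(self):
        scn = Scenario(coverage=0.5, dispersal=0.0)
        zt, zu = dispersal_update(np.array([3.0]), np.array([7.0]), scn)
        assert zt[0] == 3.0 and zu[0] == 7.0

    @given(
        st.floats(0, 500), st.floats(0, 500),
        st.floats(0, 1), st.floats(0, 1),
    )
    def test_convex_mixing(self, a, b, C, theta):
        scn = Scenario(coverage=C, dispersal=theta)
        zt, zu = dispersal_update(np.array([a]), np.array([b]), scn)
        lo, hi = min(a, b), max(a, b)
        assert lo - 1e-9 <= zt[0] <= hi + 1e-9
        assert lo - 1e-9 <= zu[0] <= hi + 1e-9
        if a == b:
            assert zt[0] == pytest.approx(a) and zu[0] == pytest.approx(a)


class TestPopulationAveragedSurvival:
    def test_degenerate_distribution_is_the_hill_curve(self):
        assert population_averaged_survival(100.0, 0.0) == pytest.approx(0.10)

    def test_scale_anchor_stable_up_to_sd_25(self):
        # individual variation barely moves the z=100 -> 10% anchor
        v = population_averaged_survival(100.0, 25.0)
        assert abs(v - 0.10) < 0.005

    def test_monte_carlo_oracle_agreement(self):
        rng = np.random.default_rng(12345)
        for mean, sd in ((100.0, 25.0), (0.0, 25.0), (500.0, 40.0)):
            draws = rng.normal(mean, sd, size=400_000)
            surv = np.where(draws > 0, draws / (900.0 + np.maximum(draws, 0)), 0.0)
            mc = surv.mean()
            assert population_averaged_survival(mean, sd) == pytest.approx(
                mc, abs=2e-3
            )

    def test_susceptible_population_tail_survival_is_tiny_but_positive(self):
        v = population_averaged_survival(0.0, 25.0)
        assert 0.0 < v < 0.02

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            population_averaged_survival(np.inf, 1.0)
        with pytest.raises(ValueError):
            population_averaged_survival(100.0, -1.0)


class TestValidation:
    def test_profile_bounds(self):
        with pytest.raises(ValueError):
            InsecticideProfile(h2=1.2, psi=0.1, x=0.5, m=0.5)
        with pytest.raises(ValueError):
            InsecticideProfile(h2=0.2, psi=0.1, x=0.5, m=0.5, z0=120.0)

    def test_scenario_threshold_ordering(self):
        with pytest.raises(ValueError):
            Scenario(withdrawal_threshold=0.08, return_threshold=0.10)

    def test_cross_resistance_bounds(self):
        with pytest.raises(ValueError):
            CrossResistance(alpha_ji=1.5)

    def test_state_rejects_negative_means(self):
        with pytest.raises(ValueError):
            ResistanceState(np.array([-1.0, 0.0]), np.array([0.0, 0.0]))
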