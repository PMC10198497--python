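"""Physiology engine: effective rates, annual update, detection and the
multistage-hazard oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mammosim as m
from mammosim.exposure_effects import ModifierSet, modifiers_for
from mammosim.tissue_dynamics import (
    EffectiveRates,
    TissueState,
    annual_update,
    armitage_doll_hazard,
    default_loss_fraction,
    detect,
    effective_rates,
)


class TestEffectiveRates:
    def test_growth_zero_before_menarche(self, parous_woman, params, effects):
        mods = modifiers_for(parous_woman, 8, effects)
        rates = effective_rates(params, mods, 8, parous_woman)
        assert np.all(rates.growth[:5] == 0.0)

    def test_breastfeeding_multiplies_every_loss_rate_by_100(
        self, parous_woman, params, effects
    ):
        bf_age = parous_woman.birth_ages[0] + 1
        plain_age = 31  # same parous pre-menopausal stage, no lactation
        mods = modifiers_for(parous_woman, bf_age, effects)
        r_bf = effective_rates(params, mods, bf_age, parous_woman)
        mods2 = modifiers_for(parous_woman, plain_age, effects)
        r_plain = effective_rates(params, mods2, plain_age, parous_woman)
        np.testing.assert_allclose(r_bf.loss / r_plain.loss, 100.0)

    def test_loss_fraction_linear_interpolation(self):
        frac = default_loss_fraction()
        assert frac[0] == 1.0
        assert frac[2] == pytest.approx(0.74)  # 1 - 2*(1-0.48)/4
        assert frac[4] == pytest.approx(0.48)
        assert frac[5] == 0.25

    def test_late_loss_elevation_from_onset_age(self, nulliparous_woman,
                                                params, effects):
        params.late_loss_onset_age = 74
        params.late_loss_factor = 2.0
        mods = modifiers_for(nulliparous_woman, 73, effects)
        before = effective_rates(params, mods, 73, nulliparous_woman)
        after = effective_rates(params, mods, 74, nulliparous_woman)
        np.testing.assert_allclose(after.loss / before.loss, 2.0)

    def test_negative_modifier_rejected(self, parous_woman, params):
        bad = ModifierSet()
        bad.growth_mult = np.full(6, -1.0)
        with pytest.raises(ValueError):
            effective_rates(params, bad, 30, parous_woman)

    def test_attenuation_scales_growth_geometrically(
        self, nulliparous_woman, params, effects
    ):
        params.growth_rate_attenuation = 1.5
        mods = modifiers_for(nulliparous_woman, 30, effects)
        rates = effective_rates(params, mods, 30, nulliparous_woman)
        ratios = rates.growth[1:5] / rates.growth[:4]
        np.testing.assert_allclose(ratios, 1.5)


class TestAnnualUpdate:
    def _rates(self, growth=0.0, loss=0.0, transform=0.0):
        return EffectiveRates(
            growth=np.full(6, growth),
            loss=np.full(6, loss),
            transform=np.full(6, transform),
        )

    def test_zero_pools_stay_zero(self, rng):
        state = TissueState(dense=0.0)
        out = annual_update(state, self._rates(0.5, 0.1, 0.9), "stochastic",
                            rng)
        assert np.all(out.classes == 0.0)

    def test_mean_field_exponential_update(self):
        state = TissueState(dense=0.0, classes=[1, 0, 0, 0, 0, 0])
        rates = EffectiveRates(
            growth=np.array([0.1, 0, 0, 0, 0, 0]),
            loss=np.array([0.05, 0, 0, 0, 0, 0]),
            transform=np.zeros(6),
        )
        out = annual_update(state, rates, "mean_field")
        assert out.classes[0] == pytest.approx(math.exp(0.05))
        assert round(out.classes[0], 4) == 1.0513

    def test_mean_field_conservation_before_growth(self):
        state = TissueState(dense=2.0, classes=[1.0, 0.5, 0.2, 0.1, 0.05, 0])
        rates = self._rates(transform=0.1)
        out = annual_update(state, rates, "mean_field")
        # no growth/loss: total transformed volume gained = influx from dense
        assert out.classes.sum() == pytest.approx(
            state.classes.sum() + 0.1 * state.dense
        )

    def test_stochastic_mean_flux_matches_poisson_mean(self):
        # v1=10, rate 0.01, q=0.1: mean volume moved to class 2 per year
        # is 0.01*10 = 0.1 (Poisson mean 1 times quantum 0.1)
        moved = []
        state = TissueState(dense=0.0, classes=[10, 0, 0, 0, 0, 0])
        rates = EffectiveRates(
            growth=np.zeros(6), loss=np.zeros(6),
            transform=np.array([0, 0.01, 0, 0, 0, 0]),
        )
        rng = np.random.default_rng(7)
        for _ in range(10_000):
            out = annual_update(state, rates, "stochastic", rng, quantum=0.1)
            moved.append(out.classes[1])
        assert np.mean(moved) == pytest.approx(0.1, rel=0.05)

    @given(
        dense=st.floats(0, 5),
        v=st.lists(st.floats(0, 5), min_size=6, max_size=6),
        transform=st.floats(0, 3),
        growth=st.floats(0, 1),
        loss=st.floats(0, 3),
    )
    @settings(max_examples=100, deadline=None)
    def test_non_negativity_for_any_admissible_rates(
        self, dense, v, transform, growth, loss
    ):
        state = TissueState(dense=dense, classes=np.array(v))
        rates = EffectiveRates(
            growth=np.full(6, growth),
            loss=np.full(6, loss),
            transform=np.full(6, transform),
        )
        rng = np.random.default_rng(0)
        out = annual_update(state, rates, "stochastic", rng, quantum=0.01)
        assert np.all(out.classes >= 0)

    def test_non_finite_state_rejected(self):
        state = TissueState(dense=1.0)
        state.classes[0] = np.nan
        with pytest.raises(FloatingPointError):
            annual_update(state, self._rates(), "mean_field")


class TestDetect:
    def test_threshold_logic(self, params):
        params.theta_clinical = 1.0
        params.theta_screen = 0.25
        empty = TissueState()
        assert not detect(empty, True, params)
        clinical = TissueState(classes=[0, 0, 0, 0, 0, 1.5])
        assert detect(clinical, False, params)
        subclinical = TissueState(classes=[0, 0, 0, 0, 0, 0.5])
        assert detect(subclinical, True, params)
        assert not detect(subclinical, False, params)


class TestSimulateIndividual:
    def test_zero_rates_no_cancer(self, parous_woman, effects):
        params = m.RateParameters(tau=0.0, tau_final=0.0, g0=0.0,
                                  g_malignant=0.0, lambda0=0.0)
        rng = np.random.default_rng(0)
        woman = m.Individual(menarche_age=12, menopause_age=50, death_age=40)
        out = m.simulate_individual(woman, params, effects, rng)
        assert not out.cancer_detected
        assert out.death_age == 40

    def test_determinism_same_seed(self, parous_woman, params, effects):
        outs = [
            m.simulate_individual(
                parous_woman, params, effects, np.random.default_rng(99)
            )
            for _ in range(2)
        ]
        assert outs[0] == outs[1]

    def test_birth_seeding_can_only_detect_after_growth(self, effects):
        # a seeded clone below threshold needs growth years before detection
        params = m.RateParameters(tau=0.0, tau_final=0.0, g0=0.0,
                                  g_malignant=0.5, lambda0=0.0,
                                  theta_clinical=1.0, theta_screen=0.5)
        woman = m.Individual(menarche_age=12, menopause_age=50, death_age=30)
        rng = np.random.default_rng(0)
        out = m.simulate_individual(
            woman, params, effects, rng, seed_schedule={0: (6, 0.01)}
        )
        assert out.cancer_detected
        assert out.detection_age == pytest.approx(
            np.ceil(np.log(1.0 / 0.01) / 0.5), abs=1
        )


class TestArmitageDollHazard:
    def test_closed_form_log_log_slopes(self):
        for k, slope in [(6, 5.0), (5, 4.0)]:
            rates = np.full(k, 1e-3)
            t1, t2 = 20.0, 60.0
            s = (
                np.log(armitage_doll_hazard(t2, rates))
                - np.log(armitage_doll_hazard(t1, rates))
            ) / (np.log(t2) - np.log(t1))
            assert s == pytest.approx(slope, abs=1e-9)

    def test_prefactor(self):
        rates = np.array([0.1, 0.2])
        assert armitage_doll_hazard(3.0, rates) == pytest.approx(
            0.1 * 0.2 * 3.0
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            armitage_doll_hazard(-1.0, [0.1])
        with pytest.raises(ValueError):
            armitage_doll_hazard(1.0, [])
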