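"""Cross-validation of the cohort engine: scalar-path agreement, the
event-driven (Gillespie) oracle, and the multistage-hazard limit."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

import mammosim as m
from mammosim.cohort import cohort_from_individuals, poisson_inverse_cdf, simulate_cohort
from mammosim.epi_stats import age_specific_incidence, log_slope
from mammosim.tissue_dynamics import EffectiveRates, TissueState, annual_update


class TestScalarVectorAgreement:
    def test_mean_field_paths_identical(self, config, effects):
        """The per-individual reference path and the vectorized engine are
        the same update; in mean-field mode (no randomness, no screening)
        they must produce identical detection ages."""
        pop = m.sample_population(config, 50, seed=5)
        pop = [
            m.Individual(**{**ind.__dict__, "screening_frequency": 0})
            for ind in pop
        ]
        params = m.RateParameters()
        co = cohort_from_individuals(pop)
        vec = simulate_cohort(
            co, params, effects, mode="mean_field", seed=0,
            use_screening=False,
        )
        for i, ind in enumerate(pop):
            out = m.simulate_individual(
                ind, params, effects, np.random.default_rng(0),
                mode="mean_field",
            )
            vec_age = vec.detection_age[i]
            if out.cancer_detected:
                assert vec_age == out.detection_age
            else:
                assert np.isnan(vec_age)


class TestPoissonQuantile:
    @pytest.mark.parametrize("lam", [0.05, 0.9, 7.0, 40.0])
    def test_moments_match_poisson(self, lam, rng):
        u = rng.random(100_000)
        x = poisson_inverse_cdf(u, np.full(100_000, lam))
        assert np.mean(x) == pytest.approx(lam, rel=0.03)
        assert np.var(x) == pytest.approx(lam, rel=0.05)

    def test_monotone_in_rate_for_fixed_uniforms(self, rng):
        u = rng.random(10_000)
        x1 = poisson_inverse_cdf(u, np.full(10_000, 0.5))
        x2 = poisson_inverse_cdf(u, np.full(10_000, 0.8))
        assert np.all(x2 >= x1)


def _gillespie_first_passage(tau1, tau2, volume, quantum, threshold, rng,
                             t_max=600.0):
    """Independent continuous-time oracle for the 2-class toy system:
    quanta enter class 1 at rate tau1*volume/q and convert to class 2 at
    rate tau2 per quantum; returns the year of first passage of class-2
    volume past the threshold (inf if never)."""
    n1 = 0
    n2 = 0
    t = 0.0
    need = int(np.ceil(threshold / quantum))
    while t < t_max:
        a1 = tau1 * volume / quantum
        a2 = tau2 * n1
        total = a1 + a2
        t += rng.exponential(1.0 / total)
        if rng.random() < a1 / total:
            n1 += 1
        else:
            n1 -= 1
            n2 += 1
            if n2 >= need:
                return int(np.ceil(t))
    return np.inf


class TestGillespieOracle:
    def test_first_passage_distribution_matches(self):
        """Annual-step engine vs an exact event-driven simulator on a
        2-class constant-rate system (KS test at n = 2,000)."""
        # rates small enough that the engine's one-year transformation
        # granularity is negligible against the event waiting times
        tau1, tau2 = 0.03, 0.04
        volume, quantum, threshold = 1.0, 0.05, 0.15
        n_rep = 2_000

        rng = np.random.default_rng(2024)
        oracle = np.array([
            _gillespie_first_passage(tau1, tau2, volume, quantum, threshold,
                                     rng)
            for _ in range(n_rep)
        ])

        rates = EffectiveRates(
            growth=np.zeros(6),
            loss=np.zeros(6),
            transform=np.array([tau1, tau2, 0, 0, 0, 0]),
        )
        engine = np.full(n_rep, np.inf)
        rng2 = np.random.default_rng(77)
        for r in range(n_rep):
            state = TissueState(dense=volume)
            for year in range(1, 601):
                state = annual_update(state, rates, "stochastic", rng2,
                                      quantum=quantum)
                if state.classes[1] >= threshold:
                    engine[r] = year
                    break

        both = np.isfinite(oracle) & np.isfinite(engine)
        assert both.mean() > 0.95
        stat, p = ks_2samp(oracle[np.isfinite(oracle)],
                           engine[np.isfinite(engine)])
        assert p > 0.01


@pytest.fixture(scope="module")
def homogeneous_cohort():
    """Identical women with constant susceptible tissue from birth and no
    reproductive transitions inside the simulated span (menopause beyond
    death), isolating the pure multistage cascade."""
    ind = m.Individual(menarche_age=0, menopause_age=150, death_age=80)
    return cohort_from_individuals([ind] * 100_000)


def _ad_params(tau_final):
    # coarse quantum = detection threshold: each woman is a sparse chain of
    # single transformation events and the first malignant quantum is the
    # detected case, the classical multistage picture
    return m.RateParameters(
        tau=0.02, tau_final=tau_final, g0=0.0, g_malignant=0.0,
        lambda0=0.0, quantum=0.08, theta_clinical=0.08,
        theta_screen=0.04, late_loss_factor=1.0,
        late_loss_onset_age=999,
    )


class TestArmitageDollLimit:
    def test_six_step_slope_near_five_and_final_step_shifts_toward_four(
        self, homogeneous_cohort, effects
    ):
        """With growth and loss off and homogeneous small rates, incidence
        follows the k-stage hazard ~ t^(k-1): log-log slope 5 for six
        steps, moving toward 4 as the final step becomes instantaneous."""
        slopes = []
        for tau_final in (0.02, 20.0):
            out = simulate_cohort(
                homogeneous_cohort, _ad_params(tau_final), effects,
                mode="stochastic", seed=3, horizon=80,
                use_screening=False, force_survival=True,
            )
            curve = age_specific_incidence(out, bins=np.arange(0, 85, 5))
            slopes.append(log_slope(curve, (15.0, 60.0)))
        assert slopes[0] == pytest.approx(5.0, abs=0.3)
        assert slopes[1] == pytest.approx(4.0, abs=0.3)
        assert slopes[1] < slopes[0]


class TestMonotonicity:
    @pytest.mark.parametrize(
        "name, values, direction",
        [
            ("tau", [4e-3, 5.1e-3, 6.5e-3], +1),
            ("g0", [0.06, 0.08, 0.10], +1),
            ("lambda0", [0.03, 0.045, 0.06], -1),
        ],
    )
    def test_cumulative_incidence_monotone_in_rates(
        self, config, effects, name, values, direction
    ):
        pop = m.sample_population(config, 30_000, seed=9)
        co = cohort_from_individuals(pop)
        cis = []
        for v in values:
            params = m.RateParameters(**{name: v})
            out = simulate_cohort(
                co, params, effects, mode="stochastic", seed=4, horizon=75,
                use_screening=False, force_survival=True,
            )
            cis.append(np.mean(out.detection_age <= 75))
        diffs = np.diff(cis) * direction
        assert np.all(diffs > 0), (name, cis)

    def test_cumulative_incidence_monotone_in_smoking_multiplier(
        self, config, effects
    ):
        import copy

        pop = m.sample_population(config, 30_000, seed=9)
        co = cohort_from_individuals(pop)
        co.smoker[:] = True
        params = m.RateParameters()
        cis = []
        for s in (1.0, 1.1, 1.3):
            e = copy.deepcopy(effects)
            e.sigma_smoke = s
            out = simulate_cohort(
                co, params, e, mode="stochastic", seed=4, horizon=75,
                use_screening=False, force_survival=True,
            )
            cis.append(np.mean(out.detection_age <= 75))
        assert cis[0] < cis[1] < cis[2]
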