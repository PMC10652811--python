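"""Virtual-cohort trials: cohort construction, simulation, comparisons."""

import numpy as np
import pandas as pd
import pytest

from cycletrial.assays import default_truth
from cycletrial.cellcycle import growth_rate
from cycletrial.trial import (
    SyntheticPosterior,
    TrialResult,
    VirtualPatient,
    build_cohort,
    compare_schedules,
    fraction_below,
    heterogeneity_sweep,
    resistance_grid,
    run_trial,
    simulate_patient,
)


@pytest.fixture(scope="module")
def posterior():
    return SyntheticPosterior(default_truth("sensitive_plusDOX"), n_draws=100, seed=1)


@pytest.fixture(scope="module")
def degenerate_posterior():
    p = SyntheticPosterior(default_truth("sensitive_plusDOX"), n_draws=1, rel_sd=0.0, seed=1)
    return p


@pytest.fixture(scope="module")
def small_trial(posterior):
    cohort = build_cohort(posterior, n=8, seed=5)
    return run_trial(cohort, ["standard", "daily_100"], seed=5)


class TestCohort:
    def test_size_and_determinism(self, posterior):
        c1 = build_cohort(posterior, n=6, seed=9)
        c2 = build_cohort(posterior, n=6, seed=9)
        assert len(c1) == 6
        assert all(a == b for a, b in zip(c1, c2))
        c3 = build_cohort(posterior, n=6, seed=10)
        assert any(a != b for a, b in zip(c1, c3))

    def test_degenerate_posterior_shares_pd_parameters(self, degenerate_posterior):
        cohort = build_cohort(degenerate_posterior, n=5, seed=0)
        assert all(p.wt == cohort[0].wt for p in cohort)
        # PK still varies between patients
        assert cohort[0].pk_palbo != cohort[1].pk_palbo

    def test_mutant_fraction_requires_mutant_posterior(self, posterior):
        with pytest.raises(ValueError):
            build_cohort(posterior, n=2, seed=0, mutant_fraction=0.5)


class TestSimulatePatient:
    def test_zero_dose_grows_at_control_eigenvalue(self, degenerate_posterior):
        patient = build_cohort(degenerate_posterior, n=1, seed=0)[0]
        days, total = simulate_patient(patient, "daily_100", horizon=20.0,
                                       dose_scale=(0.0, 0.0))
        rho = growth_rate(patient.wt.cell_cycle, patient.wt.interaction.lambda_ctrl)
        slope = (np.log(total[-1]) - np.log(total[10])) / (days[-1] - days[10])
        assert slope == pytest.approx(rho, rel=1e-3)
        assert total[0] == pytest.approx(patient.day0, rel=1e-9)

    def test_mixture_bracketed_by_pure_populations(self, degenerate_posterior):
        wt_post = degenerate_posterior
        mut_truth = default_truth("palbo_resistant")
        mut_post = SyntheticPosterior(mut_truth, n_draws=1, rel_sd=0.0, seed=2)
        finals = []
        for f in (0.0, 0.3, 0.7, 1.0):
            cohort = build_cohort({"wt": wt_post, "mutant": mut_post}, n=1, seed=4,
                                  mutant_fraction=f)
            _, total = simulate_patient(cohort[0], "daily_100", horizon=40.0)
            finals.append(total[-1])
        assert all(b > a for a, b in zip(finals, finals[1:]))  # resistant mutant grows more

    def test_step_halving_stability(self, degenerate_posterior):
        patient = build_cohort(degenerate_posterior, n=1, seed=0)[0]
        _, t1 = simulate_patient(patient, "standard", horizon=50.0, step=0.05)
        _, t2 = simulate_patient(patient, "standard", horizon=50.0, step=0.025)
        assert t1[-1] == pytest.approx(t2[-1], rel=1e-3)

    def test_invalid_step_rejected(self, degenerate_posterior):
        patient = build_cohort(degenerate_posterior, n=1, seed=0)[0]
        with pytest.raises(ValueError, match="step"):
            simulate_patient(patient, "standard", step=0.3)


class TestRunTrial:
    def test_output_shape_row_count(self, small_trial):
        frame = small_trial.to_frame()
        assert len(frame) == 8 * 2  # patients x schedules
        assert small_trial.n_patients == 8

    def test_identical_schedules_produce_identical_results(self, posterior):
        cohort = build_cohort(posterior, n=3, seed=2)
        res = run_trial(cohort, ["daily_75", "daily_75"])
        # dict keys collapse; simulate explicitly instead
        a = [simulate_patient(p, "daily_75")[1] for p in cohort]
        b = [simulate_patient(p, "daily_75")[1] for p in cohort]
        np.testing.assert_allclose(a, b)
        assert isinstance(res, TrialResult)

    def test_dominated_schedule_never_ranks_better(self, degenerate_posterior):
        """Scaling every concentration down must not reduce tumor burden."""
        patient = build_cohort(degenerate_posterior, n=1, seed=1)[0]
        _, full = simulate_patient(patient, "daily_100", dose_scale=(1.0, 1.0))
        _, weak = simulate_patient(patient, "daily_100", dose_scale=(0.5, 0.5))
        assert weak[-1] > full[-1]

    def test_reproducibility_under_fixed_seed(self, posterior):
        cohort = build_cohort(posterior, n=4, seed=3)
        r1 = run_trial(cohort, ["standard"], seed=3)
        r2 = run_trial(build_cohort(posterior, n=4, seed=3), ["standard"], seed=3)
        np.testing.assert_array_equal(r1.trajectories["standard"],
                                      r2.trajectories["standard"])


class TestComparisons:
    def test_fully_separated_samples_give_tiny_p(self):
        days = np.arange(0.0, 3.0)
        traj = {
            "a": np.tile([[1.0, 1.0, 1.0]], (50, 1)) * np.arange(1, 51)[:, None],
            "b": np.tile([[1.0, 1.0, 1.0]], (50, 1)) * np.arange(100, 150)[:, None],
        }
        res = TrialResult(days=days, trajectories=traj, schedules=["a", "b"], seed=0)
        cmp_ = compare_schedules(res, reference="a", waterfall_n=10)
        p = cmp_["pairwise"]["p_value"].iloc[0]
        assert p < 1e-10

    def test_waterfall_is_non_increasing(self, small_trial):
        cmp_ = compare_schedules(small_trial, waterfall_n=5)
        for _, grp in cmp_["waterfall"].groupby("schedule"):
            vals = grp.sort_values("rank")["day100_count"].to_numpy()
            assert np.all(np.diff(vals) <= 0)

    def test_ratio_band_of_reference_is_unity(self, small_trial):
        cmp_ = compare_schedules(small_trial)
        ref = cmp_["ratio_bands"]
        ref = ref[ref["schedule"] == "standard"]
        np.testing.assert_allclose(ref["median"], 1.0)

    def test_fraction_below_trivial_thresholds(self, small_trial):
        assert fraction_below(small_trial, threshold=np.inf)["daily_100"] == 100.0
        assert fraction_below(small_trial, threshold=0.25)["standard"] == 0.0

    def test_fraction_below_matches_direct_count(self, small_trial):
        frac = fraction_below(small_trial, threshold=0.25)
        ratio = small_trial.day100("daily_100") / small_trial.day100("standard")
        assert frac["daily_100"] == pytest.approx(100.0 * np.mean(ratio < 0.25))


class TestScenarioSweeps:
    def test_resistance_multiplier_one_reproduces_base(self, posterior):
        truth = default_truth("sensitive_plusDOX")
        table = resistance_grid(truth, schedules=("standard", "daily_100"),
                                axes={"C_P": (1.0,)}, n_patients=5, seed=8, n_draws=50)
        base = table[table["schedule"] == "daily_100"]["mean_ratio_to_ref"].iloc[0]
        post = SyntheticPosterior(truth, n_draws=50, rel_sd=0.05, seed=8)
        cohort = build_cohort(post, n=5, seed=8)
        res = run_trial(cohort, ("standard", "daily_100"), seed=8)
        direct = np.mean(res.day100("daily_100") / res.day100("standard"))
        assert base == pytest.approx(direct, rel=1e-9)

    def test_resistance_erodes_continuous_advantage(self):
        truth = default_truth("sensitive_plusDOX")
        table = resistance_grid(truth, schedules=("standard", "daily_100"),
                                axes={"C_P": (1.0, 10.0, 100.0)}, n_patients=10,
                                seed=2, n_draws=50)
        sub = table[table["schedule"] == "daily_100"].sort_values("mult_C_P")
        ratios = sub["mean_ratio_to_ref"].to_numpy()
        assert ratios[0] < ratios[1] < ratios[2]

    def test_heterogeneity_endpoints_match_homogeneous_trials(self):
        wt = SyntheticPosterior(default_truth("sensitive_plusDOX"), n_draws=30, seed=4)
        mut = SyntheticPosterior(default_truth("palbo_resistant"), n_draws=30, seed=5)
        sweep = heterogeneity_sweep(wt, mut, schedules=("daily_100",),
                                    fractions=(0.0, 0.5, 1.0), n_patients=4, seed=6)
        assert len(sweep) == 3
        med = sweep.set_index("mutant_fraction")["median_day100"]
        assert med[0.0] < med[0.5] < med[1.0]  # resistant fraction grows burden


class TestVirtualPatientValidation:
    def test_mutant_fraction_bounds(self, degenerate_posterior):
        p = build_cohort(degenerate_posterior, n=1, seed=0)[0]
        with pytest.raises(ValueError):
            VirtualPatient(pk_palbo=p.pk_palbo, pk_fulv=p.pk_fulv, wt=p.wt,
                           mutant_fraction=1.5)
        with pytest.raises(ValueError):
            VirtualPatient(pk_palbo=p.pk_palbo, pk_fulv=p.pk_fulv, wt=p.wt,
                           mutant_fraction=0.4)  # no mutant params supplied
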