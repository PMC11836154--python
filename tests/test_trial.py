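"""Markov-chain follow-up: absorbing dynamics, determinism, closed forms."""

import numpy as np
import pytest

from silicofem import (
    ImpactParams,
    StrengthSurface,
    TrialConfig,
    VirtualPatient,
    poisson_pmf,
    run_trial,
    simulate_realization,
)


def make_patient(pid="P1", strength=1e6, height=1.60, weight=66.0, stt=20.0):
    return VirtualPatient(
        id=pid,
        total_hip_aBMD=0.72,
        neck_aBMD=0.56,
        height=height,
        weight=weight,
        BMI=weight / height**2,
        soft_tissue_thickness=stt,
        strength=StrengthSurface(np.full((61, 31), float(strength))),
    )


def toy_cohort(n, strength=1e6):
    return [make_patient(f"P{i:04d}", strength=strength) for i in range(n)]


class TestSimulateRealization:
    def test_unbreakable_bones_never_fracture(self):
        cohort = toy_cohort(100, strength=1e7)
        cfg = TrialConfig(lam=1.0, years=3)
        recs, n_eval, per_year = simulate_realization(cohort, cfg, np.random.SeedSequence(1))
        assert recs == [] and per_year.sum() == 0 and n_eval > 0

    def test_zero_rate_means_zero_everything(self):
        cohort = toy_cohort(50)
        cfg = TrialConfig(lam=0.0, years=3)
        recs, n_eval, per_year = simulate_realization(cohort, cfg, np.random.SeedSequence(1))
        assert recs == [] and n_eval == 0 and per_year.sum() == 0

    def test_guaranteed_fracture_in_year_one(self):
        # effectively certain yearly fall, force always above strength
        cohort = [make_patient(strength=1e-3)]
        cfg = TrialConfig(lam=30.0, years=3, n_realizations=10)
        res = run_trial(cohort, cfg)
        assert np.all(res.fractures_per_realization == 1)
        assert np.all(res.per_year_counts[:, 0] == 1)
        assert np.all(res.per_year_counts[:, 1:] == 0)
        # the fracturing fall ends the patient's follow-up immediately
        assert np.all(res.n_strength_evaluations_per_realization == 1)

    def test_absorbing_state_no_records_after_fracture(self):
        cohort = toy_cohort(200, strength=2200.0)  # close to typical forces
        cfg = TrialConfig(lam=1.5, years=3)
        recs, _, _ = simulate_realization(cohort, cfg, np.random.SeedSequence(3))
        seen = {}
        for r in recs:
            assert r.patient_id not in seen  # at most one fracture per patient
            assert 1 <= r.year <= 3
            assert r.force > r.failure_load
            seen[r.patient_id] = r.year


class TestRunTrial:
    def test_single_realization_degenerate_spread(self):
        cohort = toy_cohort(30, strength=2000.0)
        res = run_trial(cohort, TrialConfig(lam=1.0, n_realizations=1, master_seed=5))
        assert res.sd == 0.0 and res.min == res.max == int(res.mean)

    def test_master_seed_reproducibility(self):
        cohort = toy_cohort(80, strength=2300.0)
        cfg = TrialConfig(lam=1.0, n_realizations=4, master_seed=123)
        r1 = run_trial(cohort, cfg)
        r2 = run_trial(cohort, cfg)
        assert np.array_equal(r1.fractures_per_realization, r2.fractures_per_realization)
        assert np.array_equal(
            r1.n_strength_evaluations_per_realization, r2.n_strength_evaluations_per_realization
        )
        assert r1.records == r2.records

    def test_summary_statistics_consistent(self):
        cohort = toy_cohort(100, strength=2300.0)
        res = run_trial(cohort, TrialConfig(lam=1.0, n_realizations=6, master_seed=9))
        x = res.fractures_per_realization
        assert res.min <= res.mean <= res.max
        assert np.array_equal(res.per_year_counts.sum(axis=1), x)
        assert len(res.records) == x.sum()

    def test_strengthening_bones_never_adds_fractures(self):
        # common random numbers: same master seed, surfaces scaled up
        weak = toy_cohort(300, strength=2200.0)
        strong = [make_patient(p.id, strength=2200.0 * 1.5) for p in weak]
        cfg = TrialConfig(lam=1.0, n_realizations=5, master_seed=11)
        r_weak = run_trial(weak, cfg)
        r_strong = run_trial(strong, cfg)
        assert np.all(r_strong.fractures_per_realization <= r_weak.fractures_per_realization)

    def test_missing_strength_surface_is_an_error(self):
        p = make_patient()
        p.strength = None
        with pytest.raises(ValueError, match="strength surface"):
            simulate_realization([p], TrialConfig(), np.random.SeedSequence(0))


class TestClosedFormAndOracle:
    def test_always_fracture_matches_poisson_complement(self):
        # force always exceeds strength: 3-year fracture probability is
        # P(at least one fall) = 1 - exp(-3*lam)
        n = 500
        cohort = toy_cohort(n, strength=1e-3)
        res = run_trial(cohort, TrialConfig(lam=0.65, years=3, n_realizations=4, master_seed=2))
        p = 1 - np.exp(-3 * 0.65)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(res.mean / n - p) < 3 * se / np.sqrt(4)

    def test_exhaustive_enumeration_oracle(self):
        """Five heterogeneous patients, two years, deterministic forces.

        With velocity noise off, each patient's impact force is a known
        constant, and their surface is weak on a chosen set of beta
        columns, so the per-fall fracture probability is an exact grid
        fraction.  Truncated enumeration over Poisson fall counts gives
        the exact per-patient fracture probability; the simulator's
        empirical mean must agree within 3 SE.
        """
        impact = ImpactParams(velocity_noise_cv=0.0)
        lam, years = 0.4, 2
        rng = np.random.default_rng(0)
        cohort = []
        weak_cols = [3, 8, 13, 22, 31]  # weak beta columns per patient
        p_fall = []
        for i, k in enumerate(weak_cols):
            h = 1.55 + 0.03 * i
            w = 60.0 + 3.0 * i
            stt = 15.0 + 2.0 * i
            from silicofem import attenuate_force, impact_velocity, peak_impact_force

            force = attenuate_force(
                peak_impact_force(w, impact_velocity(h, impact), impact), stt, impact
            )
            grid = np.full((61, 31), 2.0 * force)
            grid[:, : min(k, 31)] = 0.5 * force
            cohort.append(
                VirtualPatient(
                    id=f"P{i}",
                    total_hip_aBMD=0.7,
                    neck_aBMD=0.55,
                    height=h,
                    weight=w,
                    BMI=w / h**2,
                    soft_tissue_thickness=stt,
                    strength=StrengthSurface(grid),
                )
            )
            p_fall.append(min(k, 31) / 31.0)

        # oracle: truncated sum over fall counts, independent years
        def p_fracture(p):
            no_frac_year = sum(poisson_pmf(lam, n) * (1 - p) ** n for n in range(41))
            return 1 - no_frac_year**years

        expected = sum(p_fracture(p) for p in p_fall)
        R = 30_000
        res = run_trial(
            cohort,
            TrialConfig(lam=lam, years=years, n_realizations=R, master_seed=7),
            compute_convergence=False,
        )
        se = res.fractures_per_realization.std(ddof=1) / np.sqrt(R)
        assert abs(res.mean - expected) < 3 * se


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lam": -0.5},
            {"years": 0},
            {"n_realizations": 0},
            {"convergence_threshold": 0.0},
            {"timestep": 2},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrialConfig(**kwargs)
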