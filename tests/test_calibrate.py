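"""Tests of the SSQ objective, the SRES optimizer and identifiability
profiling, including toy-model oracles."""

import numpy as np
import pytest

from losartan_pkpd.calibrate import (Dataset, FitProblem, FitResult,
                                     SENTINEL_OBJECTIVE, SRESSettings,
                                     objective, profile_parameter,
                                     sres_minimize, sres_optimize,
                                     stochastic_rank)
from losartan_pkpd.reference import SHARED_REFERENCE, PYLORIC_B
from losartan_pkpd.synthetic import NoiseModel, synth_profiles

BASE = dict(SHARED_REFERENCE, b=PYLORIC_B)


def noiseless_wt_datasets(n_subjects=1):
    profs = synth_profiles(genotype="*1/*1", n_subjects=n_subjects,
                           noise=NoiseModel(cv=0.0, cv_obs=0.0), seed=0)
    return [d for p in profs for d in p.datasets()]


class TestObjective:
    def test_zero_at_generating_parameters(self):
        problem = FitProblem(datasets=noiseless_wt_datasets(),
                             free={"k_m": (0.1, 3.0)}, base=BASE)
        assert objective([1.056], problem) == pytest.approx(0.0, abs=1e-6)

    def test_single_observation_squared_distance(self):
        ds = Dataset("*1/*1", "losartan", np.array([2.0]), np.array([500.0]))
        problem = FitProblem(datasets=[ds], free={"k_m": (0.1, 3.0)}, base=BASE)
        from losartan_pkpd import reference_parameters, reference_regimen, simulate
        res = simulate(reference_parameters("*1/*1"), reference_regimen(),
                       t_eval=np.array([2.0]))
        assert objective([1.056], problem) == pytest.approx(
            (500.0 - res.Cp[0]) ** 2, rel=1e-4)

    def test_invariant_to_dataset_and_observation_order(self):
        ds = noiseless_wt_datasets()
        flipped = [Dataset(d.genotype, d.analyte, d.times[::-1].copy(),
                           d.conc[::-1].copy()) for d in reversed(ds)]
        # interp needs ascending times; re-sort to emulate permuted input
        flipped = [Dataset(d.genotype, d.analyte, np.sort(d.times),
                           d.conc[np.argsort(d.times)]) for d in flipped]
        p1 = FitProblem(datasets=ds, free={"k_m": (0.1, 3.0)}, base=BASE)
        p2 = FitProblem(datasets=flipped, free={"k_m": (0.1, 3.0)}, base=BASE)
        assert objective([0.8], p1) == objective([0.8], p2)

    def test_simulation_failure_returns_sentinel_not_exception(self):
        problem = FitProblem(datasets=noiseless_wt_datasets(),
                             free={"k_m": (0.1, 3.0)}, base=BASE)
        assert objective([-5.0], problem) == SENTINEL_OBJECTIVE


class TestStochasticRanking:
    def test_pf_zero_without_violations_is_stable_objective_sort(self):
        rng = np.random.default_rng(1)
        f = rng.uniform(size=40)
        phi = np.zeros(40)
        order = stochastic_rank(f, phi, pf=0.0, rng=np.random.default_rng(2))
        assert np.array_equal(order, np.argsort(f, kind="stable"))

    def test_pf_zero_is_feasibility_first(self):
        f = np.array([0.1, 5.0, 1.0])
        phi = np.array([3.0, 0.0, 0.0])
        order = stochastic_rank(f, phi, pf=0.0, rng=np.random.default_rng(0))
        # feasible individuals first (by objective), violator last
        assert list(order) == [2, 1, 0]


class TestSRES:
    def test_sphere_converges_to_origin(self):
        r = sres_minimize(lambda x: float(np.sum(x * x)), [(-5, 5)] * 2,
                          SRESSettings(lam=140, mu=20, generations=200, seed=1))
        assert np.all(np.abs(r.x) < 1e-3)

    def test_active_constraint_found(self):
        r = sres_minimize(lambda x: (float(x[0] ** 2), max(0.0, 1.0 - float(x[0])) ** 2),
                          [(-5, 5)], SRESSettings(lam=40, mu=7, generations=100, seed=2))
        assert r.feasible
        assert r.x[0] == pytest.approx(1.0, abs=1e-3)

    def test_same_seed_bit_identical(self):
        settings = SRESSettings(lam=20, mu=4, generations=30, seed=11)
        fun = lambda x: float((x[0] - 0.7) ** 2 + (x[1] + 0.2) ** 2)
        r1 = sres_minimize(fun, [(-2, 2)] * 2, settings)
        r2 = sres_minimize(fun, [(-2, 2)] * 2, settings)
        assert np.array_equal(r1.x, r2.x)
        assert r1.trace == r2.trace

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            SRESSettings(lam=5, mu=10)
        with pytest.raises(ValueError):
            SRESSettings(generations=0)

    def test_recovers_conversion_rate_from_noiseless_profile(self):
        problem = FitProblem(datasets=noiseless_wt_datasets(),
                             free={"k_m": (0.1, 3.0)}, base=BASE)
        r = sres_optimize(problem, SRESSettings(lam=16, mu=3, generations=30, seed=4))
        assert r.x[0] == pytest.approx(1.056, rel=0.01)


def toy_product_problem():
    # y = k1 * k2 * t: only the product is constrained by data
    t = np.linspace(1, 5, 5)
    ds = Dataset("*1/*1", "losartan", t, 2.0 * t)

    def model(values, dataset):
        return values["k1"] * values["k2"] * dataset.times

    return FitProblem(datasets=[ds], free={"k1": (0.1, 10), "k2": (0.1, 10)},
                      model=model)


def mono_exponential_problem():
    t = np.linspace(0, 5, 6)
    ds = Dataset("*1/*1", "losartan", t, 2.0 * np.exp(-0.8 * t))

    def model(values, dataset):
        return values["A"] * np.exp(-values["lam"] * dataset.times)

    return FitProblem(datasets=[ds], free={"A": (0.1, 10), "lam": (0.05, 5)},
                      model=model)


class TestIdentifiabilityProfiling:
    SETTINGS = SRESSettings(lam=20, mu=4, generations=80, seed=0)

    def test_product_parameters_unidentifiable(self):
        problem = toy_product_problem()
        optimum = FitResult(x=np.array([1.0, 2.0]), fun=0.0, violation=0.0,
                            n_eval=0, trace=[], seed=None, feasible=True,
                            names=problem.names)
        prof = profile_parameter(problem, optimum, "k1",
                                 factors=np.array([0.25, 0.5, 2.0, 4.0]),
                                 settings=self.SETTINGS)
        # k2 compensates exactly at every fixed k1
        assert prof.classification == "unidentifiable"

    def test_mono_exponential_parameters_identifiable(self):
        problem = mono_exponential_problem()
        optimum = FitResult(x=np.array([2.0, 0.8]), fun=0.0, violation=0.0,
                            n_eval=0, trace=[], seed=None, feasible=True,
                            names=problem.names)
        for name in ("A", "lam"):
            prof = profile_parameter(problem, optimum, name,
                                     factors=np.array([0.25, 0.5, 2.0, 4.0]),
                                     settings=self.SETTINGS)
            assert prof.classification == "identifiable", name

    def test_profile_grid_brackets_and_records_optimum(self):
        problem = mono_exponential_problem()
        optimum = FitResult(x=np.array([2.0, 0.8]), fun=0.0, violation=0.0,
                            n_eval=0, trace=[], seed=None, feasible=True,
                            names=problem.names)
        prof = profile_parameter(problem, optimum, "lam",
                                 factors=np.array([0.5, 2.0]), settings=self.SETTINGS)
        assert prof.values.min() < optimum.x[1] < prof.values.max()
        assert prof.opt_objective == 0.0

    def test_unknown_parameter_name_rejected(self):
        problem = mono_exponential_problem()
        optimum = FitResult(x=np.array([2.0, 0.8]), fun=0.0, violation=0.0,
                            n_eval=0, trace=[], seed=None, feasible=True,
                            names=problem.names)
        with pytest.raises(KeyError):
            profile_parameter(problem, optimum, "nope")
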