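"""Synthetic data generators: noisy sparse concentration profiles and
virtual hypertensive cohorts with a reduced-order blood-pressure surrogate.

Concentration profiles emulate the sparse clinical sampling design the model
was calibrated to (11 samples over 24 h after a single 50 mg oral dose) with
high between-subject variability: each virtual subject scales the genotype's
true curve by a multiplicative log-normal random effect and adds log-normal
observation noise, with values below a quantification floor reported as 0.

The blood-pressure response surrogate is NOT the mechanistic cardiorenal
model: it is an explicitly-labelled reduced-order stand-in that maps a
patient's AT1-blocking coefficient ``k_block`` to expected systolic and
diastolic responses through a shape-preserving monotone interpolant,
pre-calibrated so per-genotype cohort means approximate the reference
cohort-simulation outcomes.  It supports ordering and group-contrast
demonstrations, not independent hemodynamic prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.stats import t as t_dist

from .calibrate import Dataset
from .genotype import normalize_genotype, reference_kblock_table, sample_genotypes
from .metrics import SCHEDULE_H
from .model import DoseRegimen, simulate
from .reference import reference_parameters, reference_regimen

__all__ = [
    "NoiseModel",
    "SubjectProfile",
    "synth_profiles",
    "VirtualPatient",
    "BaselineSpec",
    "make_cohort",
    "SurrogateParams",
    "DEFAULT_SURROGATE",
    "bp_response_surrogate",
    "simulate_cohort_treatment",
    "cohort_summary",
    "unpaired_t_test",
    "BONFERRONI_CUTOFF",
]

#: Significance cutoff for the six-genotype comparisons (0.05 / 6).
BONFERRONI_CUTOFF = 0.05 / 6


def _lognormal_factor(rng, cv, size=None):
    """Multiplicative log-normal factor with mean 1 and coefficient of
    variation ``cv``."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    s2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-s2 / 2.0, sigma=math.sqrt(s2), size=size)


@dataclass(frozen=True)
class NoiseModel:
    """Observation noise for synthetic profiles.

    ``cv`` is the between-subject coefficient of variation of the
    multiplicative subject random effect; ``cv_obs`` the residual
    observation CV.  ``floor`` is the lower quantification limit (nM):
    values below it are reported as 0.
    """

    kind: str = "proportional-lognormal"
    cv: float = 0.5
    cv_obs: float = 0.1
    floor: float = 0.0
    sd_nM: float = 10.0  # additive-gaussian scale, used by the other kinds

    def __post_init__(self):
        if self.cv < 0 or self.cv_obs < 0 or self.floor < 0 or self.sd_nM < 0:
            raise ValueError("noise scales must be non-negative")
        if self.kind not in ("proportional-lognormal", "additive-gaussian", "combined"):
            raise ValueError(f"unknown noise kind {self.kind!r}")


@dataclass
class SubjectProfile:
    """One synthetic subject's observed concentrations at the schedule."""

    subject: int
    genotype: str
    times: np.ndarray
    losartan: np.ndarray
    e3174: np.ndarray

    def datasets(self) -> list[Dataset]:
        return [Dataset(self.genotype, "losartan", self.times, self.losartan),
                Dataset(self.genotype, "e3174", self.times, self.e3174)]


def synth_profiles(params=None, genotype: str = "*1/*1", n_subjects: int = 1,
                   schedule=SCHEDULE_H, noise: NoiseModel = NoiseModel(),
                   seed=None, regimen: DoseRegimen | None = None) -> list[SubjectProfile]:
    """Generate noisy sparse profiles for ``n_subjects`` of one genotype.

    The genotype's true curve is simulated once and sampled at ``schedule``;
    each subject applies a subject-level multiplicative random effect and
    per-observation noise.  Deterministic under a fixed seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    schedule = np.asarray(schedule, dtype=float)
    if schedule.size == 0:
        raise ValueError("schedule must be non-empty")
    genotype = normalize_genotype(genotype)
    if params is None:
        params = reference_parameters(genotype)
    if regimen is None:
        regimen = reference_regimen()
    res = simulate(params, regimen, t_end=float(max(schedule.max(), 24.0)),
                   t_eval=schedule)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_subjects):
        subj = _lognormal_factor(rng, noise.cv)
        obs = {}
        for label, curve in (("losartan", res.Cp), ("e3174", res.Cm)):
            if noise.kind == "additive-gaussian":
                y = curve + rng.normal(0.0, noise.sd_nM, size=curve.shape)
            else:
                y = curve * subj * _lognormal_factor(rng, noise.cv_obs, size=curve.shape)
                if noise.kind == "combined":
                    y = y + rng.normal(0.0, noise.sd_nM, size=curve.shape)
            y = np.where(y < max(noise.floor, 0.0), 0.0, y)
            obs[label] = np.clip(y, 0.0, None)
        out.append(SubjectProfile(subject=i, genotype=genotype, times=schedule.copy(),
                                  losartan=obs["losartan"], e3174=obs["e3174"]))
    return out


@dataclass
class VirtualPatient:
    """One virtual hypertensive patient: genotype, blocking coefficient,
    baseline pressures and (once treated) blood-pressure deltas (mmHg)."""

    id: int
    genotype: str
    k_block: float
    sbp0: float
    dbp0: float
    d_sbp: float = float("nan")
    d_dbp: float = float("nan")


@dataclass(frozen=True)
class BaselineSpec:
    """Truncated-normal baseline blood pressures for hypertensive patients.

    Defaults span grade 1-2 hypertension; SBP must exceed DBP by at least
    ``min_pulse_pressure`` (rejection sampling).
    """

    sbp_mean: float = 158.0
    sbp_sd: float = 11.0
    sbp_range: tuple = (140.0, 185.0)
    dbp_mean: float = 96.0
    dbp_sd: float = 7.0
    dbp_range: tuple = (85.0, 115.0)
    min_pulse_pressure: float = 20.0


def make_cohort(n: int, freqs=None, ethnicity: str = "European (non-Finnish)",
                genotype: str | None = None, genotype_mix: dict | None = None,
                baseline: BaselineSpec = BaselineSpec(), seed=None,
                kblock_table: dict | None = None) -> list[VirtualPatient]:
    """Build ``n`` virtual hypertensive patients.

    Genotypes come from (in precedence order) a fixed ``genotype``, a
    ``genotype_mix`` mapping diplotype -> patient count, or Hardy-Weinberg
    sampling at the given ethnicity's allele frequencies.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if genotype is not None:
        genotypes = [normalize_genotype(genotype)] * n
    elif genotype_mix is not None:
        genotypes = [normalize_genotype(g) for g, cnt in genotype_mix.items()
                     for _ in range(int(cnt))]
        if len(genotypes) != n:
            raise ValueError(f"genotype_mix counts sum to {len(genotypes)}, expected {n}")
    else:
        genotypes = sample_genotypes(freqs, ethnicity, n, rng=rng)

    table = reference_kblock_table() if kblock_table is None else kblock_table

    patients = []
    attempts = 0
    for i in range(n):
        while True:
            attempts += 1
            if attempts > max(100 * n, 1000):
                raise ValueError("baseline truncation rejects > 99% of draws; "
                                 "check the BaselineSpec configuration")
            sbp = rng.normal(baseline.sbp_mean, baseline.sbp_sd)
            dbp = rng.normal(baseline.dbp_mean, baseline.dbp_sd)
            if (baseline.sbp_range[0] <= sbp <= baseline.sbp_range[1]
                    and baseline.dbp_range[0] <= dbp <= baseline.dbp_range[1]
                    and sbp - dbp >= baseline.min_pulse_pressure):
                break
        g = genotypes[i]
        patients.append(VirtualPatient(id=i, genotype=g, k_block=float(table[g]),
                                       sbp0=float(sbp), dbp0=float(dbp)))
    return patients


# ---------------------------------------------------------------------------
# Reduced-order blood-pressure response surrogate (synthetic stand-in for the
# mechanistic cardiorenal model; calibrated to reference cohort outcomes).
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurrogateParams:
    """Pre-calibrated surrogate: monotone mean-response anchors plus noise.

    ``anchors_k`` with ``anchors_sbp``/``anchors_dbp`` define the expected
    response at treatment steady state as a function of k_block (PCHIP
    monotone interpolation between them; k_block = 0 maps to exactly 0).
    ``rel_sd_*`` is the patient-level responder effect (shared between SBP
    and DBP); ``abs_sd_*`` a small additive measurement floor (mmHg).
    """

    anchors_k: tuple = (0.0, 0.410, 0.620, 0.833, 0.866, 0.886, 1.0)
    anchors_sbp: tuple = (0.0, -1.543, -3.142, -6.763, -7.820, -8.610, -9.5)
    anchors_dbp: tuple = (0.0, -2.442, -4.277, -7.274, -7.991, -8.498, -9.2)
    rel_sd_sbp: float = 0.17
    rel_sd_dbp: float = 0.10
    abs_sd_sbp: float = 0.009
    abs_sd_dbp: float = 0.003

    def mean_curves(self):
        k = np.asarray(self.anchors_k)
        return (PchipInterpolator(k, np.asarray(self.anchors_sbp)),
                PchipInterpolator(k, np.asarray(self.anchors_dbp)))


DEFAULT_SURROGATE = SurrogateParams()


def bp_response_surrogate(patient: VirtualPatient,
                          surrogate: SurrogateParams = DEFAULT_SURROGATE,
                          seed=None, rng=None) -> tuple[float, float]:
    """Simulated (delta SBP, delta DBP) in mmHg for one patient.

    ``delta = mean(k_block) * (1 + eta) + eps`` with a patient responder
    effect ``eta`` shared between pressures and small additive noise
    ``eps``.  ``k_block = 0`` with zero noise gives exactly (0, 0).  This
    is the labelled surrogate, not the mechanistic cardiorenal model.
    """
    if not (0.0 <= patient.k_block <= 1.0):
        raise ValueError("k_block must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    f_sbp, f_dbp = surrogate.mean_curves()
    eta = rng.standard_normal()
    d_sbp = float(f_sbp(patient.k_block)) * (1.0 + surrogate.rel_sd_sbp * eta) \
        + rng.normal(0.0, surrogate.abs_sd_sbp)
    d_dbp = float(f_dbp(patient.k_block)) * (1.0 + surrogate.rel_sd_dbp * eta) \
        + rng.normal(0.0, surrogate.abs_sd_dbp)
    return d_sbp, d_dbp


def simulate_cohort_treatment(patients: list[VirtualPatient],
                              surrogate: SurrogateParams = DEFAULT_SURROGATE,
                              seed=None) -> list[VirtualPatient]:
    """Apply the surrogate to every patient (in place); returns the list."""
    rng = np.random.default_rng(seed)
    for p in patients:
        p.d_sbp, p.d_dbp = bp_response_surrogate(p, surrogate, rng=rng)
    return patients


def cohort_summary(patients: list[VirtualPatient]) -> dict:
    """Per-genotype mean +- SD, median and quartiles of the BP deltas."""
    out = {}
    by_g: dict[str, list[VirtualPatient]] = {}
    for p in patients:
        by_g.setdefault(p.genotype, []).append(p)
    for g, group in sorted(by_g.items()):
        entry = {"n": len(group)}
        for label, attr in (("sbp", "d_sbp"), ("dbp", "d_dbp")):
            x = np.array([getattr(p, attr) for p in group])
            entry[label] = {
                "mean": float(x.mean()),
                "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
                "median": float(np.median(x)),
                "q1": float(np.percentile(x, 25)),
                "q3": float(np.percentile(x, 75)),
            }
        out[g] = entry
    return out


def unpaired_t_test(x, y) -> tuple[float, float, float]:
    """Two-sided unpaired Student's t-test (pooled variance).

    Returns ``(t, p, df)`` computed from the closed-form statistic; the
    p-value uses the t distribution's survival function.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("need at least 2 observations per group")
    df = nx + ny - 2
    sp2 = (((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df)
    se = math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    t_stat = (x.mean() - y.mean()) / se
    p = 2.0 * float(t_dist.sf(abs(t_stat), df))
    return t_stat, p, float(df)
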