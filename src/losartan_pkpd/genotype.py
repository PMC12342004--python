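"""CYP2C9 genotype handling: conversion rates, E-max exposure-effect link,
per-genotype AT1-blocking coefficients, and Hardy-Weinberg genotype sampling.

The conversion rate ``k_m`` proxies CYP2C9 catalytic activity.  Homozygote
values were calibrated against clinical profiles; a heterozygote, carrying
one copy of each allele, is assigned the arithmetic mean of the two
homozygote rates (each allele contributes half the enzyme pool and the
conversion is first order).

The AT1-receptor blocking coefficient ``k_block`` (a scalar in [0, 1] that
scales losartan's inhibition of angiotensin II binding in a downstream
cardiovascular model) is linked to metabolite exposure through a sigmoid
E-max model::

    k_block = Emax * AUC^alpha / (ED50^alpha + AUC^alpha)

fitted exactly through three dose anchors (25/50/100 mg) and then evaluated
at each genotype's AUC_E-3174.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ALLELES",
    "GENOTYPES",
    "normalize_genotype",
    "km_for_genotype",
    "KM_HOMOZYGOTE",
    "EmaxCoefficients",
    "DEFAULT_ANCHORS",
    "REFERENCE_AUC_E3174",
    "WT_AUC_E3174_50MG",
    "fit_emax",
    "evaluate_emax",
    "kblock_for_genotype",
    "reference_kblock_table",
    "ALLELE_FREQUENCIES",
    "sample_genotypes",
    "InvalidGenotypeError",
    "EmaxFitError",
]

ALLELES = ("*1", "*2", "*3")

#: Calibrated first-order conversion rates for the homozygotes (1/h).
KM_HOMOZYGOTE = {"*1": 1.056, "*2": 0.823, "*3": 0.025}

#: Reference metabolite exposures (nmol*h/L) after a single 50 mg oral dose,
#: from the calibrated model; used to place each genotype on the E-max curve.
REFERENCE_AUC_E3174 = {
    "*1/*1": 3996.6,
    "*2/*2": 3640.5,
    "*3/*3": 247.9,
    "*1/*2": 3833.3,
    "*1/*3": 3003.0,
    "*2/*3": 2628.8,
}

#: Wild-type 50 mg metabolite exposure; basis of the dose-linear anchors.
WT_AUC_E3174_50MG = 3996.6

#: (AUC_E-3174, k_block) anchors for 25, 50 and 100 mg daily doses.  The
#: 25/100 mg AUCs follow from dose linearity (all reactions first order);
#: the k_block values come from blood-pressure calibration of the downstream
#: cardiovascular model (25 mg ~ no clinically significant effect).
DEFAULT_ANCHORS = (
    (0.5 * WT_AUC_E3174_50MG, 0.1),
    (1.0 * WT_AUC_E3174_50MG, 0.886),
    (2.0 * WT_AUC_E3174_50MG, 0.954),
)

GENOTYPES = ("*1/*1", "*1/*2", "*2/*2", "*1/*3", "*2/*3", "*3/*3")

#: *2 and *3 allele frequencies by ethnicity (gnomAD-style population labels).
ALLELE_FREQUENCIES = {
    "Ashkenazi Jewish": {"*2": 0.1375, "*3": 0.0832},
    "European (non-Finnish)": {"*2": 0.1319, "*3": 0.0649},
    "Middle Eastern": {"*2": 0.1212, "*3": 0.0728},
    "Amish": {"*2": 0.1524, "*3": 0.0296},
    "European (Finnish)": {"*2": 0.1142, "*3": 0.0616},
    "Remaining": {"*2": 0.1061, "*3": 0.0639},
    "South Asian": {"*2": 0.0485, "*3": 0.1101},
    "Admixed American": {"*2": 0.0787, "*3": 0.0420},
    "African/African American": {"*2": 0.0217, "*3": 0.0126},
    "East Asian": {"*2": 0.0002, "*3": 0.0302},
}


class InvalidGenotypeError(ValueError):
    pass


class EmaxFitError(RuntimeError):
    pass


def normalize_genotype(g) -> str:
    """Canonicalize a diplotype: unordered pair of {*1,*2,*3} -> '*x/*y', x<=y."""
    if isinstance(g, (tuple, list)):
        alleles = [str(x) for x in g]
    else:
        alleles = re.split(r"[/|]", str(g).strip())
    if len(alleles) != 2:
        raise InvalidGenotypeError(f"expected an allele pair, got {g!r}")
    norm = []
    for al in alleles:
        al = al.strip()
        if not al.startswith("*"):
            al = "*" + al
        if al not in ALLELES:
            raise InvalidGenotypeError(f"unknown CYP2C9 allele {al!r} in {g!r}")
        norm.append(al)
    norm.sort(key=lambda s: int(s[1:]))
    return f"{norm[0]}/{norm[1]}"


def km_for_genotype(g) -> float:
    """Conversion rate (1/h) for a diplotype: homozygotes carry the fitted
    constants; heterozygotes the arithmetic mean of the two homozygote rates."""
    a1, a2 = normalize_genotype(g).split("/")
    return 0.5 * (KM_HOMOZYGOTE[a1] + KM_HOMOZYGOTE[a2])


@dataclass(frozen=True)
class EmaxCoefficients:
    """Coefficients of the sigmoid exposure-effect curve.

    ``emax``: maximal blocking effect (unitless, <= 1); ``ed50``: metabolite
    AUC at half-maximal effect (nmol*h/L); ``alpha``: Hill exponent.
    """

    emax: float
    ed50: float
    alpha: float

    def __post_init__(self):
        if not (0 < self.emax <= 1.0 + 1e-9):
            raise EmaxFitError(f"Emax must be in (0, 1], got {self.emax}")
        if self.ed50 <= 0 or self.alpha <= 0:
            raise EmaxFitError("ED50 and alpha must be positive")

    def __call__(self, auc_value):
        return evaluate_emax(auc_value, self)

    def to_dict(self):
        return {"emax": self.emax, "ed50": self.ed50, "alpha": self.alpha}


def evaluate_emax(auc_value, coeffs: EmaxCoefficients):
    """Evaluate the E-max curve; exactly 0 at zero exposure.

    Computed on the logistic-in-log form
    ``emax / (1 + exp(alpha * (ln ED50 - ln AUC)))`` which is overflow-safe
    for large Hill exponents.
    """
    x = np.asarray(auc_value, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    z = coeffs.alpha * (math.log(coeffs.ed50) - np.log(x[pos]))
    out[pos] = coeffs.emax / (1.0 + np.exp(np.clip(z, -700, 700)))
    if np.isscalar(auc_value) or np.asarray(auc_value).ndim == 0:
        return float(out)
    return out


def _coeffs_given_alpha(alpha, l1, k1, l2, k2):
    """Closed-form Emax and ln(ED50) through anchors 1 and 2 at fixed alpha."""
    # k_i = Emax / (1 + exp(alpha*(m - l_i))), m = ln ED50
    # => exp(alpha*m) = (k1 - k2) / (k2*exp(-alpha*l2) - k1*exp(-alpha*l1))
    denom = k2 * math.exp(-alpha * (l2 - l1)) - k1
    if denom >= 0 or k1 >= k2:
        return None
    # work relative to l1 to avoid overflow: z = exp(alpha*(m - l1))
    z = (k1 - k2) / denom
    if z <= 0:
        return None
    m = math.log(z) / alpha + l1
    emax = k1 * (1.0 + z)
    return emax, m


def fit_emax(anchors=DEFAULT_ANCHORS, alpha_bracket=(0.05, 60.0)) -> EmaxCoefficients:
    """Fit the three-parameter E-max model.

    For exactly three anchors the curve is solved to pass through all of
    them: Emax and ED50 are closed-form given the Hill exponent, and the
    exponent is found by root-finding on the third anchor's residual.  For
    more than three anchors a least-squares fit (initialized from the first
    three) is used.
    """
    anchors = sorted((float(a), float(k)) for a, k in anchors)
    if len(anchors) < 3:
        raise EmaxFitError("need at least 3 anchors")
    aucs = [a for a, _ in anchors]
    ks = [k for _, k in anchors]
    if len(set(aucs)) != len(aucs):
        raise EmaxFitError("anchor AUCs must be distinct")
    if any(k1 >= k2 for k1, k2 in zip(ks, ks[1:])):
        raise EmaxFitError("anchors must be strictly increasing in k_block "
                           "(monotone sigmoid not representable otherwise)")
    if any(not (0 <= k <= 1) for k in ks):
        raise EmaxFitError("k_block anchors must lie in [0, 1]")

    if len(anchors) == 3:
        (x1, k1), (x2, k2), (x3, k3) = anchors
        l1, l2, l3 = math.log(x1), math.log(x2), math.log(x3)

        def resid(alpha):
            cg = _coeffs_given_alpha(alpha, l1, k1, l2, k2)
            if cg is None:
                return math.nan
            emax, m = cg
            z = alpha * (m - l3)
            pred = emax / (1.0 + math.exp(max(min(z, 700), -700)))
            return pred - k3

        lo, hi = alpha_bracket
        grid = np.geomspace(lo, hi, 200)
        vals = np.array([resid(al) for al in grid])
        ok = np.isfinite(vals)
        sign_change = None
        for i in range(len(grid) - 1):
            if ok[i] and ok[i + 1] and vals[i] * vals[i + 1] <= 0:
                sign_change = (grid[i], grid[i + 1])
                break
        if sign_change is None:
            raise EmaxFitError("no Hill exponent in bracket passes through all anchors")
        alpha = brentq(resid, *sign_change, xtol=1e-12, rtol=1e-14)
        emax, m = _coeffs_given_alpha(alpha, l1, k1, l2, k2)
        return EmaxCoefficients(emax=min(emax, 1.0), ed50=math.exp(m), alpha=alpha)

    # > 3 anchors: least squares, seeded by the exact three-anchor solution
    from scipy.optimize import least_squares

    seed = fit_emax(anchors[:3])
    x = np.array(aucs)
    y = np.array(ks)

    def residuals(theta):
        c = EmaxCoefficients(emax=min(theta[0], 1.0), ed50=theta[1], alpha=theta[2])
        return evaluate_emax(x, c) - y

    sol = least_squares(residuals, [seed.emax, seed.ed50, seed.alpha],
                        bounds=([1e-6, 1e-6, 1e-3], [1.0, 1e9, 200.0]))
    return EmaxCoefficients(emax=float(sol.x[0]), ed50=float(sol.x[1]), alpha=float(sol.x[2]))


def kblock_for_genotype(g, coeffs: EmaxCoefficients | None = None,
                        auc_by_genotype: dict | None = None) -> float:
    """AT1-blocking coefficient for a diplotype: the E-max curve evaluated at
    the genotype's metabolite exposure (reference table by default)."""
    if coeffs is None:
        coeffs = fit_emax()
    table = REFERENCE_AUC_E3174 if auc_by_genotype is None else {
        normalize_genotype(k): v for k, v in auc_by_genotype.items()}
    key = normalize_genotype(g)
    if key not in table:
        raise KeyError(f"no AUC_E-3174 available for genotype {key}")
    return float(evaluate_emax(table[key], coeffs))


def reference_kblock_table(coeffs: EmaxCoefficients | None = None) -> dict:
    """k_block for all six diplotypes at the reference exposures."""
    if coeffs is None:
        coeffs = fit_emax()
    return {g: kblock_for_genotype(g, coeffs) for g in GENOTYPES}


def sample_genotypes(freqs=None, ethnicity: str = "European (non-Finnish)",
                     n: int = 1, seed=None, rng=None) -> list[str]:
    """Draw ``n`` diplotypes i.i.d. under Hardy-Weinberg proportions.

    ``freqs`` maps ethnicity -> {'*2': f2, '*3': f3} (the *1 frequency is the
    remainder); defaults to the built-in table.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    table = ALLELE_FREQUENCIES if freqs is None else freqs
    if ethnicity not in table:
        raise KeyError(f"ethnicity {ethnicity!r} not in frequency table")
    f2 = float(table[ethnicity].get("*2", 0.0))
    f3 = float(table[ethnicity].get("*3", 0.0))
    if f2 < 0 or f3 < 0 or f2 + f3 > 1:
        raise ValueError("allele frequencies must be non-negative and sum to <= 1")
    p = np.array([1.0 - f2 - f3, f2, f3])
    if rng is None:
        rng = np.random.default_rng(seed)
    alleles = rng.choice(3, size=(n, 2), p=p)
    return [normalize_genotype((ALLELES[i], ALLELES[j])) for i, j in alleles]
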