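"""Reference scenario: calibrated shared parameters, dosing, and solver
defaults for the 50 mg single-oral-dose study the package reproduces.

The nine shared parameters below (everything except the genotype-specific
conversion rate ``k_m`` and the fixed pyloric frequency ``b``) were
calibrated by weighted least squares against the per-genotype reference PK
metrics (Cmax, tmax, t1/2 and AUC of both analytes for all six CYP2C9
diplotypes after a single 50 mg oral dose), with the wild-type Cmax and
metabolite exposure, the wild-type losartan half-life, and the poor-
metabolizer (*3/*3) losartan exposure and AUC ratio weighted most heavily.
``b`` is fixed at 3.95 rad/h, which puts the pyloric open/close period
(2*pi/b ~ 95 min) inside the observed 85-115 min migrating-motor-complex
range.
"""

from __future__ import annotations

from .genotype import km_for_genotype
from .model import DoseRegimen, PKParameters

__all__ = [
    "SHARED_REFERENCE",
    "PYLORIC_B",
    "reference_parameters",
    "reference_regimen",
    "SOLVER_DEFAULTS",
]

#: Pyloric-flux angular frequency (rad/h), fixed on physiological grounds.
PYLORIC_B = 3.95

#: Calibrated shared parameters (all six genotypes share these).
SHARED_REFERENCE = {
    "a": 4.547742,       # pyloric-flux amplitude (1/h)
    "k_a": 4.338263,     # intestinal absorption rate (1/h)
    "T": 0.744952,       # conversion transit delay (h)
    "CL_p": 30.52747,    # apparent losartan clearance (L/h)
    "CL_m": 17.528236,   # apparent E-3174 clearance (L/h)
    "Q": 112.555045,     # apparent inter-compartmental clearance (L/h)
    "Vp1": 53.200504,    # losartan central volume (L)
    "Vp2": 112.698277,   # losartan peripheral volume (L)
    "Vm": 58.393534,     # E-3174 central volume (L)
}

#: Solver defaults used for metric extraction.
SOLVER_DEFAULTS = {"rtol": 1e-8, "atol": 1e-10, "t_end_h": 24.0, "n_out": 2401}


def reference_parameters(genotype: str = "*1/*1", **overrides) -> PKParameters:
    """Reference :class:`PKParameters` for a CYP2C9 diplotype.

    ``k_m`` is set from the genotype (homozygote constants, arithmetic mean
    for heterozygotes); keyword overrides replace individual fields.
    """
    fields = dict(SHARED_REFERENCE, b=PYLORIC_B, k_m=km_for_genotype(genotype))
    fields.update(overrides)
    return PKParameters(**fields)


def reference_regimen(dose_mg: float = 50.0) -> DoseRegimen:
    """Single oral dose of losartan potassium at t = 0 (default 50 mg)."""
    return DoseRegimen.single_oral(dose_mg)
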