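"""Doubly-labeled-water (DLW) energetics.

The DLW method estimates CO2 production — and from it total energy
expenditure (TEE) — from the differential washout of two stable isotopes
(deuterium and oxygen-18) dosed into an animal's body water.  Deuterium
leaves only as water; oxygen-18 leaves as both water and CO2, so the gap
between the two elimination rates measures CO2 flux.

The computation chain implemented here:

1.  log-linear (slope-intercept) fits of post-dose isotope enrichment
    against time give the elimination rate ``k`` and the zero-time
    intercept for each isotope;
2.  dose size divided by the intercept gives each isotope dilution space
    ``N`` (moles of body water "seen" by that isotope);
3.  the two spaces are pooled as ``N = (N_O/1.007 + N_D/1.043)/2`` and
    converted to total body water via ``TBW = 0.01802 * N``;
4.  CO2 production is
    ``rCO2 = (N/2.078)(1.007 k_O - 1.043 k_D) - 0.0246 N 1.05 (1.007 k_O - 1.043 k_D)``;
5.  a Weir-type conversion ``TEE = 22.26 rCO2 (1.106 + 3.94/FQ)`` turns
    mol CO2/day into kcal/day, where FQ is the food quotient — the
    diet-predicted respiratory quotient, a metabolizable-energy-weighted
    mean of macronutrient oxidation coefficients (protein 0.8,
    carbohydrate 1.0, fat 0.7).

Body composition falls out of the same dilution: fat-free mass is
``TBW / 0.732`` (hydration coefficient of lean tissue) and fat mass is
the remainder of body mass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WATER_MOLAR_MASS",
    "HYDRATION_COEFFICIENT",
    "KCAL_TO_KJ",
    "MBW_EXPONENT",
    "DoseRecord",
    "KineticsFit",
    "DilutionSpaces",
    "BodyComposition",
    "FoodQuotient",
    "EnergyExpenditure",
    "fit_isotope_kinetics",
    "dilution_space_from_equivalent",
    "dilution_space",
    "pooled_dilution_space",
    "total_body_water",
    "body_composition",
    "rco2",
    "food_quotient",
    "weir_tee",
    "scale_energy",
]

WATER_MOLAR_MASS = 18.02  # g/mol
HYDRATION_COEFFICIENT = 0.732  # water fraction of fat-free mass
KCAL_TO_KJ = 4.184
MBW_EXPONENT = 0.75  # metabolic body weight: BW ** 0.75

# Oxidation coefficients entering the food quotient.
FQ_COEF_PROTEIN = 0.8
FQ_COEF_CARB = 1.0
FQ_COEF_FAT = 0.7

# rCO2 constants: (N/2.078)*x - 0.0246*N*1.05*x  ==  N*x*_RCO2_FACTOR
_RCO2_FACTOR = 1.0 / 2.078 - 0.0246 * 1.05


class DlwError(ValueError):
    """Raised for physically or statistically invalid DLW inputs."""


@dataclass(frozen=True)
class DoseRecord:
    """A doubly-labeled-water dose.

    Parameters
    ----------
    dose_mass:
        Grams of dose water ingested.
    frac_2h2o:
        Mass fraction of the dose that is labeled deuterium water
        (0.06 for a 6% 2H2O dose).
    frac_h218o:
        Mass fraction that is labeled oxygen-18 water (0.10 for 10%).
    """

    dose_mass: float
    frac_2h2o: float = 0.06
    frac_h218o: float = 0.10
    water_molar_mass: float = WATER_MOLAR_MASS

    def __post_init__(self) -> None:
        if self.dose_mass <= 0:
            raise DlwError("dose_mass must be positive")
        for f in (self.frac_2h2o, self.frac_h218o):
            if not 0 < f < 1:
                raise DlwError("dose label fractions must lie in (0, 1)")
        if self.frac_2h2o + self.frac_h218o > 1:
            raise DlwError("dose label fractions sum above 1")

    def label_moles(self, isotope: str) -> float:
        """Moles of labeled water delivered for ``isotope`` ('deuterium'|'oxygen18')."""
        frac = {"deuterium": self.frac_2h2o, "oxygen18": self.frac_h218o}[isotope]
        return self.dose_mass * frac / self.water_molar_mass

    def ppm_mol_equivalent(self, isotope: str) -> float:
        """Dose strength as ppm·mol: label moles expressed on the ppm scale.

        The label fraction of the dose is 1e6 ppm by definition of the
        excess-ppm enrichment scale used throughout this module, so the
        dose contributes ``label_moles * 1e6`` ppm·mol to the body-water
        pool.  Dividing by the zero-time intercept enrichment (ppm excess
        over the animal's pre-dose background) yields the dilution space
        in moles.
        """
        return self.label_moles(isotope) * 1e6


@dataclass(frozen=True)
class KineticsFit:
    """Log-linear washout fit for one animal-isotope series."""

    isotope: str
    k: float  # elimination rate, per day
    intercept_excess: float  # zero-time enrichment, ppm excess over background
    n_points: int
    r_squared: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise DlwError(f"non-positive elimination rate k={self.k:g} (no washout)")
        if self.intercept_excess <= 0:
            raise DlwError("non-positive zero-time intercept")


@dataclass(frozen=True)
class DilutionSpaces:
    """Per-isotope and pooled dilution spaces (moles of body water)."""

    N_D: float
    N_O: float
    ratio: float
    N_pooled: float


@dataclass(frozen=True)
class BodyComposition:
    TBW: float  # kg
    FFM: float  # kg
    FM: float  # kg
    pct_fat: float
    body_mass: float  # kg at dosing
    consistent: bool = True  # False when FFM exceeds body mass
    hydration_coefficient: float = HYDRATION_COEFFICIENT


@dataclass(frozen=True)
class FoodQuotient:
    FQ: float
    me_cp: float
    me_ndf: float
    me_tnc: float
    me_cf: float

    @property
    def me_total(self) -> float:
        return self.me_cp + self.me_ndf + self.me_tnc + self.me_cf


@dataclass(frozen=True)
class EnergyExpenditure:
    """TEE in every reporting scale used by the study tables."""

    rco2: float  # mol CO2 / day
    fq: float
    tee_kcal: float  # kcal/day
    body_mass: float = float("nan")  # kg
    tee_kj: float = field(default=float("nan"))
    tee_per_bw: float = field(default=float("nan"))  # kcal/day/kg
    tee_per_mbw: float = field(default=float("nan"))  # kcal/day/kg^0.75
    tee_kj_per_bw: float = field(default=float("nan"))
    tee_kj_per_mbw: float = field(default=float("nan"))


def fit_isotope_kinetics(
    times,
    enrichments,
    background: float = 0.0,
    isotope: str = "unknown",
    time_unit: str = "days",
) -> KineticsFit:
    """Fit the slope-intercept (log-linear) isotope washout model.

    Ordinary least squares of ``ln(enrichment - background)`` on time (days
    since dosing).  The elimination rate is minus the slope; the zero-time
    intercept is exponentiated back to the enrichment scale.  With exactly
    two post-dose points the fit is the exact two-point line.

    Parameters
    ----------
    times:
        Days since dosing, strictly increasing, all > 0 (the pre-dose
        background sample is passed via ``background``, not here).
    enrichments:
        Isotope enrichments at those times, same units as ``background``
        (ppm).  Analytical replicates should be averaged beforehand.
    background:
        Pre-dose enrichment subtracted from every sample.
    time_unit:
        ``"days"`` (default) or ``"hours"``; hours are converted so the
        elimination rate is always per day.

    Raises
    ------
    DlwError
        On fewer than two distinct post-dose time points, or any sample
        at or below background.
    """
    if time_unit not in ("days", "hours"):
        raise DlwError(f"unknown time unit {time_unit!r}")
    t = np.asarray(times, dtype=float)
    if time_unit == "hours":
        t = t / 24.0
    e = np.asarray(enrichments, dtype=float)
    if t.shape != e.shape or t.ndim != 1:
        raise DlwError("times and enrichments must be equal-length 1-D sequences")
    if len(np.unique(t)) < 2 or len(t) < 2:
        raise DlwError("insufficient samples: need >= 2 distinct post-dose time points")
    if np.any(np.diff(t) <= 0):
        raise DlwError("times must be strictly increasing within a series")
    excess = e - background
    if np.any(excess <= 0):
        raise DlwError("sample below background: post-dose enrichment <= background")

    y = np.log(excess)
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if len(t) == 2:
        r2 = 1.0  # exact line
    return KineticsFit(
        isotope=isotope,
        k=-float(slope),
        intercept_excess=float(np.exp(intercept)),
        n_points=len(t),
        r_squared=r2,
    )


def dilution_space_from_equivalent(ppm_mol_equivalent: float, intercept_excess: float) -> float:
    """Dilution space (mol) from dose strength in ppm·mol and the fit intercept."""
    if intercept_excess <= 0:
        raise DlwError("non-positive intercept enrichment")
    if ppm_mol_equivalent <= 0:
        raise DlwError("non-positive dose equivalent")
    return ppm_mol_equivalent / intercept_excess


def dilution_space(dose: DoseRecord, fit: KineticsFit) -> float:
    """Isotope dilution space N (moles of body water) for one isotope.

    The dose's labeled-water moles, on the ppm scale (label = 1e6 ppm),
    divided by the back-extrapolated zero-time excess enrichment.
    """
    return dilution_space_from_equivalent(
        dose.ppm_mol_equivalent(fit.isotope), fit.intercept_excess
    )


def pooled_dilution_space(N_D: float, N_O: float) -> DilutionSpaces:
    """Pool the two dilution spaces: ``N = (N_O/1.007 + N_D/1.043)/2``.

    The divisors correct each isotope space for its known overestimate of
    the true body-water pool (deuterium exchanges with non-aqueous
    hydrogen; oxygen-18 with carbonyl oxygen).
    """
    if N_D <= 0 or N_O <= 0:
        raise DlwError("dilution spaces must be positive")
    pooled = (N_O / 1.007 + N_D / 1.043) / 2.0
    return DilutionSpaces(N_D=N_D, N_O=N_O, ratio=N_D / N_O, N_pooled=pooled)


def total_body_water(N_pooled: float) -> float:
    """TBW (kg) from the pooled dilution space: ``TBW = 0.01802 * N``."""
    if N_pooled <= 0:
        raise DlwError("pooled dilution space must be positive")
    return 0.01802 * N_pooled


def body_composition(TBW: float, body_mass: float) -> BodyComposition:
    """Fat-free mass, fat mass and body-fat percentage from TBW.

    FFM = TBW / 0.732; FM = body mass - FFM.  If the dilution-derived FFM
    exceeds body mass the pair is physically inconsistent (mass at dosing
    differing from the mass supplied, or an inflated dilution space); the
    result is returned flagged ``consistent=False`` with a warning rather
    than raising, since the discrepancy is a data problem to surface, not
    a computational failure.
    """
    if TBW <= 0 or body_mass <= 0:
        raise DlwError("TBW and body mass must be positive")
    ffm = TBW / HYDRATION_COEFFICIENT
    fm = body_mass - ffm
    consistent = ffm <= body_mass
    if not consistent:
        warnings.warn(
            f"inconsistent dilution/body-mass pair: FFM {ffm:.2f} kg exceeds "
            f"body mass {body_mass:.2f} kg",
            stacklevel=2,
        )
    return BodyComposition(
        TBW=TBW,
        FFM=ffm,
        FM=fm,
        pct_fat=100.0 * fm / body_mass,
        body_mass=body_mass,
        consistent=consistent,
    )


def rco2(N_pooled: float, k_D: float, k_O: float) -> float:
    """CO2 production rate (mol/day) from the pooled space and both rates.

    ``rCO2 = (N/2.078)(1.007 k_O - 1.043 k_D) - 0.0246 N 1.05 (1.007 k_O - 1.043 k_D)``

    The 1.007/1.043 factors map the raw rates onto the pooled space; the
    second term subtracts fractionated evaporative water loss.
    """
    if N_pooled <= 0:
        raise DlwError("pooled dilution space must be positive")
    if k_D <= 0 or k_O <= 0:
        raise DlwError("elimination rates must be positive")
    x = 1.007 * k_O - 1.043 * k_D
    if x <= 0:
        raise DlwError(
            "non-physiological isotope turnover: 1.007*k_O must exceed 1.043*k_D"
        )
    return N_pooled * x * _RCO2_FACTOR


def food_quotient(me_cp: float, me_ndf: float, me_tnc: float, me_cf: float) -> FoodQuotient:
    """Food quotient from metabolizable-energy intake per macronutrient.

    ``FQ = (ME_CP*0.8 + ME_Carb*1.0 + ME_CF*0.7) / ME_total`` where
    carbohydrate ME is the sum of the fiber (NDF) and nonstructural
    carbohydrate (TNC) contributions.  A weighted mean of oxidation
    coefficients, hence bounded by [0.7, 1.0].
    """
    comps = (me_cp, me_ndf, me_tnc, me_cf)
    if any(c < 0 for c in comps):
        raise DlwError("ME components must be non-negative")
    total = sum(comps)
    if total <= 0:
        raise DlwError("total ME must be positive to form a food quotient")
    fq = (me_cp * FQ_COEF_PROTEIN + (me_ndf + me_tnc) * FQ_COEF_CARB + me_cf * FQ_COEF_FAT) / total
    return FoodQuotient(FQ=fq, me_cp=me_cp, me_ndf=me_ndf, me_tnc=me_tnc, me_cf=me_cf)


def weir_tee(rco2_mol_day: float, fq: float) -> float:
    """TEE (kcal/day) via the Weir conversion ``22.26 rCO2 (1.106 + 3.94/FQ)``."""
    if rco2_mol_day <= 0:
        raise DlwError("rCO2 must be positive")
    if not 0 < fq <= 1.2:
        raise DlwError("food quotient must lie in (0, 1.2]")
    return 22.26 * rco2_mol_day * (1.106 + 3.94 / fq)


def scale_energy(
    tee_kcal: float,
    body_mass: float,
    rco2_mol_day: float = float("nan"),
    fq: float = float("nan"),
) -> EnergyExpenditure:
    """Express TEE in kJ and per body weight / metabolic body weight.

    kJ = kcal * 4.184; per-BW divides by mass (kg); per-MBW divides by
    mass**0.75 (metabolic body weight), the standard interspecific
    metabolic scaling unit.  Values are returned unrounded; report tables
    round kcal and kJ to integers.
    """
    if tee_kcal <= 0 or body_mass <= 0:
        raise DlwError("TEE and body mass must be positive")
    mbw = body_mass ** MBW_EXPONENT
    kj = tee_kcal * KCAL_TO_KJ
    return EnergyExpenditure(
        rco2=rco2_mol_day,
        fq=fq,
        tee_kcal=tee_kcal,
        body_mass=body_mass,
        tee_kj=kj,
        tee_per_bw=tee_kcal / body_mass,
        tee_per_mbw=tee_kcal / mbw,
        tee_kj_per_bw=kj / body_mass,
        tee_kj_per_mbw=kj / mbw,
    )


def tee_from_fits(
    dose: DoseRecord,
    fit_d: KineticsFit,
    fit_o: KineticsFit,
    fq: float,
    body_mass: float,
) -> tuple[DilutionSpaces, BodyComposition, EnergyExpenditure]:
    """Run the full DLW chain: fits -> spaces -> TBW -> rCO2 -> TEE."""
    n_d = dilution_space(dose, fit_d)
    n_o = dilution_space(dose, fit_o)
    spaces = pooled_dilution_space(n_d, n_o)
    tbw = total_body_water(spaces.N_pooled)
    comp = body_composition(tbw, body_mass)
    r = rco2(spaces.N_pooled, fit_d.k, fit_o.k)
    tee = weir_tee(r, fq)
    return spaces, comp, scale_energy(tee, body_mass, rco2_mol_day=r, fq=fq)
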