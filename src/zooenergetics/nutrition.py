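"""Diet-side energetics: macronutrient intake, apparent digestibility, ME.

Daily feed logs (mass offered and mass remaining per item) are turned into
dry-matter macronutrient intake using a per-item composition table on a
dry-matter basis; fecal collections close the mass balance to give apparent
digestibility coefficients; and standard physiological fuel values convert
digestible macronutrient mass into metabolizable energy (ME) intake.

Conventions
-----------
* Compositions are percent of dry matter for ash, crude protein (CP),
  neutral detergent fiber (NDF) and crude fat (CF); total nonstructural
  carbohydrate (TNC) is estimated by difference,
  ``TNC = 100 - (ash + CP + NDF + CF)``.
* Mass remaining overnight is corrected for evaporative moisture loss by
  dividing by ``1 - moisture_loss_overnight`` (an item-specific fraction
  calibrated from drying trials; default 0, i.e. no correction).
* Apparent digestibility is the ratio of period-mean intake to period-mean
  fecal output, ``D_a = (intake - fecal) / intake * 100``, uncorrected for
  endogenous losses.
* Fuel values: CP 4, TNC 4, NDF 3, CF 9 kcal per gram.  Urinary and
  methane energy losses are not modeled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FUEL_VALUES",
    "NUTRIENTS",
    "FoodComposition",
    "MacronutrientTotals",
    "DigestibilityCoefficients",
    "MEIntake",
    "tnc_by_difference",
    "consumed_mass",
    "daily_intake_table",
    "period_mean_intake",
    "fecal_mean_output",
    "apparent_digestibility",
    "me_intake",
    "daily_me_table",
    "partition_me",
]

NUTRIENTS = ("cp", "ndf", "cf", "tnc")

# kcal per gram of digestible macronutrient
FUEL_VALUES = {"cp": 4.0, "tnc": 4.0, "ndf": 3.0, "cf": 9.0}

CATEGORIES = {"browse", "vegetable", "fruit", "leafy_green", "dry_commercial"}


class NutritionError(ValueError):
    pass


def tnc_by_difference(ash_pct: float, cp_pct: float, ndf_pct: float, cf_pct: float) -> float:
    """TNC (% of dry matter) by difference, clamped at zero with a warning.

    Assay percentages occasionally sum above 100 from analytical error; a
    negative carbohydrate fraction is meaningless, so the estimate clamps
    to 0 and warns rather than propagating a negative mass.
    """
    for p in (ash_pct, cp_pct, ndf_pct, cf_pct):
        if not 0 <= p <= 100:
            raise NutritionError("composition percentages must lie in [0, 100]")
    tnc = 100.0 - (ash_pct + cp_pct + ndf_pct + cf_pct)
    if tnc < 0:
        warnings.warn(
            f"assayed components sum to {100 - tnc:.1f}%; TNC clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return tnc


@dataclass(frozen=True)
class FoodComposition:
    """Dry-matter composition of one diet item.

    ``dm_fraction`` is the dry-matter fraction of as-fed mass;
    percentages are on a dry-matter basis.  ``moisture_loss_overnight``
    is the fraction of as-fed mass the item loses to evaporation between
    feeding and the next morning's weigh-back.
    """

    item_id: str
    category: str
    dm_fraction: float
    ash_pct: float
    cp_pct: float
    ndf_pct: float
    cf_pct: float
    moisture_loss_overnight: float = 0.0
    tnc_pct: float = field(init=False)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise NutritionError(
                f"unknown category {self.category!r} for item {self.item_id!r}"
            )
        if not 0 < self.dm_fraction <= 1:
            raise NutritionError("dm_fraction must lie in (0, 1]")
        if not 0 <= self.moisture_loss_overnight < 1:
            raise NutritionError("moisture_loss_overnight must lie in [0, 1)")
        object.__setattr__(
            self,
            "tnc_pct",
            tnc_by_difference(self.ash_pct, self.cp_pct, self.ndf_pct, self.cf_pct),
        )


@dataclass(frozen=True)
class MacronutrientTotals:
    """Grams dry matter per day (or a period mean of daily values)."""

    dm_g: float
    cp_g: float
    ndf_g: float
    cf_g: float
    tnc_g: float

    def as_dict(self) -> dict[str, float]:
        return {
            "dm": self.dm_g, "cp": self.cp_g, "ndf": self.ndf_g,
            "cf": self.cf_g, "tnc": self.tnc_g,
        }


@dataclass(frozen=True)
class DigestibilityCoefficients:
    """Percent apparent dry-matter digestibility per nutrient.

    ``None`` marks an undefined coefficient (zero intake of that
    nutrient); negative values (fecal output exceeding intake) are kept
    but flagged in ``flags``.
    """

    dm: float | None
    cp: float | None
    ndf: float | None
    cf: float | None
    tnc: float | None
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float | None]:
        return {"dm": self.dm, "cp": self.cp, "ndf": self.ndf, "cf": self.cf, "tnc": self.tnc}


@dataclass(frozen=True)
class MEIntake:
    """Metabolizable energy intake (kcal/day) by macronutrient."""

    me_cp: float
    me_ndf: float
    me_cf: float
    me_tnc: float

    @property
    def me_total(self) -> float:
        return self.me_cp + self.me_ndf + self.me_cf + self.me_tnc


def consumed_mass(offered_g: float, remaining_g: float, moisture_loss: float = 0.0) -> float:
    """As-fed grams consumed, correcting the weigh-back for overnight drying.

    The remaining mass was weighed after losing a fraction
    ``moisture_loss`` of its water, so the as-offered equivalent is
    ``remaining / (1 - moisture_loss)``.  Consumption is clamped to
    [0, offered]: a corrected remainder above the offer (weighing error)
    yields 0 with a warning.
    """
    if offered_g < 0 or remaining_g < 0:
        raise NutritionError("offered and remaining masses must be non-negative")
    if not 0 <= moisture_loss < 1:
        raise NutritionError("moisture_loss must lie in [0, 1)")
    corrected = remaining_g / (1.0 - moisture_loss)
    consumed = offered_g - corrected
    if consumed < 0:
        warnings.warn(
            f"corrected remainder {corrected:.1f} g exceeds offer {offered_g:.1f} g; "
            "consumption clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return consumed


def _require_compositions(items, compositions: dict[str, FoodComposition]) -> None:
    missing = sorted(set(items) - set(compositions))
    if missing:
        raise NutritionError(f"no composition entry for item(s): {', '.join(missing)}")


def daily_intake_table(
    feed_log: pd.DataFrame,
    compositions: dict[str, FoodComposition],
) -> pd.DataFrame:
    """Per animal-day dry-matter macronutrient intake from a feed log.

    Parameters
    ----------
    feed_log:
        Columns ``animal_id, date, item_id, offered_g, remaining_g``
        (as-fed grams), one row per item per day.
    compositions:
        Item composition table; every logged item must be present.

    Returns
    -------
    DataFrame indexed by ``(animal_id, date)`` with columns
    ``dm_g, cp_g, ndf_g, cf_g, tnc_g`` (grams dry matter) and
    ``browse_dm_g`` (the browse share of dry matter, for ME partitioning).
    """
    _require_compositions(feed_log["item_id"], compositions)
    rows = []
    for rec in feed_log.itertuples(index=False):
        comp = compositions[rec.item_id]
        eaten = consumed_mass(rec.offered_g, rec.remaining_g, comp.moisture_loss_overnight)
        dm = eaten * comp.dm_fraction
        rows.append({
            "animal_id": rec.animal_id,
            "date": rec.date,
            "item_id": rec.item_id,
            "category": comp.category,
            "dm_g": dm,
            "cp_g": dm * comp.cp_pct / 100.0,
            "ndf_g": dm * comp.ndf_pct / 100.0,
            "cf_g": dm * comp.cf_pct / 100.0,
            "tnc_g": dm * comp.tnc_pct / 100.0,
        })
    per_item = pd.DataFrame(rows)
    per_item["browse_dm_g"] = np.where(per_item["category"] == "browse", per_item["dm_g"], 0.0)
    cols = ["dm_g", "cp_g", "ndf_g", "cf_g", "tnc_g", "browse_dm_g"]
    return per_item.groupby(["animal_id", "date"])[cols].sum()


def period_mean_intake(daily: pd.DataFrame) -> MacronutrientTotals:
    """Period-mean daily intake from a `daily_intake_table` result (one animal)."""
    m = daily[["dm_g", "cp_g", "ndf_g", "cf_g", "tnc_g"]].mean()
    return MacronutrientTotals(
        dm_g=m["dm_g"], cp_g=m["cp_g"], ndf_g=m["ndf_g"], cf_g=m["cf_g"], tnc_g=m["tnc_g"]
    )


def fecal_mean_output(fecal_log: pd.DataFrame) -> MacronutrientTotals:
    """Mean daily fecal macronutrient output from a collection log.

    ``fecal_log`` columns: ``dry_mass_g, ash_pct, cp_pct, ndf_pct, cf_pct``
    (composition percentages on a dry-matter basis), one row per
    collection day.  TNC is taken by difference per sample.
    """
    df = fecal_log.copy()
    df["tnc_pct"] = [
        tnc_by_difference(r.ash_pct, r.cp_pct, r.ndf_pct, r.cf_pct)
        for r in df.itertuples(index=False)
    ]
    out = {
        n: float((df["dry_mass_g"] * df[f"{n}_pct"] / 100.0).mean()) for n in NUTRIENTS
    }
    return MacronutrientTotals(
        dm_g=float(df["dry_mass_g"].mean()),
        cp_g=out["cp"], ndf_g=out["ndf"], cf_g=out["cf"], tnc_g=out["tnc"],
    )


def apparent_digestibility(
    mean_intake: MacronutrientTotals,
    mean_fecal: MacronutrientTotals,
    method: str = "ratio_of_means",
) -> DigestibilityCoefficients:
    """Apparent digestibility, ``(intake - fecal) / intake * 100`` per nutrient.

    The ratio-of-means form divides mean fecal output by mean intake over
    the collection period (the standard marker-free balance-trial
    estimator); ``apparent_digestibility_from_logs`` additionally offers
    a mean-of-daily-ratios variant on date-paired logs.  Zero intake of a
    nutrient leaves that coefficient undefined (``None``), flagged, never
    silently 0; a coefficient below 0 (fecal output exceeding intake) is
    kept and flagged.
    """
    if method != "ratio_of_means":
        raise NutritionError(f"unknown digestibility method {method!r}")
    intake = mean_intake.as_dict()
    fecal = mean_fecal.as_dict()
    values: dict[str, float | None] = {}
    flags: list[str] = []
    for nutrient, i in intake.items():
        if i <= 0:
            values[nutrient] = None
            flags.append(f"{nutrient}: zero intake, coefficient undefined")
            continue
        d = (i - fecal[nutrient]) / i * 100.0
        if d < 0:
            flags.append(f"{nutrient}: fecal output exceeds intake (D={d:.1f}%)")
        values[nutrient] = d
    return DigestibilityCoefficients(flags=tuple(flags), **values)


def apparent_digestibility_from_logs(
    daily_intake: pd.DataFrame,
    fecal_log: pd.DataFrame,
    method: str = "ratio_of_means",
) -> DigestibilityCoefficients:
    """Digestibility from a daily-intake table and a fecal collection log.

    ``method="ratio_of_means"`` (default) averages intake over the whole
    intake table and fecal output over the whole log before forming each
    coefficient.  ``method="mean_of_ratios"`` pairs fecal samples with
    intake by date (only dates present in both logs), computes a daily
    coefficient, and averages those — more variance-sensitive and biased
    when intake and excretion are decoupled by gut transit, provided for
    comparison only.
    """
    if method == "ratio_of_means":
        return apparent_digestibility(period_mean_intake(daily_intake), fecal_mean_output(fecal_log))
    if method != "mean_of_ratios":
        raise NutritionError(f"unknown digestibility method {method!r}")
    intake_by_date = daily_intake.reset_index().set_index("date")
    daily_coefs: dict[str, list[float]] = {n: [] for n in ("dm",) + NUTRIENTS}
    flags: list[str] = []
    for rec in fecal_log.itertuples(index=False):
        if rec.date not in intake_by_date.index:
            continue
        day = intake_by_date.loc[rec.date]
        one_day = apparent_digestibility(
            MacronutrientTotals(
                dm_g=day["dm_g"], cp_g=day["cp_g"], ndf_g=day["ndf_g"],
                cf_g=day["cf_g"], tnc_g=day["tnc_g"],
            ),
            fecal_mean_output(pd.DataFrame([rec._asdict()])),
        )
        flags.extend(one_day.flags)
        for nutrient, value in one_day.as_dict().items():
            if value is not None:
                daily_coefs[nutrient].append(value)
    values = {
        n: (float(np.mean(v)) if v else None) for n, v in daily_coefs.items()
    }
    if not any(daily_coefs.values()):
        raise NutritionError("mean_of_ratios: no fecal dates overlap the intake log")
    return DigestibilityCoefficients(flags=tuple(flags), **values)


def me_intake(intake: MacronutrientTotals, digest: DigestibilityCoefficients) -> MEIntake:
    """ME intake: fuel value x grams consumed x digestibility/100 per nutrient."""
    d = digest.as_dict()
    grams = intake.as_dict()
    me = {}
    for nutrient in NUTRIENTS:
        coef = d[nutrient]
        if coef is None:
            me[nutrient] = 0.0
            continue
        if not 0 <= coef <= 100:
            raise NutritionError(
                f"digestibility for {nutrient} outside [0, 100]: {coef:.1f}"
            )
        me[nutrient] = FUEL_VALUES[nutrient] * grams[nutrient] * coef / 100.0
    return MEIntake(me_cp=me["cp"], me_ndf=me["ndf"], me_cf=me["cf"], me_tnc=me["tnc"])


def daily_me_table(
    feed_log: pd.DataFrame,
    compositions: dict[str, FoodComposition],
    digest: DigestibilityCoefficients,
) -> pd.DataFrame:
    """Per animal-day ME intake (kcal) with a browse / non-browse split.

    Applies the animal's period digestibility coefficients to each day's
    macronutrient intake.  Returns a DataFrame indexed by
    ``(animal_id, date)`` with per-nutrient ME columns, ``me_total``,
    and ``browse_me`` / ``nonbrowse_me``.
    """
    _require_compositions(feed_log["item_id"], compositions)
    d = digest.as_dict()
    rows = []
    for rec in feed_log.itertuples(index=False):
        comp = compositions[rec.item_id]
        eaten = consumed_mass(rec.offered_g, rec.remaining_g, comp.moisture_loss_overnight)
        dm = eaten * comp.dm_fraction
        grams = {
            "cp": dm * comp.cp_pct / 100.0,
            "ndf": dm * comp.ndf_pct / 100.0,
            "cf": dm * comp.cf_pct / 100.0,
            "tnc": dm * comp.tnc_pct / 100.0,
        }
        me = {
            f"me_{n}": FUEL_VALUES[n] * grams[n] * (d[n] or 0.0) / 100.0
            for n in NUTRIENTS
        }
        total = sum(me.values())
        rows.append({
            "animal_id": rec.animal_id,
            "date": rec.date,
            **me,
            "me_total": total,
            "browse_me": total if comp.category == "browse" else 0.0,
            "nonbrowse_me": 0.0 if comp.category == "browse" else total,
        })
    per_item = pd.DataFrame(rows)
    cols = [c for c in per_item.columns if c.startswith(("me_", "browse", "nonbrowse"))]
    return per_item.groupby(["animal_id", "date"])[cols].sum()


def partition_me(daily_me: pd.DataFrame) -> tuple[float, float]:
    """Mean daily (browse_me, nonbrowse_me) in kcal from a `daily_me_table`."""
    return float(daily_me["browse_me"].mean()), float(daily_me["nonbrowse_me"].mean())
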