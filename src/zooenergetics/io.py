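"""CSV readers/writers, run configuration, and the end-to-end analysis driver.

Interchange format is plain CSV (UTF-8, comma separator, '.' decimal,
ISO-8601 dates) plus Newick for trees.  Every reader validates its schema
up front and reports offending rows with line numbers, so a malformed
input fails at load time with an actionable message rather than deep in
the analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import allometry, dlw, nutrition, seasonal
from .nutrition import FoodComposition

__all__ = [
    "SCHEMAS",
    "read_table",
    "read_compositions",
    "read_tree",
    "RunConfig",
    "run_full_analysis",
]


class InputError(ValueError):
    pass


#: required columns and dtypes per table kind
SCHEMAS: dict[str, dict[str, str]] = {
    "isotope_samples": {
        "animal_id": "str", "isotope": "str", "time_since_dose_d": "float",
        "enrichment_ppm": "float", "is_background": "bool",
    },
    "doses": {
        "animal_id": "str", "dose_mass_g": "float",
        "frac_2h2o": "float", "frac_h218o": "float",
    },
    "feed_log": {
        "animal_id": "str", "date": "date", "item_id": "str",
        "offered_g": "float", "remaining_g": "float",
    },
    "compositions": {
        "item_id": "str", "category": "str", "dm_fraction": "float",
        "ash_pct": "float", "cp_pct": "float", "ndf_pct": "float",
        "cf_pct": "float", "moisture_loss_overnight": "float",
    },
    "fecal_log": {
        "animal_id": "str", "date": "date", "dry_mass_g": "float",
        "ash_pct": "float", "cp_pct": "float", "ndf_pct": "float", "cf_pct": "float",
    },
    "comparative": {
        "species": "str", "body_mass": "float", "tee": "float",
    },
    "body_mass": {
        "animal_id": "str", "body_mass_kg": "float", "fq": "float",
    },
}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Required columns must be present (an error names any missing one);
    unknown columns are preserved untouched.  Type coercion failures and
    null required cells are reported with 1-based file line numbers
    (header = line 1).
    """
    if schema not in SCHEMAS:
        raise InputError(f"unknown schema {schema!r}")
    spec = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    df = pd.read_csv(path)
    missing = sorted(set(spec) - set(df.columns))
    if missing:
        raise InputError(f"{path}: missing required column(s): {', '.join(missing)}")
    bad_lines: list[str] = []
    for col, kind in spec.items():
        raw = df[col]
        if raw.isna().any():
            for i in raw.index[raw.isna()]:
                bad_lines.append(f"line {i + 2}: empty {col!r}")
            continue
        try:
            if kind == "float":
                df[col] = raw.astype(float)
            elif kind == "bool":
                if raw.dtype != bool:
                    df[col] = raw.astype(str).str.lower().map(
                        {"true": True, "false": False, "1": True, "0": False}
                    )
                    if df[col].isna().any():
                        raise ValueError("unparseable boolean")
            elif kind == "date":
                df[col] = pd.to_datetime(raw, format="ISO8601").dt.date
            else:
                df[col] = raw.astype(str)
        except (ValueError, TypeError) as exc:
            coerced = pd.to_numeric(raw, errors="coerce") if kind == "float" else None
            if coerced is not None and coerced.isna().any():
                for i in coerced.index[coerced.isna()]:
                    bad_lines.append(f"line {i + 2}: bad {kind} in {col!r}: {raw[i]!r}")
            else:
                bad_lines.append(f"column {col!r}: {exc}")
    if bad_lines:
        raise InputError(f"{path}: " + "; ".join(bad_lines))
    return df


def read_compositions(path) -> dict[str, FoodComposition]:
    """Load a food composition table into per-item records (TNC by difference)."""
    df = read_table(path, "compositions")
    out: dict[str, FoodComposition] = {}
    for rec in df.itertuples(index=False):
        out[rec.item_id] = FoodComposition(
            item_id=rec.item_id, category=rec.category,
            dm_fraction=rec.dm_fraction, ash_pct=rec.ash_pct,
            cp_pct=rec.cp_pct, ndf_pct=rec.ndf_pct, cf_pct=rec.cf_pct,
            moisture_loss_overnight=rec.moisture_loss_overnight,
        )
    return out


def read_tree(path) -> dendropy.Tree:
    """Load a Newick tree (branch lengths required downstream)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"tree file not found: {path}")
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_compositions(compositions: dict[str, FoodComposition], path) -> None:
    rows = [
        {
            "item_id": c.item_id, "category": c.category, "dm_fraction": c.dm_fraction,
            "ash_pct": c.ash_pct, "cp_pct": c.cp_pct, "ndf_pct": c.ndf_pct,
            "cf_pct": c.cf_pct, "moisture_loss_overnight": c.moisture_loss_overnight,
        }
        for c in compositions.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Paths and analysis options for a full study run.

    Defaults reproduce the reference analysis choices: log base 10 on
    both allometry axes, ML Pagel's lambda, alpha 0.05 with
    Benjamini-Hochberg correction, ratio-of-means digestibility.
    """

    isotope_samples: Path | None = None
    doses: Path | None = None
    feed_log: Path | None = None
    compositions: Path | None = None
    fecal_log: Path | None = None
    comparative: Path | None = None
    tree: Path | None = None
    body_mass: Path | None = None
    out_dir: Path = Path("results")
    log_base: float = 10.0
    lambda_mode: str = "ml"  # "ml" or a fixed float
    alpha: float = 0.05
    fdr_method: str = "fdr_bh"
    digestibility_method: str = "ratio_of_means"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise InputError(f"{path}: unknown config key(s): {', '.join(unknown)}")
        path_fields = {
            "isotope_samples", "doses", "feed_log", "compositions", "fecal_log",
            "comparative", "tree", "body_mass", "out_dir",
        }
        for k in list(raw):
            if k in path_fields and raw[k] is not None:
                raw[k] = Path(raw[k])
        return cls(**raw)


def _analyze_dlw_animal(samples: pd.DataFrame, dose_row, fq: float, body_mass: float):
    fits = {}
    for isotope in ("deuterium", "oxygen18"):
        sub = samples[samples["isotope"] == isotope]
        bg_rows = sub[sub["is_background"]]
        if bg_rows.empty:
            raise InputError(f"no background sample for isotope {isotope}")
        background = float(bg_rows["enrichment_ppm"].mean())
        post = sub[~sub["is_background"]].sort_values("time_since_dose_d")
        # average analytical replicates taken at the same nominal time
        post = (
            post.groupby("time_since_dose_d", as_index=False)["enrichment_ppm"].mean()
        )
        fits[isotope] = dlw.fit_isotope_kinetics(
            post["time_since_dose_d"], post["enrichment_ppm"],
            background=background, isotope=isotope,
        )
    dose = dlw.DoseRecord(
        dose_mass=dose_row.dose_mass_g,
        frac_2h2o=dose_row.frac_2h2o,
        frac_h218o=dose_row.frac_h218o,
    )
    spaces, comp, energy = dlw.tee_from_fits(
        dose, fits["deuterium"], fits["oxygen18"], fq=fq, body_mass=body_mass
    )
    return fits, spaces, comp, energy


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage for which the config provides inputs; write a CSV bundle.

    Stages (each optional, driven by which paths are set):

    * DLW: isotope samples + doses + body-mass/FQ table -> per-animal
      elimination rates, dilution spaces, body composition and TEE in
      all reporting scales (``tee_summary.csv``).
    * Diet: feed log + compositions (+ fecal log) -> per-day intake and
      ME, period digestibility, ME partition, seasonal ANOVA/contrast
      tables (``intake_daily.csv``, ``digestibility.csv``,
      ``me_summary.csv``, ``seasonal_summary.csv``,
      ``seasonal_contrasts.csv``).
    * Allometry: comparative table + tree -> lambda-ML PGLS fit and
      observed-vs-expected percentages for the study animals
      (``pgls_fit.csv``, ``pct_expected.csv``).

    Returns the bundle as a dict of DataFrames keyed like the files.
    Raises with stage context on any failure.
    """
    out: dict[str, pd.DataFrame] = {}
    cfg = config
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    masses = read_table(cfg.body_mass, "body_mass") if cfg.body_mass else None

    mean_tee_kcal = None
    if cfg.isotope_samples and cfg.doses:
        if masses is None:
            raise InputError("DLW stage requires a body_mass table (mass + FQ per animal)")
        samples = read_table(cfg.isotope_samples, "isotope_samples")
        doses = read_table(cfg.doses, "doses").set_index("animal_id")
        rows = []
        for animal, sub in samples.groupby("animal_id"):
            if animal not in doses.index:
                raise InputError(f"no dose record for animal {animal!r}")
            minfo = masses.set_index("animal_id")
            if animal not in minfo.index:
                raise InputError(f"no body-mass/FQ row for animal {animal!r}")
            fits, spaces, comp, energy = _analyze_dlw_animal(
                sub, doses.loc[animal],
                fq=float(minfo.loc[animal, "fq"]),
                body_mass=float(minfo.loc[animal, "body_mass_kg"]),
            )
            rows.append({
                "animal_id": animal,
                "k_D_per_d": fits["deuterium"].k, "k_O_per_d": fits["oxygen18"].k,
                "N_D_mol": spaces.N_D, "N_O_mol": spaces.N_O,
                "dilution_space_ratio": spaces.ratio, "N_mol": spaces.N_pooled,
                "TBW_kg": comp.TBW, "FFM_kg": comp.FFM, "FM_kg": comp.FM,
                "body_fat_pct": comp.pct_fat, "FQ": energy.fq,
                "rCO2_mol_d": energy.rco2,
                "TEE_kcal_d": energy.tee_kcal, "TEE_kJ_d": energy.tee_kj,
                "TEE_kcal_d_BW": energy.tee_per_bw, "TEE_kcal_d_MBW": energy.tee_per_mbw,
                "TEE_kJ_d_BW": energy.tee_kj_per_bw, "TEE_kJ_d_MBW": energy.tee_kj_per_mbw,
            })
        out["tee_summary"] = pd.DataFrame(rows)
        mean_tee_kcal = float(out["tee_summary"]["TEE_kcal_d"].mean())

    if cfg.feed_log and cfg.compositions:
        comps = read_compositions(cfg.compositions)
        feed = read_table(cfg.feed_log, "feed_log")
        daily = nutrition.daily_intake_table(feed, comps)
        out["intake_daily"] = daily.reset_index()
        digest_rows, me_rows, seasonal_rows, contrast_rows = [], [], [], []
        for animal, sub in feed.groupby("animal_id"):
            daily_a = nutrition.daily_intake_table(sub, comps)
            mean_intake = nutrition.period_mean_intake(daily_a)
            if cfg.fecal_log:
                fecal = read_table(cfg.fecal_log, "fecal_log")
                fecal_a = fecal[fecal["animal_id"] == animal]
                if fecal_a.empty:
                    raise InputError(f"no fecal rows for animal {animal!r}")
                # fecal collections are averaged against the concurrent
                # two-week mean intake starting at the first collection day
                w0 = fecal_a["date"].min()
                w1 = w0 + pd.Timedelta(days=13).to_pytimedelta()
                concurrent = daily_a.reset_index()
                concurrent = concurrent[
                    (concurrent["date"] >= w0) & (concurrent["date"] <= w1)
                ].set_index(["animal_id", "date"])
                digest = nutrition.apparent_digestibility_from_logs(
                    concurrent if len(concurrent) else daily_a,
                    fecal_a, method=cfg.digestibility_method,
                )
                digest_rows.append({"animal_id": animal, **{
                    f"D_{k}_pct": v for k, v in digest.as_dict().items()
                }, "flags": "; ".join(digest.flags)})
                daily_me = nutrition.daily_me_table(sub, comps, digest)
                browse_me, nonbrowse_me = nutrition.partition_me(daily_me)
                me = nutrition.me_intake(mean_intake, digest)
                me_rows.append({
                    "animal_id": animal,
                    "ME_cp_kcal_d": me.me_cp, "ME_ndf_kcal_d": me.me_ndf,
                    "ME_tnc_kcal_d": me.me_tnc, "ME_cf_kcal_d": me.me_cf,
                    "ME_total_kcal_d": me.me_total,
                    "ME_daily_mean_kcal_d": float(daily_me["me_total"].mean()),
                    "ME_daily_sd_kcal_d": float(daily_me["me_total"].std(ddof=1)),
                    "browse_ME_kcal_d": browse_me, "nonbrowse_ME_kcal_d": nonbrowse_me,
                    "FQ": dlw.food_quotient(me.me_cp, me.me_ndf, me.me_tnc, me.me_cf).FQ,
                })
                if masses is not None:
                    minfo = masses.set_index("animal_id")
                    bm = float(minfo.loc[animal, "body_mass_kg"])
                    summ = seasonal.seasonal_summary(
                        daily_me, bm, alpha=cfg.alpha, fdr_method=cfg.fdr_method
                    )
                    s = summ.reset_index()
                    s.insert(0, "animal_id", animal)
                    seasonal_rows.append(s)
                    c = summ.attrs["contrasts"].copy()
                    c.insert(0, "animal_id", animal)
                    anova = summ.attrs["anova"]
                    c["anova_F"] = anova.f_stat
                    c["anova_df_between"] = anova.df_between
                    c["anova_df_within"] = anova.df_within
                    c["anova_p"] = anova.p_value
                    contrast_rows.append(c)
        if digest_rows:
            out["digestibility"] = pd.DataFrame(digest_rows)
            out["me_summary"] = pd.DataFrame(me_rows)
        if seasonal_rows:
            out["seasonal_summary"] = pd.concat(seasonal_rows, ignore_index=True)
            out["seasonal_contrasts"] = pd.concat(contrast_rows, ignore_index=True)

    if cfg.comparative and cfg.tree:
        comp_df = read_table(cfg.comparative, "comparative")
        tree = read_tree(cfg.tree)
        lam = None if cfg.lambda_mode == "ml" else float(cfg.lambda_mode)
        fit = allometry.pgls_fit(comp_df, tree, lam=lam, log_base=cfg.log_base)
        out["pgls_fit"] = pd.DataFrame([{
            "intercept": fit.intercept, "slope": fit.slope, "lambda": fit.lam,
            "log_likelihood": fit.log_likelihood, "sigma2": fit.sigma2,
            "n_species": fit.n_species, "log_base": fit.log_base,
        }])
        if masses is not None and mean_tee_kcal is not None:
            mean_mass = float(masses["body_mass_kg"].mean())
            exp_tee = allometry.expected_value(fit, mean_mass)
            out["pct_expected"] = pd.DataFrame([{
                "observed_TEE_kcal_d": mean_tee_kcal,
                "body_mass_kg": mean_mass,
                "expected_TEE_kcal_d": exp_tee,
                "pct_of_expected": allometry.pct_of_expected(mean_tee_kcal, exp_tee),
            }])
    elif cfg.comparative or cfg.tree:
        raise InputError("allometry stage needs both a comparative table and a tree")

    for name, df in out.items():
        df.to_csv(cfg.out_dir / f"{name}.csv", index=False)
    return out
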