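"""Seasonal intake statistics: one-way ANOVA and FDR-corrected contrasts.

Seasons follow the browse-procurement calendar of a northern-hemisphere
zoo sourcing browse locally in the growing season and from a southern
supplier otherwise: summer = May-July (local early growing season),
autumn = August-October (local late), winter = November-January
(supplier's late growing season), spring = February-April (supplier's
early).  The winter season spans the calendar year boundary; assignment
is by month only.

Daily metabolizable-energy intake is compared across seasons with a
classical one-way ANOVA, followed by all pairwise contrasts using the
pooled within-group variance and the ANOVA residual degrees of freedom
(the no-covariate equivalent of estimated-marginal-means contrasts),
with Benjamini-Hochberg false-discovery-rate correction and a compact
letter display (groups sharing a letter are not significantly different
at the chosen alpha).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from datetime import date as _date

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SEASONS",
    "SEASON_OF_MONTH",
    "assign_season",
    "AnovaResult",
    "one_way_anova",
    "pairwise_contrasts",
    "compact_letter_display",
    "seasonal_summary",
]

SEASONS = ("summer", "autumn", "winter", "spring")

SEASON_OF_MONTH = {
    5: "summer", 6: "summer", 7: "summer",
    8: "autumn", 9: "autumn", 10: "autumn",
    11: "winter", 12: "winter", 1: "winter",
    2: "spring", 3: "spring", 4: "spring",
}


class SeasonalStatsError(ValueError):
    pass


def assign_season(d) -> str:
    """Map a date (or anything with a ``month`` attribute) to its season."""
    if isinstance(d, str):
        d = _date.fromisoformat(d)
    return SEASON_OF_MONTH[d.month]


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict[str, float]
    group_n: dict[str, int]
    ms_within: float  # pooled within-group variance


def _grouped(values, groups) -> dict[str, np.ndarray]:
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups, dtype=object)
    if v.shape != g.shape:
        raise SeasonalStatsError("values and groups must have equal length")
    out = {key: v[g == key] for key in pd.unique(g)}
    if len(out) < 2:
        raise SeasonalStatsError("need at least 2 groups")
    small = [k for k, arr in out.items() if len(arr) < 2]
    if small:
        raise SeasonalStatsError(
            f"group(s) with fewer than 2 observations: {', '.join(map(str, small))}"
        )
    return out


def one_way_anova(values, groups) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA from between/within sums of squares."""
    by_group = _grouped(values, groups)
    v = np.asarray(values, dtype=float)
    grand = v.mean()
    n = len(v)
    k = len(by_group)
    ss_between = sum(len(arr) * (arr.mean() - grand) ** 2 for arr in by_group.values())
    ss_within = sum(float(np.sum((arr - arr.mean()) ** 2)) for arr in by_group.values())
    df_b, df_w = k - 1, n - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        f = 0.0 if ms_b == 0 else np.inf
    else:
        f = ms_b / ms_w
    p = float(stats.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    return AnovaResult(
        f_stat=float(f),
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        group_means={k_: float(arr.mean()) for k_, arr in by_group.items()},
        group_n={k_: int(len(arr)) for k_, arr in by_group.items()},
        ms_within=ms_w,
    )


def pairwise_contrasts(values, groups, alpha: float = 0.05, fdr_method: str = "fdr_bh") -> pd.DataFrame:
    """All pairwise group contrasts with FDR-adjusted p-values and letters.

    Each contrast uses the pooled within-group variance and the ANOVA
    residual degrees of freedom:
    ``t = (mean_i - mean_j) / sqrt(MSW * (1/n_i + 1/n_j))``, two-sided p
    from Student's t on ``df_within``.  Adjustment is Benjamini-Hochberg
    (``fdr_method="fdr_by"`` switches to Benjamini-Yekutieli).

    Returns a DataFrame with one row per pair (group_1, group_2,
    mean_diff, se, t, p_raw, p_adj, significant) carrying the compact
    letter display in ``df.attrs["letters"]``.
    """
    if fdr_method not in {"fdr_bh", "fdr_by"}:
        raise SeasonalStatsError(f"unsupported FDR method {fdr_method!r}")
    anova = one_way_anova(values, groups)
    keys = list(anova.group_means)
    rows = []
    for a, b in itertools.combinations(keys, 2):
        diff = anova.group_means[a] - anova.group_means[b]
        se = np.sqrt(anova.ms_within * (1.0 / anova.group_n[a] + 1.0 / anova.group_n[b]))
        if se == 0:
            t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        else:
            t = diff / se
        p = float(2.0 * stats.t.sf(abs(t), anova.df_within)) if np.isfinite(t) else 0.0
        rows.append({"group_1": a, "group_2": b, "mean_diff": diff, "se": se, "t": t, "p_raw": p})
    df = pd.DataFrame(rows)
    reject, p_adj, *_ = multipletests(df["p_raw"], alpha=alpha, method=fdr_method)
    df["p_adj"] = p_adj
    df["significant"] = reject
    order = sorted(keys, key=lambda k_: anova.group_means[k_], reverse=True)
    different = {
        frozenset((r.group_1, r.group_2)) for r in df.itertuples() if r.significant
    }
    df.attrs["letters"] = compact_letter_display(order, different)
    df.attrs["anova"] = anova
    return df


def compact_letter_display(
    ordered_groups: list[str], different: set[frozenset]
) -> dict[str, str]:
    """Assign shared letters to groups whose means are not significantly different.

    Insert-and-absorb construction: start from one class holding every
    group; for each significantly different pair present together in a
    class, split that class into two copies (each missing one member of
    the pair); absorb classes contained in another.  The result covers
    every non-different pair with a shared letter and never letters a
    different pair together; transitivity conflicts (a~b, b~c, a≁c)
    naturally leave b lettered with both sides.  Pair processing and
    letter order follow ``ordered_groups``, so the display is
    deterministic across runs.
    """
    idx = {g: i for i, g in enumerate(ordered_groups)}
    classes: list[list[str]] = [list(ordered_groups)]
    pairs = sorted(
        (sorted(p, key=idx.__getitem__) for p in different),
        key=lambda p: (idx[p[0]], idx[p[1]]),
    )
    for i, j in pairs:
        split: list[list[str]] = []
        for cls in classes:
            if i in cls and j in cls:
                split.append([g for g in cls if g != i])
                split.append([g for g in cls if g != j])
            else:
                split.append(cls)
        kept: list[list[str]] = []
        seen: set[frozenset] = set()
        for cls in split:
            s = frozenset(cls)
            if s in seen or any(s < frozenset(o) for o in split):
                continue
            seen.add(s)
            kept.append(cls)
        classes = kept
    classes.sort(key=lambda cls: min(idx[g] for g in cls))
    letters = {g: "" for g in ordered_groups}
    for letter, cls in zip("abcdefghijklmnopqrstuvwxyz", classes):
        for g in sorted(cls, key=idx.__getitem__):
            letters[g] += letter
    return letters


def seasonal_summary(
    daily_me: pd.DataFrame,
    body_mass: float,
    alpha: float = 0.05,
    fdr_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Season-by-season ME intake summary in every reporting scale.

    ``daily_me`` is a per-day table with a ``date`` level or column and a
    ``me_total`` column (kcal/day).  Returns mean ± SD rows per season
    for kcal, kcal/BW, kcal/MBW and their kJ analogues, with sample sizes
    and the compact letters from the pairwise contrasts on kcal/day.
    """
    from .dlw import KCAL_TO_KJ, MBW_EXPONENT

    df = daily_me.reset_index()
    df["season"] = [assign_season(d) for d in df["date"]]
    contrasts = pairwise_contrasts(df["me_total"], df["season"], alpha=alpha, fdr_method=fdr_method)
    letters = contrasts.attrs["letters"]
    mbw = body_mass ** MBW_EXPONENT
    rows = []
    for season in SEASONS:
        sub = df.loc[df["season"] == season, "me_total"]
        if sub.empty:
            continue
        kcal_mean, kcal_sd = float(sub.mean()), float(sub.std(ddof=1))
        rows.append({
            "season": season,
            "n_days": int(len(sub)),
            "me_kcal_mean": kcal_mean,
            "me_kcal_sd": kcal_sd,
            "me_kcal_per_bw_mean": kcal_mean / body_mass,
            "me_kcal_per_mbw_mean": kcal_mean / mbw,
            "me_kj_mean": kcal_mean * KCAL_TO_KJ,
            "me_kj_per_bw_mean": kcal_mean * KCAL_TO_KJ / body_mass,
            "me_kj_per_mbw_mean": kcal_mean * KCAL_TO_KJ / mbw,
            "letters": letters[season],
        })
    out = pd.DataFrame(rows).set_index("season")
    out.attrs["contrasts"] = contrasts
    out.attrs["anova"] = contrasts.attrs["anova"]
    return out
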