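"""Factorial statistics over depth x temperature x enzyme.

ANOVA variants (two-way fixed effects with optional interaction; blocked
one-way with temperature as block), Tukey HSD with compact letter
displays, assumption diagnostics (Levene, Shapiro-Wilk, residual
skewness), percent-decline summaries of trait profiles, and pairwise
enzyme trait ratios.

Sums of squares are sequential (type I), appropriate for the balanced
campaign design; unbalanced input is accepted with a logged warning.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class AnovaResult:
    table: pd.DataFrame       # index: terms + Residual; df, sum_sq, F, p
    design: str               # one_way | two_way_fixed | blocked
    response_transform: str   # none | ln
    model: object = None      # fitted statsmodels OLS (for residuals)

    def residuals(self) -> np.ndarray:
        return np.asarray(self.model.resid)


def _prepare(table: pd.DataFrame, response: str, ln_transform: bool):
    df = table.copy()
    if ln_transform:
        if (df[response] <= 0).any():
            raise ValueError("ln transform requires positive response")
        df["_y"] = np.log(df[response].astype(float))
        return df, "ln"
    df["_y"] = df[response].astype(float)
    return df, "none"


def _anova_from_formula(df, formula, design, transform):
    fit = smf.ols(formula, data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=1)
    tab = tab.rename(columns={"PR(>F)": "p"})
    # constant response: zero SS everywhere -> undefined F/p, report p = 1
    if np.allclose(tab["sum_sq"], 0.0):
        tab["F"] = 0.0
        tab["p"] = 1.0
        tab.loc["Residual", ["F", "p"]] = np.nan
    return AnovaResult(table=tab, design=design, response_transform=transform,
                       model=fit)


def anova_two_way(table: pd.DataFrame, response: str,
                  factor_a: str = "depth_cm", factor_b: str = "temperature_C",
                  interaction: bool = True,
                  ln_transform: bool = False) -> AnovaResult:
    """Two-way fixed-effects ANOVA with sequential (type I) sums of squares."""
    df, transform = _prepare(table, response, ln_transform)
    counts = df.groupby([factor_a, factor_b], observed=True).size()
    n_cells = df[factor_a].nunique() * df[factor_b].nunique()
    if interaction and (len(counts) < n_cells or (counts == 0).any()):
        raise ValueError("empty cells with interaction requested")
    if counts.nunique() > 1:
        log.warning("unbalanced design; sequential type-I SS in model order")
    fa, fb = f"C(Q('{factor_a}'))", f"C(Q('{factor_b}'))"
    formula = f"_y ~ {fa} + {fb}" + (f" + {fa}:{fb}" if interaction else "")
    return _anova_from_formula(df, formula, "two_way_fixed", transform)


def anova_blocked(table: pd.DataFrame, response: str,
                  factor: str = "depth_cm", block: str = "temperature_C",
                  ln_transform: bool = False) -> AnovaResult:
    """One-way ANOVA of ``factor`` with ``block`` as a blocking variable.

    The factor is tested against the residual after removing block
    variation; no interaction term. Every factor level must appear in
    every block.
    """
    df, transform = _prepare(table, response, ln_transform)
    counts = df.groupby([factor, block], observed=True).size()
    full = df[factor].nunique() * df[block].nunique()
    if len(counts) < full:
        present = set(counts.index)
        missing = [c for c in itertools.product(
            df[factor].unique(), df[block].unique()) if c not in present]
        raise ValueError(f"unbalanced blocks; missing cells: {missing[:5]}")
    formula = f"_y ~ C(Q('{block}')) + C(Q('{factor}'))"
    return _anova_from_formula(df, formula, "blocked", transform)


def anova_one_way(table: pd.DataFrame, response: str,
                  factor: str, ln_transform: bool = False) -> AnovaResult:
    df, transform = _prepare(table, response, ln_transform)
    return _anova_from_formula(df, f"_y ~ C(Q('{factor}'))", "one_way",
                               transform)


# --- Tukey HSD and compact letter displays -------------------------------

@dataclass(frozen=True)
class CLDResult:
    p_matrix: pd.DataFrame    # adjusted pairwise p, symmetric
    letters: dict             # level -> letter string
    means: pd.Series


def tukey_p_matrix(values: pd.Series, groups: pd.Series,
                   mse: float, df_resid: float) -> pd.DataFrame:
    """Studentized-range adjusted pairwise p-values against a supplied
    error mean square (so the ANOVA residual stratum is reused)."""
    levels = list(pd.unique(groups))
    means = values.groupby(groups, observed=True).mean()
    ns = values.groupby(groups, observed=True).size()
    k = len(levels)
    pm = pd.DataFrame(np.ones((k, k)), index=levels, columns=levels)
    for a, b in itertools.combinations(levels, 2):
        se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        if se == 0:
            p = 0.0 if means[a] != means[b] else 1.0
        else:
            q = abs(means[a] - means[b]) / se
            p = float(sps.studentized_range.sf(q, k, df_resid))
        pm.loc[a, b] = pm.loc[b, a] = p
    return pm


def compact_letters(p_matrix: pd.DataFrame, means: pd.Series,
                    alpha: float = ALPHA) -> dict:
    """Insert-and-absorb compact letter display.

    Groups sorted by descending mean; two levels share a letter iff their
    adjusted p > alpha. Produces a minimal consistent letter set.
    """
    levels = list(means.sort_values(ascending=False).index)
    # insert-and-absorb: start with one letter over all levels; split it on
    # every significant pair; drop letter sets absorbed by a superset
    letter_groups: list[set] = [set(levels)]
    for a, b in itertools.combinations(levels, 2):
        if p_matrix.loc[a, b] > alpha:
            continue
        new_groups = []
        for g in letter_groups:
            if a in g and b in g:
                new_groups.extend([g - {a}, g - {b}])
            else:
                new_groups.append(g)
        # absorb: drop duplicates and sets contained in another
        uniq = []
        for g in new_groups:
            if g and g not in uniq:
                uniq.append(g)
        letter_groups = [g for g in uniq if not any(g < h for h in uniq)]
    # deterministic order: by best (highest-mean) member
    letter_groups.sort(key=lambda g: min(levels.index(lv) for lv in g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lv: "" for lv in levels}
    for letter, grp in zip(alphabet, letter_groups):
        for lv in grp:
            out[lv] += letter
    return {lv: "".join(sorted(s)) for lv, s in out.items()}


def tukey_cld(anova: AnovaResult, table: pd.DataFrame, response: str,
              factor: str, alpha: float = ALPHA) -> CLDResult:
    """Tukey HSD on one ANOVA factor plus its compact letter display."""
    tab = anova.table
    if "Residual" not in tab.index or tab.loc["Residual", "df"] <= 0:
        raise ValueError("ANOVA has no residual degrees of freedom")
    mse = tab.loc["Residual", "sum_sq"] / tab.loc["Residual", "df"]
    y = table[response].astype(float)
    if anova.response_transform == "ln":
        y = np.log(y)
    groups = table[factor]
    levels = groups.nunique()
    if levels < 2:
        raise ValueError("factor needs >= 2 levels")
    if mse == 0:
        log.warning("zero residual variance; all non-identical pairs "
                    "declared significant")
    pm = tukey_p_matrix(y, groups, mse, tab.loc["Residual", "df"])
    means = y.groupby(groups, observed=True).mean()
    return CLDResult(p_matrix=pm, letters=compact_letters(pm, means, alpha),
                     means=means)


# --- assumption checks ---------------------------------------------------

def assumption_checks(residuals, groups=None) -> dict:
    """Advisory ANOVA diagnostics: Levene (median-centered), Shapiro-Wilk,
    residual skewness. The pipeline proceeds regardless; failures are
    logged."""
    r = np.asarray(residuals, dtype=float)
    out = {"n": r.size}
    if r.size < 3:
        log.info("assumption checks skipped: n < 3")
        out["skipped"] = True
        return out
    out["skewness"] = float(sps.skew(r))
    sw = sps.shapiro(r)
    out["shapiro_stat"], out["shapiro_p"] = float(sw.statistic), float(sw.pvalue)
    if groups is not None:
        g = pd.Series(groups)
        samples = [r[g.to_numpy() == lv] for lv in g.unique()]
        samples = [s for s in samples if s.size >= 2]
        if len(samples) >= 2:
            lv = sps.levene(*samples, center="median")
            out["levene_stat"] = float(lv.statistic)
            out["levene_p"] = float(lv.pvalue)
    for name in ("shapiro_p", "levene_p"):
        if out.get(name, 1.0) < ALPHA:
            log.warning("%s = %.3g < %.2f", name, out[name], ALPHA)
    return out


def needs_ln_transform(table: pd.DataFrame, response: str,
                       factors: list[str]) -> bool:
    """ln-transform heuristic: transform when Levene or Shapiro fails on the
    untransformed one-way residuals at alpha = 0.05 (and the response is
    positive)."""
    if (table[response] <= 0).any():
        return False
    grp = table[factors[0]]
    res = anova_one_way(table, response, factors[0])
    diag = assumption_checks(res.residuals(), grp)
    bad = (diag.get("shapiro_p", 1.0) < ALPHA
           or diag.get("levene_p", 1.0) < ALPHA)
    if bad:
        log.info("ln transform applied to %s", response)
    return bad


# --- profile summaries ---------------------------------------------------

def percent_decline(table: pd.DataFrame, value: str,
                    depth_col: str = "depth_cm",
                    temp_col: str = "temperature_C",
                    upper: tuple = ("0-10", "10-20"),
                    lower: tuple = ("60-70", "80-90"),
                    exclude_cells: list | None = None) -> dict:
    """Maximum percent decline of a trait down the profile, per temperature.

    100 * (max over upper depths - min over lower depths) / max over upper,
    computed within each temperature on depth means, then summarized as
    mean +- se across temperatures. ``exclude_cells`` lists
    (depth, temperature) pairs dropped before the calculation (for flagged
    spurious cells).
    """
    df = table.copy()
    if exclude_cells:
        for depth, temp in exclude_cells:
            df = df[~((df[depth_col] == depth)
                      & (df[temp_col].astype(float) == float(temp)))]
    per_temp = {}
    for temp, sub in df.groupby(df[temp_col].astype(float)):
        means = sub.groupby(depth_col, observed=True)[value].mean()
        up = means.reindex([d for d in upper if d in means.index]).dropna()
        lo = means.reindex([d for d in lower if d in means.index]).dropna()
        if up.empty or lo.empty:
            continue
        peak = up.max()
        if peak <= 0:
            log.warning("non-positive upper maximum at %s deg C; decline "
                        "undefined", temp)
            per_temp[temp] = np.nan
            continue
        per_temp[temp] = 100.0 * (peak - lo.min()) / peak
    vals = np.array([v for v in per_temp.values() if np.isfinite(v)])
    return {
        "per_temperature": per_temp,
        "mean": float(vals.mean()) if vals.size else np.nan,
        "se": float(vals.std(ddof=1) / np.sqrt(vals.size))
              if vals.size > 1 else np.nan,
        "n_temperatures": int(vals.size),
    }


ENZYME_PAIRS = (("BG", "LAP"), ("BG", "AP"), ("LAP", "AP"))


def enzyme_ratios(traits: pd.DataFrame,
                  value_cols: tuple = ("vmax_ds", "km", "ce_ds"),
                  keys: tuple = ("depth_cm", "core", "temperature_C")
                  ) -> pd.DataFrame:
    """Pairwise enzyme trait ratios at common coordinates.

    One row per coordinate x enzyme pair with ``<trait>_ratio`` columns;
    a missing partner or zero denominator yields a missing ratio.
    """
    out = []
    for num, den in ENZYME_PAIRS:
        a = traits[traits["enzyme"] == num].set_index(list(keys))
        b = traits[traits["enzyme"] == den].set_index(list(keys))
        common = a.index.intersection(b.index)
        if common.empty:
            continue
        row = pd.DataFrame(index=common)
        row["pair"] = f"{num}:{den}"
        for col in value_cols:
            denom = b.loc[common, col].astype(float)
            denom = denom.where(denom != 0)
            if denom.isna().any():
                log.warning("zero denominator in %s for pair %s:%s",
                            col, num, den)
            row[f"{col}_ratio"] = a.loc[common, col].astype(float) / denom
        out.append(row.reset_index())
    if not out:
        return pd.DataFrame(columns=["pair", *keys])
    return pd.concat(out, ignore_index=True)
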