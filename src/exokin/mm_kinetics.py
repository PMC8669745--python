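"""Michaelis-Menten fitting with transform-both-sides Box-Cox, and the
derived kinetic traits.

The model is v(S) = Vmax * S / (Km + S). Analytical replicates of soil
assays are strongly heteroscedastic across substrate concentrations, so
both the response and the model prediction are passed through the same
Box-Cox power transform with exponent lambda shared across the fit
(transform-both-sides, TBS). lambda is chosen by profile maximum
likelihood on a grid (default -2..2 step 0.1, refined once around the
optimum), with the Jacobian term (lambda - 1) * sum(ln v) included so
different lambdas are comparable. Parameter estimates stay on the original
scale (TBS does not reparameterize); standard errors are the asymptotic
least-squares errors at the selected lambda, and p-values come from
two-sided t statistics with n - 2 degrees of freedom.

Fits with nonsignificant Vmax or Km (p > 0.05) are gated out downstream,
mirroring the exclusion of poorly fitting models from the trait tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .assay_data import SoilContext

log = logging.getLogger(__name__)

LAMBDA_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.1), 10)


@dataclass(frozen=True)
class MMFit:
    """One Michaelis-Menten fit for an enzyme x depth x core x temperature
    (x timepoint) unit."""
    vmax: float
    km: float
    se_vmax: float
    se_km: float
    p_vmax: float
    p_km: float
    lam: float            # Box-Cox exponent (0 == log)
    n_points: int
    loglik: float
    rss_bc: float         # RSS on the Box-Cox scale at `lam`
    dropped_concentration: float | None = None
    converged: bool = True

    @property
    def gated_in(self) -> bool:
        """Significance gate: both parameters significant at alpha 0.05."""
        return (self.converged and self.vmax > 0 and self.km > 0
                and self.p_vmax <= 0.05 and self.p_km <= 0.05)


@dataclass(frozen=True)
class KineticTraits:
    """Derived traits on dry-soil and microbial-biomass bases."""
    vmax_ds: float        # nmol g-1 h-1
    km: float             # uM
    ce_ds: float          # nmol g-1 h-1 uM-1
    mbc: float            # ug C g-1
    vmax_mbc: float = np.nan   # nmol (ug MBC)-1 h-1
    ce_mbc: float = np.nan


def boxcox(y: np.ndarray, lam: float) -> np.ndarray:
    """(y**lam - 1)/lam, with the log limit at lam == 0; requires y > 0."""
    y = np.asarray(y, dtype=float)
    if abs(lam) < 1e-12:
        return np.log(y)
    return (np.power(y, lam) - 1.0) / lam


def michaelis_menten(s, vmax, km):
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


def _fit_at_lambda(s, v, lam, p0):
    """Least squares on the Box-Cox scale at fixed lambda.

    Returns (params, cov, rss) or None on failure.
    """
    tv = boxcox(v, lam)

    def model(x, vmax, km):
        mu = michaelis_menten(x, vmax, km)
        mu = np.maximum(mu, 1e-12)
        return boxcox(mu, lam)

    def jac(x, vmax, km):
        # d boxcox(mu)/d theta = mu**(lam-1) * d mu/d theta
        frac = x / (km + x)
        mu = np.maximum(vmax * frac, 1e-12)
        w = np.power(mu, lam - 1.0)
        return np.column_stack([w * frac, -w * vmax * frac / (km + x)])

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = optimize.curve_fit(
                model, s, tv, p0=p0, jac=jac, maxfev=2000,
                bounds=([1e-12, 1e-12], [np.inf, np.inf]))
    except (RuntimeError, ValueError):
        return None
    resid = tv - model(s, *popt)
    return popt, pcov, float(resid @ resid)


def _profile_loglik(rss, lam, logv_sum, n):
    """Profile Gaussian log-likelihood of the TBS model (constants dropped),
    including the Box-Cox Jacobian so lambdas are comparable."""
    if rss <= 0:
        rss = 1e-300
    return -0.5 * n * np.log(rss / n) + (lam - 1.0) * logv_sum


def _starting_values(s, v):
    """Data-driven starts: Vmax0 = max mean rate, Km0 = concentration whose
    mean rate is nearest Vmax0 / 2."""
    df = pd.DataFrame({"s": s, "v": v}).groupby("s")["v"].mean()
    vmax0 = float(df.max())
    if vmax0 <= 0:
        vmax0 = max(float(np.max(v)), 1e-6)
    km0 = float(df.index[np.argmin(np.abs(df.to_numpy() - vmax0 / 2.0))])
    return max(vmax0, 1e-6), max(km0, 1e-6)


def fit_mm(substrate_um, rate, lam: float | None = None,
           lambda_grid: np.ndarray = LAMBDA_GRID,
           refine: bool = True) -> MMFit:
    """Fit the 2-parameter MM model over all analytical replicates.

    Parameters
    ----------
    substrate_um, rate
        Paired arrays over every replicate well of one fit unit.
    lam
        Fix the Box-Cox exponent instead of profiling (lam=1 reproduces
        plain nonlinear least squares).
    """
    s = np.asarray(substrate_um, dtype=float)
    v = np.asarray(rate, dtype=float)
    pos = v > 0
    if (~pos).any():
        log.debug("fit_mm: dropping %d non-positive rates before Box-Cox",
                  int((~pos).sum()))
        s, v = s[pos], v[pos]
    n_conc = np.unique(s).size
    if n_conc < 4:
        raise ValueError(
            f"insufficient design: {n_conc} distinct concentrations (< 4)")
    n = v.size
    p0 = _starting_values(s, v)
    logv_sum = float(np.sum(np.log(v)))

    grid = np.atleast_1d(lam if lam is not None else lambda_grid)
    best = None
    warm = p0
    for lm in grid:
        res = _fit_at_lambda(s, v, lm, warm)
        if res is None:
            res = _fit_at_lambda(s, v, lm, p0)
            if res is None:
                continue
        popt, pcov, rss = res
        warm = tuple(popt)
        ll = _profile_loglik(rss, lm, logv_sum, n)
        if best is None or ll > best[0]:
            best = (ll, lm, popt, pcov, rss)
    if best is None:
        return MMFit(np.nan, np.nan, np.nan, np.nan, 1.0, 1.0, np.nan,
                     n, -np.inf, np.inf, converged=False)

    if lam is None and refine and len(grid) > 1:
        step = float(grid[1] - grid[0])
        fine = np.round(np.arange(best[1] - step, best[1] + step + 1e-9,
                                  step / 10.0), 10)
        for lm in fine:
            res = _fit_at_lambda(s, v, lm, tuple(best[2]))
            if res is None:
                continue
            popt, pcov, rss = res
            ll = _profile_loglik(rss, lm, logv_sum, n)
            if ll > best[0]:
                best = (ll, lm, popt, pcov, rss)

    ll, lm, (vmax, km), pcov, rss = best
    dof = max(n - 2, 1)
    se = np.sqrt(np.diag(pcov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.array([vmax, km]) / se
    pvals = 2.0 * sps.t.sf(np.abs(tstat), dof)
    return MMFit(vmax=float(vmax), km=float(km),
                 se_vmax=float(se[0]), se_km=float(se[1]),
                 p_vmax=float(pvals[0]), p_km=float(pvals[1]),
                 lam=float(lm), n_points=n, loglik=float(ll),
                 rss_bc=float(rss))


def _rss_at(s, v, vmax, km, lam):
    """RSS on the Box-Cox scale for given parameters (no fitting)."""
    mu = np.maximum(michaelis_menten(s, vmax, km), 1e-12)
    r = boxcox(v, lam) - boxcox(mu, lam)
    return float(r @ r)


def drop_bad_concentration(substrate_um, rate, fit: MMFit,
                           ic_threshold: float = 2.0
                           ) -> tuple[np.ndarray, np.ndarray, MMFit]:
    """Drop at most one substrate concentration that consistently misfits.

    A concentration qualifies only when every one of its replicates has a
    residual of the same sign (e.g. uniform suppression from inhibition at
    high substrate) and removing it improves the information criterion by
    more than ``ic_threshold``. The improvement is scored on the reduced
    data at the refit's lambda — refit RSS against the RSS of the original
    parameters — so the two models are compared on identical responses
    (likelihoods across different Box-Cox datasets are not comparable).
    Returns (s, v, fit), unchanged when nothing qualifies.
    """
    s = np.asarray(substrate_um, dtype=float)
    v = np.asarray(rate, dtype=float)
    if not fit.converged:
        return s, v, fit
    resid = v - michaelis_menten(s, fit.vmax, fit.km)
    candidates = []
    for conc in np.unique(s):
        mask = s == conc
        r = resid[mask]
        if r.size == 0 or not (np.all(r > 0) or np.all(r < 0)):
            continue
        if np.unique(s[~mask]).size < 4:
            continue
        s_red, v_red = s[~mask], v[~mask]
        pos = v_red > 0
        s_red, v_red = s_red[pos], v_red[pos]
        # score the candidate at the base fit's lambda (cheap); the full
        # lambda profile is rerun only for the accepted drop
        quick = _fit_at_lambda(s_red, v_red, fit.lam,
                               (max(fit.vmax, 1e-6), max(fit.km, 1e-6)))
        if quick is None:
            continue
        rss_refit = quick[2]
        rss_base = _rss_at(s_red, v_red, fit.vmax, fit.km, fit.lam)
        if rss_base <= 1e-20 or rss_refit <= 1e-20:
            continue  # both essentially perfect; nothing to improve
        # equal k, identical data: AIC gain reduces to n*ln(RSS ratio)
        gain = v_red.size * np.log(rss_base / rss_refit)
        if gain > ic_threshold:
            candidates.append((gain, conc))
    if not candidates:
        return s, v, fit
    gain, conc = max(candidates, key=lambda c: c[0])
    keep = s != conc
    try:
        refit = fit_mm(s[keep], v[keep])
    except ValueError:
        return s, v, fit
    if not refit.converged:
        return s, v, fit
    return s[keep], v[keep], replace(refit, dropped_concentration=float(conc))


def select_incubation_time(vmax_by_unit_time: pd.DataFrame,
                           tolerance: float = 0.05,
                           unit_cols: list[str] | None = None) -> float:
    """Pick one incubation time for a temperature batch.

    ``vmax_by_unit_time`` has columns ``timepoint_h`` and ``vmax`` (one row
    per fit unit x timepoint for the batch). Each fit unit's Vmax is first
    normalized by that unit's across-timepoint maximum (units span orders
    of magnitude down the profile, so raw medians would be dominated by
    mid-ranked units); the chosen time is then the minimum timepoint whose
    median relative Vmax is within ``tolerance`` of the batch-best median —
    the shortest incubation that already reaches the highest Vmax.
    """
    df = vmax_by_unit_time.dropna(subset=["vmax"]).copy()
    if df.empty:
        raise ValueError("no converged fits at any timepoint")
    if unit_cols:
        unit_max = df.groupby(unit_cols)["vmax"].transform("max")
    else:
        unit_max = df["vmax"].max()
    df["_rel"] = df["vmax"] / unit_max
    med = df.groupby("timepoint_h")["_rel"].median()
    best = med.max()
    ok = med[med >= best * (1.0 - tolerance)]
    return float(ok.index.min())


def mbc_from_fumigation(c_fum: float, c_nonfum: float) -> tuple[float, bool]:
    """Microbial biomass C by chloroform-fumigation extraction.

    MBC = fumigated extractable C - non-fumigated extractable C, with no
    extraction-efficiency correction (no k_EC). Returns (mbc, warning_flag);
    the flag marks a negative difference, possible in noisy deep samples.
    """
    mbc = float(c_fum) - float(c_nonfum)
    flagged = mbc < 0
    if flagged:
        log.warning("negative fumigation difference: %.3g", mbc)
    return mbc, flagged


def derive_traits(fit: MMFit, ctx: SoilContext) -> KineticTraits:
    """Kinetic traits from a gated-in fit and its soil context.

    ce_ds = vmax/km; biomass-basis traits divide by MBC (ug C per g dry
    soil). When MBC is non-positive the dry-soil traits are still returned
    and the biomass-basis ones are NaN.
    """
    ce_ds = fit.vmax / fit.km
    traits = KineticTraits(vmax_ds=fit.vmax, km=fit.km, ce_ds=ce_ds,
                           mbc=ctx.mbc)
    if not np.isfinite(ctx.mbc) or ctx.mbc <= 0:
        log.warning("non-positive MBC (%s); biomass-basis traits undefined",
                    ctx.mbc)
        return traits
    vmax_mbc = fit.vmax / ctx.mbc
    return replace(traits, vmax_mbc=vmax_mbc, ce_mbc=vmax_mbc / fit.km)
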