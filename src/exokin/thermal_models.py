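"""Temperature-sensitivity models for enzyme Vmax, Km and CE.

Three complementary descriptions:

* ``q10_fit`` — OLS of ln(parameter) on temperature in deg C;
  Q10 = exp(10 * slope).
* ``arrhenius_fit`` — OLS of ln(Vmax) on 1/T (kelvin); Ea = -slope * R.
* ``mmrt_fit`` — Macromolecular Rate Theory. The activation heat capacity
  dCp (usually < 0) curves the Arrhenius line into a unimodal rate-
  temperature response:

      ln k(T) = ln(kB*T/h) - [dH + dCp*(T - T0)] / (R*T)
                           + [dS + dCp*ln(T/T0)] / R

  with dH, dS the activation enthalpy/entropy at the reference temperature
  T0 (315 K here). Moving ln(kB*T/h) to the left-hand side makes the model
  linear in (dH, dS, dCp), so the least-squares fit is solved exactly by
  linear algebra — no iteration, no convergence failures. The temperature
  optimum Topt (argmax of k) has the closed form (dCp*T0 - dH)/(dCp + R);
  the point of maximum temperature sensitivity TSmax (inflection of k(T),
  where dk/dT peaks) is located numerically by bisection below Topt.

Fits whose Topt or TSmax falls outside 0..200 deg C do not describe a
credible unimodal response over the assay range and are flagged invalid.

Model comparison uses Gaussian log-likelihoods from the RSS with additive
constants dropped (differences are unaffected); parameter counts include
the residual variance, so Arrhenius has k=3 and MMRT k=4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy import stats as sps

log = logging.getLogger(__name__)

R_GAS = 8.314          # J mol-1 K-1
KB = 1.380649e-23      # J K-1
PLANCK = 6.62607015e-34  # J s
T0_DEFAULT = 315.0     # K, reference temperature for dH and dS
CELSIUS = 273.15

VALID_BAND_C = (0.0, 200.0)


@dataclass(frozen=True)
class Q10Fit:
    slope: float          # per deg C
    q10: float
    r_squared: float
    range_label: str = ""
    parameter_kind: str = "vmax"


@dataclass(frozen=True)
class ArrheniusFit:
    slope: float          # K (slope of ln v vs 1/T)
    ea: float             # J mol-1
    r_squared: float
    rss: float
    n: int


@dataclass(frozen=True)
class MMRTFit:
    dcp: float            # J mol-1 K-1
    dh: float             # J mol-1 (at T0)
    ds: float             # J mol-1 K-1 (at T0)
    t0: float             # K
    topt: float           # K
    tsmax: float          # K
    valid: bool
    rss: float
    n: int
    converged: bool = True


def _positive(values, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if (arr <= 0).any():
        bad = np.flatnonzero(arr <= 0)
        raise ValueError(f"{what} must be > 0; offending index {bad[0]} "
                         f"(value {arr[bad[0]]})")
    return arr


def q10_fit(temperature_c, value, range_label: str = "",
            parameter_kind: str = "vmax") -> Q10Fit:
    """Q10 from OLS of ln(value) on temperature in deg C."""
    t = np.asarray(temperature_c, dtype=float)
    v = _positive(value, "q10_fit values")
    if t.size < 3:
        raise ValueError(f"need >= 3 points, got {t.size}")
    res = sps.linregress(t, np.log(v))
    return Q10Fit(slope=float(res.slope), q10=float(np.exp(10.0 * res.slope)),
                  r_squared=float(res.rvalue) ** 2, range_label=range_label,
                  parameter_kind=parameter_kind)


def arrhenius_fit(temperature_c, vmax) -> ArrheniusFit:
    """Activation energy from OLS of ln(Vmax) on 1/T (kelvin); Ea = -slope*R."""
    t = np.asarray(temperature_c, dtype=float) + CELSIUS
    v = _positive(vmax, "arrhenius_fit vmax")
    if t.size < 3:
        raise ValueError(f"need >= 3 points, got {t.size}")
    x = 1.0 / t
    y = np.log(v)
    res = sps.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    return ArrheniusFit(slope=float(res.slope),
                        ea=float(-res.slope * R_GAS),
                        r_squared=float(res.rvalue) ** 2,
                        rss=float(resid @ resid), n=t.size)


def mmrt_ln_rate(t_kelvin, dcp, dh, ds, t0: float = T0_DEFAULT) -> np.ndarray:
    """ln k(T) under MMRT with the kB*T/h pre-factor."""
    t = np.asarray(t_kelvin, dtype=float)
    return (np.log(KB * t / PLANCK)
            - (dh + dcp * (t - t0)) / (R_GAS * t)
            + (ds + dcp * np.log(t / t0)) / R_GAS)


def _dlnk_dt(t, dcp, dh, t0):
    """g(T) = d ln k / dT (dS drops out)."""
    return 1.0 / t + (dh - dcp * t0) / (R_GAS * t * t) + dcp / (R_GAS * t)


def _d2lnk_dt2(t, dcp, dh, t0):
    return (-1.0 / t**2 - 2.0 * (dh - dcp * t0) / (R_GAS * t**3)
            - dcp / (R_GAS * t**2))


def mmrt_topt(dcp: float, dh: float, t0: float = T0_DEFAULT) -> float:
    """Closed-form temperature optimum: stationary point of ln k.

    Topt = (dCp*T0 - dH)/(dCp + R). When dCp >= -R the rate has no finite
    maximum and the returned value falls outside the validity band.
    """
    denom = dcp + R_GAS
    if denom == 0:
        return np.inf
    return (dcp * t0 - dh) / denom


def mmrt_tsmax(dcp: float, dh: float, t0: float = T0_DEFAULT,
               xtol: float = 0.01) -> float:
    """Inflection of the rate curve k(T): maximum of dk/dT.

    Solves g(T)^2 + g'(T) = 0 (with g = d ln k/dT) by bisection below Topt,
    to ``xtol`` kelvin. Defined on the rate curve, not the ln-rate curve.
    Returns NaN when no sign change exists in the search window.
    """
    topt = mmrt_topt(dcp, dh, t0)

    def f(t):
        return (_dlnk_dt(t, dcp, dh, t0) ** 2
                + _d2lnk_dt2(t, dcp, dh, t0))

    hi = min(topt, 520.0) - 1e-6
    lo = 150.0
    if not np.isfinite(hi) or hi <= lo:
        return np.nan
    # bracket by scanning for a sign change
    grid = np.linspace(lo, hi, 200)
    fv = f(grid)
    sign_change = np.flatnonzero(np.diff(np.sign(fv)) != 0)
    if sign_change.size == 0:
        return np.nan
    i = sign_change[-1]  # closest bracket below topt
    return float(optimize.brentq(f, grid[i], grid[i + 1], xtol=xtol))


def mmrt_fit(temperature_c, ln_vmax, t0: float = T0_DEFAULT) -> MMRTFit:
    """Fit MMRT to ln(Vmax) over the assay temperatures.

    The model is linear in (dH, dS, dCp) after subtracting ln(kB*T/h), so
    the exact least-squares solution is obtained by ``lstsq``.
    """
    t = np.asarray(temperature_c, dtype=float) + CELSIUS
    y = np.asarray(ln_vmax, dtype=float)
    if t.size < 4:
        raise ValueError(f"need >= 4 points for 3 parameters, got {t.size}")
    rhs = y - np.log(KB * t / PLANCK)
    X = np.column_stack([
        -1.0 / (R_GAS * t),                                   # dH
        np.full(t.size, 1.0 / R_GAS),                          # dS
        -(t - t0) / (R_GAS * t) + np.log(t / t0) / R_GAS,      # dCp
    ])
    coef, _, rank, _ = np.linalg.lstsq(X, rhs, rcond=None)
    if rank < 3:
        return MMRTFit(np.nan, np.nan, np.nan, t0, np.nan, np.nan,
                       valid=False, rss=np.inf, n=t.size, converged=False)
    dh, ds, dcp = (float(c) for c in coef)
    resid = rhs - X @ coef
    rss = float(resid @ resid)
    topt = mmrt_topt(dcp, dh, t0)
    tsmax = mmrt_tsmax(dcp, dh, t0)
    lo, hi = VALID_BAND_C
    valid = (np.isfinite(topt) and np.isfinite(tsmax)
             and lo <= topt - CELSIUS <= hi
             and lo <= tsmax - CELSIUS <= hi)
    return MMRTFit(dcp=dcp, dh=dh, ds=ds, t0=t0, topt=float(topt),
                   tsmax=float(tsmax), valid=bool(valid), rss=rss, n=t.size)


# --- information-criterion comparison -----------------------------------

@dataclass(frozen=True)
class ModelComparison:
    """AIC/AICc/BIC for candidate thermal models fit to one ln(Vmax) series.

    ``table`` maps model name -> dict with loglik, k, aic, aicc, bic,
    rel_likelihood (exp(-dAICc/2) vs the AICc-best model).
    """
    table: dict
    best: str


def _gauss_loglik(rss: float, n: int) -> float:
    # constants dropped; differences between models are unchanged
    if rss <= 0:
        rss = 1e-300
    return -0.5 * n * np.log(rss / n)


def information_criteria(rss: float, n: int, k: int) -> dict:
    ll = _gauss_loglik(rss, n)
    aic = 2 * k - 2 * ll
    bic = k * np.log(n) - 2 * ll
    if n - k - 1 <= 0:
        log.warning("AICc undefined for n=%d, k=%d", n, k)
        aicc = np.nan
    else:
        aicc = aic + 2 * k * (k + 1) / (n - k - 1)
        if n - k - 1 == 1:
            log.info("AICc denominator is 1 (n=%d, k=%d): legal but "
                     "heavily penalized", n, k)
    return {"loglik": ll, "k": k, "aic": aic, "aicc": aicc, "bic": bic}


def compare_models(arr: ArrheniusFit, mmrt: MMRTFit,
                   n: int | None = None) -> ModelComparison:
    """Compare Arrhenius vs MMRT fits of the same ln(Vmax) series.

    k counts mean-model parameters plus the residual variance:
    Arrhenius 2+1=3, MMRT 3+1=4. Relative likelihood uses AICc when defined
    for both models, else AIC.
    """
    if n is None:
        n = arr.n
    if n != arr.n or n != mmrt.n:
        raise ValueError("models must be fit to the same response vector")
    table = {
        "arrhenius": information_criteria(arr.rss, n, k=3),
        "mmrt": information_criteria(mmrt.rss, n, k=4),
    }
    crit = "aicc"
    if any(np.isnan(m["aicc"]) for m in table.values()):
        crit = "aic"
    best = min(table, key=lambda name: table[name][crit])
    ref = table[best][crit]
    for m in table.values():
        m["rel_likelihood"] = float(np.exp(-(m[crit] - ref) / 2.0))
    return ModelComparison(table=table, best=best)
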