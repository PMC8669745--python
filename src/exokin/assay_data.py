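"""Data model and reduction of raw plate fluorescence to activity rates.

A fluorometric exoenzyme assay reads the fluorescence of MUF or AMC released
by enzymatic hydrolysis of a synthetic substrate. Raw well fluorescence is
converted to a quench-corrected net signal using batch-wise controls
(homogenate blanks, substrate blanks, and standard curves with and without
soil homogenate), then to a potential activity rate in nmol per g dry soil
per h via the emission coefficient of the unquenched standard curve and the
assay geometry (200 uL homogenate from a 1 g fresh soil / 100 mL buffer
slurry per well).

Reduction conventions: the emission coefficient is the unquenched standard
slope (fluorescence per nmol in well); the quench coefficient is the ratio
quenched/unquenched slope per depth x temperature batch; net sample signal
is divided by the quench coefficient; standard intercepts are retained for
diagnostics but only slopes enter the coefficients, since blanks already
capture baseline fluorescence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import design

ASSAY_COLUMNS = [
    "enzyme", "depth_cm", "core", "temperature_C", "substrate_uM",
    "replicate", "timepoint_h", "role", "fluorescence",
]
ROLES = ("sample", "standard", "quench_standard",
         "homogenate_blank", "substrate_blank")

SOIL_COLUMNS = [
    "depth_cm", "core", "dry_matter_fraction",
    "c_fumigated", "c_nonfumigated", "doc", "tdn",
]


class SchemaError(ValueError):
    """Input table does not match the documented schema."""


@dataclass(frozen=True)
class StandardCurve:
    """OLS line through (nmol in well, fluorescence) standard points."""
    slope: float
    intercept: float
    r_squared: float
    standard_type: str = "MUF"
    quenched: bool = False


@dataclass(frozen=True)
class BatchCoefficients:
    """Per depth x temperature batch reduction coefficients."""
    emission_coef: float          # fluorescence units per nmol in well
    quench_coef: float            # quenched slope / unquenched slope
    homogenate_blank: float       # fluorescence units
    substrate_blank: dict = field(default_factory=dict)  # per substrate_uM

    def substrate_blank_at(self, substrate_um: float) -> float:
        return self.substrate_blank.get(float(substrate_um), 0.0)


@dataclass(frozen=True)
class SoilContext:
    """Soil properties needed to express rates per g dry soil and per MBC."""
    depth_interval: str
    core: int
    dry_matter_fraction: float
    mbc: float = np.nan            # ug C per g dry soil
    doc: float = np.nan
    tdn: float = np.nan
    homogenate_soil_mass: float = design.HOMOGENATE_SOIL_MASS_G
    buffer_volume: float = design.BUFFER_VOLUME_ML
    well_homogenate_volume: float = design.WELL_HOMOGENATE_VOLUME_ML
    well_substrate_volume: float = design.WELL_SUBSTRATE_VOLUME_ML

    def __post_init__(self):
        if not 0.0 < self.dry_matter_fraction <= 1.0:
            raise ValueError(
                f"dry_matter_fraction must lie in (0, 1], got "
                f"{self.dry_matter_fraction}")


def read_assay_table(path) -> pd.DataFrame:
    """Read the long-format well table, validating coordinates.

    One row per well. Sample wells carry ``substrate_uM`` from the enzyme's
    series; standards carry ``standard_nmol``. Returns the typed DataFrame
    (all roles); split on ``role`` downstream.
    """
    df = pd.read_csv(path)
    missing = [c for c in ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    if df.empty:
        return df

    bad_role = ~df["role"].isin(ROLES)
    if bad_role.any():
        raise SchemaError(
            f"unknown role at row(s) {df.index[bad_role].tolist()[:5]}")
    bad_enz = ~df["enzyme"].isin(design.ENZYMES)
    if bad_enz.any():
        raise SchemaError(
            f"unknown enzyme at row(s) {df.index[bad_enz].tolist()[:5]}")
    bad_depth = ~df["depth_cm"].isin(design.DEPTH_INTERVALS)
    if bad_depth.any():
        raise SchemaError(
            f"unknown depth interval at row(s) "
            f"{df.index[bad_depth].tolist()[:5]}")
    bad_t = ~df["temperature_C"].astype(float).isin(design.TEMPERATURES)
    if bad_t.any():
        raise SchemaError(
            f"temperature outside assay set at row(s) "
            f"{df.index[bad_t].tolist()[:5]}")

    samples = df["role"] == "sample"
    for enz, sub in df[samples].groupby("enzyme"):
        series = design.SUBSTRATE_SERIES[enz]
        bad = ~sub["substrate_uM"].astype(float).isin(series)
        if bad.any():
            raise SchemaError(
                f"substrate_uM outside the {enz} series at row(s) "
                f"{sub.index[bad].tolist()[:5]}")
    if (df.loc[samples, "replicate"].astype(int) >
            max(design.REPLICATES)).any():
        raise SchemaError("replicate index exceeds design maximum of 4")

    if not np.isfinite(df["fluorescence"].astype(float)).all():
        bad = ~np.isfinite(df["fluorescence"].astype(float))
        raise SchemaError(
            f"non-numeric fluorescence at row(s) {df.index[bad].tolist()[:5]}")
    return df


def read_soil_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SOIL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    return df


def soil_context_from_row(row: pd.Series, mbc: float | None = None) -> SoilContext:
    from .mm_kinetics import mbc_from_fumigation
    if mbc is None:
        mbc, _ = mbc_from_fumigation(row["c_fumigated"], row["c_nonfumigated"])
    return SoilContext(
        depth_interval=row["depth_cm"], core=int(row["core"]),
        dry_matter_fraction=float(row["dry_matter_fraction"]),
        mbc=float(mbc), doc=float(row["doc"]), tdn=float(row["tdn"]))


def fit_standard_curve(amount_nmol, fluorescence, standard_type: str = "MUF",
                       quenched: bool = False) -> StandardCurve:
    """Ordinary least-squares standard curve: fluorescence vs nmol in well."""
    x = np.asarray(amount_nmol, dtype=float)
    y = np.asarray(fluorescence, dtype=float)
    if x.size < 3:
        raise ValueError(f"need >= 3 standard points, got {x.size}")
    if np.unique(x).size < 2:
        raise ValueError("degenerate standard design: all amounts identical")
    res = sps.linregress(x, y)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue) ** 2,
                         standard_type=standard_type, quenched=quenched)


def quench_coefficient(unquenched: StandardCurve,
                       quenched: StandardCurve) -> float:
    """Ratio of quenched to unquenched standard-curve slopes.

    Corrects for fluorescence absorbed or scattered by the soil homogenate;
    typically <= 1 and smaller in organic-rich surface soils.
    """
    if unquenched.slope <= 0:
        raise ValueError(
            f"unquenched standard slope must be > 0, got {unquenched.slope}")
    return quenched.slope / unquenched.slope


def net_fluorescence(raw, homogenate_blank, substrate_blank, quench):
    """Quench-corrected net assay fluorescence.

    net = (raw - homogenate_blank) / quench - substrate_blank
    """
    quench = float(quench)
    if quench <= 0:
        raise ValueError(f"quench coefficient must be > 0, got {quench}")
    return (np.asarray(raw, dtype=float) - homogenate_blank) / quench \
        - substrate_blank


def activity_rate(net, coef: BatchCoefficients, ctx: SoilContext,
                  incubation_h: float):
    """Convert net fluorescence to nmol per g dry soil per h.

    nmol released in the well is net / emission_coef; the well received
    well_homogenate_volume / buffer_volume of a slurry containing
    homogenate_soil_mass g fresh soil, i.e. homogenate_soil_mass x
    dry_matter_fraction g dry soil. Negative net passes through (QC removes
    it downstream).
    """
    if incubation_h <= 0:
        raise ValueError(f"incubation must be > 0 h, got {incubation_h}")
    if coef.emission_coef <= 0:
        raise ValueError(
            f"emission coefficient must be > 0, got {coef.emission_coef}")
    dry_g_in_well = (ctx.homogenate_soil_mass * ctx.dry_matter_fraction
                     * ctx.well_homogenate_volume / ctx.buffer_volume)
    nmol = np.asarray(net, dtype=float) / coef.emission_coef
    return nmol / (dry_g_in_well * incubation_h)


def batch_coefficients(table: pd.DataFrame, enzyme: str, depth: str,
                       temperature: float) -> BatchCoefficients:
    """Derive reduction coefficients from the control rows of one batch.

    A batch is the set of standards/blanks incubated together with the
    assays of one enzyme at one temperature; quench standards contain the
    homogenate of one depth interval, so quench is per depth x temperature.
    """
    mask = ((table["enzyme"] == enzyme)
            & (table["temperature_C"].astype(float) == float(temperature)))
    batch = table[mask]
    std = batch[(batch["role"] == "standard")]
    qstd = batch[(batch["role"] == "quench_standard")
                 & (batch["depth_cm"] == depth)]
    if std.empty or qstd.empty:
        raise SchemaError(
            f"batch {enzyme}@{temperature}C depth {depth}: missing standard "
            "or quench-standard rows")
    FLUOR = "fluorescence"
    unq = fit_standard_curve(std["standard_nmol"], std[FLUOR],
                             design.FLUOROPHORE[enzyme], quenched=False)
    q = fit_standard_curve(qstd["standard_nmol"], qstd[FLUOR],
                           design.FLUOROPHORE[enzyme], quenched=True)
    hb = batch[(batch["role"] == "homogenate_blank")
               & (batch["depth_cm"] == depth)][FLUOR].mean()
    sb_rows = batch[batch["role"] == "substrate_blank"]
    sb = {float(c): float(g[FLUOR].mean())
          for c, g in sb_rows.groupby(sb_rows["substrate_uM"].astype(float))}
    return BatchCoefficients(
        emission_coef=unq.slope,
        quench_coef=quench_coefficient(unq, q),
        homogenate_blank=0.0 if np.isnan(hb) else float(hb),
        substrate_blank=sb)


def reduce_wells(table: pd.DataFrame, soil: pd.DataFrame) -> pd.DataFrame:
    """Reduce every sample well to a rate (nmol g-1 dry soil h-1).

    Returns the sample rows with a ``rate_nmol_g_h`` column; batch
    coefficients are computed once per enzyme x depth x temperature and
    soil context joined per depth x core.
    """
    ctx_by = {(r["depth_cm"], int(r["core"])): soil_context_from_row(r)
              for _, r in soil.iterrows()}
    samples = table[table["role"] == "sample"].copy()
    out = []
    for (enz, depth, temp), grp in samples.groupby(
            ["enzyme", "depth_cm", "temperature_C"], sort=False):
        coef = batch_coefficients(table, enz, depth, float(temp))
        for (core, tp), sub in grp.groupby(["core", "timepoint_h"],
                                           sort=False):
            ctx = ctx_by[(depth, int(core))]
            sb = sub["substrate_uM"].astype(float).map(
                coef.substrate_blank_at).to_numpy()
            net = net_fluorescence(sub["fluorescence"].to_numpy(),
                                   coef.homogenate_blank, sb,
                                   coef.quench_coef)
            rate = activity_rate(net, coef, ctx, float(tp))
            res = sub.copy()
            res["rate_nmol_g_h"] = rate
            out.append(res)
    reduced = pd.concat(out, ignore_index=True)
    return reduced.drop(columns=["role"])
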