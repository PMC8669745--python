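"""Synthetic fluorometric campaign generator.

Stands in for the field campaign: a ground-truth parameter set
(``TruthProfile``) drives simulation of every well the plate reader would
produce — sample wells, standard and quench-standard dilution series,
homogenate and substrate blanks — so the entire reduction/QC/fitting
pipeline can be exercised and checked against known truth.

What it emulates: the full factorial design (3 enzymes x 6 depths x
6 temperatures x 8 substrate concentrations x 4 analytical replicates x
3 cores x 3 timepoints); near-continuous exponential decline of Vmax with
depth (e-folding 22.6 cm, ~96% gone by 60-90 cm); Km decline to a deep
plateau at ~15% of the surface value; unimodal MMRT temperature response
of Vmax; depth-dependent quenching (strongest in organic-rich surface
soil); heteroscedastic (multiplicative lognormal) fluorescence noise;
rare negative readings and single-replicate outliers; fluorescence
accumulation that is sub-linear at 1 h in cold assays and saturates after
4 h at warm temperatures, so incubation-time selection has real work.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import design
from .thermal_models import (mmrt_ln_rate, mmrt_topt, R_GAS, T0_DEFAULT,
                             CELSIUS)


@dataclass(frozen=True)
class CampaignConfig:
    enzymes: tuple = design.ENZYMES
    depths: tuple = design.DEPTH_INTERVALS
    temperatures: tuple = design.TEMPERATURES
    cores: tuple = design.CORES
    replicates: tuple = design.REPLICATES
    timepoints: tuple = design.TIMEPOINTS
    substrate_series: dict = field(
        default_factory=lambda: dict(design.SUBSTRATE_SERIES))
    #: multiplicative fluorescence noise, coefficient of variation
    cv: float = 0.10
    #: probability a sample well reads below its blanks (negative rate)
    negative_rate: float = 0.008
    #: probability a replicate is a gross outlier, and its multiplier
    outlier_rate: float = 0.03
    outlier_factor: float = 3.0
    #: sd of extract measurements (fraction of value) for MBC/DOC/TDN
    extract_cv: float = 0.0
    #: relative noise on standard/blank control wells
    standard_cv: float = 0.02
    seed: int = 0

    @property
    def n_fit_units(self) -> int:
        return (len(self.enzymes) * len(self.depths)
                * len(self.temperatures) * len(self.cores))

    @property
    def n_sample_wells(self) -> int:
        n_conc = {len(v) for v in self.substrate_series.values()}
        assert len(n_conc) == 1
        return (self.n_fit_units * n_conc.pop() * len(self.replicates)
                * len(self.timepoints))


#: per-enzyme surface kinetics and MMRT shape. dH is set from the target
#: Topt of 338 K via the closed form dH = dCp*T0 - Topt*(dCp + R); dCp of
#: -0.79 kJ/mol/K for the MUF enzymes and -1.32 for LAP.
ENZYME_TRUTH = {
    #            vmax0 (nmol/g/h at Tref), km0 (uM), dCp (J/mol/K)
    "BG":  {"vmax0": 250.0, "km0": 180.0, "dcp": -790.0},
    "LAP": {"vmax0": 120.0, "km0": 260.0, "dcp": -1320.0},
    "AP":  {"vmax0": 900.0, "km0": 300.0, "dcp": -790.0},
}

TOPT_TARGET_K = 338.05
TREF_C = 25.0          # temperature at which vmax0 is stated

VMAX_EFOLD_CM = 22.6   # Vmax(z) = vmax0 * exp(-z / 22.6)
KM_PLATEAU = 0.15      # deep Km as a fraction of the surface value
KM_EFOLD_CM = 9.0      # reaches ~the plateau by 30 cm

#: surface-to-depth quenching (organic matter quenches fluorescence)
QUENCH_BY_DEPTH = {
    "0-10": 0.60, "10-20": 0.66, "30-40": 0.74,
    "50-60": 0.80, "60-70": 0.84, "80-90": 0.90,
}

MBC_SURFACE = 650.0    # ug C / g dry soil
MBC_EFOLD_CM = 14.0    # steepest decline over the upper 30 cm
MBC_FLOOR = 25.0
DOC_SURFACE, DOC_EFOLD = 420.0, 30.0
TDN_SURFACE, TDN_EFOLD = 38.0, 35.0
DMF_SURFACE, DMF_DEEP = 0.55, 0.80  # dry matter fraction rises with depth

EMISSION_COEF = {"MUF": 480.0, "AMC": 520.0}  # fluorescence units per nmol
HOMOGENATE_BLANK = 60.0
SUBSTRATE_BLANK_PER_UM = 0.08  # fluorescence per uM substrate in well


@dataclass
class TruthProfile:
    """Ground truth driving one synthetic campaign."""
    vmax_ref: dict       # (enzyme, depth) -> nmol/g/h at TREF_C
    km: dict             # (enzyme, depth) -> uM
    mmrt: dict           # enzyme -> {dcp, dh, ds, t0}
    mbc: dict            # depth -> ug/g
    doc: dict
    tdn: dict
    dry_matter_fraction: dict
    quench_coef: dict    # depth -> ratio
    cv: float
    negative_rate: float
    outlier_rate: float

    def vmax_at(self, enzyme: str, depth: str, temperature_c: float) -> float:
        """True Vmax (nmol/g/h) at a temperature, MMRT-scaled from TREF_C."""
        p = self.mmrt[enzyme]
        t = temperature_c + CELSIUS
        tref = TREF_C + CELSIUS
        scale = np.exp(mmrt_ln_rate(t, p["dcp"], p["dh"], p["ds"], p["t0"])
                       - mmrt_ln_rate(tref, p["dcp"], p["dh"], p["ds"],
                                      p["t0"]))
        return self.vmax_ref[(enzyme, depth)] * float(scale)

    def rate(self, enzyme: str, depth: str, temperature_c: float,
             substrate_um: float) -> float:
        vmax = self.vmax_at(enzyme, depth, temperature_c)
        km = self.km[(enzyme, depth)]
        return vmax * substrate_um / (km + substrate_um)

    def to_json(self, path) -> None:
        def enc(d):
            return {"|".join(map(str, k)) if isinstance(k, tuple) else str(k):
                    v for k, v in d.items()}
        payload = {k: (enc(v) if isinstance(v, dict) else v)
                   for k, v in asdict(self).items()}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "TruthProfile":
        raw = json.loads(Path(path).read_text())
        def dec(d, tuple_key):
            out = {}
            for k, v in d.items():
                if tuple_key:
                    enz, depth = k.split("|")
                    out[(enz, depth)] = v
                else:
                    out[k] = v
            return out
        return cls(
            vmax_ref=dec(raw["vmax_ref"], True), km=dec(raw["km"], True),
            mmrt=raw["mmrt"], mbc=raw["mbc"], doc=raw["doc"],
            tdn=raw["tdn"],
            dry_matter_fraction=raw["dry_matter_fraction"],
            quench_coef=raw["quench_coef"], cv=raw["cv"],
            negative_rate=raw["negative_rate"],
            outlier_rate=raw["outlier_rate"])


def make_truth(config: CampaignConfig | None = None,
               seed: int | None = None) -> TruthProfile:
    """Deterministic truth profile for a campaign configuration.

    The default truth has no random component — the study conditions are
    fixed — but a seed perturbs core-independent baselines reproducibly in
    the well simulator, so the same seed always yields the same campaign.
    """
    config = config or CampaignConfig()
    vmax_ref, km = {}, {}
    for enz in config.enzymes:
        p = ENZYME_TRUTH[enz]
        for depth in config.depths:
            z = design.DEPTH_MIDPOINTS[depth]
            vmax_ref[(enz, depth)] = p["vmax0"] * float(np.exp(-z / VMAX_EFOLD_CM))
            km[(enz, depth)] = p["km0"] * float(
                KM_PLATEAU + (1 - KM_PLATEAU) * np.exp(-z / KM_EFOLD_CM))
    mmrt = {}
    for enz in config.enzymes:
        dcp = ENZYME_TRUTH[enz]["dcp"]
        dh = dcp * T0_DEFAULT - TOPT_TARGET_K * (dcp + R_GAS)
        mmrt[enz] = {"dcp": dcp, "dh": dh, "ds": -110.0, "t0": T0_DEFAULT}
        assert abs(mmrt_topt(dcp, dh) - TOPT_TARGET_K) < 1e-6
    mbc, doc, tdn, dmf = {}, {}, {}, {}
    for depth in config.depths:
        z = design.DEPTH_MIDPOINTS[depth]
        mbc[depth] = MBC_FLOOR + (MBC_SURFACE - MBC_FLOOR) * float(
            np.exp(-z / MBC_EFOLD_CM))
        doc[depth] = DOC_SURFACE * float(np.exp(-z / DOC_EFOLD))
        tdn[depth] = TDN_SURFACE * float(np.exp(-z / TDN_EFOLD))
        dmf[depth] = DMF_DEEP - (DMF_DEEP - DMF_SURFACE) * float(
            np.exp(-z / 40.0))
    return TruthProfile(
        vmax_ref=vmax_ref, km=km, mmrt=mmrt, mbc=mbc, doc=doc, tdn=tdn,
        dry_matter_fraction=dmf, quench_coef=dict(QUENCH_BY_DEPTH),
        cv=config.cv, negative_rate=config.negative_rate,
        outlier_rate=config.outlier_rate)


def _time_factor(temperature_c: float, timepoint_h: float) -> float:
    """Apparent-rate multiplier encoding product accumulation kinetics.

    Cold assays (< 16 C) need long incubation (1 h under-reads, 24 h is
    full); 16 C saturates by 4 h; warm assays (>= 25 C) are complete at
    1 h and the signal stops accumulating after ~4 h, so the 24 h apparent
    rate collapses to 4/24 of the true rate.
    """
    if temperature_c < 16.0:
        return {1.0: 0.60, 4.0: 0.90}.get(timepoint_h, 1.0)
    if temperature_c < 25.0:
        return {1.0: 0.80}.get(timepoint_h, 1.0)
    if timepoint_h <= 4.0:
        return 1.0
    return 4.0 / timepoint_h


def simulate_plate(truth: TruthProfile, config: CampaignConfig, enzyme: str,
                   depth: str, core: int, temperature_c: float,
                   timepoint_h: float, rng: np.random.Generator,
                   include_controls: bool = True) -> pd.DataFrame:
    """Simulate the wells of one enzyme x depth x core x temperature x
    timepoint plate, with matching batch controls."""
    rows = []
    fluorophore = design.FLUOROPHORE[enzyme]
    emission = EMISSION_COEF[fluorophore]
    quench = truth.quench_coef[depth]
    dmf = truth.dry_matter_fraction[depth]
    dry_g_in_well = (design.HOMOGENATE_SOIL_MASS_G * dmf
                     * design.WELL_HOMOGENATE_VOLUME_ML
                     / design.BUFFER_VOLUME_ML)
    tf = _time_factor(temperature_c, timepoint_h)
    sigma = np.sqrt(np.log1p(config.cv ** 2))  # lognormal with unit mean
    for conc in config.substrate_series[enzyme]:
        v = truth.rate(enzyme, depth, temperature_c, conc) * tf
        nmol = v * dry_g_in_well * timepoint_h
        net_true = nmol * emission
        sblank = SUBSTRATE_BLANK_PER_UM * conc
        for rep in config.replicates:
            signal = net_true
            if config.cv > 0:
                signal = signal * rng.lognormal(-sigma ** 2 / 2.0, sigma)
            u = rng.random()
            if u < config.negative_rate:
                # analytical error: reading below the blanks
                signal = -abs(rng.normal(0.0, 0.05 * max(net_true, 1.0)))
            elif u < config.negative_rate + config.outlier_rate:
                signal = signal * config.outlier_factor
            raw = quench * (signal + sblank) + HOMOGENATE_BLANK
            rows.append((enzyme, depth, core, temperature_c, conc, rep,
                         timepoint_h, "sample", raw, np.nan))
    df = pd.DataFrame(rows, columns=[*_WELL_COLS])
    if include_controls:
        df = pd.concat(
            [df, simulate_controls(truth, enzyme, depth, temperature_c, rng,
                                   config)],
            ignore_index=True)
    return df


_WELL_COLS = ("enzyme", "depth_cm", "core", "temperature_C", "substrate_uM",
              "replicate", "timepoint_h", "role", "fluorescence",
              "standard_nmol")


def simulate_controls(truth: TruthProfile, enzyme: str, depth: str,
                      temperature_c: float, rng: np.random.Generator,
                      config: CampaignConfig) -> pd.DataFrame:
    """Standards, quench standards and blanks for one batch (duplicated
    wells, as in the assay protocol)."""
    fluorophore = design.FLUOROPHORE[enzyme]
    emission = EMISSION_COEF[fluorophore]
    quench = truth.quench_coef[depth]
    rows = []
    scv = config.standard_cv
    noise = (lambda: rng.normal(1.0, scv)) if scv > 0 else (lambda: 1.0)
    for conc in design.STANDARD_SERIES_UM[fluorophore]:
        nmol = design.standard_nmol_in_well(conc)
        for _ in range(2):
            rows.append((enzyme, depth, 0, temperature_c, np.nan, 0, 0.0,
                         "standard", emission * nmol * noise(), nmol))
            rows.append((enzyme, depth, 0, temperature_c, np.nan, 0, 0.0,
                         "quench_standard",
                         emission * quench * nmol * noise()
                         + HOMOGENATE_BLANK, nmol))
    for _ in range(2):
        rows.append((enzyme, depth, 0, temperature_c, np.nan, 0, 0.0,
                     "homogenate_blank", HOMOGENATE_BLANK * noise(), np.nan))
        for conc in config.substrate_series[enzyme]:
            rows.append((enzyme, depth, 0, temperature_c, conc, 0, 0.0,
                         "substrate_blank",
                         SUBSTRATE_BLANK_PER_UM * conc * noise(), np.nan))
    return pd.DataFrame(rows, columns=[*_WELL_COLS])


def simulate_campaign(config: CampaignConfig | None = None,
                      seed: int | None = None,
                      out_dir=None) -> dict:
    """Simulate the full campaign.

    Returns a dict with ``assay`` (well table), ``soil`` (context table),
    ``truth`` and ``manifest`` (declared counts); writes assay.csv,
    soil.csv, truth.json and manifest.json when ``out_dir`` is given.
    """
    config = config or CampaignConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    truth = make_truth(config, seed)
    frames = []
    for enz in config.enzymes:
        for depth in config.depths:
            for temp in config.temperatures:
                controls = simulate_controls(truth, enz, depth, temp, rng,
                                             config)
                frames.append(controls)
                for core in config.cores:
                    for tp in config.timepoints:
                        frames.append(simulate_plate(
                            truth, config, enz, depth, core, temp, tp, rng,
                            include_controls=False))
    assay = pd.concat(frames, ignore_index=True)
    soil_rows = []
    ecv = config.extract_cv
    for depth in config.depths:
        for core in config.cores:
            jitter = (lambda x: x * rng.normal(1.0, ecv)) if ecv > 0 \
                else (lambda x: x)
            c_nonfum = jitter(truth.doc[depth] * 0.55)
            c_fum = c_nonfum + jitter(truth.mbc[depth])
            soil_rows.append({
                "depth_cm": depth, "core": core,
                "dry_matter_fraction": truth.dry_matter_fraction[depth],
                "c_fumigated": c_fum, "c_nonfumigated": c_nonfum,
                "doc": jitter(truth.doc[depth]),
                "tdn": jitter(truth.tdn[depth]),
            })
    soil = pd.DataFrame(soil_rows)
    manifest = {
        "n_fit_units": config.n_fit_units,
        "n_sample_wells": config.n_sample_wells,
        "n_sample_wells_per_timepoint":
            config.n_sample_wells // len(config.timepoints),
        "n_rows_total": int(len(assay)),
        "seed": int(seed),
    }
    assert int((assay["role"] == "sample").sum()) == config.n_sample_wells
    result = {"assay": assay, "soil": soil, "truth": truth,
              "manifest": manifest}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        assay.to_csv(out / "assay.csv", index=False)
        soil.to_csv(out / "soil.csv", index=False)
        truth.to_json(out / "truth.json")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return result
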