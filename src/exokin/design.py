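"""Factorial design of the fluorometric exoenzyme assay campaign.

Three hydrolases (BG = beta-glucosidase, LAP = leucine aminopeptidase,
AP = acid phosphatase) assayed at six mineral-soil depth intervals from
triplicate cores, at six incubation temperatures, over eight enzyme-specific
substrate concentrations with four analytical replicates, read at three
nominal timepoints. These constants define the default campaign; every
module validates coordinates against them.
"""

from __future__ import annotations

ENZYMES = ("BG", "LAP", "AP")

#: depth intervals in cm, surface first
DEPTH_INTERVALS = ("0-10", "10-20", "30-40", "50-60", "60-70", "80-90")

#: midpoint depth (cm) of each interval, used by the truth profiles
DEPTH_MIDPOINTS = {
    "0-10": 5.0,
    "10-20": 15.0,
    "30-40": 35.0,
    "50-60": 55.0,
    "60-70": 65.0,
    "80-90": 85.0,
}

#: assay incubation temperatures, deg C
TEMPERATURES = (4.0, 10.0, 16.0, 25.0, 35.0, 50.0)

#: realistic in-situ field subset used for Q10 regressions
FIELD_TEMPERATURES = (4.0, 10.0, 16.0, 25.0, 35.0)

#: substrate concentration series (uM), eight levels per enzyme
SUBSTRATE_SERIES = {
    "BG": (10.0, 30.0, 60.0, 100.0, 150.0, 250.0, 450.0, 800.0),
    "LAP": (10.0, 20.0, 40.0, 70.0, 110.0, 190.0, 350.0, 600.0),
    "AP": (10.0, 40.0, 80.0, 130.0, 200.0, 350.0, 700.0, 1200.0),
}

#: fluorophore released by each enzyme's synthetic substrate
FLUOROPHORE = {"BG": "MUF", "LAP": "AMC", "AP": "MUF"}

#: standard-curve concentration series (uM in well), six two-fold dilutions
STANDARD_SERIES_UM = {
    "MUF": (0.625, 1.25, 2.5, 5.0, 10.0, 20.0),
    "AMC": (0.3125, 0.625, 1.25, 2.5, 5.0, 10.0),
}

CORES = (1, 2, 3)
REPLICATES = (1, 2, 3, 4)

#: nominal fluorescence read times, h
TIMEPOINTS = (1.0, 4.0, 24.0)

#: assay geometry
WELL_HOMOGENATE_VOLUME_ML = 0.200
WELL_SUBSTRATE_VOLUME_ML = 0.050
BUFFER_VOLUME_ML = 100.0
HOMOGENATE_SOIL_MASS_G = 1.0  # g fresh soil per BUFFER_VOLUME_ML

WELL_VOLUME_ML = WELL_HOMOGENATE_VOLUME_ML + WELL_SUBSTRATE_VOLUME_ML


def standard_nmol_in_well(conc_um: float) -> float:
    """nmol of free fluorophore in a standard well at a given concentration."""
    return conc_um * WELL_VOLUME_ML  # 1 uM == 1 nmol/mL


def n_fit_units(n_enzymes: int = 3, n_depths: int = 6, n_temperatures: int = 6,
                n_cores: int = 3) -> int:
    """Number of enzyme x depth x temperature x core Michaelis-Menten fit
    units in the factorial design (324 for the default campaign)."""
    return n_enzymes * n_depths * n_temperatures * n_cores
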