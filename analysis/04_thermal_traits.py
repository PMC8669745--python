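"""Temperature-sensitivity estimates per enzyme x depth x core.

From the kinetic trait table: Q10 of Vmax, Km and CE over the field range
(4-35 C), Arrhenius activation energy over the same range, MMRT (dCp,
Topt, TSmax) over the full range (4-50 C) with the 0-200 C validity rule,
and the Arrhenius-vs-MMRT information-criterion comparison. Writes
thermal.csv and prints the headline means.

Run:  python analysis/04_thermal_traits.py
"""

import argparse
from pathlib import Path

import pandas as pd

from exokin import pipeline, qc_filters

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--traits", type=Path,
                    default=ROOT / "results" / "traits.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    traits = pd.read_csv(args.traits)
    ledger = qc_filters.ExclusionLedger()
    thermal = pipeline.thermal_traits(traits, ledger)

    args.out.mkdir(parents=True, exist_ok=True)
    thermal.to_csv(args.out / "thermal.csv", index=False)

    valid = thermal[thermal.get("mmrt_valid", True) == True]  # noqa: E712
    n_invalid = ledger.counts.get("mmrt_invalid", 0)
    print(f"{len(thermal)} enzyme x depth x core thermal fits; "
          f"{n_invalid} MMRT fits outside the 0-200 C validity band")
    for enz, grp in thermal.groupby("enzyme"):
        q = grp["q10_vmax_ds"].dropna()
        ea = grp["ea_kj_mol"].dropna()
        print(f"  {enz}: Q10(Vmax, 4-35C) = {q.mean():.2f} +- "
              f"{q.sem():.2f}, Ea = {ea.mean():.1f} +- {ea.sem():.1f} kJ/mol")
    if len(valid):
        print(f"  MMRT (valid fits): Topt = {valid['topt_c'].mean():.1f} C, "
              f"TSmax = {valid['tsmax_c'].mean():.1f} C, "
              f"dCp = {valid['dcp_kj_mol_k'].mean():.2f} kJ/mol/K")
    if "best_model" in thermal:
        frac = (thermal["best_model"] == "mmrt").mean()
        print(f"  MMRT preferred by AICc in {100 * frac:.0f}% of fits")


if __name__ == "__main__":
    main()
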