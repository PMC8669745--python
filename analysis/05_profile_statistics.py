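"""Factorial statistics over the recovered trait tables.

Per enzyme and kinetic trait: two-way fixed-effects ANOVA (depth x
temperature), blocked ANOVA (depth with temperature as block), Tukey HSD
compact letter displays over depths, assumption diagnostics, maximum
percent decline with depth, and pairwise enzyme trait ratios. Writes
anova.csv, letters.csv, declines.csv and ratios.csv.

Run:  python analysis/05_profile_statistics.py
"""

import argparse
from pathlib import Path

import pandas as pd

from exokin import profile_stats as ps

ROOT = Path(__file__).resolve().parents[1]

TRAITS = ["vmax_ds", "vmax_mbc", "km", "ce_ds", "ce_mbc"]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--traits", type=Path,
                    default=ROOT / "results" / "traits.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    traits = pd.read_csv(args.traits)
    args.out.mkdir(parents=True, exist_ok=True)

    anova_rows, letter_rows, decline_rows = [], [], []
    for enz, sub in traits.groupby("enzyme"):
        for trait in TRAITS:
            tab = sub.dropna(subset=[trait])
            if tab.empty:
                continue
            ln = ps.needs_ln_transform(tab, trait, ["depth_cm"])
            res = ps.anova_two_way(tab, trait, ln_transform=ln)
            for term, row in res.table.iterrows():
                anova_rows.append({
                    "enzyme": enz, "trait": trait, "term": term,
                    "transform": res.response_transform,
                    "df": row["df"], "F": row.get("F"), "p": row.get("p")})
            cld = ps.tukey_cld(res, tab, trait, "depth_cm")
            for depth, letters in cld.letters.items():
                letter_rows.append({"enzyme": enz, "trait": trait,
                                    "depth_cm": depth, "letters": letters,
                                    "mean": cld.means[depth]})
            dec = ps.percent_decline(tab, trait)
            decline_rows.append({"enzyme": enz, "trait": trait,
                                 "mean_decline_pct": dec["mean"],
                                 "se": dec["se"],
                                 "n_temperatures": dec["n_temperatures"]})

    anova = pd.DataFrame(anova_rows)
    anova.to_csv(args.out / "anova.csv", index=False)
    pd.DataFrame(letter_rows).to_csv(args.out / "letters.csv", index=False)
    declines = pd.DataFrame(decline_rows)
    declines.to_csv(args.out / "declines.csv", index=False)
    ratios = ps.enzyme_ratios(traits)
    ratios.to_csv(args.out / "ratios.csv", index=False)

    sig = anova[(anova["term"].str.contains("depth")) & (anova["p"] < 0.05)]
    print(f"ANOVA: depth effect significant in {len(sig)} of "
          f"{len(anova[anova['term'].str.contains('depth')])} "
          "enzyme x trait tables")
    vd = declines[declines["trait"] == "vmax_ds"]
    print("Vmax/ds percent decline (surface -> 60-90 cm):")
    for _, r in vd.iterrows():
        print(f"  {r['enzyme']}: {r['mean_decline_pct']:.1f} +- "
              f"{r['se']:.1f}% over {r['n_temperatures']:.0f} temperatures")
    print(f"{len(ratios)} enzyme-pair ratio rows written")


if __name__ == "__main__":
    main()
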