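"""Reduce raw plate fluorescence to rates and apply the exclusion rules.

Reads results/campaign/{assay,soil}.csv, converts each sample well to a
quench-corrected rate per g dry soil, removes negative readings and
IQR replicate outliers, and writes rates.csv plus the exclusion ledger.

Run:  python analysis/02_reduce_and_qc.py
"""

import argparse
from pathlib import Path

from exokin import assay_data, pipeline, qc_filters

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--campaign", type=Path,
                    default=ROOT / "results" / "campaign")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    assay = assay_data.read_assay_table(args.campaign / "assay.csv")
    soil = assay_data.read_soil_table(args.campaign / "soil.csv")
    rates, ledger = pipeline.reduce_and_qc(assay, soil)

    args.out.mkdir(parents=True, exist_ok=True)
    rates.to_csv(args.out / "rates.csv", index=False)
    summary = qc_filters.exclusion_summary(ledger)
    summary.to_csv(args.out / "exclusions.csv", index=False)

    total = ledger.total_excluded
    pct = 100.0 * total / ledger.inspected if ledger.inspected else 0.0
    print(f"reduced {ledger.inspected} sample wells -> {len(rates)} kept")
    print(f"excluded {total} ({pct:.1f}%): "
          + ", ".join(f"{r}={c}" for r, c in ledger.counts.items()))


if __name__ == "__main__":
    main()
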