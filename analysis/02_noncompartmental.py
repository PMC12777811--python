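#!/usr/bin/env python
"""Non-compartmental analysis of every serum and lymph profile.

Reads results/dataset/, runs BLQ handling, trapezoidal AUC, terminal
slope selection and (for the IV animal) CL/MRT/Vss, and writes the tidy
per-profile table results/nca.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from lymphpk.io import read_study_dir
from lymphpk.pipeline import nca_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "dataset")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    dataset = read_study_dir(args.data)
    table = nca_table(dataset, lloq=1.0)
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "nca.csv", index=False)

    iv = table[table.route == "iv"].iloc[0]
    print(
        f"IV reference: AUC_inf={iv.auc_inf:.1f} ng*h/ml, CL={iv.cl:.1f} l/h, "
        f"Vss={iv.vss:.0f} l, t1/2={iv.t_half:.2f} h"
    )
    with pd.option_context("display.width", 160):
        cols = ["animal_id", "period", "formulation", "fluid", "cmax", "tmax", "auc_inf"]
        print(table[table.route == "oral"][cols].to_string(index=False))
    print(f"wrote {(args.out / 'nca.csv').relative_to(ROOT)}")


if __name__ == "__main__":
    main()
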