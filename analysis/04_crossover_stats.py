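#!/usr/bin/env python
"""Cross-over statistics: formulation comparison tables and a power demo.

Runs the full study pipeline (paired t-tests across formulations at
alpha 0.05, mean +/- SD summaries with significance markers) on
results/dataset/, then estimates the empirical power of the paired
design (n=3) to detect a 3-fold lymph-exposure difference over 500
seeded replicates, together with its type-I error under no difference.

Writes the summary/comparison tables and results/power.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from lymphpk.io import read_study_dir, write_results
from lymphpk.pipeline import run_study
from lymphpk.stats import paired_ttest

ROOT = Path(__file__).resolve().parents[1]


def paired_power(ratio: float, n_animals: int = 3, cv: float = 0.35,
                 n_reps: int = 500, seed: int = 0) -> float:
    """Empirical rejection rate of the paired t-test on log lymph AUC
    when period exposures differ by ``ratio`` (log-normal variability of
    the given CV on each measurement)."""
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))
    hits = 0
    for _ in range(n_reps):
        base = rng.lognormal(np.log(3e4), sigma, n_animals)
        other = ratio * rng.lognormal(np.log(3e4), sigma, n_animals)
        _, p, _ = paired_ttest(np.log(base), np.log(other))
        hits += p < 0.05
    return hits / n_reps


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "dataset")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    ap.add_argument("--seed", type=int, default=2026)
    args = ap.parse_args()

    dataset = read_study_dir(args.data)
    tables = run_study(dataset, lloq=1.0, truncation_time=8.0)
    keep = {k: v for k, v in tables.items() if k.startswith(("summary", "comparisons", "recovery"))}
    write_results(keep, args.out)
    print("== formulation summary (24 h collection; * = paired p < 0.05) ==")
    print(tables["summary_full_formatted"].to_string(index=False))
    if "recovery" in tables:
        print("\n== recovery against simulator truth ==")
        print(tables["recovery"].round(3).to_string(index=False))

    power = paired_power(ratio=3.0, seed=args.seed)
    type1 = paired_power(ratio=1.0, seed=args.seed + 1)
    pd.DataFrame(
        [{"design": "paired n=3, 3-fold lymph AUC ratio, CV 35%",
          "power": power, "type1_error": type1, "n_replicates": 500}]
    ).to_csv(args.out / "power.csv", index=False)
    print(f"\npaired design power for a 3-fold lymph AUC difference: {power:.2f} "
          f"(type-I error under the null: {type1:.3f})")
    print(f"wrote tables to {args.out.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
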