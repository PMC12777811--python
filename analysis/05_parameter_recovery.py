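#!/usr/bin/env python
"""Parameter-recovery validation of the whole estimation pipeline.

Two experiments against the simulator's closed-form truths:

1. a noise-free grid over the lymph-routing fraction (phi_lymph 0.05 to
   0.5, 20 animals each, 24 h collection) checking that the pipeline
   recovers F_AL to within 5% relative and F_RL within 2 percentage
   points;
2. a 200-animal cohort with 15% proportional measurement error checking
   the median absolute F_RL error stays under 3 percentage points.

Writes results/recovery_grid.csv and results/recovery_noise.csv.
"""

import argparse
from pathlib import Path

from lymphpk import validation as V

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=2026)
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    grid = V.f_al_recovery_grid()
    grid.to_csv(args.out / "recovery_grid.csv", index=False)
    print("== noise-free grid over phi_lymph (n=200 animals) ==")
    print(f"max |F_AL relative error|: {grid.f_al_rel_error_pct.abs().max():.3f}% "
          "(gate: < 5%)")
    print(f"max |F_RL error|: {grid.f_rl_error_pp.abs().max():.3f} pp (gate: < 2 pp)")

    noisy = V.f_rl_noise_recovery(n_animals=200, residual_cv=0.15, seed=args.seed)
    noisy.to_csv(args.out / "recovery_noise.csv", index=False)
    print("\n== 15% residual noise, 200 animals ==")
    print(f"median |F_RL error|: {noisy.f_rl_error_pp.abs().median():.3f} pp "
          "(gate: < 3 pp)")

    print(f"\nsimulator vs closed form, max relative error: "
          f"{V.simulator_closed_form_max_rel_error():.2e}")
    print(f"trapezoid empirical convergence order: "
          f"{V.trapezoid_convergence_order():.2f}")
    print(f"wrote tables to {args.out.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
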