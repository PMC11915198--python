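#!/usr/bin/env python
"""Recovery of planted causes: one strong-effect scenario per cause kind.

Each scenario plants a single cause (weather step or landscape barrier) with
an effect at least 3 noise SDs. Reports the fraction of truth-labelled stops
whose final attribution contains the planted cause, and verifies the
decision-tree hierarchy on a stacked barrier where water, fuel-load and
land-cover edges coincide.
"""

from pathlib import Path

from firestops.evaluation import planted_recovery, stacked_barrier_suppression

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    table = planted_recovery(seed=11)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "planted_recovery.csv", index=False)
    print("planted-cause recovery (one single-cause scenario per kind):")
    print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    total = (table["recovered_frac"] * table["n_affected"]).sum() / table["n_affected"].sum()
    print(f"suite recovery: {total * 100:.1f}% of {table['n_affected'].sum()} affected stops")

    stacked = stacked_barrier_suppression(seed=11)
    print("\nstacked barrier (water + fuel-load + land-cover on one line):")
    print(f"  raw co-triggering at {stacked['n_co_triggered_raw']}/{stacked['n_affected']} stops;"
          f" surviving flags: water at {stacked['water_recovered_frac'] * 100:.0f}%,"
          f" lower-priority leaks: {stacked['lower_priority_leaks']}")
    print(f"table -> {RESULTS / 'planted_recovery.csv'}")


if __name__ == "__main__":
    main()
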