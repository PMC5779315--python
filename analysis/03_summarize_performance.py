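#!/usr/bin/env python
"""Summarize the coded-model trial table into the per-(set size, delay)
performance table the fits consume: normalized mean squared error, SEM
across participants, and the pooled trial variance used by the likelihood.
Writes results/performance_coded.csv."""

from pathlib import Path

from stmbound import performance_table, read_trials

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    trials = read_trials(OUT / "trials_coded.csv")
    table = performance_table(trials)
    table.points.to_csv(OUT / "performance_coded.csv", index=False)
    print(table.points.to_string(index=False))
    print(f"\nbaseline delay T0 = {table.baseline_delay} s; "
          f"wrote {OUT / 'performance_coded.csv'}")


if __name__ == "__main__":
    main()
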