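#!/usr/bin/env python
"""Generate the synthetic delayed-estimation datasets used downstream: one
from the coded-storage bound at its published operating point (N = 10,
1/2D = 2.28 s) and one from the direct-storage model at resource 1215 s.
Writes results/trials_coded.csv and results/trials_direct.csv."""

from pathlib import Path

from stmbound import ExperimentDesign, GenerativeModel, generate_dataset, write_trials

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    design = ExperimentDesign()
    for name, model, seed in [
        ("coded", GenerativeModel(kind="coded", n_channels=10.0, inv_2d=2.28), 11),
        ("direct", GenerativeModel(kind="direct", n_channels=10.0, inv_2d=121.5), 12),
    ]:
        trials = generate_dataset(design, model, seed=seed)
        path = OUT / f"trials_{name}.csv"
        write_trials(trials, path)
        print(
            f"{name}: {len(trials)} trials, "
            f"{trials['subject'].nunique()} subjects -> {path}"
        )


if __name__ == "__main__":
    main()
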