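#!/usr/bin/env python
"""Adjudicate between the storage models on the coded-generated data:
Gaussian trial likelihoods with empirical per-cell variances, BIC with the
k ln(2 pi n) penalty, and pointwise p-values of the cell means under each
model.  Writes results/comparison.json."""

import json
from pathlib import Path

from stmbound import compare_models, fit_coded, fit_direct, performance_table, read_trials

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    trials = read_trials(OUT / "trials_coded.csv")
    table = performance_table(trials)
    direct = fit_direct(table)
    _, coded = fit_coded(table)
    report = compare_models(trials, table, direct, coded)

    payload = {
        "delta_bic": report.delta_bic,
        "bic_direct": vars(report.bic_direct),
        "bic_coded": vars(report.bic_coded),
        "pvalues_direct": report.pvalues_direct.to_dict(orient="records"),
        "pvalues_coded": report.pvalues_coded.to_dict(orient="records"),
    }
    (OUT / "comparison.json").write_text(json.dumps(payload, indent=2))

    print(f"BIC direct = {report.bic_direct.bic:.1f} (k=1), "
          f"BIC coded = {report.bic_coded.bic:.1f} (k=2)")
    print(f"delta BIC = {report.delta_bic:.1f}  (positive favors coded; "
          ">10 is very strong evidence)")
    frac_bad = (report.pvalues_direct["p"] < 0.05).mean()
    print(f"cells rejecting the direct model at p < 0.05: {frac_bad:.0%}; "
          f"coded: {(report.pvalues_coded['p'] < 0.05).mean():.0%}")
    print(f"wrote {OUT / 'comparison.json'}")


if __name__ == "__main__":
    main()
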