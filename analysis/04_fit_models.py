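#!/usr/bin/env python
"""Fit both storage models to the coded-generated performance table with
anchored weighted least squares, plus the 6-item-only OLS variant of the
direct fit and leave-one-subject-out refits of the coded fit.  Writes
results/fits.json."""

import json
from pathlib import Path

from stmbound import (
    fit_coded,
    fit_direct,
    fit_direct_6item_ols,
    jackknife_fits,
    performance_table,
    read_trials,
)
from stmbound.fitting import default_inv2d_grid, default_n_grid

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    trials = read_trials(OUT / "trials_coded.csv")
    table = performance_table(trials)

    direct = fit_direct(table)
    direct6 = fit_direct_6item_ols(table)
    _, coded = fit_coded(table)
    jack = jackknife_fits(trials, "coded", default_n_grid(80), default_inv2d_grid(80))

    payload = {
        "direct": {"rho_s": direct.rho, "wsse": direct.wsse},
        "direct_6item_ols": {"rho_s": direct6.rho, "wsse": direct6.wsse},
        "coded": {
            "n_channels": coded.n_channels,
            "inv2d_s": coded.inv_2d,
            "resource_s": coded.resource,
            "wsse": coded.wsse,
        },
        "coded_jackknife": {
            "per_left_out": jack.drop(columns="wsse").to_dict(orient="records"),
            "se": jack.attrs["jackknife_se"],
        },
    }
    (OUT / "fits.json").write_text(json.dumps(payload, indent=2))

    print(f"direct:  N/2D = {direct.rho:.1f} s (WSSE {direct.wsse:.3f})")
    print(f"coded:   N = {coded.n_channels:.2f}, 1/2D = {coded.inv_2d:.2f} s, "
          f"resource N/2D = {coded.resource:.1f} s (WSSE {coded.wsse:.4f})")
    print(f"jackknife SE on N: {jack.attrs['jackknife_se']['n_channels']:.2f}")
    print(f"wrote {OUT / 'fits.json'}")


if __name__ == "__main__":
    main()
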