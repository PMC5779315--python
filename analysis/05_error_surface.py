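#!/usr/bin/env python
"""Map the coded-model WSSE landscape over the log-spaced (N, 1/2D) grid:
the near-diagonal valley of good fits and the neural resource N/2D along
it.  Writes results/surface.csv, results/valley.csv and a heat-map PNG
under scratch/."""

from pathlib import Path

import numpy as np
import pandas as pd

from stmbound import fit_coded, performance_table, read_trials

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    trials = read_trials(OUT / "trials_coded.csv")
    table = performance_table(trials)
    surf, fit = fit_coded(table)

    nn, vv = np.meshgrid(surf.n_grid, surf.inv2d_grid, indexing="ij")
    pd.DataFrame(
        {"n_channels": nn.ravel(), "inv2d_s": vv.ravel(), "wsse": surf.wsse.ravel()}
    ).to_csv(OUT / "surface.csv", index=False)
    valley = pd.DataFrame(
        {
            "n_channels": surf.n_grid,
            "inv2d_s": surf.valley_inv2d,
            "wsse": surf.valley_wsse,
            "resource_s": surf.resource_curve,
        }
    )
    valley.to_csv(OUT / "valley.csv", index=False)

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        pcm = ax.pcolormesh(
            surf.n_grid, surf.inv2d_grid, np.log10(surf.wsse).T, shading="auto"
        )
        ax.plot(surf.n_grid, surf.valley_inv2d, "w-", lw=1, label="valley")
        ax.plot([fit.n_channels], [fit.inv_2d], "r*", ms=10, label="best fit")
        ax.set(xscale="log", yscale="log", xlabel="N", ylabel="1/2D (s)")
        fig.colorbar(pcm, label="log10 WSSE")
        ax.legend()
        scratch = ROOT / "scratch"
        scratch.mkdir(exist_ok=True)
        fig.savefig(scratch / "error_surface.png", dpi=120, bbox_inches="tight")
        print(f"heat map -> {scratch / 'error_surface.png'}")
    except ImportError:
        pass

    big_n = valley[valley.n_channels > 30]
    print(f"best fit: N = {fit.n_channels:.2f}, 1/2D = {fit.inv_2d:.2f} s")
    print(
        "resource along the valley: "
        f"{valley.resource_s.iloc[0]:.0f} s at N = 1, "
        f"{float(np.median(big_n.resource_s)):.0f} s median for N > 30 "
        "(roughly constant at large N: log N and log 1/2D trade off)"
    )
    print(f"wrote {OUT / 'surface.csv'} and {OUT / 'valley.csv'}")


if __name__ == "__main__":
    main()
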