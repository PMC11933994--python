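#!/usr/bin/env python
"""Plot the waiting-list survival curves for every strategy.

Reads results/km_curves.csv (written by 02_run_scenarios.py; this script
re-runs the suite if it is missing) and draws the probability of still
waiting over the 10-year horizon, one panel per expansion family, status quo
dashed in each panel.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

OUTDIR = Path(__file__).resolve().parents[1] / "results"

PANELS = {
    "10% list expansion + DDT": ["wl10"] + [f"wl10_ddt{p}" for p in (10, 25, 50, 100)],
    "10% list expansion + LDT": ["wl10"] + [f"wl10_ldt{p}" for p in (25, 50, 100, 200)],
    "50% list expansion + DDT": ["wl50"] + [f"wl50_ddt{p}" for p in (10, 25, 50, 100)],
    "50% list expansion + LDT": ["wl50"] + [f"wl50_ldt{p}" for p in (25, 50, 100, 200)],
}


def main() -> None:
    curves_path = OUTDIR / "km_curves.csv"
    if not curves_path.exists():
        from kidneywait.report import RunConfig, run_suite

        run_suite(RunConfig(seed=20221, output_dir=str(OUTDIR)))
    km = pd.read_csv(curves_path)
    fig, axes = plt.subplots(2, 2, figsize=(11, 8), sharex=True, sharey=True)
    sq = km[km.scenario == "status_quo"]
    for ax, (title, names) in zip(axes.ravel(), PANELS.items()):
        for name in names:
            grp = km[km.scenario == name]
            ax.plot(grp.month, grp.survival, label=name, lw=1.4)
        ax.plot(sq.month, sq.survival, "k--", label="status_quo", lw=1.2)
        ax.set_title(title)
        ax.set_ylim(0, 1)
        ax.legend(fontsize=7)
    for ax in axes[1]:
        ax.set_xlabel("months since listing")
    for ax in axes[:, 0]:
        ax.set_ylabel("probability of still waiting")
    fig.tight_layout()
    out = OUTDIR / "figures"
    out.mkdir(exist_ok=True)
    fig.savefig(out / "km_curves.png", dpi=150)
    print(f"figure -> {out / 'km_curves.png'}")


if __name__ == "__main__":
    main()
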