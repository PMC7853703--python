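#!/usr/bin/env python
"""Build the two-period comparison tables and the volume box plots.

Reads results/cohort_recovered.csv (from 02_recover_volumes.py; falls back
to the ground-truth cohort), writes the clinical and neuroimaging comparison
tables to results/tables/, and draws box plots of the imaging volumes by
period (results/figures/volumes_by_period.png).
"""

from pathlib import Path

import pandas as pd

from ctpstroke.cohort_stats import build_tables

OUT = Path("results")


def main() -> None:
    source = OUT / "cohort_recovered.csv"
    if not source.exists():
        source = OUT / "cohort_truth.csv"
    frame = pd.read_csv(source)
    clinical, neuro = build_tables(frame)
    tables = OUT / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    clinical.to_csv(tables / "table_clinical.csv", index=False)
    neuro.to_csv(tables / "table_neuroimaging.csv", index=False)
    print(f"input: {source}")
    print(neuro.to_string(index=False))

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import numpy as np

        feats = [
            ("total_recovered", "total hypoperfused [ml]"),
            ("core_recovered", "core [ml]"),
            ("infarct_recovered", "final infarct [ml]"),
        ]
        fig, axes = plt.subplots(1, len(feats), figsize=(10, 3.2), sharey=False)
        for ax, (col, label) in zip(axes, feats):
            use = col if col in frame and frame[col].notna().all() else col.replace(
                "_recovered", "_true"
            )
            groups = [g[use].to_numpy() for _, g in frame.groupby("period")]
            ax.boxplot(groups, tick_labels=list(frame.groupby("period").groups))
            ax.set_title(label, fontsize=9)
        fig.tight_layout()
        figdir = OUT / "figures"
        figdir.mkdir(parents=True, exist_ok=True)
        fig.savefig(figdir / "volumes_by_period.png", dpi=120)
        print(f"wrote {figdir / 'volumes_by_period.png'}")
    except ImportError:
        print("matplotlib unavailable; skipped the figure")


if __name__ == "__main__":
    main()
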