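"""Figure rendering from a written results directory (profile analogues:
variance partition bars, scaled-prevalence heatmap, CWM by cluster,
environmental trends)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def render_figures(results_dir: Path, out_dir: Path) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    vp_path = results_dir / "variance_partition.csv"
    if vp_path.exists():
        vp = pd.read_csv(vp_path, index_col=0)
        fig, ax = plt.subplots(figsize=(8, 4))
        vp.mean(axis=0).plot.bar(ax=ax, color="steelblue")
        ax.set_ylabel("mean proportion of explained variance")
        fig.tight_layout()
        f = out_dir / "fig_variance_partition.png"
        fig.savefig(f, dpi=120)
        plt.close(fig)
        written.append(f)

    prev_path = results_dir / "rcp_prevalence_scaled.csv"
    if prev_path.exists():
        prev = pd.read_csv(prev_path, index_col=0)
        fig, ax = plt.subplots(figsize=(10, 3))
        im = ax.imshow(prev.to_numpy(), aspect="auto", cmap="viridis", vmin=0, vmax=1)
        ax.set_yticks(range(len(prev.index)), [f"RCP {i}" for i in prev.index])
        ax.set_xlabel("species")
        fig.colorbar(im, label="scaled prevalence")
        fig.tight_layout()
        f = out_dir / "fig_rcp_prevalence.png"
        fig.savefig(f, dpi=120)
        plt.close(fig)
        written.append(f)

    cwm_path = results_dir / "cwm_per_sample.csv"
    lab_path = results_dir / "rcp_assignment.csv"
    if cwm_path.exists() and lab_path.exists():
        cwm = pd.read_csv(cwm_path, index_col=0)
        lab = pd.read_csv(lab_path, index_col=0).iloc[:, 0]
        fig, axes = plt.subplots(2, 3, figsize=(10, 6), sharex=True)
        for ax, trait in zip(axes.ravel(), cwm.columns):
            cwm.assign(rcp=lab).boxplot(column=trait, by="rcp", ax=ax)
            ax.set_title(trait)
            ax.set_xlabel("")
        fig.suptitle("community-weighted mean traits by RCP")
        fig.tight_layout()
        f = out_dir / "fig_cwm_by_rcp.png"
        fig.savefig(f, dpi=120)
        plt.close(fig)
        written.append(f)

    return written
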