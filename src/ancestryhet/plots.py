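"""Minimal diagnostic plots (violin of excess heterozygosity by dataset)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_excess_by_dataset(summaries, path: str | Path) -> Path:
    """Violin + jitter of individual excess heterozygosity per dataset,
    colored by environment (lab red, pond blue)."""
    path = Path(path)
    datasets = sorted(summaries["dataset_id"].unique())
    fig, ax = plt.subplots(figsize=(1.2 * len(datasets) + 2, 4))
    colors = {"lab": "tab:red", "pond": "tab:blue"}
    for i, ds in enumerate(datasets):
        sub = summaries[summaries["dataset_id"] == ds]
        vals = sub["excess_het"].to_numpy()
        env = sub["environment"].iloc[0]
        parts = ax.violinplot(vals, positions=[i], widths=0.8, showextrema=False)
        for body in parts["bodies"]:
            body.set_facecolor(colors.get(env, "gray"))
            body.set_alpha(0.4)
        ax.scatter([i] * len(vals), vals, s=2, alpha=0.3, color=colors.get(env, "gray"))
        ax.errorbar(i, vals.mean(), yerr=1.96 * vals.std(ddof=1) / len(vals) ** 0.5,
                    fmt="o", color="black", capsize=3, ms=4)
    ax.axhline(0.0, color="gray", lw=0.8, ls="--")
    ax.set_xticks(range(len(datasets)))
    ax.set_xticklabels(datasets, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("excess ancestry heterozygosity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
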