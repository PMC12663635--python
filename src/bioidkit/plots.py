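"""Basic figure exports (volcano and dot plot) for scored/classified tables."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

_CLASS_COLORS = {"increased": "tab:red", "decreased": "tab:blue", "unchanged": "0.6"}
_BORDER_COLORS = {"black": "black", "blue": "tab:blue", "light_blue": "lightblue"}


def volcano_plot(table, path, fc_threshold: float = 2.0, alpha: float = 0.05) -> None:
    """Scatter of -log10 p vs log2 fold change, coloured by class."""
    import numpy as np

    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, color in _CLASS_COLORS.items():
        sub = table[table["class"] == cls]
        ax.scatter(sub["log2_fc"], sub["neg_log10_p"], s=10, c=color, label=cls)
    for x in (np.log2(fc_threshold), -np.log2(fc_threshold)):
        ax.axvline(x, ls=":", c="k", lw=0.8)
    ax.axhline(-np.log10(alpha), ls=":", c="k", lw=0.8)
    ax.set_xlabel("log2 fold change (ciliated / cycling)")
    ax.set_ylabel("-log10 p")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def dot_plot(records, path) -> None:
    """Prey-by-dataset dot plot: colour = capped counts, size = relative, border = BFDR bin."""
    df = records.copy()
    df["dataset"] = df["bait_id"].where(
        df["condition"].isna(), df["bait_id"] + " (" + df["condition"].fillna("") + ")"
    )
    xcats = sorted(df["dataset"].unique())
    ycats = sorted(df["prey_id"].unique())
    xi = {c: i for i, c in enumerate(xcats)}
    yi = {c: i for i, c in enumerate(ycats)}
    fig, ax = plt.subplots(figsize=(1 + 0.5 * len(xcats), 1 + 0.25 * len(ycats)))
    sc = ax.scatter(
        [xi[d] for d in df["dataset"]],
        [yi[p] for p in df["prey_id"]],
        s=20 + 180 * df["size_value"],
        c=df["color_value"],
        cmap="viridis",
        vmin=0,
        vmax=50,
        edgecolors=[_BORDER_COLORS[b] for b in df["border_class"]],
        linewidths=1.2,
    )
    ax.set_xticks(range(len(xcats)), xcats, rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(len(ycats)), ycats, fontsize=7)
    fig.colorbar(sc, ax=ax, label="control-subtracted counts (capped at 50)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
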