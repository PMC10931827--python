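"""Optional scatter plots for biplot results (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402

from .projection import BiplotResult  # noqa: E402


def biplot_figure(result: BiplotResult, title: str = ""):
    """Samples (blue) and genes (red) on PC1/PC2 with explained variance."""
    fig, ax = plt.subplots(figsize=(6, 5))
    gc = result.gene_coords
    sc = result.sample_scores
    ax.scatter(gc["PC1"], gc["PC2"], s=12, c="tab:red", alpha=0.6,
               label=f"genes (n={len(gc)})")
    ax.scatter(sc["PC1"], sc["PC2"], s=30, c="tab:blue",
               label=f"samples (n={len(sc)})")
    for name, row in sc.iterrows():
        ax.annotate(str(name), (row["PC1"], row["PC2"]), fontsize=7,
                    xytext=(2, 2), textcoords="offset points")
    ev = result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({ev[0]:.1%})")
    ax.set_ylabel(f"PC2 ({ev[1]:.1%})" if len(ev) > 1 else "PC2")
    ax.axvline(0.0, color="grey", lw=0.6)
    ax.axhline(0.0, color="grey", lw=0.6)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
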