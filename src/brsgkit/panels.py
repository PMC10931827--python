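"""Named gene-panel profiling across samples, regions and groups.

Panels are small curated gene lists (vesicular transporters, glycinergic/
neurofilament axon genes, TCA-cycle enzymes, ...) whose per-sample FPKM
profiles and region × group means summarize where and in which experimental
group a process is active.  Built-in panels ship as an editable TSV data
file; two of them are deliberately partial seeds — the mitophagy panel lists
only its firmly named members (Prkcd, Pink1, Park2, Gak) of a larger set, and
the myelin panel ships as the Mbp seed to be extended by the user — rather
than guessed completions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import pandas as pd

from .io import GenePanel, read_panels_tsv


@dataclass
class PanelProfile:
    """Per-sample values and region × group means for one panel."""

    panel: GenePanel
    long: pd.DataFrame            # columns: gene, sample, region, group, fpkm
    means: pd.DataFrame           # MultiIndex (region, group) × genes
    missing_genes: tuple[str, ...]


def builtin_panels() -> list[GenePanel]:
    """The panels shipped with the package (see the data file for membership)."""
    with resources.as_file(
        resources.files("brsgkit.data") / "panels.tsv"
    ) as path:
        return read_panels_tsv(path)


def get_panel(name: str) -> GenePanel:
    for p in builtin_panels():
        if p.name == name:
            return p
    raise KeyError(f"no builtin panel named {name!r}")


def prefix_panel(gene_universe: Sequence[str], prefixes: Sequence[str],
                 name: str | None = None) -> GenePanel | None:
    """Panel of all genes whose symbol starts with any prefix.

    Matching is anchored at the symbol start and case-sensitive, so ``Rpl``
    selects cytoplasmic large-subunit ribosomal genes without catching the
    mitochondrial ``Mrpl`` family.  Returns None (with the empty-match
    semantics documented by the caller) when nothing matches.
    """
    if not prefixes:
        raise ValueError("prefix list is empty")
    hits = sorted({g for g in gene_universe
                   if any(g.startswith(p) for p in prefixes)})
    if not hits:
        return None
    return GenePanel(name=name or "+".join(prefixes) + "*", genes=tuple(hits))


def panel_profile(matrix: pd.DataFrame, metadata: pd.DataFrame,
                  panel: GenePanel) -> PanelProfile:
    """Profile a panel: long-format per-sample FPKM plus region × group means.

    Panel genes absent from the matrix are reported in ``missing_genes``,
    never silently dropped; at least one must be present.
    """
    present = [g for g in panel.genes if g in matrix.index]
    missing = tuple(g for g in panel.genes if g not in matrix.index)
    if not present:
        raise ValueError(f"no gene of panel {panel.name!r} is in the matrix")
    sub = matrix.loc[present, [s for s in matrix.columns if s in metadata.index]]
    long = (sub.rename_axis("gene").reset_index()
            .melt(id_vars="gene", var_name="sample", value_name="fpkm"))
    long["region"] = long["sample"].map(metadata["region"])
    long["group"] = long["sample"].map(metadata["group"])
    long = long[["gene", "sample", "region", "group", "fpkm"]]
    means = (long.pivot_table(index=["region", "group"], columns="gene",
                              values="fpkm", aggfunc="mean", observed=True)
             [present])
    return PanelProfile(panel=panel, long=long, means=means,
                        missing_genes=missing)


def group_contrast(profile: PanelProfile, group_a: str, group_b: str,
                   per_region: bool = True) -> pd.DataFrame:
    """Mean ratio (A/B) and difference (A−B) per gene, per region.

    A zero group-B mean leaves the ratio undefined: the row is flagged
    (``ratio_defined=False``) with a NaN ratio rather than an infinity.
    """
    groups = set(profile.long["group"])
    for g in (group_a, group_b):
        if g not in groups:
            raise ValueError(f"unknown group label {g!r}; present: {sorted(groups)}")
    grouping = ["region", "gene"] if per_region else ["gene"]
    means = (profile.long.groupby(grouping + ["group"], observed=True)["fpkm"]
             .mean().unstack("group"))
    out = pd.DataFrame({"mean_a": means[group_a],
                        "mean_b": means[group_b]}).reset_index()
    out["difference"] = out["mean_a"] - out["mean_b"]
    out["ratio_defined"] = out["mean_b"] > 0
    out["ratio"] = out["mean_a"].where(out["ratio_defined"]) / out["mean_b"]
    out.insert(0, "group_b", group_b)
    out.insert(0, "group_a", group_a)
    return out
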