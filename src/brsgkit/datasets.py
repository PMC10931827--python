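"""Bundled worked-example data.

``load_midbrain_example`` returns the published per-region mean FPKM table
for 25 midbrain-enriched mouse genes across the five regions (HPC, HPT, STR,
MRN, VTA), together with the reference tissue-specificity index printed
alongside each row and the selection rule its table segment implies (genes in
the shared MRN/VTA segment use the combined-pair rule).  It is the standard
desk check for the TSI implementation: recomputing every row's TSI from its
means must reproduce the reference column at two decimals.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: region columns of the worked example, in declared order
MIDBRAIN_REGIONS = ("HPC", "HPT", "STR", "MRN", "VTA")
#: the combined pair of the worked example
MIDBRAIN_PAIR = ("MRN", "VTA")


def load_midbrain_example() -> pd.DataFrame:
    """The midbrain worked-example table, indexed by gene symbol.

    Columns: ``segment`` (VTA / MRN / MRN/VTA), ``rule`` (single / combined),
    the five region means, and ``tsi_reference`` (printed at 2 dp).
    """
    with resources.as_file(
        resources.files("brsgkit.data") / "midbrain_region_means.tsv"
    ) as path:
        df = pd.read_csv(path, sep="\t")
    return df.set_index("gene")


def midbrain_region_means() -> pd.DataFrame:
    """Just the genes × regions mean matrix of the worked example."""
    return load_midbrain_example()[list(MIDBRAIN_REGIONS)]


def midbrain_brsg_table() -> pd.DataFrame:
    """The worked example rendered as a BRSG table.

    Assignments follow the published table segments (single-region genes to
    their segment's region, shared genes to the MRN/VTA pair); the TSI column
    is recomputed at full precision from the region means with the rule the
    segment implies.  Shaped like :func:`brsgkit.selection.select_brsgs`
    output, so breakdown and enrichment accept it directly.
    """
    from .selection import tsi_combined, tsi_single  # local: avoid cycle

    df = load_midbrain_example()
    records = []
    for gene, row in df.iterrows():
        profile = row[list(MIDBRAIN_REGIONS)].astype(float)
        if row["rule"] == "single":
            tsi, assigned, tie = tsi_single(profile)
            x_max = float(profile.max())
        else:
            tsi = tsi_combined(profile, MIDBRAIN_PAIR)
            assigned = "/".join(MIDBRAIN_PAIR)
            x_max = float(profile[list(MIDBRAIN_PAIR)].sum())
            tie = False
        rec = {"gene": gene, "rule": row["rule"], "assigned_region": assigned,
               "tsi": tsi, "x_max": x_max, "tie": tie}
        for r in MIDBRAIN_REGIONS:
            rec[f"mean_{r}"] = float(row[r])
        records.append(rec)
    table = pd.DataFrame(records)
    table.attrs["regions"] = list(MIDBRAIN_REGIONS)
    table.attrs["pair"] = MIDBRAIN_PAIR
    return table
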