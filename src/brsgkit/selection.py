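"""Tissue-specificity scoring and brain-region-specific gene (BRSG) selection.

The statistic is the tissue-specificity index over per-region mean FPKM
``x_1..x_n`` (default five regions):

    TSI = x_max / sum_i x_i                     (single-region rule)
    TSI = (x_a + x_b) / sum_i x_i               (combined-pair rule)

The combined-pair rule handles genes shared between two similar regions (the
midbrain dopaminergic/serotonergic pair VTA and MRN): their summed mean
replaces the single maximum in the numerator.  A gene is selected as a BRSG
when its TSI strictly exceeds a soft threshold τ (default 0.5); the
single-region rule takes precedence — the combined rule is consulted only for
genes that do not pass on a single region, so a gene like Dbh with a dominant
single region stays assigned to it even though its pair-summed share is larger.

TSI ranges from 1/n_regions (perfectly uniform expression) to 1 (fully
confined).  It is scale-free: multiplying a gene's FPKM by any positive
constant leaves it unchanged.

Region means pool all samples of a region across groups: specificity is a
property of the region, not of the experimental contrast.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: separator used to render a combined pair as a single assigned-region label
PAIR_SEP = "/"


class UndefinedTsiError(ValueError):
    """Raised when TSI is undefined (all region means zero)."""


def region_means(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    regions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Arithmetic mean FPKM per gene per region, all groups pooled.

    Returns a genes × regions DataFrame in declared region order.  Every
    declared region must contribute at least one sample.
    """
    if regions is None:
        regions = list(dict.fromkeys(metadata["region"]))
    out = {}
    for region in regions:
        cols = [s for s in matrix.columns
                if s in metadata.index and metadata.at[s, "region"] == region]
        if not cols:
            raise ValueError(f"region {region!r} has no samples in the matrix")
        out[region] = matrix[cols].mean(axis=1)
    return pd.DataFrame(out, index=matrix.index)[list(regions)]


def tsi_single(profile: pd.Series) -> tuple[float, str, bool]:
    """Single-region TSI of one region-mean profile.

    Returns ``(tsi, argmax_region, tied)``; ties on the maximum are broken by
    declared region order and flagged.  Raises :class:`UndefinedTsiError` on an
    all-zero profile.
    """
    x = profile.to_numpy(dtype=float)
    total = x.sum()
    if total <= 0:
        raise UndefinedTsiError(f"all-zero region profile: {profile.name!r}")
    x_max = x.max()
    winners = np.flatnonzero(x == x_max)
    return float(x_max / total), str(profile.index[winners[0]]), len(winners) > 1


def tsi_combined(profile: pd.Series, pair: tuple[str, str]) -> float:
    """Combined-pair TSI: the two designated regions' summed mean over the total."""
    a, b = pair
    if a == b:
        raise ValueError(f"combined pair must name two distinct regions, got {pair}")
    for r in pair:
        if r not in profile.index:
            raise ValueError(f"pair region {r!r} not in profile regions "
                             f"{list(profile.index)}")
    total = float(profile.to_numpy(dtype=float).sum())
    if total <= 0:
        raise UndefinedTsiError(f"all-zero region profile: {profile.name!r}")
    return float((profile[a] + profile[b]) / total)


def select_brsgs_from_means(
    means: pd.DataFrame,
    pair: tuple[str, str] | None = ("MRN", "VTA"),
    tau: float = 0.5,
    min_max_fpkm: float = 0.0,
) -> pd.DataFrame:
    """BRSG selection on a precomputed genes × regions mean table.

    Per gene: if the single-region TSI strictly exceeds ``tau`` the gene is
    selected under the ``single`` rule and assigned to its argmax region;
    otherwise, if a pair is declared and the combined-pair TSI strictly
    exceeds ``tau``, it is selected under the ``combined`` rule and assigned
    to the pair; otherwise it is excluded.  All-zero genes are skipped with a
    log entry.  ``min_max_fpkm`` optionally drops genes whose maximal region
    mean falls below a floor (default 0, i.e. no floor).

    Returns a DataFrame with columns ``gene``, ``rule``, ``assigned_region``,
    ``tsi`` (full precision), ``x_max``, ``tie`` and one ``mean_<region>``
    column per region, sorted by (rule, assigned_region, -tsi, gene).
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"threshold tau must be in (0, 1), got {tau}")
    if pair is not None and pair[0] == pair[1]:
        raise ValueError(f"combined pair must name two distinct regions, got {pair}")
    regions = list(means.columns)
    if pair is not None:
        for r in pair:
            if r not in regions:
                raise ValueError(f"pair region {r!r} not among regions {regions}")
    x = means.to_numpy(dtype=float)
    totals = x.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        logger.info("select_brsgs: skipped %d gene(s) with all-zero profile",
                    int(zero.sum()))
    records = []
    for i, gene in enumerate(means.index):
        if zero[i]:
            continue
        row = x[i]
        x_max = row.max()
        if x_max < min_max_fpkm:
            continue
        winners = np.flatnonzero(row == x_max)
        single = x_max / totals[i]
        if single > tau:
            rule, assigned = "single", regions[winners[0]]
            tsi, num = single, x_max
        elif pair is not None:
            ia, ib = regions.index(pair[0]), regions.index(pair[1])
            num = row[ia] + row[ib]
            combined = num / totals[i]
            if combined > tau:
                rule, assigned, tsi = "combined", PAIR_SEP.join(pair), combined
            else:
                continue
        else:
            continue
        rec = {"gene": gene, "rule": rule, "assigned_region": assigned,
               "tsi": float(tsi), "x_max": float(num),
               "tie": bool(len(winners) > 1 and rule == "single")}
        for r, v in zip(regions, row):
            rec[f"mean_{r}"] = float(v)
        records.append(rec)
    cols = (["gene", "rule", "assigned_region", "tsi", "x_max", "tie"]
            + [f"mean_{r}" for r in regions])
    table = pd.DataFrame(records, columns=cols)
    if len(table):
        table = table.sort_values(
            ["rule", "assigned_region", "tsi", "gene"],
            ascending=[True, True, False, True], kind="mergesort",
        ).reset_index(drop=True)
    table.attrs["regions"] = regions
    table.attrs["pair"] = pair
    table.attrs["tau"] = tau
    return table


def select_brsgs(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    pair: tuple[str, str] | None = ("MRN", "VTA"),
    tau: float = 0.5,
    regions: Sequence[str] | None = None,
    min_max_fpkm: float = 0.0,
) -> pd.DataFrame:
    """BRSG selection from an aligned matrix + metadata (see
    :func:`select_brsgs_from_means`)."""
    means = region_means(matrix, metadata, regions=regions)
    return select_brsgs_from_means(means, pair=pair, tau=tau,
                                   min_max_fpkm=min_max_fpkm)


def breakdown_by_expression(
    brsg_table: pd.DataFrame,
    thresholds: Sequence[float] = (100.0, 1000.0),
    regions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-region BRSG counts, total and above each FPKM threshold.

    A combined-pair gene counts towards *both* member regions; its tier
    membership in a region uses that region's own mean (strict ``>``).
    Single-rule genes use their assigned region's mean.
    """
    thr = list(thresholds)
    if any(b <= a for a, b in zip(thr, thr[1:])) or any(t <= 0 for t in thr):
        raise ValueError(f"thresholds must be positive and strictly increasing: {thr}")
    if regions is None:
        regions = brsg_table.attrs.get("regions")
    if regions is None:
        mean_cols = [c for c in brsg_table.columns if c.startswith("mean_")]
        regions = [c[len("mean_"):] for c in mean_cols]
    counts = {r: {"total": 0, **{f">{t:g} FPKM": 0 for t in thr}} for r in regions}
    for _, row in brsg_table.iterrows():
        members = (row["assigned_region"].split(PAIR_SEP)
                   if row["rule"] == "combined" else [row["assigned_region"]])
        for region in members:
            counts[region]["total"] += 1
            m = row[f"mean_{region}"]
            for t in thr:
                if m > t:
                    counts[region][f">{t:g} FPKM"] += 1
    out = pd.DataFrame(counts).T
    out.index.name = "region"
    return out
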