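"""Reading, validation and writing of expression matrices, sample metadata and panels.

On-disk conventions
-------------------
* Expression TSV: one header row of sample ids, first column of gene ids,
  non-negative FPKM values.  Genes-as-rows is canonical; an orientation flag
  handles transposed exports.
* Metadata TSV: columns ``sample_id``, ``region``, ``group``.
* Panel TSV: long format, columns ``panel_name``, ``gene_id``.

Missing cells are hard errors, never imputed zeros — a silently zero-filled
cell would distort every downstream specificity score.  Identifiers are
case-sensitive symbols and are never remapped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Brain regions of the chronic social stress design, in declared order.
DEFAULT_REGIONS: tuple[str, ...] = ("HPC", "HPT", "STR", "MRN", "VTA")
#: Experimental groups: unexposed controls, chronically aggressive "winners"
#: and chronically defeated "losers" (depressive).
DEFAULT_GROUPS: tuple[str, ...] = ("control", "aggressive", "depressive")


class ExpressionIOError(ValueError):
    """Raised for any violation of the on-disk contracts above."""


@dataclass(frozen=True)
class GenePanel:
    """A named, duplicate-free, non-empty list of gene symbols."""

    name: str
    genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.name:
            raise ExpressionIOError("panel name must be non-empty")
        if len(self.genes) == 0:
            raise ExpressionIOError(f"panel {self.name!r} is empty")
        seen: set[str] = set()
        for g in self.genes:
            if g in seen:
                raise ExpressionIOError(
                    f"panel {self.name!r} lists gene {g!r} more than once"
                )
            seen.add(g)

    def __len__(self) -> int:
        return len(self.genes)


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ExpressionIOError(f"duplicate {what} identifier: {lab!r}")
        seen.add(lab)


def validate_expression_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory genes × samples FPKM matrix.

    Checks uniqueness of gene and sample identifiers, absence of missing
    cells, and non-negativity.  Returns the matrix unchanged (float dtype).
    """
    _check_unique(list(matrix.index), "gene")
    _check_unique(list(matrix.columns), "sample")
    try:
        values = matrix.astype(float)
    except (TypeError, ValueError) as exc:
        raise ExpressionIOError(f"non-numeric expression value: {exc}") from exc
    if values.isna().any().any():
        gene, sample = next(
            (g, s)
            for g in values.index
            for s in values.columns
            if pd.isna(values.at[g, s])
        )
        raise ExpressionIOError(
            f"missing/non-numeric cell at gene {gene!r}, sample {sample!r}"
        )
    if (values < 0).any().any():
        gene, sample = next(
            (g, s)
            for g in values.index
            for s in values.columns
            if values.at[g, s] < 0
        )
        raise ExpressionIOError(
            f"negative FPKM {values.at[gene, sample]} at gene {gene!r}, "
            f"sample {sample!r}"
        )
    return values


def read_expression_tsv(path: str | Path, genes_as_rows: bool = True) -> pd.DataFrame:
    """Read an FPKM matrix from TSV into a genes × samples DataFrame.

    Parameters
    ----------
    path
        TSV with one header row of sample ids and a first column of gene ids
        (the transpose if ``genes_as_rows=False``).
    genes_as_rows
        Orientation of the file on disk.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "sample" if genes_as_rows else "gene")
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    if not genes_as_rows:
        raw = raw.T
    for col in raw.columns:
        bad = pd.to_numeric(raw[col], errors="coerce")
        if bad.isna().any() and not raw[col].isna().any():
            gene = raw.index[bad.isna().argmax()]
            raise ExpressionIOError(
                f"non-numeric cell at gene {gene!r}, sample {col!r} in {path}"
            )
    return validate_expression_matrix(raw)


def read_metadata_tsv(
    path: str | Path,
    region_labels: Sequence[str] = DEFAULT_REGIONS,
    group_labels: Sequence[str] = DEFAULT_GROUPS,
) -> pd.DataFrame:
    """Read sample metadata; returns a DataFrame indexed by sample_id with
    ``region`` and ``group`` columns validated against the declared label sets."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "region", "group"}
    missing = required - set(meta.columns)
    if missing:
        raise ExpressionIOError(f"metadata missing columns: {sorted(missing)}")
    _check_unique(list(meta["sample_id"]), "sample")
    regions, groups = set(region_labels), set(group_labels)
    for _, row in meta.iterrows():
        if row["region"] not in regions:
            raise ExpressionIOError(
                f"unknown region label {row['region']!r} for sample "
                f"{row['sample_id']!r}; declared regions: {sorted(regions)}"
            )
        if row["group"] not in groups:
            raise ExpressionIOError(
                f"unknown group label {row['group']!r} for sample "
                f"{row['sample_id']!r}; declared groups: {sorted(groups)}"
            )
    return meta.set_index("sample_id")[["region", "group"]]


def align(
    matrix: pd.DataFrame, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict matrix and metadata to their shared samples.

    The matrix's original column order is preserved; metadata rows are
    reordered to match.  Dropped samples on either side are logged.
    Idempotent: aligning an aligned pair is the identity.
    """
    shared = [s for s in matrix.columns if s in metadata.index]
    if not shared:
        raise ExpressionIOError("no samples shared between matrix and metadata")
    dropped_m = [s for s in matrix.columns if s not in metadata.index]
    dropped_s = [s for s in metadata.index if s not in set(matrix.columns)]
    if dropped_m:
        logger.info("align: dropped %d matrix sample(s) without metadata: %s",
                    len(dropped_m), dropped_m)
    if dropped_s:
        logger.info("align: dropped %d metadata sample(s) without expression: %s",
                    len(dropped_s), dropped_s)
    return matrix[shared], metadata.loc[shared]


def write_table(records: pd.DataFrame, path: str | Path,
                sort_by: str | Sequence[str] | None = None) -> None:
    """Write a flat table as TSV with header.

    Row order is deterministic: the input order, or ``sort_by`` columns
    (stable mergesort) when given.  Two writes of equal input are
    byte-identical.
    """
    out = records
    if sort_by is not None:
        out = records.sort_values(sort_by, kind="mergesort")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False)


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a genes × samples matrix in the canonical genes-as-rows layout."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def write_metadata_tsv(metadata: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    metadata.rename_axis("sample_id").reset_index().to_csv(path, sep="\t", index=False)


def read_panels_tsv(path: str | Path) -> list[GenePanel]:
    """Read gene panels from a long-format TSV (``panel_name<TAB>gene_id``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"panel_name", "gene_id"} <= set(df.columns):
        raise ExpressionIOError(
            f"panel file {path} must have columns panel_name, gene_id"
        )
    panels = []
    for name in df["panel_name"].drop_duplicates():
        genes = tuple(df.loc[df["panel_name"] == name, "gene_id"])
        panels.append(GenePanel(name=name, genes=genes))
    return panels


def write_panels_tsv(panels: Iterable[GenePanel], path: str | Path) -> None:
    rows = [
        {"panel_name": p.name, "gene_id": g} for p in panels for g in p.genes
    ]
    write_table(pd.DataFrame(rows, columns=["panel_name", "gene_id"]), path)
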