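"""Config-driven end-to-end orchestration.

``run_pipeline`` executes: align → region means → BRSG selection → expression
breakdown → (optional) network enrichment → per-set PCA biplot + side tests +
clustering → panel profiles, writing every table plus a JSON manifest with the
package version, seed, config echo and per-file SHA-256 checksums.  A single
config seed governs all stochastic stages (sub-seeds are spawned
deterministically), so a rerun with the same inputs and seed gives identical
checksums.  Any stage failure aborts the run with the stage name; files
already written by the failed run are removed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from . import __version__
from .io import (DEFAULT_GROUPS, DEFAULT_REGIONS, align, read_expression_tsv,
                 read_metadata_tsv, read_panels_tsv, write_table)
from .network import TierSpec, enrichment_report, read_string_links
from .panels import builtin_panels, group_contrast, panel_profile
from .projection import ahc_cluster, pca_biplot, side_counts, side_preference_tests
from .selection import breakdown_by_expression, region_means, select_brsgs_from_means
from .simulate import (SyntheticExpressionSpec, SyntheticPpiSpec,
                       generate_expression, generate_ppi, write_truth_tsv)
from .io import write_expression_tsv, write_metadata_tsv
from .network import write_string_links

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Human-readable, aggregated configuration problems."""


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class RunConfig(BaseModel):
    """Validated pipeline configuration (unknown keys are rejected)."""

    model_config = ConfigDict(extra="forbid")

    expression: Path
    metadata: Path
    outdir: Path
    ppi: Optional[Path] = None
    panels: Optional[Path] = None
    regions: list[str] = Field(default=list(DEFAULT_REGIONS))
    groups: list[str] = Field(default=list(DEFAULT_GROUPS))
    pair: Optional[tuple[str, str]] = ("MRN", "VTA")
    tau: float = 0.5
    min_max_fpkm: float = 0.0
    expression_tiers: list[float] = Field(default=[100.0, 1000.0])
    tier_cutoffs: dict[str, float] = Field(
        default={"low": 0.150, "medium": 0.4, "high": 0.7, "highest": 0.9})
    n_permutations: int = 999
    seed: int = 0
    pca_standardize: bool = True
    n_clusters: int = 2
    contrast_groups: Optional[tuple[str, str]] = ("aggressive", "control")

    @field_validator("tau")
    @classmethod
    def _tau_open_interval(cls, v: float) -> float:
        if not 0.0 < v < 1.0:
            raise ValueError(f"tau must be in (0, 1), got {v}")
        return v

    @field_validator("expression_tiers")
    @classmethod
    def _tiers_increasing(cls, v: list[float]) -> list[float]:
        if any(t <= 0 for t in v) or any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError(f"expression tiers must be positive increasing: {v}")
        return v

    @field_validator("n_permutations")
    @classmethod
    def _min_permutations(cls, v: int) -> int:
        if v < 99:
            raise ValueError(f"n_permutations must be >= 99, got {v}")
        return v

    def tier_spec(self) -> TierSpec:
        return TierSpec(cutoffs=tuple(self.tier_cutoffs.items()))


class SimConfig(BaseModel):
    """Configuration of the synthetic-bundle generator (``brsg-kit simulate``)."""

    model_config = ConfigDict(extra="forbid")

    outdir: Path
    n_genes: int = 2000
    replicates: int = 3
    regions: list[str] = Field(default=list(DEFAULT_REGIONS))
    groups: list[str] = Field(default=list(DEFAULT_GROUPS))
    n_single_region: int = 20
    n_shared_pair: int = 17
    shared_pair: tuple[str, str] = ("MRN", "VTA")
    fold: float = 10.0
    n_group_effect: int = 0
    group_fold: float = 2.0
    cv: float = 0.3
    background_prob: float = 0.02
    module_prob: float = 0.3
    seed: int = 0


def _load_yaml_model(path: str | Path, model: type[BaseModel]) -> BaseModel:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return model.model_validate(raw)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "(root)"
            lines.append(f"  - {loc}: {err['msg']}")
        raise ConfigError(
            f"invalid config {path} ({len(lines)} problem(s)):\n" + "\n".join(lines)
        ) from exc


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a run config; raises ConfigError listing every problem."""
    return _load_yaml_model(path, RunConfig)


def validate_sim_config(path: str | Path) -> SimConfig:
    return _load_yaml_model(path, SimConfig)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_simulation(config: SimConfig) -> dict:
    """Write a synthetic bundle (expression/metadata/ppi/truth TSVs)."""
    spec = SyntheticExpressionSpec(
        n_genes=config.n_genes, regions=tuple(config.regions),
        groups=tuple(config.groups), replicates=config.replicates,
        n_single_region=config.n_single_region,
        n_shared_pair=config.n_shared_pair,
        shared_pair=config.shared_pair, fold=config.fold,
        n_group_effect=config.n_group_effect, group_fold=config.group_fold,
        cv=config.cv, seed=config.seed,
    )
    matrix, metadata, truth = generate_expression(spec)
    sets = dict(truth.single_region_genes)
    sets["shared-pair"] = truth.genes_with_label("shared-pair")
    sets = {k: v for k, v in sets.items() if v}
    graph, _ = generate_ppi(
        SyntheticPpiSpec(background_prob=config.background_prob,
                         module_prob=config.module_prob, seed=config.seed + 1),
        genes=list(matrix.index), gene_sets=sets,
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression_tsv(matrix, outdir / "expression.tsv")
    write_metadata_tsv(metadata, outdir / "metadata.tsv")
    write_string_links(graph, outdir / "ppi.tsv")
    write_truth_tsv(truth, outdir / "truth.tsv")
    files = ["expression.tsv", "metadata.tsv", "ppi.tsv", "truth.tsv"]
    return {"outdir": str(outdir), "files": files, "seed": config.seed}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    rng_seeds = np.random.SeedSequence(config.seed).spawn(2)
    enrich_seed = int(rng_seeds[0].generate_state(1)[0] % (2 ** 31))

    def _write(df: pd.DataFrame, name: str, **kw) -> None:
        path = outdir / name
        write_table(df, path, **kw)
        written.append(path)

    stage = "load"
    try:
        matrix = read_expression_tsv(config.expression)
        metadata = read_metadata_tsv(config.metadata,
                                     region_labels=config.regions,
                                     group_labels=config.groups)
        stage = "align"
        matrix, metadata = align(matrix, metadata)

        stage = "region_means"
        means = region_means(matrix, metadata, regions=config.regions)

        stage = "select_brsgs"
        brsg = select_brsgs_from_means(means, pair=config.pair, tau=config.tau,
                                       min_max_fpkm=config.min_max_fpkm)
        out = brsg.copy()
        out["tsi"] = out["tsi"].round(2)   # reported at 2 dp; full precision internal
        _write(out, "brsg_table.tsv")

        stage = "breakdown"
        bd = breakdown_by_expression(brsg, thresholds=config.expression_tiers,
                                     regions=config.regions)
        _write(bd.reset_index(), "breakdown.tsv")

        if config.ppi is not None:
            stage = "enrichment"
            graph = read_string_links(config.ppi)
            rep = enrichment_report(graph, brsg, tiers=config.tier_spec(),
                                    n_permutations=config.n_permutations,
                                    seed=enrich_seed)
            _write(rep, "enrichment.tsv")

        stage = "projection"
        side_rows, score_frames, coord_frames, cluster_rows = [], [], [], []
        for region_label, genes in _region_sets(brsg).items():
            sample_ids = _samples_for(metadata, region_label)
            if len(genes) < 2 or len(sample_ids) < 2:
                continue
            bp = pca_biplot(matrix, genes=genes, samples=sample_ids,
                            standardize=config.pca_standardize)
            sc = bp.sample_scores.rename_axis("sample").reset_index()
            sc.insert(0, "set", region_label)
            score_frames.append(sc)
            gc = bp.gene_coords.rename_axis("gene").reset_index()
            gc.insert(0, "set", region_label)
            coord_frames.append(gc)
            counts = side_counts(bp.gene_coords["PC1"])
            for test in side_preference_tests(counts):
                side_rows.append({
                    "set": region_label, "n_left": counts.n_left,
                    "n_right": counts.n_right, "n_zero": counts.n_zero,
                    "n": test.n, "k": test.k, "sidedness": test.sidedness,
                    "p_value": test.p_value,
                })
            if len(genes) >= config.n_clusters and len(genes) >= 2:
                cl = ahc_cluster(matrix[sample_ids], genes=genes,
                                 n_clusters=config.n_clusters)
                for gene, lab in cl.labels.items():
                    cluster_rows.append({"set": region_label, "gene": gene,
                                         "cluster": int(lab),
                                         "linkage": cl.method})
        if score_frames:
            _write(pd.concat(score_frames, ignore_index=True),
                   "biplot_scores.tsv")
            _write(pd.concat(coord_frames, ignore_index=True),
                   "biplot_loadings.tsv")
        if side_rows:
            _write(pd.DataFrame(side_rows), "side_tests.tsv")
        if cluster_rows:
            _write(pd.DataFrame(cluster_rows), "clusters.tsv")

        stage = "panels"
        panels = (read_panels_tsv(config.panels) if config.panels is not None
                  else builtin_panels())
        prof_frames, contrast_frames = [], []
        for panel in panels:
            if not any(g in matrix.index for g in panel.genes):
                logger.info("panel %r: no gene present, skipped", panel.name)
                continue
            prof = panel_profile(matrix, metadata, panel)
            long = prof.long.copy()
            long.insert(0, "panel", panel.name)
            prof_frames.append(long)
            if config.contrast_groups is not None:
                ga, gb = config.contrast_groups
                con = group_contrast(prof, ga, gb)
                con.insert(0, "panel", panel.name)
                contrast_frames.append(con)
        if prof_frames:
            _write(pd.concat(prof_frames, ignore_index=True),
                   "panel_profile.tsv")
        if contrast_frames:
            _write(pd.concat(contrast_frames, ignore_index=True),
                   "group_contrast.tsv")

        stage = "manifest"
        manifest = {
            "package": "brsgkit",
            "version": __version__,
            "seed": config.seed,
            "config": json.loads(config.model_dump_json()),
            "files": {p.name: _sha256(p) for p in sorted(written)},
        }
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc


def _region_sets(brsg: pd.DataFrame) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for _, row in brsg.iterrows():
        sets.setdefault(row["assigned_region"], []).append(row["gene"])
    return sets


def _samples_for(metadata: pd.DataFrame, region_label: str) -> list[str]:
    regions = region_label.split("/")
    return list(metadata.index[metadata["region"].isin(regions)])
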