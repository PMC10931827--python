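"""Synthetic FPKM matrices and scored interaction graphs with planted truth.

The expression generator emulates the study design the toolkit targets: five
brain regions, each sampled in three groups (control / aggressive / depressive)
of three animals, with gene-level log-normal baseline FPKM, multiplicative
log-normal measurement noise, and three kinds of planted signal —

* single-region genes elevated ``fold``-fold in one region,
* shared-pair genes elevated in both members of one designated region pair
  (the midbrain VTA/MRN situation), and
* group-effect genes elevated ``group_fold``-fold in designated groups,
  optionally restricted to a subset of regions.

The graph generator produces an Erdős–Rényi background with extra within-set
edges for planted modules, and assigns every edge a confidence score drawn
uniformly within one of the four standard tier bands so tier filtering is
exercised end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import DEFAULT_GROUPS, DEFAULT_REGIONS

#: Score bands (half-open) corresponding to the low/medium/high/highest
#: confidence tiers of scored interaction databases.
TIER_BANDS: tuple[tuple[float, float], ...] = (
    (0.150, 0.4),
    (0.4, 0.7),
    (0.7, 0.9),
    (0.9, 1.0),
)


@dataclass(frozen=True)
class SyntheticExpressionSpec:
    """Parameters of the synthetic expression experiment.

    Defaults encode the emulated design: 5 regions × 3 groups × 3 replicates,
    2000 genes, 20 planted single-region genes per region, 17 genes shared by
    the (MRN, VTA) pair, tenfold elevation, and 30% multiplicative noise.
    Baseline FPKM are log-normal (meanlog 2, sdlog 1.5), i.e. median ≈ 7 FPKM
    with a heavy right tail, as bulk RNA-seq FPKM distributions are.
    """

    n_genes: int = 2000
    regions: tuple[str, ...] = DEFAULT_REGIONS
    groups: tuple[str, ...] = DEFAULT_GROUPS
    replicates: int = 3
    baseline_log_mean: float = 2.0
    baseline_log_sd: float = 1.5
    n_single_region: int = 20
    n_shared_pair: int = 17
    shared_pair: tuple[str, str] = ("MRN", "VTA")
    fold: float = 10.0
    n_group_effect: int = 0
    group_fold: float = 2.0
    affected_groups: tuple[str, ...] = ("aggressive", "depressive")
    #: optional region restriction of the group effect (None = all regions),
    #: so e.g. a hypothalamic hormone elevation in affected groups can be
    #: emulated.
    group_effect_regions: tuple[str, ...] | None = None
    cv: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError("fold elevation must be >= 1")
        if self.cv < 0:
            raise ValueError("noise CV must be >= 0")
        if min(self.n_genes, self.n_single_region, self.n_shared_pair,
               self.n_group_effect, self.replicates) < 0:
            raise ValueError("counts must be non-negative")
        n_planted = (self.n_single_region * len(self.regions)
                     + self.n_shared_pair + self.n_group_effect)
        if n_planted > self.n_genes:
            raise ValueError(
                f"{n_planted} planted genes exceed n_genes={self.n_genes}"
            )
        for r in self.shared_pair:
            if r not in self.regions:
                raise ValueError(f"shared-pair region {r!r} not in regions")
        for g in self.affected_groups:
            if g not in self.groups:
                raise ValueError(f"affected group {g!r} not in groups")


@dataclass(frozen=True)
class SyntheticPpiSpec:
    """Parameters of the synthetic scored interaction graph."""

    background_prob: float = 0.02
    module_prob: float = 0.3
    #: sampling weight of each tier band for background / module edge scores
    background_band_weights: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    module_band_weights: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.background_prob, self.module_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("edge probabilities must be in [0, 1]")
        for w in (self.background_band_weights, self.module_band_weights):
            if len(w) != len(TIER_BANDS) or min(w) < 0 or sum(w) <= 0:
                raise ValueError("band weights must be non-negative, one per tier")


@dataclass
class GroundTruth:
    """Planted labels backing recovery checks.

    ``gene_labels`` maps every gene to one of ``background``,
    ``single-region:<R>``, ``shared-pair`` or ``group-effect`` (a partition).
    ``edge_modules`` maps planted module names to their gene sets.
    """

    gene_labels: pd.Series
    edge_modules: dict[str, frozenset[str]] = field(default_factory=dict)

    def genes_with_label(self, label: str) -> list[str]:
        return list(self.gene_labels.index[self.gene_labels == label])

    @property
    def single_region_genes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gene, lab in self.gene_labels.items():
            if lab.startswith("single-region:"):
                out.setdefault(lab.split(":", 1)[1], []).append(gene)
        return out

    @property
    def background_genes(self) -> list[str]:
        return self.genes_with_label("background")


def generate_expression(
    spec: SyntheticExpressionSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (matrix, metadata, truth) under ``spec``.

    A planted single-region gene has expectation ``fold × baseline`` in every
    sample of its target region and ``baseline`` elsewhere; shared-pair genes
    are elevated in both pair regions; group-effect genes are elevated
    ``group_fold``-fold in the affected groups.  Identical spec (incl. seed)
    gives identical output.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    samples, regions_col, groups_col = [], [], []
    for region in spec.regions:
        for group in spec.groups:
            for rep in range(1, spec.replicates + 1):
                samples.append(f"{region}_{group}_{rep}")
                regions_col.append(region)
                groups_col.append(group)
    metadata = pd.DataFrame(
        {"region": regions_col, "group": groups_col},
        index=pd.Index(samples, name="sample_id"),
    )

    labels = np.array(["background"] * spec.n_genes, dtype=object)
    cursor = 0
    for region in spec.regions:
        labels[cursor:cursor + spec.n_single_region] = f"single-region:{region}"
        cursor += spec.n_single_region
    labels[cursor:cursor + spec.n_shared_pair] = "shared-pair"
    cursor += spec.n_shared_pair
    labels[cursor:cursor + spec.n_group_effect] = "group-effect"

    baseline = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd,
                             size=spec.n_genes)
    effect = np.ones((spec.n_genes, len(samples)))
    region_arr = np.asarray(regions_col)
    group_arr = np.asarray(groups_col)
    for i, lab in enumerate(labels):
        if lab.startswith("single-region:"):
            effect[i, region_arr == lab.split(":", 1)[1]] = spec.fold
        elif lab == "shared-pair":
            effect[i, np.isin(region_arr, spec.shared_pair)] = spec.fold
        elif lab == "group-effect":
            mask = np.isin(group_arr, spec.affected_groups)
            if spec.group_effect_regions is not None:
                mask &= np.isin(region_arr, spec.group_effect_regions)
            effect[i, mask] = spec.group_fold

    if spec.cv > 0:
        # log-normal multiplicative noise with unit mean and the requested CV
        sigma = np.sqrt(np.log1p(spec.cv ** 2))
        noise = rng.lognormal(-sigma ** 2 / 2, sigma, size=effect.shape)
    else:
        noise = 1.0
    values = baseline[:, None] * effect * noise
    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                          columns=samples)
    truth = GroundTruth(gene_labels=pd.Series(labels, index=genes, name="label"))
    return matrix, metadata, truth


def generate_ppi(
    spec: SyntheticPpiSpec,
    genes: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]] | None = None,
) -> tuple[nx.Graph, GroundTruth]:
    """Generate a scored graph over ``genes`` with planted dense modules.

    Background edges appear independently with ``background_prob``;
    additionally each within-set pair of every planted module appears with
    ``module_prob`` (union; a collision keeps the module score draw).
    """
    gene_sets = dict(gene_sets or {})
    universe = set(genes)
    for name, members in gene_sets.items():
        unknown = set(members) - universe
        if unknown:
            raise ValueError(
                f"module {name!r} contains genes outside the universe: "
                f"{sorted(unknown)[:5]}"
            )
    rng = np.random.default_rng(spec.seed)
    graph = nx.Graph()
    graph.add_nodes_from(genes)

    def _draw_score(weights: Sequence[float]) -> float:
        w = np.asarray(weights, dtype=float)
        band = TIER_BANDS[rng.choice(len(TIER_BANDS), p=w / w.sum())]
        return float(rng.uniform(band[0], band[1]))

    gene_list = list(genes)
    n = len(gene_list)
    if spec.background_prob > 0:
        iu = np.triu_indices(n, k=1)
        hit = rng.random(len(iu[0])) < spec.background_prob
        for a, b in zip(iu[0][hit], iu[1][hit]):
            graph.add_edge(gene_list[a], gene_list[b],
                           score=_draw_score(spec.background_band_weights))
    for members in gene_sets.values():
        mem = list(members)
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                if rng.random() < spec.module_prob:
                    graph.add_edge(mem[i], mem[j],
                                   score=_draw_score(spec.module_band_weights))
    labels = pd.Series("background", index=list(genes), name="label")
    truth = GroundTruth(
        gene_labels=labels,
        edge_modules={k: frozenset(v) for k, v in gene_sets.items()},
    )
    return graph, truth


def write_truth_tsv(truth: GroundTruth, path) -> None:
    truth.gene_labels.rename_axis("gene_id").reset_index().to_csv(
        path, sep="\t", index=False
    )
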