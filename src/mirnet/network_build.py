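"""Construction of rule-defined miRNA networks and cluster detection.

Every network is an undirected simple graph whose nodes are mature miRNA
ids.  Three rule families are implemented:

* seed networks — edges between matures sharing the identical 6-mer seed,
  so each connected component is a clique (a miRNA family);
* genomic-distance networks — edges between matures whose precursor loci
  lie on the same chromosome closer than a bp threshold (strict), which
  approximates polycistronic clusters at 2 kb and tolerates genomic
  reorganization at 50 kb;
* target-overlap networks — edges between matures sharing more than a
  threshold fraction of predicted mRNA targets.

Plus the two derived variants: dropping components smaller than a minimum
size, and a single-pass minimum-degree filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import networkx as nx

from mirnet.annotation_io import (
    MatureMiRNA,
    PrecursorLocus,
    TargetPredictionTable,
    normalize_mirna_id,
)

logger = logging.getLogger(__name__)

RULE_NAMES = (
    "Seed2_7",
    "Genomic_Distance_2k",
    "Genomic_Distance_50k",
    "Genomic_Distance_50k_clusters_3+",
    "Diana50",
    "TargetScan54",
    "DianaTarBase50",
    "TargetScan54_degree_10+",
    "custom",
)


@dataclass
class MiRNANetwork:
    """An undirected simple graph of mature-miRNA nodes plus its rule."""

    rule_name: str
    threshold: float | None
    species_code: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def validate(self) -> None:
        assert not any(u == v for u, v in self.graph.edges), "self-loop found"

    def with_graph(self, graph: nx.Graph, rule_name: str | None = None) -> "MiRNANetwork":
        return MiRNANetwork(
            rule_name=rule_name or self.rule_name,
            threshold=self.threshold,
            species_code=self.species_code,
            graph=graph,
        )


@dataclass
class GenomicCluster:
    """A connected component of a genomic-distance network with its bp envelope."""

    cluster_id: str
    member_ids: set[str]
    chrom: str
    span_start: int
    span_end: int

    @property
    def size(self) -> int:
        return len(self.member_ids)

    @property
    def span_bp(self) -> int:
        return self.span_end - self.span_start


def _species(matures: Sequence[MatureMiRNA]) -> str:
    codes = {m.species_code for m in matures}
    return codes.pop() if len(codes) == 1 else "mixed"


def build_seed_network(matures: Sequence[MatureMiRNA]) -> MiRNANetwork:
    """Connect every pair of matures with the identical seed.

    By construction each connected component is a clique: the matures of
    one family (one seed).
    """
    g = nx.Graph()
    by_seed: dict[str, list[str]] = {}
    for m in matures:
        g.add_node(m.id, seed=m.seed)
        by_seed.setdefault(m.seed, []).append(m.id)
    for members in by_seed.values():
        members = sorted(members)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                g.add_edge(a, b)
    net = MiRNANetwork("Seed2_7", None, _species(matures), g)
    logger.info("Seed2_7: %d nodes, %d edges", net.n_nodes(), net.n_edges())
    return net


def interval_gap(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Gap in bp between two 0-based half-open intervals; 0 if they touch or overlap."""
    return max(start_b - end_a, start_a - end_b, 0)


def build_genomic_network(
    matures: Sequence[MatureMiRNA],
    loci: Sequence[PrecursorLocus],
    threshold_bp: int,
    same_strand_only: bool = False,
) -> MiRNANetwork:
    """Connect matures whose precursor loci are closer than ``threshold_bp``.

    Two matures are linked iff some locus of one and some locus of the
    other sit on the same chromosome with an inter-interval gap strictly
    below the threshold; overlapping or book-ended loci have gap 0, so
    matures sharing a precursor are always linked.  Matures with multiple
    loci use the minimum gap over all locus pairs.  Matures without any
    locus are excluded (and logged).  Strand is ignored unless
    ``same_strand_only`` is set.
    """
    if threshold_bp <= 0:
        raise ValueError("threshold_bp must be positive")
    by_norm = {m.norm_id: m for m in matures}
    # (mature_id, locus) placements, one per copy of the mature
    placements: dict[str, list[tuple[str, PrecursorLocus]]] = {}
    located: set[str] = set()
    for locus in loci:
        for mature_id in locus.mature_ids:
            m = by_norm.get(normalize_mirna_id(mature_id))
            if m is None:
                continue
            placements.setdefault(locus.chrom, []).append((m.id, locus))
            located.add(m.id)
    skipped = [m.id for m in matures if m.id not in located]
    if skipped:
        logger.info(
            "genomic network: %d mature(s) without loci excluded (first: %s)",
            len(skipped),
            skipped[0],
        )
    g = nx.Graph()
    g.add_nodes_from(sorted(located))
    for chrom, placed in placements.items():
        placed.sort(key=lambda t: (t[1].start, t[1].end, t[0]))
        for i, (id_a, loc_a) in enumerate(placed):
            for id_b, loc_b in placed[i + 1 :]:
                if loc_b.start - loc_a.end >= threshold_bp:
                    break  # starts are sorted: every later locus is at least this far
                if id_a == id_b:
                    continue
                if same_strand_only and loc_a.strand != loc_b.strand:
                    continue
                if interval_gap(loc_a.start, loc_a.end, loc_b.start, loc_b.end) < threshold_bp:
                    g.add_edge(id_a, id_b)
    rule = {2000: "Genomic_Distance_2k", 50000: "Genomic_Distance_50k"}.get(threshold_bp, "custom")
    net = MiRNANetwork(rule, float(threshold_bp), _species(matures), g)
    logger.info("%s: %d nodes, %d edges", rule, net.n_nodes(), net.n_edges())
    return net


def connected_components(network: MiRNANetwork) -> list[set[str]]:
    """Components ordered by size (desc), then by lexicographic smallest member."""
    comps = [set(c) for c in nx.connected_components(network.graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def filter_clusters_min_size(network: MiRNANetwork, min_size: int = 3) -> MiRNANetwork:
    """Keep only nodes in connected components of at least ``min_size`` nodes."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    keep: set[str] = set()
    for comp in nx.connected_components(network.graph):
        if len(comp) >= min_size:
            keep |= comp
    sub = network.graph.subgraph(keep).copy()
    name = (
        f"{network.rule_name}_clusters_{min_size}+"
        if not network.rule_name.endswith("+")
        else network.rule_name
    )
    if network.rule_name == "Genomic_Distance_50k" and min_size == 3:
        name = "Genomic_Distance_50k_clusters_3+"
    return network.with_graph(sub, rule_name=name)


def overlap_coefficient(a: set[str], b: set[str]) -> float:
    """|A ∩ B| / min(|A|, |B|); 0 when either set is empty."""
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def jaccard_index(a: set[str], b: set[str]) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def build_target_overlap_network(
    targets: TargetPredictionTable,
    threshold_fraction: float,
    overlap_measure: Literal["overlap", "jaccard"] = "overlap",
    rule_name: str = "custom",
    species_code: str = "unknown",
) -> MiRNANetwork:
    """Connect matures sharing more than ``threshold_fraction`` of targets.

    The default measure is the min-denominator overlap coefficient
    |A∩B| / min(|A|,|B|); Jaccard is available as an option.  The
    inequality is strict.  miRNAs with empty target sets stay as isolated
    nodes.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    measure = {"overlap": overlap_coefficient, "jaccard": jaccard_index}[overlap_measure]
    g = nx.Graph()
    ids = sorted(targets.targets)
    g.add_nodes_from(ids)
    for i, a in enumerate(ids):
        ta = targets.targets[a]
        if not ta:
            continue
        for b in ids[i + 1 :]:
            tb = targets.targets[b]
            if tb and measure(ta, tb) > threshold_fraction:
                g.add_edge(a, b)
    net = MiRNANetwork(rule_name, threshold_fraction, species_code, g)
    logger.info(
        "target overlap (%s > %.2f): %d nodes, %d edges",
        overlap_measure,
        threshold_fraction,
        net.n_nodes(),
        net.n_edges(),
    )
    return net


def filter_min_degree(network: MiRNANetwork, min_degree: int = 10) -> MiRNANetwork:
    """Drop nodes whose degree in the INPUT graph is below ``min_degree``.

    Single pass — degrees are taken once from the input network, so this is
    not an iterated k-core; the surviving subgraph keeps its layout
    semantics.
    """
    if min_degree < 0:
        raise ValueError("min_degree must be >= 0")
    keep = [n for n, d in network.graph.degree if d >= min_degree]
    sub = network.graph.subgraph(keep).copy()
    name = network.rule_name
    if name == "TargetScan54" and min_degree == 10:
        name = "TargetScan54_degree_10+"
    return network.with_graph(sub, rule_name=name)


def genomic_clusters(
    network: MiRNANetwork, loci: Sequence[PrecursorLocus]
) -> list[GenomicCluster]:
    """One :class:`GenomicCluster` per component, with its bp envelope.

    The span is max end − min start over all member loci.  A component
    whose loci span several chromosomes is impossible when the network was
    built by :func:`build_genomic_network`; it trips an assertion.
    """
    loci_by_mature: dict[str, list[PrecursorLocus]] = {}
    for locus in loci:
        for mature_id in locus.mature_ids:
            loci_by_mature.setdefault(normalize_mirna_id(mature_id), []).append(locus)
    clusters: list[GenomicCluster] = []
    for comp in connected_components(network):
        member_loci = [
            locus for mid in comp for locus in loci_by_mature.get(normalize_mirna_id(mid), [])
        ]
        if not member_loci:
            continue
        chroms = {locus.chrom for locus in member_loci}
        assert len(chroms) == 1, (
            f"component {sorted(comp)[:3]}... spans chromosomes {sorted(chroms)}; "
            "not a genomic-distance component"
        )
        clusters.append(
            GenomicCluster(
                cluster_id="",
                member_ids=set(comp),
                chrom=chroms.pop(),
                span_start=min(locus.start for locus in member_loci),
                span_end=max(locus.end for locus in member_loci),
            )
        )
    clusters.sort(key=lambda c: (-c.size, c.chrom, c.span_start))
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = f"cluster_{i:03d}"
    return clusters
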