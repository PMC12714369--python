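"""Cross-species network projection and edge-conservation scoring.

A network in species A is projected into species B through an ortholog
map by replacing both endpoints of each edge with their (optionally
syntenic) orthologs, expanding one-to-many relations as a Cartesian
product. Conservation between two experimentally tested networks counts
an A edge as *tested* when both endpoints have at least one ortholog
present among B's nodes (i.e. the interaction was assayable in both
screens) and *conserved* when any ortholog combination is an edge of B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .exceptions import ConfigurationError, DomainError
from .network import ROLE_DUAL, ROLE_PROMOTER, ROLE_TF, NetworkNode, RegulatoryNetwork

RELATIONS = ("one2one", "one2many", "many2many")


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    relation: str = "one2one"
    syntenic: bool = True


class OrthologMap:
    """Two-way gene pairing between species A and species B."""

    def __init__(
        self,
        pairs: list[OrthologPair],
        species_a: str = "speciesA",
        species_b: str = "speciesB",
    ) -> None:
        self.species_a = species_a
        self.species_b = species_b
        self.pairs = list(dict.fromkeys(pairs))  # unique, order-preserving
        self._a2b: dict[str, list[OrthologPair]] = {}
        self._b2a: dict[str, list[OrthologPair]] = {}
        for p in self.pairs:
            self._a2b.setdefault(p.gene_a, []).append(p)
            self._b2a.setdefault(p.gene_b, []).append(p)

    def __len__(self) -> int:
        return len(self.pairs)

    def orthologs_of_a(self, gene_a: str, require_syntenic: bool = False) -> list[str]:
        return [
            p.gene_b
            for p in self._a2b.get(gene_a, ())
            if p.syntenic or not require_syntenic
        ]

    def orthologs_of_b(self, gene_b: str, require_syntenic: bool = False) -> list[str]:
        return [
            p.gene_a
            for p in self._b2a.get(gene_b, ())
            if p.syntenic or not require_syntenic
        ]


def read_ortholog_map(
    source, species_a: str = "speciesA", species_b: str = "speciesB"
) -> OrthologMap:
    """Read an ortholog TSV: gene_a, gene_b, relation, syntenic (0/1)."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    required = {"gene_a", "gene_b"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"ortholog map is missing columns: {sorted(missing)}")
    pairs = []
    for rec in df.to_dict("records"):
        relation = str(rec.get("relation", "one2one") or "one2one")
        if relation not in RELATIONS:
            raise ConfigurationError(f"unknown homology relation {relation!r}")
        syn = str(rec.get("syntenic", "1") or "1") in ("1", "true", "True")
        pairs.append(OrthologPair(str(rec["gene_a"]), str(rec["gene_b"]), relation, syn))
    return OrthologMap(pairs, species_a, species_b)


def write_ortholog_map(omap: OrthologMap, path) -> None:
    pd.DataFrame(
        [
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "relation": p.relation,
                "syntenic": int(p.syntenic),
            }
            for p in omap.pairs
        ]
    ).to_csv(path, sep="\t", index=False)


@dataclass
class ProjectionResult:
    network: RegulatoryNetwork
    n_source_edges: int
    n_projected_edges: int
    n_dropped_edges: int  # source edges with an unmapped endpoint


def project_network(
    net: RegulatoryNetwork,
    omap: OrthologMap,
    require_syntenic: bool = True,
    name: str | None = None,
) -> ProjectionResult:
    """Project each edge through the ortholog map (Cartesian expansion).

    Edges whose TF or promoter has no (syntenic) ortholog are dropped
    and counted; duplicate projected edges collapse; projected edges
    carry provenance "projected".
    """
    if net.species and omap.species_a and net.species != omap.species_a:
        raise ConfigurationError(
            f"network species {net.species!r} does not match ortholog map "
            f"species_a {omap.species_a!r}"
        )
    proj = RegulatoryNetwork(
        name=name or f"{net.name}_projected", species=omap.species_b
    )
    dropped = 0
    for e in net.edges:
        tfs_b = omap.orthologs_of_a(e.tf_id, require_syntenic)
        proms_b = omap.orthologs_of_a(e.promoter_id, require_syntenic)
        if not tfs_b or not proms_b:
            dropped += 1
            continue
        for tb in tfs_b:
            for pb in proms_b:
                proj.add_edge(tb, pb, provenance="projected")
    # carry family/process labels onto projected nodes where unambiguous
    for node in net.nodes.values():
        for gb in omap.orthologs_of_a(node.node_id, require_syntenic):
            if gb in proj.nodes:
                tgt = proj.nodes[gb]
                if node.family and not tgt.family and tgt.is_tf:
                    tgt.family = node.family
                if node.process and not tgt.process:
                    tgt.process = node.process
    return ProjectionResult(proj, net.n_edges, proj.n_edges, dropped)


@dataclass
class ConservationReport:
    tested_a: int
    conserved_a: int
    tested_b: int
    conserved_b: int
    conserved_edges_a: list[tuple[str, str]] = field(default_factory=list)
    conserved_edges_b: list[tuple[str, str]] = field(default_factory=list)

    @property
    def fraction_a(self) -> float:
        return self.conserved_a / self.tested_a if self.tested_a else 0.0

    @property
    def fraction_b(self) -> float:
        return self.conserved_b / self.tested_b if self.tested_b else 0.0


def _direction(
    edges: list[tuple[str, str]],
    partner_nodes: set[str],
    partner_edges: set[tuple[str, str]],
    ortho,
) -> tuple[int, list[tuple[str, str]]]:
    tested = 0
    conserved: list[tuple[str, str]] = []
    for tf, prom in edges:
        tf_orth = [g for g in ortho(tf) if g in partner_nodes]
        prom_orth = [g for g in ortho(prom) if g in partner_nodes]
        if not tf_orth or not prom_orth:
            continue
        tested += 1
        if any((t, p) in partner_edges for t in tf_orth for p in prom_orth):
            conserved.append((tf, prom))
    return tested, conserved


def conserved_edges(
    net_a: RegulatoryNetwork,
    net_b: RegulatoryNetwork,
    omap: OrthologMap,
    require_syntenic: bool = False,
) -> ConservationReport:
    """Score edge conservation between two networks in both directions."""
    if len(omap) == 0:
        raise DomainError("ortholog map is empty")
    nodes_a = set(net_a.nodes)
    nodes_b = set(net_b.nodes)
    pairs_a = [(e.tf_id, e.promoter_id) for e in net_a.edges]
    pairs_b = [(e.tf_id, e.promoter_id) for e in net_b.edges]
    tested_a, cons_a = _direction(
        pairs_a, nodes_b, net_b.edge_pairs,
        lambda g: omap.orthologs_of_a(g, require_syntenic),
    )
    tested_b, cons_b = _direction(
        pairs_b, nodes_a, net_a.edge_pairs,
        lambda g: omap.orthologs_of_b(g, require_syntenic),
    )
    return ConservationReport(
        tested_a=tested_a,
        conserved_a=len(cons_a),
        tested_b=tested_b,
        conserved_b=len(cons_b),
        conserved_edges_a=cons_a,
        conserved_edges_b=cons_b,
    )


@dataclass
class MergeResult:
    network: RegulatoryNetwork
    edge_sources: dict[tuple[str, str], str]  # a_only / b_only / both

    @property
    def counts(self) -> dict[str, int]:
        out = {"a_only": 0, "b_only": 0, "both": 0}
        for v in self.edge_sources.values():
            out[v] += 1
        return out


def merge_networks(
    net_a_projected: RegulatoryNetwork,
    net_b: RegulatoryNetwork,
    name: str = "merged",
) -> MergeResult:
    """Union of two same-species networks with per-edge source flags."""
    merged = RegulatoryNetwork(name=name, species=net_b.species)
    sources: dict[tuple[str, str], str] = {}
    for e in net_a_projected.edges:
        merged.add_edge(e.tf_id, e.promoter_id, provenance=e.provenance)
        sources[e.pair] = "a_only"
    for e in net_b.edges:
        if e.pair in sources:
            sources[e.pair] = "both"
        else:
            merged.add_edge(e.tf_id, e.promoter_id, provenance=e.provenance)
            sources[e.pair] = "b_only"
    # preserve richer node metadata from either input
    for src in (net_a_projected, net_b):
        for node in src.nodes.values():
            tgt = merged.nodes.get(node.node_id)
            if tgt is None:
                continue
            if node.family and not tgt.family:
                tgt.family = node.family
            if node.process and not tgt.process:
                tgt.process = node.process
    return MergeResult(merged, sources)
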