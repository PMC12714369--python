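"""Data model and I/O for protein-DNA interaction (PDI) networks.

A regulatory network here is a directed graph whose edges run from a
transcription factor (TF) to a gene promoter, typically established by a
yeast one-hybrid screen. Nodes live in a single gene-identifier space: a
gene can act as a TF (it has outgoing edges), as a promoter (incoming
edges), or as both ("TF_and_promoter" — the diamond nodes of network
figures). Degree statistics follow the field convention: indegree of a
gene is the number of distinct TFs binding its promoter, outdegree the
number of distinct promoters its TF product binds.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .exceptions import ConfigurationError, EmptyInputError

logger = logging.getLogger(__name__)

ROLE_TF = "TF"
ROLE_PROMOTER = "promoter"
ROLE_DUAL = "TF_and_promoter"
VALID_ROLES = frozenset({ROLE_TF, ROLE_PROMOTER, ROLE_DUAL})

#: default mapping of logical fields to edge-list column names
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "tf": "tf",
    "promoter": "promoter",
    "family": "family",
    "process": "process",
    "provenance": "provenance",
}


@dataclass
class NetworkNode:
    """A gene participating in a PDI network.

    ``family`` is a TF-family label and is only meaningful for TF-capable
    nodes; ``process`` is a free-text functional-module label (e.g.
    "Nitrogen transporter") used in module summaries.
    """

    node_id: str
    display_name: str = ""
    role: str = ROLE_TF
    family: str = ""
    species: str = ""
    process: str = ""

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ConfigurationError(
                f"invalid role {self.role!r} for node {self.node_id!r}; "
                f"expected one of {sorted(VALID_ROLES)}"
            )

    @property
    def is_tf(self) -> bool:
        return self.role in (ROLE_TF, ROLE_DUAL)

    @property
    def is_promoter(self) -> bool:
        return self.role in (ROLE_PROMOTER, ROLE_DUAL)


@dataclass(frozen=True)
class PDIEdge:
    """A directed TF -> promoter interaction."""

    tf_id: str
    promoter_id: str
    provenance: str = ""

    @property
    def pair(self) -> tuple[str, str]:
        return (self.tf_id, self.promoter_id)


class RegulatoryNetwork:
    """Directed TF->promoter interaction graph with node metadata.

    Edges are unique (tf, promoter) pairs; insertion order is preserved.
    """

    def __init__(self, name: str = "network", species: str = "") -> None:
        self.name = name
        self.species = species
        self.nodes: dict[str, NetworkNode] = {}
        self._edges: dict[tuple[str, str], PDIEdge] = {}

    # -- construction -------------------------------------------------

    def add_node(self, node: NetworkNode) -> None:
        self.nodes[node.node_id] = node

    def ensure_node(self, node_id: str, role: str) -> NetworkNode:
        """Add ``node_id`` with ``role``, widening an existing role to dual
        when the node participates on both sides of edges."""
        existing = self.nodes.get(node_id)
        if existing is None:
            node = NetworkNode(node_id=node_id, role=role, species=self.species)
            self.nodes[node_id] = node
            return node
        if existing.role != role and existing.role != ROLE_DUAL:
            existing.role = ROLE_DUAL
        return existing

    def add_edge(self, tf_id: str, promoter_id: str, provenance: str = "") -> bool:
        """Add an edge, inferring/widening endpoint roles.

        Returns True if the edge was new, False if it was a duplicate.
        """
        key = (tf_id, promoter_id)
        self.ensure_node(tf_id, ROLE_TF)
        self.ensure_node(promoter_id, ROLE_PROMOTER)
        if key in self._edges:
            return False
        self._edges[key] = PDIEdge(tf_id, promoter_id, provenance)
        return True

    # -- access -------------------------------------------------------

    @property
    def edges(self) -> list[PDIEdge]:
        return list(self._edges.values())

    @property
    def edge_pairs(self) -> set[tuple[str, str]]:
        return set(self._edges)

    def has_edge(self, tf_id: str, promoter_id: str) -> bool:
        return (tf_id, promoter_id) in self._edges

    def __len__(self) -> int:
        return len(self._edges)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    @property
    def tf_ids(self) -> list[str]:
        return [n.node_id for n in self.nodes.values() if n.is_tf]

    @property
    def promoter_ids(self) -> list[str]:
        return [n.node_id for n in self.nodes.values() if n.is_promoter]

    def out_neighbors(self) -> dict[str, set[str]]:
        """tf_id -> set of promoter_ids it binds."""
        out: dict[str, set[str]] = {}
        for tf, prom in self._edges:
            out.setdefault(tf, set()).add(prom)
        return out

    def in_neighbors(self) -> dict[str, set[str]]:
        """promoter_id -> set of tf_ids binding it."""
        inn: dict[str, set[str]] = {}
        for tf, prom in self._edges:
            inn.setdefault(prom, set()).add(tf)
        return inn

    def validate(self) -> None:
        """Check structural invariants; raise ConfigurationError on failure."""
        for tf, prom in self._edges:
            if tf not in self.nodes or prom not in self.nodes:
                raise ConfigurationError(f"edge ({tf}, {prom}) has missing endpoint")
            if not self.nodes[tf].is_tf:
                raise ConfigurationError(f"edge source {tf!r} is not TF-capable")
            if not self.nodes[prom].is_promoter:
                raise ConfigurationError(f"edge target {prom!r} is not promoter-capable")
        for node in self.nodes.values():
            if node.family and not node.is_tf:
                raise ConfigurationError(
                    f"node {node.node_id!r} has family {node.family!r} but is not a TF"
                )

    def copy(self, name: str | None = None) -> "RegulatoryNetwork":
        out = RegulatoryNetwork(name or self.name, self.species)
        for node in self.nodes.values():
            out.add_node(replace(node))
        for edge in self._edges.values():
            out._edges[edge.pair] = edge
        return out


@dataclass
class DegreeRecord:
    node_id: str
    indegree: int
    outdegree: int


# ---------------------------------------------------------------------
# I/O


def _resolve_columns(df: pd.DataFrame, column_map: Mapping[str, str] | None):
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    for logical in ("tf", "promoter"):
        if cmap[logical] not in df.columns:
            raise ConfigurationError(
                f"required column {cmap[logical]!r} (for {logical!r}) not found; "
                f"available: {list(df.columns)}"
            )
    return cmap


def read_edge_list(
    source,
    column_map: Mapping[str, str] | None = None,
    name: str = "network",
    species: str = "",
    node_attributes: pd.DataFrame | None = None,
    provenance: str = "",
) -> RegulatoryNetwork:
    """Build a deduplicated network from a TSV edge list.

    ``source`` is a path or text stream with a header row. Roles are
    inferred from edge participation (both sides -> TF_and_promoter) and
    may be overridden by ``node_attributes`` (columns node_id, role,
    family, process). Duplicate (tf, promoter) rows collapse to one edge
    with a logged count; rows with blank identifiers are rejected with a
    warning.
    """
    try:
        df = pd.read_csv(source, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyInputError("edge list is empty") from None
    if df.empty:
        raise EmptyInputError("edge list has a header but no rows")
    cmap = _resolve_columns(df, column_map)

    net = RegulatoryNetwork(name=name, species=species)
    n_dup = 0
    n_blank = 0
    fam_col = cmap["family"] if cmap["family"] in df.columns else None
    proc_col = cmap["process"] if cmap["process"] in df.columns else None
    prov_col = cmap["provenance"] if cmap["provenance"] in df.columns else None
    for row in df.itertuples(index=False):
        rec = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        tf = str(rec.get(cmap["tf"], "") or "").strip()
        prom = str(rec.get(cmap["promoter"], "") or "").strip()
        if not tf or not prom or tf == "nan" or prom == "nan":
            n_blank += 1
            continue
        prov = provenance
        if prov_col:
            v = rec.get(prov_col)
            if isinstance(v, str) and v.strip() and v != "nan":
                prov = v.strip()
        if not net.add_edge(tf, prom, provenance=prov):
            n_dup += 1
            continue
        if fam_col:
            v = rec.get(fam_col)
            if isinstance(v, str) and v.strip() and v != "nan":
                net.nodes[tf].family = v.strip()
        if proc_col:
            v = rec.get(proc_col)
            if isinstance(v, str) and v.strip() and v != "nan":
                net.nodes[prom].process = v.strip()
    if n_blank:
        logger.warning("rejected %d rows with blank identifiers", n_blank)
    if n_dup:
        logger.warning("collapsed %d duplicate edge rows", n_dup)
    net.duplicate_rows_collapsed = n_dup  # type: ignore[attr-defined]
    net.blank_rows_rejected = n_blank  # type: ignore[attr-defined]
    if node_attributes is not None:
        apply_node_attributes(net, node_attributes)
    net.validate()
    return net


def read_node_attributes(source) -> pd.DataFrame:
    """Read a node-attribute TSV (node_id, role, family, process)."""
    df = pd.read_csv(source, sep="\t", dtype=str).fillna("")
    if "node_id" not in df.columns:
        raise ConfigurationError("node attribute table requires a 'node_id' column")
    return df


def apply_node_attributes(net: RegulatoryNetwork, attrs: pd.DataFrame) -> None:
    """Override inferred roles/metadata from an attribute table."""
    for rec in attrs.to_dict("records"):
        nid = str(rec.get("node_id", "")).strip()
        if not nid or nid not in net.nodes:
            continue
        node = net.nodes[nid]
        for fld in ("role", "family", "process", "display_name", "species"):
            val = str(rec.get(fld, "") or "").strip()
            if val:
                if fld == "role" and val not in VALID_ROLES:
                    raise ConfigurationError(f"invalid role {val!r} for node {nid!r}")
                setattr(node, fld, val)


def write_network(net: RegulatoryNetwork, path, fmt: str = "tsv") -> None:
    """Serialize a network as tsv, sif (relation token "pd"), or graphml."""
    path = Path(path)
    if fmt == "tsv":
        rows = [
            {
                "tf": e.tf_id,
                "promoter": e.promoter_id,
                "family": net.nodes[e.tf_id].family,
                "process": net.nodes[e.promoter_id].process,
                "provenance": e.provenance,
            }
            for e in net.edges
        ]
        pd.DataFrame(rows, columns=["tf", "promoter", "family", "process", "provenance"]).to_csv(
            path, sep="\t", index=False
        )
    elif fmt == "sif":
        with open(path, "w") as fh:
            for e in net.edges:
                fh.write(f"{e.tf_id}\tpd\t{e.promoter_id}\n")
    elif fmt == "graphml":
        g = to_networkx(net)
        nx.write_graphml(g, path)
    else:
        raise ConfigurationError(f"unsupported network format {fmt!r}")


def to_networkx(net: RegulatoryNetwork) -> nx.DiGraph:
    """Export as a networkx DiGraph with role/family node attributes."""
    g = nx.DiGraph(name=net.name)
    for node in net.nodes.values():
        g.add_node(
            node.node_id,
            role=node.role,
            family=node.family,
            process=node.process,
            display_name=node.display_name,
        )
    for e in net.edges:
        g.add_edge(e.tf_id, e.promoter_id, provenance=e.provenance)
    return g


# ---------------------------------------------------------------------
# Degree statistics


def degree_table(net: RegulatoryNetwork) -> pd.DataFrame:
    """One row per node with indegree/outdegree over distinct partners."""
    out = net.out_neighbors()
    inn = net.in_neighbors()
    rows = [
        {
            "node_id": nid,
            "indegree": len(inn.get(nid, ())),
            "outdegree": len(out.get(nid, ())),
        }
        for nid in sorted(net.nodes)
    ]
    return pd.DataFrame(rows, columns=["node_id", "indegree", "outdegree"])


@dataclass
class HubReport:
    """Promoters/TFs whose connectivity exceeds strict thresholds."""

    indegree_threshold: int
    outdegree_threshold: int
    hub_promoters: list[tuple[str, int]] = field(default_factory=list)
    hub_tfs: list[tuple[str, int]] = field(default_factory=list)
    n_promoters_at_or_below: int = 0
    n_tfs_at_or_below: int = 0


def hub_report(
    net: RegulatoryNetwork, indegree_threshold: int = 0, outdegree_threshold: int = 0
) -> HubReport:
    """Promoters with indegree > threshold and TFs with outdegree > threshold,
    plus complement counts (nodes at or below each threshold)."""
    if indegree_threshold < 0 or outdegree_threshold < 0:
        raise ConfigurationError("thresholds must be >= 0")
    deg = degree_table(net)
    deg = deg.set_index("node_id")
    rep = HubReport(indegree_threshold, outdegree_threshold)
    for nid in sorted(net.promoter_ids):
        d = int(deg.loc[nid, "indegree"])
        if d > indegree_threshold:
            rep.hub_promoters.append((nid, d))
        else:
            rep.n_promoters_at_or_below += 1
    for nid in sorted(net.tf_ids):
        d = int(deg.loc[nid, "outdegree"])
        if d > outdegree_threshold:
            rep.hub_tfs.append((nid, d))
        else:
            rep.n_tfs_at_or_below += 1
    rep.hub_promoters.sort(key=lambda t: (-t[1], t[0]))
    rep.hub_tfs.sort(key=lambda t: (-t[1], t[0]))
    return rep


def network_from_edges(
    edges: Iterable[tuple[str, str]], name: str = "network", species: str = ""
) -> RegulatoryNetwork:
    """Convenience constructor from (tf, promoter) pairs."""
    net = RegulatoryNetwork(name=name, species=species)
    for tf, prom in edges:
        net.add_edge(tf, prom)
    return net


def network_to_tsv_string(net: RegulatoryNetwork) -> str:
    buf = io.StringIO()
    rows = [{"tf": e.tf_id, "promoter": e.promoter_id} for e in net.edges]
    pd.DataFrame(rows, columns=["tf", "promoter"]).to_csv(buf, sep="\t", index=False)
    return buf.getvalue()
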