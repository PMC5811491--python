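"""Protein-protein interaction networks and guilt-by-association prediction.

The workflow mirrors the standard comorbidity network-medicine recipe:

1. clean a pooled physical-interaction edge list (drop self-interactions,
   collapse redundant unordered pairs);
2. map each disease's genes onto the network ("seed nodes") and extract a
   disease-specific subnetwork of the seeds plus their first neighbors;
3. intersect the two disease subnetworks into a shared subnetwork;
4. rank non-disease genes by how many of the diseases' common genes they
   directly interact with, and call those with degree >= 5 new candidates
   (guilt by association).

Interaction metadata (detection method, publication) is ignored: an edge is
an unordered pair of gene symbols. By default a disease subnetwork contains
only edges incident to at least one seed; the induced alternative (which
additionally keeps neighbor-neighbor edges) is available for sensitivity
analysis.
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Collection, Iterable
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .catalog import GeneSet, normalize_symbol
from .errors import (
    EmptyInputError,
    EmptyIntersectionError,
    MalformedRecordError,
    UnknownNodeError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Edge",
    "RawEdgeList",
    "InteractionNetwork",
    "Subnetwork",
    "SharedSubnetwork",
    "Candidate",
    "CandidateRanking",
    "read_edge_list",
    "clean_network",
    "extract_disease_subnetwork",
    "intersect_subnetworks",
    "degree_to_targets",
    "predict_candidates",
    "write_edge_list",
]

#: canonical undirected edge: a sorted 2-tuple of symbols
Edge = tuple[str, str]

EDGE_MODES = ("seed-incident", "induced")


def canonical_edge(u: str, v: str) -> Edge:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class RawEdgeList:
    """Interaction records as parsed, before cleaning: duplicates and
    self-interactions are retained so their removal can be reported."""

    records: tuple[tuple[str, str], ...]

    def __len__(self) -> int:
        return len(self.records)


class InteractionNetwork:
    """A simple undirected interaction network.

    Invariants: no self-loops, no duplicate unordered pairs, no isolated
    nodes (every node has at least one edge).
    """

    def __init__(self, graph: nx.Graph) -> None:
        loops = list(nx.selfloop_edges(graph))
        if loops:
            raise MalformedRecordError(f"network contains self-loops, e.g. {loops[:3]}")
        isolated = [n for n, d in graph.degree() if d == 0]
        if isolated:
            raise MalformedRecordError(
                f"network contains isolated node(s), e.g. {sorted(isolated)[:3]}"
            )
        self.graph = graph

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_edges_from(canonical_edge(u, v) for u, v in edges)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[Edge]:
        return {canonical_edge(u, v) for u, v in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def read_edge_list(path: str | Path, *, dialect: str = "tsv") -> RawEdgeList:
    """Parse an interaction file into raw records (cleaning is separate).

    ``tsv``: two-plus columns, first two are the interactors. ``sif``:
    simple interaction format ``source relation target [target ...]``; each
    target yields one record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list dialect {dialect!r}")
    records: list[tuple[str, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        ctx = f"{path.name}:{lineno}"
        if dialect == "tsv":
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise MalformedRecordError(f"{ctx}: expected >= 2 tab-separated columns")
            u = normalize_symbol(fields[0], context=ctx)
            v = normalize_symbol(fields[1], context=ctx)
            records.append((u, v))
        else:  # sif
            fields = stripped.split()
            if len(fields) == 1:
                # SIF permits bare isolated nodes; they carry no interaction
                continue
            if len(fields) < 3:
                raise MalformedRecordError(f"{ctx}: SIF line needs source, relation, target(s)")
            src = normalize_symbol(fields[0], context=ctx)
            for tgt in fields[2:]:
                records.append((src, normalize_symbol(tgt, context=ctx)))
    if not records:
        raise EmptyInputError(f"{path}: no interaction records found")
    return RawEdgeList(records=tuple(records))


def clean_network(raw: RawEdgeList | InteractionNetwork) -> InteractionNetwork:
    """Remove self-interacting pairs and collapse redundant unordered
    duplicates; drop nodes left without any edge. Idempotent."""
    if isinstance(raw, InteractionNetwork):
        records: Iterable[tuple[str, str]] = raw.edges
        n_records = raw.n_edges
    else:
        records = raw.records
        n_records = len(raw.records)
    loops = 0
    unique: set[Edge] = set()
    for u, v in records:
        if u == v:
            loops += 1
            continue
        unique.add(canonical_edge(u, v))
    dups = n_records - loops - len(unique)
    if loops or dups:
        logger.info(
            "clean_network: removed %d self-interaction(s) and %d redundant pair(s)",
            loops, dups,
        )
    if not unique:
        raise EmptyInputError("no edges remain after cleaning")
    return InteractionNetwork.from_edges(unique)


@dataclass(frozen=True)
class Subnetwork:
    """A disease-specific subnetwork: mapped seed nodes plus their first
    neighbors, with the connecting edges."""

    seeds: frozenset[str]
    neighbors: frozenset[str]
    edges: frozenset[Edge]
    unmapped_seeds: frozenset[str]
    edge_mode: str = "seed-incident"

    @property
    def nodes(self) -> frozenset[str]:
        return self.seeds | self.neighbors

    @property
    def n_nodes(self) -> int:
        return len(self.seeds) + len(self.neighbors)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def extract_disease_subnetwork(
    net: InteractionNetwork,
    seeds: GeneSet | Collection[str],
    *,
    edge_mode: str = "seed-incident",
) -> Subnetwork:
    """Map disease genes onto the network and take seeds + first neighbors.

    ``seed-incident`` keeps only edges touching at least one mapped seed;
    ``induced`` keeps all edges among seeds and neighbors.
    """
    if edge_mode not in EDGE_MODES:
        raise ValueError(f"edge_mode must be one of {EDGE_MODES}, got {edge_mode!r}")
    seed_symbols = set(seeds.members if isinstance(seeds, GeneSet) else seeds)
    if not seed_symbols:
        raise EmptyInputError("no seed genes supplied")
    mapped = seed_symbols & net.nodes
    unmapped = seed_symbols - mapped
    if not mapped:
        raise EmptyIntersectionError(
            f"none of the {len(seed_symbols)} seed genes map into the network"
        )
    if unmapped:
        logger.info("%d/%d seed gene(s) not in the network", len(unmapped), len(seed_symbols))
    incident = {
        canonical_edge(u, v)
        for seed in mapped
        for u, v in net.graph.edges(seed)
    }
    neighbors = {n for e in incident for n in e} - mapped
    if edge_mode == "induced":
        edges = {
            canonical_edge(u, v)
            for u, v in net.graph.subgraph(mapped | neighbors).edges
        }
    else:
        edges = incident
    return Subnetwork(
        seeds=frozenset(mapped),
        neighbors=frozenset(neighbors),
        edges=frozenset(edges),
        unmapped_seeds=frozenset(unmapped),
        edge_mode=edge_mode,
    )


ROLE_A_SEED = "a_seed_only"
ROLE_B_SEED = "b_seed_only"
ROLE_COMMON_SEED = "common_seed"
ROLE_NEIGHBOR = "neighbor_only"


@dataclass(frozen=True)
class SharedSubnetwork:
    """Node/edge intersection of two disease subnetworks, with each shared
    node's role assigned by disease gene-list membership."""

    shared_nodes: frozenset[str]
    shared_edges: frozenset[Edge]
    roles: dict[str, str]

    @property
    def role_counts(self) -> Counter:
        return Counter(self.roles.values())

    @property
    def n_nodes(self) -> int:
        return len(self.shared_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.shared_edges)


def intersect_subnetworks(
    a: Subnetwork,
    b: Subnetwork,
    set_a: GeneSet | Collection[str],
    set_b: GeneSet | Collection[str],
) -> SharedSubnetwork:
    """Common subnetwork: shared nodes and shared interaction pairs.

    Roles: in both gene lists -> common seed; in one -> that disease's
    seed; in neither -> first-neighbor-only node. An empty intersection is
    a valid (empty) result.
    """
    genes_a = set(set_a.members if isinstance(set_a, GeneSet) else set_a)
    genes_b = set(set_b.members if isinstance(set_b, GeneSet) else set_b)
    shared_nodes = a.nodes & b.nodes
    shared_edges = a.edges & b.edges
    if not shared_nodes:
        logger.warning("subnetwork intersection is empty")
    roles: dict[str, str] = {}
    for node in shared_nodes:
        in_a, in_b = node in genes_a, node in genes_b
        if in_a and in_b:
            roles[node] = ROLE_COMMON_SEED
        elif in_a:
            roles[node] = ROLE_A_SEED
        elif in_b:
            roles[node] = ROLE_B_SEED
        else:
            roles[node] = ROLE_NEIGHBOR
    return SharedSubnetwork(
        shared_nodes=frozenset(shared_nodes),
        shared_edges=frozenset(shared_edges),
        roles=roles,
    )


def degree_to_targets(
    shared: SharedSubnetwork, node: str, targets: Collection[str]
) -> int:
    """Number of shared-subnetwork edges from ``node`` to a target gene."""
    if node not in shared.shared_nodes:
        raise UnknownNodeError(f"{node!r} is not a shared-subnetwork node")
    target_set = set(targets)
    return sum(
        1
        for u, v in shared.shared_edges
        if (u == node and v in target_set) or (v == node and u in target_set)
    )


@dataclass(frozen=True)
class Candidate:
    gene: str
    degree_to_common: int
    partners: tuple[str, ...]  # the common genes it touches, sorted


@dataclass(frozen=True)
class CandidateRanking:
    """Predicted new candidate genes, ranked by degree to the common genes
    (descending), name ascending on ties."""

    candidates: tuple[Candidate, ...]
    min_degree: int

    def __len__(self) -> int:
        return len(self.candidates)

    def genes(self) -> list[str]:
        return [c.gene for c in self.candidates]


def predict_candidates(
    shared: SharedSubnetwork,
    common_genes: Collection[str],
    known_a: GeneSet | Collection[str],
    known_b: GeneSet | Collection[str],
    *,
    min_degree: int = 5,
) -> CandidateRanking:
    """Guilt-by-association prediction of new disease candidates.

    A shared-subnetwork node qualifies if it is absent from both known
    disease gene lists and directly interacts with at least ``min_degree``
    of the common genes (genes on both lists that mapped to the network).
    """
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    genes_a = set(known_a.members if isinstance(known_a, GeneSet) else known_a)
    genes_b = set(known_b.members if isinstance(known_b, GeneSet) else known_b)
    known = genes_a | genes_b
    target_set = set(common_genes)
    # adjacency from the shared edges only
    partners_of: dict[str, set[str]] = {}
    for u, v in shared.shared_edges:
        if v in target_set:
            partners_of.setdefault(u, set()).add(v)
        if u in target_set:
            partners_of.setdefault(v, set()).add(u)
    found = [
        Candidate(gene=node, degree_to_common=len(partners), partners=tuple(sorted(partners)))
        for node, partners in partners_of.items()
        if node not in known and node in shared.shared_nodes and len(partners) >= min_degree
    ]
    found.sort(key=lambda c: (-c.degree_to_common, c.gene))
    return CandidateRanking(candidates=tuple(found), min_degree=min_degree)


def write_edge_list(
    edges: Iterable[Edge], path: str | Path, *, dialect: str = "tsv"
) -> None:
    """Write edges as two-column TSV or SIF (deterministically sorted)."""
    ordered = sorted(canonical_edge(u, v) for u, v in edges)
    if dialect == "tsv":
        lines = [f"{u}\t{v}" for u, v in ordered]
    elif dialect == "sif":
        lines = [f"{u}\tpp\t{v}" for u, v in ordered]
    else:
        raise ValueError(f"unknown edge-list dialect {dialect!r}")
    Path(path).write_text("\n".join(lines) + "\n")
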