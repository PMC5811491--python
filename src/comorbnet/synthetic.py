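"""Synthetic study generators with planted ground truth.

Every stage of the comorbidity pipeline can be exercised without any
database download: a synthetic gene universe, an annotation collection,
two partially overlapping disease gene sets that over-sample "planted"
terms, and an interaction network with planted candidate hubs wired to
the diseases' shared genes. A :class:`SyntheticTruth` record stores what
was planted so recovery can be scored exactly.

A single integer seed drives a hierarchical ``numpy`` ``SeedSequence``;
each artifact draws from its own child stream, so e.g. the network can be
regenerated without disturbing the gene sets.

Background interactions follow an independent-pair (Erdos-Renyi-style)
model: the edge count is binomial over the allowed pairs and the pairs are
uniform without replacement. Pairs linking a planted candidate to a shared
gene are excluded from the background so the degree recorded at planting
time equals the realized degree in the emitted network. Degree-sequence
(scale-free) backgrounds are out of scope: the threshold rule under test
only depends on candidate-to-shared-gene degrees, and the independent-pair
model admits closed-form checks.
"""

from __future__ import annotations

import json
import math
from collections.abc import Collection, Sequence
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .catalog import GeneSet, write_gene_list
from .enrichment import AnnotationCollection, AnnotationTerm, write_gmt
from .errors import InfeasibleConstraintError
from .network import InteractionNetwork, canonical_edge, write_edge_list

__all__ = [
    "SyntheticTruth",
    "generate_universe",
    "generate_annotations",
    "generate_disease_sets",
    "generate_ppi",
    "write_bundle",
    "paper_scale_preset",
    "PAPER_SCALE",
]


@dataclass
class SyntheticTruth:
    """Ground-truth record of everything planted by the generators."""

    planted_terms_a: tuple[str, ...] = ()
    planted_terms_b: tuple[str, ...] = ()
    planted_shared_terms: tuple[str, ...] = ()
    planted_shared_genes: frozenset[str] = frozenset()
    planted_candidates: tuple[tuple[str, int], ...] = ()
    parameters: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["planted_shared_genes"] = sorted(self.planted_shared_genes)
        payload["planted_candidates"] = [list(c) for c in self.planted_candidates]
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_terms_a=tuple(payload["planted_terms_a"]),
            planted_terms_b=tuple(payload["planted_terms_b"]),
            planted_shared_terms=tuple(payload["planted_shared_terms"]),
            planted_shared_genes=frozenset(payload["planted_shared_genes"]),
            planted_candidates=tuple((g, int(d)) for g, d in payload["planted_candidates"]),
            parameters=payload.get("parameters", {}),
        )


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent child streams spawned from one integer seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_universe(n_genes: int, seed: int | np.random.Generator = 0) -> tuple[str, ...]:
    """Distinct synthetic symbols G0001...; deterministic given the seed
    (symbol naming is sequential, so any seed yields the same universe of a
    given size)."""
    if n_genes < 1:
        raise InfeasibleConstraintError("n_genes must be >= 1")
    width = max(4, len(str(n_genes)))
    return tuple(f"G{i:0{width}d}" for i in range(1, n_genes + 1))


def generate_annotations(
    universe: Sequence[str],
    n_terms: int,
    size_range: tuple[int, int],
    seed: int | np.random.Generator,
    *,
    category: str = "pathway",
) -> AnnotationCollection:
    """Random annotation terms: sizes uniform in ``size_range``, members
    sampled without replacement per term, universe = the input universe."""
    lo, hi = size_range
    pool = sorted(universe)
    if not (1 <= lo <= hi <= len(pool)):
        raise InfeasibleConstraintError(
            f"size_range {size_range} infeasible for universe of {len(pool)}"
        )
    rng = _rng(seed)
    width = max(3, len(str(n_terms)))
    terms = []
    for i in range(1, n_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(pool, size=size, replace=False).tolist())
        terms.append(
            AnnotationTerm(term_id=f"T{i:0{width}d}", name=f"synthetic term {i}", members=members)
        )
    return AnnotationCollection(category=category, terms=terms, universe=pool)


def _planted_members(
    collection: AnnotationCollection,
    term_ids: Sequence[str],
    hit_fraction: float,
    rng: np.random.Generator,
) -> set[str]:
    chosen: set[str] = set()
    for tid in term_ids:
        members = sorted(collection[tid].members)
        n_hit = math.ceil(hit_fraction * len(members))
        chosen |= set(rng.choice(members, size=n_hit, replace=False).tolist())
    return chosen


def generate_disease_sets(
    universe: Sequence[str],
    collection: AnnotationCollection,
    planted_a: Sequence[str],
    planted_b: Sequence[str],
    hit_fraction: float,
    set_size_a: int,
    set_size_b: int,
    shared_count: int,
    seed: int | np.random.Generator,
    *,
    name_a: str = "disease_a",
    name_b: str = "disease_b",
) -> tuple[GeneSet, GeneSet, SyntheticTruth]:
    """Two disease gene sets with planted enrichment and a controlled overlap.

    Each disease set contains ``ceil(hit_fraction * |term|)`` members of
    each of its planted terms plus uniform background genes, and the two
    sets share exactly ``shared_count`` genes. Shared genes are drawn
    preferentially from terms planted in both diseases, so the
    shared-pathway comparison has a known ground truth.
    """
    if not 0 < hit_fraction <= 1:
        raise InfeasibleConstraintError("hit_fraction must be in (0, 1]")
    if shared_count > min(set_size_a, set_size_b):
        raise InfeasibleConstraintError("shared_count exceeds a set size")
    rng = _rng(seed)
    pool = set(universe)

    members_a = _planted_members(collection, planted_a, hit_fraction, rng)
    members_b = _planted_members(collection, planted_b, hit_fraction, rng)
    if len(members_a) > set_size_a or len(members_b) > set_size_b:
        raise InfeasibleConstraintError(
            "planted term member budget exceeds the requested set size(s)"
        )
    shared_terms = tuple(sorted(set(planted_a) & set(planted_b)))
    shared_pool = set()
    for tid in shared_terms:
        shared_pool |= collection[tid].members

    shared_now = members_a & members_b
    if len(shared_now) > shared_count:
        raise InfeasibleConstraintError(
            f"planted sampling already shares {len(shared_now)} genes "
            f"(> requested {shared_count}); lower hit_fraction or raise shared_count"
        )

    def room_a() -> int:
        return set_size_a - len(members_a)

    def room_b() -> int:
        return set_size_b - len(members_b)

    # 1) promote genes already planted on one side, preferring shared-term members
    deficit = shared_count - len(shared_now)
    one_sided = sorted((members_a ^ members_b) & shared_pool)
    rng.shuffle(one_sided)
    for g in one_sided:
        if deficit == 0:
            break
        if g in members_a and g not in members_b and room_b() > 0:
            members_b.add(g)
            deficit -= 1
        elif g in members_b and g not in members_a and room_a() > 0:
            members_a.add(g)
            deficit -= 1
    # 2) fresh shared genes from shared-term members, then from the universe
    for candidates in (
        sorted(shared_pool - members_a - members_b),
        sorted(pool - members_a - members_b - shared_pool),
    ):
        if deficit == 0:
            break
        candidates = list(candidates)
        rng.shuffle(candidates)
        for g in candidates:
            if deficit == 0:
                break
            if room_a() > 0 and room_b() > 0:
                members_a.add(g)
                members_b.add(g)
                deficit -= 1
    if deficit > 0:
        raise InfeasibleConstraintError("could not realize the requested shared_count")

    # 3) disjoint background fill keeps the overlap exact
    remaining = sorted(pool - members_a - members_b)
    rng.shuffle(remaining)
    need_a, need_b = room_a(), room_b()
    if need_a + need_b > len(remaining):
        raise InfeasibleConstraintError("universe too small for the requested set sizes")
    members_a |= set(remaining[:need_a])
    members_b |= set(remaining[need_a : need_a + need_b])

    shared_genes = frozenset(members_a & members_b)
    assert len(shared_genes) == shared_count and len(members_a) == set_size_a
    assert len(members_b) == set_size_b

    truth = SyntheticTruth(
        planted_terms_a=tuple(planted_a),
        planted_terms_b=tuple(planted_b),
        planted_shared_terms=shared_terms,
        planted_shared_genes=shared_genes,
        parameters={
            "hit_fraction": hit_fraction,
            "set_size_a": set_size_a,
            "set_size_b": set_size_b,
            "shared_count": shared_count,
            "universe_size": len(pool),
        },
    )
    gs_a = GeneSet(name=name_a, members=frozenset(members_a), disease_label=name_a,
                   source_tags=frozenset({"synthetic"}))
    gs_b = GeneSet(name=name_b, members=frozenset(members_b), disease_label=name_b,
                   source_tags=frozenset({"synthetic"}))
    return gs_a, gs_b, truth


def generate_ppi(
    universe: Sequence[str],
    background_edge_prob: float,
    planted_candidates: Sequence[int],
    shared_genes: Collection[str],
    seed: int | np.random.Generator,
    *,
    exclude: Collection[str] = (),
    isolate: Collection[str] = (),
) -> tuple[InteractionNetwork, SyntheticTruth]:
    """Interaction network with planted candidate hubs.

    ``planted_candidates`` lists the requested degree-to-shared-genes of
    each planted node; the nodes themselves are picked from the universe
    outside ``shared_genes`` and ``exclude`` (pass the union of the disease
    gene sets there so no planted candidate is a known disease gene).
    ``isolate`` lists genes to keep out of the network entirely (emulating
    disease genes absent from the interactome). The emitted network is
    already clean: no self-loops, no duplicates, no isolated nodes.
    """
    rng = _rng(seed)
    nodes = sorted(universe)
    shared = sorted(set(shared_genes))
    isolate_set = set(isolate)
    if not set(shared) <= set(nodes):
        raise InfeasibleConstraintError("shared_genes must lie in the universe")
    if any(d > len(shared) for d in planted_candidates):
        raise InfeasibleConstraintError("requested degree exceeds |shared_genes|")
    if not 0 <= background_edge_prob < 1:
        raise InfeasibleConstraintError("background_edge_prob must be in [0, 1)")

    eligible = sorted(set(nodes) - set(shared) - set(exclude) - isolate_set)
    if len(planted_candidates) > len(eligible):
        raise InfeasibleConstraintError("not enough eligible nodes for planted candidates")
    cand_nodes = [str(g) for g in rng.choice(eligible, size=len(planted_candidates), replace=False)]

    edges: set[tuple[str, str]] = set()
    planted: list[tuple[str, int]] = []
    for node, degree in zip(cand_nodes, planted_candidates):
        partners = rng.choice(shared, size=int(degree), replace=False)
        for p in partners:
            edges.add(canonical_edge(node, str(p)))
        planted.append((node, int(degree)))

    # background: binomial count over allowed pairs, pairs uniform w/o replacement
    cand_set = set(cand_nodes)
    shared_set = set(shared)
    usable = [n for n in nodes if n not in isolate_set]
    n_use = len(usable)
    n_pairs = n_use * (n_use - 1) // 2
    forbidden = len(cand_set) * len(shared_set)  # candidate-shared pairs never background
    n_allowed = n_pairs - forbidden
    m = int(rng.binomial(n_allowed, background_edge_prob)) if background_edge_prob > 0 else 0
    background: set[tuple[str, str]] = set()
    while len(background) < m:
        batch = max(64, 2 * (m - len(background)))
        ii = rng.integers(0, n_use, size=batch)
        jj = rng.integers(0, n_use, size=batch)
        for i, j in zip(ii, jj):
            if len(background) >= m:
                break
            if i == j:
                continue
            u, v = usable[i], usable[j]
            if (u in cand_set and v in shared_set) or (v in cand_set and u in shared_set):
                continue
            e = canonical_edge(u, v)
            if e in edges or e in background:
                continue
            background.add(e)
    edges |= background

    truth = SyntheticTruth(
        planted_candidates=tuple(sorted(planted)),
        planted_shared_genes=frozenset(shared),
        parameters={
            "background_edge_prob": background_edge_prob,
            "universe_size": len(nodes),
            "n_background_edges": m,
            "n_allowed_pairs": n_allowed,
            "isolated_genes": sorted(isolate_set),
        },
    )
    return InteractionNetwork.from_edges(edges), truth


def _merge_truth(a: SyntheticTruth, b: SyntheticTruth) -> SyntheticTruth:
    return SyntheticTruth(
        planted_terms_a=a.planted_terms_a,
        planted_terms_b=a.planted_terms_b,
        planted_shared_terms=a.planted_shared_terms,
        planted_shared_genes=a.planted_shared_genes or b.planted_shared_genes,
        planted_candidates=b.planted_candidates,
        parameters={**a.parameters, **b.parameters},
    )


#: study-scale default configuration for the synthetic bundle: disease set
#: sizes and overlap match the nicotine-addiction/schizophrenia study
#: (276/331 genes, 52 shared, 51 of them present in the interactome) and
#: the candidate layer plants 11 hubs at degree >= 5 plus sub-threshold
#: decoys, mirroring the 11 reported guilt-by-association candidates.
PAPER_SCALE = {
    "n_genes": 3000,
    "n_terms": 100,
    "term_size_range": (10, 40),
    "n_planted_per_disease": 6,
    "n_planted_shared": 3,
    "hit_fraction": 0.6,
    "set_size_a": 276,
    "set_size_b": 331,
    "shared_count": 52,
    "background_edge_prob": 5e-4,
    "candidate_degrees": (9, 8, 8, 7, 7, 6, 6, 5, 5, 5, 5),
    "decoy_degrees": (4, 3, 2, 1),
    "n_ppi_shared": 51,
}


def paper_scale_preset(
    seed: int, overrides: dict | None = None
) -> tuple[GeneSet, GeneSet, AnnotationCollection, InteractionNetwork, SyntheticTruth]:
    """Generate the full study-scale synthetic bundle in memory."""
    params = {**PAPER_SCALE, **(overrides or {})}
    rng_ann, rng_sets, rng_ppi = child_rngs(seed, 3)
    universe = generate_universe(params["n_genes"])
    collection = generate_annotations(
        universe, params["n_terms"], params["term_size_range"], rng_ann
    )
    n_plant = params["n_planted_per_disease"]
    n_shared_terms = params["n_planted_shared"]
    term_ids = [t.term_id for t in collection.terms]
    planted_shared = term_ids[:n_shared_terms]
    planted_a = planted_shared + term_ids[n_shared_terms : n_shared_terms + (n_plant - n_shared_terms)]
    planted_b = planted_shared + term_ids[
        n_shared_terms + (n_plant - n_shared_terms) : n_shared_terms + 2 * (n_plant - n_shared_terms)
    ]
    set_a, set_b, truth_sets = generate_disease_sets(
        universe,
        collection,
        planted_a,
        planted_b,
        params["hit_fraction"],
        params["set_size_a"],
        params["set_size_b"],
        params["shared_count"],
        rng_sets,
        name_a="disease_a",
        name_b="disease_b",
    )
    shared_genes = sorted(truth_sets.planted_shared_genes)
    # one shared gene deliberately absent from the interactome, so only
    # n_ppi_shared of them map (the study's 51-of-52 situation)
    n_in_ppi = params["n_ppi_shared"]
    missing = shared_genes[n_in_ppi:]
    ppi_shared = shared_genes[:n_in_ppi]
    net, truth_net = generate_ppi(
        universe,
        params["background_edge_prob"],
        list(params["candidate_degrees"]) + list(params["decoy_degrees"]),
        ppi_shared,
        rng_ppi,
        exclude=set_a.members | set_b.members,
        isolate=missing,
    )
    truth = _merge_truth(truth_sets, truth_net)
    truth.parameters["seed"] = seed
    truth.parameters["candidate_degrees"] = list(params["candidate_degrees"])
    truth.parameters["decoy_degrees"] = list(params["decoy_degrees"])
    truth.parameters["min_degree"] = 5
    return set_a, set_b, collection, net, truth


def write_bundle(
    outdir: str | Path,
    set_a: GeneSet,
    set_b: GeneSet,
    collection: AnnotationCollection,
    net: InteractionNetwork | None,
    truth: SyntheticTruth,
) -> dict[str, Path]:
    """Write a synthetic input bundle in the same formats the pipeline
    reads: plain gene lists, GMT, edge-list TSV, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes_a": outdir / f"{set_a.name}.genes.txt",
        "genes_b": outdir / f"{set_b.name}.genes.txt",
        "gmt": outdir / f"{collection.category}.gmt",
        "truth": outdir / "truth.json",
    }
    write_gene_list(set_a, paths["genes_a"])
    write_gene_list(set_b, paths["genes_b"])
    write_gmt(collection, paths["gmt"])
    if net is not None:
        paths["ppi"] = outdir / "ppi_edges.tsv"
        write_edge_list(net.edges, paths["ppi"])
    truth.to_json(paths["truth"])
    return paths
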