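"""Modified reciprocal-best-BLAST-hit (RBH) clustering.

Inter-species edges are reciprocal best hits after a 40/40 identity and
coverage filter ("exceeded 40%", so strict inequalities by default).
Intra-species edges link paralogs at >= 90% identity and coverage that are
reciprocal within each other's first ten hits.  Edges are condensed into
clusters by connected components, and clusters containing plastid-predicted
members are trimmed back to members with a qualifying hit (>= 40/40) to at
least one plastid anchor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .types import Cluster, HomologyEdge, SimilarityHit, clusters_from_sets

__all__ = [
    "reciprocal_best_pairs",
    "intra_species_better_pairs",
    "merge_components",
    "trim_cluster",
    "TrimResult",
    "build_hit_lookup",
    "run_rbh_pipeline",
]


def _passes(
    hit: SimilarityHit,
    min_identity: float,
    min_coverage: float,
    coverage_mode: str,
    strict: bool,
) -> bool:
    if coverage_mode == "both":
        covs = (hit.query_cov, hit.target_cov)
    elif coverage_mode == "query":
        covs = (hit.query_cov,)
    else:
        raise ValueError(f"unknown coverage mode {coverage_mode!r}")
    if strict:
        return hit.identity > min_identity and all(c > min_coverage for c in covs)
    return hit.identity >= min_identity and all(c >= min_coverage for c in covs)


def _best_hits(
    hits: Iterable[SimilarityHit],
    min_identity: float,
    min_coverage: float,
    coverage_mode: str,
    strict: bool,
) -> dict[str, SimilarityHit]:
    """Best surviving hit per query: bitscore, then identity, then target id."""
    best: dict[str, SimilarityHit] = {}
    for hit in hits:
        if hit.is_self:
            continue
        if not _passes(hit, min_identity, min_coverage, coverage_mode, strict):
            continue
        cur = best.get(hit.query)
        if cur is None or (-hit.bitscore, -hit.identity, hit.target) < (
            -cur.bitscore, -cur.identity, cur.target
        ):
            best[hit.query] = hit
    return best


def reciprocal_best_pairs(
    hits_ab: Sequence[SimilarityHit],
    hits_ba: Sequence[SimilarityHit],
    min_identity: float = 40.0,
    min_coverage: float = 40.0,
    coverage_mode: str = "both",
    strict: bool = True,
) -> list[HomologyEdge]:
    """Reciprocal best hits between two species' all-vs-all hit tables.

    Both directions are filtered first (identity and coverage must exceed
    the thresholds), then each query's best surviving hit is taken; an edge
    is emitted iff the best hits are mutual.  Tables must come from two
    different searches (A vs B and B vs A).
    """
    ids_a = {h.query for h in hits_ab}
    ids_b = {h.query for h in hits_ba}
    if ids_a & ids_b:
        raise ValueError(
            "forward and reverse hit tables share query ids; for a species "
            "against itself use intra_species_better_pairs"
        )
    best_ab = _best_hits(hits_ab, min_identity, min_coverage, coverage_mode, strict)
    best_ba = _best_hits(hits_ba, min_identity, min_coverage, coverage_mode, strict)
    edges = []
    for a, hit in sorted(best_ab.items()):
        back = best_ba.get(hit.target)
        if back is not None and back.target == a:
            edges.append(HomologyEdge(a, hit.target, kind="inter_species_rbh"))
    return edges


def intra_species_better_pairs(
    self_hits: Sequence[SimilarityHit],
    min_identity: float = 90.0,
    min_coverage: float = 90.0,
    top_k: int = 10,
    coverage_mode: str = "both",
) -> list[HomologyEdge]:
    """Reciprocal "better" hits within one species' self-vs-self table.

    An edge (a, b) requires b within a's first ``top_k`` hits and a within
    b's first ``top_k``, with both direction hits at >= ``min_identity`` and
    >= ``min_coverage`` ("at least 90%", so inclusive).  "First" follows the
    hit-list rank order; self-hits are excluded before ranking.
    """
    per_query: dict[str, list[SimilarityHit]] = {}
    for hit in self_hits:
        if hit.is_self:
            continue
        per_query.setdefault(hit.query, []).append(hit)

    qualifying: dict[str, set[str]] = {}
    for query, hits in per_query.items():
        hits.sort(key=lambda h: h.rank)
        qualifying[query] = {
            h.target
            for h in hits[:top_k]
            if _passes(h, min_identity, min_coverage, coverage_mode, strict=False)
        }
    edges = set()
    for a, targets in qualifying.items():
        for b in targets:
            if a in qualifying.get(b, ()):
                edges.add(HomologyEdge(a, b, kind="intra_species_better"))
    return sorted(edges, key=lambda e: e.pair)


def merge_components(
    edges: Iterable[HomologyEdge],
    all_ids: Iterable[str],
) -> list[Cluster]:
    """Condense edges into clusters by connected components.

    Ids carrying no edge become singleton clusters.  The result is a
    partition of ``all_ids`` and is independent of edge order.
    """
    graph = nx.Graph()
    graph.add_nodes_from(all_ids)
    for edge in edges:
        if edge.a not in graph or edge.b not in graph:
            raise KeyError(f"edge {edge.pair} references unknown id")
        graph.add_edge(edge.a, edge.b)
    return clusters_from_sets(nx.connected_components(graph))


def build_hit_lookup(
    hits: Iterable[SimilarityHit],
    coverage: str = "min",
) -> dict[tuple[str, str], tuple[float, float]]:
    """Symmetric (identity, coverage) lookup keyed by canonical id pair.

    Where several hits exist for a pair (both directions, repeated HSPs)
    the best identity is kept.  ``coverage`` selects how the two coverages
    of a hit collapse into one: ``min`` (default, conservative) or ``query``.
    """
    lookup: dict[tuple[str, str], tuple[float, float]] = {}
    for hit in hits:
        if hit.is_self:
            continue
        key = tuple(sorted((hit.query, hit.target)))
        cov = min(hit.query_cov, hit.target_cov) if coverage == "min" else hit.query_cov
        cur = lookup.get(key)
        if cur is None or (hit.identity, cov) > cur:
            lookup[key] = (hit.identity, cov)
    return lookup


@dataclass(frozen=True)
class TrimResult:
    cluster: Cluster
    removed: tuple[str, ...]
    #: True when the cluster had no plastid anchor and was left unchanged.
    no_anchor: bool = False


def trim_cluster(
    cluster: Cluster,
    hit_lookup: Mapping[tuple[str, str], tuple[float, float]],
    plastid_set: Iterable[str],
    min_identity: float = 40.0,
    min_coverage: float = 40.0,
) -> TrimResult:
    """Trim members lacking a qualifying hit to any plastid anchor.

    Retained members are the plastid-predicted anchors plus every member
    with at least ``min_identity``/``min_coverage`` to one of them.  Pairs
    absent from the lookup count as below threshold.  A cluster with no
    plastid member is returned unchanged, flagged ``no_anchor``.
    """
    anchors = set(cluster.members) & set(plastid_set)
    if not anchors:
        return TrimResult(cluster=cluster, removed=(), no_anchor=True)
    kept = set(anchors)
    for member in cluster.members:
        if member in kept:
            continue
        for anchor in anchors:
            entry = hit_lookup.get(tuple(sorted((member, anchor))))
            if entry is not None and entry[0] >= min_identity and entry[1] >= min_coverage:
                kept.add(member)
                break
    removed = tuple(sorted(set(cluster.members) - kept))
    return TrimResult(
        cluster=Cluster(cluster.id, tuple(sorted(kept))), removed=removed
    )


def run_rbh_pipeline(
    inter_hits: Mapping[tuple[str, str], Sequence[SimilarityHit]],
    intra_hits: Mapping[str, Sequence[SimilarityHit]],
    all_ids: Iterable[str],
    plastid_set: Iterable[str] = (),
    min_identity: float = 40.0,
    min_coverage: float = 40.0,
    expand_identity: float = 90.0,
    expand_coverage: float = 90.0,
    top_k: int = 10,
    trim: bool = True,
) -> list[Cluster]:
    """Full RBH clustering: edges, component merge, optional trimming.

    ``inter_hits`` maps ordered species pairs (a, b) to the a-vs-b hit
    table (both orders must be present); ``intra_hits`` maps each species
    to its self-vs-self table.
    """
    edges: list[HomologyEdge] = []
    seen_pairs = set()
    for (sp_a, sp_b), hits_ab in inter_hits.items():
        if sp_a == sp_b:
            raise ValueError("inter-species table keyed by identical species")
        if (sp_b, sp_a) in seen_pairs:
            continue
        seen_pairs.add((sp_a, sp_b))
        hits_ba = inter_hits.get((sp_b, sp_a), ())
        edges.extend(
            reciprocal_best_pairs(
                hits_ab, hits_ba, min_identity=min_identity, min_coverage=min_coverage
            )
        )
    for hits in intra_hits.values():
        edges.extend(
            intra_species_better_pairs(
                hits,
                min_identity=expand_identity,
                min_coverage=expand_coverage,
                top_k=top_k,
            )
        )
    clusters = merge_components(edges, all_ids)
    plastid = set(plastid_set)
    if not trim or not plastid:
        return clusters
    lookup = build_hit_lookup(
        [h for hits in inter_hits.values() for h in hits]
        + [h for hits in intra_hits.values() for h in hits]
    )
    return [
        trim_cluster(c, lookup, plastid, min_identity, min_coverage).cluster
        for c in clusters
    ]
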