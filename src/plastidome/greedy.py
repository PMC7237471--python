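"""Greedy-centroid clustering with random reseeding.

The initial pass scans sequences in length-sorted order; each sequence
joins the first centroid it matches at the identity/coverage thresholds or
founds a new cluster (classic greedy centroid behaviour).  Because a long
early centroid can capture part of a family and strand the rest, the
partition is then healed by reseeding: one random member is drawn from each
initial cluster, the seeds are length-sorted and prepended to the full
length-sorted list, and the pass is re-run at a stricter identity (90% by
default) with relaxed coverage (0.4 both ways).  Clusters from all runs
that share any member are merged by connected components.  Repeating the
reseed run with fresh random draws (100 times in the full protocol)
converges; the merged cluster count is non-increasing in the number of
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

from .types import Cluster, ProteinRecord, clusters_from_sets

__all__ = [
    "AlignmentStats",
    "GreedyRunParams",
    "AlignmentScorer",
    "pairwise_identity",
    "greedy_pass",
    "reseed",
    "iterative_cluster",
    "IterativeResult",
]


@dataclass(frozen=True)
class AlignmentStats:
    """Identity and coverages of one semi-global pairwise alignment.

    Identity is matches over alignment columns (terminal free gaps
    excluded, internal gaps counted); coverage is the aligned span over the
    full sequence length, per side.  All values are fractions in [0, 1].
    """

    identity: float
    query_cov: float
    target_cov: float


@dataclass(frozen=True)
class GreedyRunParams:
    """Thresholds (fractions in (0, 1]) and acceptance mode for one pass.

    ``target_cov`` may be 0 to disable the target-side coverage test (the
    initial pass constrains query coverage only).  ``mode`` is ``first``
    (join the first qualifying centroid, the documented greedy behaviour)
    or ``best`` (highest-identity qualifying centroid).
    """

    identity: float
    query_cov: float
    target_cov: float = 0.0
    mode: str = "first"

    def __post_init__(self) -> None:
        for name in ("identity", "query_cov"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not (0 <= self.target_cov <= 1):
            raise ValueError("target_cov must be in [0, 1]")
        if self.mode not in ("first", "best"):
            raise ValueError(f"unknown acceptance mode {self.mode!r}")


class AlignmentScorer:
    """Semi-global aligner with per-pair memoisation.

    Fixed scoring scheme: match +1, mismatch -1, gap open -2, gap extend
    -1, end gaps free.  Reseeded passes re-align the same pairs many times,
    so results are cached by id pair.
    """

    def __init__(self) -> None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1.0
        aligner.mismatch_score = -1.0
        aligner.open_gap_score = -2.0
        aligner.extend_gap_score = -1.0
        # free end gaps on both sequences -> semi-global
        aligner.open_end_insertion_score = 0.0
        aligner.extend_end_insertion_score = 0.0
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
        self._aligner = aligner
        self._cache: dict[tuple[str, str], AlignmentStats] = {}
        self._score_cache: dict[tuple[str, str], float] = {}

    def stats(self, query: ProteinRecord, target: ProteinRecord) -> AlignmentStats:
        key = (query.id, target.id)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        result = self._compute(query.sequence, target.sequence)
        self._cache[key] = result
        # identity is symmetric; coverages swap
        self._cache[(target.id, query.id)] = AlignmentStats(
            identity=result.identity,
            query_cov=result.target_cov,
            target_cov=result.query_cov,
        )
        return result

    def score(self, query: ProteinRecord, target: ProteinRecord) -> float:
        """Optimal semi-global alignment score (symmetric, cached)."""
        key = (query.id, target.id)
        cached = self._score_cache.get(key)
        if cached is None:
            cached = float(self._aligner.score(query.sequence, target.sequence))
            self._score_cache[key] = cached
            self._score_cache[(target.id, query.id)] = cached
        return cached

    def cannot_qualify(
        self, query: ProteinRecord, target: ProteinRecord, params: "GreedyRunParams"
    ) -> bool:
        """Exact score-based rejection test, valid for identity > 2/3.

        A qualifying optimal alignment (identity >= t over C columns with
        C >= qcov * len(query)) scores at least (3t - 2) * qcov * len(query)
        under the +1/-1/-2/-1 scheme, so anything scoring below that bound
        cannot decode to a qualifying alignment.  Saves the expensive
        alignment decode on the stringent expansion passes.
        """
        if params.identity <= 2.0 / 3.0:
            return False
        bound = (3.0 * params.identity - 2.0) * params.query_cov * query.length
        return self.score(query, target) < bound

    def _compute(self, a: str, b: str) -> AlignmentStats:
        if not a or not b:
            raise ValueError("cannot align an empty sequence")
        if a == b:
            return AlignmentStats(1.0, 1.0, 1.0)
        alignment = self._aligner.align(a, b)[0]
        t_segs, q_segs = alignment.aligned  # target = a, query = b
        if len(t_segs) == 0:
            return AlignmentStats(0.0, 0.0, 0.0)
        matches = 0
        aligned_len = 0
        for (ts, te), (qs, qe) in zip(t_segs, q_segs):
            aligned_len += te - ts
            matches += sum(u == v for u, v in zip(a[ts:te], b[qs:qe]))
        a_span = int(t_segs[-1][1] - t_segs[0][0])
        b_span = int(q_segs[-1][1] - q_segs[0][0])
        columns = a_span + b_span - aligned_len
        identity = matches / columns if columns else 0.0
        return AlignmentStats(
            identity=identity,
            query_cov=a_span / len(a),
            target_cov=b_span / len(b),
        )


_default_scorer = AlignmentScorer()


def pairwise_identity(a: str | ProteinRecord, b: str | ProteinRecord) -> AlignmentStats:
    """Semi-global identity/coverage between two sequences.

    Accepts raw strings or records; deterministic and symmetric in
    identity.  Coverage is reported for ``a`` (query) and ``b`` (target).
    """
    if isinstance(a, str):
        a = ProteinRecord(id=f"q:{hash(a)}", species="", sequence=a)
    if isinstance(b, str):
        b = ProteinRecord(id=f"t:{hash(b)}", species="", sequence=b)
    return _default_scorer.stats(a, b)


def _length_sorted(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    # stable: length descending, id ascending for reproducible ties
    return sorted(records, key=lambda r: (-r.length, r.id))


def _qualifies(stats: AlignmentStats, params: GreedyRunParams) -> bool:
    return (
        stats.identity >= params.identity
        and stats.query_cov >= params.query_cov
        and stats.target_cov >= params.target_cov
    )


def greedy_pass(
    records: Sequence[ProteinRecord],
    params: GreedyRunParams,
    scorer: AlignmentScorer | None = None,
    presorted: bool = False,
) -> list[Cluster]:
    """One greedy centroid pass over length-sorted records.

    Records are scanned in order (sorted by length descending unless
    ``presorted``); each joins the first (or best, per ``params.mode``)
    centroid whose alignment meets all thresholds, else founds a new
    cluster.  Duplicate ids later in the scan (prepended seeds) are skipped.
    """
    scorer = scorer or AlignmentScorer()
    ordered = list(records) if presorted else _length_sorted(records)
    centroids: list[ProteinRecord] = []
    members: dict[str, list[str]] = {}
    seen: set[str] = set()
    for record in ordered:
        if record.id in seen:
            continue
        seen.add(record.id)
        chosen: ProteinRecord | None = None
        best_identity = -1.0
        for centroid in centroids:
            if scorer.cannot_qualify(record, centroid, params):
                continue
            stats = scorer.stats(record, centroid)
            if not _qualifies(stats, params):
                continue
            if params.mode == "first":
                chosen = centroid
                break
            if stats.identity > best_identity:
                best_identity = stats.identity
                chosen = centroid
        if chosen is None:
            centroids.append(record)
            members[record.id] = [record.id]
        else:
            members[chosen.id].append(record.id)
    return clusters_from_sets(members.values())


def reseed(
    clusters: Sequence[Cluster],
    records_by_id: Mapping[str, ProteinRecord],
    rng: np.random.Generator,
) -> list[ProteinRecord]:
    """Draw one uniform random member per cluster, length-sorted descending."""
    if not clusters:
        raise ValueError("no clusters to reseed from")
    seeds = []
    for cluster in clusters:
        pick = cluster.members[int(rng.integers(len(cluster.members)))]
        seeds.append(records_by_id[pick])
    return _length_sorted(seeds)


@dataclass(frozen=True)
class IterativeResult:
    clusters: tuple[Cluster, ...]
    #: merged cluster count after the initial pass and after each iteration
    count_trajectory: tuple[int, ...]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def iterative_cluster(
    records: Sequence[ProteinRecord],
    init_identity: float = 0.4,
    init_qcov: float = 0.4,
    expand_identity: float = 0.9,
    expand_cov: float = 0.4,
    iterations: int = 100,
    rng_seed: int = 0,
    mode: str = "first",
    scorer: AlignmentScorer | None = None,
) -> IterativeResult:
    """Initial greedy pass plus randomly reseeded expansion passes, merged.

    Each iteration reseeds from the *initial* partition (one random member
    per initial cluster), prepends the length-sorted seeds to the full
    length-sorted list, and re-runs the pass at ``expand_identity`` with
    query and target coverage ``expand_cov``.  Clusters from all runs
    sharing any member are merged (connected components of co-membership).
    A single RNG seed drives all reseeds, so runs are bit-reproducible.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    scorer = scorer or AlignmentScorer()
    records_by_id = {r.id: r for r in records}
    if len(records_by_id) != len(records):
        raise ValueError("duplicate record ids")
    ordered = _length_sorted(records)

    init_params = GreedyRunParams(
        identity=init_identity, query_cov=init_qcov, target_cov=0.0, mode=mode
    )
    expand_params = GreedyRunParams(
        identity=expand_identity, query_cov=expand_cov, target_cov=expand_cov,
        mode=mode,
    )
    initial = greedy_pass(ordered, init_params, scorer=scorer, presorted=True)

    # union-find over co-membership across all runs
    parent: dict[str, str] = {r.id: r.id for r in records}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union_cluster(member_ids: Sequence[str]) -> None:
        root = find(member_ids[0])
        for m in member_ids[1:]:
            parent[find(m)] = root

    for cluster in initial:
        union_cluster(cluster.members)

    def component_count() -> int:
        return len({find(i) for i in parent})

    trajectory = [component_count()]
    rng = np.random.default_rng(rng_seed)
    for _ in range(iterations):
        seeds = reseed(initial, records_by_id, rng)
        scan = seeds + ordered
        run = greedy_pass(scan, expand_params, scorer=scorer, presorted=True)
        for cluster in run:
            union_cluster(cluster.members)
        trajectory.append(component_count())

    groups: dict[str, list[str]] = {}
    for rec_id in parent:
        groups.setdefault(find(rec_id), []).append(rec_id)
    clusters = clusters_from_sets(groups.values())
    return IterativeResult(clusters=tuple(clusters), count_trajectory=tuple(trajectory))
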