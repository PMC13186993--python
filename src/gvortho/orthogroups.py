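"""Two-stage sequence/structure orthogroup clustering with a connectivity
merge step.

The pipeline mirrors structure-informed orthogroup construction for
ORFan-rich viral proteomes: proteins are first clustered on sequence identity
(default 20% identity, 70% bidirectional coverage), the cluster
representatives are then clustered on structural similarity (TM-score >= 0.4,
70% coverage) and every protein inherits its representative's structural
cluster. A final merge step joins clusters when more than 65% of the members
of one cluster have a structural hit to at least one member of the other,
recovering remote homologies (e.g. RNA-polymerase subunits) that the
stringent coverage thresholds miss. Partitions are compared by normalized
mutual information.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from sklearn.metrics import normalized_mutual_info_score

from .io_formats import Clustering, EdgeKind, SimilarityEdge

logger = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 0.2
DEFAULT_MIN_TM = 0.4
DEFAULT_MIN_COV = 0.7
DEFAULT_MERGE_THRESHOLD = 0.65


@dataclass(frozen=True)
class MergeEvent:
    """Connectivity evaluation of one cluster pair during the merge step."""

    cluster_a: str
    cluster_b: str
    fraction_a_to_b: float
    fraction_b_to_a: float
    merged: bool


def filter_edges(edges: Iterable[SimilarityEdge], min_score: float,
                 min_cov: float) -> list[SimilarityEdge]:
    """Keep edges with score >= min_score and coverage of BOTH query and
    target >= min_cov; self-edges are dropped."""
    return [e for e in edges
            if not e.is_self
            and e.score >= min_score
            and e.coverage_query >= min_cov
            and e.coverage_target >= min_cov]


def _adjacency(edges: Iterable[SimilarityEdge]) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {}
    for e in edges:
        adj.setdefault(e.query_id, set()).add(e.target_id)
        adj.setdefault(e.target_id, set()).add(e.query_id)
    return adj


def cluster_greedy(edges: Sequence[SimilarityEdge], min_score: float,
                   min_cov: float, universe: Iterable[str],
                   lengths: Mapping[str, int] | None = None,
                   mode: str = "set_cover") -> Clustering:
    """Greedy set-cover clustering of a similarity graph.

    Edges are first filtered (score >= ``min_score``, bidirectional coverage
    >= ``min_cov``, self-edges ignored). Candidate representatives are sorted
    by retained-edge degree (ties: longer protein first when ``lengths`` is
    given, then lexicographic ID); each representative claims all its not yet
    claimed neighbours. Proteins in ``universe`` with no retained edge become
    singletons. ``mode="components"`` clusters by connected components
    instead (representative = highest-degree member with the same tie-break).
    """
    universe = set(universe)
    retained = filter_edges(edges, min_score, min_cov)
    for e in retained:
        for p in (e.query_id, e.target_id):
            if p not in universe:
                raise ValueError(f"protein {p!r} referenced by an edge is "
                                 f"missing from the universe")
    adj = _adjacency(retained)
    degree = {p: len(adj.get(p, ())) for p in universe}

    def sort_key(p: str):
        return (-degree[p], -(lengths or {}).get(p, 0), p)

    order = sorted(universe, key=sort_key)
    assignment: dict[str, str] = {}
    representatives: dict[str, str] = {}

    if mode == "set_cover":
        for p in order:
            if p in assignment:
                continue
            assignment[p] = p
            representatives[p] = p
            for q in sorted(adj.get(p, ())):
                if q not in assignment:
                    assignment[q] = p
    elif mode == "components":
        seen: set[str] = set()
        for p in order:
            if p in seen:
                continue
            # BFS over the retained graph
            comp = {p}
            frontier = [p]
            while frontier:
                nxt: list[str] = []
                for u in frontier:
                    for v in adj.get(u, ()):
                        if v not in comp:
                            comp.add(v)
                            nxt.append(v)
                frontier = nxt
            seen |= comp
            rep = min(comp, key=sort_key)
            representatives[rep] = rep
            for q in comp:
                assignment[q] = rep
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return Clustering(assignment=assignment, representatives=representatives)


def compose_two_stage(seq_clustering: Clustering,
                      struct_clustering_of_reps: Clustering) -> Clustering:
    """Compose the sequence stage with the structural stage on representatives.

    Every protein inherits the structural cluster of its sequence-cluster
    representative, so the final cluster count equals the structural-stage
    cluster count.
    """
    struct_assign = struct_clustering_of_reps.assignment
    assignment: dict[str, str] = {}
    for protein, seq_cid in seq_clustering.assignment.items():
        rep = seq_clustering.representatives[seq_cid]
        if rep not in struct_assign:
            raise ValueError(f"representative {rep!r} absent from the "
                             f"structural stage")
        assignment[protein] = struct_assign[rep]
    used = set(assignment.values())
    representatives: dict[str, str] = {}
    for cid, rep in struct_clustering_of_reps.representatives.items():
        if cid not in used:
            continue
        if assignment.get(rep) == cid:
            representatives[cid] = rep
        else:
            # structural stage may carry proteins outside the composed
            # universe; fall back to the smallest inherited member
            representatives[cid] = min(p for p, c in assignment.items()
                                       if c == cid)
    return Clustering(assignment=assignment, representatives=representatives)


def link_fraction(cluster_a: Iterable[str], cluster_b: Iterable[str],
                  edges: Iterable[SimilarityEdge] | Mapping[str, set[str]],
                  ) -> float:
    """Fraction of cluster_a members with >= 1 (undirected) structural hit
    into cluster_b.

    ``edges`` may be pre-filtered similarity edges or a ready adjacency map.
    """
    a, b = set(cluster_a), set(cluster_b)
    if not a or not b:
        raise ValueError("link_fraction requires non-empty clusters")
    adj = edges if isinstance(edges, Mapping) else _adjacency(
        e for e in edges if not e.is_self)
    linked = sum(1 for p in a if adj.get(p, set()) & b)
    return linked / len(a)


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: str, y: str) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


def merge_clusters(clustering: Clustering,
                   edges: Sequence[SimilarityEdge],
                   threshold: float = DEFAULT_MERGE_THRESHOLD,
                   iterate: bool = False,
                   ) -> tuple[Clustering, list[MergeEvent]]:
    """Merge clusters connected above the connectivity threshold.

    For every cluster pair with at least one cross edge, the link fraction is
    computed in both directions on the ORIGINAL clusters; the pair is
    eligible when the fraction is strictly greater than ``threshold`` in at
    least one direction ("over 65% of proteins in one cluster"). Eligible
    pairs are closed transitively with union-find, so the cluster count never
    increases. With ``iterate=True`` eligibility is re-evaluated on the
    merged clusters until a fixpoint.

    Returns the merged clustering and all :class:`MergeEvent` records with a
    nonzero fraction. The representative of a merged cluster is the
    representative of the largest constituent (ties: lexicographic).
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    current = clustering
    all_events: list[MergeEvent] = []
    while True:
        clusters = current.clusters()
        adj = _adjacency(e for e in edges if not e.is_self)
        # candidate pairs: clusters bridged by at least one edge
        assign = current.assignment
        pairs: set[tuple[str, str]] = set()
        for p, neighbours in adj.items():
            if p not in assign:
                continue
            ca = assign[p]
            for q in neighbours:
                if q not in assign:
                    continue
                cb = assign[q]
                if ca != cb:
                    pairs.add((min(ca, cb), max(ca, cb)))
        uf = _UnionFind(clusters.keys())
        events: list[MergeEvent] = []
        for ca, cb in sorted(pairs):
            fab = link_fraction(clusters[ca], clusters[cb], adj)
            fba = link_fraction(clusters[cb], clusters[ca], adj)
            merged = max(fab, fba) > threshold
            events.append(MergeEvent(ca, cb, fab, fba, merged))
            if merged:
                uf.union(ca, cb)
        all_events.extend(events)
        if not any(ev.merged for ev in events):
            break
        # rebuild the clustering from the union-find groups
        groups: dict[str, list[str]] = {}
        for cid in clusters:
            groups.setdefault(uf.find(cid), []).append(cid)
        assignment: dict[str, str] = {}
        representatives: dict[str, str] = {}
        for member_cids in groups.values():
            # largest constituent wins; ties go to the lexicographically
            # smallest representative
            largest = min(member_cids,
                          key=lambda c: (-len(clusters[c]),
                                         current.representatives[c]))
            rep = current.representatives[largest]
            new_cid = largest
            representatives[new_cid] = rep
            for cid in member_cids:
                for p in clusters[cid]:
                    assignment[p] = new_cid
        current = Clustering(assignment=assignment,
                             representatives=representatives)
        if not iterate:
            break
    logger.info("merge_clusters: %d -> %d clusters",
                clustering.n_clusters, current.n_clusters)
    return current, all_events


def compare_clusterings_nmi(c1: Clustering, c2: Clustering) -> float:
    """Normalized mutual information between two partitions.

    Restricted to proteins present in both universes; arithmetic-mean
    normalization; symmetric in its arguments.
    """
    shared = sorted(c1.universe & c2.universe)
    if not shared:
        raise ValueError("clusterings share no proteins")
    labels1 = [c1.assignment[p] for p in shared]
    labels2 = [c2.assignment[p] for p in shared]
    return float(normalized_mutual_info_score(labels1, labels2,
                                              average_method="arithmetic"))


def two_stage_pipeline(sequence_edges: Sequence[SimilarityEdge],
                       structure_edges: Sequence[SimilarityEdge],
                       universe: Iterable[str],
                       min_identity: float = DEFAULT_MIN_IDENTITY,
                       min_tm: float = DEFAULT_MIN_TM,
                       min_cov: float = DEFAULT_MIN_COV,
                       merge_threshold: float = DEFAULT_MERGE_THRESHOLD,
                       merge_on_representatives: bool = False,
                       ) -> tuple[Clustering, Clustering, Clustering,
                                  list[MergeEvent]]:
    """Run sequence clustering, structural clustering of representatives,
    composition, and the connectivity merge.

    Returns (sequence clustering, composed clustering, merged clustering,
    merge events). The merge step by default evaluates connectivity over all
    proteins; ``merge_on_representatives`` restricts the structural edges to
    representatives first.
    """
    universe = set(universe)
    seq = cluster_greedy(sequence_edges, min_identity, min_cov, universe)
    reps = set(seq.representatives.values())
    struct_edges_reps = [e for e in structure_edges
                         if e.query_id in reps and e.target_id in reps]
    struct = cluster_greedy(struct_edges_reps, min_tm, min_cov, reps)
    composed = compose_two_stage(seq, struct)
    merge_edges = filter_edges(structure_edges, min_tm, min_cov)
    if merge_on_representatives:
        merge_edges = [e for e in merge_edges
                       if e.query_id in reps and e.target_id in reps]
    merged, events = merge_clusters(composed, merge_edges,
                                    threshold=merge_threshold)
    return seq, composed, merged, events
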