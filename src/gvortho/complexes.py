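"""Ranking and grouping of homologous PDB complexes, and interface-edge
networks from chain coordinates.

A complex hit records, per PDB entry, which chains have homologs among the
query proteins. Hits are ranked by the number of homologous chains and
grouped greedily by cosine similarity of their homologous-protein sets, so
redundant depositions of the same complex collapse onto one representative.
Putative direct interactions are read off the representative complex
geometry: two homolog-bearing chains are connected when their minimum
inter-chain point distance is below 8 Å (strict).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

DEFAULT_INTERFACE_CUTOFF = 8.0  # Å
DEFAULT_GROUP_SIM = 0.8
_BRUTE_FORCE_MAX_POINTS = 5000


@dataclass
class ComplexHitSet:
    """Per-PDB-entry chain -> homologous query proteins map."""

    pdb_id: str
    chain_hits: dict[str, set[str]] = field(default_factory=dict)

    @property
    def n_homologous_chains(self) -> int:
        return sum(1 for homologs in self.chain_hits.values() if homologs)

    @property
    def homolog_set(self) -> frozenset[str]:
        return frozenset(p for homologs in self.chain_hits.values()
                         for p in homologs)


@dataclass
class ChainPoints:
    """3-D point set (Å) of one chain; Cα or all-atom, caller's choice."""

    pdb_id: str
    chain_id: str
    points: Sequence[tuple[float, float, float]]

    def __post_init__(self) -> None:
        if len(self.points) == 0:
            raise ValueError(f"chain {self.pdb_id}/{self.chain_id} has no "
                             f"points")
        arr = np.asarray(self.points, dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError(f"non-finite coordinates in chain "
                             f"{self.pdb_id}/{self.chain_id}")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)


def complex_cosine_similarity(set_a: Iterable[str],
                              set_b: Iterable[str]) -> float:
    """Cosine of the binary incidence vectors of two homolog sets:
    |a & b| / sqrt(|a| * |b|)."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("cosine similarity of an empty set is undefined")
    return len(a & b) / math.sqrt(len(a) * len(b))


@dataclass
class ComplexGroup:
    representative: ComplexHitSet
    members: list[ComplexHitSet]


def rank_and_group_complexes(hits: Sequence[ComplexHitSet],
                             sim_threshold: float = DEFAULT_GROUP_SIM,
                             ) -> list[ComplexGroup]:
    """Sort complexes by homologous-chain count and group redundant ones.

    Hits are sorted descending by ``n_homologous_chains`` (ties by pdb_id)
    and greedily assigned to the first existing group whose representative's
    homolog set has cosine similarity >= ``sim_threshold``; otherwise they
    open a new group. Each representative therefore has the maximal chain
    count within its group, and the groups partition the input.
    """
    if not hits:
        raise ValueError("no complex hits to group")
    ranked = sorted(hits, key=lambda h: (-h.n_homologous_chains, h.pdb_id))
    groups: list[ComplexGroup] = []
    for hit in ranked:
        placed = False
        for group in groups:
            rep_set = group.representative.homolog_set
            if rep_set and hit.homolog_set and complex_cosine_similarity(
                    rep_set, hit.homolog_set) >= sim_threshold:
                group.members.append(hit)
                placed = True
                break
        if not placed:
            groups.append(ComplexGroup(representative=hit, members=[hit]))
    return groups


def min_interchain_distance(points_a: np.ndarray,
                            points_b: np.ndarray) -> float:
    """Minimum pairwise distance between two point sets.

    Direct pairwise scan for small sets; k-d tree beyond
    ``_BRUTE_FORCE_MAX_POINTS`` points.
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if len(a) + len(b) <= _BRUTE_FORCE_MAX_POINTS:
        return float(cdist(a, b).min())
    tree = cKDTree(b)
    d, _ = tree.query(a, k=1)
    return float(d.min())


def interface_edges(chains: Sequence[ChainPoints],
                    cutoff: float = DEFAULT_INTERFACE_CUTOFF,
                    homologs: Mapping[str, str] | None = None,
                    ) -> list[tuple[str, str, float]]:
    """Edges between homolog-labelled chains closer than ``cutoff`` Å.

    ``homologs`` maps chain_id -> query protein; only labelled chains are
    considered, and edges are emitted on the protein labels (sorted pair)
    together with the minimum distance. The cutoff is strict: a pair at
    exactly ``cutoff`` gets no edge.
    """
    if homologs is None:
        homologs = {c.chain_id: c.chain_id for c in chains}
    labelled = [c for c in chains if c.chain_id in homologs]
    if len(labelled) < 2:
        raise ValueError("need >= 2 homolog-labelled chains")
    edges: list[tuple[str, str, float]] = []
    for i, ca in enumerate(labelled):
        for cb in labelled[i + 1:]:
            dmin = min_interchain_distance(ca.array, cb.array)
            if dmin < cutoff:
                pa, pb = sorted((homologs[ca.chain_id], homologs[cb.chain_id]))
                edges.append((pa, pb, dmin))
    return sorted(edges)
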