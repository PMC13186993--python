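"""Consensus transmembrane calling, Fisher-exact enrichment, the nucleoid
spectral-count filter, and reciprocal-best-hit label transfer.

These are the annotation layers around the clustering and interactome
modules: a protein is called transmembrane when at least ``k`` of the
configured predictors agree (default 2 of 3, reducing single-predictor false
positives); term and shape enrichments use Fisher's exact test on 2x2 tables
with the sample odds ratio ad/bc; nucleoid candidates must be seen with >= 2
peptides and be nucleoid-exclusive or >= 2-fold nucleoid-enriched in the
pellet or the supernatant comparison; and region/expression labels are
transferred between proteomes through mutual best hits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .io_formats import SimilarityEdge


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows = group membership, columns = property."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative entry in contingency table")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty contingency table")


@dataclass(frozen=True)
class SpectralCountRecord:
    protein_id: str
    peptides: int
    nucleoid_pellet: int
    nucleoid_supernatant: int
    virion_pellet: int
    virion_supernatant: int

    def __post_init__(self) -> None:
        if self.peptides < 0 or min(self.nucleoid_pellet,
                                    self.nucleoid_supernatant,
                                    self.virion_pellet,
                                    self.virion_supernatant) < 0:
            raise ValueError("negative spectral count")


@dataclass(frozen=True)
class TermEnrichment:
    term: str
    n_study: int
    n_background: int
    odds_ratio: float
    p_value: float
    corrected_p: float
    significant: bool


def consensus_tmd(calls: Mapping[str, Mapping[str, bool]],
                  k: int = 2) -> dict[str, bool]:
    """Positive iff >= k predictors call a transmembrane domain.

    ``calls``: protein -> predictor -> bool; a predictor absent for a
    protein counts as False. The predictor set is the union over proteins
    and must contain at least ``k`` predictors.
    """
    predictors = sorted({p for c in calls.values() for p in c})
    if k > len(predictors):
        raise ValueError(f"k={k} exceeds the {len(predictors)} configured "
                         f"predictors")
    return {protein: sum(bool(c.get(p, False)) for p in predictors) >= k
            for protein, c in calls.items()}


def fisher_exact_2x2(table: ContingencyTable2x2,
                     alternative: str = "two_sided",
                     ) -> tuple[float, float]:
    """Sample odds ratio ad/bc and exact hypergeometric p-value.

    OR is inf when bc = 0 and ad > 0, NaN when both products are 0.
    ``alternative`` in {two_sided, greater, less}.
    """
    alt = alternative.replace("_", "-")
    if alt not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    ad = table.a * table.d
    bc = table.b * table.c
    if bc == 0:
        odds = math.nan if ad == 0 else math.inf
    else:
        odds = ad / bc
    result = stats.fisher_exact([[table.a, table.b], [table.c, table.d]],
                                alternative=alt)
    return odds, float(result.pvalue)


def go_enrichment(study: Iterable[str], background: Iterable[str],
                  annotations: Mapping[str, Iterable[str]],
                  alpha: float = 0.01) -> list[TermEnrichment]:
    """One-sided (greater) Fisher term enrichment of a study set against a
    background, Bonferroni-corrected over the tested terms.

    Terms are used exactly as annotated (no ontology propagation; callers may
    pre-propagate with an ancestor table). A term is significant when its
    Bonferroni-corrected p is below ``alpha``.
    """
    study = set(study)
    background = set(background)
    if not study:
        raise ValueError("empty study set")
    if not study <= background:
        raise ValueError("study set must be a subset of the background")
    term_members: dict[str, set[str]] = {}
    for protein in background:
        for term in annotations.get(protein, ()):
            term_members.setdefault(term, set()).add(protein)
    if not any(term_members.get(t, set()) & study for t in term_members):
        raise ValueError("annotations cover no study protein")
    rest = background - study
    m = len(term_members)
    results: list[TermEnrichment] = []
    for term in sorted(term_members):
        members = term_members[term]
        a = len(members & study)
        b = len(study) - a
        c = len(members & rest)
        d = len(rest) - c
        odds, p = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d),
                                   alternative="greater")
        corrected = min(1.0, m * p)
        results.append(TermEnrichment(
            term=term, n_study=a, n_background=len(members),
            odds_ratio=odds, p_value=p, corrected_p=corrected,
            significant=corrected < alpha))
    return results


def nucleoid_enrichment_filter(records: Iterable[SpectralCountRecord],
                               min_peptides: int = 2,
                               min_ratio: float = 2.0) -> set[str]:
    """Spectral-count filter for nucleoid-enriched proteins.

    Enriched iff identified with >= ``min_peptides`` peptides AND, in the
    pellet or the supernatant comparison, the protein is nucleoid-exclusive
    (nucleoid count > 0, virion count 0) or at least ``min_ratio``-fold more
    abundant in the nucleoid fraction.
    """
    def branch(nucleoid: int, virion: int) -> bool:
        if nucleoid == 0:
            return False
        if virion == 0:
            return True
        return nucleoid / virion >= min_ratio

    enriched: set[str] = set()
    for r in records:
        if r.peptides < min_peptides:
            continue
        if branch(r.nucleoid_pellet, r.virion_pellet) or \
                branch(r.nucleoid_supernatant, r.virion_supernatant):
            enriched.add(r.protein_id)
    return enriched


def _best_hits(hits: Iterable[SimilarityEdge]) -> dict[str, str]:
    """query -> best target by (lowest e-value, highest score, lexicographic
    target)."""
    best: dict[str, SimilarityEdge] = {}
    for e in hits:
        cur = best.get(e.query_id)
        if cur is None or (e.evalue, -e.score, e.target_id) < (
                cur.evalue, -cur.score, cur.target_id):
            best[e.query_id] = e
    return {q: e.target_id for q, e in best.items()}


def reciprocal_best_hit(hits_ab: Iterable[SimilarityEdge],
                        hits_ba: Iterable[SimilarityEdge],
                        ) -> list[tuple[str, str]]:
    """Mutual-best-hit pairs (a, b) between two proteomes.

    A pair is kept iff b is a's best hit in the A->B search and a is b's
    best hit in B->A. Ties are broken deterministically (e-value, then
    score, then target ID), giving a one-to-one partial matching.
    """
    ab = _best_hits(hits_ab)
    ba = _best_hits(hits_ba)
    return sorted((a, b) for a, b in ab.items() if ba.get(b) == a)


def transfer_labels(pairs: Sequence[tuple[str, str]],
                    labels: Mapping[str, str]) -> dict[str, str]:
    """Carry labels of B-proteins over to their RBH partners in A."""
    return {a: labels[b] for a, b in pairs if b in labels}


def shape_region_table(cluster_shape: Mapping[str, str],
                       protein_cluster: Mapping[str, str],
                       protein_region: Mapping[str, str],
                       region_a: str, region_b: str,
                       level: str = "protein") -> ContingencyTable2x2:
    """Build the icosahedral-vs-mixed x region 2x2 table.

    Rows: shape class of the protein's cluster (icosahedral_only vs mixed;
    unknown-shape clusters are skipped). Columns: ``region_a`` vs
    ``region_b``. ``level="protein"`` counts proteins; ``level="cluster"``
    counts distinct clusters (a cluster contributes to a region when at
    least one of its proteins lies there).
    """
    cells = {("icosahedral_only", region_a): set(),
             ("icosahedral_only", region_b): set(),
             ("mixed", region_a): set(),
             ("mixed", region_b): set()}
    for protein, cluster in protein_cluster.items():
        shape = cluster_shape.get(cluster)
        region = protein_region.get(protein)
        if shape not in ("icosahedral_only", "mixed"):
            continue
        if region not in (region_a, region_b):
            continue
        key = protein if level == "protein" else cluster
        cells[(shape, region)].add(key)
    return ContingencyTable2x2(
        a=len(cells[("icosahedral_only", region_a)]),
        b=len(cells[("icosahedral_only", region_b)]),
        c=len(cells[("mixed", region_a)]),
        d=len(cells[("mixed", region_b)]),
    )
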