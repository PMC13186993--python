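"""Cluster-level taxonomic annotation.

Given an orthogroup clustering, a genome taxonomy and a protein -> genome
map, this module assigns each cluster the taxonomic level of its last common
ancestor (LCA), flags genus ORFans of a focal virus, counts and bins paralogs
of the focal genome, and classifies clusters by the virion shape of their
member genomes (icosahedral-only vs mixed).

The LCA level of a cluster is the DEEPEST rank (species deepest,
superkingdom shallowest) at which every member genome carries the same
non-absent taxon. An absent rank (e.g. subfamily outside the one family
where it is annotated) can never be the LCA rank. If even the superkingdom
differs, the sentinel ``"none"`` is returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .io_formats import Clustering, RANKS, TaxonomyTable, VirionShape

#: Ranks deepest-first, the order in which the LCA scan proceeds.
RANKS_DEEP_FIRST = tuple(reversed(RANKS))

NO_COMMON_RANK = "none"

PARALOG_BINS = ("0", "1", "2-5", "6-10", "11-20", "21+")


@dataclass(frozen=True)
class ClusterAnnotation:
    cluster_id: str
    lca_rank: str
    lca_taxon: str | None
    is_genus_orfan: bool
    paralog_count: int
    paralog_bin: str
    shape_class: str


def lca_level(members: Iterable[str], genome_of: Mapping[str, str],
              taxonomy: TaxonomyTable) -> tuple[str, str | None]:
    """Deepest rank at which all member genomes share one non-absent taxon.

    Returns ``(rank, taxon)``; ``("none", None)`` when not even the
    superkingdom is shared. Raises ``KeyError`` for a member whose genome is
    unknown to the taxonomy.
    """
    members = list(members)
    if not members:
        raise ValueError("empty cluster")
    genomes = sorted({genome_of[m] for m in members})
    lineages = [taxonomy.lineage(g) for g in genomes]
    for rank in RANKS_DEEP_FIRST:
        values = {lin[rank] for lin in lineages}
        if len(values) == 1:
            taxon = next(iter(values))
            if taxon is not None:
                return rank, taxon
    return NO_COMMON_RANK, None


def paralog_bin(count: int) -> str:
    if count < 0:
        raise ValueError("negative paralog count")
    if count <= 1:
        return str(count)
    if count <= 5:
        return "2-5"
    if count <= 10:
        return "6-10"
    if count <= 20:
        return "11-20"
    return "21+"


def paralog_counts(clustering: Clustering, genome_of: Mapping[str, str],
                   focal_genome: str) -> dict[str, tuple[int, str]]:
    """Per-cluster count (and bin) of focal-genome proteins."""
    out: dict[str, tuple[int, str]] = {}
    for cid, members in clustering.clusters().items():
        n = sum(1 for p in members if genome_of.get(p) == focal_genome)
        out[cid] = (n, paralog_bin(n))
    return out


def shape_class(members: Iterable[str], genome_of: Mapping[str, str],
                taxonomy: TaxonomyTable) -> str:
    """Classify a cluster by the virion shapes of its member genomes.

    ``mixed`` as soon as one genome with a non-icosahedral virion is present
    (monotone in cluster growth); ``icosahedral_only`` when every genome with
    a known shape is icosahedral and at least one shape is known; ``unknown``
    when no shape is known.
    """
    shapes = {taxonomy.shape(genome_of[m]) for m in members}
    if VirionShape.non_icosahedral in shapes:
        return "mixed"
    if VirionShape.icosahedral in shapes:
        return "icosahedral_only"
    return "unknown"


def annotate_clusters(clustering: Clustering, genome_of: Mapping[str, str],
                      taxonomy: TaxonomyTable, focal_genome: str,
                      focal_genus: str | None = None,
                      ) -> dict[str, ClusterAnnotation]:
    """Full per-cluster annotation: LCA level, ORFan status, paralogs, shape.

    A cluster is a genus ORFan when its LCA rank is genus or species and that
    genus is the focal genus (by default the focal genome's own genus).
    """
    if focal_genus is None:
        focal_genus = taxonomy.taxon(focal_genome, "genus")
    counts = paralog_counts(clustering, genome_of, focal_genome)
    annotations: dict[str, ClusterAnnotation] = {}
    for cid, members in clustering.clusters().items():
        rank, taxon = lca_level(members, genome_of, taxonomy)
        genera = {taxonomy.taxon(genome_of[m], "genus") for m in members}
        orfan = (rank in ("genus", "species")
                 and focal_genus is not None
                 and genera == {focal_genus})
        n, pbin = counts[cid]
        annotations[cid] = ClusterAnnotation(
            cluster_id=cid,
            lca_rank=rank,
            lca_taxon=taxon,
            is_genus_orfan=orfan,
            paralog_count=n,
            paralog_bin=pbin,
            shape_class=shape_class(members, genome_of, taxonomy),
        )
    return annotations


def lca_histogram(annotations: Mapping[str, ClusterAnnotation]) -> dict[str, int]:
    """Cluster counts per LCA rank (the conservation-level profile)."""
    hist = {rank: 0 for rank in RANKS_DEEP_FIRST}
    hist[NO_COMMON_RANK] = 0
    for ann in annotations.values():
        hist[ann.lca_rank] += 1
    return hist


def write_annotations(annotations: Mapping[str, ClusterAnnotation]) -> str:
    lines = ["cluster_id\tlca_rank\tlca_taxon\torfan\tparalog_count\t"
             "paralog_bin\tshape_class"]
    for cid in sorted(annotations):
        a = annotations[cid]
        lines.append("\t".join([
            a.cluster_id, a.lca_rank, a.lca_taxon or "",
            "1" if a.is_genus_orfan else "0",
            str(a.paralog_count), a.paralog_bin, a.shape_class,
        ]))
    return "\n".join(lines) + "\n"
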