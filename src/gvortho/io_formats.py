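"""Readers and writers for the tabular formats the toolkit consumes.

All downstream modules operate on the in-memory domain types defined here:
:class:`SimilarityEdge` (one pairwise sequence- or structure-similarity hit),
:class:`TaxonomyTable` (genome lineages over eight ranks plus virion shape),
:class:`Clustering` (a partition of protein IDs with designated
representatives) and :class:`AbundanceMatrix` (proteins x samples label-free
MS intensities with a bait/control design).

Conventions
-----------
* Tables are tab-separated. Similarity tables are accepted with or without a
  header (columns matched by name when a header is present, by position
  otherwise) — the convention of ``easy-search``-style search-tool output.
* Identifiers are case-sensitive opaque strings.
* Intensity 0 and empty cells are stored as missing (standard MS convention).
* Floats are written with 6 significant digits; write-then-read round trips
  are identity up to that precision.
* Readers never silently drop rows: anything flagged (e.g. self-edges) is
  counted and reported through the module logger.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"

#: Fixed rank order, shallowest to deepest.
RANKS = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "subfamily",
    "genus",
    "species",
)

SIMILARITY_COLUMNS = ("query", "target", "score", "qcov", "tcov", "evalue")


class FormatError(ValueError):
    """A malformed or invalid input table."""


class EdgeKind(str, Enum):
    sequence = "sequence"
    structure = "structure"


class VirionShape(str, Enum):
    icosahedral = "icosahedral"
    non_icosahedral = "non_icosahedral"
    unknown = "unknown"


@dataclass(frozen=True)
class SimilarityEdge:
    """One pairwise similarity hit.

    ``score`` is a fraction in [0, 1]: sequence-identity fraction for
    ``kind == sequence``, TM-score for ``kind == structure``. Coverage is
    reported for both query and target because clustering requires
    bidirectional coverage.
    """

    query_id: str
    target_id: str
    score: float
    coverage_query: float
    coverage_target: float
    evalue: float
    kind: EdgeKind = EdgeKind.sequence

    def __post_init__(self) -> None:
        for name in ("score", "coverage_query", "coverage_target"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise FormatError(f"{name}={v!r} outside [0, 1] for edge "
                                  f"{self.query_id}-{self.target_id}")
        if self.evalue < 0:
            raise FormatError(f"negative evalue for edge "
                              f"{self.query_id}-{self.target_id}")

    @property
    def is_self(self) -> bool:
        return self.query_id == self.target_id


@dataclass
class TaxonomyTable:
    """Genome -> ordered 8-rank lineage plus virion shape.

    Absent ranks are stored as ``None`` (never as empty strings). ``species``
    must be present for every genome; ``subfamily`` commonly is not.
    """

    lineages: dict[str, dict[str, str | None]] = field(default_factory=dict)
    shapes: dict[str, VirionShape] = field(default_factory=dict)

    def add(self, genome_id: str, lineage: Mapping[str, str | None],
            shape: VirionShape = VirionShape.unknown) -> None:
        if genome_id in self.lineages:
            raise FormatError(f"duplicate genome_id {genome_id!r}")
        row = {rank: lineage.get(rank) or None for rank in RANKS}
        if not row["species"]:
            raise FormatError(f"genome {genome_id!r} has no species")
        self.lineages[genome_id] = row
        self.shapes[genome_id] = shape

    def lineage(self, genome_id: str) -> dict[str, str | None]:
        try:
            return self.lineages[genome_id]
        except KeyError:
            raise KeyError(f"unknown genome {genome_id!r}") from None

    def taxon(self, genome_id: str, rank: str) -> str | None:
        return self.lineage(genome_id)[rank]

    def shape(self, genome_id: str) -> VirionShape:
        return self.shapes.get(genome_id, VirionShape.unknown)

    @property
    def genomes(self) -> list[str]:
        return list(self.lineages)

    def validate_tree_consistency(self) -> list[str]:
        """Warn when the taxonomy is not tree-shaped.

        In a consistent taxonomy, two genomes sharing a taxon at a deep rank
        also share every shallower (non-absent) rank. Returns the list of
        warning messages (also logged).
        """
        warnings: list[str] = []
        genomes = self.genomes
        for i, ga in enumerate(genomes):
            la = self.lineages[ga]
            for gb in genomes[i + 1:]:
                lb = self.lineages[gb]
                shared_deep = False
                for rank in reversed(RANKS):  # deepest first
                    a, b = la[rank], lb[rank]
                    if a is not None and a == b:
                        shared_deep = True
                    elif shared_deep and a is not None and b is not None:
                        msg = (f"genomes {ga!r}/{gb!r} share a deeper rank but "
                               f"differ at {rank} ({a!r} vs {b!r})")
                        warnings.append(msg)
                        logger.warning("taxonomy inconsistency: %s", msg)
                        break
        return warnings


@dataclass
class Clustering:
    """A partition of protein IDs into clusters with representatives.

    ``assignment`` is total over the protein universe; each representative is
    a member of its own cluster. Cluster IDs are stable given the input.
    """

    assignment: dict[str, str] = field(default_factory=dict)
    representatives: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, rep in self.representatives.items():
            if self.assignment.get(rep) != cid:
                raise FormatError(
                    f"representative {rep!r} is not a member of its own "
                    f"cluster {cid!r}")
        missing = set(self.assignment.values()) - set(self.representatives)
        if missing:
            raise FormatError(f"clusters without representative: {sorted(missing)}")

    @property
    def universe(self) -> set[str]:
        return set(self.assignment)

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    def members(self, cluster_id: str) -> set[str]:
        return {p for p, c in self.assignment.items() if c == cluster_id}

    def clusters(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {cid: set() for cid in self.representatives}
        for p, c in self.assignment.items():
            out[c].add(p)
        return out


@dataclass
class AbundanceMatrix:
    """Proteins x samples intensity matrix with a bait/control design.

    ``intensities`` holds raw (or, after preprocessing, log2) values with NaN
    for missing; ``design`` maps every sample (column) to a condition,
    conventionally ``"bait"`` or ``"control"``.
    """

    intensities: pd.DataFrame
    design: dict[str, str]
    contaminant_flags: dict[str, bool] = field(default_factory=dict)
    bait_name: str | None = None
    log_scale: bool = False
    #: protein x condition counts of pre-imputation quantified replicates,
    #: filled in by preprocessing (None on freshly read matrices)
    quantified_counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [s for s in self.intensities.columns if s not in self.design]
        if missing:
            raise FormatError(f"samples missing from design: {missing}")
        conditions = set(self.design.values())
        for cond in conditions:
            if not any(self.design[s] == cond
                       for s in self.intensities.columns):
                raise FormatError(f"condition {cond!r} has no samples")
        if not self.log_scale:
            vals = self.intensities.to_numpy()
            if (vals[~pd.isna(vals)] <= 0).any():
                raise FormatError("present intensities must be strictly "
                                  "positive (zeros are missing)")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.intensities.columns
                if self.design[s] == condition]

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.intensities.columns:
            c = self.design[s]
            if c not in seen:
                seen.append(c)
        return seen


# ---------------------------------------------------------------------------
# Similarity tables
# ---------------------------------------------------------------------------

def _as_lines(stream: TextIO | str | Iterable[str]) -> list[str]:
    if isinstance(stream, str):
        return stream.splitlines()
    if hasattr(stream, "read"):
        return stream.read().splitlines()
    return list(stream)


def read_similarity_table(stream: TextIO | str,
                          kind: EdgeKind | str = EdgeKind.sequence,
                          column_map: Sequence[str] | None = None,
                          ) -> list[SimilarityEdge]:
    """Read a TSV of pairwise hits into :class:`SimilarityEdge` records.

    Columns are ``query, target, score, qcov, tcov, evalue``; a header row is
    detected by column names, otherwise positional order is assumed (or the
    order given in ``column_map``). Input row order is preserved. Self-edges
    are kept but counted and logged.
    """
    kind = EdgeKind(kind)
    lines = [ln for ln in _as_lines(stream) if ln.strip()]
    if not lines:
        return []
    order = list(column_map) if column_map else list(SIMILARITY_COLUMNS)
    first = lines[0].rstrip("\n").split("\t")
    start = 0
    if set(c.strip().lower() for c in first) >= set(SIMILARITY_COLUMNS):
        order = [c.strip().lower() for c in first]
        start = 1
    idx = {name: order.index(name) for name in SIMILARITY_COLUMNS}
    edges: list[SimilarityEdge] = []
    n_self = 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        fields = line.rstrip("\n").split("\t")
        if len(fields) < len(order):
            raise FormatError(f"line {lineno}: expected {len(order)} columns, "
                              f"got {len(fields)}")
        try:
            edge = SimilarityEdge(
                query_id=fields[idx["query"]],
                target_id=fields[idx["target"]],
                score=float(fields[idx["score"]]),
                coverage_query=float(fields[idx["qcov"]]),
                coverage_target=float(fields[idx["tcov"]]),
                evalue=float(fields[idx["evalue"]]),
                kind=kind,
            )
        except FormatError as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
        except ValueError as exc:
            raise FormatError(f"line {lineno}: malformed value ({exc})") from None
        if edge.is_self:
            n_self += 1
        edges.append(edge)
    if n_self:
        logger.info("read_similarity_table: %d self-edges flagged", n_self)
    return edges


def write_similarity_table(edges: Iterable[SimilarityEdge],
                           stream: TextIO | None = None) -> str:
    out = stream or io.StringIO()
    out.write("\t".join(SIMILARITY_COLUMNS) + "\n")
    for e in edges:
        out.write("\t".join([
            e.query_id, e.target_id,
            FLOAT_FMT % e.score, FLOAT_FMT % e.coverage_query,
            FLOAT_FMT % e.coverage_target, FLOAT_FMT % e.evalue,
        ]) + "\n")
    return out.getvalue() if stream is None else ""


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

def read_taxonomy_table(stream: TextIO | str) -> TaxonomyTable:
    """Read a genome taxonomy TSV (genome_id, 8 ranks, shape).

    Empty rank cells are recorded as absent. Duplicate genome IDs and missing
    species are errors.
    """
    lines = [ln for ln in _as_lines(stream) if ln.strip()]
    if not lines:
        return TaxonomyTable()
    header = [c.strip().lower() for c in lines[0].split("\t")]
    expected = ["genome_id", *RANKS, "shape"]
    start = 1 if header[0] == "genome_id" else 0
    if start == 0:
        header = expected
    table = TaxonomyTable()
    for lineno, line in enumerate(lines[start:], start=start + 1):
        fields = line.rstrip("\n").split("\t")
        row = dict(zip(header, fields))
        genome = row.get("genome_id", "").strip()
        if not genome:
            raise FormatError(f"line {lineno}: empty genome_id")
        lineage = {rank: (row.get(rank, "").strip() or None) for rank in RANKS}
        shape_raw = row.get("shape", "").strip() or "unknown"
        try:
            shape = VirionShape(shape_raw)
        except ValueError:
            raise FormatError(f"line {lineno}: unknown shape {shape_raw!r}")
        try:
            table.add(genome, lineage, shape)
        except FormatError as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
    return table


def write_taxonomy_table(table: TaxonomyTable,
                         stream: TextIO | None = None) -> str:
    out = stream or io.StringIO()
    out.write("\t".join(["genome_id", *RANKS, "shape"]) + "\n")
    for genome, lineage in table.lineages.items():
        cells = [genome] + [(lineage[r] or "") for r in RANKS]
        cells.append(table.shape(genome).value)
        out.write("\t".join(cells) + "\n")
    return out.getvalue() if stream is None else ""


# ---------------------------------------------------------------------------
# Clustering membership tables
# ---------------------------------------------------------------------------

def read_clustering(stream: TextIO | str) -> Clustering:
    """Read a two-column (representative_id, member_id) membership TSV."""
    assignment: dict[str, str] = {}
    representatives: dict[str, str] = {}
    lines = [ln for ln in _as_lines(stream) if ln.strip()]
    start = 0
    if lines and lines[0].split("\t")[0].strip().lower() == "representative_id":
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise FormatError(f"line {lineno}: expected 2 columns")
        rep, member = fields[0], fields[1]
        if member in assignment:
            raise FormatError(f"line {lineno}: protein {member!r} assigned twice")
        assignment[member] = rep
        representatives[rep] = rep
    return Clustering(assignment=assignment, representatives=representatives)


def write_clustering(clustering: Clustering,
                     stream: TextIO | None = None) -> str:
    out = stream or io.StringIO()
    out.write("representative_id\tmember_id\n")
    for cid in sorted(clustering.representatives):
        rep = clustering.representatives[cid]
        for member in sorted(clustering.members(cid)):
            out.write(f"{rep}\t{member}\n")
    return out.getvalue() if stream is None else ""


# ---------------------------------------------------------------------------
# Abundance matrices
# ---------------------------------------------------------------------------

def read_abundance_matrix(stream: TextIO | str, design_stream: TextIO | str,
                          ) -> AbundanceMatrix:
    """Read a wide intensity TSV plus a (sample_id, condition[, bait_name])
    design TSV.

    Zeros and empty cells become missing. An optional boolean ``contaminant``
    column in the matrix marks contaminant proteins. Every matrix sample must
    appear in the design.
    """
    text = "\n".join(_as_lines(stream))
    df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0)
    contaminants: dict[str, bool] = {}
    for col in list(df.columns):
        if col.strip().lower() == "contaminant":
            contaminants = {
                str(p): bool(int(v)) if not pd.isna(v) else False
                for p, v in df[col].items()
            }
            df = df.drop(columns=[col])
    df = df.astype(float)
    if (df.to_numpy() < 0).any():
        raise FormatError("negative intensity in abundance matrix")
    df = df.mask(df == 0)  # zeros are missing

    design: dict[str, str] = {}
    bait_name: str | None = None
    dlines = [ln for ln in _as_lines(design_stream) if ln.strip()]
    start = 1 if dlines and dlines[0].split("\t")[0].strip().lower() == "sample_id" else 0
    for line in dlines[start:]:
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise FormatError("design rows need sample_id and condition")
        design[fields[0]] = fields[1]
        if len(fields) > 2 and fields[2]:
            bait_name = fields[2]
    missing = [s for s in df.columns if s not in design]
    if missing:
        raise FormatError(f"samples missing from design: {missing}")
    return AbundanceMatrix(intensities=df, design=design,
                           contaminant_flags=contaminants,
                           bait_name=bait_name)


def write_abundance_matrix(matrix: AbundanceMatrix,
                           stream: TextIO | None = None) -> str:
    out = stream or io.StringIO()
    df = matrix.intensities
    out.write("protein_id\t" + "\t".join(df.columns) + "\n")
    for pid, row in df.iterrows():
        cells = [pid]
        for v in row:
            cells.append("" if pd.isna(v) else FLOAT_FMT % v)
        out.write("\t".join(cells) + "\n")
    return out.getvalue() if stream is None else ""


def write_design(matrix: AbundanceMatrix,
                 stream: TextIO | None = None) -> str:
    out = stream or io.StringIO()
    out.write("sample_id\tcondition\tbait_name\n")
    for s in matrix.sample_ids:
        out.write(f"{s}\t{matrix.design[s]}\t{matrix.bait_name or ''}\n")
    return out.getvalue() if stream is None else ""


# ---------------------------------------------------------------------------
# Auxiliary small tables
# ---------------------------------------------------------------------------

def read_key_value_table(stream: TextIO | str, n_cols: int = 2,
                         header: bool = True) -> list[tuple[str, ...]]:
    """Generic strict reader for small auxiliary TSVs (predictor calls,
    region labels, expression clusters, spectral counts, PDB hits, chain
    coordinates are all thin wrappers over this)."""
    lines = [ln for ln in _as_lines(stream) if ln.strip()]
    start = 1 if header and lines else 0
    rows: list[tuple[str, ...]] = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        fields = tuple(line.rstrip("\n").split("\t"))
        if len(fields) < n_cols:
            raise FormatError(f"line {lineno}: expected >= {n_cols} columns")
        rows.append(fields)
    return rows


def read_predictor_calls(stream: TextIO | str) -> tuple[list[str], dict[str, dict[str, bool]]]:
    """Read a (protein, predictor1, predictor2, ...) 0/1 call table.

    Returns (predictor names, protein -> predictor -> bool).
    """
    lines = [ln for ln in _as_lines(stream) if ln.strip()]
    if not lines:
        raise FormatError("empty predictor-call table")
    header = lines[0].rstrip("\n").split("\t")
    predictors = header[1:]
    calls: dict[str, dict[str, bool]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.rstrip("\n").split("\t")
        if len(fields) != len(header):
            raise FormatError(f"line {lineno}: column count mismatch")
        calls[fields[0]] = {p: bool(int(v)) for p, v in zip(predictors, fields[1:])}
    return predictors, calls


def read_region_labels(stream: TextIO | str) -> dict[str, str]:
    return {r[0]: r[1] for r in read_key_value_table(stream)}


def read_chain_points(stream: TextIO | str):
    """Read (pdb_id, chain_id, x, y, z) rows into ChainPoints objects."""
    from .complexes import ChainPoints  # local import avoids a cycle
    rows = read_key_value_table(stream, n_cols=5)
    grouped: dict[tuple[str, str], list[tuple[float, float, float]]] = {}
    for pdb_id, chain_id, x, y, z, *_ in rows:
        pt = (float(x), float(y), float(z))
        if not all(math.isfinite(c) for c in pt):
            raise FormatError(f"non-finite coordinate for {pdb_id}/{chain_id}")
        grouped.setdefault((pdb_id, chain_id), []).append(pt)
    return [ChainPoints(pdb_id=k[0], chain_id=k[1], points=v)
            for k, v in grouped.items()]
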