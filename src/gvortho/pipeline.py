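"""End-to-end orchestration: cluster -> merge -> annotate and
ipms -> select -> networks, from a single flat config.

Every run writes its artifacts plus a machine-readable JSON report (cluster
counts per stage, LCA histogram, interactors per bait, communities) and logs
every parameter and seed, so output files are reproducible byte-for-byte
from (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import interactome, orthogroups, taxonomy as taxmod
from .io_formats import (read_abundance_matrix, read_similarity_table,
                         read_taxonomy_table, write_clustering)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat run configuration; CLI flags override file values."""

    sequence_edges: str | None = None
    structure_edges: str | None = None
    taxonomy: str | None = None
    genome_map: str | None = None       # TSV protein -> genome
    focal_genome: str | None = None
    abundance: str | None = None
    design: str | None = None
    out_dir: str = "gvortho_out"
    min_cov: float = 0.7
    min_identity: float = 0.2
    min_tm: float = 0.4
    merge_threshold: float = 0.65
    lfc_min: float = 1.0
    p_max: float = 0.01
    k_tmd: int = 2
    interface_cutoff: float = 8.0
    min_reps: int = 3
    normalization: str = "median_mad"
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        checks = [
            (0 < self.min_cov <= 1, "min_cov"),
            (0 <= self.min_identity <= 1, "min_identity"),
            (0 <= self.min_tm <= 1, "min_tm"),
            (0 < self.merge_threshold <= 1, "merge_threshold"),
            (0 < self.p_max <= 1, "p_max"),
            (self.min_reps >= 1, "min_reps"),
            (self.k_tmd >= 1, "k_tmd"),
            (self.interface_cutoff > 0, "interface_cutoff"),
        ]
        for ok, name in checks:
            if not ok:
                raise ValueError(f"config value {name} out of range")


def load_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` config file (TOML-style scalars)."""
    values: dict[str, object] = {}
    known = {f for f in RunConfig.__dataclass_fields__ if f != "extras"}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key = value")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip().strip('"').strip("'")
        if key not in known:
            values.setdefault("extras", {})[key] = val  # type: ignore[union-attr]
            continue
        ftype = RunConfig.__dataclass_fields__[key].type
        if "float" in str(ftype):
            values[key] = float(val)
        elif "int" in str(ftype):
            values[key] = int(val)
        else:
            values[key] = val
    return RunConfig(**values)  # type: ignore[arg-type]


def dump_config(config: RunConfig) -> str:
    lines = []
    for key, value in asdict(config).items():
        if key == "extras" or value is None:
            continue
        lines.append(f"{key} = {value}")
    return "\n".join(lines) + "\n"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stage graph and return the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: v for k, v in asdict(config).items()
                               if k != "extras" and v is not None},
                    "stages": {}}

    if config.sequence_edges and config.structure_edges:
        try:
            report["stages"].update(_run_clustering(config, out))
        except Exception as exc:  # noqa: BLE001 - reported with stage name
            raise StageError("clustering", exc) from exc
    if config.abundance and config.design:
        try:
            report["stages"].update(_run_ipms(config, out))
        except Exception as exc:  # noqa: BLE001
            raise StageError("ipms", exc) from exc
    if not report["stages"]:
        raise StageError("config", ValueError("no stage inputs configured"))

    (out / "report.json").write_text(json.dumps(report, indent=2,
                                                sort_keys=True) + "\n")
    return report


def _run_clustering(config: RunConfig, out: Path) -> dict:
    seq_edges = read_similarity_table(
        Path(config.sequence_edges).read_text(), kind="sequence")
    struct_edges = read_similarity_table(
        Path(config.structure_edges).read_text(), kind="structure")
    universe = {e.query_id for e in seq_edges} | \
        {e.target_id for e in seq_edges} | \
        {e.query_id for e in struct_edges} | \
        {e.target_id for e in struct_edges}
    seq, composed, merged, events = orthogroups.two_stage_pipeline(
        seq_edges, struct_edges, universe,
        min_identity=config.min_identity, min_tm=config.min_tm,
        min_cov=config.min_cov, merge_threshold=config.merge_threshold)
    (out / "clusters_sequence.tsv").write_text(write_clustering(seq))
    (out / "clusters_composed.tsv").write_text(write_clustering(composed))
    (out / "clusters_merged.tsv").write_text(write_clustering(merged))
    stage: dict = {
        "clustering": {
            "n_proteins": len(universe),
            "clusters_sequence": seq.n_clusters,
            "clusters_composed": composed.n_clusters,
            "clusters_merged": merged.n_clusters,
            "n_merge_events": sum(1 for e in events if e.merged),
        }
    }
    logger.info("clustering: %d -> %d -> %d clusters", seq.n_clusters,
                composed.n_clusters, merged.n_clusters)

    if config.taxonomy and config.genome_map and config.focal_genome:
        tax = read_taxonomy_table(Path(config.taxonomy).read_text())
        genome_of = {}
        for line in Path(config.genome_map).read_text().splitlines()[1:]:
            if line.strip():
                protein, genome = line.split("\t")[:2]
                genome_of[protein] = genome
        annotations = taxmod.annotate_clusters(
            merged, genome_of, tax, config.focal_genome)
        (out / "cluster_annotations.tsv").write_text(
            taxmod.write_annotations(annotations))
        stage["annotation"] = {
            "lca_histogram": taxmod.lca_histogram(annotations),
            "n_genus_orfans": sum(1 for a in annotations.values()
                                  if a.is_genus_orfan),
        }
    return stage


def _run_ipms(config: RunConfig, out: Path) -> dict:
    matrix = read_abundance_matrix(Path(config.abundance).read_text(),
                                   Path(config.design).read_text())
    processed = interactome.preprocess_abundance(
        matrix, min_reps=config.min_reps, normalization=config.normalization)
    records = interactome.moderated_t_test(processed)
    selected = interactome.select_interactors(
        records, lfc_min=config.lfc_min, p_max=config.p_max,
        min_reps=config.min_reps)
    lines = ["protein_id\tlog2fc\tp_value\tadjusted_p\tselected\t"
             "invalidated\tn_quantified_bait\tn_quantified_control"]
    for r in sorted(records, key=lambda r: r.protein_id):
        lines.append("\t".join([
            r.protein_id, f"{r.log2fc:.6g}", f"{r.p_value:.6g}",
            f"{r.adjusted_p:.6g}", str(int(r.selected)),
            str(int(r.invalidated)), str(r.n_quantified_bait),
            str(r.n_quantified_control)]))
    (out / "enrichment.tsv").write_text("\n".join(lines) + "\n")
    bait = matrix.bait_name or "bait"
    return {"ipms": {
        "n_tested": len(records),
        "interactors": {bait: sorted(selected)},
        "n_selected": len(selected),
        "n_invalidated": sum(1 for r in records if r.invalidated),
    }}
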