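"""Seeded generators for every input the toolkit consumes, with known
ground truth.

Three generators emulate the study's data universe at desk scale:

* :func:`simulate_orthogroups` — planted orthogroups of proteins spread over
  a tree-consistent 8-rank taxonomy, emitting sequence- and structure-
  similarity edge lists. Within-group similarities lie above the clustering
  thresholds, between-group similarities below; *planted splits* realize the
  merge-step scenario: one true group emitted as two sequence-level cliques
  whose representatives share no structural edge but whose members cross-link
  with a fraction drawn above the 65% merge threshold.
* :func:`simulate_ipms` — spike-in bait-vs-control label-free abundance
  matrices (3v3 design) with log-normal intensities, MNAR censoring below an
  intensity threshold and MCAR dropout.
* :func:`simulate_complexes` — 3-D chain point clouds placed so that
  designated contact pairs have a minimum distance inside the interface
  window (4, 8) Å and all other pairs are farther than 10 Å.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .complexes import ChainPoints, min_interchain_distance
from .io_formats import (AbundanceMatrix, EdgeKind, SimilarityEdge,
                         TaxonomyTable, VirionShape, RANKS)

# a priori study-condition defaults (see docs/methods.md)
DEFAULT_CV = 0.2
DEFAULT_EFFECT_LOG2FC = 2.0
DEFAULT_MCAR_RATE = 0.02
DEFAULT_MNAR_THRESHOLD = 20.5
DEFAULT_BASELINE_RANGE = (20.0, 30.0)


@dataclass
class OrthogroupTruth:
    true_group: dict[str, str]
    genome_of: dict[str, str]
    planted_splits: list[tuple[str, tuple[str, ...], tuple[str, ...], float]]
    edge_dropout_rate: float
    spurious_edge_rate: float

    @property
    def n_groups(self) -> int:
        return len(set(self.true_group.values()))


@dataclass
class SpikeTruth:
    true_interactors: set[str]
    effect_log2fc: float
    cv: float
    missingness: tuple[float, float]
    baseline_log2: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Taxonomy + orthogroups
# ---------------------------------------------------------------------------

def _random_taxonomy(n_genomes: int, rng: np.random.Generator,
                     ) -> TaxonomyTable:
    """Balanced-ish random taxonomy tree over the 8 ranks.

    Built by recursive splitting of the genome list, so tree consistency
    holds by construction. The subfamily rank is assigned only inside one
    designated family, reproducing partially annotated real taxonomies.
    Virion shape is drawn per family (icosahedral / non-icosahedral /
    unknown) so shape is a family-level trait.
    """
    genome_ids = [f"g{i:03d}" for i in range(n_genomes)]
    lineages: dict[str, dict[str, str | None]] = {
        g: {r: None for r in RANKS} for g in genome_ids}
    counters = {r: 0 for r in RANKS}

    def split(indices: list[str], rank_i: int, subfamily_family: str | None):
        rank = RANKS[rank_i]
        if rank == "species":
            for g in indices:
                lineages[g]["species"] = f"sp_{g}"
            return
        if rank == "superkingdom":
            parts = [indices]
        else:
            n_parts = int(rng.integers(1, min(3, len(indices)) + 1))
            shuffled = list(indices)
            rng.shuffle(shuffled)
            cuts = sorted(rng.choice(range(1, len(indices)), size=n_parts - 1,
                                     replace=False)) if n_parts > 1 else []
            parts, prev = [], 0
            for c in [*cuts, len(indices)]:
                parts.append(shuffled[prev:c])
                prev = c
        for part in parts:
            if not part:
                continue
            counters[rank] += 1
            name = f"{rank[:4]}_{counters[rank]:03d}"
            if rank == "subfamily":
                family = lineages[part[0]]["family"]
                if family == subfamily_family:
                    for g in part:
                        lineages[g][rank] = name
                # else: subfamily stays absent
            else:
                for g in part:
                    lineages[g][rank] = name
            split(sorted(part), rank_i + 1, subfamily_family)

    split(genome_ids, 0, None)
    # designate the first family as the one carrying subfamily annotations
    families = sorted({lineages[g]["family"] for g in genome_ids
                       if lineages[g]["family"]})
    designated = families[0] if families else None
    # rerun the subfamily/genus/species levels with the designated family:
    # simplest correct approach — assign subfamily = genus-prefix groups
    for g in genome_ids:
        if lineages[g]["family"] == designated:
            lineages[g]["subfamily"] = f"subf_{lineages[g]['family']}"

    shapes_by_family: dict[str | None, VirionShape] = {}
    table = TaxonomyTable()
    for g in genome_ids:
        fam = lineages[g]["family"]
        if fam not in shapes_by_family:
            shapes_by_family[fam] = VirionShape(
                ["icosahedral", "non_icosahedral", "unknown"][
                    int(rng.integers(0, 3))])
        table.add(g, lineages[g], shapes_by_family[fam])
    return table


def simulate_orthogroups(n_genomes: int = 12, n_groups: int = 20,
                         paralog_rate: float = 0.3,
                         noise: tuple[float, float] = (0.0, 0.0),
                         seed: int = 0, n_splits: int = 0,
                         ) -> tuple[set[str], TaxonomyTable,
                                    list[SimilarityEdge],
                                    list[SimilarityEdge], OrthogroupTruth]:
    """Planted orthogroups with sequence and structure similarity edges.

    Returns (protein universe, taxonomy, sequence edges, structure edges,
    truth). ``noise = (edge_dropout_rate, spurious_edge_rate)``. The first
    ``n_splits`` groups are planted as merge-step scenarios (two cliques
    cross-linked above the 65% threshold in one direction).
    """
    if n_groups <= 0 or n_genomes <= 0:
        raise ValueError("n_groups and n_genomes must be positive")
    dropout, spurious = noise
    if not (0 <= dropout < 1 and 0 <= spurious < 1):
        raise ValueError("noise rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    taxonomy = _random_taxonomy(n_genomes, rng)
    genomes = taxonomy.genomes

    true_group: dict[str, str] = {}
    genome_of: dict[str, str] = {}
    groups: dict[str, list[str]] = {}
    pid = 0
    for gi in range(n_groups):
        gid = f"OG{gi:04d}"
        min_size = 8 if gi < n_splits else 1
        size_goal = max(min_size, int(rng.integers(1, 9)))
        members: list[str] = []
        while len(members) < size_goal:
            genome = genomes[int(rng.integers(0, len(genomes)))]
            n_copies = 1 + int(rng.poisson(paralog_rate))
            for _ in range(n_copies):
                protein = f"p{pid:05d}"
                pid += 1
                members.append(protein)
                genome_of[protein] = genome
                true_group[protein] = gid
        groups[gid] = members
    universe = set(true_group)
    if n_groups > len(universe):
        raise ValueError("more groups than proteins")

    seq_edges: list[SimilarityEdge] = []
    struct_edges: list[SimilarityEdge] = []
    planted: list[tuple[str, tuple[str, ...], tuple[str, ...], float]] = []

    def clique(members: Sequence[str], out: list, kind: EdgeKind,
               lo: float, hi: float) -> None:
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                out.append(SimilarityEdge(
                    a, b, float(rng.uniform(lo, hi)),
                    float(rng.uniform(0.75, 0.95)),
                    float(rng.uniform(0.75, 0.95)),
                    float(rng.uniform(1e-30, 1e-5)), kind))

    for gi, (gid, members) in enumerate(groups.items()):
        members = sorted(members)
        if gi < n_splits:
            half = len(members) // 2
            part_a, part_b = members[:half], members[half:]
            # two sequence families -> two composed clusters
            clique(part_a, seq_edges, EdgeKind.sequence, 0.3, 0.9)
            clique(part_b, seq_edges, EdgeKind.sequence, 0.3, 0.9)
            clique(part_a, struct_edges, EdgeKind.structure, 0.5, 0.95)
            clique(part_b, struct_edges, EdgeKind.structure, 0.5, 0.95)
            rep_a, rep_b = min(part_a), min(part_b)
            frac = float(rng.uniform(0.70, 0.95))
            n_linked = max(int(math.ceil(frac * len(part_a))),
                           int(math.floor(0.66 * len(part_a))) + 1)
            n_linked = min(n_linked, len(part_a))
            linked = sorted(part_a)[:n_linked]
            for a in linked:
                choices = [b for b in part_b
                           if not (a == rep_a and b == rep_b)]
                b = choices[int(rng.integers(0, len(choices)))]
                struct_edges.append(SimilarityEdge(
                    a, b, float(rng.uniform(0.45, 0.9)),
                    float(rng.uniform(0.75, 0.95)),
                    float(rng.uniform(0.75, 0.95)),
                    float(rng.uniform(1e-20, 1e-5)), EdgeKind.structure))
            planted.append((gid, tuple(part_a), tuple(part_b),
                            n_linked / len(part_a)))
        else:
            # 1-3 sequence families, rejoined by the structural stage
            n_fam = int(rng.integers(1, min(3, len(members)) + 1)) \
                if len(members) > 1 else 1
            fams = [members[i::n_fam] for i in range(n_fam)]
            for fam in fams:
                if len(fam) > 1:
                    clique(fam, seq_edges, EdgeKind.sequence, 0.3, 0.9)
            clique(members, struct_edges, EdgeKind.structure, 0.5, 0.95)

    protected = set()
    for _, part_a, part_b, _ in planted:
        protected |= {frozenset((a, b)) for a in part_a for b in part_b}

    def apply_noise(edges: list[SimilarityEdge], kind: EdgeKind,
                    ) -> list[SimilarityEdge]:
        kept = [e for e in edges
                if frozenset((e.query_id, e.target_id)) in protected
                or rng.random() >= dropout]
        n_spurious = int(round(spurious * len(edges)))
        proteins = sorted(universe)
        for _ in range(n_spurious):
            a, b = rng.choice(len(proteins), size=2, replace=False)
            pa, pb = proteins[int(a)], proteins[int(b)]
            kept.append(SimilarityEdge(
                pa, pb, float(rng.uniform(0.41, 0.7)),
                float(rng.uniform(0.71, 0.9)), float(rng.uniform(0.71, 0.9)),
                float(rng.uniform(1e-10, 1e-3)), kind))
        return kept

    if dropout > 0 or spurious > 0:
        seq_edges = apply_noise(seq_edges, EdgeKind.sequence)
        struct_edges = apply_noise(struct_edges, EdgeKind.structure)

    # all-vs-all searches always report the self-hit; emitting it keeps the
    # edge files self-contained (singleton groups stay in the universe when
    # the universe is reconstructed from the files alone)
    seq_edges.extend(
        SimilarityEdge(p, p, 1.0, 1.0, 1.0, 0.0, EdgeKind.sequence)
        for p in sorted(universe))
    struct_edges.extend(
        SimilarityEdge(p, p, 1.0, 1.0, 1.0, 0.0, EdgeKind.structure)
        for p in sorted(universe))

    truth = OrthogroupTruth(true_group=true_group, genome_of=genome_of,
                            planted_splits=planted,
                            edge_dropout_rate=dropout,
                            spurious_edge_rate=spurious)
    return universe, taxonomy, seq_edges, struct_edges, truth


def truth_clustering(truth: OrthogroupTruth):
    """The ground-truth partition as a Clustering object."""
    from .io_formats import Clustering
    assignment = dict(truth.true_group)
    reps: dict[str, str] = {}
    for protein, gid in sorted(assignment.items()):
        reps.setdefault(gid, protein)
    # representative must be a member; use the smallest protein ID per group
    representatives = {gid: rep for gid, rep in reps.items()}
    # cluster ids must equal assignment values; remap rep ids onto group ids
    return Clustering(
        assignment=assignment,
        representatives={gid: representatives[gid] for gid in representatives})


# ---------------------------------------------------------------------------
# IP-MS spike-in matrices
# ---------------------------------------------------------------------------

def simulate_ipms(n_proteins: int = 1000, n_spikes: int = 50,
                  effect_log2fc: float = DEFAULT_EFFECT_LOG2FC,
                  cv: float = DEFAULT_CV,
                  missingness: tuple[float, float] = (DEFAULT_MCAR_RATE,
                                                      DEFAULT_MNAR_THRESHOLD),
                  seed: int = 0, n_reps: int = 3,
                  ) -> tuple[AbundanceMatrix, SpikeTruth]:
    """Spike-in bait-vs-control abundance matrix with known truth.

    Protein log2 baselines are uniform on [20, 30]; replicate log2
    intensities are normal around the baseline with sd = log2(1 + cv);
    spiked proteins are shifted by ``effect_log2fc`` in the bait condition.
    ``missingness = (mcar_rate, mnar_log2_threshold)``: values below the
    threshold are censored (missing not at random), then completely-at-random
    dropout is applied.
    """
    if n_spikes > n_proteins:
        raise ValueError("n_spikes exceeds n_proteins")
    mcar, mnar_threshold = missingness
    if not 0 <= mcar < 1:
        raise ValueError("mcar rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    proteins = [f"prot{i:05d}" for i in range(n_proteins)]
    spikes = set(proteins[i] for i in
                 rng.choice(n_proteins, size=n_spikes, replace=False))
    sd = math.log2(1.0 + cv)
    lo, hi = DEFAULT_BASELINE_RANGE
    baselines = rng.uniform(lo, hi, size=n_proteins)

    bait_cols = [f"bait_{i + 1}" for i in range(n_reps)]
    ctrl_cols = [f"control_{i + 1}" for i in range(n_reps)]
    log2_vals = np.empty((n_proteins, 2 * n_reps))
    for i, protein in enumerate(proteins):
        shift = effect_log2fc if protein in spikes else 0.0
        log2_vals[i, :n_reps] = baselines[i] + shift + \
            rng.normal(0.0, sd, size=n_reps)
        log2_vals[i, n_reps:] = baselines[i] + rng.normal(0.0, sd, size=n_reps)

    missing = log2_vals < mnar_threshold
    if mcar > 0:
        missing |= rng.random(log2_vals.shape) < mcar
    intensities = np.power(2.0, log2_vals)
    intensities[missing] = np.nan

    df = pd.DataFrame(intensities, index=proteins,
                      columns=[*bait_cols, *ctrl_cols])
    design = {c: "bait" for c in bait_cols}
    design.update({c: "control" for c in ctrl_cols})
    matrix = AbundanceMatrix(intensities=df, design=design)
    truth = SpikeTruth(true_interactors=spikes, effect_log2fc=effect_log2fc,
                       cv=cv, missingness=missingness,
                       baseline_log2={p: float(b)
                                      for p, b in zip(proteins, baselines)})
    return matrix, truth


# ---------------------------------------------------------------------------
# Complex geometries
# ---------------------------------------------------------------------------

def simulate_complexes(n_chains: int = 4,
                       contact_pairs: Sequence[tuple[int, int]] = (),
                       seed: int = 0, points_per_chain: int = 20,
                       ) -> tuple[list[ChainPoints],
                                  set[tuple[str, str]]]:
    """Chain point clouds with controlled interface geometry.

    Designated ``contact_pairs`` (chain indices) end up with a minimum
    inter-chain distance drawn in (4, 8) Å; all other pairs are farther than
    10 Å. Raises on geometric infeasibility (verified post hoc).
    """
    for i, j in contact_pairs:
        if not (0 <= i < n_chains and 0 <= j < n_chains) or i == j:
            raise ValueError(f"invalid contact pair ({i}, {j})")
    rng = np.random.default_rng(seed)
    spacing = 50.0
    radius = max(40.0, spacing * n_chains / (2.0 * math.pi))
    centers = np.array([
        [radius * math.cos(2 * math.pi * i / n_chains),
         radius * math.sin(2 * math.pi * i / n_chains), 0.0]
        for i in range(n_chains)])

    clouds: list[np.ndarray] = []
    for i in range(n_chains):
        pts = rng.normal(0.0, 1.5, size=(points_per_chain, 3))
        norms = np.linalg.norm(pts, axis=1)
        pts[norms > 4.0] *= (4.0 / norms[norms > 4.0])[:, None]
        clouds.append(centers[i] + pts)

    pair_set = {tuple(sorted(p)) for p in contact_pairs}
    for i, j in sorted(pair_set):
        t = float(rng.uniform(4.5, 7.5))
        u = centers[j] - centers[i]
        u /= np.linalg.norm(u)
        mid = (centers[i] + centers[j]) / 2.0
        qi = mid - (t / 2.0) * u
        qj = mid + (t / 2.0) * u
        clouds[i] = np.vstack([clouds[i], qi])
        clouds[j] = np.vstack([clouds[j], qj])

    chains = [ChainPoints(pdb_id="synth", chain_id=f"C{i}",
                          points=[tuple(p) for p in clouds[i]])
              for i in range(n_chains)]
    truth = {(f"C{i}", f"C{j}") for i, j in pair_set}

    for i in range(n_chains):
        for j in range(i + 1, n_chains):
            d = min_interchain_distance(clouds[i], clouds[j])
            if (i, j) in pair_set:
                if not (4.0 < d < 8.0):
                    raise ValueError(
                        f"geometric infeasibility: contact pair ({i},{j}) "
                        f"at {d:.2f} Å")
            elif d <= 10.0:
                raise ValueError(
                    f"geometric infeasibility: non-contact pair ({i},{j}) "
                    f"at {d:.2f} Å")
    return chains, truth
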