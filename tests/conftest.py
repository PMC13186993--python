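"""Shared fixtures: tiny deterministic inputs built in memory."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gvortho.io_formats import (AbundanceMatrix, Clustering, EdgeKind,
                                SimilarityEdge, TaxonomyTable, VirionShape)


def make_clustering(groups: dict[str, list[str]]) -> Clustering:
    """Clustering from {cluster_id: members}; representative = first member."""
    assignment = {p: cid for cid, members in groups.items() for p in members}
    representatives = {cid: members[0] for cid, members in groups.items()}
    return Clustering(assignment=assignment, representatives=representatives)


def edge(a: str, b: str, score: float = 0.9, cov: float = 0.9,
         evalue: float = 1e-10, kind: str = "structure") -> SimilarityEdge:
    return SimilarityEdge(a, b, score, cov, cov, evalue, EdgeKind(kind))


@pytest.fixture
def small_taxonomy() -> TaxonomyTable:
    """Six genomes in two phyla; subfamily annotated only in family fam_a."""
    table = TaxonomyTable()
    rows = [
        # genome, phylum, class, order, family, subfamily, genus, shape
        ("g1", "ph1", "cl1", "or1", "fam_a", "subf_a", "gen1", "icosahedral"),
        ("g2", "ph1", "cl1", "or1", "fam_a", "subf_a", "gen1", "icosahedral"),
        ("g3", "ph1", "cl1", "or1", "fam_a", "subf_a", "gen2", "icosahedral"),
        ("g4", "ph1", "cl1", "or2", "fam_b", None, "gen3", "non_icosahedral"),
        ("g5", "ph2", "cl2", "or3", "fam_c", None, "gen4", "unknown"),
        ("g6", "ph2", "cl2", "or3", "fam_c", None, "gen5", "icosahedral"),
    ]
    for genome, ph, cl, orr, fam, subf, gen, shape in rows:
        table.add(genome, {
            "superkingdom": "Viruses", "phylum": ph, "class": cl,
            "order": orr, "family": fam, "subfamily": subf,
            "genus": gen, "species": f"sp_{genome}",
        }, VirionShape(shape))
    return table


def make_matrix(values: np.ndarray, n_bait: int = 3,
                contaminants: dict[str, bool] | None = None,
                ) -> AbundanceMatrix:
    n, m = values.shape
    cols = [f"bait_{i+1}" for i in range(n_bait)] + \
        [f"control_{i+1}" for i in range(m - n_bait)]
    df = pd.DataFrame(values, index=[f"p{i}" for i in range(n)], columns=cols)
    design = {c: ("bait" if c.startswith("bait") else "control")
              for c in cols}
    return AbundanceMatrix(intensities=df, design=design,
                           contaminant_flags=contaminants or {})
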