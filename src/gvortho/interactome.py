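"""IP-MS differential enrichment and bait-network construction.

The statistical track mirrors standard label-free co-immunoprecipitation
analysis: proteins quantified in fewer than ``min_reps`` replicates of every
condition (and contaminants) are discarded; intensities are log2-transformed
and normalized per sample; missing values are imputed — regression against
correlated neighbour proteins for values partially observed within a
condition, a deterministic low quantile for values totally absent from a
condition; bait vs control is tested with an empirical-Bayes moderated
t-statistic (per-protein variances shrunk toward a prior estimated from the
marginal distribution of sample variances); interactors are selected at
log2FC >= 1 and p < 0.01, and selections quantified in fewer than three
pre-imputation replicates of the more abundant condition are invalidated
(p set to 1).

The network track summarizes baits pairwise with
``weight = Nc + 10 * Ndc`` (Nc shared interactors, Ndc direct bait-in-bait
detections, 0-2), partitions the bait graph with seeded Louvain modularity
maximization, and assembles the annotated global bait -> prey network.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special, stats

from .io_formats import AbundanceMatrix

logger = logging.getLogger(__name__)

REGION_PRECEDENCE = ("membrane", "nucleoid", "vf_il", "virion")

D0_CAP = 1e6  # "infinite" shrinkage cap for the prior degrees of freedom


@dataclass
class EnrichmentRecord:
    """Per-protein differential-abundance result (bait minus control)."""

    protein_id: str
    log2fc: float
    p_value: float
    adjusted_p: float = math.nan
    selected: bool = False
    invalidated: bool = False
    n_quantified_bait: int = 0
    n_quantified_control: int = 0
    t_statistic: float = math.nan
    df_total: float = math.nan


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def preprocess_abundance(matrix: AbundanceMatrix, min_reps: int = 3,
                         normalization: str = "median_mad",
                         imputation: tuple[str, str] = ("slsa", "detquantile"),
                         require_both_conditions: bool = False,
                         slsa_neighbors: int = 10,
                         detquantile_quantile: float = 0.025,
                         detquantile_factor: float = 1.0,
                         ) -> AbundanceMatrix:
    """Filter, log2-transform, normalize and impute an abundance matrix.

    Proteins flagged as contaminants are removed, as are proteins quantified
    in fewer than ``min_reps`` replicates of every condition (with
    ``require_both_conditions`` the stricter reading — ``min_reps`` in each
    condition — applies). Pre-imputation replicate counts per condition are
    kept on the result (``quantified_counts``) for downstream invalidation.

    Normalization (after log2):

    ``median_mad``
        Per-sample median centering, then equalization of the sample MADs to
        their across-sample median. The global log2 scale is preserved so
        that fold-change thresholds keep their meaning.
    ``bait_median``
        Center each sample on the bait protein's abundance (the matrix must
        carry ``bait_name``), re-anchored at the bait's median so values stay
        on the original scale.
    ``none``
        No normalization.

    Imputation: values missing in a condition where the protein is partially
    observed are predicted by least squares against the ``slsa_neighbors``
    most correlated fully observed proteins; values totally absent from a
    condition are set to a deterministic low quantile (default 2.5th
    percentile) of each sample's observed values.
    """
    if matrix.log_scale:
        raise ValueError("matrix already log-transformed")
    df = matrix.intensities.copy()
    conditions = matrix.conditions
    for cond in conditions:
        if not matrix.samples_of(cond):
            raise ValueError(f"condition {cond!r} has no samples")
    if max(len(matrix.samples_of(c)) for c in conditions) < min_reps:
        raise ValueError(f"no condition has >= {min_reps} samples")

    # contaminant and replicate filters (counts taken pre-imputation)
    keep = [p for p in df.index if not matrix.contaminant_flags.get(p, False)]
    n_contaminants = len(df.index) - len(keep)
    df = df.loc[keep]
    counts = pd.DataFrame(
        {cond: df[matrix.samples_of(cond)].notna().sum(axis=1)
         for cond in conditions})
    if require_both_conditions:
        ok = (counts >= min_reps).all(axis=1)
    else:
        ok = (counts >= min_reps).any(axis=1)
    n_low = int((~ok).sum())
    df = df.loc[ok]
    counts = counts.loc[ok]
    logger.info("preprocess: dropped %d contaminants, %d low-replicate "
                "proteins; %d retained", n_contaminants, n_low, len(df))

    logged = np.log2(df)

    if normalization == "median_mad":
        medians = logged.median(axis=0)
        centered = logged.sub(medians, axis=1)
        mads = centered.apply(lambda col: _mad(col.dropna().to_numpy()))
        target = float(np.median(mads[mads > 0])) if (mads > 0).any() else 1.0
        scale = mads.where(mads > 0, other=target)
        normalized = centered.mul(target / scale, axis=1)
    elif normalization == "bait_median":
        if matrix.bait_name is None or matrix.bait_name not in logged.index:
            raise ValueError("bait_median normalization requires the bait "
                             "protein to be present in the matrix")
        bait_row = logged.loc[matrix.bait_name]
        anchor = float(bait_row.median())
        normalized = logged.sub(bait_row - anchor, axis=1)
    elif normalization == "none":
        normalized = logged
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    imputed = _impute(normalized, matrix, conditions, imputation,
                      slsa_neighbors, detquantile_quantile,
                      detquantile_factor)

    return AbundanceMatrix(intensities=imputed, design=dict(matrix.design),
                           contaminant_flags={}, bait_name=matrix.bait_name,
                           log_scale=True, quantified_counts=counts)


def _impute(logged: pd.DataFrame, matrix: AbundanceMatrix,
            conditions: Sequence[str], imputation: tuple[str, str],
            k: int, quantile: float, factor: float) -> pd.DataFrame:
    partial_method, absent_method = imputation
    if partial_method not in ("slsa", "none") or absent_method not in (
            "detquantile", "none"):
        raise ValueError(f"unknown imputation pair {imputation!r}")
    out = logged.copy()
    if not logged.isna().to_numpy().any():
        return out

    # deterministic low quantile per sample, for condition-wide absences
    low = {s: float(np.nanquantile(logged[s].to_numpy(), quantile)) * factor
           for s in logged.columns}

    complete = logged.dropna(axis=0)
    values = logged.to_numpy()
    col_index = {s: i for i, s in enumerate(logged.columns)}
    cond_cols = {c: [col_index[s] for s in matrix.samples_of(c)]
                 for c in conditions}
    complete_arr = complete.to_numpy()

    for i, pid in enumerate(logged.index):
        row = values[i]
        if not np.isnan(row).any():
            continue
        observed_cols = np.flatnonzero(~np.isnan(row))
        for cond in conditions:
            cols = np.array(cond_cols[cond])
            miss = cols[np.isnan(row[cols])]
            if miss.size == 0:
                continue
            obs_in_cond = cols[~np.isnan(row[cols])]
            if obs_in_cond.size == 0:
                if absent_method == "detquantile":
                    for j in miss:
                        out.iat[i, j] = low[logged.columns[j]]
                continue
            if partial_method != "slsa":
                continue
            pred = _slsa_predict(row, observed_cols, miss, complete,
                                 complete_arr, pid, k)
            for j, v in zip(miss, pred):
                out.iat[i, j] = v
    return out


def _slsa_predict(row: np.ndarray, observed_cols: np.ndarray,
                  missing_cols: np.ndarray, complete: pd.DataFrame,
                  complete_arr: np.ndarray, pid: str, k: int) -> np.ndarray:
    """Least-squares prediction of missing cells from correlated complete
    rows (falls back to the observed mean when no usable neighbour exists)."""
    fallback = float(np.mean(row[observed_cols]))
    if complete.empty or observed_cols.size < 2:
        return np.full(missing_cols.size, fallback)
    neighbours = complete_arr
    if pid in complete.index:
        mask = complete.index != pid
        neighbours = complete_arr[mask]
    if neighbours.shape[0] == 0:
        return np.full(missing_cols.size, fallback)
    y = row[observed_cols]
    sub = neighbours[:, observed_cols]
    yc = y - y.mean()
    subc = sub - sub.mean(axis=1, keepdims=True)
    denom = np.sqrt((subc ** 2).sum(axis=1) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, (subc * yc).sum(axis=1) / denom, 0.0)
    k_eff = min(k, neighbours.shape[0], max(1, observed_cols.size - 1))
    top = np.argsort(-np.abs(corr))[:k_eff]
    X = np.column_stack([np.ones(observed_cols.size),
                         neighbours[top][:, observed_cols].T])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    Xmiss = np.column_stack([np.ones(missing_cols.size),
                             neighbours[top][:, missing_cols].T])
    pred = Xmiss @ coef
    return np.where(np.isfinite(pred), pred, fallback)


# ---------------------------------------------------------------------------
# Moderated t-test
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(sample_vars: np.ndarray, df_residual: float,
                            ) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square prior
    (d0, s0^2) from the marginal distribution of log sample variances.

    Degenerate cases: fewer than two positive variances, or an observed
    log-variance spread no larger than expected from sampling alone, give
    d0 = D0_CAP ("infinite" shrinkage).
    """
    s2 = np.asarray(sample_vars, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 >= 0)]
    if s2.size < 2:
        s0 = float(np.mean(s2)) if s2.size else 1.0
        return D0_CAP, s0
    med = float(np.median(s2))
    if med == 0:
        med = 1.0
    s2 = np.maximum(s2, 1e-5 * med)  # offset exact-zero variances
    z = np.log(s2)
    e = z - special.digamma(df_residual / 2.0) + math.log(df_residual / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df_residual / 2.0))
    if evar <= 0:
        return D0_CAP, float(np.mean(s2))
    d0 = 2.0 * _trigamma_inverse(evar)
    d0 = min(d0, D0_CAP)
    s0_sq = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def moderated_t_test(matrix: AbundanceMatrix, bait: str = "bait",
                     control: str = "control",
                     d0_override: float | None = None,
                     ) -> list[EnrichmentRecord]:
    """Empirical-Bayes moderated two-sample t-test per protein.

    Requires a fully imputed log-scale matrix with >= 2 samples per
    condition. The per-protein pooled variance s^2 (d = n_b + n_c - 2
    residual df) is shrunk to ``s2_post = (d0*s0^2 + d*s^2) / (d0 + d)``
    with (d0, s0^2) estimated by :func:`estimate_variance_prior`; the
    two-sided p-value comes from a t distribution with d0 + d degrees of
    freedom. ``d0_override=0`` reduces to the ordinary pooled t-test.
    """
    if not matrix.log_scale:
        raise ValueError("moderated_t_test expects a log2-scale matrix")
    bait_samples = matrix.samples_of(bait)
    ctrl_samples = matrix.samples_of(control)
    if len(bait_samples) < 2 or len(ctrl_samples) < 2:
        raise ValueError("each condition needs >= 2 samples")
    data = matrix.intensities
    if data.isna().to_numpy().any():
        raise ValueError("matrix contains missing values; impute first")

    xb = data[bait_samples].to_numpy()
    xc = data[ctrl_samples].to_numpy()
    nb, nc = xb.shape[1], xc.shape[1]
    d = nb + nc - 2
    mean_b = xb.mean(axis=1)
    mean_c = xc.mean(axis=1)
    ss = ((xb - mean_b[:, None]) ** 2).sum(axis=1) + \
         ((xc - mean_c[:, None]) ** 2).sum(axis=1)
    s2 = ss / d

    if d0_override is not None:
        d0 = float(d0_override)
        _, s0_sq = estimate_variance_prior(s2, d)
        if d0 == 0:
            s0_sq = 0.0
    else:
        d0, s0_sq = estimate_variance_prior(s2, d)

    s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
    se = np.sqrt(s2_post * (1.0 / nb + 1.0 / nc))
    log2fc = mean_b - mean_c
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, np.where(log2fc == 0, 0.0, np.inf))
    # total df capped at the pooled residual df (n_proteins * d), the
    # behaviour of the published empirical-Bayes procedure
    df_total = min(d0 + d, len(s2) * d, D0_CAP)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)

    counts = matrix.quantified_counts
    records: list[EnrichmentRecord] = []
    for i, pid in enumerate(data.index):
        nqb = int(counts.loc[pid, bait]) if counts is not None else nb
        nqc = int(counts.loc[pid, control]) if counts is not None else nc
        records.append(EnrichmentRecord(
            protein_id=pid, log2fc=float(log2fc[i]), p_value=float(p[i]),
            n_quantified_bait=nqb, n_quantified_control=nqc,
            t_statistic=float(t[i]), df_total=float(df_total)))
    return records


def select_interactors(records: Sequence[EnrichmentRecord],
                       lfc_min: float = 1.0, p_max: float = 0.01,
                       min_reps: int = 3) -> set[str]:
    """Apply the selection and invalidation rules, mutating the records.

    Selection: log2FC >= ``lfc_min`` and p < ``p_max``. A selected protein
    quantified (pre-imputation) in fewer than ``min_reps`` replicates of the
    condition in which it is more abundant is invalidated: its p-value is
    reset to 1 and it is deselected. Benjamini-Hochberg adjusted p-values
    are attached for audit only.
    """
    if records:
        pvals = np.array([r.p_value for r in records])
        adj = stats.false_discovery_control(pvals, method="bh")
        for r, a in zip(records, adj):
            r.adjusted_p = float(a)
    selected: set[str] = set()
    for r in records:
        r.selected = (r.log2fc >= lfc_min) and (r.p_value < p_max)
        r.invalidated = False
        if r.selected:
            n_more = (r.n_quantified_bait if r.log2fc >= 0
                      else r.n_quantified_control)
            if n_more < min_reps:
                r.invalidated = True
                r.selected = False
                r.p_value = 1.0
            else:
                selected.add(r.protein_id)
    return selected


# ---------------------------------------------------------------------------
# Bait networks
# ---------------------------------------------------------------------------

def build_bait_network(interactors: Mapping[str, Iterable[str]],
                       baits: Sequence[str] | None = None) -> nx.Graph:
    """Pairwise bait summary graph with weight = Nc + 10 * Ndc.

    Nc is the number of shared interactors of the two baits; Ndc counts the
    directions (0, 1 or 2) in which one bait appears in the other's
    interactor set. Pairs with weight 0 get no edge; every bait is a node.
    """
    if baits is None:
        baits = list(interactors)
    if len(set(baits)) != len(baits):
        raise ValueError("bait listed twice")
    sets = {b: set(interactors.get(b, ())) for b in baits}
    g = nx.Graph()
    g.add_nodes_from(baits)
    for i, a in enumerate(baits):
        for b in baits[i + 1:]:
            nc = len(sets[a] & sets[b])
            ndc = int(b in sets[a]) + int(a in sets[b])
            weight = nc + 10 * ndc
            if weight > 0:
                g.add_edge(a, b, Nc=nc, Ndc=ndc, weight=weight)
    return g


def detect_communities(network: nx.Graph, seed: int = 0) -> list[set[str]]:
    """Seeded Louvain partition of the weighted bait graph.

    Modularity-maximizing communities; isolated nodes come out as their own
    communities. The returned list is canonicalized by each community's
    smallest member ID.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    communities = nx.community.louvain_communities(
        network, weight="weight", seed=seed)
    return sorted((set(c) for c in communities), key=lambda c: min(c))


def _resolve_region(protein: str, membrane: set[str],
                    region_labels: Mapping[str, Iterable[str] | str],
                    ) -> str:
    labels = region_labels.get(protein, ())
    if isinstance(labels, str):
        labels = {labels}
    else:
        labels = set(labels)
    if protein in membrane:
        labels.add("membrane")
    for region in REGION_PRECEDENCE:
        if region in labels:
            return region
    return "virion_unassigned"


def assemble_global_network(interactors: Mapping[str, Iterable[str]],
                            membrane: Iterable[str] = (),
                            region_labels: Mapping[str, Iterable[str] | str]
                            | None = None,
                            host_proteins: Iterable[str] = (),
                            categories: Mapping[str, str] | None = None,
                            expression: Mapping[str, str] | None = None,
                            experiment_of: Mapping[str, str] | None = None,
                            ) -> nx.DiGraph:
    """Annotated global bait -> prey network.

    One directed edge per selected interactor of each bait (edge count equals
    the sum of interactor-set sizes). Node attributes: origin (host when the
    protein is a known host accession, else viral), region with precedence
    membrane > nucleoid > vf_il > virion (host preys are always region
    ``host``; unannotated viral preys ``virion_unassigned``), functional
    category and expression cluster (GV1-GV5 or ``none``).
    """
    membrane = set(membrane)
    host = set(host_proteins)
    region_labels = region_labels or {}
    categories = categories or {}
    expression = expression or {}
    g = nx.DiGraph()
    for bait, preys in interactors.items():
        for node in (bait, *preys):
            if node in g:
                continue
            origin = "host" if node in host else "viral"
            region = "host" if origin == "host" else _resolve_region(
                node, membrane, region_labels)
            g.add_node(node, origin=origin, region=region,
                       category=categories.get(node, "unknown"),
                       expression_cluster=expression.get(node, "none"),
                       is_bait=node in interactors)
        for prey in preys:
            g.add_edge(bait, prey,
                       experiment=(experiment_of or {}).get(bait, bait))
    return g
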