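"""Adjusted drug–disease similarity: normalization, clustering, cluster bonus.

Proximity p is mapped to a normalized similarity s = (m - p) / m, with m the
largest proximity observed in the run, then pushed through a sigmoid with a
cluster-quality bonus:

    AS = 1 / (1 + exp(-c * ((1 + QC) * s - d_mid)))

QC rewards drug–disease pairs that fall in the same modularity cluster of the
significant-association bipartite network: it is the mean edge weight (s) of
that shared cluster, and 0 when the two nodes are in different clusters.
Defaults c = 30 and d_mid = 0.5 place the sigmoid midpoint at half the
normalized range with near-saturation at the extremes.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import greedy_modularity_communities

logger = logging.getLogger(__name__)

DEFAULT_STEEPNESS = 30.0
DEFAULT_MIDPOINT = 0.5


def normalized_similarity(p: float, m: float) -> float:
    """(m - p) / m, in [0, 1]; m must be the global maximum proximity."""
    if m <= 0:
        raise ValueError("m must be positive")
    if p < 0 or p > m:
        raise ValueError(f"proximity {p} outside [0, m={m}]")
    return (m - p) / m


def adjusted_similarity(
    s, qc, c: float = DEFAULT_STEEPNESS, d_mid: float = DEFAULT_MIDPOINT
):
    """Sigmoid of (1+qc)*s - d_mid with steepness c; elementwise on arrays."""
    if c <= 0:
        raise ValueError("steepness c must be positive")
    s = np.asarray(s, dtype=float)
    qc = np.asarray(qc, dtype=float)
    out = 1.0 / (1.0 + np.exp(-c * ((1.0 + qc) * s - d_mid)))
    return float(out) if out.ndim == 0 else out


def detect_clusters(
    edges: Iterable[tuple[str, str, float]]
) -> dict[str, int]:
    """Partition the weighted bipartite drug–disease graph by greedy
    modularity maximization (CNM). Deterministic: nodes and edges are
    inserted in sorted order and cluster ids are assigned by smallest member.
    """
    edge_list = sorted((str(u), str(v), float(w)) for u, v, w in edges)
    if not edge_list:
        raise ValueError("empty association graph")
    g = nx.Graph()
    nodes = sorted({n for u, v, _ in edge_list for n in (u, v)})
    g.add_nodes_from(nodes)
    for u, v, w in edge_list:
        g.add_edge(u, v, weight=w)
    communities = greedy_modularity_communities(g, weight="weight")
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    labels: dict[str, int] = {}
    for cid, comm in enumerate(communities):
        for node in comm:
            labels[node] = cid
    logger.info("detect_clusters: %d nodes -> %d clusters", len(nodes), len(communities))
    return labels


def quality_cluster_score(
    drug: str,
    disease: str,
    clusters: Mapping[str, int],
    edge_weights: Mapping[frozenset, float],
) -> float:
    """Mean intra-cluster edge weight of the shared cluster; 0 across clusters."""
    try:
        cd, cs = clusters[drug], clusters[disease]
    except KeyError as exc:
        raise ValueError(f"node {exc.args[0]!r} has no cluster label") from None
    if cd != cs:
        return 0.0
    intra = [w for e, w in edge_weights.items()
             if all(clusters.get(n) == cd for n in e)]
    if not intra:
        return 0.0
    return min(1.0, float(np.mean(intra)))


def build_association_table(
    prox: pd.DataFrame,
    alpha: float = 0.05,
    c: float = DEFAULT_STEEPNESS,
    d_mid: float = DEFAULT_MIDPOINT,
    keep_all: bool = False,
) -> pd.DataFrame:
    """Turn a proximity table into AssociationRecords.

    m = max(p) over ALL evaluated pairs; clustering runs on the significant
    (adj_pval < alpha) bipartite graph weighted by s, and the cluster bonus
    qc only applies where both endpoints carry labels from that graph.
    By default only significant pairs are returned; ``keep_all`` keeps every
    evaluated pair with a boolean ``significant`` column (non-significant
    pairs get qc = 0 unless both endpoints happen to share a cluster).
    Returns columns: drug, disease, p, z, pval, adj_pval, s, cluster_drug,
    cluster_disease, qc, adjusted_similarity [, significant].
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    required = {"drug", "disease", "p", "adj_pval"}
    if not required.issubset(prox.columns):
        raise ValueError(f"proximity table missing columns {required - set(prox.columns)}")
    m = float(prox["p"].max())
    if m <= 0:
        # every drug sits inside its disease module; similarity saturates at 1
        m = 1.0
        logger.warning("all proximities are 0; normalization uses m=1")
    out = prox.copy()
    out["s"] = (m - out["p"]) / m
    out["significant"] = out["adj_pval"] < alpha
    sig = out[out["significant"]]
    if sig.empty:
        logger.warning("no significant associations at alpha=%g", alpha)
        clusters, cluster_mean = {}, {}
    else:
        # drug and disease name spaces may overlap; prefix for clustering only
        edges = [("d:" + r.drug, "x:" + r.disease, r.s) for r in sig.itertuples()]
        clusters = detect_clusters(edges)
        weights = {frozenset(("d:" + r.drug, "x:" + r.disease)): r.s
                   for r in sig.itertuples()}
        cluster_mean = {}
        for cid in set(clusters.values()):
            intra = [w for e, w in weights.items()
                     if all(clusters[n] == cid for n in e)]
            cluster_mean[cid] = min(1.0, float(np.mean(intra))) if intra else 0.0
    out["cluster_drug"] = [clusters.get("d:" + d) for d in out["drug"]]
    out["cluster_disease"] = [clusters.get("x:" + d) for d in out["disease"]]
    out["qc"] = [
        cluster_mean[cd] if cd is not None and cd == cs else 0.0
        for cd, cs in zip(out["cluster_drug"], out["cluster_disease"])
    ]
    out["adjusted_similarity"] = adjusted_similarity(
        out["s"].to_numpy(), out["qc"].to_numpy(), c=c, d_mid=d_mid)
    if not keep_all:
        out = out[out["significant"]].drop(columns="significant")
    return out.reset_index(drop=True)
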