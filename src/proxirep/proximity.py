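"""Network proximity of a drug-target module to a disease-gene module.

The proximity of drug module T to disease module S is the mean, over targets
t in T, of the hop distance to the nearest disease gene:

    p(T, S) = (1/|T|) * sum_t min_s d(t, s)

Small p means the drug's targets sit in or next to the disease neighborhood.
Significance is assessed against a degree-preserving permutation null: each
module is replaced by a random node set with a matched degree profile, and
the left tail (closeness) of the resulting null distribution gives an
empirical p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .interactome import InteractomeGraph, NodeSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# degree binning

class DegreeBins:
    """Partition of graph nodes into degree classes used by the null.

    A randomized stand-in for a node is drawn from that node's bin, so the
    null preserves the degree profile of the original module up to bin
    resolution. ``log`` bins (powers of two, merged upward until each bin
    holds at least ``min_size`` nodes) are the pipeline default; ``exact``
    bins hold one degree value each.
    """

    def __init__(self, bin_of_degree: dict[int, int], members: dict[int, list[str]]):
        self._bin_of_degree = bin_of_degree
        self._members = {b: sorted(m) for b, m in members.items()}

    @classmethod
    def exact(cls, g: InteractomeGraph) -> "DegreeBins":
        degrees = g.degrees()
        bins: dict[int, int] = {}
        members: dict[int, list[str]] = {}
        for b, deg in enumerate(sorted(set(degrees.values()))):
            bins[deg] = b
        for node, deg in degrees.items():
            members.setdefault(bins[deg], []).append(node)
        return cls(bins, members)

    @classmethod
    def log(cls, g: InteractomeGraph, min_size: int = 100) -> "DegreeBins":
        """Logarithmic (base-2) degree bins merged upward to >= min_size nodes."""
        degrees = g.degrees()
        degs = np.array(sorted(degrees.values()))
        max_deg = int(degs[-1]) if degs.size else 0
        # raw power-of-two edges: [0,1), [1,2), [2,4), [4,8), ...
        edges = [0, 1]
        while edges[-1] <= max_deg:
            edges.append(edges[-1] * 2)
        raw_bin_of_degree = {}
        for d in range(max_deg + 1):
            raw_bin_of_degree[d] = int(np.searchsorted(edges, d, side="right")) - 1
        counts: dict[int, int] = {}
        for d in degrees.values():
            counts[raw_bin_of_degree[d]] = counts.get(raw_bin_of_degree[d], 0) + 1
        # merge ascending: accumulate consecutive raw bins until >= min_size;
        # an undersized top remainder joins the previous group
        max_raw = max(raw_bin_of_degree.values())
        groups: list[list[int]] = []
        cur: list[int] = []
        acc = 0
        for rid in range(max_raw + 1):
            cur.append(rid)
            acc += counts.get(rid, 0)
            if acc >= min_size:
                groups.append(cur)
                cur, acc = [], 0
        if cur:
            if groups:
                groups[-1].extend(cur)
            else:
                groups.append(cur)
        merged_id = {rid: grp[0] for grp in groups for rid in grp}
        bin_of_degree = {d: merged_id[raw_bin_of_degree[d]] for d in range(max_deg + 1)}
        members: dict[int, list[str]] = {}
        for node, deg in degrees.items():
            members.setdefault(bin_of_degree[deg], []).append(node)
        return cls(bin_of_degree, members)

    def bin_id(self, degree: int) -> int:
        try:
            return self._bin_of_degree[degree]
        except KeyError:
            raise ValueError(f"degree {degree} not covered by binning") from None

    def members_of(self, bin_id: int) -> list[str]:
        return self._members[bin_id]


def degree_matched_random_set(
    g: InteractomeGraph,
    original: NodeSet,
    bins: DegreeBins,
    rng: np.random.Generator,
) -> NodeSet:
    """Random node set of the same size as *original*, one draw per member
    from that member's degree bin, sampled without replacement within bins.

    Iteration is over sorted members/bins so rng consumption (and hence the
    result for a given generator state) does not depend on set hash order.
    """
    need: dict[int, int] = {}
    for node in sorted(original, key=str):
        b = bins.bin_id(g.degree(node))
        need[b] = need.get(b, 0) + 1
    picked: list[str] = []
    for bin_id, k in sorted(need.items()):
        pool = bins.members_of(bin_id)
        if k > len(pool):
            raise ValueError(
                f"degree bin {bin_id} holds {len(pool)} nodes but {k} draws "
                f"requested; use coarser binning")
        idx = rng.choice(len(pool), size=k, replace=False)
        picked.extend(pool[i] for i in idx)
    return NodeSet(frozenset(picked), label=f"null({original.label})")


# ---------------------------------------------------------------------------
# proximity and significance

def proximity(g: InteractomeGraph, T: NodeSet, S: NodeSet) -> float:
    """Average shortest-path distance from drug targets to nearest disease gene."""
    t_r = T.restrict(g)
    s_r = S.restrict(g)
    if len(t_r) == 0:
        raise ValueError(f"drug module {T.label!r} is empty after interactome restriction")
    if len(s_r) == 0:
        raise ValueError(f"disease module {S.label!r} is empty after interactome restriction")
    dist = g.distance_to_set_array(s_r)
    vals = dist[g.node_indices(t_r)]
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError(f"no target of {T.label!r} can reach {S.label!r}; "
                         "run on the largest connected component")
    if finite.size < vals.size:
        logger.warning("proximity(%s,%s): %d unreachable targets excluded",
                       T.label, S.label, vals.size - finite.size)
    return float(finite.mean())


@dataclass
class NullDistribution:
    samples: np.ndarray
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.mean = float(self.samples.mean())
        self.sd = float(self.samples.std(ddof=0))


@dataclass
class ProximitySignificance:
    p_obs: float
    z: float
    pval: float
    null: NullDistribution
    degenerate: bool  # True when the null collapsed (sd == 0); z is set to 0


def _null_proximity_sample(
    g: InteractomeGraph,
    T: NodeSet,
    S: NodeSet,
    bins: DegreeBins,
    rng: np.random.Generator,
    mode: str,
) -> float:
    t = degree_matched_random_set(g, T, bins, rng) if mode in ("both", "targets") else T
    s = degree_matched_random_set(g, S, bins, rng) if mode in ("both", "genes") else S
    return proximity(g, t, s)


def proximity_significance(
    g: InteractomeGraph,
    T: NodeSet,
    S: NodeSet,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    bins: DegreeBins | None = None,
    mode: str = "both",
) -> ProximitySignificance:
    """Empirical left-tail significance of p(T, S) under the degree-matched null.

    pval = (1 + #{null <= p_obs}) / (n_perm + 1); z = (p_obs - mean) / sd.
    ``mode`` chooses which side(s) the null randomizes: both | targets | genes.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if mode not in ("both", "targets", "genes"):
        raise ValueError(f"unknown randomization mode {mode!r}")
    rng = np.random.default_rng() if rng is None else rng
    bins = DegreeBins.log(g) if bins is None else bins
    t_r, s_r = T.restrict(g), S.restrict(g)
    p_obs = proximity(g, t_r, s_r)
    if mode == "targets":
        # disease side is fixed: one BFS serves every permutation
        dist = g.distance_to_set_array(s_r)
        t_mat = _null_index_matrix(g, t_r, bins, rng, n_perm)
        vals = dist[t_mat]
        with np.errstate(invalid="ignore"):
            samples = np.where(np.isfinite(vals), vals, np.nan)
        samples = np.nanmean(samples, axis=1)
    else:
        samples = np.array([
            _null_proximity_sample(g, t_r, s_r, bins, rng, mode)
            for _ in range(n_perm)
        ])
    null = NullDistribution(samples)
    pval = (1 + int(np.sum(samples <= p_obs))) / (n_perm + 1)
    degenerate = null.sd == 0.0
    if degenerate:
        logger.warning("proximity null for (%s,%s) is degenerate (sd=0); z set to 0",
                       T.label, S.label)
        z = 0.0
    else:
        z = (p_obs - null.mean) / null.sd
    return ProximitySignificance(p_obs, z, pval, null, degenerate)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# batch screening

def _distinct_rows(rng: np.random.Generator, pool_size: int, k: int,
                   n_rows: int) -> np.ndarray:
    """(n_rows, k) integer matrix; each row holds k distinct uniform draws
    from range(pool_size). Rejection-resamples rows with duplicates."""
    if k > pool_size:
        raise ValueError(f"cannot draw {k} distinct values from {pool_size}")
    if k == pool_size:
        return np.tile(np.arange(pool_size), (n_rows, 1))
    out = rng.integers(0, pool_size, size=(n_rows, k))
    while True:
        srt = np.sort(out, axis=1)
        bad = np.flatnonzero((srt[:, 1:] == srt[:, :-1]).any(axis=1))
        if bad.size == 0:
            return out
        out[bad] = rng.integers(0, pool_size, size=(bad.size, k))


def _null_index_matrix(g: InteractomeGraph, module: NodeSet, bins: DegreeBins,
                       rng: np.random.Generator, n_perm: int) -> np.ndarray:
    """(n_perm, |module|) node-index matrix of degree-matched random sets."""
    need: dict[int, int] = {}
    for node in sorted(module, key=str):
        b = bins.bin_id(g.degree(node))
        need[b] = need.get(b, 0) + 1
    cols = []
    for bin_id in sorted(need):
        pool = bins.members_of(bin_id)
        k = need[bin_id]
        if k > len(pool):
            raise ValueError(
                f"degree bin {bin_id} holds {len(pool)} nodes but {k} draws "
                f"requested; use coarser binning")
        pool_idx = g.node_indices(pool)
        cols.append(pool_idx[_distinct_rows(rng, len(pool), k, n_perm)])
    return np.concatenate(cols, axis=1)


def score_pairs(
    g: InteractomeGraph,
    drug_targets: dict[str, set[str]],
    disease_genes: dict[str, set[str]],
    n_perm: int = 1000,
    seed: int = 0,
    bins: DegreeBins | None = None,
    mode: str = "both",
) -> pd.DataFrame:
    """Proximity + significance for every drug × disease pair, BH-adjusted
    across all pairs.

    For efficiency the disease-side permutations (one distance map each) are
    shared across all drugs of a disease; the drug side is resampled per drug
    per permutation. Columns: drug, disease, p, z, pval, adj_pval,
    n_targets_used, n_genes_used.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    bins = DegreeBins.log(g) if bins is None else bins
    drug_sets = {d: NodeSet(t, d).restrict(g) for d, t in sorted(drug_targets.items())}
    disease_sets = {d: NodeSet(s, d).restrict(g) for d, s in sorted(disease_genes.items())}
    for name, ns in {**drug_sets, **disease_sets}.items():
        if len(ns) == 0:
            raise ValueError(f"module {name!r} is empty after interactome restriction")

    order = g.node_order()
    rows = []
    row_ids = np.arange(n_perm)[:, None]
    for disease, S in disease_sets.items():
        dist_obs = g.distance_to_set_array(S)
        if mode in ("both", "genes"):
            s_idx = _null_index_matrix(g, S, bins, rng, n_perm)
            null_dists = np.vstack([
                g.distance_to_set_array([order[i] for i in s_idx[k]])
                for k in range(n_perm)
            ])  # n_perm x n_nodes
        else:
            null_dists = None
        for drug, T in drug_sets.items():
            t_idx = g.node_indices(T)
            p_obs = float(dist_obs[t_idx].mean())
            if mode in ("both", "targets"):
                t_mat = _null_index_matrix(g, T, bins, rng, n_perm)
                if null_dists is None:
                    null_p = dist_obs[t_mat].mean(axis=1)
                else:
                    null_p = null_dists[row_ids, t_mat].mean(axis=1)
            else:
                null_p = null_dists[:, t_idx].mean(axis=1)
            null = NullDistribution(null_p)
            pval = (1 + int(np.sum(null_p <= p_obs))) / (n_perm + 1)
            z = 0.0 if null.sd == 0 else (p_obs - null.mean) / null.sd
            rows.append({
                "drug": drug, "disease": disease, "p": p_obs, "z": z,
                "pval": pval, "n_targets_used": len(T), "n_genes_used": len(S),
            })
    df = pd.DataFrame(rows)
    df["adj_pval"] = bh_adjust(df["pval"].to_numpy())
    df["seed"] = seed
    df["n_perm"] = n_perm
    logger.info("score_pairs: %d pairs scored (%d drugs x %d diseases)",
                len(df), len(drug_sets), len(disease_sets))
    return df
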