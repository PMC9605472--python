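"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* a degree-heterogeneous (preferential-attachment) interactome with a
  connected planted disease module, "true" drugs whose targets sit in or
  next to that module, and "decoy" drugs with uniformly random targets;
* case/control expression matrices with a planted fraction of mean-shifted
  genes and optional additive batch offsets;
* drug rank profiles that either reverse a disease signature (up genes
  scored low, down genes scored high) or are uncorrelated noise.

Every generator is a pure function of (parameters, seed). Defaults are
desk-scale: a 2,000-node interactome, 5 diseases, 100 drugs, expression
datasets of 5,000 genes — the full pipeline runs in minutes on one CPU.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import DrugProfile, write_long_profiles
from .interactome import InteractomeGraph, write_edge_list
from .signatures import CASE, CONTROL, DiseaseSignature, ExpressionDataset

logger = logging.getLogger(__name__)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators; fully determined by
    (parameters, seed)."""

    disease_modules: dict[str, list[str]] = field(default_factory=dict)
    focus_disease: str = ""
    true_drugs: dict[str, list[str]] = field(default_factory=dict)
    decoy_drugs: dict[str, list[str]] = field(default_factory=dict)
    planted_de_genes: dict[str, str] = field(default_factory=dict)  # gene -> up|down
    reverser_drugs: list[str] = field(default_factory=list)
    neutral_drugs: list[str] = field(default_factory=list)
    seeds: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def simulate_interactome(
    n_nodes: int = 2000, mean_degree: float = 6.0, seed: int = 0
) -> InteractomeGraph:
    """Connected preferential-attachment graph with a heavy-tailed degree
    distribution (Barabási–Albert with m ≈ mean_degree / 2)."""
    if n_nodes < 50:
        raise ValueError("n_nodes must be >= 50")
    m = max(1, int(round(mean_degree / 2)))
    if m >= n_nodes:
        raise ValueError("mean_degree too large for n_nodes")
    g = nx.barabasi_albert_graph(n_nodes, m, seed=seed)
    g = nx.relabel_nodes(g, {i: _gene_name(i) for i in g.nodes()})
    return InteractomeGraph(g)


def _grow_connected_module(
    g: nx.Graph, size: int, rng: np.random.Generator
) -> list[str]:
    """Seeded expansion: start from a random node, repeatedly absorb a
    random neighbor of the current module."""
    nodes = sorted(g.nodes())
    start = nodes[rng.integers(len(nodes))]
    module = {start}
    frontier = set(g.neighbors(start))
    while len(module) < size:
        if not frontier:
            raise ValueError(f"cannot grow a connected module of size {size}")
        cand = sorted(frontier)
        pick = cand[rng.integers(len(cand))]
        module.add(pick)
        frontier.update(g.neighbors(pick))
        frontier -= module
    return sorted(module)


def plant_modules(
    g: InteractomeGraph,
    disease_size: int = 50,
    n_true: int = 10,
    n_decoy: int = 90,
    targets_per_drug: int = 5,
    seed: int = 0,
    n_diseases: int = 1,
) -> SyntheticTruth:
    """Plant disease modules plus true/decoy drug-target sets.

    One connected module is grown per disease. True drugs draw their targets
    from the FIRST (focus) disease's module and its first neighbors, so
    their proximity to it is at most 1 by construction; decoys draw targets
    uniformly at random from the whole graph.
    """
    if disease_size < 2 or disease_size > g.n_nodes // 2:
        raise ValueError("infeasible disease module size")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seeds={"modules": seed})
    for d in range(n_diseases):
        name = f"DIS{d:02d}"
        truth.disease_modules[name] = _grow_connected_module(
            g.graph, disease_size, rng)
    truth.focus_disease = "DIS00"
    focus = set(truth.disease_modules["DIS00"])
    halo = sorted(focus | {nb for m in focus for nb in g.graph.neighbors(m)})
    all_nodes = sorted(g.nodes())
    if targets_per_drug > len(halo):
        raise ValueError("targets_per_drug exceeds module neighborhood size")
    for i in range(n_true):
        idx = rng.choice(len(halo), size=targets_per_drug, replace=False)
        truth.true_drugs[f"true{i:03d}"] = sorted(halo[j] for j in idx)
    for i in range(n_decoy):
        idx = rng.choice(len(all_nodes), size=targets_per_drug, replace=False)
        truth.decoy_drugs[f"decoy{i:03d}"] = sorted(all_nodes[j] for j in idx)
    return truth


def simulate_expression(
    n_genes: int = 5000,
    n_case: int = 50,
    n_control: int = 50,
    de_fraction: float = 0.1,
    effect_size: float = 1.5,
    batch_shift: float = 0.0,
    n_batches: int = 1,
    seed: int = 0,
    planted: dict[str, str] | None = None,
) -> tuple[ExpressionDataset, dict[str, str]]:
    """Case/control matrix: standard-normal baseline, a planted fraction of
    genes mean-shifted by ±effect_size in cases (random direction), and an
    additive per-batch offset of b * batch_shift for batch index b.

    ``planted`` fixes the affected genes and their directions (gene ->
    up|down), so several cohorts of the same disease can share one signal;
    by default a fresh de_fraction of genes is drawn.
    Returns the dataset and the planted truth (gene -> up|down).
    """
    if not 0 < de_fraction < 1:
        raise ValueError("de_fraction must be in (0, 1)")
    if n_case < 2 or n_control < 2:
        raise ValueError("each group needs >= 2 samples")
    rng = np.random.default_rng(seed)
    genes = [_gene_name(i) for i in range(n_genes)]
    samples = [f"case{i:03d}" for i in range(n_case)] + \
              [f"ctrl{i:03d}" for i in range(n_control)]
    x = rng.standard_normal((n_genes, n_case + n_control))
    if planted is None:
        n_de = int(round(de_fraction * n_genes))
        de_idx = rng.choice(n_genes, size=n_de, replace=False)
        directions = rng.choice([1.0, -1.0], size=n_de)
    else:
        index_of = {gene: i for i, gene in enumerate(genes)}
        missing = set(planted) - set(index_of)
        if missing:
            raise ValueError(f"planted genes outside the universe: {sorted(missing)[:5]}")
        de_idx = np.array([index_of[gene] for gene in sorted(planted)])
        directions = np.array([1.0 if planted[gene] == "up" else -1.0
                               for gene in sorted(planted)])
    x[de_idx, :n_case] += directions[:, None] * effect_size
    truth = {genes[i]: ("up" if d > 0 else "down")
             for i, d in zip(de_idx, directions)}
    classes = pd.Series([CASE] * n_case + [CONTROL] * n_control, index=samples)
    batch = None
    if n_batches > 1:
        # interleave batches across both classes so batch is not confounded
        assign = np.arange(n_case + n_control) % n_batches
        assign = rng.permutation(assign)
        x += (assign * batch_shift)[None, :]
        batch = pd.Series([f"batch{b}" for b in assign], index=samples)
    ds = ExpressionDataset(pd.DataFrame(x, index=genes, columns=samples),
                           classes, batch)
    return ds, truth


def simulate_drug_profiles(
    signature: DiseaseSignature,
    universe: list[str],
    n_reversers: int = 5,
    n_neutrals: int = 20,
    noise_sd: float = 0.25,
    seed: int = 0,
    cell_lines: tuple[str, ...] = ("NPC", "NEU"),
    signal: float = 3.0,
    reverser_names: list[str] | None = None,
    neutral_names: list[str] | None = None,
) -> tuple[list[DrugProfile], SyntheticTruth]:
    """Drug rank profiles over the full gene universe.

    Reversers score the signature's up genes around -signal and its down
    genes around +signal (plus Gaussian noise), i.e. they push disease-up
    genes to the bottom and disease-down genes to the top of the ranked
    list; neutral drugs score every gene independently N(0, 1).
    """
    sig_genes = set(signature.up_genes) | set(signature.down_genes)
    if not sig_genes:
        raise ValueError("empty disease signature")
    if not sig_genes <= set(universe):
        raise ValueError("signature genes must be a subset of the universe")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    up_mask = np.isin(universe, list(signature.up_genes))
    down_mask = np.isin(universe, list(signature.down_genes))
    if reverser_names is not None and len(reverser_names) != n_reversers:
        raise ValueError("reverser_names length must equal n_reversers")
    if neutral_names is not None and len(neutral_names) != n_neutrals:
        raise ValueError("neutral_names length must equal n_neutrals")
    if set(reverser_names or []) & set(neutral_names or []):
        raise ValueError("reverser and neutral drug names must be disjoint")
    profiles: list[DrugProfile] = []
    truth = SyntheticTruth(seeds={"profiles": seed})
    for i in range(n_reversers):
        name = reverser_names[i] if reverser_names else f"rev{i:03d}"
        truth.reverser_drugs.append(name)
        for cl in cell_lines:
            base = rng.standard_normal(len(universe))
            base[up_mask] = -signal + noise_sd * rng.standard_normal(up_mask.sum())
            base[down_mask] = signal + noise_sd * rng.standard_normal(down_mask.sum())
            profiles.append(DrugProfile(name, cl, pd.Series(base, index=universe)))
    for i in range(n_neutrals):
        name = neutral_names[i] if neutral_names else f"neu{i:03d}"
        truth.neutral_drugs.append(name)
        for cl in cell_lines:
            scores = rng.standard_normal(len(universe))
            profiles.append(DrugProfile(name, cl, pd.Series(scores, index=universe)))
    return profiles, truth


# ---------------------------------------------------------------------------
# file emission (the exact formats the pipeline reads)

def write_inputs(
    outdir: str | Path,
    g: InteractomeGraph,
    truth: SyntheticTruth,
    indications: dict[str, list[str]] | None = None,
) -> None:
    """Edge-list TSV, drug-target TSV, disease-gene TSV, indication TSV,
    truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_edge_list(g, outdir / "interactome.tsv")
    with open(outdir / "drug_targets.tsv", "w") as fh:
        for drug, targets in sorted({**truth.true_drugs, **truth.decoy_drugs}.items()):
            for t in targets:
                fh.write(f"{drug}\t{t}\n")
    with open(outdir / "disease_genes.tsv", "w") as fh:
        for disease, genes in sorted(truth.disease_modules.items()):
            for gene in genes:
                fh.write(f"{disease}\t{gene}\n")
    if indications:
        with open(outdir / "indications.tsv", "w") as fh:
            for drug, inds in sorted(indications.items()):
                for ind in inds:
                    fh.write(f"{drug}\t{ind}\n")
    truth.to_json(outdir / "truth.json")


def read_two_column_sets(path: str | Path) -> dict[str, set[str]]:
    """TSV of (label, gene) rows -> label -> gene set (drug targets or
    disease genes)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["label", "gene"],
                     dtype=str)
    return {label: set(sub["gene"]) for label, sub in df.groupby("label")}
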