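"""Orchestration of the two pipelines from a single reproducible config.

* repurposing: interactome -> proximity -> permutation significance ->
  clustering -> adjusted similarity -> association network (+ specificity
  and indication summaries);
* validation: disease signatures -> connectivity enrichment against drug
  profiles -> integer reversal score per network drug.

Every run is a pure function of (config, seed): the config (including the
seed) is serialized verbatim into the run metadata and all tabular outputs
are written deterministically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import association, connectivity, interactome, proximity, repurposing
from . import signatures as sigmod
from . import synthetic

logger = logging.getLogger(__name__)


@dataclass
class ExpressionInput:
    """One disease-signature cohort: one or more matrices sharing an
    annotation schema; several matrices merge into one batch-corrected
    dataset."""

    name: str
    matrices: list[str]
    annotations: list[str]
    method: str = "pooled_t"      # pooled_t | moderated_t
    mode: str = "adjusted"        # adjusted | raw p-value threshold
    alpha: float = 0.01
    log2: bool = True


@dataclass
class RunConfig:
    outdir: str = "runs/out"
    seed: int = 0
    # repurposing inputs
    interactome_path: str | None = None
    drug_targets_path: str | None = None
    disease_genes_path: str | None = None
    indications_path: str | None = None
    focus_disease: str | None = None
    # validation inputs
    expression: list[ExpressionInput] = field(default_factory=list)
    profiles_path: str | None = None
    # parameters; n_perm must keep the empirical floor 1/(n_perm+1) well
    # below alpha/m for the BH step-up to admit discoveries among m pairs
    n_perm: int = 10000
    alpha: float = 0.05
    c: float = repurposing.DEFAULT_STEEPNESS
    d_mid: float = repurposing.DEFAULT_MIDPOINT
    null_mode: str = "targets"
    iqr_percentile: float = 10.0
    min_indication_count: int = 5
    # synthetic-generation parameters (used by the simulate stage)
    synthetic: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        expr = [ExpressionInput(**e) for e in raw.pop("expression", [])]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(expression=expr, **raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stage(name):
    """Decorator: re-raise any stage failure with the stage name attached."""
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        inner.__name__ = fn.__name__
        inner.__doc__ = fn.__doc__
        return inner
    return wrap


# ---------------------------------------------------------------------------
# simulate

@_stage("simulate")
def run_simulate(config: RunConfig) -> synthetic.SyntheticTruth:
    """Generate all pipeline inputs with planted truth into config.outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = {
        "n_nodes": 2000, "mean_degree": 6.0, "n_diseases": 5,
        "disease_size": 50, "n_true": 10, "n_decoy": 90,
        "targets_per_drug": 5, "n_datasets": 3, "n_genes": 5000,
        "n_case": 50, "n_control": 50, "de_fraction": 0.1,
        "effect_size": 1.5, "batch_shift": 0.0, "n_batches": 1,
        "n_reversers": 5, "n_neutrals": 20, "noise_sd": 0.25,
    }
    p.update(config.synthetic)
    seed = config.seed
    g = synthetic.simulate_interactome(p["n_nodes"], p["mean_degree"], seed)
    truth = synthetic.plant_modules(
        g, p["disease_size"], p["n_true"], p["n_decoy"],
        p["targets_per_drug"], seed=seed + 1, n_diseases=p["n_diseases"])

    # original-indication table: decoys get plausible indication classes
    rng_ind = list(sorted(truth.decoy_drugs))
    indications = {d: [f"Indication{(i % 7):02d}"] for i, d in enumerate(rng_ind)}
    indications.update({d: ["Indication00"] for d in truth.true_drugs})
    synthetic.write_inputs(outdir / "inputs", g, truth, indications)

    # expression cohorts sharing one planted disease signal
    planted_up, planted_down = [], []
    shared_planted: dict[str, str] | None = None
    for k in range(p["n_datasets"]):
        ds, de_truth = synthetic.simulate_expression(
            p["n_genes"], p["n_case"], p["n_control"], p["de_fraction"],
            p["effect_size"], p["batch_shift"], p["n_batches"],
            seed=seed + 10 + k, planted=shared_planted)
        shared_planted = de_truth
        ds.values.round(6).to_csv(outdir / "inputs" / f"expression{k}.tsv", sep="\t")
        ann = pd.DataFrame({"sample": ds.values.columns,
                            "class": ds.sample_class.values})
        if ds.batch is not None:
            ann["batch"] = ds.batch.values
        ann.to_csv(outdir / "inputs" / f"annotation{k}.tsv", sep="\t", index=False)
        if k == 0:
            truth.planted_de_genes = de_truth
            planted_up = sorted(gn for gn, d in de_truth.items() if d == "up")
            planted_down = sorted(gn for gn, d in de_truth.items() if d == "down")

    # drug profiles: reversers named after true drugs, neutrals after decoys
    planted_sig = sigmod.DiseaseSignature("planted", planted_up, planted_down)
    universe = [synthetic._gene_name(i) for i in range(p["n_genes"])]
    rev_names = sorted(truth.true_drugs)[: p["n_reversers"]]
    neu_names = sorted(truth.decoy_drugs)[: p["n_neutrals"]]
    profiles, ptruth = synthetic.simulate_drug_profiles(
        planted_sig, universe, p["n_reversers"], p["n_neutrals"],
        p["noise_sd"], seed=seed + 100,
        reverser_names=rev_names, neutral_names=neu_names)
    synthetic.write_long_profiles(profiles, outdir / "inputs" / "profiles.tsv")
    truth.reverser_drugs = ptruth.reverser_drugs
    truth.neutral_drugs = ptruth.neutral_drugs
    truth.seeds = {"root": seed}
    truth.to_json(outdir / "inputs" / "truth.json")
    logger.info("simulate: inputs written to %s", outdir / "inputs")
    return truth


def synthetic_config(outdir: str | Path, seed: int, **overrides) -> RunConfig:
    """A RunConfig whose input paths point at the simulate-stage outputs."""
    inputs = Path(outdir) / "inputs"
    synth = overrides.pop("synthetic", {})
    n_datasets = synth.get("n_datasets", 3)
    expression = [
        ExpressionInput(
            name=f"DS{k}",
            matrices=[str(inputs / f"expression{k}.tsv")],
            annotations=[str(inputs / f"annotation{k}.tsv")],
            method="pooled_t", mode="adjusted", alpha=0.01, log2=False)
        for k in range(n_datasets)
    ]
    return RunConfig(
        outdir=str(outdir), seed=seed,
        interactome_path=str(inputs / "interactome.tsv"),
        drug_targets_path=str(inputs / "drug_targets.tsv"),
        disease_genes_path=str(inputs / "disease_genes.tsv"),
        indications_path=str(inputs / "indications.tsv"),
        profiles_path=str(inputs / "profiles.tsv"),
        focus_disease="DIS00",
        expression=expression,
        synthetic=synth,
        **overrides,
    )


# ---------------------------------------------------------------------------
# repurposing

@_stage("repurposing")
def run_repurposing(config: RunConfig) -> association.DrugDiseaseNetwork:
    """interactome -> proximity significance -> adjusted similarity ->
    association network; writes all module outputs under outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = interactome.read_interactome(config.interactome_path)
    g = interactome.largest_connected_component(g)
    drug_targets = synthetic.read_two_column_sets(config.drug_targets_path)
    disease_genes = synthetic.read_two_column_sets(config.disease_genes_path)
    prox = proximity.score_pairs(
        g, drug_targets, disease_genes, n_perm=config.n_perm,
        seed=config.seed, mode=config.null_mode)
    prox.to_csv(outdir / "proximity.tsv", sep="\t", index=False,
                float_format="%.6f")
    assoc = repurposing.build_association_table(
        prox, alpha=config.alpha, c=config.c, d_mid=config.d_mid)
    gene_counts = {d: len(s & g.nodes()) for d, s in disease_genes.items()}
    metadata = {"config": config.to_dict(), "config_hash": config.config_hash(),
                "seed": config.seed,
                "n_nodes": g.n_nodes, "n_edges": g.n_edges}
    net = association.build_association_network(
        assoc, alpha=config.alpha, disease_gene_counts=gene_counts,
        metadata=metadata)
    association.write_network(net, outdir)
    if not assoc.empty:
        cluster_rows = []
        for r in assoc.itertuples():
            cluster_rows.append((r.drug, "drug", r.cluster_drug))
            cluster_rows.append((r.disease, "disease", r.cluster_disease))
        pd.DataFrame(sorted(set(cluster_rows)),
                     columns=["node", "type", "cluster"]).to_csv(
            outdir / "clusters.tsv", sep="\t", index=False)
    if config.focus_disease and config.focus_disease in set(net.links["disease"]):
        spec = association.classify_specificity(net, config.focus_disease)
        pd.DataFrame(
            [(d, "specific" if not o else "shared", ";".join(o))
             for d, o in sorted(spec.items())],
            columns=["drug", "specificity", "shared_with"],
        ).to_csv(outdir / "specificity.tsv", sep="\t", index=False)
        if config.indications_path:
            ind = association.read_indications(config.indications_path)
            dist = association.indication_distribution(
                net, config.focus_disease, ind, config.min_indication_count)
            dist.to_csv(outdir / "indication_distribution.tsv", sep="\t",
                        index=False)
    return net


# ---------------------------------------------------------------------------
# validation

@_stage("signatures")
def build_signatures(config: RunConfig) -> list[sigmod.DiseaseSignature]:
    """Run the expression pipeline per cohort and threshold into signatures."""
    out = []
    for cohort in config.expression:
        parts = []
        for mat_path, ann_path in zip(cohort.matrices, cohort.annotations):
            parts.append(sigmod.load_expression_dataset(
                mat_path, ann_path, log2=cohort.log2))
        ds = parts[0] if len(parts) == 1 else sigmod.merge_batches(parts)
        if ds.batch is not None and ds.batch.nunique() >= 2:
            ds = sigmod.batch_correct(ds)
        ds = sigmod.iqr_filter(ds, config.iqr_percentile)
        de = sigmod.differential_expression(ds, method=cohort.method)
        out.append(sigmod.make_disease_signature(
            de, cohort.name, mode=cohort.mode, alpha=cohort.alpha))
    return out


@_stage("validation")
def run_validation(
    config: RunConfig,
    network: association.DrugDiseaseNetwork | None = None,
) -> pd.DataFrame:
    """Score every focus-disease drug of the network against every disease
    signature; writes enrichment and score tables. Returns the score table."""
    outdir = Path(config.outdir)
    if network is None:
        network = association.read_network(outdir)
    if not config.expression:
        raise ValueError("no expression cohorts configured")
    if config.focus_disease not in set(network.links["disease"]):
        raise ValueError(f"focus disease {config.focus_disease!r} not in network")
    sigs = build_signatures(config)
    sigmod.write_gmt(sigs, outdir / "signatures.gmt")
    candidate_drugs = set(
        network.links.loc[network.links["disease"] == config.focus_disease,
                          "drug"])
    profiles = [p for p in connectivity.read_long_profiles(config.profiles_path)
                if p.drug in candidate_drugs]
    enr = connectivity.enrichment_table(profiles, sigs)
    enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
               float_format="%.6f")
    scores = connectivity.gsea_score(enr, n_datasets=len(sigs),
                                     drugs=candidate_drugs)
    scores.to_csv(outdir / "gsea_scores.tsv", sep="\t", index=False)
    logger.info("validation: %d drugs scored against %d signatures",
                len(scores), len(sigs))
    return scores


def run_all(config: RunConfig) -> tuple[association.DrugDiseaseNetwork, pd.DataFrame]:
    """simulate (if no inputs configured) -> repurpose -> validate."""
    if config.interactome_path is None:
        run_simulate(config)
        config = synthetic_config(config.outdir, config.seed,
                                  synthetic=config.synthetic,
                                  n_perm=config.n_perm, alpha=config.alpha,
                                  c=config.c, d_mid=config.d_mid,
                                  null_mode=config.null_mode)
    net = run_repurposing(config)
    scores = run_validation(config, net)
    return net, scores
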