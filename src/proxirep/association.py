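"""Final weighted bipartite drug–disease network, specificity, indications."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class DrugDiseaseNetwork:
    """Significant drug–disease links weighted by adjusted similarity.

    ``links`` holds one row per significant (drug, disease) pair with at
    least the columns drug, disease, adj_pval, adjusted_similarity.
    ``disease_gene_counts`` is display metadata (node sizes scale with the
    number of associated genes).
    """

    links: pd.DataFrame
    disease_gene_counts: dict[str, int] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def drugs(self) -> list[str]:
        return sorted(self.links["drug"].unique())

    @property
    def diseases(self) -> list[str]:
        return sorted(self.links["disease"].unique())

    def n_links(self) -> int:
        return len(self.links)


def build_association_network(
    records: pd.DataFrame,
    alpha: float = 0.05,
    disease_gene_counts: dict[str, int] | None = None,
    metadata: dict | None = None,
) -> DrugDiseaseNetwork:
    """Keep records with adj_pval < alpha as network links."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    required = {"drug", "disease", "adj_pval", "adjusted_similarity"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {missing}")
    links = records[records["adj_pval"] < alpha].copy()
    if links.duplicated(["drug", "disease"]).any():
        raise ValueError("duplicate (drug, disease) pairs in records")
    if links.empty:
        logger.warning("association network is empty at alpha=%g", alpha)
    meta = dict(metadata or {})
    meta["alpha"] = alpha
    net = DrugDiseaseNetwork(links.reset_index(drop=True),
                             dict(disease_gene_counts or {}), meta)
    logger.info("association network: %d drugs, %d diseases, %d links",
                len(net.drugs), len(net.diseases), net.n_links())
    return net


def classify_specificity(
    network: DrugDiseaseNetwork, focus_disease: str
) -> dict[str, list[str]]:
    """For each drug linked to the focus disease: [] if linked only there
    ("specific"), else the sorted list of other linked diseases ("shared")."""
    if focus_disease not in set(network.links["disease"]):
        raise ValueError(f"disease {focus_disease!r} not in network")
    by_drug = network.links.groupby("drug")["disease"].agg(set)
    out: dict[str, list[str]] = {}
    for drug, diseases in by_drug.items():
        if focus_disease in diseases:
            out[drug] = sorted(diseases - {focus_disease})
    return out


def indication_distribution(
    network: DrugDiseaseNetwork,
    focus_disease: str,
    indications: dict[str, list[str]],
    min_count: int = 5,
) -> pd.DataFrame:
    """Count focus-disease drugs per original medical indication, descending.

    A drug with several indications counts once per indication; drugs absent
    from the table count under "unknown". Rows with count < min_count drop.
    """
    drugs = network.links.loc[network.links["disease"] == focus_disease, "drug"]
    counts: dict[str, int] = {}
    for drug in drugs:
        for ind in indications.get(drug) or ["unknown"]:
            counts[ind] = counts.get(ind, 0) + 1
    df = pd.DataFrame(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
                      columns=["indication", "count"])
    return df[df["count"] >= min_count].reset_index(drop=True)


def read_indications(path: str | Path) -> dict[str, list[str]]:
    """2-column TSV (drug, indication), one row per pair."""
    df = pd.read_csv(path, sep="\t", header=None, names=["drug", "indication"],
                     dtype=str)
    out: dict[str, list[str]] = {}
    for r in df.itertuples():
        out.setdefault(r.drug, []).append(r.indication)
    return out


# ---------------------------------------------------------------------------
# export / import

def write_network(net: DrugDiseaseNetwork, outdir: str | Path) -> None:
    """GraphML + TSV edge table + similarity matrix + JSON metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net.links.to_csv(outdir / "associations.tsv", sep="\t", index=False,
                     float_format="%.6f")
    matrix = net.links.pivot(index="disease", columns="drug",
                             values="adjusted_similarity")
    matrix.to_csv(outdir / "similarity_matrix.tsv", sep="\t",
                  float_format="%.6f")
    g = nx.Graph()
    for dis in net.diseases:
        g.add_node("disease:" + dis, kind="disease",
                   n_genes=int(net.disease_gene_counts.get(dis, 0)))
    for drug in net.drugs:
        g.add_node("drug:" + drug, kind="drug")
    for r in net.links.itertuples():
        g.add_edge("drug:" + r.drug, "disease:" + r.disease,
                   adjusted_similarity=float(r.adjusted_similarity))
    nx.write_graphml(g, outdir / "network.graphml")
    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump(net.metadata, fh, indent=2, sort_keys=True, default=str)


def read_network(outdir: str | Path) -> DrugDiseaseNetwork:
    outdir = Path(outdir)
    links = pd.read_csv(outdir / "associations.tsv", sep="\t")
    with open(outdir / "run_metadata.json") as fh:
        metadata = json.load(fh)
    return DrugDiseaseNetwork(links, metadata=metadata)
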