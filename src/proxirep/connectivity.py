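"""Connectivity-style enrichment: does a drug reverse a disease signature?

A drug profile is the full ranked list of genes ordered by the drug's
transcriptional effect (rank 1 = most up-regulated by the drug; ties broken
by gene id). For each disease signature, a two-tag-set Kolmogorov–Smirnov
statistic locates the signature's up and down gene sets within that list:

    es_up  = ks(up tags),  es_down = ks(down tags)
    es     = (es_up - es_down) / 2   if the two have opposite signs, else 0

A drug whose profile pushes the disease's up genes to the bottom and its
down genes to the top has es < 0 — the complementary-profile (reversal)
pattern. The integer connectivity score of a drug is the number of disease
signatures (out of n tested) with aggregated es < 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NOT_AVAILABLE = "not_available"
AVAILABLE = "available"


@dataclass
class DrugProfile:
    """Full ranked expression response of one drug in one cell line."""

    drug: str
    cell_line: str
    scores: pd.Series  # gene -> differential score; gene ids unique

    def __post_init__(self) -> None:
        if self.scores.index.duplicated().any():
            raise ValueError("duplicate gene ids in drug profile")

    def ranked_genes(self) -> list[str]:
        """Genes ordered by decreasing score (rank 1 = most up-regulated);
        ties broken by gene id."""
        order = sorted(self.scores.index, key=lambda g: (-self.scores[g], g))
        return order


def ks_enrichment(tags: Iterable[str], profile: DrugProfile) -> float:
    """Two-sided KS running-sum statistic of tag positions in the profile.

    With tag positions V(1..t) (1-based, sorted) among n ranked genes:
        a = max_j (j/t - V(j)/n)
        b = max_j (V(j)/n - (j-1)/t)
    Returns a if a > b else -b: positive when tags crowd the top of the
    list, negative when they crowd the bottom.
    """
    ranked = profile.ranked_genes()
    pos_of = {g: i + 1 for i, g in enumerate(ranked)}
    tags = set(tags)
    present = sorted(pos_of[g] for g in tags if g in pos_of)
    missing = len(tags) - len(present)
    if missing:
        logger.info("ks_enrichment: %d of %d tags absent from profile %s/%s",
                    missing, len(tags), profile.drug, profile.cell_line)
    if not present:
        raise ValueError(
            f"no tag gene present in profile {profile.drug}/{profile.cell_line}")
    n = len(ranked)
    t = len(present)
    v = np.asarray(present, dtype=float)
    j = np.arange(1, t + 1, dtype=float)
    a = float(np.max(j / t - v / n))
    b = float(np.max(v / n - (j - 1) / t))
    return a if a > b else -b


def combined_es(es_up: float, es_down: float) -> float:
    """(es_up - es_down)/2 when the two statistics disagree in sign, else 0.

    Opposite signs mean the up and down tag sets sit at opposite ends of the
    drug list — a coherent (mimicking or reversing) relationship; same-sign
    results are incoherent and scored 0.
    """
    if np.sign(es_up) == np.sign(es_down):
        return 0.0
    return (es_up - es_down) / 2.0


def enrichment_table(
    profiles: Sequence[DrugProfile],
    signatures: Sequence,  # DiseaseSignature
) -> pd.DataFrame:
    """es_up/es_down/es for every profile x signature.

    Profiles in which no signature gene occurs get NaN entries (unavailable).
    Columns: drug, dataset, cell_line, es_up, es_down, es.
    """
    rows = []
    for prof in profiles:
        for sig in signatures:
            try:
                es_up = ks_enrichment(sig.up_genes, prof)
                es_down = ks_enrichment(sig.down_genes, prof)
                es = combined_es(es_up, es_down)
            except ValueError:
                es_up = es_down = es = np.nan
            rows.append({"drug": prof.drug, "dataset": sig.name,
                         "cell_line": prof.cell_line,
                         "es_up": es_up, "es_down": es_down, "es": es})
    return pd.DataFrame(rows)


def gsea_score(
    enrichment: pd.DataFrame,
    n_datasets: int,
    drugs: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Integer reversal score per drug: the number of datasets whose
    cell-line-averaged es is negative.

    Drugs with no available enrichment row anywhere (or absent from the
    table entirely) get availability = not_available. Passing ``drugs``
    forces a row for every listed drug.
    """
    rows = []
    all_drugs = sorted(set(enrichment["drug"]) | set(drugs or []))
    for drug in all_drugs:
        sub = enrichment[(enrichment["drug"] == drug) & enrichment["es"].notna()]
        if sub.empty:
            rows.append({"drug": drug, "score": pd.NA,
                         "availability": NOT_AVAILABLE})
            continue
        per_dataset = sub.groupby("dataset")["es"].mean()
        score = int((per_dataset < 0).sum())
        if score > n_datasets:
            raise ValueError("more datasets scored than n_datasets")
        rows.append({"drug": drug, "score": score, "availability": AVAILABLE})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O

def read_rnk_profile(path: str | Path, drug: str, cell_line: str) -> DrugProfile:
    s = pd.read_csv(path, sep="\t", header=None, index_col=0).iloc[:, 0]
    return DrugProfile(drug, cell_line, s)


def read_long_profiles(path: str | Path) -> list[DrugProfile]:
    """Long-format table: drug, cell_line, gene, score (TSV with header)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for (drug, cl), sub in df.groupby(["drug", "cell_line"], sort=True):
        out.append(DrugProfile(drug, cl, sub.set_index("gene")["score"]))
    return out


def write_long_profiles(profiles: Sequence[DrugProfile], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"drug": p.drug, "cell_line": p.cell_line,
                      "gene": p.scores.index, "score": p.scores.to_numpy()})
        for p in profiles
    ]
    pd.concat(frames).to_csv(path, sep="\t", index=False)
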