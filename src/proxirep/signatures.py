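"""Disease expression signatures from case/control microarray-style data.

Pipeline order (fixed): preprocess (log2, probe collapse) -> merge batches ->
batch correct -> IQR variance filter -> differential expression -> threshold
into ordered up/down gene lists. The DE statistic is a pooled-variance
two-sample t test; a moderated variant shrinks per-gene variances toward a
common prior (empirical Bayes) for small cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from .proximity import bh_adjust

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with class (case/control) labels
    and optional batch labels, all indexed by sample name."""

    values: pd.DataFrame
    sample_class: pd.Series
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.sample_class.index):
            self.sample_class = self.sample_class.reindex(self.values.columns)
        if self.sample_class.isna().any():
            raise ValueError("every sample needs a case/control label")
        bad = set(self.sample_class.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"unknown sample classes {bad}")
        if self.batch is not None:
            self.batch = self.batch.reindex(self.values.columns)

    @property
    def n_genes(self) -> int:
        return len(self.values)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def class_columns(self, cls: str) -> pd.Index:
        return self.values.columns[self.sample_class == cls]


@dataclass
class DiseaseSignature:
    """Ordered up/down gene lists; each ordered by increasing fold change."""

    name: str
    up_genes: list[str]
    down_genes: list[str]
    fold_change: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self) -> None:
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up and down gene lists overlap")


# ---------------------------------------------------------------------------
# preprocessing

def preprocess_expression(
    ds: ExpressionDataset, log2: bool = True, collapse: bool = True
) -> ExpressionDataset:
    """Optional log2(x+1) transform and probe-to-gene mean collapse."""
    vals = ds.values
    if not np.isfinite(vals.to_numpy()).all():
        bad = vals.index[~np.isfinite(vals).all(axis=1)].tolist()
        raise ValueError(f"non-finite expression values in rows {bad[:10]}")
    if log2:
        if (vals.to_numpy() <= -1).any():
            raise ValueError("values must exceed -1 for the log2(x+1) transform")
        vals = np.log2(vals + 1.0)
    if collapse and vals.index.duplicated().any():
        n_before = len(vals)
        vals = vals.groupby(level=0, sort=False).mean()
        logger.info("probe collapse: %d rows -> %d genes", n_before, len(vals))
    return replace(ds, values=vals)


def merge_batches(datasets: list[ExpressionDataset]) -> ExpressionDataset:
    """Concatenate cohorts on the intersection of their gene sets; each
    input dataset becomes one batch."""
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets to merge")
    genes = datasets[0].values.index
    for ds in datasets[1:]:
        genes = genes.intersection(ds.values.index)
    if len(genes) == 0:
        raise ValueError("merged gene set is empty (no shared gene symbols)")
    genes = genes.sort_values()
    mats, classes, batches = [], [], []
    for i, ds in enumerate(datasets):
        suffix = f"__b{i}"
        sub = ds.values.loc[genes]
        sub = sub.rename(columns={c: c + suffix for c in sub.columns})
        mats.append(sub)
        classes.append(ds.sample_class.rename(index=lambda c: c + suffix))
        batches.append(pd.Series(f"batch{i}", index=sub.columns))
    merged = ExpressionDataset(
        pd.concat(mats, axis=1), pd.concat(classes), pd.concat(batches))
    logger.info("merge_batches: %d cohorts -> %d genes x %d samples",
                len(datasets), merged.n_genes, merged.n_samples)
    return merged


def batch_correct(ds: ExpressionDataset) -> ExpressionDataset:
    """Per-gene location/scale batch adjustment.

    Within each batch, each gene is standardized and then mapped back to the
    grand gene mean and the pooled within-batch gene standard deviation
    (weighted by batch degrees of freedom), so per-batch gene means coincide
    afterward while the case/control contrast inside batches is preserved.
    When a gene has zero variance inside a batch, the scale step is skipped
    for that gene/batch (location still adjusted).
    """
    if ds.batch is None or ds.batch.nunique() < 2:
        raise ValueError("batch correction needs >= 2 batches")
    counts = ds.batch.value_counts()
    if (counts < 2).any():
        raise ValueError("every batch needs >= 2 samples")
    x = ds.values.to_numpy(dtype=float).copy()
    grand_mean = x.mean(axis=1, keepdims=True)
    batch_ids = ds.batch.unique()
    batch_cols = {b: np.flatnonzero((ds.batch == b).to_numpy()) for b in batch_ids}
    # pooled WITHIN-batch variance: total variance would also carry the very
    # batch offsets being removed and inflate the restored scale
    num = np.zeros(x.shape[0])
    den = 0
    for b in batch_ids:
        sub = x[:, batch_cols[b]]
        num += sub.var(axis=1, ddof=1) * (len(batch_cols[b]) - 1)
        den += len(batch_cols[b]) - 1
    pooled_sd = np.sqrt(num / den)[:, None]
    n_skipped = 0
    for b in batch_ids:
        cols = batch_cols[b]
        sub = x[:, cols]
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        zero = (sd == 0).ravel()
        scale = np.where(sd == 0, 1.0, pooled_sd / np.where(sd == 0, 1.0, sd))
        scale[pooled_sd.ravel() == 0] = 1.0
        x[:, cols] = (sub - mu) * scale + grand_mean
        n_skipped += int(zero.sum())
    if n_skipped:
        logger.info("batch_correct: scale step skipped for %d gene/batch "
                    "combinations with zero variance", n_skipped)
    return replace(ds, values=pd.DataFrame(x, index=ds.values.index,
                                           columns=ds.values.columns))


def iqr_filter(ds: ExpressionDataset, percentile: float = 10.0) -> ExpressionDataset:
    """Drop genes whose interquartile range falls strictly below the given
    percentile of the per-gene IQR distribution (linear-interpolation
    quantiles)."""
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    if ds.n_genes < 10:
        raise ValueError("IQR filter needs >= 10 genes")
    x = ds.values.to_numpy(dtype=float)
    q75, q25 = np.percentile(x, [75, 25], axis=1)
    iqr = q75 - q25
    thresh = np.percentile(iqr, percentile)
    keep = iqr >= thresh
    logger.info("iqr_filter: removed %d of %d genes (IQR < %.4g)",
                int((~keep).sum()), ds.n_genes, thresh)
    return replace(ds, values=ds.values.loc[keep])


# ---------------------------------------------------------------------------
# differential expression

def _squeeze_variances(s2: np.ndarray, df: int) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-gene sample variances toward a
    common prior (scaled inverse chi-square), Smyth moment estimator.

    Returns (posterior variances, prior df d0); d0 = inf means complete
    pooling (variance distribution narrower than chi-square sampling noise).
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = np.var(e, ddof=1)
    target = e_var - special.polygamma(1, df / 2.0)
    if target <= 0:
        d0 = np.inf
        s0_sq = np.exp(e_mean)
        post = np.full_like(s2, s0_sq)
        return post, d0
    # invert trigamma(d0/2) = target by Newton iteration
    y = 0.5 + 1.0 / target
    for _ in range(50):
        tri = special.polygamma(1, y)
        delta = tri * (1.0 - tri / target) / special.polygamma(2, y)
        if not np.isfinite(delta):
            break
        y += delta
        if abs(delta) < 1e-10 * y:
            break
    d0 = 2.0 * y
    s0_sq = np.exp(e_mean + special.digamma(y) - np.log(y))
    post = (d0 * s0_sq + df * s2) / (d0 + df)
    return post, float(d0)


def differential_expression(
    ds: ExpressionDataset, method: str = "pooled_t"
) -> pd.DataFrame:
    """Per-gene two-sample test of case vs control.

    ``pooled_t``: equal-variance Student t, df = n1 + n2 - 2, two-sided.
    ``moderated_t``: same contrast but with per-gene variances shrunk toward
    an empirical-Bayes prior (df added accordingly) — appropriate for small
    cohorts where per-gene variance estimates are unstable.

    Returns a DataFrame indexed by gene with columns mean_case, mean_control,
    fold_change (case - control), t, pval, adj_pval, direction.
    """
    if method not in ("pooled_t", "moderated_t"):
        raise ValueError(f"unknown method {method!r}")
    case_cols = ds.class_columns(CASE)
    ctrl_cols = ds.class_columns(CONTROL)
    n1, n2 = len(case_cols), len(ctrl_cols)
    if n1 < 2 or n2 < 2:
        raise ValueError("each class needs >= 2 samples")
    xc = ds.values[case_cols].to_numpy(dtype=float)
    xk = ds.values[ctrl_cols].to_numpy(dtype=float)
    mean_case, mean_ctrl = xc.mean(axis=1), xk.mean(axis=1)
    diff = mean_case - mean_ctrl
    ss = xc.var(axis=1, ddof=1) * (n1 - 1) + xk.var(axis=1, ddof=1) * (n2 - 1)
    df = n1 + n2 - 2
    s2 = ss / df
    if method == "moderated_t":
        s2, d0 = _squeeze_variances(s2, df)
        total_df = df + (d0 if np.isfinite(d0) else 1e6)
    else:
        total_df = df
    se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    pval = np.where(
        se == 0,
        np.where(diff == 0, 1.0, np.finfo(float).tiny),
        2.0 * stats.t.sf(np.abs(np.where(se == 0, 0.0, t)), total_df),
    )
    t = np.where(se == 0,
                 np.where(diff == 0, 0.0, np.where(diff > 0, np.inf, -np.inf)),
                 t)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame({
        "mean_case": mean_case,
        "mean_control": mean_ctrl,
        "fold_change": diff,
        "t": t,
        "pval": pval,
        "adj_pval": bh_adjust(pval),
        "direction": np.where(diff >= 0, "up", "down"),
    }, index=ds.values.index)
    return out


def make_disease_signature(
    de: pd.DataFrame, name: str, mode: str = "adjusted", alpha: float = 0.01
) -> DiseaseSignature:
    """Threshold a DE table into ordered up/down gene lists.

    ``adjusted`` keeps genes with adj_pval < alpha; ``raw`` thresholds the
    unadjusted p-values instead (the fallback for small cohorts where no
    gene survives adjustment). Lists are ordered by increasing fold change.
    """
    if mode not in ("adjusted", "raw"):
        raise ValueError(f"unknown mode {mode!r}")
    col = "adj_pval" if mode == "adjusted" else "pval"
    hits = de[de[col] < alpha].sort_values("fold_change", kind="mergesort")
    up = hits.index[hits["direction"] == "up"].tolist()
    down = hits.index[hits["direction"] == "down"].tolist()
    if not up and not down:
        logger.warning("signature %r is empty at %s alpha=%g", name, mode, alpha)
    return DiseaseSignature(name, up, down, hits["fold_change"])


# ---------------------------------------------------------------------------
# I/O

def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Genes x samples TSV, first column gene id."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gct(path: str | Path) -> pd.DataFrame:
    """GCT 1.2: version line, dims line, then NAME/Description + samples."""
    df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
    return df.drop(columns=[df.columns[0]])  # Description column


def read_annotation(path: str | Path) -> tuple[pd.Series, pd.Series | None]:
    """Sample annotation TSV with columns sample, class[, batch]."""
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("sample")
    batch = df["batch"] if "batch" in df.columns else None
    return df["class"], batch


def load_expression_dataset(matrix_path, annotation_path,
                            log2: bool = True, collapse: bool = True) -> ExpressionDataset:
    mat = read_expression_tsv(matrix_path)
    cls, batch = read_annotation(annotation_path)
    ds = ExpressionDataset(mat, cls.reindex(mat.columns),
                           batch.reindex(mat.columns) if batch is not None else None)
    return preprocess_expression(ds, log2=log2, collapse=collapse)


def write_gmt(signatures: list[DiseaseSignature], path: str | Path) -> None:
    """Two sets per signature: NAME_UP and NAME_DN."""
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([f"{sig.name}_UP", "na", *sig.up_genes]) + "\n")
            fh.write("\t".join([f"{sig.name}_DN", "na", *sig.down_genes]) + "\n")


def write_rnk(de: pd.DataFrame, path: str | Path) -> None:
    """Ranked gene list (gene, fold change), increasing."""
    de["fold_change"].sort_values().to_csv(path, sep="\t", header=False)
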