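"""Differential-expression screening, Venn partition, clustering, concordance.

DEGs are screened per winter stage between the two graft combinations,
separately in rootstock and scion tissue, with the pass rule
|fold change| >= 1.5 and Benjamini-Hochberg FDR <= 0.05.  The fold
change is the ratio of pseudo-counted group means; the test is a
two-sided Welch t-test on log2(value + c).  The BH family is one
(tissue, stage) contrast.  Gene dynamics are clustered with k-means on
z-standardized stage-mean profiles.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_FC = 1.5
DEFAULT_FDR = 0.05


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, >= raw p)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def welch_t(a: np.ndarray, b: np.ndarray, axis: int = 1):
    """Two-sided Welch t-test along ``axis``; NaN p (zero variance, equal
    means) is reported as p = 1."""
    t, p = stats.ttest_ind(a, b, axis=axis, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    return t, p


def _groups(expr: ExpressionMatrix, tissue: str, stage: str, contrast) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    if contrast is None:
        contrast = expr.combinations[:2]
    ids_a = expr.sample_ids(combination=contrast[0], tissue=tissue, stage=stage)
    ids_b = expr.sample_ids(combination=contrast[1], tissue=tissue, stage=stage)
    for comb, ids in zip(contrast, (ids_a, ids_b)):
        if not ids:
            raise ValueError(f"no samples for (tissue={tissue}, stage={stage}, combination={comb})")
    a = expr.values[ids_a].to_numpy(float)
    b = expr.values[ids_b].to_numpy(float)
    keep = ~((a == 0).all(axis=1) & (b == 0).all(axis=1))
    return a[keep], b[keep], expr.genes[keep]


def test_differential_expression(
    expr: ExpressionMatrix,
    tissue: str,
    stage: str,
    contrast: tuple[str, str] | None = None,
    *,
    fc_threshold: float = DEFAULT_FC,
    fdr_threshold: float = DEFAULT_FDR,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene DE records for one (tissue, stage) contrast.

    Returns a DataFrame with columns gene_id, tissue, stage, log2fc,
    p, fdr, passed.  ``passed`` is |fold change| >= ``fc_threshold``
    (ratio scale, i.e. |log2fc| >= log2(fc_threshold)) and
    ``fdr <= fdr_threshold``.  Genes with all-zero values in both
    groups are excluded before testing.
    """
    a, b, genes = _groups(expr, tissue, stage, contrast)
    c = pseudocount
    log2fc = np.log2(a.mean(axis=1) + c) - np.log2(b.mean(axis=1) + c)
    _, p = welch_t(np.log2(a + c), np.log2(b + c))
    fdr = benjamini_hochberg(p)
    passed = (np.abs(log2fc) >= math.log2(fc_threshold)) & (fdr <= fdr_threshold)
    return pd.DataFrame(
        {"gene_id": genes, "tissue": tissue, "stage": stage,
         "log2fc": log2fc, "p": p, "fdr": fdr, "passed": passed}
    ).reset_index(drop=True)


def deg_screen(expr: ExpressionMatrix, contrast=None, **kwargs) -> pd.DataFrame:
    """DE records for every (tissue, stage) cell, concatenated."""
    sheet = expr.samples.loc[list(expr.values.columns)]
    tables = [
        test_differential_expression(expr, tissue, stage, contrast, **kwargs)
        for tissue in dict.fromkeys(sheet["tissue"])
        for stage in expr.stages
    ]
    return pd.concat(tables, ignore_index=True)


@dataclass(frozen=True)
class VennPartition:
    """Three-way partition of rootstock vs scion DEG sets."""

    rootstock_only: frozenset
    scion_only: frozenset
    shared: frozenset
    per_stage_counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        sets = (self.rootstock_only, self.scion_only, self.shared)
        for s, t in itertools.combinations(sets, 2):
            if s & t:
                raise ValueError("Venn partition sets must be pairwise disjoint")

    @property
    def union(self) -> frozenset:
        return self.rootstock_only | self.scion_only | self.shared


def filter_and_partition(rootstock_records: pd.DataFrame, scion_records: pd.DataFrame) -> VennPartition:
    """Union passing genes per tissue over stages, then partition.

    ``per_stage_counts`` reports how many genes pass per (tissue,
    stage) plus a pooled row per tissue.
    """
    def _union(records: pd.DataFrame) -> set:
        return set(records.loc[records["passed"], "gene_id"])

    rs, sc = _union(rootstock_records), _union(scion_records)
    counts = []
    for name, records in (("rootstock", rootstock_records), ("scion", scion_records)):
        for stage, grp in records.groupby("stage", sort=False):
            counts.append((name, stage, int(grp["passed"].sum())))
        counts.append((name, "pooled", len(_union(records))))
    table = pd.DataFrame(counts, columns=["tissue", "stage", "n_pass"])
    return VennPartition(
        rootstock_only=frozenset(rs - sc),
        scion_only=frozenset(sc - rs),
        shared=frozenset(rs & sc),
        per_stage_counts=table,
    )


@dataclass
class ClusterResult:
    assignments: pd.Series  # gene_id -> cluster index
    centroids: np.ndarray  # (k, n_cells) standardized profiles
    wcss: float
    profiles: pd.DataFrame  # the standardized profiles clustered


def cluster_dynamics(
    expr: ExpressionMatrix,
    genes,
    k: int,
    seed: int,
    *,
    tissue: str = "rootstock",
    n_init: int = 10,
) -> ClusterResult:
    """K-means on z-standardized (combination x stage) mean profiles.

    Profiles are per-gene stage means in ``tissue`` across both
    combinations (6 cells for a 2 x 3 design), standardized per gene.
    Deterministic given ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    means = expr.stage_means(genes)
    cells = means.loc[:, means.columns.get_level_values("tissue") == tissue]
    mat = cells.to_numpy(float)
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (mat - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    n_distinct = np.unique(z, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds number of distinct profiles ({n_distinct})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(z)
    profiles = pd.DataFrame(z, index=cells.index, columns=cells.columns)
    return ClusterResult(
        assignments=pd.Series(km.labels_, index=cells.index, name="cluster"),
        centroids=km.cluster_centers_,
        wcss=float(km.inertia_),
        profiles=profiles,
    )


@dataclass(frozen=True)
class ConcordanceResult:
    r: float
    r2: float
    p: float


def concordance(x, y) -> ConcordanceResult:
    """Pearson correlation between paired measurements (e.g. qPCR vs
    RPKM), with R^2 = r^2 and a two-sided t-distribution p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return ConcordanceResult(r=float(res.statistic), r2=float(res.statistic) ** 2, p=float(res.pvalue))


def filter_differential_metabolites(
    values: pd.DataFrame,
    samples: pd.DataFrame,
    contrast: tuple[str, str] | None = None,
    *,
    fc_threshold: float = DEFAULT_FC,
    p_threshold: float = 0.05,
    pseudocount: float = 1.0,
) -> tuple[dict[str, set], pd.DataFrame]:
    """Differentially accumulated metabolites per tissue, pooled over stages.

    Same machinery as the gene screen, but the pass rule gates on the
    raw p-value (p <= 0.05), without multiplicity adjustment.
    """
    expr = ExpressionMatrix(values, samples)
    sheet = samples.loc[list(values.columns)]
    records = []
    for tissue in dict.fromkeys(sheet["tissue"]):
        for stage in expr.stages:
            a, b, ids = _groups(expr, tissue, stage, contrast)
            c = pseudocount
            log2fc = np.log2(a.mean(axis=1) + c) - np.log2(b.mean(axis=1) + c)
            _, p = welch_t(np.log2(a + c), np.log2(b + c))
            passed = (np.abs(log2fc) >= math.log2(fc_threshold)) & (p <= p_threshold)
            records.append(pd.DataFrame(
                {"gene_id": ids, "tissue": tissue, "stage": stage,
                 "log2fc": log2fc, "p": p, "passed": passed}))
    table = pd.concat(records, ignore_index=True)
    pooled = {
        tissue: set(grp.loc[grp["passed"], "gene_id"])
        for tissue, grp in table.groupby("tissue", sort=False)
    }
    return pooled, table
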