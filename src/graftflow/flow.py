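"""Seasonal-flow inference: correlation screen and direction calls.

From a gene universe (by default the DEGs shared between rootstock and
scion), the screen keeps genes whose scion and rootstock 3-point stage
profiles are Pearson-correlated at r >= 0.7 within a graft combination;
kept genes then receive one movement call per stage: upward
(rootstock -> scion) when the rootstock stage mean exceeds the scion
mean, downward in the opposite case, and no call on an exact tie.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_R_MIN = 0.7


def rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between matching rows of two equal-shape matrices.

    Rows where either side has zero variance yield NaN.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a0 = a - a.mean(axis=1, keepdims=True)
    b0 = b - b.mean(axis=1, keepdims=True)
    num = (a0 * b0).sum(axis=1)
    den = np.sqrt((a0**2).sum(axis=1) * (b0**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, np.nan)
    return r


@dataclass
class ScreenResult:
    """Outcome of the scion/rootstock correlation screen."""

    table: pd.DataFrame  # gene_id, combination, r, kept
    kept: dict[str, set]  # combination -> kept gene set
    both: set
    only: dict[str, set]  # combination -> genes unique to it
    skipped: pd.DataFrame  # zero-variance profiles (gene_id, combination)

    @property
    def union(self) -> set:
        return set().union(*self.kept.values()) if self.kept else set()


def stage_profiles(expr: ExpressionMatrix, genes=None) -> pd.DataFrame:
    """Stage-mean profiles, columns (combination, tissue, stage)."""
    return expr.stage_means(genes)


def correlation_screen(
    expr: ExpressionMatrix,
    genes,
    r_min: float = DEFAULT_R_MIN,
    *,
    level: str = "stage_means",
) -> ScreenResult:
    """Keep genes whose scion and rootstock profiles correlate at r >= r_min.

    ``level='stage_means'`` (default) correlates the two 3-point stage
    mean profiles per combination; ``level='replicates'`` correlates
    replicate-matched sample values (3 x n_replicates points).  Genes
    with a zero-variance profile are skipped and logged, never kept.
    """
    genes = list(genes)
    rows = []
    skipped = []
    kept: dict[str, set] = {}
    sheet = expr.samples.loc[list(expr.values.columns)]
    combos = list(dict.fromkeys(sheet["combination"]))
    means = expr.stage_means(genes)
    for comb in combos:
        if level == "stage_means":
            sc = means[comb]["scion"][list(expr.stages)].to_numpy(float)
            rs = means[comb]["rootstock"][list(expr.stages)].to_numpy(float)
        elif level == "replicates":
            sc_cols, rs_cols = [], []
            for stage in expr.stages:
                sc_ids = expr.sample_ids(comb, "scion", stage)
                rs_ids = expr.sample_ids(comb, "rootstock", stage)
                n = min(len(sc_ids), len(rs_ids))
                sc_cols += sc_ids[:n]
                rs_cols += rs_ids[:n]
            sc = expr.values.loc[genes, sc_cols].to_numpy(float)
            rs = expr.values.loc[genes, rs_cols].to_numpy(float)
        else:
            raise ValueError("level must be 'stage_means' or 'replicates'")
        r = rowwise_pearson(sc, rs)
        keep = np.zeros(len(genes), bool)
        for i, gene in enumerate(genes):
            if np.isnan(r[i]):
                skipped.append((gene, comb))
                continue
            keep[i] = r[i] >= r_min
            rows.append((gene, comb, float(r[i]), bool(keep[i])))
        kept[comb] = {g for g, k in zip(genes, keep) if k}
    if skipped:
        logger.warning("skipped %d zero-variance profiles in correlation screen", len(skipped))
    both = set.intersection(*kept.values()) if kept else set()
    only = {c: kept[c] - set().union(*(kept[o] for o in combos if o != c)) for c in combos}
    return ScreenResult(
        table=pd.DataFrame(rows, columns=["gene_id", "combination", "r", "kept"]),
        kept=kept,
        both=both,
        only=only,
        skipped=pd.DataFrame(skipped, columns=["gene_id", "combination"]),
    )


def classify_flow(screen: ScreenResult, expr: ExpressionMatrix) -> pd.DataFrame:
    """One movement call per (kept gene, combination, stage).

    upward  <=> rootstock stage mean > scion stage mean;
    downward <=> scion mean > rootstock mean.
    Exact ties produce no call (counted in ``.attrs['n_ties']``).
    A missing stage mean raises, naming the gene and stage.
    """
    means = expr.stage_means()
    r_of = screen.table.set_index(["gene_id", "combination"])["r"]
    rows = []
    n_ties = 0
    for comb, genes in screen.kept.items():
        for gene in sorted(genes):
            for stage in expr.stages:
                rs = means.at[gene, (comb, "rootstock", stage)]
                sc = means.at[gene, (comb, "scion", stage)]
                if np.isnan(rs) or np.isnan(sc):
                    raise ValueError(f"missing stage mean for gene {gene} at stage {stage}")
                if rs > sc:
                    direction = "upward"
                elif sc > rs:
                    direction = "downward"
                else:
                    n_ties += 1
                    continue
                rows.append((gene, comb, stage, float(r_of.loc[(gene, comb)]),
                             direction, float(rs), float(sc)))
    if n_ties:
        logger.warning("%d exact scion/rootstock ties produced no flow call", n_ties)
    calls = pd.DataFrame(
        rows, columns=["gene_id", "combination", "stage", "r",
                       "direction", "rootstock_mean", "scion_mean"])
    calls.attrs["n_ties"] = n_ties
    return calls


def nonredundant_mobile_union(
    calls: pd.DataFrame,
    combinations=None,
    stages=None,
) -> tuple[set, pd.DataFrame]:
    """Union of called genes plus a per-(combination, stage) count table.

    The table has columns upward, downward, total with
    total = upward + downward on every row.
    """
    union = set(calls["gene_id"]) if len(calls) else set()
    combos = list(combinations) if combinations is not None else \
        list(dict.fromkeys(calls["combination"])) if len(calls) else []
    stage_list = list(stages) if stages is not None else \
        list(dict.fromkeys(calls["stage"])) if len(calls) else []
    rows = []
    for comb in combos:
        for stage in stage_list:
            sub = calls[(calls["combination"] == comb) & (calls["stage"] == stage)] \
                if len(calls) else calls
            up = int((sub["direction"] == "upward").sum()) if len(calls) else 0
            down = int((sub["direction"] == "downward").sum()) if len(calls) else 0
            rows.append((comb, stage, up, down, up + down))
    table = pd.DataFrame(rows, columns=["combination", "stage", "upward", "downward", "total"])
    return union, table
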