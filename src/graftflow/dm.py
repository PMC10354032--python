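"""Degree-of-mobility statistic for bidirectional stem transport.

For relative-expression series measured above (a) and below (b) a
reference position (a graft junction or an infiltrated leaf), with T1
the pre-treatment reference timepoint:

    S_{a/b} = [RE_{a/b}(Tn) - RE_{a/b}(T1)] / RE_{a/b}(T1)
    DM      = (S_b - S_a) / |S_a + S_b|

DM > 0 is read as upward movement and DM < 0 as downward (the stated
convention: a larger relative change below the junction signals upward
transport).  DM is unbounded and is never clamped.  Zero denominators
(including the S_a = S_b = 0 no-change case) make the statistic
undefined; table-level functions report these as missing values with a
reason code, never as 0.

The same statistic applies to RNA-seq stage means by treating the
scion as the "above" series, the rootstock as "below", and a reference
stage (CA by default) as T1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix


class UndefinedStatisticError(ValueError):
    """The DM statistic (or a relative change) is undefined for this input."""


def relative_change(series, tn, t1=None) -> float:
    """S = (RE(Tn) - RE(T1)) / RE(T1) for one position's series.

    ``series`` maps timepoint labels to positive RE values (mapping or
    pandas Series); ``t1`` defaults to the first timepoint.
    """
    s = pd.Series(series, dtype=float)
    if t1 is None:
        t1 = s.index[0]
    if tn not in s.index or t1 not in s.index:
        raise ValueError(f"timepoint {tn if tn not in s.index else t1} not in series")
    re1 = float(s[t1])
    if re1 == 0:
        raise UndefinedStatisticError("RE(T1) = 0: relative change undefined")
    return (float(s[tn]) - re1) / re1


@dataclass(frozen=True)
class DMResult:
    s_a: float
    s_b: float
    dm: float
    direction: str  # upward | downward | none


def dm_stem(s_a: float, s_b: float) -> DMResult:
    """DM = (S_b - S_a)/|S_a + S_b|; raises when S_a + S_b = 0."""
    denom = abs(s_a + s_b)
    if denom == 0:
        raise UndefinedStatisticError("S_a + S_b = 0: DM undefined")
    dm = (s_b - s_a) / denom
    direction = "upward" if dm > 0 else "downward" if dm < 0 else "none"
    return DMResult(s_a=float(s_a), s_b=float(s_b), dm=float(dm), direction=direction)


def dm_from_qpcr(qpcr: pd.DataFrame) -> pd.DataFrame:
    """DM per series and post-reference timepoint from a long qPCR table.

    Expects columns series_id, position ('above'|'below'), timepoint,
    RE.  The first timepoint of each series is the reference T1.
    Undefined entries carry NaN with a status reason.
    """
    rows = []
    for sid, grp in qpcr.groupby("series_id", sort=False):
        above = grp[grp["position"] == "above"].set_index("timepoint")["RE"]
        below = grp[grp["position"] == "below"].set_index("timepoint")["RE"]
        timepoints = [t for t in dict.fromkeys(grp["timepoint"])]
        t1 = timepoints[0]
        for tn in timepoints[1:]:
            try:
                s_a = relative_change(above, tn, t1)
                s_b = relative_change(below, tn, t1)
            except UndefinedStatisticError:
                rows.append((sid, tn, np.nan, np.nan, np.nan, "none", "undefined_reference_zero"))
                continue
            try:
                res = dm_stem(s_a, s_b)
                rows.append((sid, tn, s_a, s_b, res.dm, res.direction, "ok"))
            except UndefinedStatisticError:
                rows.append((sid, tn, s_a, s_b, np.nan, "none", "undefined_zero_denominator"))
    return pd.DataFrame(rows, columns=["series_id", "timepoint", "S_a", "S_b", "DM", "direction", "status"])


def dm_from_expression(
    expr: ExpressionMatrix,
    gene: str,
    combination: str,
    *,
    reference_stage: str | None = None,
    above_tissue: str = "scion",
    below_tissue: str = "rootstock",
) -> pd.DataFrame:
    """DM per non-reference stage from RPKM stage means of one gene.

    The reference stage (default: the first stage, CA) plays T1; the
    ``above_tissue`` stage means play RE_a and ``below_tissue`` RE_b.
    A zero reference-stage mean raises (the statistic is undefined for
    the gene); zero-denominator stages are rows with NaN and a status.
    """
    means = expr.stage_means([gene])
    ref = reference_stage or expr.stages[0]
    if ref not in expr.stages:
        raise ValueError(f"unknown reference stage {ref}")
    series = {}
    for label, tissue in (("a", above_tissue), ("b", below_tissue)):
        vals = {stage: float(means.at[gene, (combination, tissue, stage)]) for stage in expr.stages}
        if vals[ref] == 0:
            raise UndefinedStatisticError(
                f"reference-stage ({ref}) mean is 0 for gene {gene} in {tissue}")
        series[label] = pd.Series(vals)
    rows = []
    for stage in expr.stages:
        if stage == ref:
            continue
        s_a = relative_change(series["a"], stage, ref)
        s_b = relative_change(series["b"], stage, ref)
        try:
            res = dm_stem(s_a, s_b)
            rows.append((gene, combination, stage, s_a, s_b, res.dm, res.direction, "ok"))
        except UndefinedStatisticError:
            rows.append((gene, combination, stage, s_a, s_b, np.nan, "none",
                         "undefined_zero_denominator"))
    return pd.DataFrame(rows, columns=["gene_id", "combination", "stage",
                                       "S_a", "S_b", "DM", "direction", "status"])
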