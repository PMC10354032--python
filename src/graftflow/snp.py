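"""SNP-based validation of transcript translocation across the graft.

Rootstock-genotype-specific variant sites (alt allele present in the
rootstock genotype under coverage/count/frequency gates, absent in the
scion genotype) are searched for in scion RNA reads.  Per gene,
combination and stage, pooled alt reads constitute translocation
evidence when they clear a minimum-read threshold and a one-sided
binomial test against the sequencing-error rate.  The mobility score of
a gene counts the stages (0-3) at which such evidence is concordant
with an upward seasonal-flow call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SNPCallingParams:
    """Gates for genotype-specific SNP calling and translocation evidence.

    ``min_coverage``/``min_count``/``min_frequency`` implement the
    coverage 10 / count 10 / frequency 20% presence rule; an allele is
    "present" in a genotype iff site depth >= min_coverage, allele
    reads >= min_count and allele frequency >= min_frequency.
    ``homozygous_only`` additionally requires alt frequency >=
    ``hom_frequency`` in the rootstock genotype (the analysis is
    restricted to homozygous rootstock SNPs by default).
    """

    min_coverage: int = 10
    min_count: int = 10
    min_frequency: float = 0.20
    min_alt_reads_translocation: int = 2
    error_rate: float = 0.001
    homozygous_only: bool = True
    hom_frequency: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 < self.min_frequency <= 1.0:
            raise ValueError("min_frequency must lie in (0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")
        if self.min_coverage < 1 or self.min_count < 0:
            raise ValueError("coverage/count gates must be positive")


def _present(allele_count: np.ndarray, depth: np.ndarray, params: SNPCallingParams) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(depth > 0, allele_count / np.maximum(depth, 1), 0.0)
    return (depth >= params.min_coverage) & (allele_count >= params.min_count) & (freq >= params.min_frequency)


def call_genotype_specific_snps(
    variants: pd.DataFrame,
    scion_genotype: str,
    rootstock_genotypes,
    params: SNPCallingParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Flag sites whose alt allele is specific to a rootstock genotype.

    ``variants`` needs ``AD_ref_<genotype>`` / ``AD_alt_<genotype>``
    columns for the scion genotype and every rootstock genotype.  Sites
    with zero depth in any required genotype are excluded and counted
    in the returned QC report.  Adds one boolean column
    ``specific_<rootstock>`` per rootstock genotype.
    """
    params = params or SNPCallingParams()
    required = [scion_genotype, *rootstock_genotypes]
    depths = {}
    for g in required:
        try:
            ref = variants[f"AD_ref_{g}"].to_numpy(float)
            alt = variants[f"AD_alt_{g}"].to_numpy(float)
        except KeyError as exc:
            raise ValueError(f"allele depths missing for genotype {g}") from exc
        depths[g] = (ref, alt, ref + alt)

    usable = np.ones(len(variants), bool)
    for g in required:
        usable &= depths[g][2] > 0
    n_excluded = int((~usable).sum())

    out = variants.loc[usable].copy()
    qc = {"n_sites_in": int(len(variants)), "n_zero_depth_excluded": n_excluded}
    sc_ref, sc_alt, sc_dp = (d[usable] for d in depths[scion_genotype])
    scion_alt_present = _present(sc_alt, sc_dp, params)
    scion_ref_present = _present(sc_ref, sc_dp, params)
    for g in rootstock_genotypes:
        rs_ref, rs_alt, rs_dp = (d[usable] for d in depths[g])
        alt_present = _present(rs_alt, rs_dp, params)
        specific = alt_present & ~scion_alt_present & scion_ref_present
        if params.homozygous_only:
            with np.errstate(invalid="ignore", divide="ignore"):
                alt_freq = np.where(rs_dp > 0, rs_alt / np.maximum(rs_dp, 1), 0.0)
            specific &= alt_freq >= params.hom_frequency
        out[f"specific_{g}"] = specific
        qc[f"n_specific_{g}"] = int(specific.sum())
    return out, qc


def detect_translocation(
    allele_counts: pd.DataFrame,
    specific_sites: pd.DataFrame,
    params: SNPCallingParams,
    rootstock_of: dict[str, str],
    genes=None,
) -> tuple[pd.DataFrame, list]:
    """Evidence for rootstock transcripts in scion RNA, per gene/stage.

    Alt and total reads are summed over a gene's specific sites and all
    scion replicates of a (combination, stage) cell.  Evidence requires
    alt >= ``min_alt_reads_translocation`` and a one-sided binomial
    tail P(X >= alt | n=total, p=error_rate) < 0.05.  Queried genes
    without any specific site are returned as unassessable, never as
    negative evidence.
    """
    frames = []
    for comb, g in rootstock_of.items():
        col = f"specific_{g}"
        if col not in specific_sites.columns:
            raise ValueError(f"specific-site table lacks column {col}")
        sites = specific_sites.loc[specific_sites[col], ["chrom", "pos"]]
        sub = allele_counts[allele_counts["combination"] == comb].merge(
            sites, on=["chrom", "pos"], how="inner")
        frames.append(sub)
    pooled = pd.concat(frames, ignore_index=True) if frames else allele_counts.iloc[0:0]

    rows = []
    if len(pooled):
        grouped = pooled.groupby(["gene_id", "combination", "stage"], sort=False)
        for (gene, comb, stage), grp in grouped:
            alt = int(grp["alt_count"].sum())
            total = int((grp["alt_count"] + grp["ref_count"]).sum())
            if total > 0 and params.error_rate > 0:
                p = float(stats.binom.sf(alt - 1, total, params.error_rate)) if alt > 0 else 1.0
            else:
                # error-free model: any alt read is impossible by chance
                p = 0.0 if alt > 0 else 1.0
            evidence = alt >= params.min_alt_reads_translocation and p < 0.05
            rows.append((gene, comb, stage, alt, total, p, evidence))
    evidence_table = pd.DataFrame(
        rows, columns=["gene_id", "combination", "stage",
                       "alt_reads", "total_reads", "p", "evidence"])
    assessable = set(evidence_table["gene_id"]) if len(evidence_table) else set()
    unassessable = sorted(set(genes) - assessable) if genes is not None else []
    if unassessable:
        logger.info("%d genes have no specific sites and are unassessable", len(unassessable))
    return evidence_table, unassessable


def score_mobility(
    evidence: pd.DataFrame,
    flow_calls: pd.DataFrame,
    *,
    concordant_direction: str = "upward",
) -> pd.DataFrame:
    """Stage-concordance mobility score per (gene, combination).

    Score = number of stages (max 3) with translocation evidence AND a
    flow call in ``concordant_direction`` (upward by default: SNP
    translocation into the scion can only support rootstock -> scion
    movement; pass 'downward' together with rootstock-side evidence for
    the symmetric mode).  Output includes per-stage concordance flags,
    the integer score, and ``validated`` (score >= 1) /
    ``high_consistency`` (score == 3) flags.
    """
    flow_key = flow_calls.set_index(["gene_id", "combination", "stage"])["direction"]
    stages = list(dict.fromkeys(evidence["stage"])) if len(evidence) else []
    rows = []
    if len(evidence):
        for (gene, comb), grp in evidence.groupby(["gene_id", "combination"], sort=False):
            flags = {}
            for stage in stages:
                ev = grp.loc[grp["stage"] == stage, "evidence"]
                has_ev = bool(ev.any())
                direction = flow_key.get((gene, comb, stage))
                flags[stage] = has_ev and direction == concordant_direction
            score = sum(flags.values())
            rows.append((gene, comb, *[flags[s] for s in stages], score))
    table = pd.DataFrame(
        rows, columns=["gene_id", "combination", *[f"concordant_{s}" for s in stages], "score"])
    if len(table):
        table["validated"] = table["score"] >= 1
        table["high_consistency"] = table["score"] == 3
    else:
        table["validated"] = pd.Series(dtype=bool)
        table["high_consistency"] = pd.Series(dtype=bool)
    return table
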