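"""Synthetic grafted-transcriptome generator with known ground truth.

Emulates the statistical structure of a scion/rootstock grafting study
sampled at three winter stages (cold acclimation CA, deep winter DW,
de-acclimation DA) in two graft combinations that share the scion
cultivar but differ in rootstock:

* genotype variant tables with a configurable heterozygous-site
  fraction (~1.2% in apple cultivars) plus "informative" sites that are
  homozygous-alt in one rootstock genotype and homozygous-ref in the
  scion genotype;
* an RPKM-like expression matrix (2 combinations x 2 tissues x 3 stages
  x n replicates) in which planted mobile genes have scion and
  rootstock stage profiles driven by one shared latent trajectory (so
  their Pearson correlation tends to 1 as replicate dispersion tends to
  0) with the source tissue strictly more abundant;
* scion RNA allele counts at informative sites, with the rootstock
  haplotype appearing at the planted translocation fraction for genes
  that are upwardly mobile at that stage and at the sequencing-error
  rate otherwise;
* qPCR-style relative-expression series above/below a junction with a
  plantable degree-of-mobility value.

Every draw comes from numpy Generators derived deterministically from
``SimulationParams.seed``, so identical parameters give identical
outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

# fixed sub-stream ids so each generator is reproducible in isolation
_STREAMS = {"variants": 0, "expression": 1, "counts": 2, "qpcr": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class SimulationParams:
    """Study-design and noise parameters for the simulator.

    The defaults mirror the grafting design the pipeline targets:
    2 graft combinations x 2 tissues x 3 winter stages x 4 replicates
    (48 samples) and ~1.2% genotype heterozygosity.
    """

    n_genes: int = 2000
    n_replicates: int = 4
    stages: tuple[str, ...] = ("CA", "DW", "DA")
    combinations: tuple[str, str] = ("Gala-G202", "Gala-M9")
    scion_genotype: str = "Gala"
    rootstock_genotypes: tuple[str, str] = ("G202", "M9")
    heterozygosity: float = 0.012
    n_mobile: int = 100
    mobile_direction_mix: float = 0.5  # fraction of mobile genes moving upward
    translocation_fraction: float = 0.3
    dispersion: float = 0.15  # sd of log-normal multiplicative replicate noise
    fold_range: tuple[float, float] = (2.0, 4.0)
    n_deg_shared_nonmobile: int = 50
    n_deg_rootstock_only: int = 300
    n_deg_scion_only: int = 50
    genome_length: int = 200_000
    informative_sites_per_gene: int = 3
    error_rate: float = 0.001  # sequencing-error alt-read rate
    coverage_mean: float = 50.0  # scion RNA coverage at informative sites
    coverage_dist: str = "poisson"  # "poisson" | "fixed"
    dna_coverage_mean: float = 40.0
    stage_sigma: float = 0.6  # log-scale spread of seasonal stage effects
    mobile_source_fold: float = 2.0  # source-tissue excess for mobile genes
    tissue_shared_profiles: bool = False  # share null stage profiles across tissues
    n_timepoints: int = 4  # qPCR series length (T1 = pre-treatment)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_replicates <= 0:
            raise ValueError("n_genes and n_replicates must be positive")
        if len(self.stages) != 3:
            raise ValueError("exactly three winter stages are expected")
        if len(self.combinations) != 2 or len(self.rootstock_genotypes) != 2:
            raise ValueError("two graft combinations / rootstock genotypes required")
        for name in ("heterozygosity", "mobile_direction_mix", "translocation_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_mobile > self.n_genes:
            raise ValueError("n_mobile cannot exceed n_genes")
        planted = (
            self.n_mobile
            + self.n_deg_shared_nonmobile
            + self.n_deg_rootstock_only
            + self.n_deg_scion_only
        )
        if planted > self.n_genes:
            raise ValueError("planted gene classes exceed n_genes")
        if self.dispersion < 0 or self.stage_sigma < 0:
            raise ValueError("dispersion parameters must be non-negative")
        if self.coverage_dist not in ("poisson", "fixed"):
            raise ValueError("coverage_dist must be 'poisson' or 'fixed'")

    @property
    def rootstock_of(self) -> dict[str, str]:
        """Map graft combination -> its rootstock genotype."""
        return dict(zip(self.combinations, self.rootstock_genotypes))

    @property
    def genotypes(self) -> tuple[str, ...]:
        return (self.scion_genotype, *self.rootstock_genotypes)


def gene_ids(params: SimulationParams) -> list[str]:
    return [f"Mdg{i:05d}" for i in range(params.n_genes)]


# ----------------------------------------------------------------------
# genotype variants
# ----------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def generate_genotype_variants(params: SimulationParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate biallelic DNA variants for the three genotypes.

    The genome surrogate is ``genome_length`` positions on one contig,
    partitioned into equal-length gene intervals.  Each genotype gets a
    Binomial(L, heterozygosity) number of heterozygous sites; in
    addition each gene carries ``informative_sites_per_gene`` sites per
    rootstock genotype that are homozygous-alt in that rootstock and
    homozygous-ref in the scion (the sites that can betray transcript
    translocation).  With ``heterozygosity=0`` the genome is invariant
    and no sites (informative or otherwise) are emitted.

    Returns
    -------
    variants : DataFrame
        One row per site: chrom, pos (1-based), ref, alt, gene_id,
        ``GT_<genotype>`` calls and simulated ``AD_ref_<genotype>`` /
        ``AD_alt_<genotype>`` sequencing depths, plus an
        ``informative_for`` column naming the rootstock genotype a site
        is diagnostic for ('' otherwise).
    gene_map : DataFrame
        SNP-to-gene map (chrom, pos, gene_id) for all emitted sites.
    """
    rng = _rng(params.seed, "variants")
    genes = gene_ids(params)
    L = params.genome_length
    gene_len = L // params.n_genes
    if gene_len < 1:
        raise ValueError("genome_length smaller than n_genes")
    L_used = gene_len * params.n_genes

    cols = ["chrom", "pos", "ref", "alt", "gene_id", "informative_for"]
    for g in params.genotypes:
        cols += [f"GT_{g}", f"AD_ref_{g}", f"AD_alt_{g}"]
    empty = pd.DataFrame(columns=cols)
    if params.heterozygosity == 0.0:
        return empty, empty[["chrom", "pos", "gene_id"]].copy()

    n_info = params.informative_sites_per_gene
    expected = 3 * params.heterozygosity * L_used + 2 * n_info * params.n_genes
    if expected > 0.5 * L_used or gene_len < 2 * n_info + 2:
        raise ValueError(
            f"genome_length={L} too small to realize heterozygosity="
            f"{params.heterozygosity} with {n_info} informative sites per gene"
        )

    het_sets: dict[str, np.ndarray] = {}
    for g in params.genotypes:
        n_het = rng.binomial(L_used, params.heterozygosity)
        het_sets[g] = rng.choice(L_used, size=n_het, replace=False) + 1

    used = set()
    for pos in het_sets.values():
        used.update(pos.tolist())

    # informative sites: per gene, n_info for each rootstock genotype
    info_pos: dict[str, list[int]] = {g: [] for g in params.rootstock_genotypes}
    for i in range(params.n_genes):
        lo = i * gene_len + 1
        candidates = [p for p in range(lo, lo + gene_len) if p not in used]
        need = 2 * n_info
        if len(candidates) < need:
            raise ValueError(f"gene interval {i} too dense to place informative sites")
        picked = rng.choice(len(candidates), size=need, replace=False)
        picked_pos = [candidates[j] for j in picked]
        used.update(picked_pos)
        info_pos[params.rootstock_genotypes[0]].extend(picked_pos[:n_info])
        info_pos[params.rootstock_genotypes[1]].extend(picked_pos[n_info:])

    all_pos = np.array(sorted(used), dtype=int)
    n_sites = all_pos.size
    ref_idx = rng.integers(0, 4, n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, n_sites)) % 4

    het_lookup = {g: set(v.tolist()) for g, v in het_sets.items()}
    info_lookup = {g: set(v) for g, v in info_pos.items()}
    informative_for = np.full(n_sites, "", dtype=object)
    gt: dict[str, np.ndarray] = {}
    for g in params.genotypes:
        calls = np.full(n_sites, "0/0", dtype=object)
        in_het = np.fromiter((p in het_lookup[g] for p in all_pos), bool, n_sites)
        calls[in_het] = "0/1"
        gt[g] = calls
    for g in params.rootstock_genotypes:
        in_info = np.fromiter((p in info_lookup[g] for p in all_pos), bool, n_sites)
        gt[g][in_info] = "1/1"
        gt[params.scion_genotype][in_info] = "0/0"
        informative_for[in_info] = g

    variants = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": all_pos,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "gene_id": [genes[(p - 1) // gene_len] for p in all_pos],
            "informative_for": informative_for,
        }
    )
    # per-genotype DNA sequencing depths consistent with the calls
    for g in params.genotypes:
        cov = rng.poisson(params.dna_coverage_mean, n_sites)
        alt_p = np.select(
            [gt[g] == "0/0", gt[g] == "0/1", gt[g] == "1/1"],
            [params.error_rate, 0.5, 1.0 - params.error_rate],
        )
        alt = rng.binomial(cov, alt_p)
        variants[f"GT_{g}"] = gt[g]
        variants[f"AD_ref_{g}"] = cov - alt
        variants[f"AD_alt_{g}"] = alt

    gene_map = variants[["chrom", "pos", "gene_id"]].copy()
    return variants, gene_map


# ----------------------------------------------------------------------
# expression matrix + truth table
# ----------------------------------------------------------------------

def sample_id(combination: str, tissue: str, stage: str, replicate: int) -> str:
    return f"{combination}_{tissue}_{stage}_R{replicate}"


def generate_expression_dataset(params: SimulationParams) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate the RPKM-like matrix and its ground-truth table.

    Baseline abundances are log-normal; replicate noise is multiplicative
    log-normal with sd ``dispersion``.  Planted mobile genes share one
    latent 3-point stage trajectory between scion and rootstock (per
    gene), with the source tissue boosted by ``mobile_source_fold``;
    planted DEGs differ between combinations by a factor drawn from
    ``fold_range``.  Non-mobile genes get independent per-tissue stage
    trajectories (shared across combinations) unless
    ``tissue_shared_profiles`` is set.
    """
    if params.n_replicates < 2:
        raise ValueError("n_replicates must be >= 2 for differential testing")
    rng = _rng(params.seed, "expression")
    G = params.n_genes
    combos = params.combinations
    tissues = ("scion", "rootstock")
    S = len(params.stages)
    R = params.n_replicates

    # gene role assignment
    order = rng.permutation(G)
    k = 0
    mobile = order[k : k + params.n_mobile]; k += params.n_mobile
    shared_nm = order[k : k + params.n_deg_shared_nonmobile]; k += params.n_deg_shared_nonmobile
    rs_only = order[k : k + params.n_deg_rootstock_only]; k += params.n_deg_rootstock_only
    sc_only = order[k : k + params.n_deg_scion_only]

    upward = rng.random(params.n_mobile) < params.mobile_direction_mix

    logb = np.log(rng.lognormal(mean=3.0, sigma=1.2, size=G))
    traj = rng.normal(0.0, params.stage_sigma, (G, 2, S))  # per gene x tissue
    if params.tissue_shared_profiles:
        traj[:, 1, :] = traj[:, 0, :]
    log_mu = logb[:, None, None, None] + traj[:, None, :, :]  # (G, C, T, S)
    log_mu = np.broadcast_to(log_mu, (G, 2, 2, S)).copy()

    # mobile genes: one latent trajectory shared across tissues & combinations
    lat = rng.normal(0.0, params.stage_sigma, (params.n_mobile, S))
    log_mu[mobile] = logb[mobile, None, None, None] + lat[:, None, None, :]
    boost = math.log(params.mobile_source_fold)
    log_mu[mobile[upward], :, 1, :] += boost  # rootstock is the source
    log_mu[mobile[~upward], :, 0, :] += boost  # scion is the source

    def _comb_shift(idx: np.ndarray, tissue_slice) -> None:
        if idx.size == 0:
            return
        folds = rng.uniform(*params.fold_range, idx.size)
        signs = rng.choice([-1.0, 1.0], idx.size)
        log_mu[idx, 1, tissue_slice, :] += (signs * np.log(folds))[:, None, None] \
            if isinstance(tissue_slice, slice) else (signs * np.log(folds))[:, None]

    _comb_shift(mobile, slice(None))       # DEG in both tissues, same shift
    _comb_shift(shared_nm, slice(None))
    _comb_shift(rs_only, 1)
    _comb_shift(sc_only, 0)

    noise = np.exp(rng.normal(0.0, params.dispersion, (G, 2, 2, S, R))) \
        if params.dispersion > 0 else np.ones((G, 2, 2, S, R))
    values = np.exp(log_mu)[..., None] * noise

    columns, records = [], []
    for ci, comb in enumerate(combos):
        for ti, tissue in enumerate(tissues):
            for si, stage in enumerate(params.stages):
                for r in range(1, R + 1):
                    columns.append(sample_id(comb, tissue, stage, r))
                    records.append((comb, tissue, stage, r))
    flat = values.reshape(G, -1)
    genes = gene_ids(params)
    frame = pd.DataFrame(flat, index=pd.Index(genes, name="gene_id"), columns=columns)
    sheet = pd.DataFrame(records, index=columns, columns=["combination", "tissue", "stage", "replicate"])
    sheet.index.name = "sample_id"

    is_mobile = np.zeros(G, bool)
    is_mobile[mobile] = True
    direction = np.full(G, "none", dtype=object)
    direction[mobile[upward]] = "upward"
    direction[mobile[~upward]] = "downward"
    source = np.full(G, "", dtype=object)
    source[mobile[upward]] = "rootstock"
    source[mobile[~upward]] = "scion"
    deg_rs = np.zeros(G, bool); deg_rs[np.concatenate([mobile, shared_nm, rs_only])] = True
    deg_sc = np.zeros(G, bool); deg_sc[np.concatenate([mobile, shared_nm, sc_only])] = True
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "is_mobile": is_mobile,
            "source_tissue": source,
            "translocation_fraction": np.where(is_mobile, params.translocation_fraction, 0.0),
            "deg_rootstock": deg_rs,
            "deg_scion": deg_sc,
        }
    )
    for stage in params.stages:
        truth[f"direction_{stage}"] = direction
    expr = ExpressionMatrix(frame, sheet, stages=tuple(params.stages))
    return expr, truth


# ----------------------------------------------------------------------
# scion RNA allele counts
# ----------------------------------------------------------------------

def generate_scion_allele_counts(
    truth: pd.DataFrame,
    variants: pd.DataFrame,
    params: SimulationParams,
) -> pd.DataFrame:
    """Simulate ref/alt read counts in scion RNA at informative sites.

    For each scion sample and informative site of the matching rootstock
    genotype, coverage is drawn from the configured distribution (mean
    ``coverage_mean``) and the alt-read proportion is the gene's
    translocation fraction when the gene is upwardly mobile at that
    stage, and the sequencing-error rate otherwise.  Sites without a
    gene assignment are skipped (counted and logged).
    """
    rng = _rng(params.seed, "counts")
    truth_idx = truth.set_index("gene_id")
    rows = []
    n_unmapped = 0
    for comb in params.combinations:
        g = params.rootstock_of[comb]
        sites = variants[variants["informative_for"] == g]
        for _, site in sites.iterrows():
            gene = site["gene_id"]
            if not gene or gene not in truth_idx.index:
                n_unmapped += 1
                continue
            tf = truth_idx.at[gene, "translocation_fraction"]
            for stage in params.stages:
                up = truth_idx.at[gene, f"direction_{stage}"] == "upward"
                p = tf if up else params.error_rate
                for r in range(1, params.n_replicates + 1):
                    if params.coverage_dist == "fixed":
                        cov = int(round(params.coverage_mean))
                    else:
                        cov = int(rng.poisson(params.coverage_mean))
                    alt = int(rng.binomial(cov, p)) if cov > 0 else 0
                    rows.append(
                        (
                            site["chrom"], int(site["pos"]),
                            sample_id(comb, "scion", stage, r),
                            comb, stage, r, gene, cov - alt, alt,
                        )
                    )
    if n_unmapped:
        logger.warning("skipped %d informative sites without a gene assignment", n_unmapped)
    counts = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "sample_id", "combination", "stage", "replicate",
                 "gene_id", "ref_count", "alt_count"],
    )
    counts.attrs["n_unmapped_skipped"] = n_unmapped
    return counts


# ----------------------------------------------------------------------
# qPCR-style relative-expression series
# ----------------------------------------------------------------------

def generate_qpcr_timeseries(
    params: SimulationParams,
    *,
    baseline_above: float = 1.0,
    baseline_below: float = 1.0,
    slopes_above=None,
    slopes_below=None,
    series_id: str = "sim",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two positive relative-expression series (above/below) over T1..Tn.

    ``slopes_*`` are the planted relative changes S(Tn) per post-reference
    timepoint; when omitted they are drawn uniformly from (-0.8, 3.0).
    The planted degree-of-mobility DM = (S_b - S_a)/|S_a + S_b| is
    recorded per timepoint in the returned truth frame (NaN with status
    when the denominator vanishes).
    """
    n = params.n_timepoints
    if n < 2:
        raise ValueError("at least two timepoints are required")
    if baseline_above <= 0 or baseline_below <= 0:
        raise ValueError("RE(T1) must be positive; the statistic is undefined otherwise")
    rng = _rng(params.seed, "qpcr")
    if slopes_above is None:
        slopes_above = rng.uniform(-0.8, 3.0, n - 1)
    if slopes_below is None:
        slopes_below = rng.uniform(-0.8, 3.0, n - 1)
    slopes_above = np.asarray(slopes_above, float)
    slopes_below = np.asarray(slopes_below, float)
    if slopes_above.size != n - 1 or slopes_below.size != n - 1:
        raise ValueError("need one slope per post-reference timepoint")
    if (slopes_above <= -1).any() or (slopes_below <= -1).any():
        raise ValueError("slopes must exceed -1 to keep RE positive")

    timepoints = [f"T{i}" for i in range(1, n + 1)]
    rows = [(series_id, "above", "T1", baseline_above), (series_id, "below", "T1", baseline_below)]
    truth_rows = []
    for i, tp in enumerate(timepoints[1:]):
        s_a, s_b = float(slopes_above[i]), float(slopes_below[i])
        rows.append((series_id, "above", tp, baseline_above * (1.0 + s_a)))
        rows.append((series_id, "below", tp, baseline_below * (1.0 + s_b)))
        denom = abs(s_a + s_b)
        dm = (s_b - s_a) / denom if denom != 0 else float("nan")
        truth_rows.append((series_id, tp, s_a, s_b, dm,
                           "ok" if denom != 0 else "undefined_zero_denominator"))
    series = pd.DataFrame(rows, columns=["series_id", "position", "timepoint", "RE"])
    truth = pd.DataFrame(truth_rows, columns=["series_id", "timepoint", "S_a", "S_b", "DM", "status"])
    return series, truth


# ----------------------------------------------------------------------
# one-call orchestration
# ----------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    params: SimulationParams
    expression: ExpressionMatrix
    truth: pd.DataFrame
    variants: pd.DataFrame
    gene_map: pd.DataFrame
    allele_counts: pd.DataFrame
    qpcr: pd.DataFrame
    qpcr_truth: pd.DataFrame


def simulate_dataset(params: SimulationParams) -> SimulatedDataset:
    """Generate every pipeline input under one seed."""
    variants, gene_map = generate_genotype_variants(params)
    expr, truth = generate_expression_dataset(params)
    counts = generate_scion_allele_counts(truth, variants, params)
    qpcr, qpcr_truth = generate_qpcr_timeseries(params)
    return SimulatedDataset(params, expr, truth, variants, gene_map, counts, qpcr, qpcr_truth)
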