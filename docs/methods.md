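# Methods

## Study design being modelled

The pipeline targets a grafting design with two scion/rootstock
combinations sharing the scion cultivar ('Gala' on a cold-tolerant
'G202' or cold-susceptible 'M9' rootstock), two stem tissues per tree
(scion side and rootstock side of the graft junction), three winter
stages (CA = cold acclimation, DW = deep winter, DA = de-acclimation)
and 4 biological replicates: 48 RNA samples in total. Abundances are
RPKM-like non-negative values. Mobility of an mRNA is defined
*operationally*: a transcript present on both sides of the junction
whose seasonal expression patterns in scion and rootstock are highly
correlated, with the per-stage direction assigned to the tissue of
higher abundance (movement is assumed concentration-driven).

## Simulator

The simulator emulates the statistical structure this analysis relies
on, not the sequencing process.

* **Baseline abundance**: per-gene log-normal (log-mean 3.0, log-sd
  1.2), giving a median around 20 RPKM with a realistic right tail.
* **Seasonal structure**: per gene × tissue, stage effects are drawn
  i.i.d. normal on the log scale with sd `stage_sigma = 0.6`. For
  non-mobile genes these trajectories are *independent between tissues*
  (different tissues and genotypes have different seasonal dynamics),
  which makes the 3-point correlation null well defined; they are
  shared across combinations, so the between-combination DEG null
  holds exactly. A `tissue_shared_profiles` flag forces identical
  trajectories in both tissues instead.
* **Mobile genes** (`n_mobile`): scion and rootstock share one latent
  3-point trajectory per gene, so the scion/rootstock stage-profile
  correlation tends to 1 as replicate dispersion tends to 0. The source
  tissue (rootstock for upward movers, scion for downward; mixed by
  `mobile_direction_mix = 0.5`) is boosted by `mobile_source_fold = 2`,
  making the direction rule recoverable. Mobile genes are planted as
  DEGs in both tissues, mirroring the fact that the mobility screen
  operates on the shared DEG set.
* **DEGs**: combination effects are multiplicative with a factor drawn
  from `fold_range = (2, 4)` and random sign — comfortably above the
  1.5 screening threshold so that recovery failures indicate pipeline
  defects, not borderline effects.
* **Replicate noise**: multiplicative log-normal with sd `dispersion`
  (default 0.15). Counts are not modelled; the downstream analysis
  operates on RPKM-like values, so log-normal noise is the natural
  match. (A negative-binomial count layer was considered and dropped:
  nothing downstream consumes counts.)
* **Variants**: one contig partitioned into equal gene intervals; each
  genotype receives Binomial(L, h) heterozygous sites with
  h = `heterozygosity` = 0.012 (the ~1.15–1.24% range measured in apple
  cultivars). Each gene additionally carries
  `informative_sites_per_gene = 3` sites per rootstock genotype that
  are homozygous-alt in that rootstock and homozygous-ref in the scion.
  DNA depths are Poisson(40) with binomial allele sampling
  (error 0.001). A genome too short to host the requested sites raises
  rather than silently truncating. With `heterozygosity = 0` the genome
  is invariant and no sites are emitted.
* **Scion RNA allele counts**: at informative sites, coverage is
  Poisson(`coverage_mean = 50`) (or fixed, for distributional tests);
  the alt proportion is the gene's `translocation_fraction` (default
  0.3) at stages where the gene is upwardly mobile and the sequencing
  error rate (0.001) otherwise.
* **qPCR series**: two positive series (above/below) over
  `n_timepoints = 4` with plantable relative-change slopes; the implied
  DM value per timepoint is recorded as truth.

All draws come from named `numpy` sub-generators derived from one seed;
identical parameters give byte-identical outputs.

**What the simulator does not capture**: read-level artefacts (mapping
bias, PCR duplicates, 3' coverage bias), gene–gene correlation,
compositional normalization effects, allele-specific expression in the
absence of movement, and paralog cross-mapping that could mimic
translocated SNPs in real data. Passing recovery tests therefore
demonstrates the correctness of the screening logic under the model's
assumptions, not robustness to those artefacts.

## Differential expression

The DE method is deliberately transparent: a two-sided Welch t-test on
log2(x + 1) per gene, fold change as the ratio of pseudo-counted group
means ((mean_A + c)/(mean_B + c), c = 1), BH adjustment within one
(tissue, stage) family, pass at |fold change| ≥ 1.5 and FDR ≤ 0.05.
Genes that are all-zero in both groups are excluded before testing
(0/0 fold changes are meaningless). Zero-variance/equal-mean cells
produce p = 1 rather than NaN. The pseudo-count and thresholds are
arguments throughout. Metabolite screening reuses the same machinery
with the raw-p rule (p ≤ 0.05, no FDR) that is conventional for the
much smaller metabolite panels.

K-means clustering of DEG dynamics operates on per-gene z-standardized
stage-mean profiles over the (combination × stage) cells of one tissue,
Euclidean distance, `n_init = 10` restarts, fixed seed; constant
profiles standardize to the zero vector. Requesting more clusters than
distinct profiles is an error.

## Flow inference

Correlation is computed between the two 3-point stage-mean profiles
(means over replicates only), per combination. With n = 3 the null
probability of r ≥ 0.7 is large (≈ 0.25 for independent Gaussian
profiles) — this is a property of the published screen itself, and the
test-suite checks the empirical pass rate against a permutation oracle
rather than pretending the screen is specific. A replicate-level
correlation mode (3 × n_rep paired points) is available behind
`level="replicates"` for users who want a tighter null.

Direction calls compare stage means; exact ties produce no call and are
counted, never assigned arbitrarily. Calls are invariant to any common
positive rescaling of the data. The non-redundant mobile set is the
union of called genes over stages and combinations, reported with a
per-(combination, stage) count table satisfying total = upward +
downward.

## SNP translocation validation

An allele is *present* in a genotype iff depth ≥ 10, allele reads ≥ 10
and allele frequency ≥ 20% (each gate independently configurable). A
site is rootstock-specific iff alt is present in the rootstock
genotype, and in the scion genotype alt is not present while ref is.
By default the rootstock alt must also be near-homozygous (frequency
≥ 0.9), restricting the analysis to homozygous rootstock SNPs — the
informative subset for intra-species grafts. Sites with zero depth in
any required genotype are excluded and counted in a QC report.

Translocation evidence pools alt/total reads over a gene's specific
sites and replicates per (combination, stage); it requires ≥ 2 alt
reads *and* a one-sided binomial tail P(X ≥ alt | total, error rate)
< 0.05, so sequencing error cannot masquerade as translocation. Genes
without specific sites are "unassessable", never negative.

The mobility score counts stages (0–3) with evidence concordant with an
upward flow call — translocated rootstock alleles in scion RNA can only
support rootstock → scion movement. The score-3 subset is the
high-consistency set. This stage-concordance definition is an
interpretation (the original scoring rule is not fully specified in
public sources) and is the package's documented convention. A symmetric
mode (scion-specific alleles in rootstock reads scored against downward
calls) is available via `concordant_direction="downward"` given
rootstock-side allele counts.

## DM statistic

DM = (S_b − S_a)/|S_a + S_b| with S = [RE(Tn) − RE(T1)]/RE(T1).
The sign convention follows the statistic's definition verbatim: a
larger relative change *below* the junction gives DM > 0, read as
upward movement. (One may find this counter-intuitive — the recipient
tissue shows the larger relative gain under this reading — but the
implementation does not reinterpret it.) DM is unbounded and never
clamped; values like −2.16 are legitimate. Undefined cases — RE(T1) = 0,
or S_a + S_b = 0 (including the no-change case S_a = S_b = 0) — raise
`UndefinedStatisticError` at the scalar level and appear as NaN rows
with a reason code in table-level output, never as 0. For RNA-seq
input, defaults map scion → above, rootstock → below and use the first
stage (CA) as T1; all three are arguments.

## Cross-species consistency

Ortholog mapping de-duplicates targets and counts unmapped sources.
The reference overlap percentage is truncated (not rounded) to one
decimal, matching the one-decimal convention of the numbers users will
compare against. The confidence level of a shared ortholog is the
number of (combination, stage) flow calls matching the reference
direction; "consistent" means level ≥ 1, with a stricter majority-vote
mode behind `mode="majority"`. Both the consistent count and the
fraction of assessed targets are reported, since percentage bases vary
between publications.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run simulations at
4000–5000 genes with 100–200 planted mobile genes — the package's
chosen desk-scale analog of a full transcriptome, large enough for the
statistical checks (null calibration within 3 SE, binomial
goodness-of-fit on > 1000 sites, permutation oracles with 50 shuffles)
while keeping a full run in seconds. Recovery tests use fixed seeds;
tolerance choices are stated per test (1e-10 for exact arithmetic
recovery, 1e-12 for closed-form oracles, 3 SE for stochastic rates).

## Known limitations

* The r ≥ 0.7 screen on 3 points has a high false-keep rate by
  construction; the package reports it honestly rather than tightening
  the published rule.
* Downward mobility has no SNP-based validation path in the default
  configuration (scion alleles are shared between combinations and
  rootstock-side RNA counts are not simulated).
* The DE test assumes approximate log-normality of RPKM within groups;
  count-based tests (e.g. negative-binomial GLMs) are out of scope
  because the pipeline's inputs are normalized abundances.
* Ortholog inference itself, GO/KEGG enrichment and network
  reconstruction are out of scope; the cross-species module consumes a
  user-supplied map and reference list.
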