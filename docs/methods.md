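# Methods

This note describes the statistical models behind each estimator, the
assumptions they make, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Mean ribosome load from spike-in-calibrated polysome fractions

A sucrose-gradient run resolves mRNAs by the number of ribosomes they carry:
two zero-ribosome fractions (free mRNPs and 40S-bound), then 80S, disome,
trisome, ... up to the 10-some. Because an identical amount *S* of spike-in
molecules is added to every fraction, per-fraction TPMs convert to absolute
molecule counts:

    M_i^k = TPM_i^k * S / TPM_S^k

with TPM_S^k the summed spike-in TPM of fraction *k*. Normalizing M_i^k over
fractions gives p_i^k, the probability that a molecule of gene *i* carries
*k* ribosomes (the free and 40S fractions are pooled into k = 0, since both
carry zero elongating ribosomes).

Under low ribosome density per transcript, loads are Poisson distributed,
and the mean load λ is estimated by fitting the Poisson pmf to p_i^k by
minimum Pearson chi-square (a maximum-likelihood objective is available via
`method="mle"`). The chi-square at the optimum is reported, but only as a
*relative* quality score across genes: without per-fraction error estimates
on p_i^k it is not an absolute goodness-of-fit test.

**Tail handling.** The gradient does not resolve loads above 10; physically,
material heavier than the 10-some pools into the deepest collected fraction.
The default model therefore places the entire Poisson tail mass
P(K ≥ 10) in the k = 10 bin (`tail="collapse"`). The alternative of
conditioning the pmf on K ≤ 10 (`tail="renormalize"`) is exposed, but it
mis-models heavily loaded transcripts: on tail-collapsed data the
renormalized fit is biased upward by ~16% at λ = 8, while the collapsed
model recovers every λ in [0, 10] essentially exactly. Use the renormalized
mode only if the heavy shoulder of the gradient was discarded rather than
pooled.

The classical truncated weighted mean Σ_k k·p_k is reported alongside
(`mrl_truncated`); it agrees with λ to <0.5% for λ ≤ 2 and saturates below
the true load as tail mass appears — the defect the Poisson fit corrects.
`mrl_per_nt` divides λ by transcript length (nt); CDS length can be supplied
instead, as the appropriate denominator is a matter of convention.

**Numerics.** The fit scans λ on a 0.01-step grid over [0, 10] (the pmf
matrix is precomputed once) and refines the best cell by bounded 1-D
minimization to |Δλ| < 1e-4. Chi-square cells with model mass below 1e-12
are skipped to avoid division blow-ups; they do not affect the optimum
materially. A gene with p_0 = 1 exactly is returned as λ = 0, χ² = 0,
flagged `degenerate`. Replicates are fitted separately and λ averaged by
default; pooling counts before the fit is a flag (`pool_replicates`) —
per-replicate fitting preserves replicate-level spread information, and the
two agree exactly in the noise-free limit.

## Protein synthesis rates from pulsed SILAC

After the heavy-to-light medium switch, each heavy peptide's intensity
decays as I(t) = I0·e^(−kt). The model is linear in I0, so for any k the
optimal amplitude is the projection I0*(k) = Σ_t I_t e^(−kt) / Σ_t e^(−2kt),
leaving a one-dimensional profiled least-squares problem in k. Least squares
is taken on linear intensities (not logs): the projection is exact only on
the linear scale. The profiled objective is scanned on a 200-point geometric
grid over [0, 1] /min — rates above 1 /min (half-life < 42 s) are not
plausible for proteins; the bound is configurable — and refined by bounded
minimization to a relative tolerance of 1e-6 in k. The profiled optimum
agrees with a full two-parameter nonlinear least-squares fit to better than
1e-6 in k (checked against a `scipy.optimize.least_squares` oracle).

Peptides need at least three finite positive intensities; fitted rates below
1e-5 /min are discarded as spurious (strictly "smaller than": the boundary
value is kept). Because intensities of different peptides are not comparable
but rates are, per-protein aggregation is the unweighted mean of surviving
peptide rates, with the spread (max − min) kept as a crude fluctuation
measure. Rates are computed per replicate and normalized per replicate.

**Copy-number normalization.** Two conventions are implemented and the one
used is recorded in the output. `as-stated` divides the accumulation rate by
the protein copy number per cell (synthesis_rate = k/N). `steady-state`
applies the balance s = k·N. The two differ by N²; which is appropriate
depends on whether the target quantity is a per-copy renewal rate or a
per-cell molecular flux, and the module deliberately surfaces rather than
resolves the choice. Default: `as-stated`.

## Elongation rate from harringtonine run-off

Harringtonine traps initiating ribosomes at the start codon while elongating
ribosomes run off; after τ seconds the first ~v·τ codons are depleted.
Replicate coverage is pooled by summation, genes are aligned at the start
codon, and coverage is combined position-wise across genes. The combination
divides the position-wise sum by the number of genes covering the position:
with heterogeneous gene lengths a raw sum would fall off artificially past
the shortest gene's end. On the region all included genes cover this equals
the plain sum up to the normalization constant. The combined profile is
averaged in half-open 5-codon windows and divided by the mean over windows
inside the 800–1000-codon region. A per-gene-normalized variant (each gene
scaled to unit mean first, giving equal gene weights instead of read-depth
weights) is available via `per_gene_norm`.

By default only genes spanning the full normalization region (≥ 1000
codons) enter the metagene; `min_length=None` admits shorter genes for the
positions they cover.

The *starting location* of a time point is where the normalized curve first
reaches 0.5 walking from the start codon, refined by linear interpolation
between the adjacent window centers (window-granular resolution would
quantize the rate estimate). The elongation rate is the ordinary
least-squares slope of starting location versus run-off time, in codons/s
(numerically aa/s). The τ = 0 curve checks flatness but is excluded from the
fit by default — the drug has not acted yet; `include_t0` overrides.

**Normalization-region depletion guard.** At fast rates or late times the
front can overrun the 800–1000-codon region itself (8 codons/s × 150 s =
1200 codons). Normalizing by a depleted region rescales the residual
background toward 1 and the 0.5-crossing collapses to codon 0. The guard
compares each time point's raw region coverage with the earliest time
point's (same genes, so gene-composition effects cancel); a region that lost
more than half its reference coverage flags the curve
`norm_region_depleted` and removes that time point from the rate fit, with a
warning. The factor 2 sits far from both failure modes: the crossing
misbehaves only once the region falls below ~2× the residual floor (≈ 0.1
of baseline), while intact regions stay near 1.

## A-site codon enrichment

A slowly decoded codon dwells longer in the A-site and is over-represented
among footprints. The observed usage of codon *c* is the proportion of
footprints with *c* at the A-site — located at floor((pos5 + offset)/3)
codons, where the A-site offset is the read-length-dependent P-site offset
plus 3 nt, and frame ambiguity after offsetting is resolved by floor
division (deterministic, consistent with P-site conventions). The expected
usage is the codon composition of the coding regions averaged with weights
proportional to each CDS's footprint count. Enrichment is the elementwise
ratio over the 61 sense codons (the A-site of an elongating ribosome never
holds a stop codon).

The first 15 codons after the start and the last 5 before the stop are
excluded — library-preparation and initiation/termination artifacts
concentrate there — and the exclusion is applied symmetrically to the
observed and the expected side, which keeps the null ratio exactly 1 in
expectation. Each footprint contributes one A-site observation; no coverage
smoothing is applied. Footprints are dropped with per-reason counters
(unknown length, unknown transcript, A-site outside the CDS, inside an
excluded window, or on an in-frame stop).

Under uniform dwell weights the enrichment estimator is binomial-calibrated:
per-codon deviations from 1 have standard deviation ≈ sqrt((1−p)/(n·p)) with
p ≈ 1/61, i.e. ~1.7% at 2×10⁵ reads, and the expected maximum over 61
codons is then ~4.4%. Single-sample checks of a ±5% band at that depth are
therefore near the boundary by construction; calibration claims should be
read per replicate-consensus (the emulated experiments are biological
triplicates) or at greater depth, tightening as 1/√n.

## Footprint QC and quantification

Coordinates are 0-based half-open; a transcript is 5'UTR [0, u), CDS
[u, u+c), 3'UTR [u+c, u+c+t). P-site offsets per read length are estimated
as the modal distance between annotated start codons and footprint 5' ends,
searched over the plausible 10–14 nt window — initiating ribosomes pile up
with their P-site on the start codon, making the mode sharp. Length classes
with fewer than 500 reads inherit the global modal offset and are flagged.
Frame proportions tabulate P-sites mod 3 relative to the start codon; region
proportions assign each read by its P-site, with reads outside the
transcript counted separately. TPM is the length-normalized read rate scaled
to 10⁶; RPKM is reads per kilobase per million mapped reads. For footprints
the length denominator is the CDS (translation output is per coding region);
transcript length is selectable for RNA-seq parity. Translation efficiency
is footprint TPM over mRNA TPM per gene, with log2 fold-changes computed
for genes with positive TE in both conditions. Inputs are assumed
deduplicated (multi-mapper removal is upstream).

## What the generators emulate — and what they do not

All generators derive their random streams from a single `SimConfig.seed`
(per-generator substreams, so outputs are byte-identical across runs).

* **Polysome fractions.** Per gene, a total molecule count (log-normal,
  median 10⁴) is split across fractions by the Poisson(λ) load pmf with
  mass at K ≥ 11 pooled into fraction 10 and the k = 0 mass split between
  free and 40S; spike-ins add an exactly equal total S = 10⁵ (10 species)
  to every fraction; sequencing resamples reads multinomially at the
  configured depth (10⁵/fraction by default; `fraction_noise="none"` gives
  the noise-free limit, exact to closed form). The sampling-noise model of
  fraction TPMs is configuration, not an assertion about the assay.
* **pSILAC.** Per-protein rates shared by 1–10 peptides, log-uniform over
  (10⁻³, 0.05) /min (half-lives ~14 min–11.5 h, the plausible range for a
  dividing cell line); peptide amplitudes log-normal; multiplicative
  log-normal noise at CV 0.1; nine chase times from 0 to 660 min.
* **Run-off coverage.** A hard front at v·τ codons over a flat per-gene
  baseline, with a residual floor of 5% of baseline behind the front and
  optional log-normal coverage noise; default v = 4.55 codons/s, the rate
  measured in the liver-cancer cells these simulations emulate; genes of
  1000–1500 codons so the metagene normalization region is covered.
* **Footprints.** Random-sense-codon CDSs flanked by 60-nt UTRs; A-site
  codons sampled with transcript-abundance × codon-dwell weights (uniform
  dwell by default — the null), a 3× initiation-proximal bonus on the
  first decoded codon (the start-codon pile-up real libraries show, and the
  signal the offset estimator relies on), read lengths 27–31 nt peaked at
  29–30 with P-site offsets 11–13 nt, and optional ±1 nt jitter on the 5'
  ends (default 0, i.e. exact 3-nt periodicity).

Not emulated: raw reads, alignment artifacts, rRNA contamination, ribosome
collisions or queueing, non-Poisson load mixtures, mass spectra,
missing-value structure of MS intensities, arginine-to-proline conversion,
codon-level variation in elongation speed along the run-off front, and UTR
footprints. Passing recovery tests on these simulations demonstrates that
the estimators invert their own generative assumptions at realistic depths
and noise levels — not that real libraries satisfy those assumptions.

## Problem sizes used by the recovery checks

The bundled recovery checks (`tests/test_acceptance.py`,
`scripts/acceptance.py`) run at: 200 genes × 3 replicates × 10⁵
reads/fraction for load recovery; a 99-point λ grid for fit
self-consistency; 50/200 proteins for clean/noisy rate recovery and a
20-series NLS cross-check; fronts at 3, 5 and 8 codons/s over 12 genes × 2
replicates; 2×10⁵ reads × 50 CDSs for codon-enrichment calibration; and
5×10⁴ reads × 30 transcripts for the QC conservation checks. These sizes
give each statistic comfortable margin relative to its tolerance while the
whole battery completes in seconds.

## Known limitations

* The Poisson load model shares the experiment's assumption of low ribosome
  density; transcripts with strongly non-Poisson load (e.g. bursty
  initiation) will show elevated relative χ², but no absolute test is made.
* The spike-in total S is taken as known; errors in S propagate
  proportionally into absolute counts (though not into the load pmf, which
  is scale-free within a fraction as long as all fractions share S).
* The pSILAC fit ignores heteroskedasticity of MS intensities; with
  log-normal noise a weighted or log-scale fit would be more efficient, but
  the linear-scale projection is what makes the amplitude elimination
  exact.
* The run-off estimator reports a single global (metagene) rate; per-gene
  rates are out of scope.
* Codon enrichment is a marginal ratio statistic; it does not model
  context effects, pause sites, or tRNA abundance.
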