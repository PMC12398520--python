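# transdyn

Estimators for mRNA translation dynamics in mammalian cells, built for
multi-omic experiments that combine polysome profiling, ribosome profiling
(steady-state and harringtonine run-off), and pulsed-SILAC proteomics — the
kind of data used to dissect how initiation, elongation and ribosome load
shape protein output from endogenous mRNAs.

The package is aimed at computational biologists who have per-fraction
expression tables, footprint alignments or peptide intensity time courses
in hand and need the downstream statistics, plus a synthetic-data generator
with known ground truth so every estimator can be validated end to end
without touching raw sequencing data.

## What it computes

**Mean ribosome load (MRL) from spike-in-calibrated polysome fractions.**
With an equal total *S* of spike-in molecules in every gradient fraction,
TPMs convert to absolute counts, M_i^k = TPM_i^k · S / TPM_S^k, and
normalizing over fractions k = 0..10 gives the probability p_i^k that an
mRNA of gene *i* carries *k* ribosomes. Assuming low ribosome density, loads
are Poisson, p(k; λ) = λ^k e^(−λ)/k!, and λ (the MRL) is fitted per gene by
minimum Pearson χ² with the unresolved tail (k > 10) pooled into the last
fraction. The classical truncated mean Σ_k k·p_k — which saturates for
heavily loaded transcripts — is reported for comparison, as is λ per
nucleotide.

**Protein synthesis rates from pSILAC.** Heavy-peptide intensities decay as
I(t) = I0·e^(−kt); I0 is projected out in closed form and k found by 1-D
profiled least squares. Rates below 10⁻⁵/min are discarded as spurious;
per-protein rates are the mean over peptides (spread = max − min), optionally
normalized by protein copies per cell.

**Global elongation rate from ribosome run-off.** Metagene coverage curves
(5-codon windows, normalized to the 800–1000-codon region) are built per
harringtonine time point; the run-off front's *starting location* is the
first 0.5-crossing of the normalized curve, and the elongation rate is the
slope of starting location vs time (aa/s).

**A-site codon enrichment.** Observed A-site codon usage over
footprint-weighted expected usage across coding regions, with the first 15
and last 5 codons of each CDS excluded; 61 sense codons.

**Ribo-seq QC and quantification.** Read-length distributions, per-length
P-site offsets (modal distance to start codons), reading-frame and
5'UTR/CDS/3'UTR proportions, TPM/RPKM, translation efficiency
(TE = footprint TPM / mRNA TPM) and TE log2 fold-changes.

**Synthetic data.** `transdyn.synthetic` generates all of the above inputs
with known truth: Poisson loads partitioned into fractions with equal
spike-in totals, exponentially decaying peptide intensities with
multiplicative noise, run-off coverage with a front advancing at a fixed
codon/s rate, and footprints with length-dependent P-site offsets.

See `docs/methods.md` for model assumptions, numerical choices and the
limits of what the simulations demonstrate.

## Worked example

Estimate mean ribosome loads on a small simulated fraction table and recover
an elongation rate from simulated run-off coverage:

```python
from transdyn import (SimConfig, simulate_fraction_table, estimate_loads,
                      simulate_runoff_coverage, run_runoff_analysis)

cfg = SimConfig(seed=42, n_genes=5, n_replicates=3, depth=1e5)
table, truth = simulate_fraction_table(cfg)
est = estimate_loads(table, spikein_total=cfg.n_spikein_molecules)
print(est.merge(truth, on="gene_id")
         [["gene_id", "lambda", "chi2", "mrl_truncated", "truth_lambda"]]
         .round(4).to_string(index=False))

cov = simulate_runoff_coverage(SimConfig(seed=42, n_runoff_genes=12, n_replicates=2))
curves, fit = run_runoff_analysis(cov)
print(f"elongation rate: {fit.slope:.3f} aa/s  (r2 = {fit.r2:.5f})")
```

prints

```
  gene_id  lambda   chi2  mrl_truncated  truth_lambda
gene00000  6.4693 0.0061         6.3494        6.4513
gene00001  2.3439 0.0013         2.3420        2.3447
gene00002  3.5590 0.0042         3.5549        3.5332
gene00003  5.2070 0.0042         5.1787        5.2457
gene00004  6.6102 0.0027         6.4720        6.6215
```

```
elongation rate: 4.550 aa/s  (r2 = 0.99999)
```

The fitted `lambda` tracks the planted `truth_lambda` to ~1% at this
sequencing depth, while `mrl_truncated` — the plain weighted mean over
resolved fractions — already undershoots noticeably for the heavily loaded
genes. The run-off fit recovers the simulated front speed (4.55 codons/s,
the rate such cells actually show) through a 5% residual noise floor; `chi2`
is a relative fit-quality score across genes, not an absolute test.

The same steps are available from the shell:

```bash
transdyn simulate fractions --seed 42 --out sim/
transdyn mrl --fractions sim/fractions.tsv --spikein-total 100000 --out mrl.tsv
transdyn simulate runoff --seed 42 --out sim/
transdyn runoff --coverage sim/runoff_coverage.tsv --out fit/
```

plus `transdyn psilac`, `transdyn codons`, `transdyn qc`, `transdyn
quantify` and `transdyn te` for the other estimators. All tables are plain
TSV; footprints may also be SAM/BAM and coverage may be BigWig.

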