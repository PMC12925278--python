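# Methods

## Scope and model

`infosome-lfq` implements the statistical pipeline for a label-free
quantitative (LFQ) proteomics comparison of extracellular vesicles (EVs)
from two macrophage states: a resting control and an NLRP3-inflammasome-
activated condition whose EVs are enriched in inflammatory cargo. The
experimental design it targets is hierarchical: each condition has three
biological replicates; each biological replicate's EV protein extract is
separated into gel fractions (two for control, four for treatment, because
the treatment lanes carry more protein); each fraction is injected into the
LC-MS/MS instrument two to three times (technical replicates). The pipeline
consumes protein-level search-engine exports, never raw spectra.

The stages, in order:

1. **Identification stringency filter.** A protein enters the analysis only
   if its search-engine probability is strictly greater than 0.99, it has at
   least 2 unique peptides, and at least 2 total and 2 unique spectral
   counts. Probability thresholds are strict inequalities (a literal reading
   of ">99.0 %"); count thresholds are inclusive. A peptide-level >0.95
   filter is available for exports that are not pre-aggregated.
2. **Hierarchical aggregation.** A fraction's intensity is the arithmetic
   mean of its *observed* technical replicates; a biological replicate's
   intensity is the sum of its *observed* fractions. A cell is missing only
   when every contributor is missing. Summing with missing-as-zero would
   penalize a replicate for a single dropped injection in a way the mean
   rule does not, so observed-only is used at both levels; the cost is that
   a biological replicate with a genuinely undetected fraction is
   underestimated by that fraction's share (see Limitations).
3. **Missingness filter.** Within each group the fraction of missing
   biological replicates is computed per protein; a protein is retained if
   at least one group has ≤ 70 % missing. With n = 3 this means one
   observed replicate (66.7 % missing) suffices.
4. **Median imputation.** Each missing cell is replaced by the median of the
   protein's observed values within the same group, on the linear intensity
   scale (imputation precedes the log2 transform, matching the stage order
   of the workflow the pipeline reproduces). If a group has no observation
   for the protein, the median of the protein's observed values across all
   samples is used instead.
5. **log2 + median alignment.** Intensities are log2-transformed and each
   sample receives an additive shift aligning its median to the highest
   per-sample median (equivalently, multiplicative scaling of raw
   intensities). The reference sample's shift is zero; median ties are
   broken by first column order, which cannot change any shift magnitude.
   Shifts are returned for inspection.
6. **Differential abundance.** Per protein, Welch's unequal-variance t-test
   on the log2 values, two-sided, with Welch–Satterthwaite degrees of
   freedom; the effect size is the difference of group means of log2 values.
   A protein is *up* when log2FC ≥ 1 (inclusive — "fold change ≥ 2") with
   p < 0.05 (strict), *down* by the mirrored rule, otherwise *ns*.
   Benjamini–Hochberg q-values over all tested proteins are reported as an
   extra column; selection deliberately uses the raw p-value to match the
   workflow being reproduced. Degenerate zero-variance pairs return p = 1
   for equal means and the smallest positive double (flagged in the log)
   for unequal means.
7. **Presence/absence overlap.** A protein is "detected" in a condition if
   observed in ≥ 1 biological replicate before imputation (the threshold is
   a parameter); the two detection sets are partitioned into
   condition-unique and shared compartments.
8. **Over-representation analysis.** Hypergeometric upper-tail test of a
   query list against GMT gene sets, restricted to a background universe
   that defaults to the quantified protein list of the same run (standard
   ORA practice — conditioning on what could have been observed). Sets
   overlapping the query in fewer than 2 ids are not tested. miRNA-target
   enrichment is the same test with miRNA→target GMT sets; no annotation
   databases are bundled.
9. **Livak relative quantification.** For qPCR validation arms:
   ΔCt = Ct_target − Ct_reference per sample, ΔΔCt relative to the
   arithmetic mean ΔCt of the calibrator condition, relative expression
   2^(−ΔΔCt). The arithmetic-mean calibrator makes the calibrator group's
   *geometric* mean expression exactly 1. Amplification efficiency is
   assumed ~100 % for both primers (no Pfaffl correction).

## Synthetic-data generator

No raw dataset ships with the package; `infosome_lfq.simulate` generates
experiments with known truth so every stage is testable. Per protein, the
baseline log2 abundance is Normal(22, 2) — typical of MS1 intensities on a
log2 scale. A spiked subset (default 10 %) receives a true effect of
|log2FC| = 2 in the treatment group, sign randomized 50/50 so both the up
and down branches of the classifier are exercised. The biological-replicate
linear abundance is split across that replicate's fractions by a Dirichlet
draw (concentration 2 per fraction, giving visibly uneven gel-slice
shares), so the pipeline's sum-across-fractions rule is the exact inverse
of the generative split — this makes the aggregation stage analytically
testable. Each injection multiplies the fraction value by lognormal noise
with CV 0.2 (a typical label-free technical CV). Dropout is applied per
injection: intensity-dependent (MNAR) with probability
`0.6 · expit(−0.9 · (log2 x − 17.5))` plus 2 % uniform (MCAR). At the
defaults this yields ~15 % missing run-level cells concentrated in the
low-intensity tail. Identification records are drawn so ~5 % of proteins
independently fail each stringency criterion.

Deliberate simplifications relative to real data: no biological
between-replicate variability beyond the technical chain (all replicates of
a group share the same true abundance); no peptide-to-protein roll-up, no
shared-peptide ambiguity, no between-run alignment artifacts; missingness
is independent across injections given intensity; identification evidence
is independent of abundance. Consequently, passing tests demonstrate the
*statistical machinery* is correct under the stated design, not that the
pipeline overcomes peptide-level or alignment pathologies of real
LC-MS/MS data. Because group abundance differences of |log2FC| = 2 rarely
push proteins below the detection floor at these settings, the default
synthetic experiment produces few condition-unique detections; the Venn
stage is exercised by dedicated tests with harsher dropout rather than by
the default run.

## Numerical and design choices

* Zero intensities in exports are treated as missing: search engines write
  0 for non-detection, and a measured zero is not meaningful on this scale.
* All grouping flows through the run-design table; column order never
  carries meaning. Outputs are deterministically ordered (p ascending, ties
  broken lexicographically by id) and floats round-trip bit-identically
  through TSV (shortest-repr writing, round-trip parsing).
* The "70 % of samples" rule counts biological replicates after
  aggregation, within each group.
* Welch's statistic and the Welch–Satterthwaite df are computed in-package
  (the degenerate zero-variance contract above is part of the definition);
  p-values come from the Student-t survival function, BH from
  statsmodels, the hypergeometric tail from scipy. Tests verify each
  against independent references: a separately coded textbook Welch
  implementation and scipy's `ttest_ind`, exhaustive enumeration of draws
  for every hypergeometric parameter combination with N ≤ 12, and a
  hand-coded BH step-up.
* **Calibration note.** Welch's test at n = 3 vs 3 is conservative: under
  an equal-variance Gaussian null its empirical size at the 0.05 level is
  ≈ 0.0345 (measured over 200,000 simulated proteins; scipy agrees
  p-for-p). This is a property of the Welch–Satterthwaite approximation at
  tiny samples, not an implementation artifact; the suite asserts the size
  is near and not above nominal.
* **Noise-free limit.** With dropout off and technical CV → 0 the pipeline
  inverts the generative model exactly, *except* that per-sample median
  alignment injects a small group-level offset whenever spiked effects
  shift a sample's median relative to the other group — of order
  baseline_sd·√(n_spiked)/n_proteins (~0.04 log2 units at defaults). The
  exact-recovery test therefore also shrinks the baseline spread to ~0, so
  more than half of all proteins pin the sample medians and the alignment
  offset vanishes (~1e-9); fractionation, aggregation, imputation and
  normalization all remain active, and recovered log2FCs match truth to
  < 1e-6.
* Problem sizes in the test and acceptance runs — 2,000-protein
  experiments, 10 simulation seeds, a 20,000-protein null — were chosen as
  the smallest sizes at which the Monte-Carlo error of each reported rate
  is well below the margins being asserted.

## Limitations

* Observed-only fraction summation biases biological-replicate totals
  downward when a whole fraction is undetected; at default dropout this
  contributes a mean log2FC bias well inside ±0.02, but it grows with
  MNAR severity and fraction count.
* Raw-p selection (no FDR gate) reproduces the target workflow but admits
  the usual multiplicity caveats; q-values are provided for re-thresholding.
* Median imputation with n = 3 replicates can only copy an observed value
  or the group median; variance is understated for imputed cells and no
  uncertainty is propagated.
* The ORA background must match how the query was derived; the default
  (quantified set) is correct for the pipeline's own calls but not for
  externally derived lists.
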