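# Methods

This note records the statistical procedures the package implements,
the defaults it fixes where the underlying experimental conventions
leave a choice open, and what the synthetic-data generators do and do
not emulate.

## Consensus PWM

The NBE consensus `CUGAGGA` is turned into a log-likelihood position
weight matrix: at each position the consensus base carries probability
*p* (`match_probability`, default 0.85) and the remaining mass is split
equally over the other three bases; scores are `log2` ratios against a
background base distribution (default uniform 0.25), so they are in
bits and the consensus 7-mer is the strict global maximum. The 0.85
default gives a sharply peaked but non-degenerate matrix — one
mismatch costs ~4.1 bits — and is exposed as a parameter everywhere
(API and CLI) because downstream empirical p-values depend only on
score *ranks*, which are invariant to both the log base and, for a
uniform background, to the exact value of *p*. RNA (U) and DNA (T)
alphabets are canonicalized to a single internal alphabet so promoter
DNA and selected RNA reads compare directly.

Sequence logos report per-position base frequencies and information
content `2 − H` bits. No small-sample correction is applied: the logo
is a deterministic function of the observed frequencies, which keeps
test expectations exact; for the gene-scale inputs the scan produces
(hundreds to thousands of 7-mers) the correction would be ≤ a few
hundredths of a bit.

## Promoter scanning and the permutation null

Windows span −50..+150 relative to the TSS (offset 0 = first
transcribed base), scanned on the sense strand only — the physical
target is nascent RNA, which mirrors the sense strand — with each
7-mer assigned the offset of its 5′-most base. 7-mers containing an
ambiguous base are unscoreable: they are excluded from null draws and
carried as missing values in tracks, and per-offset averages are taken
over the genes with data rather than imputed.

The null distribution draws, per sample: a window uniformly at random,
a uniform permutation of that window's letters, and a 7-mer at a
uniform offset. Permuting a window and reading at a uniform offset is
equivalent to sampling seven letters without replacement in order,
which is how it is implemented. This scheme preserves each promoter's
base composition (the property that makes the null "composition
matched") while also being a draw of permuted 7-mer scores; an
alternative that shuffles each observed 7-mer in place is available
behind the `scheme` flag. Empirical p-values use the add-one rule
`p = (1 + #{null ≥ s})/(N + 1)`, so p ∈ (0, 1] and the similarity
index −log10(p) is always finite; N defaults to 100,000 with a floor
of 1,000.

Two numerical subtleties are worth knowing. First, with a *uniform*
background the PWM score of a 7-mer depends only on its number of
consensus matches, so null scores occupy just eight atoms and
empirical p-values are coarsely discrete — fine for ranking and for
the group tests, but a one-sample uniformity check of the p-values is
only meaningful with a non-uniform background (the calibration tests
use A/T-skewed 0.28/0.21/0.24/0.27), which spreads scores over
thousands of values. Second, because the null CDF is itself estimated
from N draws, a KS uniformity test of p-values computed against that
fixed null inherits O(N^−1/2) estimation noise and rejects slightly
more often than its nominal level; with N = 10,000 and 5,000 scores
the check is still informative but occasional small KS p-values under
a true null are expected.

Group comparisons use, per gene, the maximum similarity index in the
pause region +10..+30, compared between groups with a two-sided
two-sample Kolmogorov–Smirnov test and Welch's unequal-variance
t-test. Heat-map rows order by that same statistic (descending) so the
ordering matches the test value. Ties in the per-gene best-match 7-mer
resolve to the 5′-most occurrence.

## Read-pool enrichment

Pools are unique sequences with multiplicities plus a total-read
normalizer. Matching is fixed-length Hamming-distance matching with a
mismatch budget (default 1); ambiguous bases never match. A read
counts as motif-positive once regardless of how many windows match,
weighted by multiplicity (a `unit="unique"` flag switches to counting
unique sequences, since the underlying experimental reports are
ambiguous about the unit). MPM = 10⁶ × positive/total. Enrichment is a
two-sided Fisher's exact test on the 2×2 motif-positive/negative ×
target/control table; the odds ratio is ad/bc with a Haldane 0.5
continuity correction applied (and flagged) only when a cell is zero.
The per-variable-position breakdown assigns each single-mismatch read
to the pattern position where its 5′-most best hit differs, with exact
matches reported separately.

`dominant_kmer` summarizes a ranked pool by the k-mer *present* in the
most of the top-n sequences (presence, not occurrence count), with
lexicographic tie-breaking; it is a desk-scale summarizer, not a motif
discovery algorithm.

## Binding quantification

The Hill model `response = B + A·[P]ⁿ/(K_dⁿ + [P]ⁿ)` is fit by
bounded nonlinear least squares (K_d > 0, 0.01 ≤ n ≤ 10), with the
half-saturation concentration as the K_d initial guess. For
fraction-bound (F-EMSA) data B and A are fixed at 0 and 1 unless
overridden; polarization (FP) data fit both freely in raw mP. The Hill
coefficient is free by default with a `fix_n` option, standard errors
come from the fit covariance, and a fit whose K_d lands at or beyond
the top of the concentration grid is flagged with a censoring
suggestion (e.g. ">2000").

Replicates aggregate as unweighted mean ± sample s.d.; a single
replicate reports the fit's own standard error. Censored estimates
(">2000 nM" rows) carry a lower bound, aggregate to the smallest
bound, and are refused by the free-energy functions with an explicit
error rather than silently propagated.

Free energies use ΔG° = −RT ln K_d (K_d in molar,
R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹) and ΔΔG° = −RT ln(K_d,A/K_d,B), where
the molar conversion cancels; uncertainties propagate first-order
(σ_ΔG = RT σ/K_d, quadrature for differences). The default temperature
is 298 K — the published humanized-mutant ΔΔG° of −0.15 kcal/mol is
reproduced exactly by the printed F-EMSA K_ds at that temperature — and
is exposed as a parameter. F-EMSA K_ds are the default assay for ΔΔG°
comparisons. A known limitation: for RNA pairs involving TAR, ΔΔG°
computed from the two assays' printed (rounded, two-significant-figure)
K_ds can disagree by ~3× the propagated σ, so cross-assay agreement is
only asserted for the aptamer pairs where it holds; unrounded K_ds
would be needed to do better.

## Synthetic data

The generators are pure functions of (config, seed) and return truth
manifests listing exactly what was planted.

- **Promoters**: i.i.d. (order-0) background with, per window, at most
  one motif copy embedded with group-specific probability (defaults
  0.6 paused / 0.1 non-paused, 500 genes per group), at a
  truncated-normal offset centred on +25 (s.d. 3), each motif position
  independently mutated at rate 0.10. The 0.10 default makes planted
  copies "degenerate" (about half carry ≥1 mismatch over 7 positions)
  while keeping them detectable in a 10,000-score null. Order-0
  background means no core-promoter elements (TATA/Inr/DPE), no
  dinucleotide structure and no compositional gradient around the TSS;
  passing recovery tests therefore demonstrates the statistics, not
  robustness to real promoter sequence structure.
- **Selection pools**: 100,000 reads of 50 nt; a naive fraction (0.01)
  carries one exact motif copy; selection reweights motif-bearing
  reads by enrichment^cycles (5², matching a two-cycle
  no-amplification selection) and resamples at constant pool size; the
  control resamples the naive pool uniformly. No PCR bias or
  sequencing-error model.
- **Titrations**: 12-point two-fold dilution from 2 µM down (≈1 nM
  floor), Gaussian noise (default σ = 0.05 fraction-bound units),
  F-EMSA responses clipped to [0, 1]; FP uses 80 mP baseline and
  120 mP amplitude.

## Problem sizes

Defaults used by the test suite and the reproduction script: 500 genes
per group and nulls of 10⁴ for scan-level checks (the full 10⁵-score
null remains the library default), 200-seed batches for calibration
checks at 50 genes per group and nulls of 10³, a 16-cell
(K_d × n × noise) × 13-replicate grid for K_d recovery, and 10⁵-read
pools for enrichment. These sizes give stable statistics (Monte-Carlo
error well inside every asserted band) at desk scale.

## Known limitations

- Exact genome-scale figures (gene counts, heat maps over thousands of
  real promoters) require a genome and curated gene lists and are out
  of scope; the scan consumes any FASTA/BED input of the right shape.
- The PWM's match probability and log base are conventions, not fitted
  quantities; only p-value ranks are invariant to them.
- Matching implements fixed-length patterns with a mismatch budget
  only (no gaps, no IUPAC degeneracy, no full pattern language).
- The exact-identity read dedup stands in for sequence *clustering*;
  near-duplicate reads are distinct sequences here.
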