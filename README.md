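# nbescan

Quantitative analysis of NELF-E RNA recognition: promoter-proximal
scanning for the NELF-E binding element (NBE), motif enrichment in
SELEX read pools, and Hill-equation binding quantification with
binding-free-energy comparisons.

## Who this is for

NELF (Negative Elongation Factor) stalls RNA polymerase II just
downstream of the transcription start site (TSS); its E subunit binds
nascent RNA through an RRM domain whose consensus target, the NBE, is
`CUGAGGA`. This package is for researchers asking three related
questions about such a motif:

1. **Is the motif enriched where pausing happens?** Promoter windows
   (−50..+150 around the TSS, sense strand) are scanned with a
   consensus-derived position weight matrix (PWM); scores become
   empirical p-values against a permutation null, and paused vs
   non-paused gene groups are compared in the +10..+30 pause region.
2. **Does the protein select the motif from a complex RNA pool?**
   Mismatch-tolerant motif counts in target vs control read pools are
   normalized to multiplicity per million reads (MPM) and tested with
   Fisher's exact test.
3. **How strong and how specific is binding?** Titrations (F-EMSA
   fraction bound, or fluorescence polarization in mP) are fit to a
   Hill curve; replicate K_d values are aggregated and converted to
   ΔG°/ΔΔG° with propagated uncertainty.

A seeded synthetic-data generator emulates all inputs (promoter
windows with planted degenerate motifs, selection-enriched read pools,
noisy titrations), so the whole pipeline runs without any external
download.

## The model in brief

**PWM score.** For consensus base probability *p* (default 0.85) and
background *b*, position *i* scores `log2(p_i(base)/b(base))` bits; a
7-mer's score is the positional sum, and the consensus is the unique
maximum over all 4⁷ 7-mers.

**Similarity index.** Each 7-mer score *s* gets an empirical p-value
against *N* scores of composition-permuted promoter sequence
(default N = 100,000):

    p = (1 + #{null ≥ s}) / (N + 1),      index = −log10(p)

Group differences use the per-gene maximum index in +10..+30, compared
by a two-sample Kolmogorov–Smirnov test and Welch's unequal-variance
t-test.

**Binding.** `response = B + A·[P]ⁿ / (K_dⁿ + [P]ⁿ)` fit by nonlinear
least squares (B = 0, A = 1 fixed for fraction-bound data), then

    ΔG° = −RT ln K_d,   ΔΔG° = −RT ln(K_d,A / K_d,B)

with R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹, T = 298 K by default;
|ΔΔG°| = RT·ln 2 ≈ 0.41 kcal/mol per two-fold affinity change.

## Worked example

```python
import nbescan as nb
from nbescan.datasets import get_affinity

# 1. promoter scan on synthetic paused/non-paused promoters
windows, truth = nb.simulate_promoters(nb.PromoterSimConfig(seed=7))
pwm = nb.build_pwm("CUGAGGA", match_probability=0.85)
results = nb.PromoterScanModel(windows, pwm).fit(null_n=10_000, seed=8)
print(results.summary())

# 2. specificity of the humanized Drosophila NELF-E mutant
ddg = nb.delta_delta_g(get_affinity("dNELF-E(mut)", "NApt1min"),
                       get_affinity("dNELF-E(mut)", "TAR"))
print(ddg)

# 3. Hill fit of a simulated F-EMSA titration (true Kd 44 nM)
series, _ = nb.simulate_titration(nb.BindingSimConfig(kd_nM=44.0, seed=9))
print(nb.fit_hill(series[0]).summary())
```

prints

```
Promoter scan results
  genes scanned : 1000
  consensus     : CUGAGGA (match p = 0.85)
  null          : 10000 scores, scheme=window_permute, seed=8
Pause-region similarity comparison (+10..+30)
  paused: n=500, mean max index=2.586
  non_paused: n=500, mean max index=1.593
  KS test:      D=0.4320, p=2.86e-42
  Welch t-test: t=16.0273, p=6.65e-51
ddG = -0.154 +- 0.087 kcal/mol @ 298 K
Hill fit (FEMSA, sim x sim)
  Kd        = 43.91 +- 4.6 nM
  Hill n    = 0.935 +- 0.081
  amplitude = 1 +- 0
  baseline  = 0 +- 0
  RSS = 0.02436, converged = True
```

Reading the output: paused genes carry a planted NBE near +25 six
times more often than non-paused genes, and both tests resolve the
group difference decisively. The ΔΔG° of −0.15 kcal/mol says the
humanized mutant binds the SELEX aptamer and HIV-1 TAR with nearly the
same free energy (well under the 0.5 kcal/mol ≈ two-fold-change
guide). The Hill fit recovers the simulated K_d of 44 nM within its
standard error.

The same stages are available from the shell:

```sh
nbe-scan simulate promoters --seed 7 -o sim/
nbe-scan scan --fasta sim/promoters.fasta --groups sim/groups.tsv \
    --null-n 10000 --seed 8 -o scan_out/
nbe-scan selex --pattern CUGAGGA --mismatches 1 \
    --target selected.fastq --control control.fastq -o selex_out/
nbe-scan fit --titration rep1.tsv --titration rep2.tsv --fix-n -o kd.json
nbe-scan ddg --kd-a 350 --sd-a 50 --kd-b 270 --sd-b 10
```

Coordinate conventions: BED input is 0-based half-open (TSS = `start`
on `+`, `end−1` on `−`); window offsets are TSS-anchored with offset 0
at the first transcribed base, and a 7-mer is assigned the offset of
its 5′-most base.

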