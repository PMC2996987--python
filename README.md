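# oscan

Out-of-frame stop codon (hidden stop) analysis for prokaryotic coding
sequences.

A stop trinucleotide read in a shifted reading frame of a gene — frame +2
(one nucleotide downstream, the frame after a +1 ribosomal frameshift) or
frame +3 (−1 frameshift) — terminates translation shortly after an
accidental frameshift, limiting the cost of frameshift peptides. The
*ambush hypothesis* predicts that coding sequences are selected to carry an
excess of these out-of-frame stop codons (OSCs). Whether a genome has
"more OSCs than expected" depends entirely on the null model: OSC counts
are driven by G+C content, codon usage, codon-pair (dicodon) bias and
phase-specific oligonucleotide bias, and the coding frame's own avoidance
of in-frame stops skews shifted-frame trinucleotide statistics, which is
why naive k-mer odds ratios are inadequate here.

`oscan` is for comparative genomicists who want that question answered per
genome with explicit, nested null models:

* **counting** — per-gene and per-genome OSC counts and densities (per 100
  codons) in frames +2/+3, stop-codon usage bias per frame, G+C (overall
  and per codon position), GC/AT skews;
* **null models** — maximum-likelihood, zero-pseudocount models trained on
  each genome's own CDS: i.i.d. codon usage, dipeptide chain, dicodon
  chain, and three-periodic (phase-aware) nucleotide Markov models of
  order 2 and 5; all generate stop-free random genes matching the
  genome's gene-length multiset;
* **inference** — Monte Carlo expected densities (200 trials by default),
  one-sample t-test of observed vs expected, Benjamini-Hochberg FDR across
  genomes, percentage deviation 100·(obs − E)/E; an exact closed-form
  expectation for the i.i.d. model serves as an internal oracle;
* **statistics** — paired frame tests, PCA of usage bias, OLS with nested
  ANOVA comparison, stepwise AIC, PMVD relative importance with bootstrap,
  Spearman correlation;
* **synthesis** — generator of stop-free synthetic genomes with controlled
  G+C (exponential tilting), gene-length distribution, translation table
  (11, 4, 2, 3, 13) and an optionally planted dicodon-level OSC excess,
  so the whole pipeline is testable without downloads.

## Worked example

```python
from oscan import (SynthesisSpec, synth_genome, genome_osc_stats,
                   composition_stats, run_expectation)

genome = synth_genome(SynthesisSpec(n_genes=200, gc_target=0.45, seed=42,
                                    osc_excess_epsilon=0.02))
obs = genome_osc_stats(genome)
comp = composition_stats(genome)
print(f"genes: {len(genome.cds)}   codons: {obs.total_codons}   G+C: {comp.gc:.3f}")
print(f"observed OSC density: +2 {obs.density2:.3f}  +3 {obs.density3:.3f}  "
      f"total {obs.density_total:.3f} per 100 codons")

res = run_expectation(genome, "codon_usage", n_trials=200, seed=1)
fs = res.frames["both"]
print(f"expected under codon-usage model: {fs.mean_expected:.3f} ± {fs.sd_expected:.3f}")
print(f"pct deviation: {fs.pct_deviation:+.2f}%   t = {fs.t_stat:.1f}   "
      f"p = {fs.p_value:.3g}   direction = {fs.direction}")
```

Output:

```
genes: 200   codons: 60000   G+C: 0.450
observed OSC density: +2 6.565  +3 6.340  total 12.905 per 100 codons
expected under codon-usage model: 12.834 ± 0.129
pct deviation: +0.55%   t = -7.8   p = 3.77e-13   direction = over
```

The genome was synthesised with a small dicodon-level OSC excess planted
(ε = 0.02), and the analysis flags it: observed density (12.905/100
codons) exceeds the mean over 200 genomes simulated from the i.i.d.
codon-usage model fitted to this genome (12.834 ± 0.129), a deviation of
+0.55% called as overrepresentation. Part of the planted excess is
absorbed by the refit codon frequencies — docs/methods.md quantifies this.
Each result also carries `p_pred`, a calibrated alternative p-value that
treats the observed density as a single draw from the trial distribution;
the primary t-test is the far more sensitive detection statistic.

Real genomes enter through the same interface: a manifest TSV (columns
`path format organism genus division table_id ogt_category ogt_celsius`)
pointing at GenBank or FASTA files, e.g.

```sh
oscan synth --n-genomes 3 --seed 5 --out genomes/
oscan all --manifest genomes/manifest.tsv \
      --models periodic2,periodic5,codon,dicodon,dipeptide \
      --trials 200 --seed 42 --alpha 0.05 --out results/
```

which writes `metrics.tsv` (one row of densities/usage/composition per
genome), `expectation.tsv` (one row per genome × model × frame) and
`summary.json` (over/under/ns tallies per model and frame).

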