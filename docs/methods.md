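# Methods

## The quantity under study

An out-of-frame stop codon (OSC, "hidden stop") is a stop trinucleotide
read in one of the two shifted reading frames of a protein-coding
sequence: frame +2 starts one nucleotide downstream of the annotated frame
(the frame a ribosome sees after a +1 frameshift), frame +3 two
nucleotides downstream (a −1 frameshift). OSCs terminate translation soon
after an accidental frameshift and so cap the metabolic cost of frameshift
peptides; the ambush hypothesis predicts selection for an excess of them.
`oscan` measures that excess: it compares each genome's observed OSC
density against the density expected under null models that preserve
successively richer layers of coding-sequence composition.

Within one CDS of L codons, each shifted frame is scanned as
non-overlapping triplets (L − 1 windows per frame), and every window spans
exactly one junction of adjacent codons: frame +2 reads the last two
nucleotides of codon *i* plus the first of codon *i+1*, frame +3 the last
nucleotide of codon *i* plus the first two of codon *i+1*. No window spans
a gene boundary. Densities are reported per 100 codons with the genome's
total sense-codon count as denominator.

## Sequence handling

CDS come from GenBank flat files (coding-strand extraction via the feature
location) or pre-curated multi-FASTA. Filters: annotated pseudogenes,
sequences with ambiguous bases, lengths not divisible by 3, CDS with
internal in-frame stops (annotation artifacts, selenoproteins), and genes
shorter than 100 sense codons are excluded, each tallied by reason.
Terminal stop codons are stripped by default (`keep_terminal_stop`
restores them) so that every retained sequence consists of sense codons
only; this removes all special-casing between nucleotide-level and
codon-level models, and the minimum-length filter counts the remaining
sense codons, which makes filtering idempotent. Genetic codes are NCBI
translation tables (11 default; 4, 2, 3, 13 supported), taken from
Biopython; only the stop-codon set and the forward table are used.

## Null models

Two nested model families are fitted per genome by maximum likelihood with
zero pseudocounts:

* **codon-based chains** — `codon_usage` (i.i.d. sense codons),
  `dipeptide` (first-order chain over amino acids, with synonymous codons
  drawn from genome-wide usage within each amino acid), `dicodon`
  (first-order chain over codons). The i.i.d. model is the special case of
  both chains with constant rows.
* **three-periodic nucleotide chains** of order m (m = 2 and 5 in
  practice; any m ≥ 1 is supported): the transition table for a position
  depends on its codon phase (0-based index mod 3), capturing
  phase-specific trinucleotide (m = 2) and hexanucleotide (m = 5) bias.

Zero pseudocounts matter: a chain trained on stop-free genes assigns
probability zero to any emission that would complete an in-frame stop, so
in-frame stop avoidance — the feature that makes naive k-mer odds ratios
inapplicable to this problem — is preserved exactly. Smoothing would leak
stop codons into the reading frame.

Generation details (all open choices, resolved as follows):

* Unseen order-m contexts back off to the longest shorter context with
  data at the same phase; lower-order tables are obtained by marginalising
  the full-order count table. Stop-completing emissions are masked at
  every back-off order, so generated genes are stop-free by construction,
  not merely with high probability.
* The initial m-mer of each gene is drawn from the empirical distribution
  of gene-initial m-mers (start codons emerge naturally rather than being
  forced).
* A dicodon/dipeptide chain state with no outgoing transitions restarts
  from the marginal distribution; this is unreachable for training-set
  states but guards generated-data edge cases.
* Simulated genomes reproduce the exact multiset of the target genome's
  gene lengths.
* RNG is NumPy's MT19937 (Mersenne-Twister) behind `numpy.random.Generator`;
  one stream is derived per (master seed, trial index) and genes within a
  trial are generated sequentially from that stream, which keeps results
  independent of execution order while allowing whole-trial vectorised
  sampling for the i.i.d. model.

## Monte Carlo expectation and tests

For each genome × model, 200 trials (configurable) each generate a full
synthetic genome and score it; per-trial densities for frames +2, +3 and
both form the null sample. The observed density is compared with the
one-sample t-test taking the simulated values as the sample and the
observed density as the reference constant, two-tailed; q-values are
Benjamini-Hochberg across genomes within each (model, frame) family at
α = 0.05, and the percentage deviation 100·(observed − mean expected)/mean
expected is positive for overrepresentation.

This reference-value t statistic divides the observed-vs-mean gap by the
standard error of the simulated mean (SD/√n_trials). Because the observed
genome is itself one realisation on the single-trial scale, the statistic
grows like √n_trials under a true null: it is a sensitive ranking
statistic but an anticonservative significance measure. Each result
therefore also carries `p_pred`, the calibrated prediction-interval
alternative that treats the observed density as one draw from the trial
distribution (t on the gap divided by SD·√(1 + 1/n)); under a true null
its distribution is uniform, which the test suite verifies. Directions and
q-values follow the primary t-test.

For the i.i.d. codon model the expectation is also available in closed
form: every shifted-frame window spans one codon junction, so
E[N_f] = (L − 1)·p_f per gene with p_f obtained by enumerating all sense
codon pairs. A marginal-propagation analogue exists for dicodon chains.
These oracles are independent of the Monte Carlo path and anchor its
correctness in the tests (agreement within 3 standard errors at 200
trials).

## Descriptive statistics

Per-gene frame asymmetry uses a paired t-test on (n2 − n3). OSC usage bias
(relative frequencies of the stop codons within each shifted frame,
normalised per frame — two simplices of three, matching the per-frame
analyses the usage bias feeds) is summarised by PCA on the centered,
unscaled matrix (all variables share the frequency scale); component signs
are fixed by making each component's largest-magnitude loading positive.
OLS regressions (statsmodels) support nested-model ANOVA F-tests and
stepwise AIC selection (Gaussian AIC, greedy add/drop from the full model,
ties broken by column order). Relative importance uses proportional
marginal variance decomposition: sequential R² increments averaged over
all p! regressor orderings with Feldman's data-dependent weights (each
ordering weighted by the product over its prefixes of the inverse
remaining unexplained variance), computed by exact enumeration (p ≤ 6) —
the designs of interest have at most the three positional G+C fractions —
with case-resampling bootstrap percentile intervals (1000 replicates by
default). For orthogonal designs PMVD reduces to the LMG (equal-weight)
decomposition and both equal the marginal R² contributions, which the
tests exploit as a closed-form check; shares always sum to the model R².
The growth-temperature analysis regresses percentage deviation on OGT plus
G+C and AT skew, mapping categorical labels (psychrophile 10, mesophile
37, thermophile 60, hyperthermophile 85 °C) to midpoints when no numeric
optimum is available.

## Synthetic genomes

The synthesis module generates stop-free CDS sets with controlled
composition so every stage is testable without external data:

* **G+C targeting** by exponential tilting: sense-codon frequencies are
  reweighted by exp(λ·gc(codon)) with λ solved by Brent root-finding so
  the expected coding G+C hits the target (tolerance 1e-4). Tilting a
  uniform base distribution factorises across codon positions, so the
  three positional G+C fractions are nearly equal ("positionally
  unbiased").
* **Planted OSC excess** on the dicodon chain: transitions into codon
  pairs whose junction forms an OSC (either frame) are multiplied by
  (1 + ε) and rows renormalised — junction-local selection on codon pairs,
  scorable exactly by the dicodon oracle. ε = −1 removes junction OSCs
  entirely.
* Default gene length 300 codons (fixed, keeps tests fast); a lognormal
  option (median 300, σ 0.4, floor 100) adds length realism. Default
  G+C 0.5, the centre of the prokaryotic range.

Two planted-excess facts discovered with the oracles, relevant to
interpreting recovery experiments: (i) row renormalisation and the
marginal drift of the chain's stationary distribution mean that the
realised chain-vs-i.i.d. excess at ε = 0.02 is ≈1.3%, not 2%; (ii) when
the i.i.d. expectation model is refit on the planted genome itself — as
the expectation pipeline does — the refit marginal absorbs part of the
excess, leaving a measured deviation of ≈0.95% at G+C 0.5 (larger at
higher G+C). Mean measured deviation is strictly increasing in ε, which is
the property the suite asserts.

What the generator does not emulate: real operon structure, amino-acid
composition constraints, strand-specific mutational skews (generated
genomes have near-zero GC/AT skew), horizontal transfer mosaicism, and
annotation noise. Passing tests therefore demonstrate correctness of the
counting, modelling and inference machinery under controlled composition,
not the empirical prevalence of OSC selection in real genomes — that
question requires running the same pipeline on annotated genomes via the
manifest interface.

## Problem sizes

Defaults used by the test suite and the reproduction script: genomes of
40-400 genes × 150-300 codons (up to 10⁵ codons), 200 Monte Carlo trials
per genome, 10⁶ nt for parameter-recovery checks, 100-genome cohorts for
null-calibration experiments, G+C sweeps over {0.30…0.70}. These sizes
give sampling errors comfortably below the tolerances asserted while
keeping a full run in minutes on one core.

## Known limitations

* Exact analytic OSC expectations exist only for the i.i.d. codon model
  and the dicodon chain; periodic and dipeptide models rely on Monte
  Carlo.
* The primary p-value is the reference-value t-test described above;
  treat it as a ranking/detection statistic and use `p_pred` when a
  calibrated error rate is needed.
* Orders ≥ 6 are not offered (parameter counts outgrow prokaryotic
  genome sizes).
* No gene prediction and no download client: annotations are taken as
  given via GenBank/FASTA plus a manifest TSV.
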