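# Methods

## Screen model

A pooled shRNA dropout screen infects a cell population with a barcoded
knockdown library (5 shRNA species per gene by default), splits it into an
untreated control arm and a drug-treated arm, and reads construct abundance
out by barcode sequencing. A gene whose knockdown *sensitizes* cells to the
drug loses representation in the treated arm; its protein product "protects"
against the drug and is a candidate target for a synergistic partner
compound.

The simulator models barcode counts as negative binomial with mean `nb_mean`
and dispersion φ (variance μ + μ²/φ) — the standard over-dispersion model
for sequencing counts. Treatment multiplies the expected count by a survival
factor s:

- s = 1 − `kill_fraction` for ordinary shRNAs (default kill 0.9: the
  treatment kills about 90% of cells at the screening dose), and
- s = (1 − `kill_fraction`) · β for shRNAs of planted sensitizer genes,
  where β = `sensitizer_survival_multiplier` ∈ (0, 1] is the effect size
  (default 0.1, a strong sensitizer).

A multiplicative survival factor applied only under treatment is the
simplest mechanism producing under-representation of sensitizer shRNAs, and
makes the expected depth-normalized treated:control ratio of a sensitizer
shRNA equal β up to the renormalization induced by fixing sequencing depth
(negligible when sensitizers are a small fraction of the library). If
`reads_per_sample` is set, each arm is multinomially resampled to that fixed
depth, emulating a sequencer; otherwise raw NB counts are returned.

Barcodes are random 18-mers drawn by rejection so that all pairwise Hamming
distances are ≥ 3, which makes 1-mismatch assignment provably unambiguous
(a read barcode within distance 1 of two library barcodes would force those
barcodes within distance 2 of each other). Read emission writes
left-anchor + barcode + right-anchor with independent per-base substitution
errors in the barcode and constant placeholder qualities (Q30); quality
values are ignored downstream.

What the simulator does **not** model: PCR chimeras, index hopping, GC bias,
indels in reads, cell-lineage drift, or infection multiplicity. Passing
tests therefore demonstrate correctness of the deconvolution/hit-calling
arithmetic under a clean noise model, not robustness to those artefacts in
real sequencing data.

## Deconvolution

Barcode extraction matches the last 8 bases of the left anchor exactly
(configurable; the full primer sequences of a given assay should be supplied
as the library's anchors) and takes the following `barcode_length` bases.
Assignment allows at most one mismatch by default; an exact match always
wins, and a read equidistant from two library barcodes is unassigned rather
than guessed. Reads are scanned on the given strand only, since amplicon
orientation is fixed by nested PCR. The count table maintains the
conservation invariant assigned + unassigned = total per sample.

## Hit calling

Counts are normalized to counts-per-million over assigned reads ("relative
representation" made concrete as CPM). Each shRNA's ratio is
r = (CPM_treated + c)/(CPM_control + c) with pseudocount c = 0.5 by default,
which keeps ratios finite for shRNAs that drop to zero; with c = 0, shRNAs
at zero control CPM are flagged unusable and excluded. The two calling
criteria are taken literally: a gene is a hit when **at least 3** of its
species have r **strictly below 0.3**. "Similar changes" is operationalized
as each counted species individually passing the ratio criterion; no
additional concordance statistic is imposed, and no multiple-testing
correction is applied — the procedure is threshold-based, not p-value-based.
Output ordering is deterministic: n_depleted descending, median ratio
ascending, then gene id.

## Over-representation

The enrichment stage is a hypergeometric over-representation analysis (ORA)
of the binary hit list: for a set with K members inside the assayed universe
of N genes, of which k are among the n hits, p = P(X ≥ k) under the
hypergeometric null, with Benjamini–Hochberg adjustment across sets. This is
a deliberate, transparent substitution for rank-based GSEA-style enrichment
plus network/compound-database lookups: ORA needs only the hit list and the
screen universe, is exactly testable by combinatorial enumeration, and uses
the screen's assayed genes — not the whole genome — as the correct
background. Identifiers are matched case-insensitively after whitespace
stripping; no alias mapping is attempted. Sets with fewer than 3 universe
members after trimming are excluded; the default reporting cutoff is
q < 0.05.

## Median-effect and combination-index analysis

Single-agent dose–response follows the median-effect equation
fa/fu = (D/Dm)^m, fitted by ordinary least squares on
(log10 D, log10(fa/fu)). Points with fa ∈ {0, 1} have undefined logits and
are excluded with a warning rather than clipped, because clipping biases the
slope; at least two interior points are required. A non-positive fitted
slope is flagged (`monotone = False`) and refuses inversion instead of
silently producing nonsense doses.

The combination index uses the two-term Loewe form CI = d1/Dx1 + d2/Dx2
with no product term — the form under which a drug is exactly additive with
itself (sham-combination identity, verified to 1e-9). Both fixed-ratio
designs (total dose + ratio) and arbitrary (d1, d2, fa) triplets are
accepted, since practical experiments often test a single fixed subtoxic
dose pair per partner drug. Classification uses a tolerance band τ = 0.05
around CI = 1: synergy below 1 − τ, antagonism above 1 + τ. The combination
simulator places dose pairs on a fixed ratio ray so that the Loewe sum
equals a planted α at every grid effect level, giving an exact ground truth
for recovery tests; optional noise is Gaussian on logit(fa).

## In-vivo burden

Trajectories of %-labelled cells follow
percent(t) = baseline · exp(rate · t), capped at 100%, with lognormal
mouse-level noise of unit mean and specified coefficient of variation
(noise on a percentage is multiplicative; the cap reflects the measurement
ceiling). Defaults: baseline 7% (the burden at which treatment typically
starts in the xenograft design emulated), 4 mice per group, sampling days
0/11/24. Fold changes are per-mouse ratios to baseline; the group summary
uses the geometric mean of fold changes (ratios are log-scaled quantities)
and the sample SD (n − 1) of percentages, reported as absent for singleton
groups. Significance testing (e.g. two-way ANOVA) is out of scope; the
summary table is what such a test would consume.

## Numerical and design choices

- All RNG flows through explicit integer seeds (numpy `default_rng`); no
  global state, and identical seeds give bit-identical outputs.
- Hit-call tie-breaks, enrichment ordering (p, then set name) and report
  formats are deterministic.
- The hypergeometric tail is computed by `scipy.stats.hypergeom.sf`, BH by
  `statsmodels`; tests verify both against exhaustive enumeration and
  hand-computed step-up examples.
- Barcode assignment is served by a precomputed 1-mismatch neighborhood
  index; tests verify equivalence with an exhaustive Hamming scan on random
  libraries.

## Problem sizes

Tests and the acceptance script run on deliberately compact instances chosen
to exercise every code path while completing quickly: screens of 200 genes ×
5 shRNAs at mean count 1000 (dispersion 20) with 10 planted sensitizers for
recovery metrics, 100,000 reads for the read-level round trip, 5–8-point
dose grids for synergy, and 4 mice × 3 days × 2–4 groups in vivo. These
sizes already give stable metrics (sensitivity and false-discovery
proportion are exact 1.0/0.0 at the default effect size across seeds).

## Known limitations

- ORA ignores the magnitude of depletion; a rank-based method could use it.
- The median-effect fit assumes a single-site Hill-type response; biphasic
  curves will fit poorly (visible through low |r|).
- The hit caller's thresholds are fixed rules, not error-controlled
  statistics; the false-positive behaviour depends on sequencing depth and
  dispersion (calibrated here only under the simulator's NB model).
- Deconvolution handles substitutions but not indels, which shift the
  barcode frame and land in the unassigned tally.
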