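# Methods

This note documents the models, conventions and numerical choices behind
`mirscreen`, and what the synthetic generators do and do not emulate.

## Coordinates and hairpin geometry

All coordinates are 0-based, half-open internally; GFF3's 1-based inclusive
convention is converted once at the parsing boundary. RNA input is mapped to
the DNA alphabet (U→T) on ingestion so a single alphabet serves all matching.

A hairpin's stem/loop map comes from its annotated mature arms, not from
secondary-structure folding: positions inside either mature arm are stem, the
interval strictly between the arms is loop, and unannotated flanks adopt the
nearest arm's stem label. When only one arm is annotated there is no
principled loop boundary, so we use a deterministic geometric rule: the
missing arm is taken as the mirror image of the annotated arm about the
sequence midpoint and the loop is the interval strictly between arm and
mirror (empty when they touch or cross). This is conservative — it never
shrinks the loop relative to the two-arm case for symmetric hairpins — and is
fully testable; it is our convention, chosen because the single-arm case is
otherwise undefined.

A guide's region class is decided by its **cut-site** position (the boundary
3 nt 5' of the PAM), because the indel forms at the cut; the protospacer span
is irrelevant to where the lesion lands.

## Seed sites

The miRNA seed is positions 2–7 (position 1 = 5' nucleotide). Canonical site
classes on the UTR: 6mer (Watson–Crick complement of the seed), 7mer-m8
(pairing extended to position 8), 7mer-A1 (adenosine opposite position 1),
8mer (both). Every seed-complementary locus is reported once at its strongest
class; positions containing N never match. Site mutagenesis replaces the UTR
bases pairing seed positions 3–7 (a pentamer) with a caller-supplied
UTR-strand replacement, leaving every other base untouched.

## Guide design

* On-target scores are **inputs** (TSV keyed by protospacer). Efficiency
  models of the Rule Set 2 / Azimuth family are trained predictors; this
  package consumes their output and supplies a deterministic hash-based
  surrogate for fixtures.
* The CFD score is the product of per-position mismatch penalties and a PAM
  penalty; matched positions contribute 1.0, and a missing table key is an
  error (never a silent default).
* "Bin I" off-targets are counted as loci with CFD ≥ a configurable
  threshold, default 1.0 (perfect-cutting loci). The upstream designer's bin
  taxonomy is not public, so the threshold is exposed in the API; the
  exclusion rule (count > 3) applies to whatever bin is configured.
* Filter thresholds are exclusive exactly as specified: a guide is dropped
  iff score < 0.2 or bin-I count > 3; boundary values are kept.
* Selection is per-hairpin: all non-loop candidates strictly precede loop
  candidates; within a stratum the order is (higher on-target score, fewer
  bin-I loci, lexicographic protospacer), which makes manifests byte-identical
  across reruns. Hairpins with fewer than 3 surviving candidates are
  excluded.
* Non-targeting padding solves k = f·n/(1−f) and rounds half-away-from-zero
  (74 guides for a 7,332-guide library at f = 0.01); sampling is without
  replacement under the run seed.
* Off-target enumeration is an exhaustive scan intended for fixture-scale
  genomes (kilobases); there is deliberately no genome-scale index.

## Screen analysis

Counts are scaled to 10⁷ reads per sample, and fold changes use a
pseudocount of 5: fc = log2((norm + 5)/(norm_T0 + 5)). These are the
documented conventions of the BAGEL tool family; both are parameters.

The Bayes factor is supervised: per iteration the essential and
non-essential reference gene lists are bootstrap-resampled (with
replacement, same size), Gaussian KDEs (Scott bandwidth) of the drawn
genes' terminal-timepoint guide fold changes (all replicates pooled) form
the two class densities, and every gene absent from the training draw is
scored by the summed log2 density ratio of its observations. The final BF is
the mean over the iterations in which the gene was scored; reference genes
are therefore scored on their out-of-bag iterations. Densities are evaluated
on a fixed 512-point grid spanning the data ±1 and linearly interpolated —
this makes 1000 iterations on a ~7,400-guide screen run in well under a
minute — and floored at 2⁻³⁰ to contain log-ratios for out-of-support fold
changes without affecting ranks.

FDR is 1 − precision from the walk down the BF ranking over reference genes,
with tie blocks sharing the precision at their block boundary and a
cumulative-maximum monotonisation so FDR never decreases with decreasing BF.
PR-AUC over the reference genes (average precision) supports choosing the
analysis timepoint. The hit rule is strict: BF > 0 **and** FDR < 0.1.

## Synthetic screens

The generator models a pooled dropout screen minimally but with the
statistical structure the analysis assumes: T0 guide abundances are
log-normal around the culture representation (default 1000 cells/guide,
σ = 0.5); a guide with depletion rate e (log2 units at the terminal
timepoint, default −4 for planted essential miRNAs and essential-control
genes) decays multiplicatively as 2^(e·t/T); sequencing is a multinomial
draw of depth × n_guides reads per sample (default 500×); and a gamma
multiplier (dispersion 0.1) adds replicate-to-replicate overdispersion.
Guide efficiency varies multiplicatively (normal, mean 1, sd 0.15), so a
zero effect is a true null. Default timepoints are 9/18/27 population
days with three replicates, matching a 27-day screen passaged in thirds.

Not emulated: multiplicity-of-infection effects (single-integration
assumption — infection statistics do not alter the count model at this
scale), guide-level off-target toxicity, copy-number artefacts, read-level
errors, or batch effects. Passing tests therefore demonstrate correctness of
the estimator under its own generative assumptions, not robustness to every
real-screen pathology.

The default synthetic manifest reproduces the target library composition:
1,649 hairpin targets carrying 6,532 guides (64 targets at 3 guides, the
rest at 4), 100 + 100 control genes at 4 guides, and 74 non-targeting
guides (7,406 total).

## Dose-response and synergy

The 4PL model is response = bottom + (top − bottom)/(1 + (d/EC50)^h), with
the dose-0 limit handled analytically (top for h > 0). Initialisation is
deterministic from the data (top/bottom from the response range, EC50 from
the geometric mean of positive doses, slope sign from the dose-ordered
trend); flat responses are rejected as unidentifiable rather than fitted.
The reported IC50 is the relative (curve-midpoint) EC50, the standard 4PL
convention.

ZIP scoring converts viability to inhibition y = 1 − v/100, fits 4PL curves
to both monotherapy margins, forms the zero-interaction expectation
y_A + y_B − y_A·y_B from the fitted (clipped to [0,1]) margins, and averages
δ = (observed − expected)·100 over all combination wells. No surface
smoothing or baseline correction is applied — the score is the plain mean-δ
ZIP estimand — so scores from tools that add such corrections can differ
slightly. Classification uses the conventional closed interval: < 0
antagonistic, 0–5 additive (boundaries additive), > 5 synergistic.

The surface simulator builds exactly this estimand's null (Bliss combination
of two Hill curves) plus an additive interaction term on combination wells,
so a planted +10% interaction is recovered as a score of ≈10 by
construction.

## Problem sizes in the test suite

Unit and property tests run on fixture-scale inputs (kilobase genomes,
≤ ~1,200-guide screens). The end-to-end recovery check runs at the full
library composition (7,406 guides, 3 replicates) with 300 bootstrap
iterations; `scripts/acceptance.py` uses 1,000 iterations, the analysis
default. Null-screen calibration uses 20 independent seeds at 100 miRNA
targets each. All generators and the BF pipeline are deterministic given
their seeds.

## Known limitations

* Off-target search is exhaustive-scan only; real genome-scale design needs
  an external aligner/indexer upstream.
* The expression filter equates "highly expressed" with the constitutive
  criterion (≥5 reads in ≥80% of lines); no additional magnitude cutoff is
  applied.
* Reference-based FDR is optimistic above the first-ranked reference genes
  (precision is undefined there and treated as 1 before monotonisation);
  this mirrors the behaviour of the underlying method family.
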