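# Methods

## Model

`itempop` treats matrix-based HLA-DRB1 binding prediction as a fixed,
pluggable input and builds the population-level risk assessment on top of
it.  The moving parts, in pipeline order:

**Frame scoring.**  A protein of length L has L−8 overlapping 9-mer
frames (1-based starts).  Each allele is described by a 9×20
position-specific scoring matrix; a frame's raw score is the sum of the
nine position entries (the standard additive PSSM convention).  Raw
scores are standardised to Z-scores against an analytic null: residues
drawn i.i.d. from a background amino-acid distribution, under which the
null mean and variance are sums of per-position background-weighted row
moments.  The default background is uniform over the 20 residues; any
distribution (e.g. proteome frequencies) can be supplied, and the
calibration is deterministic rather than Monte-Carlo.  Matrices whose
null variance is zero are rejected as degenerate.  Cutoffs are inclusive:
Z ≥ 1.64 is a binding "hit", Z ≥ 1.28 a "likely" hit.  Only the 1.64 tier
contributes to aggregate scores; the likely tier is reported but
unscored.

**Protein score.**  With A = frames × alleles assessments, O = Σ Z over
hit cells, and e0 = E[Z·1{Z ≥ θ}] = φ(θ) (standard-normal density at the
hit cutoff, ≈ 0.10396 at θ = 1.64), the score is (O − A·e0)/A × 1000 —
excess hit-weighted Z content per 1000 assessments.  This form is
zero-centred for background-random proteins, deterministic given the
inputs, and spans roughly ±100 in practice; a protein with no hits at all
sits at −e0·1000 ≈ −103.96.  Aggregating hit Z magnitudes (not hit
counts) was a design choice: it preserves the strength of strong binders
and makes the null expectation analytic.

**Tregitope adjustment.**  Regulatory T-cell epitopes are supplied as a
registry of peptides and matched by exact substring (no fuzzy matching);
overlapping matches are merged into maximal spans.  A frame is masked
only if its entire 9-mer lies inside a span — frames straddling a
boundary are kept.  The adjusted score zeroes masked frames'
contributions to O while leaving A unchanged, which guarantees
adjusted ≤ raw.  The proteome benchmark annotations shipped with score
reports (human proteome median −9.05, secreted-protein median −23.08)
derive from the original proprietary matrices; they are metadata for
orienting the scale and are not recomputable here — nor are published
absolute scores for specific biologics, which is why the test suite
replaces them with the synthetic-data properties below.

**Population weighting.**  Carrier frequency is the fraction of
individuals carrying at least one copy of an allele.  Multi-study records
are aggregated by sample-size-weighted mean, with alleles unreported by a
contributing study counted as 0 % in that study (renormalising over
reporting studies only is available as a flag).  The analysis panel keeps
alleles carried at > 1 % (strict) in at least one population.  Weighted
scores use carrier fractions restricted to the panel and renormalised to
sum to 1, so scores are comparable across populations with different
panel coverage; uniform weights recover the unweighted score exactly.

**Resampling.**  The frequency tables are point estimates; their sampling
uncertainty is propagated with a parametric bootstrap: each resample
redraws every panel allele's carrier count Binomial(total_n, carrier)
independently at the population's aggregated sample size (drawing whole
constituent studies is a config mode when per-study data exist; a joint
Dirichlet draw was considered and rejected because carrier fractions of
different alleles are not a partition of unity).  100 resamples per
population by default.  Resample i of every population uses the same
per-index RNG substream (`SeedSequence(seed, spawn_key=(i,))`), giving
common random numbers across populations, so the i-th scores form a
matched pair.

**Comparison.**  Populations are compared per protein by the two-sided
Wilcoxon signed-rank test on the index-paired resample scores (exact null
for n ≤ 25 without ties, normal approximation with tie correction
otherwise; zero differences dropped by the classic convention, Pratt as
an option).  Medians are reported descriptively alongside.  When a
protein has identical scores in every resample (e.g. zero predicted
hits), the comparison is reported as degenerate rather than tested.
Effect size is the matched-pairs rank-biserial r = (W⁺ − W⁻)/(W⁺ + W⁻),
with categorical interpretation under editable schemes (Cohen-style,
Funder–Ozer-style, and a correlation-strength wording are shipped; none
is privileged).  P-values across proteins are adjusted within each score
type by the six canonical methods {Bonferroni, Holm, Hochberg, Hommel,
BH, BY}.

**Individual (iTEM) scores.**  The same score restricted to one allele
pair: (o_a + o_b − 2F·e0)/(2F) × 1000 for heterozygous pairs,
(o_a − F·e0)/F × 1000 for homozygous (counting the allele once; counting
it twice cancels in the normalisation, so both conventions coincide).
All k(k+1)/2 unordered panel pairs, homozygotes included, form the
per-protein distribution; quartile boundaries are linear-interpolation
quantiles of the adjusted scores, with boundary ties assigned downward
(quartile 1 = lowest risk).

**Differential pairs.**  The joint carrier probability of a pair is the
product of the two carrier fractions (homozygous = square), treating
carriage as independent; Hardy–Weinberg genotype frequencies
(p = 1 − √(1−P); 2·p_a·p_b) are provided as a utility but are not the
default convention, because the carrier-product convention is the one
validated against the packaged reference tables (below).  Pairs with
max joint probability > 5 % and |between-population difference| > 5 %
(both strict) are flagged, labelled by dominant population and sorted by
|difference|.

## Packaged reference data

`itempop/data/table1_carrier_frequencies.csv` holds aggregated HLA-DRB1
carrier percentages for a Japanese and a Caucasian reference population
(26 alleles after the 1 % filter).  On these tables the differential-pair
analysis yields exactly 3 Caucasian-dominant pairs — the unordered pairs
over {DRB1\*03:01, DRB1\*07:01} — and 6 Japanese-dominant pairs — over
{DRB1\*09:01, DRB1\*04:05, DRB1\*15:02}.  The aggregated sample sizes
behind the published percentages are not public; the fixture carries
nominal totals (5 000 Japanese, 20 000 Caucasian, reflecting the 7 vs 27
contributing samples) that affect only bootstrap width, never the
differential-pair counts.

## Synthetic data: what it emulates and what it does not

The generator exists so the full pipeline runs with no proprietary
inputs.  Matrix entries are i.i.d. standard Gaussians, chosen so that the
marginal null of a random 9-mer's raw score is exactly normal and the e0
constant and ≈ 5 % hit rate at Z ≥ 1.64 are provable properties rather
than approximations.  For a *fixed* matrix the null is a sum of nine
discrete uniform draws — close to normal but not exactly, which is why
null-calibration checks compare against each matrix's own Monte-Carlo
null rather than against 0.05 verbatim.

Planted proteins are built constructively: the planted 9-mer takes the
target allele's best residues (greedy argmax first, then sampling among
the top five per position when the argmax leaks an off-target hit at the
planted frame), and every other (frame, allele) cell is driven below the
likely tier by a WalkSAT-style local search — greedy single-residue
changes minimising a squared-hinge penalty on near-threshold cells, with
noise moves to escape local minima, bounded retries, and full
regeneration on failure.  Ground truth is exact, so tests can demand zero
missed plants and zero spurious calls.  Planted constructions default to
4 alleles and ~150 residues: requiring *every* cell of a frame × allele
grid to stay below Z = 1.28 is a dense constraint-satisfaction problem
whose hardness grows quickly with the allele count (at 8 alleles a random
frame is fully clean with probability ≈ 0.9⁸ ≈ 0.43), and the smaller
panel keeps generation reliable and fast without changing what the test
establishes.  Unconstrained random proteins (the null ensemble) are
generated directly at any size.

Synthetic data emulates: allele-specific binding preferences, epitope
and Tregitope placement, carrier-frequency structure with controllable
differential pairs, and paired score samples with a planted location
shift.  It does not emulate: real binding-motif structure (anchor
positions, pocket chemistry), linkage between HLA loci, antibody
framework/CDR architecture, or ATA biology.  Passing tests therefore
establish the *computational* properties of the pipeline — calibration,
recovery, invariants, determinism — not the predictive validity of any
particular matrix set on real biologics.

## Numerical choices

- Threshold comparisons are inclusive (Z = 1.64 is a hit); filter
  comparisons are strict (> 1 %, > 5 %).
- Quartile boundaries use linear interpolation; boundary ties go to the
  lower quartile.
- All randomness flows from `numpy` `SeedSequence`s derived from a single
  seed; resample substreams are keyed by index only, so populations are
  pairable and runs are bit-for-bit reproducible (the run manifest's
  timestamp is the single non-deterministic output field).
- Files carry percentages 0–100 with two decimals; all internal math is
  on fractions.  Coordinates in per-frame/per-span outputs are 1-based
  inclusive.
- Degenerate comparisons (all paired differences zero) and degenerate
  matrices (zero null variance) raise in the low-level API; the model
  layer converts the former into annotated no-difference rows.

## Problem sizes used in the checks

Null calibration uses 200 random proteins of length 300 against 8
matrices (467 200 assessments) plus 10⁶-draw Monte-Carlo nulls per
matrix; planted recovery uses 50 seeded constructions with 1–3 plants;
the Tregitope invariant uses 1 000 random proteins with a 200-peptide
registry; test calibration uses 200 replicates of 50 pairs per condition.
These sizes give Monte-Carlo standard errors comfortably below the
asserted tolerances while keeping the whole suite inside a couple of
minutes.

## Limitations

- The Z-calibration is analytic against a background distribution; the
  original predictor's calibration (per-allele peptide reference sets) is
  not public, so absolute Z-scores from real matrices need not coincide.
- The score's functional form (hit-Z excess per 1000 assessments) matches
  the published scale's behaviour (zero-centred, ±100-ish range) but is a
  reconstruction; published per-biologic values are not reproducible
  without the original matrices and exact sequences.
- Joint carrier probabilities assume independent carriage; real HLA
  haplotype structure violates this, and the convention is validated only
  against the packaged reference tables' differential-pair counts.
- Only HLA-DRB1 is modelled; DP/DQ restriction and non-HLA drivers of
  ATA are out of scope.
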