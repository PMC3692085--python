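# Methods

## The pentamer model

The central assumption is that the time-averaged structural features of a
base pair in duplex B-DNA are determined, to useful accuracy, by its local
sequence context out to the next-nearest neighbor — i.e. by the pentamer
centered on it.  Under that assumption a finite table suffices: there are
4^5 = 1024 pentamers, and because a double helix has no intrinsic reading
direction, a pentamer and its reverse complement describe the same physical
segment, leaving 512 equivalence classes (every odd-length k-mer differs
from its reverse complement, so classes always have two members; for even
k, reverse-complement palindromes make the count (4^k + 4^(k/2))/2, hence
10 dinucleotide and 136 tetranucleotide classes).

Per class the table stores six numbers: MGW and ProT of the central bp, and
Roll and HelT of the two central bp steps (step 1 joins pentamer positions
2–3, step 2 joins 3–4).  These four parameters are invariant under strand
exchange, which is why they can be pooled across strands with no sign
bookkeeping; reverse-complementing a pentamer only exchanges step 1 and
step 2.  Parameters that flip sign under strand exchange (Slide, Tilt, …)
are deliberately out of scope.

## Mining (table construction)

Input is a collection of *structural records*: per-fragment, per-position
measurements from analysed conformational ensembles — two minor-groove
width levels per nucleotide, ProT per bp, Roll/HelT per step.  Each record
is treated as the ensemble average of one fragment; the table averages over
occurrences (records × positions) with equal weight.

**Three-level MGW.**  The groove width assigned to bp *i* is the arithmetic
mean of three consecutive levels of the groove-width ladder: the last level
of nucleotide *i−1* and the two levels of nucleotide *i*.  This symmetric
window makes the value independent of which strand is the leading strand.
Position 1 has no preceding level and is undefined.  Implementation detail:
the two outer levels are summed before the middle one, so the sum is
bitwise invariant when the record is read from the opposite strand.

**Record reversal.**  Reading a record from the opposite strand reverses
ProT per bp and Roll/HelT per step.  The groove-level ladder reverses with
a one-position shift (`flat'[g] = flat[2L−2−g]`, 0-based): a plain reversal
would map the three-level windows (centered on odd ladder indices) onto
even indices, off by one level; the shifted reversal maps each bp's window
exactly onto its partner's.  The single leftover terminal level pads a
position whose MGW is undefined on the original strand and is never mined.

**Trimming.**  By default the outermost 2 bp of every record are excluded
from mining (`trim=2`): fragment ends of simulated DNA fray and their
measurements are not representative.  The exclusion is configurable since
it is a property of the training data, not of the model.

**Strand handling.**  Each occurrence is counted once, from the forward
strand; canonical-class merging alone guarantees strand symmetry.
(`both_strands=True` mines reverse complements too — it exactly doubles
every count and leaves every mean unchanged, and exists so occurrence
counts can be compared against either convention.)  Per-class sums are
accumulated in (class, value)-sorted order, which makes mining a corpus and
mining its reverse-complemented mirror produce bitwise-identical tables
despite floating-point non-associativity.

## Prediction

For a query of length L (5 ≤ L ≤ 10^6 by default; the cap is configurable),
bp *i* with 3 ≤ i ≤ L−2 takes the central-bp entries of the pentamer
centered on it.  A step is covered by up to two pentamers (as step 2 of the
left one and step 1 of the right one); interior steps take the unweighted
mean of the two, boundary steps (2 and L−2) the single covering value.
The unweighted mean is forced by strand invariance: any asymmetric
weighting would break the exact mirror property.  Everything else — the
two terminal bp and one terminal step per end, windows containing non-ACGT
letters, classes absent from an incomplete table — is undefined (NaN in
memory, `NA` on disk).  When one of a step's two covering pentamers is
undefined and the other is not, the defined one is used; a step is NA only
when no covering pentamer is defined.

Coordinates are 1-based and inclusive in the public interface and in output
files (step *s* joins bp *s* and *s+1*, labelled `s-s+1`); internal arrays
are 0-based NumPy arrays.

Prediction is vectorized over precomputed length-1024 lookup arrays indexed
by oriented pentamer code; ~10^6 bp predict in a few seconds on one core,
so chromosome-scale batches are minutes, not hours.

## Validation machinery

**Symmetrization** applies only to self-reverse-complementary sequences
(e.g. CGCGAATTCGCG), whose intrinsic shape must be mirror-symmetric;
averaging element *i* with element *n+1−i* removes crystal-packing
asymmetry from experimental profiles.  It is a projection (idempotent), and
on predictions of palindromes it is a no-op, since class merging already
forces exact symmetry.

**Deformation filtering** excises positions of experimental structures
whose values are unattainable by relaxed B-DNA — MGW > 8.5 Å or < 1.5 Å,
HelT > 45°, |Roll| > 20° (strict inequalities) — along with 3-bp flanks on
each side.  A deformed step invalidates both bp it joins; flank dilation
acts on bp; a step is valid only if both its bp are.  Criteria are
evaluated on the measured side only (the filter exists to remove
crystal-packing and binding artifacts; table-derived predictions cannot
exceed the cutoffs), and the resulting mask is applied to both sides of
every feature.  Flanks never cross structure boundaries because masks are
computed per structure before concatenation.

**Correlation** concatenates per-structure feature vectors, ordered by
position within each structure, into one global vector per feature, and
computes Spearman's ρ with fractional (mean-rank) ties.  The
implementation delegates to `scipy.stats.spearmanr`, with one guard: when
the two rank vectors are identical (or exactly reversed) the result is
returned as ±1.0, since the generic `cov/sqrt(var·var)` route can land one
ulp inside the interval on heavily tied input.  Fewer than 3 valid pairs or
zero rank variance yield NaN with a warning rather than a number.

**Leave-one-out cross-validation** rebuilds the table once per record with
that record's contributions subtracted from precomputed per-class
sufficient statistics (O(#records · (L + 1024)) overall rather than
re-mining from scratch each round), predicts the held-out sequence, pairs
predictions with the record's own measurements at all defined positions,
concatenates across rounds, and reports the four ρ values plus coverage
diagnostics.  Positions whose class is absent from the held-out table are
masked and counted, never imputed.

## The synthetic generator

The generator exists because realistic training data (conformational
ensembles of thousands of fragments) cannot ship with a package; it
produces corpora whose ground truth is known exactly, so the mining and
validation machinery can be tested end to end.

*What it emulates*: per-fragment records with pentamer-determined means
plus i.i.d. Gaussian noise; a training design of 2121 fragments of
12–27 bp (the default), which covers all 512 classes with a mean occurrence
of ~44–48; groove-width ladders whose three-level means equal the intended
per-bp MGW.

*What it does not emulate*: sequence-dependent correlations along the
helix, end-fraying, anharmonic flexibility (e.g. TpA hinge steps), or any
real physics.  Passing tests therefore demonstrate that the machinery is
correct, not that a synthetic table predicts real DNA.

Design choices worth recording:

* **Tetramer-consistent steps.**  A step is covered by two overlapping
  pentamers, so a single ground-truth value per step only exists if the
  pentamer step entries agree wherever they overlap.  Roll and HelT are
  therefore drawn per canonical tetramer (the step plus one flanking bp on
  each side, 136 classes) and expanded into pentamer step entries; MGW and
  ProT are drawn per canonical pentamer.  Without this, zero-noise
  round-trip identity and exact LOOCV could not both hold.
* **Dyadic grid.**  Ground-truth draws are snapped to multiples of 2^−20.
  At these magnitudes all sums/differences of such values are exact in
  doubles, and means of n identical values round back to the value itself,
  so "exact recovery" tests assert bitwise equality instead of a tolerance.
* **Ranges.**  MGW ~ U[4.5, 7.0] Å, ProT ~ U[−20, 0]°, Roll ~ U[−12, 15]°,
  HelT ~ U[29, 41]° — centred on B-DNA norms (5.8 Å, ~35°, ~0°), wide
  enough to give every class a distinct signature, and strictly inside the
  deformation-filter cutoffs so filtering is a no-op on clean data.  The
  MGW range also guarantees positive groove levels after the ladder
  construction below.
* **Groove-level construction.**  Each nucleotide's second level (shared
  by two adjacent bp windows) is set to the mean of the two adjacent bp
  targets; each first level absorbs the remainder (`3t − s_prev − s_self`),
  so the three-level mean is exactly the target while the three levels
  entering a window genuinely differ — the MGW averaging code is tested on
  non-degenerate input, not on a constant ladder.  MGW noise is applied
  per level with sd √3·σ, giving the three-level mean sd σ (adjacent bp
  noise is then weakly correlated through the shared level; the per-class
  recovery error still scales as σ/√n because same-class occurrences sit
  at distinct loci).
* **Coverage by construction.**  Fragments first chop an order-5 de Bruijn
  cycle with overlaps of 4 + 2·trim bp, so every pentamer class lands in
  the minable interior of some fragment; remaining fragments are uniform
  random and raise occurrence counts.  Regeneration from the same seed is
  bit-identical.
* **Terminal filler.**  Positions/steps without a full pentamer/tetramer
  context receive fixed B-DNA anchor values (5.75 Å, −10°, 2°, 35°); they
  are never mined (trim plus window geometry) and never compared
  (predictions are undefined there).

## Problem sizes and degenerate inputs

Tests and the acceptance script use corpora of 150–2121 fragments and
repeat noisy-recovery measurements over 10–20 seeds; these sizes give
full class coverage and stable statistics while keeping the whole suite in
tens of seconds.  Degenerate inputs are specified rather than accidental:
L = 5 predicts exactly one bp (position 3) and two steps (2 and 3); L < 5
is an error; a batch with one bad sequence reports it and continues; an
empty record collection, empty batch, or empty concatenation is an error;
`flank=0` reduces filtering to pure thresholding; records shorter than
2·trim + 5 are logged and skipped.

## Known limitations

* A table is only as good as its training records; the package validates
  machinery, not force fields.
* The deformation filter's criteria are fixed thresholds; borderline values
  exactly at a cutoff are retained (strict inequalities).
* The two-pentamer step average is the only place where overlapping
  information is combined; no smoothing or higher-order context is applied.
* Missing table classes propagate as NA; there is deliberately no
  interpolation between related pentamers.
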