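# Methods

## Definitions and coordinate conventions

All coordinates are 1-based and inclusive on both ends; "position 2" means
the residue right after an initial methionine.  Sequences are upper-case
strings over the 20 standard amino-acid letters plus the ambiguity letters
X, B, Z, U and O.  Ambiguity letters are legal residues but are excluded
from every composition numerator *and* denominator, so all frequency vectors
are over exactly 20 letters.  Every FASTA entry is treated as one protein;
no isoform collapsing is attempted.

## Repeat detection

**Pure regions** are maximal runs of the target residue (default alanine) of
length ≥ `min_len` (default 4).  This is equivalent to requiring `min_len`
target residues in a window of `min_len` and extending until a non-target
residue.

**Impure regions** are found by a window-union search with window 6 and
threshold 4 by default:

1. every window of `window` residues containing ≥ `window_min_count` target
   residues qualifies; windows shorter than `window` at the sequence termini
   qualify under the same count, so a repeat at the C-terminus is called
   exactly as its mirror image at the N-terminus would be;
2. the residue spans of qualifying windows are unioned and merged;
3. each merged span is trimmed so it begins and ends on the target residue
   (an impurity outside the homorepeat proper is not part of the region);
4. spans of final length < 5 or with fewer than `window_min_count` targets
   are dropped;
5. by default, all-target spans are dropped too (they are the pure regions);
   `require_impurity=False` gives the inclusive variant.

The two searches run independently: a protein contributes to both lists and
a pure run may sit inside an impure span.  The exact merging, trimming and
terminal-window choices above are design decisions of this package; they are
parameterised (`window`, `window_min_count`, `min_len`, `require_impurity`)
so their effect on counts can be explored.  Detection is validated against
independent brute-force enumeration (maximal runs; explicit window
enumeration + union) on tens of thousands of random sequences across a
parameter grid.

Count summaries class pure regions by length {4, >4} and impure by
{5, 6, >6}, reporting regions and distinct hosting proteins per class.

## Impurity statistics

Impure regions are stratified by region length (not alanine count) into
classes 5, 6, >6 plus pooled "All".  Per letter: frequency among impurity
occurrences in the class, and the pooled frequency divided by the letter's
proteome background frequency (the All/Bg ratio).  Letters never observed as
impurities get frequency 0 and ratio 0 rather than being absent, keeping the
output schema stable.  An impurity at offset k (1-based) in a region of
length L has relative position (k − ½)/L ∈ (0, 1): the centre of any region
is exactly 0.5, and reversing a region maps x to 1 − x.

## Flank context

Position −j is the residue j places before the region start, +j the residue
j places after the region end (j = 1…10 by default).  Positions outside the
protein reduce that position's denominator; they are never counted as a
pseudo-letter, keeping per-position frequencies comparable.  Flanks are not
masked against other detected regions or against alanine — the alanine
enrichment around polyA is itself a finding, not an artefact.  Each region
is one observation; multiple regions of the same protein enter
independently.  Enrichment is the elementwise frequency/background ratio;
it is an error for a letter with positive flank frequency to have zero
background.  The marker summary reads off single cells (G+1, M−1, S−1, S+1,
V−1, V+1) and averages the P and G rows over all 20 flank positions
(an average over positions, not occurrences, matching the per-position
presentation of the profiles).

## Position within proteins and targeting peptides

Relative position of a region is midpoint/L by default (a long N-terminal
repeat should not look artificially terminal); start/L is retained because
the targeting-peptide table is start-based, and the mode is recorded in all
outputs.  Location stratification uses the closed label set {Nucleus,
Cytoplasm, Mitochondrion, Secreted, Other/Mixed}; unannotated proteins fall
into Other/Mixed; empty groups are omitted and listed.  Pairwise group
comparisons use the package's Mann–Whitney U test, two-sided (conservative
even for directional claims; direction is read from medians), unadjusted by
default with an optional Holm step-down flag.

The Mann–Whitney statistic is the rank-sum U for the first sample with
average ranks for ties.  When min(n₁, n₂) ≤ 8 and there are no ties, the
two-sided p-value is computed from the exact null distribution — the
coefficients of the Gaussian binomial [n₁+n₂ choose n₁]_q, built by exact
integer polynomial arithmetic — as twice the smaller tail, capped at 1.
Otherwise the normal approximation is used with tie-corrected variance
n₁n₂/12 · ((N+1) − Σ(t³−t)/(N(N−1))) and a 0.5 continuity correction.  The
implementation is cross-checked in the test suite against independent
brute-force enumeration and against scipy's asymptotic path, and its null
rejection rate is verified to be calibrated at α = 0.05.

The targeting-peptide table takes the most N-terminal region per protein
(smallest start; ties broken toward the longer region) and classes proteins
by its start: 2 (right after the initial methionine), 3–20, >20.  A region
starting at coordinate 1 has no methionine before it and gets its own class
"1", never counted in "2"; "any" is the sum of all four classes so that
"no polyA" + "any" equals the proteome size exactly.  Proteins missing from
the annotation table count as peptide call "other".  Pure and impure regions
are pooled for this table.

## Structural propensity

The 27 classes are the ordered triples over {α, β, γ}.  The table is a TSV
resource (tripeptide + 27 probability columns, rows validated to sum to 1
within 1e-6); tripeptides absent from the table fall back to the uniform
1/27 vector with a logged, counted warning, so partial fixture tables are
usable.  The published context-integration equation of the original
tripeptide predictor is not public in closed form; this package uses a
declarative substitute honouring the same i±2 context span: residue i takes
the weighted average of the class vectors of tripeptides centred at i−2…i+2
with weights (1, 2, 4, 2, 1), dropping out-of-range neighbours and
renormalising.  Weights are exposed; (0,0,1,0,0) reproduces the raw lookup.
Terminal residues carry no prediction.  Numerical agreement with the
original predictor's published outputs is explicitly not claimed; the
profiles are for comparing positions within one analysis.

Aggregation predicts over each region extended by 12 residues (clipped to
the protein), maps residues to relative positions (0 inside the region,
±1…±12 in the flanks) and averages the reduced fractions per position over
all regions, reporting only ±10 so the outer reported positions are immune
to window-end artefacts.  The reduction conserves probability exactly and
aggregation is linear in the n-weighted sense; both are asserted in tests.

## Emergence classification

A repeat's coordinates are mapped to alignment columns by counting non-gap
reference positions.  Over those columns, gap_fraction is the fraction
gapped in the chosen ortholog; calls are insertion (≥ 0.8), substitution
(≤ 0.2), mixed otherwise.  The thresholds are operational defaults — the
literature narrates this classification over curated cases without stating
cutoffs — and are reported with every call.  Classification is pairwise
(reference vs one ortholog); consensus across orthologs is a loop in the
CLI, not a model.

## Synthetic data

The generator emulates the statistical structure the analyses measure:
i.i.d. background residues (default uniform over 20 letters; any composition
can be supplied), planted pure/impure regions from a per-length plan,
impurity letters drawn from a configurable composition, flank-bias rules,
a start-position rule (a fraction of regions forced to position 2 behind a
forced initial methionine, the rest uniform with 12 residues of clearance),
and annotation couplings (peptide-call probabilities per start class;
location labels drawn from bands of relative position).  One region is
planted per protein, which keeps the truth ledger exhaustive without
modelling inter-region interactions; multi-region proteins are exercised
with hand-built records in the unit tests.

Three guarantees make planted-parameter recovery exact rather than
approximate:

* spontaneous background stretches that the detectors would call are
  rejected and redrawn until detection equals the truth ledger (flag
  `suppress_background_runs`; disable for stress tests);
* planted impure regions never contain an internal alanine run reaching the
  pure threshold, so no nested pure regions appear that the ledger does not
  know about;
* a biased flank position carries its letter with probability exactly p
  (the alternative draw excludes that letter and the target), so the
  planted +1 frequency is p itself, and residues adjacent to planted
  regions are never the target, so planted coordinates are maximal.

The study-condition spec used for end-to-end validation plants 1000
proteins (lengths 150–400), 300 pure and 400 impure regions (600 impurity
occurrences), proline impurities at exactly 3× background (the remaining
mass shared proportionally), glycine at +1 with probability 0.4, 30% of
regions at start 2, and mTP probability 0.5 for start-class-2 proteins vs
0.02 elsewhere.  These sizes give 3-standard-error recovery bands of about
±0.9 on the proline ratio, ±0.056 on the +1 frequency and ±10 percentage
points on %mTP, and the whole battery runs in seconds.

What the generator does *not* emulate: realistic amino-acid composition
correlations along sequences, isoform redundancy, evolutionary divergence,
multiple repeats per protein, or codon-level structure.  Passing recovery
tests therefore demonstrates correctness of the measurement machinery under
the stated sampling model, not biological conclusions about real proteomes —
those require real proteome FASTA and annotation inputs, which the same
pipeline consumes unchanged.

The propensity fixture generator builds a caricature table: the all-alanine
tripeptide gets its helix mass directly (ααα = bias), G/P-containing
tripeptides share a chosen Others mass over the 25 non-ααα/βββ classes, the
remainder is uniform with optional jitter.  With all biases at 0 the table
is exactly uniform — the fixed point of the context average, which several
identity tests exploit.  Note the uniform baseline already has
Others = 25/27 ≈ 0.926, so a visible "Others spike" requires a breaker bias
above that value.

## Degenerate inputs and numerical choices

Empty proteomes, zero standard residues, empty samples, regions out of
bounds, unknown vocabulary labels, duplicate ids, non-normalised propensity
rows and infeasible planting plans are hard errors with specific messages.
Frequencies at positions with zero denominator are NaN, not 0.  Probability
sums are enforced to 1e-9 in tests; propensity table rows to 1e-6 on load.
All randomness flows from a single integer seed through numpy Generators;
derived streams use distinct fixed second words of the seed sequence, and
the same seed reproduces byte-identical FASTA output.
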