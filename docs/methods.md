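# Methods

## The model

A genome's *domain repertoire* is the multiset of Pfam-style domain
families encoded by its predicted proteins, summarized as an integer copy
count per family. Given repertoires for a set of taxa and a rooted species
tree, repertoire evolution is modeled as independent per-family change
along branches, scored by **Wagner (linear) parsimony**: copy counts are
ordered, additive (meristic) characters, and changing count *i* to *j*
along a branch costs |i − j| unit events. The reconstruction minimizes the
total cost over all assignments of counts to internal nodes; branch
lengths are carried for display but never enter the optimization (parsimony
is time-free).

Unit changes are then read as biological events per branch: a family
appearing from count 0 is one **gain** (any additional copies on the same
branch are duplications), each unit increment of an existing family is one
**duplication**, and each unit decrement is one **loss** — so a branch on
which a four-copy family disappears carries four loss events. By
construction the total number of called events equals the parsimony cost;
this identity is asserted in the tests.

Assumptions worth stating explicitly: families evolve independently
(cross-family processes such as domain fission/fusion are invisible);
copy-number change is stepwise with symmetric unit cost (no rate asymmetry
between gain and loss); hits are counted without overlap resolution, so
every profile-HMM match above threshold is one copy (an optional
per-query envelope-overlap de-duplication exists but is off by default);
and the species tree is known, rooted, and fixed.

## Upstream stages and their conventions

**ORF calling.** ORFs are ATG-initiated and stop-terminated, scanned in
all three frames of both strands. Coordinates are 0-based, half-open, on
the forward strand regardless of ORF strand; the stop codon is inside the
nucleotide span and outside the translation. Two modes: `maximal` (default;
only the first ATG after the previous in-frame stop opens an ORF, bounding
output size) and `all-starts` (every ATG opens an ORF, the literal "all
possible reading frames" reading). ORFs truncated by the sequence end are
excluded by default (`include_incomplete` to keep them). The minimum
translated length defaults to 50 aa — a conventional noise floor for
six-frame scans, configurable because it is a convention, not a law.
Degenerate IUPAC codes never match ATG or a stop, and any codon containing
one translates to `X`; only the standard genetic code is used (the target
genomes are nuclear eukaryotic loci).

**Hit filtering.** The inclusion rule keeps a hit iff its full-sequence
E-value ≤ 10⁻³ **and** its per-domain conditional E-value ≤ 10⁻³, both
inclusive. "Per-domain conditional value" is read as the domtblout
c-Evalue column — HMMER's own "conditional E-value" — not the independent
i-Evalue. Thresholds are parameters (`FilterCriteria`) with those defaults.

**Matrix.** Columns are the lexicographically sorted union of family names
(byte-stable output); all-zero columns are dropped at build time since
zero-variance characters can produce no events. Counts, not
presence/absence, are the character states; a presence/absence view exists
for completeness, as does a NEXUS writer (digit symbols, so counts > 9 are
rejected with a clear error) for legacy parsimony software.

## Numerical and algorithmic choices

**State bound.** The dynamic programme runs over states 0..max(leaf
counts). For linear cost this is provably sufficient: any optimal
assignment can be clamped into the observed leaf range without increasing
any branch cost.

**Two reconstruction routes.** The Farris interval down-pass handles
strictly binary trees in O(nodes); the Sankoff-style DP with cost matrix
|i − j| handles arbitrary multifurcations in O(nodes × states²). They are
proven equivalent in the tests by an exhaustive sweep: every rooted binary
tree shape with 2–6 leaves crossed with every leaf-state vector in
{0..4}ⁿ (for a fixed shape the full state sweep makes leaf labeling
irrelevant, so this is the complete labeled sweep with duplicates
removed), plus brute-force enumeration — exhaustive for ≤ 4 leaves, a
seeded 200-vector sample per shape at 5–6 leaves, where enumeration of all
internal assignments is the only super-exponential part.

**Tie-break.** Most-parsimonious reconstructions are generally non-unique.
The canonical assignment takes the smallest state in the root's optimal
set, then assigns each node preorder the state minimizing its subtree cost
plus the distance to its parent's assigned state, ties toward the smaller
state. This biases ancestral counts low — i.e., toward gains/duplications
rather than losses near the root. The bias is a choice, not a consequence
of parsimony; `root-largest` is available, and reported event
decompositions are policy-dependent even though the total cost never is.

**Root-edge identifiability.** Rooted parsimony cannot distinguish a unit
loss on one branch incident to the root from a unit copy addition on its
sister: both histories have cost 1 and identical leaf data. Under the
default tie-break such a loss is reconstructed as the equivalent addition
on the sister branch. The synthetic-recovery test accounts for exactly
this class (and nothing else) when comparing called events with the
simulator's truth log.

**Degenerate inputs.** Single-leaf trees are parsed and serialized;
constant characters reconstruct as constant with zero cost; empty hit
lists give empty repertoires; an empty matrix round-trips as a header-only
TSV. Duplicate ids (FASTA, ORF, taxa, leaf labels) are rejected
everywhere, as are E-values ≤ 0, ragged matrix rows, and negative counts.

## The synthetic generator

`synthetic_data` emulates the *shape* of the study's inputs, not their
biology:

- **Trees**: a pure-birth (Yule) process — with k extant lineages the next
  split waits Exponential(birth_rate · k) — gives rooted, binary,
  ultrametric trees like time-calibrated summaries of a Bayesian run. The
  simulator is validated against the closed-form expected root height
  Σₖ₌₂..ₙ 1/(k·birth_rate) by Monte Carlo (2,000 replicates, 3 standard
  errors).
- **Repertoires**: along each branch an exact Gillespie walk draws events
  with rates gain_rate (per family pool), dup_rate·C(t) and loss_rate·C(t)
  (per existing copy, re-evaluated after every event), so losses can never
  drive a count negative. Defaults — gain 0.1, duplication 0.2, loss 0.2
  per unit branch length, a 12-family root repertoire (Ca_hom_mod plus
  eleven background families at 1–3 copies) on 20-leaf trees of height
  ≈ Σ 1/k — produce a few dozen events per run, the same order as the
  per-family event counts in the worked example. Every unit event is
  logged, and replaying the log from the root must reproduce every leaf
  repertoire exactly (a tested invariant). An optional per-family event
  cap yields the ≤ 1-event regime in which parsimony provably recovers the
  log branch-exactly (modulo the root-edge class above).
- **Genomes**: planted ORFs (ATG + deterministic reverse translation +
  TAA) separated by stop-rich A/T spacers with TAA stamped in all three
  frames; having no G, spacers contain no start codon on either strand, so
  planted ORFs are recovered exactly even in maximal mode.
- **domtblout fixtures**: one passing hit per repertoire copy (both
  E-values ≤ 10⁻⁴) plus decoys failing exactly one of the two criteria,
  exercising the AND in the filter.

What passing these tests does *not* show: real six-frame scans produce
orders of magnitude more ORFs and hits, real E-value distributions are not
two well-separated clumps, real repertoire evolution is neither
independent across families nor unit-stepwise, and real trees carry
uncertainty the pipeline ignores. The generator establishes correctness of
the machinery, not calibration against genomes.

## Problem sizes

The test suite and acceptance checks run at desk scale by design: trees of
2–20 leaves, matrices up to 20 × 500, 100-replicate recovery and replay
sweeps, the exhaustive ≤ 6-leaf oracle sweep (~10⁵ instances), and 2,000
Yule replicates — a few tens of seconds in total. The full-scale study
setting (20 complete genomes, a Pfam release, HMMER runs, thousands of
families and ~10⁴ events) exercises no additional code path; its inputs
are external downloads this package deliberately treats as supplied files.

## Known limitations

- Parsimony underestimates events on long branches (no multiple-hit
  correction) and offers no uncertainty quantification; likelihood or
  Bayesian count models are out of scope.
- Event decomposition on a branch is the minimal one; a reconstructed
  0 → 3 change is called 1 gain + 2 duplications even though other
  histories (e.g. three independent gains of diverged copies) are
  biologically possible.
- Copy counts from unresolved overlapping hits can double-count split
  alignments of one physical domain; the optional de-duplication trades
  that against merging tandem repeats.
- The iTOL export anchors events to child nodes; iTOL renders them at the
  node, not mid-branch.
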