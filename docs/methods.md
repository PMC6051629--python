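# Methods

This note documents the models, conventions and numerical choices behind
`ppikernel`, including the places where the underlying protocol left a design
decision open and what this package chose.

## Alignment and the HSSP/HVAL machinery

All pairwise similarity runs through one deterministic aligner: global
Needleman–Wunsch with affine gaps (Gotoh), BLOSUM62, gap open 10, gap extend
0.5, end gaps penalized. Percent identity (PIDE) is identities divided by the
alignment length counting every column, gapped ones included — the whole-chain
convention the HSSP curve assumes. The aligner is a numba-compiled dynamic
program (redundancy reduction and negative sampling perform 10⁴–10⁵
alignments per run); the test suite certifies it against
`Bio.Align.PairwiseAligner` configured identically, asserting exact optimal-
score agreement on random sequences. Argument order is canonicalized
internally, so `align_identity(a, b)` is exactly symmetric; ties among
co-optimal alignments are broken by a fixed traceback preference
(match > gap-in-second > gap-in-first), making results reproducible.

Whether the original HVAL computations used local or global alignments, and
with which gap penalties, is not stated anywhere authoritative; the choices
above are this package's own and are exposed as constants in `_align`.

The HSSP threshold is implemented exactly as the closed form
`T(L) = 480·L^(−0.32·(1+e^(−L/1000)))` between the 100%-identity floor
(L ≤ 11) and the 19.5 plateau (L > 450). Note a genuine property of this
closed form: it has a shallow local minimum near L ≈ 400 and rises by < 0.05
percentage points before the plateau, so "monotone decay" only holds to that
tolerance. `T(250) ≈ 20.72`, hence HVAL = 20 at length 250 ↔ ≈ 40.7%
identity, the calibration anchor.

Boundary semantics are deliberately asymmetric, matching the protocol as
printed: redundancy reduction removes interactions whose proteins reach
HVAL **> 20** to the retained set (HVAL exactly 20 is kept), while negative
sampling and interactome candidacy require HVAL **< 20** (exactly 20 is
excluded).

## Curation

Evidence reliability is the maximum score over an interaction's evidence
entries; the retention filter is inclusive (≥ 5). Methods missing from the
score table get the lowest score (1) with a logged warning — absence of
annotation quality must never promote an interaction past the filter.
Reference-proteome mapping requires ≥ 95% identity (inclusive), best match
wins, ties to the lexicographically smallest reference id (which makes the
mapping invariant under reference shuffling). Unmappable pairs are logged
and dropped; no fuzzy identifier resolution is attempted. Organism tiers:
fewer than 200 non-redundant interactions → no model; 200–500 → fixed
hyperparameters, cross-validation only; strictly more than 500 → grid search.

Redundancy reduction is a greedy single pass. Visit order is descending
evidence score, then pair id — so the best-evidenced representative of each
similarity cluster survives and the result does not depend on input file
order (the original protocol does not state its order).

## Profiles

Profiles are L × 20 row-stochastic tables. Rows from PSSM percentage columns
are divided by 100, floored at ε = 1e−4 and renormalized; the floor keeps the
kernel's −ln p conservation cost finite for never-observed residues.
All-zero PSSM rows (no alignment coverage) fall back to a point mass on the
query residue. Conservation costs use the natural logarithm: the σ range
4–11 is consistent with nats, where a uniform position costs
−ln(1/20) ≈ 3.0 per residue. Both the floor and the log base are package
decisions — the kernel definition itself fixes neither.

The sequence-only fallback (`pseudo_profile`) mixes a point mass on the
observed residue with the BLOSUM62-implied substitution distribution
q(b|a) ∝ 2^(s(a,b)/2) (half-bit scores, flat background), weight `alpha`
(default 0.1). `alpha = 0` yields point-mass ("delta") profiles, under which
the profile kernel reduces exactly to the spectrum kernel — the limit the
test suite uses as an independent reference. Nonstandard residues (X) get
uniform rows so they cannot manufacture conserved k-mers.

## Kernel

Neighborhood membership is strict (`cost < σ`): "conservation exceeds σ"
maps to a strict upper bound on the −log cost. Enumeration is depth-first
over the k-mer trie with branch-and-bound pruning on the running cost plus
the best achievable remainder; the contract — certified on randomized
instances — is exact equality with literal 20^k enumeration.

Pair construction sums the two L2-normalized per-protein vectors. This is
symmetric in the pair, keeps the Gram matrix positive semidefinite, and in
the normalized kernel K'(x,y) = K(x,y)/√(K(x,x)K(y,y)) gives unit diagonal.
The precise pairwise combination used historically for this kernel family is
not restated in the immediate protocol; the normalized sum is this package's
choice, and tensor-product alternatives are out of scope. Feature vectors
are stored sparse with string keys — exactness over speed at desk scale.

## SVM, calibration and evaluation

The SVM is scikit-learn's `SVC(kernel="precomputed")`, default cost C = 1 on
the normalized kernel (the protocol never states C; it is exposed).
Calibration is a Platt sigmoid fitted by Newton iterations on the training
decision values with the standard prior-adjusted targets; published-style
outputs are probabilities, but no calibration method is named anywhere, so
Platt is a documented package decision. Predictions are computed row-wise
(one dot product per query row) so results are bit-identical regardless of
how callers batch their queries.

Precision–recall curves are evaluated on a fixed grid of 100 recall levels
(0.01…1.00; the grid density is a package choice). At each grid recall the
precision of the smallest prediction set achieving at least that recall is
reported. Error bars: across cross-validation folds, the standard deviation
of fold precisions; for single hold-out curves, a binomial error. The
binomial error is implemented in two modes: `as_printed` returns the
variance-like count n·p·(1−p) exactly as the protocol prints it, and
`standard_error` returns √(p(1−p)/n), which is what plots should use — the
printed form is dimensionally a count, and this package does not guess which
was intended; both are available, plots default to the standard error.

The selection statistic is the mean of mean-precisions over grid points with
recall ≤ 20%. Cross-validation re-splits positives and re-samples negatives
per repetition (the protocol places sampling inside the repetition loop);
5 folds × 5 repetitions = 25 fits. Fold splitting is on interactions, which
is only leak-free because redundancy reduction has already made interaction
protein sets disjoint and mutually dissimilar — the splitter asserts protein
disjointness at runtime and refuses non-reduced positive sets. The grid
search splits positives 2/3–1/3 (seeded), cross-validates every (k, σ) on
the training two-thirds, breaks ties toward smaller k then smaller σ, trains
a final model on the whole training split and evaluates it once on the held
third. Class imbalance is handled only by the 10:1 sampling design — no
class weights.

## Negative sampling

Eligible proteins have HVAL < 20 to every positive-set protein; sampling is
uniform over eligible unordered pairs, excluding positive pairs, via
rejection sampling (or full enumeration when the requested count is a large
fraction of the pool), reproducible from the recorded seed. The sampler
fails loudly, stating the shortfall, when the constraint leaves too few
pairs.

## Interactome bookkeeping

Candidate pairs are all C(n, 2) combinations of proteins dissimilar to every
training positive (HVAL < 20 — the same constraint as negatives; the
protocol's wording varies between sections, and this package uses the strict
form consistently). The model records the proteins of its positive training
pairs separately from all training proteins, since only the former define
the exclusion. The published-set budget is exactly per_protein × n_proteins
(default 10 per protein); published resources round such budgets to
presentation-friendly numbers, so a `round_to` granularity knob exists, but
rounding is treated as presentation, not method. Accuracy against an
external reference is 100 · n_correct / n_evidence over the predictions that
have a reference call at all, reported to two decimals; the reference tables
bundled in `organisms.py` are inputs (published statistics), not outputs.

## Synthetic data

The generator emulates exactly the statistical structure the pipeline
assumes and nothing more: homolog families (founders i.i.d. uniform over 20
residues; members by per-residue substitution at rate 0.15, which at lengths
200–300 keeps within-family HVAL comfortably above 20 while unrelated
sequences sit near 5% identity, far below), planted positives on disjoint
protein pairs sharing a small set of motif pairs (default 4 pairs of length-4
motifs — few enough that every cross-validation fold sees motifs present in
training), and evidence drawn from a miniature method-score table so a
configurable fraction of interactions fails the ≥ 5 filter. Defaults: 500
proteins, 50 families of 2, 50 positives, 20% failing evidence.

What it does **not** emulate: realistic phylogeny (substitutions are i.i.d.,
no indels within families), realistic degree distributions (every synthetic
protein interacts at most once), amino-acid composition bias, or the
evidence-method mixture of real databases. Passing tests therefore
demonstrate that the machinery is correct and that planted sequence signal
is recoverable under the stated homology structure — not that any particular
precision level transfers to real proteomes.

## Problem sizes used in the checked runs

The end-to-end acceptance run uses a 600-protein organism with 200 planted
positives (motif length 4), point-mass profiles, (k = 4, σ = 4), 10:1
negatives and a single 5-fold cross-validation pass — 5 fits on ~1,760-pair
kernels — and requires the mean precision up to 20% recall to reach at least
three times the 1/11 prevalence baseline. The negative-sampling contract is
checked at the generator's default scale (500 proteins, 50 positives, 500
negatives, every endpoint re-verified against every positive protein).
Kernel–oracle equivalence uses 50 random profile instances with k ≤ 3, where
literal 20^k enumeration is still cheap.

## Known limitations

- The full published workflow (PSI-BLAST profiles against an 80%
  non-redundant database, 2018 database snapshots, 768-organism taxonomy
  grouping) is out of scope; profile *generation* is not implemented, only
  ingestion and the sequence-only fallback.
- MITAB support is the minimal column subset (interactor ids + detection
  method); no controlled-vocabulary resolution.
- The aligner's gap convention and the pair-combination rule are documented
  choices, not protocol facts; absolute numbers that depend on them (e.g.
  exact HVALs near the cut) can differ from other implementations.
- `grid_search` over the full 32-combination grid with 25 fits per
  combination is expensive at real-organism scale; the implementation is
  exact but intended to be driven with reduced grids when exploring.
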