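# Methods

`dnasekit` reconstructs how a repertoire of gene families — here the
vertebrate DNase1 and DNase2 endonuclease families — was assembled over
evolutionary time. The pipeline has four analytic stages (alignment,
profile-HMM classification, feature verification, gain/loss dating plus
synteny) and a synthetic-data generator that provides ground truth for
all of them. This note records the models, the tunable parameters with
their defaults, and the design choices made where the design was
genuinely open.

## Pairwise and progressive alignment

Pairwise global alignment is Needleman–Wunsch with affine gaps, BLOSUM62
scoring, gap open 11 and gap extension 1 in the BLAST convention (a gap
of length *k* costs 11 + *k*); `X` scores 0 against every residue. The
implementation delegates to Biopython's `PairwiseAligner`; among
co-optimal alignments the first in its deterministic enumeration order
is returned, which fixes the traceback without affecting scores.

Percent identity of a pair is 100 × (identical columns) / (columns
where both rows hold residues). Excluding gap columns from the
denominator makes the statistic insensitive to terminal overhangs; it is
one of several conventions in circulation, so identities computed here
can differ by a point or two from values produced by other aligners and
conventions. Identity matrices are clustered with average linkage on
100 − identity, the usual choice behind clustered identity heatmaps.

The progressive multiple aligner builds a UPGMA guide tree from the
identity distances and merges groups by profile–profile global
alignment (mean cross-group BLOSUM62 column score, affine gaps, ties
broken diagonal > gap-in-B > gap-in-A). It exists to prepare curated
orthogroup alignments and synthetic fixtures; it makes no claim to
match any particular production aligner column-for-column. Maximum
likelihood phylogenetics is out of scope; neighbor joining
(`nj_tree`, via scikit-bio) serves as the quick monophyly check, and is
exact on additive distances.

## Profile HMMs

One profile per orthogroup is estimated from a multiple alignment.
Columns with residue occupancy ≥ 0.5 become match states. Match
emissions are residue counts plus 1.0 × the Robinson–Robinson
background frequencies, normalized. Transitions are counted from each
row's implied match/insert/delete path and smoothed additively with
α = 0.1; plain add-one smoothing would assign roughly ten percent
probability per position to indels that a gapless 16-row alignment
never exhibits, badly misrepresenting the observed paths, so a lighter
prior is the default (`transition_pseudocount`).

The architecture is glocal (Plan7-style): entry into the first match
state and exit from the last are mandatory, terminal match states
cannot be deleted, and background-emitting N/C flank states (self-loop
0.9) absorb overhangs. The null model is i.i.d. background, so flank
emissions cancel in the odds ratio. Forward and Viterbi run in natural
log space (log-sum-exp; the silent-delete chain is vectorized as a
cumulative log-add with a telescoping offset) and report bit scores;
sequences of 10,000 residues score without underflow.

E-values use the standard extreme-value form E = *dbsize* ·
exp(−λ(S − μ)). μ and λ come from a maximum-likelihood Gumbel fit to
forward scores of 200 seeded random background sequences of length
equal to the match count. `dbsize` defaults to the number of records
scanned and is exposed explicitly, since significance thresholds of
this kind are inherently database-size relative. Classification is by
best match among hits with E ≤ 1e-20 (the scan default), ties broken by
higher bit score then lexicographic label. Only protein-level scanning
is implemented; six-frame DNA search is out of scope.

Profiles serialize to a plain-text format at 6 significant digits that
round-trips byte-identically; loaded profiles are validated with a
tolerance matching that precision.

## Diagnostic features

Orthogroup assignments are verified against independent sequence
fingerprints. Reference residue labels (C4, C32, C101, C104, C173,
C209 in human DNase1 numbering; the DNase2-family cysteine pairs and
the two phospholipase-D HxK catalytic positions) are defined as match
states of each profile and anchored onto an arbitrary member through
its Viterbi path — robust to indels, unlike absolute positions. A
cysteine pair is reported only when both positions are mapped and both
residues are literally cysteine.

C-terminal classification is a deterministic cascade, most specific
signal first: GPI > BASIC > SMB > EL > NONE, with all constants in
`FeatureConfig`:

* **GPI**: an ω-site candidate (S/G/A/N/D/C) within the last 40
  residues, a 6-residue spacer, and a tail of ≥ 8 residues to the
  terminus with mean Kyte–Doolittle hydropathy ≥ 1.0; the most
  N-terminal qualifying ω is reported.
* **BASIC**: net charge ≥ +4 over the last 12 residues (K/R = +1,
  D/E = −1, H = 0).
* **SMB** (somatomedin-B-like): ≥ 6 cysteines in the last 60 residues.
* **EL**: the sequence ends exactly "EL".

The signal-peptide heuristic accepts a sequence when an 8-residue
window within the first 35 residues has mean hydropathy ≥ 1.6 and the
region before the window has non-negative net charge. These detectors
stand in for external predictors; their constants are package
decisions, exercised and defined by the synthetic fixtures, and no
accuracy claim is made for real proteomes beyond what those fixtures
test. Mismatches between detected features and an orthogroup's
expected signature produce warning flags on the call — never
rejection, because a missing basic tail (as in lamprey DNase1L3) is
itself a finding.

## Gain/loss events and synteny

Presence/absence matrices mark a taxon/orthogroup cell true when at
least one call exists; flagged calls still count. Taxa present in the
matrix but absent from the tree are an error rather than silently
dropped.

Events are reconstructed per orthogroup under Dollo parsimony: each
family arises exactly once and may be lost repeatedly. The gain sits on
the stem branch *above* the MRCA of the presence taxa (so a gain next
to the root still has a finite time window when the Newick provides a
root edge length); one loss sits on the stem of every maximal subtree
under the gain that contains no presence taxon. This placement
minimizes losses for a single gain, which the suite verifies against an
exhaustive labeling search. Dollo rather than Fitch because a gene
family's repeated independent origin is not a plausible alternative;
where the data genuinely cannot distinguish an early origin plus loss
from a later origin, the ambiguity is surfaced as the width of the
gain-branch interval rather than resolved.

The species tree is a chronogram (Newick, branch lengths in Myr,
ultrametric); node ages are derived from depths, with an optional
explicit root age. Event intervals are (parent-node age, child-node
age). Tandem-duplication windows are the daughter family's gain
interval, clipped so they cannot predate the parent family's own
origin.

Synteny uses 0-based half-open coordinates; '+' means transcription in
ascending coordinates. Same-strand neighbors are tandem; divergent
strands with the minus-strand gene upstream are head-to-head (the two
5′ ends face a shared bidirectional promoter region); the converse is
tail-to-tail; different chromosomes are unlinked (distance −1).
Overlapping spans report distance 0 with a warning. Intervening genes
are those strictly inside the intergenic gap.

## The synthetic-data generator

The generator emulates the *structure* of real repertoire data, not its
sequence evolution:

* **Histories**: presence propagates from a per-orthogroup gain branch;
  losses are a Poisson process at 0.0004 events/Myr/lineage (roughly
  two expected losses per family on the bundled tree, matching the
  density of documented losses); lost lineages stay lost. A
  deterministic reference history encodes the published DNase
  narrative: DNase1 and DNase2b ancestral to chordates; DNase2,
  DNase1L3 and DNase1L1L arising before the jawless/jawed split;
  DNase1L4 and DNase1L5 in early jawed vertebrates; DNase1L1 on the
  bony-vertebrate stem; DNase1L4-2 in Neopterygii; DNase1L2 on the
  amniote stem; losses including DNase2 in birds, DNase1L1L in birds
  and placentals, and DNase2b in agnathans, snakes and monotremes.
* **Tree**: a bundled 21-leaf chordate chronogram with round
  TimeTree-style ages (amniote crown 312 Myr under a tetrapod crown of
  352, bony-vertebrate crown 435 under a gnathostome crown of 473, root
  650 with a 50-Myr root stem). Shipped as an editable Newick fixture.
* **Members**: each orthogroup has a fixed consensus architecture —
  signal-peptide prefix (or a deliberately polar N terminus for the
  intracellular DNase1L4 group), a 215-residue background-composition
  core carrying the family's cysteine pairs and HxK motifs at fixed
  reference columns, and the family's C-terminal class suffix. Seed
  alignments are 16 substitution-mutated copies (rate 0.05, never to
  cysteine, diagnostic columns protected), members are walks of the
  resulting profile with diagnostic states pinned and indels suppressed
  within two states of them (diagnostic residues sit in conserved
  motif blocks), and the terminal implants are written over the ends.
* **Decoys**: residue-shuffled members — composition-matched nulls,
  the hardest negative that is still honestly negative.
* **Gene tables**: coordinates constructed so that a planted
  arrangement, distance and intervening-gene count are recovered
  verbatim.

What passing tests therefore show: the classifier separates
profile-generated families from composition-matched noise at E ≤ 1e-20,
the detectors recognize cleanly implanted signals, and the event
reconstruction is exact on identifiable histories. What they do not
show: performance on real proteomes, whose members diverge along the
tree (no substitution-model branch lengths are simulated), whose
signals are degraded, and whose alignments contain errors.

## Numerical choices and degenerate inputs

* Log-space throughout the HMM; no probability-space accumulation.
* Viterbi traceback ties prefer M > D > I; alignment DP ties follow the
  deterministic enumeration order noted above.
* A sequence shorter than the mandatory terminal matches scores −inf
  and is unassignable; a length-1 sequence against a 1-state profile is
  a single M path.
* Calibration refuses degenerate (near-zero-variance) score samples.
* Sequences shorter than 30 residues get C-terminal class NONE with a
  warning; shorter than 25, no signal-peptide call.
* All generators accept integer seeds (or a `numpy` Generator) and are
  bit-reproducible for a fixed seed.

## Problem sizes

The bundled experiments use 10 orthogroups on the 21-taxon tree, 16-row
seed alignments, ~245–270-residue members, 20 sampled members per
orthogroup for recovery measurements, 1,000 decoys for the
false-positive rate, 200 background samples per profile calibration,
and 20 replicate histories for loss-branch recovery. Exhaustive oracles
run at: alignments ≤ 8 residues, profiles ≤ 5 match states with
sequences ≤ 6 over a reduced alphabet, and Dollo instances ≤ 8 leaves.

## Known limitations

* The E-value calibration fits the whole null-score distribution, not
  only its tail; for the decision threshold used here (1e-20, hundreds
  of bits above the null) this is inconsequential, but tail E-values
  near 1 are approximate.
* The identity convention and in-house aligners mean percent identities
  are comparable within the package but only approximately against
  other tools (± a couple of points).
* `duplication_interval` brackets a tandem duplication by branch ages;
  it cannot narrow the window below the tree's resolution.
* The signal-peptide and GPI heuristics are deliberately simple;
  SignalP-class accuracy on real sequences is neither attempted nor
  claimed.
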