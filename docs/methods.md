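# Methods

## Model

The package models PaperClip assembly purely at the sequence level. DNA is a
validated string over {A, C, G, T}; duplexes are a pair of strands with an
alignment offset and an explicit list of single-stranded overhangs. The
model assumes perfect Watson–Crick complementarity everywhere: ambiguity
codes are rejected at the boundary rather than propagated, because every
downstream decision (seam ligation, sticky-end matching, overhang-fidelity
checks) requires exact base identity. No thermodynamics are computed —
annealing is treated as finding the unique maximal fully-complementary
register between two strands, which is the correct abstraction for oligos
designed to have one dominant register, and deliberately wrong for
arbitrary sequences (see Limitations).

Coordinates in all reports are 1-based and inclusive, following
molecular-biology convention. "External" designates the seam-bearing end of
a half-Clip, i.e. the end distal from the part's own sequence; the internal
end faces the part interior. (Viewed from the Clip rather than the part the
same ends are sometimes called "inner"; this package consistently uses the
part-centric naming.)

## Design algorithm

For a part P of length ≥ 40 and seam s (3 nt, default `GCC`; s′ = rc(s)):

1. UF = s + P[1..40]; UR = rc(P[1..37]). Annealed: the Upstream half-Clip,
   with a 5′ s overhang externally and a 3-base 3′ overhang (P[38..40])
   internally.
2. DF = the suffix of length 40 − t, where t is the smallest trim such that
   the suffix does not begin with s or s′; DR = s′ + rc(suffix of length
   |DF| − 3). Annealed: the Downstream half-Clip, 5′ s′ external overhang,
   3-base 5′ internal overhang that by construction is never seam-valued.

Two consequences worth noting:

* Successive trim candidates start at consecutive positions, and the only
  pair of overlapping 3-mers that are both in {`GCC`,`GGC`} is `GGC`
  followed by `GCC`; therefore t ≤ 2 for any sequence. The configurable
  `max_trim` (default 6) is a defensive bound, reachable only with custom
  seam pairs, not with any single seam and its complement.
* DR's homology window shrinks in lockstep with DF (|DR| = |DF|), keeping
  the 3-base internal stagger constant; trims of 1–2 nt leave ≥ 34 nt of
  priming homology on every Clip arm.

Orientation variants UFx/DRx exchange the 3-base external prefixes of UF
and DR and reuse UR and DF as their annealing partners. In the flipped
frame the seam-adjacent homology arms are 37 nt rather than 40 (the length
of the reused reverse windows); the half-Clip duplexes are recorded in the
junction frame (flipped-forward strand on top), so external overhangs
classify identically in both orientations. Parts of 40–76 nt are designed
with a warning because their upstream and downstream windows overlap; parts
shorter than 40 nt must be supplied as intervening sequences.

Amplification uses UF and DR directly as primers; the predicted amplicon is
s + P + s (DR's s′ prefix reads as s on the forward strand). For ligase
chain reaction assembly, seam-free variants of UF or DR are derived by
stripping the 3-base prefix, avoiding the 3-base terminal overlap that
would otherwise block LCR.

## Intervening sequences

A short element S (15–200 nt accepted; the method is validated on 60 and
100 bp, and the floor guarantees two non-empty duplex halves) becomes four
oligos split after top-strand base m: s+S[1..m] / rc(S[1..m+5]) and
S[m+1..] / s′+rc(S[m+6..]). The two duplexes carry complementary 5-base
5′ sticky ends (S[m+1..m+5]), so ligating all four strands restores s+S on
the top strand exactly. The default split is the midpoint, searched ±5 for
a sticky end that is neither homopolymeric nor self-complementary (either
would permit mis-ligation); a sequence with no admissible split near the
midpoint is rejected rather than silently split badly. These duplexes are
constructed analytically from the design geometry instead of re-annealed,
since their double-stranded halves may be shorter than any register the
generic annealer would accept unambiguously.

## Assembly planning and simulation

An assembly is a circular arrangement whose first element is the backbone.
Each adjacency, including the wrap-around, is covered by one Clip ligation
tube; a junction with an intervening sequence expands into the two-tube
chain (downstream half + upstream intervening duplex; downstream
intervening duplex + next upstream half; then merge). The simulated
construct concatenates, per element, its sequence (reverse complement if
flipped), then seam [+ intervening + seam] — so the junction count equals
element count plus intervening count, and the length is Σ parts + Σ
intervening + 3 × junctions. The seam copies that PCR adds to part termini
and the seam inside the Clip are identical and overlapping, and are merged
to a single 3-base seam per junction, which is what homology-directed
assembly produces. The backbone↔part junctions use the same seam as
part↔part junctions. The canonical rotation starts at backbone base 1.
The `pcr` / `cell_extract` method flag changes only worksheet notes; both
routes yield the same sequence.

Single-part recircularization (a part's own Downstream + Upstream
half-Clips) is supported and yields the part plus one seam.

## Validation

* **Identity screen** — every unordered pair of element sequences is
  compared forward and against the reverse complement; each element is also
  screened against itself for internal direct repeats and inverted repeats.
  This is deliberately broader than a plain pairwise forward comparison
  because recombination acts on double-stranded DNA. A shared region is an
  error when strictly longer than the threshold (default 40 nt: exactly 40
  passes, 41 fails). The production search is a binary search over shared
  k-mer sets (O(n log n) expected); a quadratic dynamic-programming
  longest-common-substring computation in the test suite is the
  independent correctness reference.
* **Repeated parts** — any part id occurring twice in one plan is an error,
  including a flipped duplicate (whose identity surfaces on the opposite
  strand).
* **Overhang fidelity** — a seam-valued downstream internal overhang is an
  error (unreachable given the trimming rule; kept as a self-check); a
  seam-valued upstream internal overhang (part bases 38–40, which the
  design cannot change) is a warning, as is a mutually complementary pair
  of internal overhangs within one ligation tube.
* **Reading frame** — at each junction between consecutive CDS parts, the
  seam inserts one codon (GCC → Ala, CTA → Leu). The frame test uses the
  cumulative length of the upstream CDS parts in the run, mod 3 (seams are
  3 nt and never shift frame); for a two-part fusion this reduces to the
  upstream CDS length. An out-of-frame seam or an in-frame stop-codon seam
  is a warning. Junctions carrying intervening sequences are reported
  informationally and not frame-checked, since the element's own length
  governs the frame.

Validation is pure: the same plan always yields the identical,
deterministically ordered report (sorted by element index, then code).

## Synthetic data

The fixture generator emulates the inputs the method is used on: random
uniform-composition parts of 200–400 nt by default (promoter/RBS/ORF-scale
elements; a 600-nt sequence stands in for a minimal backbone), with
optional planted pathologies — seam-valued suffixes to force trimming,
shared identical regions of exact length (plant boundaries are pinned with
mismatching flanks so 40/41-nt boundary tests are exact), and CDS frame
structures. Two fixed toy parts cover the hand-checkable cases: TOY1
(60 nt, trim-free) and TOY2 (44 nt, 40-nt suffix beginning `GCC`, one trim
step). Generated parts do not model real-sequence features — biased
composition, long homopolymers, natural repeats, or restriction-site
content — so passing tests demonstrate the correctness of the design
algebra, not that any particular natural sequence is assemblable; the
validator exists precisely to screen real inputs.

Problem sizes throughout the suite are desk-scale (parts ≤ 600 nt,
libraries ≤ 10 parts, 200 oracle pairs ≤ 300 nt, 1000 random intervening
designs), chosen because every quantity checked is exact and independent of
scale.

## Numerical and design choices

* Annealing requires a unique maximal fully-complementary register of
  ≥ 10 bp; ties raise an ambiguity error rather than picking arbitrarily.
* The seam-collision test uses {s, s′} generically, so `CTA`/`TAG`
  (BrickClip) and custom seams work unchanged; a seam equal to its own
  reverse complement is rejected at construction.
* Oligo sheets, worksheets, plans and reports are deterministic given
  identical inputs (stable sort keys everywhere); plan files are recomputed
  from the part sequences on load rather than trusted.
* Bench constants rendered into protocols (100 μM resuspension, 40 μM
  annealing, 14 μM half-Clips in ligation, 16 °C/1 h, 65 °C/20 min) are the
  method's published working conditions and are presentation-layer only.

## Limitations

Sequence-level modelling only: no melting temperatures, secondary
structure, ligation kinetics, transformation efficiency, or host biology
(counter-selection markers are metadata). The annealer is not a general
alignment tool — it answers "what duplex do these designed oligos form",
not "would these oligos anneal in practice". The identity screen bounds
*intra-construct* homology; it does not screen against host genomes.
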