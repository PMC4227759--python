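"""Elementary nucleic-acid sequence model shared by all design modules.

DNA is represented by :class:`NucSeq`, a validated uppercase ``str`` subclass
over the strict {A, C, G, T} alphabet; ambiguity codes are rejected because
overhang complementarity must be exact for ligation-fidelity reasoning.
Duplex geometry (annealed oligo pairs with single-stranded overhangs) is
modelled explicitly so that downstream modules can classify sticky ends.

All user-facing coordinates are 1-based and inclusive, following
molecular-biology convention; Python slicing internally is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

from Bio.Seq import Seq

__all__ = [
    "NucSeq",
    "SeamSpec",
    "Overhang",
    "Duplex",
    "reverse_complement",
    "anneal",
    "AnnealingError",
]

_ALPHABET = frozenset("ACGT")

#: Minimum double-stranded length accepted by :func:`anneal`. Shorter duplexes
#: are never used by the design algorithm and would invite spurious alignments.
MIN_DUPLEX_LEN = 10


class NucSeq(str):
    """An uppercase DNA sequence over {A, C, G, T}, 5'→3'.

    Lowercase input is normalised to uppercase. Empty strings and any
    character outside the strict alphabet (including IUPAC ambiguity codes
    such as N, R, Y) raise ``ValueError`` naming the offending 1-based
    position.
    """

    __slots__ = ()

    def __new__(cls, bases: str) -> "NucSeq":
        s = str(bases).upper()
        if not s:
            raise ValueError("empty sequence is not a valid NucSeq")
        for i, ch in enumerate(s):
            if ch not in _ALPHABET:
                raise ValueError(
                    f"invalid character {ch!r} at position {i + 1}: "
                    "only A/C/G/T are allowed (ambiguity codes rejected)"
                )
        return super().__new__(cls, s)

    def reverse_complement(self) -> "NucSeq":
        return NucSeq(str(Seq(self).reverse_complement()))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"NucSeq({str.__repr__(self)})"


def reverse_complement(s: str) -> NucSeq:
    """Watson-Crick reverse complement, 5'→3'.

    ``reverse_complement`` is an involution: ``rc(rc(s)) == s``.
    """
    return NucSeq(s).reverse_complement()


@dataclass(frozen=True)
class SeamSpec:
    """The 3-base seam ('scar') left between adjacent parts.

    The default GCC seam encodes alanine when it falls in frame within a
    protein fusion. The BrickClip variant uses CTA to emulate BioBrick
    (RFC10) junction products. A seam must not be its own reverse
    complement, otherwise upstream and downstream external overhangs would
    be indistinguishable and ligation order could not be enforced.
    """

    top: NucSeq = NucSeq("GCC")
    name: str = "paperclip"

    def __post_init__(self) -> None:
        top = NucSeq(self.top)
        object.__setattr__(self, "top", top)
        if len(top) != 3:
            raise ValueError(f"seam must be exactly 3 bases, got {len(top)}")
        if top == top.reverse_complement():
            raise ValueError(
                f"seam {top} is its own reverse complement; the two seam "
                "overhangs would be identical and could self-ligate"
            )

    @property
    def bottom(self) -> NucSeq:
        """The seam as it appears on the bottom strand, 5'→3' (rc of top)."""
        return self.top.reverse_complement()


#: Seam presets by name.
PAPERCLIP_SEAM = SeamSpec(NucSeq("GCC"), "paperclip")
BRICKCLIP_SEAM = SeamSpec(NucSeq("CTA"), "brickclip")


Strand = Literal["top", "bottom"]
EndChemistry = Literal["five_prime", "three_prime"]
Position = Literal["external", "internal"]


@dataclass(frozen=True)
class Overhang:
    """A single-stranded extension at one end of a duplex.

    ``sequence`` is given 5'→3' on its own strand. ``position`` records
    whether the overhang faces away from the part it belongs to (external,
    i.e. the seam side) or toward the part interior (internal); annealing
    alone cannot decide this, so it is assigned by the design layer.
    """

    sequence: NucSeq
    strand: Strand
    end_chemistry: EndChemistry
    position: Optional[Position] = None

    def with_position(self, position: Position) -> "Overhang":
        return Overhang(self.sequence, self.strand, self.end_chemistry, position)


@dataclass(frozen=True)
class Duplex:
    """Two annealed strands with explicit overhang bookkeeping.

    ``alignment_offset`` is the 1-based position, on the top strand, paired
    with the bottom strand's 3'-most base (may be ≤ 0 if the bottom strand
    protrudes leftward). Within the double-stranded window the bottom strand
    is exactly the reverse complement of the corresponding top window.
    """

    top_strand: NucSeq
    bottom_strand: NucSeq
    alignment_offset: int
    overhangs: tuple[Overhang, ...] = field(default_factory=tuple)

    @property
    def duplex_length(self) -> int:
        """Number of paired base pairs."""
        top_len = len(self.top_strand)
        bot_len = len(self.bottom_strand)
        start = max(1, self.alignment_offset)  # 1-based on top
        end = min(top_len, self.alignment_offset + bot_len - 1)
        return max(0, end - start + 1)

    @property
    def is_blunt(self) -> bool:
        return not self.overhangs

    def overhang_at(self, *, strand: Strand, end_chemistry: EndChemistry) -> Optional[Overhang]:
        for oh in self.overhangs:
            if oh.strand == strand and oh.end_chemistry == end_chemistry:
                return oh
        return None


class AnnealingError(ValueError):
    """Raised when two strands cannot form a unique duplex."""


def _complementary_alignments(
    top: NucSeq, rc_bottom: NucSeq, min_duplex: int
) -> list[tuple[int, int]]:
    """All offsets where the overlap of ``rc_bottom`` against ``top`` is fully
    complementary, with the overlap length. Offset is 0-based position of
    rc_bottom's first base on the top coordinate (may be negative)."""
    hits = []
    for offset in range(-len(rc_bottom) + 1, len(top)):
        lo = max(0, offset)
        hi = min(len(top), offset + len(rc_bottom))
        overlap = hi - lo
        if overlap < min_duplex:
            continue
        if top[lo:hi] == rc_bottom[lo - offset : hi - offset]:
            hits.append((offset, overlap))
    return hits


def anneal(top: str, bottom: str, min_duplex: int = MIN_DUPLEX_LEN) -> Duplex:
    """Anneal two oligonucleotides into a duplex.

    The strands must share a unique maximal fully-complementary alignment of
    at least ``min_duplex`` bp (default 10, mirroring bench annealing by slow
    cooling, where designed pairs have one dominant register; the
    intervening-sequence module relaxes this for its short duplex halves).
    Non-flush ends are reported as :class:`Overhang` entries with
    ``position`` left unassigned.

    Raises
    ------
    AnnealingError
        If no alignment of ≥ ``min_duplex`` bp exists ("strands do not
        anneal") or if several alignments tie for maximal length
        ("ambiguous annealing").
    """
    top_seq = NucSeq(top)
    bottom_seq = NucSeq(bottom)
    rc_bottom = bottom_seq.reverse_complement()

    hits = _complementary_alignments(top_seq, rc_bottom, min_duplex)
    if not hits:
        raise AnnealingError(
            f"strands do not anneal (no complementary alignment ≥ {min_duplex} bp)"
        )
    best = max(overlap for _, overlap in hits)
    maximal = [offset for offset, overlap in hits if overlap == best]
    if len(maximal) > 1:
        raise AnnealingError(
            f"ambiguous annealing: {len(maximal)} equally long ({best} bp) alignments"
        )
    offset = maximal[0]

    overhangs: list[Overhang] = []
    # Left end. rc_bottom's first base corresponds to the bottom strand's
    # 3' end; bottom protruding left is therefore a 3' bottom overhang.
    if offset > 0:
        overhangs.append(
            Overhang(NucSeq(top_seq[:offset]), "top", "five_prime")
        )
    elif offset < 0:
        protruding = rc_bottom[:-offset]
        overhangs.append(
            Overhang(reverse_complement(protruding), "bottom", "three_prime")
        )
    # Right end. rc_bottom's last base is the bottom strand's 5' end.
    right_excess = (offset + len(rc_bottom)) - len(top_seq)
    if right_excess < 0:
        overhangs.append(
            Overhang(NucSeq(top_seq[right_excess:]), "top", "three_prime")
        )
    elif right_excess > 0:
        protruding = rc_bottom[len(rc_bottom) - right_excess :]
        overhangs.append(
            Overhang(reverse_complement(protruding), "bottom", "five_prime")
        )

    return Duplex(
        top_strand=top_seq,
        bottom_strand=bottom_seq,
        alignment_offset=offset + 1,  # 1-based on top
        overhangs=tuple(overhangs),
    )
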