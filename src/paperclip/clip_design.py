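"""The four-step Clip oligonucleotide design algorithm.

Each DNA part is equipped with four oligonucleotides that, annealed
pairwise, form the two half-Clips flanking the part in any assembly:

1. UF (upstream forward, ~43 nt): the seam (default GCC) prepended to the
   first 40 bases of the part's forward strand.
2. UR (upstream reverse, ~37 nt): reverse complement of the first 37 bases.
   UF+UR anneal into the Upstream half-Clip — a 5' seam overhang at the
   external end and a 3-base 3' overhang (part bases 38-40) at the internal
   end.
3. DF (downstream forward, ~40 nt): the last 40 bases, unless they begin
   with the seam or its reverse complement, in which case leading bases are
   trimmed one at a time until the collision disappears. The collision test
   is generalised to {seam.top, seam.bottom} so alternative seams (e.g.
   BrickClip's CTA/TAG) work unchanged.
4. DR (downstream reverse, ~40 nt): seam bottom strand prepended to the
   reverse complement of a suffix three bases shorter than DF. DF+DR anneal
   into the Downstream half-Clip — a 5' seam-bottom overhang at the external
   end and a 3-base 5' overhang (never seam-valued) at the internal end.

Parts usable in both orientations additionally get UFx and DRx, which are
UF and DR with their external 3-base prefixes exchanged; they reuse the
existing UR and DF to form the half-Clips of the flipped part.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

from .seqcore import (
    Duplex,
    NucSeq,
    Overhang,
    PAPERCLIP_SEAM,
    SeamSpec,
    anneal,
    reverse_complement,
)

__all__ = [
    "Part",
    "Oligo",
    "HalfClip",
    "PartTooShortError",
    "TrimExhaustedError",
    "DEFAULT_MAX_TRIM",
    "design_upstream_half_clip",
    "design_downstream_half_clip",
    "design_part_oligos",
    "design_orientation_variants",
    "amplification_primers",
    "lcr_primer_variant",
]

#: First-window size of the design algorithm (bases of part sequence copied
#: into UF and DF before any trimming).
WINDOW = 40
#: Reverse-oligo windows are three bases shorter than their forward partner.
REVERSE_GAP = 3
#: Default bound on seam-collision trimming; unbounded trimming would erode
#: the priming homology of the downstream half-Clip.
DEFAULT_MAX_TRIM = 6

MIN_PART_LEN = WINDOW
#: Below this length the UF and DF windows do not overlap; shorter parts are
#: designable but the windows share sequence, which merits a warning.
NON_OVERLAP_LEN = 2 * WINDOW - 3  # 77: windows [1..40] and [L-39..L] disjoint

OligoRole = Literal[
    "UF", "UR", "DF", "DR", "UFx", "DRx",
    "IS_UF", "IS_UR", "IS_DF", "IS_DR", "LCR_UF", "LCR_DR",
]


@dataclass(frozen=True)
class Part:
    """A named DNA part to be assembled.

    ``is_cds`` marks protein-coding parts for reading-frame checks;
    ``allow_flip`` requests the two extra orientation-variant oligos.
    Parts shorter than 40 nt cannot host a design window and must be routed
    through intervening-sequence design instead.
    """

    id: str
    seq: NucSeq
    is_cds: bool = False
    allow_flip: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", NucSeq(self.seq))
        if not self.id:
            raise ValueError("part id must be non-empty")


@dataclass(frozen=True)
class Oligo:
    """A single-stranded oligonucleotide with its design role."""

    name: str
    role: OligoRole
    seq: NucSeq
    phosphorylated: bool = True


@dataclass(frozen=True)
class HalfClip:
    """An annealed duplex matching one end of one part.

    ``external_overhang`` is the 3-base seam overhang distal from the part's
    sequence; ``internal_overhang`` faces the part interior and exists only
    to keep the half-Clip's inner end from blunt-ligating. ``trim`` records
    how many leading bases were removed from the downstream window to avoid
    a seam collision (always 0 for upstream half-Clips).
    """

    part_id: str
    side: Literal["upstream", "downstream"]
    forward_oligo: Oligo
    reverse_oligo: Oligo
    duplex: Duplex
    external_overhang: Overhang
    internal_overhang: Overhang
    trim: int = 0


class PartTooShortError(ValueError):
    """Part shorter than the 40-base design window."""


class TrimExhaustedError(ValueError):
    """Seam-collision trimming exceeded the configured maximum."""


_overlap_warned: set[tuple[str, int]] = set()


def _require_length(part: Part) -> None:
    if len(part.seq) < MIN_PART_LEN:
        raise PartTooShortError(
            f"part {part.id!r} is {len(part.seq)} nt, shorter than the "
            f"{MIN_PART_LEN}-base design window; supply it as an intervening "
            "sequence (four-oligo route) instead"
        )
    key = (part.id, len(part.seq))
    if len(part.seq) < NON_OVERLAP_LEN and key not in _overlap_warned:
        _overlap_warned.add(key)  # warn once per part, not per operation
        warnings.warn(
            f"part {part.id!r} is {len(part.seq)} nt: its upstream and "
            "downstream design windows overlap",
            stacklevel=3,
        )


def design_upstream_half_clip(part: Part, seam: SeamSpec = PAPERCLIP_SEAM) -> HalfClip:
    """Design UF/UR and anneal them into the Upstream half-Clip."""
    _require_length(part)
    uf_seq = NucSeq(seam.top + part.seq[:WINDOW])
    ur_seq = reverse_complement(part.seq[: WINDOW - REVERSE_GAP])
    uf = Oligo(f"{part.id}_UF", "UF", uf_seq)
    ur = Oligo(f"{part.id}_UR", "UR", ur_seq)
    duplex = anneal(uf_seq, ur_seq)
    external = duplex.overhang_at(strand="top", end_chemistry="five_prime")
    internal = duplex.overhang_at(strand="top", end_chemistry="three_prime")
    assert external is not None and internal is not None
    return HalfClip(
        part_id=part.id,
        side="upstream",
        forward_oligo=uf,
        reverse_oligo=ur,
        duplex=duplex,
        external_overhang=external.with_position("external"),
        internal_overhang=internal.with_position("internal"),
        trim=0,
    )


def downstream_windows(
    part: Part, seam: SeamSpec = PAPERCLIP_SEAM, max_trim: int = DEFAULT_MAX_TRIM
) -> tuple[NucSeq, int]:
    """The trimmed downstream forward window and the trim count.

    Returns the shortest trim ``t ≥ 0`` such that the length-(40−t) suffix of
    the part does not begin with the seam on either strand.
    """
    _require_length(part)
    forbidden = {str(seam.top), str(seam.bottom)}
    for t in range(max_trim + 1):
        window = part.seq[len(part.seq) - (WINDOW - t):]
        if window[:3] not in forbidden:
            return NucSeq(window), t
    raise TrimExhaustedError(
        f"seam-collision trimming exhausted for part {part.id!r}: the last "
        f"{WINDOW}..{WINDOW - max_trim} bases all begin with {seam.top}/{seam.bottom}"
    )


def design_downstream_half_clip(
    part: Part, seam: SeamSpec = PAPERCLIP_SEAM, max_trim: int = DEFAULT_MAX_TRIM
) -> HalfClip:
    """Design DF/DR (with seam-collision trimming) and anneal the Downstream half-Clip."""
    df_seq, t = downstream_windows(part, seam, max_trim)
    dr_window = part.seq[len(part.seq) - (len(df_seq) - REVERSE_GAP):]
    dr_seq = NucSeq(seam.bottom + reverse_complement(dr_window))
    df = Oligo(f"{part.id}_DF", "DF", df_seq)
    dr = Oligo(f"{part.id}_DR", "DR", dr_seq)
    duplex = anneal(df_seq, dr_seq)
    external = duplex.overhang_at(strand="bottom", end_chemistry="five_prime")
    internal = duplex.overhang_at(strand="top", end_chemistry="five_prime")
    assert external is not None and internal is not None
    return HalfClip(
        part_id=part.id,
        side="downstream",
        forward_oligo=df,
        reverse_oligo=dr,
        duplex=duplex,
        external_overhang=external.with_position("external"),
        internal_overhang=internal.with_position("internal"),
        trim=t,
    )


def design_orientation_variants(
    part: Part, seam: SeamSpec = PAPERCLIP_SEAM, max_trim: int = DEFAULT_MAX_TRIM
) -> tuple[Oligo, Oligo]:
    """UFx and DRx: UF and DR with their external seam prefixes exchanged.

    UFx pairs with the existing UR to form a downstream-type half-Clip for
    the flipped part; DRx pairs with the existing DF to form its
    upstream-type half-Clip.
    """
    df_seq, _ = downstream_windows(part, seam, max_trim)
    dr_window = part.seq[len(part.seq) - (len(df_seq) - REVERSE_GAP):]
    ufx = Oligo(f"{part.id}_UFx", "UFx", NucSeq(seam.bottom + part.seq[:WINDOW]))
    drx = Oligo(f"{part.id}_DRx", "DRx", NucSeq(seam.top + reverse_complement(dr_window)))
    return ufx, drx


def design_part_oligos(
    part: Part, seam: SeamSpec = PAPERCLIP_SEAM, max_trim: int = DEFAULT_MAX_TRIM
) -> list[Oligo]:
    """All oligos for one part: UF, UR, DF, DR, plus UFx/DRx when flip-enabled."""
    up = design_upstream_half_clip(part, seam)
    down = design_downstream_half_clip(part, seam, max_trim)
    oligos = [up.forward_oligo, up.reverse_oligo, down.forward_oligo, down.reverse_oligo]
    if part.allow_flip:
        oligos.extend(design_orientation_variants(part, seam, max_trim))
    return oligos


def flipped_half_clips(
    part: Part, seam: SeamSpec = PAPERCLIP_SEAM, max_trim: int = DEFAULT_MAX_TRIM
) -> tuple[HalfClip, HalfClip]:
    """The (upstream, downstream) half-Clips of a part used in reverse orientation.

    In the flipped frame the part's forward strand is the reverse complement
    of its stored sequence. The upstream half-Clip of the flipped part is
    DRx annealed with DF; the downstream half-Clip is UFx annealed with UR.
    Duplexes are recorded in the junction frame (flipped-forward strand on
    top), so the external seam overhangs classify exactly as in the plain
    orientation; the seam-adjacent homology arms are 37 nt instead of 40
    because the variants reuse the 37-nt reverse windows.
    """
    if not part.allow_flip:
        raise ValueError(f"part {part.id!r} is not flip-enabled (allow_flip=False)")
    up_plain = design_upstream_half_clip(part, seam)
    down_plain = design_downstream_half_clip(part, seam, max_trim)
    ufx, drx = design_orientation_variants(part, seam, max_trim)

    # Flipped upstream half-Clip: top strand (flipped-forward) is DRx =
    # seam.top + first 37 of the flipped sequence, bottom strand is DF.
    # External 5' seam.top overhang on top; internal 3-base 5' overhang on
    # the bottom strand.
    up_duplex = anneal(drx.seq, down_plain.forward_oligo.seq)
    up_ext = up_duplex.overhang_at(strand="top", end_chemistry="five_prime")
    up_int = up_duplex.overhang_at(strand="bottom", end_chemistry="five_prime")
    assert up_ext is not None and up_int is not None
    up = HalfClip(
        part_id=part.id,
        side="upstream",
        forward_oligo=drx,
        reverse_oligo=down_plain.forward_oligo,
        duplex=up_duplex,
        external_overhang=up_ext.with_position("external"),
        internal_overhang=up_int.with_position("internal"),
        trim=down_plain.trim,
    )

    # Flipped downstream half-Clip: junction-frame top strand is UR (the
    # last 37 bases of the flipped sequence), bottom strand is UFx carrying
    # the 5' seam.bottom external overhang; internal 3' bottom overhang.
    down_duplex = anneal(up_plain.reverse_oligo.seq, ufx.seq)
    down_ext = down_duplex.overhang_at(strand="bottom", end_chemistry="five_prime")
    down_int = down_duplex.overhang_at(strand="bottom", end_chemistry="three_prime")
    assert down_ext is not None and down_int is not None
    down = HalfClip(
        part_id=part.id,
        side="downstream",
        forward_oligo=ufx,
        reverse_oligo=up_plain.reverse_oligo,
        duplex=down_duplex,
        external_overhang=down_ext.with_position("external"),
        internal_overhang=down_int.with_position("internal"),
        trim=0,
    )
    return up, down


def amplification_primers(
    part: Part, seam: SeamSpec = PAPERCLIP_SEAM, max_trim: int = DEFAULT_MAX_TRIM
) -> tuple[Oligo, Oligo, NucSeq]:
    """UF and DR double as PCR primers for the part.

    The predicted amplicon is ``seam.top + part + seam.top``: UF introduces
    the seam at the upstream end, and DR's seam-bottom prefix appears as
    seam.top on the forward strand's 3' end.
    """
    up = design_upstream_half_clip(part, seam)
    down = design_downstream_half_clip(part, seam, max_trim)
    amplicon = NucSeq(seam.top + part.seq + seam.top)
    return up.forward_oligo, down.reverse_oligo, amplicon


def lcr_primer_variant(
    part: Part,
    which: Literal["UF", "DR"],
    seam: SeamSpec = PAPERCLIP_SEAM,
    max_trim: int = DEFAULT_MAX_TRIM,
) -> Oligo:
    """Seam-free version of UF or DR for ligase-chain-reaction assembly.

    If both seam-bearing primers were used, the amplicon's two terminal
    seam copies would create a 3-base overlap between adjacent fragments
    that prevents LCR; one primer must omit its seam prefix.
    """
    if which == "UF":
        up = design_upstream_half_clip(part, seam)
        stripped = NucSeq(up.forward_oligo.seq[3:])
        return Oligo(f"{part.id}_LCR_UF", "LCR_UF", stripped)
    if which == "DR":
        down = design_downstream_half_clip(part, seam, max_trim)
        stripped = NucSeq(down.reverse_oligo.seq[3:])
        return Oligo(f"{part.id}_LCR_DR", "LCR_DR", stripped)
    raise ValueError(f"which must be 'UF' or 'DR', got {which!r}")
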