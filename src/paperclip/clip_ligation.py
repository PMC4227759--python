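"""Clip formation by ligation, intervening-sequence design, and bench worksheets.

A Clip is the ligation product of the Downstream half-Clip of one part and
the Upstream half-Clip of the next: the two 3-base seam overhangs (GCC/GGC
by default) anneal and are sealed, yielding a double-stranded bridge whose
two homology arms match the adjacent part ends. Short intervening elements
(RBSs, linkers, tags) enter as four extra oligos forming two duplexes whose
internal 5-base sticky ends are exact reverse complements, so ligating the
four strands restores the sequence of interest flanked by seams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .clip_design import HalfClip, Oligo
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
    "Clip",
    "InterveningDesign",
    "LigationTube",
    "MergeStep",
    "LigationWorksheet",
    "ligate_clip",
    "design_intervening",
    "intervening_ligation_plan",
    "render_bench_protocol",
]

#: Length of the complementary single-stranded sticky ends joining the two
#: intervening-sequence duplexes.
STICKY_END_LEN = 5
#: Admissible intervening-sequence lengths (method validated on 60/100 bp;
#: the floor guarantees two ≥5-nt duplex halves, the ceiling keeps the
#: element in synthesis-friendly oligo territory).
MIN_INTERVENING_LEN = 15
MAX_INTERVENING_LEN = 200
#: Search radius around the midpoint for an admissible sticky-end split.
SPLIT_SEARCH_RADIUS = 5


@dataclass(frozen=True)
class Clip:
    """The double-stranded bridge spanning one junction.

    ``top_strand`` runs 5'→3' from the upstream part into the downstream
    part of the junction; ``seam_position`` is the 1-based index of the
    seam's first base on it. ``homology_left``/``homology_right`` give how
    many bases match the flanking parts' 3' and 5' ends respectively.
    """

    upstream_part_id: str
    downstream_part_id: str
    top_strand: NucSeq
    bottom_strand: NucSeq
    seam_position: int
    homology_left: int
    homology_right: int
    seam: SeamSpec = PAPERCLIP_SEAM

    @property
    def name(self) -> str:
        return f"{self.upstream_part_id}--{self.downstream_part_id}"

    @property
    def seam_top(self) -> NucSeq:
        return NucSeq(
            self.top_strand[self.seam_position - 1 : self.seam_position + 2]
        )


def ligate_clip(down: HalfClip, up: HalfClip, seam: SeamSpec = PAPERCLIP_SEAM) -> Clip:
    """Ligate a Downstream half-Clip to an Upstream half-Clip.

    The external overhangs must be the complementary seam pair: seam.bottom
    (5' bottom overhang) on the downstream half, seam.top (5' top overhang)
    on the upstream half. The junction reads downstream-half part →
    upstream-half part.
    """
    if down.side != "downstream" or up.side != "upstream":
        raise ValueError(
            f"ligate_clip needs (downstream, upstream) half-Clips, got "
            f"({down.side}, {up.side})"
        )
    if (
        down.external_overhang.sequence != seam.bottom
        or up.external_overhang.sequence != seam.top
    ):
        raise ValueError(
            "incompatible external overhangs: "
            f"{down.external_overhang.sequence}/{up.external_overhang.sequence} "
            f"do not form the {seam.top}/{seam.bottom} seam"
        )
    down_top = down.duplex.top_strand
    up_top = up.duplex.top_strand  # begins with seam.top
    top = NucSeq(down_top + up_top)
    bottom = NucSeq(up.duplex.bottom_strand + down.duplex.bottom_strand)
    return Clip(
        upstream_part_id=down.part_id,
        downstream_part_id=up.part_id,
        top_strand=top,
        bottom_strand=bottom,
        seam_position=len(down_top) + 1,
        homology_left=len(down_top),
        homology_right=len(up_top) - len(seam.top),
        seam=seam,
    )


@dataclass(frozen=True)
class InterveningDesign:
    """Four-oligo realisation of a short intervening sequence S.

    The sequence is split after top-strand base m. The upstream duplex
    (IS_UF + IS_UR) carries the seam.top external overhang and a 5-base
    5' bottom overhang; the downstream duplex (IS_DF + IS_DR) carries the
    complementary 5-base 5' top overhang (``sticky_end`` = S[m+1..m+5]) and
    the seam.bottom external overhang. Ligating all four strands restores
    seam.top + S on the top strand.
    """

    seq: NucSeq
    split: int  # 1-based index of the last top-strand base of the upstream duplex
    oligos: tuple[Oligo, Oligo, Oligo, Oligo]  # IS_UF, IS_UR, IS_DF, IS_DR
    sticky_end: NucSeq
    seam: SeamSpec = PAPERCLIP_SEAM

    # The duplexes are constructed from the known design geometry rather than
    # re-aligned: their double-stranded halves can be shorter than any
    # register the generic annealer would accept unambiguously.

    @property
    def upstream_duplex(self) -> Duplex:
        seam_len = len(self.seam.top)
        return Duplex(
            top_strand=self.oligos[0].seq,
            bottom_strand=self.oligos[1].seq,
            alignment_offset=seam_len + 1,
            overhangs=(
                Overhang(self.seam.top, "top", "five_prime", "external"),
                Overhang(
                    reverse_complement(self.sticky_end), "bottom", "five_prime", "internal"
                ),
            ),
        )

    @property
    def downstream_duplex(self) -> Duplex:
        return Duplex(
            top_strand=self.oligos[2].seq,
            bottom_strand=self.oligos[3].seq,
            alignment_offset=STICKY_END_LEN + 1,
            overhangs=(
                Overhang(self.sticky_end, "top", "five_prime", "internal"),
                Overhang(self.seam.bottom, "bottom", "five_prime", "external"),
            ),
        )

    def reconstructed_top(self) -> NucSeq:
        """Top strand of the fully ligated product (seam.top + S)."""
        return NucSeq(self.oligos[0].seq + self.oligos[2].seq)

    def reconstructed_bottom(self) -> NucSeq:
        """Bottom strand of the fully ligated product (seam.bottom + rc(S))."""
        return NucSeq(self.oligos[3].seq + self.oligos[1].seq)


def _is_homopolymer(s: str) -> bool:
    return len(set(s)) == 1


def _is_self_complementary(s: str) -> bool:
    return s == str(reverse_complement(s))


def design_intervening(
    seq: str,
    seam: SeamSpec = PAPERCLIP_SEAM,
    split: Optional[int] = None,
    name: str = "IS",
) -> InterveningDesign:
    """Design the four-oligo set for an intervening sequence.

    When ``split`` is not given, the midpoint is used, searching up to ±5
    positions for a sticky end that is neither a homopolymer nor
    self-complementary (either property would allow mis-ligation).
    """
    s = NucSeq(seq)
    n = len(s)
    if not MIN_INTERVENING_LEN <= n <= MAX_INTERVENING_LEN:
        raise ValueError(
            f"intervening sequence must be {MIN_INTERVENING_LEN}-"
            f"{MAX_INTERVENING_LEN} nt, got {n}"
        )

    def admissible(m: int) -> bool:
        return STICKY_END_LEN <= m <= n - STICKY_END_LEN

    if split is not None:
        if not admissible(split):
            raise ValueError(
                f"split must lie in [{STICKY_END_LEN}, {n - STICKY_END_LEN}], got {split}"
            )
        m = split
    else:
        mid = n // 2
        for delta in sorted(range(-SPLIT_SEARCH_RADIUS, SPLIT_SEARCH_RADIUS + 1), key=abs):
            cand = mid + delta
            if not admissible(cand):
                continue
            sticky = s[cand : cand + STICKY_END_LEN]
            if not _is_homopolymer(sticky) and not _is_self_complementary(sticky):
                m = cand
                break
        else:
            raise ValueError(
                "no admissible split: every sticky end near the midpoint is "
                "homopolymeric or self-complementary"
            )

    sticky = NucSeq(s[m : m + STICKY_END_LEN])
    tail = s[m + STICKY_END_LEN :]  # empty when the split sits 5 nt from the end
    rc_tail = str(reverse_complement(tail)) if tail else ""
    is_uf = Oligo(f"{name}_UF", "IS_UF", NucSeq(seam.top + s[:m]))
    is_ur = Oligo(f"{name}_UR", "IS_UR", reverse_complement(s[: m + STICKY_END_LEN]))
    is_df = Oligo(f"{name}_DF", "IS_DF", NucSeq(s[m:]))
    is_dr = Oligo(f"{name}_DR", "IS_DR", NucSeq(seam.bottom + rc_tail))
    return InterveningDesign(
        seq=s, split=m, oligos=(is_uf, is_ur, is_df, is_dr), sticky_end=sticky, seam=seam
    )


@dataclass(frozen=True)
class LigationTube:
    """One ligation reaction: the duplexes mixed in a single tube."""

    tube_id: str
    contents: tuple[str, ...]  # human-readable duplex/half-Clip labels
    incubation: str = "16°C for 1 h, then heat-inactivate at 65°C for 20 min"


@dataclass(frozen=True)
class MergeStep:
    tube_ids: tuple[str, ...]
    incubation: str = "mix tube contents, 16°C for a further 1 h"


@dataclass(frozen=True)
class LigationWorksheet:
    """Bench plan: tubes to set up, then merges, realizing every junction."""

    tubes: tuple[LigationTube, ...]
    merge_steps: tuple[MergeStep, ...] = ()
    reagent_notes: str = ""

    def __add__(self, other: "LigationWorksheet") -> "LigationWorksheet":
        notes = "\n".join(x for x in (self.reagent_notes, other.reagent_notes) if x)
        return LigationWorksheet(
            self.tubes + other.tubes, self.merge_steps + other.merge_steps, notes
        )


def _half_clip_label(hc: HalfClip) -> str:
    return f"{hc.part_id} {hc.side} half-Clip ({hc.forward_oligo.name}+{hc.reverse_oligo.name})"


def clip_ligation_tube(down: HalfClip, up: HalfClip, tube_id: str) -> LigationTube:
    return LigationTube(tube_id, (_half_clip_label(down), _half_clip_label(up)))


def intervening_ligation_plan(
    design: InterveningDesign,
    flanking_down: HalfClip,
    flanking_up: HalfClip,
    tube_prefix: str = "T",
) -> LigationWorksheet:
    """Two-tube scheme for a junction carrying an intervening sequence.

    Tube 1: downstream half-Clip + upstream intervening duplex (joined by
    the seam overhangs). Tube 2: downstream intervening duplex + upstream
    half-Clip of the following part. After 1 h the tubes are mixed and the
    5-base sticky ends restore the sequence of interest.
    """
    if flanking_down.side != "downstream" or flanking_up.side != "upstream":
        raise ValueError(
            "intervening_ligation_plan needs (downstream, upstream) flanking half-Clips"
        )
    is_name = design.oligos[0].name.rsplit("_", 1)[0]
    t1 = LigationTube(
        f"{tube_prefix}1",
        (
            _half_clip_label(flanking_down),
            f"{is_name} upstream duplex ({design.oligos[0].name}+{design.oligos[1].name})",
        ),
    )
    t2 = LigationTube(
        f"{tube_prefix}2",
        (
            f"{is_name} downstream duplex ({design.oligos[2].name}+{design.oligos[3].name})",
            _half_clip_label(flanking_up),
        ),
    )
    merge = MergeStep((t1.tube_id, t2.tube_id))
    return LigationWorksheet((t1, t2), (merge,))


#: Bench constants rendered into protocols (overridable via render args).
RESUSPENSION_UM = 100
ANNEALING_UM = 40
LIGATION_UM = 14


def render_bench_protocol(
    worksheet: LigationWorksheet,
    reaction_volume_ul: float = 10.0,
) -> str:
    """Human-readable Markdown protocol for a ligation worksheet.

    Embeds the method's working concentrations: oligos resuspended at
    100 μM; phosphorylation/annealing at 40 μM each oligo (anneal by slow
    cooling 95°C → 4°C); half-Clips ligated at 14 μM each, 16°C for 1 h,
    heat inactivation 65°C for 20 min. Volumes scale with the reaction size.
    """
    if not worksheet.tubes:
        return ""
    # Each half-Clip stock is at ANNEALING_UM after annealing; volume to
    # reach LIGATION_UM in the final reaction:
    vol_each = reaction_volume_ul * LIGATION_UM / ANNEALING_UM
    lines = [
        "# Ligation protocol",
        "",
        "## Oligo preparation",
        f"- Resuspend each oligonucleotide to {RESUSPENSION_UM} μM in nuclease-free water.",
        f"- Mix forward and reverse oligos ({ANNEALING_UM} μM each), phosphorylate "
        "with T4 polynucleotide kinase + 1 mM ATP, 30 min at 37°C.",
        "- Add NaCl to 500 mM and anneal by slow cooling from 95°C to 4°C "
        "(~0.1°C/s) to form each half-Clip / duplex.",
        "",
        "## Ligations",
    ]
    for tube in worksheet.tubes:
        lines.append(f"### Tube {tube.tube_id} ({reaction_volume_ul:g} μl)")
        for item in tube.contents:
            lines.append(
                f"- {vol_each:.2f} μl {item} (final concentration {LIGATION_UM} μM)"
            )
        lines.append("- T4 DNA ligase + 1 mM ATP; incubate " + tube.incubation + ".")
        lines.append("")
    if worksheet.merge_steps:
        lines.append("## Merges")
        for step in worksheet.merge_steps:
            lines.append(f"- Combine tubes {', '.join(step.tube_ids)}: {step.incubation}.")
        lines.append("")
    if worksheet.reagent_notes:
        lines.append("## Notes")
        lines.append(worksheet.reagent_notes)
        lines.append("")
    return "\n".join(lines)
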