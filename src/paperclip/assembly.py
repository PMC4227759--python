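"""Assembly planning and in-silico simulation of the circular product.

An assembly is an ordered circular arrangement of a backbone plus parts
(optionally flipped, optionally followed by a short intervening sequence).
Each adjacency — including the wrap-around from the last element back to the
backbone — is realised by one Clip (or, where an intervening sequence is
inserted, a two-tube chain of ligations). The predicted construct is the
circular concatenation of the elements joined by 3-base seams: the terminal
seam copies that PCR puts on every part and the seam carried by the Clip are
identical and collapse onto a single seam per junction during
homology-directed assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Optional, Sequence

from .clip_design import (
    HalfClip,
    Oligo,
    Part,
    design_downstream_half_clip,
    design_part_oligos,
    design_upstream_half_clip,
    flipped_half_clips,
)
from .clip_ligation import (
    Clip,
    InterveningDesign,
    LigationWorksheet,
    clip_ligation_tube,
    design_intervening,
    intervening_ligation_plan,
    ligate_clip,
)
from .seqcore import NucSeq, PAPERCLIP_SEAM, SeamSpec, reverse_complement

__all__ = [
    "AssemblyElement",
    "Junction",
    "AssemblyPlan",
    "PredictedConstruct",
    "plan_assembly",
    "simulate_assembly",
    "count_oligos",
    "OligoReuseReport",
    "part_input_forms",
]

AssemblyMethod = Literal["pcr", "cell_extract"]


@dataclass(frozen=True)
class AssemblyElement:
    """One slot of the circular arrangement (element 1 is the backbone)."""

    part_id: str
    flipped: bool = False
    intervening_after: Optional[NucSeq] = None

    def __post_init__(self) -> None:
        if self.intervening_after is not None:
            object.__setattr__(self, "intervening_after", NucSeq(self.intervening_after))


@dataclass(frozen=True)
class Junction:
    """One adjacency and the ligation chain realizing it.

    A plain junction is one Clip; an intervening junction carries the
    four-oligo design and counts as two Clips' worth of ligation products
    (the two tube products joined by the 5-base sticky ends).
    """

    left_part_id: str
    right_part_id: str
    clip: Optional[Clip] = None
    intervening: Optional[InterveningDesign] = None

    @property
    def n_clips(self) -> int:
        return 2 if self.intervening is not None else 1


@dataclass(frozen=True)
class AssemblyPlan:
    """A fully planned circular assembly: elements, junctions, worksheet."""

    elements: tuple[AssemblyElement, ...]
    junctions: tuple[Junction, ...]
    worksheet: LigationWorksheet
    library: Mapping[str, Part]
    seam: SeamSpec = PAPERCLIP_SEAM
    method: AssemblyMethod = "pcr"
    name: str = "assembly"
    circular: bool = True

    @property
    def n_clips(self) -> int:
        return sum(j.n_clips for j in self.junctions)


def _half_clips_for(
    part: Part, flipped: bool, seam: SeamSpec
) -> tuple[HalfClip, HalfClip]:
    """(upstream, downstream) half-Clips of the element as oriented in the plan."""
    if flipped:
        if not part.allow_flip:
            raise ValueError(
                f"element requests flipped orientation but part {part.id!r} "
                "has allow_flip=False (orientation-variant oligos not designed)"
            )
        return flipped_half_clips(part, seam)
    return (
        design_upstream_half_clip(part, seam),
        design_downstream_half_clip(part, seam),
    )


def plan_assembly(
    library: Mapping[str, Part],
    order: Sequence[AssemblyElement],
    seam: SeamSpec = PAPERCLIP_SEAM,
    method: AssemblyMethod = "pcr",
    name: str = "assembly",
) -> AssemblyPlan:
    """Turn an ordered arrangement into Clips and a ligation worksheet.

    One Clip covers each adjacent pair and the wrap-around pair; junctions
    with an intervening sequence expand into the two-tube chain. Duplicate
    part ids are rejected here (homology-directed assembly cannot tolerate
    repeated parts; see the validation module for the full constraint set).
    """
    elements = tuple(order)
    if len(elements) < 1:
        raise ValueError("an assembly needs at least one element")
    seen: set[str] = set()
    for el in elements:
        if el.part_id not in library:
            raise KeyError(f"unknown part {el.part_id!r} (not in library)")
        if el.part_id in seen:
            raise ValueError(
                f"duplicate part {el.part_id!r}: assemblies cannot contain repetitive parts"
            )
        seen.add(el.part_id)

    junctions: list[Junction] = []
    worksheet = LigationWorksheet(())
    n = len(elements)
    for i, el in enumerate(elements):
        nxt = elements[(i + 1) % n]
        part = library[el.part_id]
        next_part = library[nxt.part_id]
        _, down = _half_clips_for(part, el.flipped, seam)
        up, _ = _half_clips_for(next_part, nxt.flipped, seam)
        if el.intervening_after is not None:
            design = design_intervening(
                el.intervening_after, seam, name=f"IS{i + 1}"
            )
            chain = intervening_ligation_plan(design, down, up, tube_prefix=f"J{i + 1}.")
            # One logical junction chain covers part -> IS -> next part; it
            # is recorded as a single Junction (two ligation products).
            junctions.append(Junction(el.part_id, nxt.part_id, intervening=design))
            worksheet = worksheet + chain
        else:
            clip = ligate_clip(down, up, seam)
            junctions.append(Junction(el.part_id, nxt.part_id, clip=clip))
            worksheet = worksheet + LigationWorksheet(
                (clip_ligation_tube(down, up, f"J{i + 1}"),)
            )
    notes = {
        "pcr": "Assembly route: PCR (Clips extend parts by mutual priming; "
        "circular product forms by homology-directed extension).",
        "cell_extract": "Assembly route: cell-extract mediated homologous "
        "recombination (mix parts and Clips with extract; transform directly).",
    }[method]
    worksheet = LigationWorksheet(worksheet.tubes, worksheet.merge_steps, notes)
    return AssemblyPlan(
        elements=elements,
        junctions=tuple(junctions),
        worksheet=worksheet,
        library=dict(library),
        seam=seam,
        method=method,
        name=name,
    )


@dataclass(frozen=True)
class ConstructFeature:
    kind: Literal["part", "seam", "intervening"]
    start: int  # 1-based, inclusive
    end: int
    label: str
    strand: int = 1  # -1 for flipped parts


@dataclass(frozen=True)
class PredictedConstruct:
    """The in-silico circular product at its canonical rotation.

    The sequence starts at base 1 of the first element (the backbone);
    ``junctions`` lists (position, seam 3-mer, left element, right element)
    with position the 1-based start of the seam on the canonical rotation.
    """

    seq: NucSeq
    junctions: tuple[tuple[int, NucSeq, str, str], ...]
    features: tuple[ConstructFeature, ...]
    name: str = "construct"

    @property
    def length(self) -> int:
        return len(self.seq)


def simulate_assembly(plan: AssemblyPlan) -> PredictedConstruct:
    """Predict the circular construct sequence with seam-annotated junctions.

    Per element in order: the element sequence (reverse-complemented if
    flipped), then — if an intervening sequence follows — a seam and the
    intervening sequence, then the seam joining to the next element. The
    assembled circle contains nicks at the bench; sequence-wise the product
    is the seam-joined concatenation.
    """
    chunks: list[str] = []
    junctions: list[tuple[int, NucSeq, str, str]] = []
    features: list[ConstructFeature] = []
    seam = plan.seam
    pos = 1  # running 1-based coordinate

    def emit(s: str) -> tuple[int, int]:
        nonlocal pos
        chunks.append(s)
        start = pos
        pos += len(s)
        return start, pos - 1

    n = len(plan.elements)
    for i, el in enumerate(plan.elements):
        part = plan.library[el.part_id]
        part_seq = reverse_complement(part.seq) if el.flipped else part.seq
        start, end = emit(part_seq)
        features.append(
            ConstructFeature("part", start, end, el.part_id, -1 if el.flipped else 1)
        )
        nxt = plan.elements[(i + 1) % n]
        if el.intervening_after is not None:
            s_start, s_end = emit(seam.top)
            features.append(ConstructFeature("seam", s_start, s_end, "seam"))
            junctions.append((s_start, seam.top, el.part_id, f"IS{i + 1}"))
            is_start, is_end = emit(el.intervening_after)
            features.append(
                ConstructFeature("intervening", is_start, is_end, f"IS{i + 1}")
            )
            left = f"IS{i + 1}"
        else:
            left = el.part_id
        s_start, s_end = emit(seam.top)
        features.append(ConstructFeature("seam", s_start, s_end, "seam"))
        junctions.append((s_start, seam.top, left, nxt.part_id))

    seq = NucSeq("".join(chunks))
    return PredictedConstruct(
        seq=seq,
        junctions=tuple(junctions),
        features=tuple(features),
        name=plan.name,
    )


@dataclass(frozen=True)
class OligoReuseReport:
    """Oligo/half-Clip/Clip accounting across one or more plans on a shared library."""

    n_parts: int
    n_oligos: int
    n_amplification_primers: int
    n_half_clips: int
    n_distinct_clips: int
    oligos: tuple[Oligo, ...]
    clips_by_plan: Mapping[str, tuple[str, ...]]
    shared_clips: tuple[str, ...]  # clips appearing in more than one plan

    def render(self) -> str:
        lines = [
            f"Parts in library:            {self.n_parts}",
            f"Distinct oligonucleotides:   {self.n_oligos}",
            f"  of which PCR primers:      {self.n_amplification_primers} (UF and DR of each part)",
            f"Distinct half-Clips:         {self.n_half_clips}",
            f"Distinct Clips across plans: {self.n_distinct_clips}",
        ]
        for plan_name, clips in self.clips_by_plan.items():
            lines.append(f"Plan {plan_name}: clips {', '.join(clips) if clips else '(none)'}")
        if self.shared_clips:
            lines.append(f"Clips reused between plans: {', '.join(self.shared_clips)}")
        return "\n".join(lines)


def count_oligos(
    plans: Sequence[AssemblyPlan],
    seam: SeamSpec = PAPERCLIP_SEAM,
) -> OligoReuseReport:
    """Account for oligo reuse: a library of n parts (d flip-enabled) needs
    only 4n + 2d oligos to support assemblies in any order, 2n of which
    (UF and DR) double as the PCR amplification primers."""
    if not plans:
        raise ValueError("count_oligos needs at least one plan")
    library = plans[0].library
    for p in plans[1:]:
        if dict(p.library) != dict(library):
            raise ValueError("plans must share one part library")
    seam = plans[0].seam

    oligos: list[Oligo] = []
    seen_seqs: set[str] = set()
    for part_id in sorted(library):
        for oligo in design_part_oligos(library[part_id], seam):
            if str(oligo.seq) not in seen_seqs:
                seen_seqs.add(str(oligo.seq))
                oligos.append(oligo)
    n_parts = len(library)
    n_flip = sum(1 for p in library.values() if p.allow_flip)
    n_half_clips = 2 * n_parts + 2 * n_flip

    clips_by_plan: dict[str, tuple[str, ...]] = {}
    clip_plans: dict[str, list[str]] = {}
    for plan in plans:
        names = []
        for j in plan.junctions:
            label = f"{j.left_part_id}--{j.right_part_id}"
            if j.intervening is not None:
                label += "(+IS)"
            names.append(label)
            clip_plans.setdefault(label, []).append(plan.name)
        clips_by_plan[plan.name] = tuple(names)
    shared = tuple(sorted(c for c, ps in clip_plans.items() if len(ps) > 1))

    return OligoReuseReport(
        n_parts=n_parts,
        n_oligos=len(oligos),
        n_amplification_primers=2 * n_parts,
        n_half_clips=n_half_clips,
        n_distinct_clips=len(clip_plans),
        oligos=tuple(oligos),
        clips_by_plan=clips_by_plan,
        shared_clips=shared,
    )


#: The five accepted physical forms of a DNA part, with practical notes.
_INPUT_FORMS = (
    ("pcr_product", "PCR product amplified with the part's UF and DR primers", ""),
    ("linearized_plasmid", "plasmid linearized outside the part", ""),
    (
        "uncut_plasmid",
        "undigested circular plasmid carrying the part",
        "lowest assembly efficiency of the five forms",
    ),
    ("excised_exact", "part excised precisely at its ends", ""),
    (
        "excised_with_flanks",
        "part excised with up to 32 bp of flanking DNA",
        "",
    ),
)


def part_input_forms(part: Part) -> list[dict[str, str]]:
    """Advisory record of the physical forms in which a part can enter assembly.

    Purely informational metadata for order sheets; none of the forms needs a
    DNA purification step before assembly.
    """
    records = [
        {"part_id": part.id, "form": form, "description": desc, "notes": notes}
        for form, desc, notes in _INPUT_FORMS
    ]
    records.append(
        {
            "part_id": part.id,
            "form": "any",
            "description": "general note",
            "notes": "no DNA purification step is required prior to assembly",
        }
    )
    return records
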