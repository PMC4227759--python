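"""Design-rule validation for planned assemblies.

Because assembly is homology-directed, a construct must not contain
repeated parts or stretches of identity longer than 40 bases anywhere —
during amplification or recombination the region between two copies would
be spliced out. Identity screening here is conservative: every unordered
pair of element sequences is compared on both strands, and each sequence is
screened against itself for internal direct and inverted repeats, since
homology acts on double-stranded DNA.

Additional checks cover seam/overhang fidelity (internal overhangs must
never be seam-valued, or a half-Clip could ligate at the wrong end) and
reading-frame bookkeeping for protein fusions (the 3-base seam inserts one
codon — alanine for GCC — which is only innocuous if it lands in frame).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Iterable, Literal, Optional

from Bio.Seq import Seq

from .assembly import AssemblyPlan, _half_clips_for
from .seqcore import NucSeq, reverse_complement

__all__ = [
    "Finding",
    "ValidationReport",
    "DEFAULT_IDENTITY_THRESHOLD",
    "longest_common_substring",
    "check_identical_regions",
    "check_repeated_parts",
    "check_overhang_fidelity",
    "check_reading_frame",
    "validate_design",
]

#: A construct may share at most this many bases of identity between any two
#: regions; longer identity is spliced out by the homology machinery.
DEFAULT_IDENTITY_THRESHOLD = 40

Severity = Literal["error", "warning", "info"]


@dataclass(frozen=True)
class Finding:
    """One validation observation.

    ``code`` is a stable machine-readable identifier; ``locus`` names the
    part(s) or junction concerned; ``measured`` carries the offending
    quantity (e.g. a shared-region length) where one exists.
    """

    code: str
    severity: Severity
    message: str
    locus: str
    measured: Optional[int] = None


@dataclass(frozen=True)
class ValidationReport:
    findings: tuple[Finding, ...]

    @property
    def passed(self) -> bool:
        return not any(f.severity == "error" for f in self.findings)

    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    def render(self) -> str:
        lines = [f"Validation: {'PASSED' if self.passed else 'FAILED'} "
                 f"({len(self.findings)} finding(s))"]
        for f in self.findings:
            measured = f" [measured={f.measured}]" if f.measured is not None else ""
            lines.append(f"  {f.severity.upper():7s} {f.code} @ {f.locus}: {f.message}{measured}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {"passed": self.passed, "findings": [asdict(f) for f in self.findings]},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ValidationReport":
        data = json.loads(text)
        return cls(tuple(Finding(**f) for f in data["findings"]))


def longest_common_substring(a: str, b: str) -> tuple[int, int, int]:
    """Length and 1-based start coordinates (in a, in b) of the longest
    common substring, via binary search over shared k-mer sets.

    Ties are broken toward the smallest start in ``a``, then in ``b``.
    """
    a, b = str(a), str(b)
    if not a or not b:
        return 0, 0, 0

    def find(k: int) -> Optional[tuple[int, int]]:
        if k == 0:
            return (1, 1)
        if k > len(a) or k > len(b):
            return None
        kmers: dict[str, int] = {}
        for i in range(len(a) - k + 1):
            kmers.setdefault(a[i : i + k], i)
        best: Optional[tuple[int, int]] = None
        for j in range(len(b) - k + 1):
            i = kmers.get(b[j : j + k])
            if i is not None and (best is None or (i, j) < best):
                best = (i, j)
        return best

    lo, hi = 0, min(len(a), len(b))
    best_k, best_pos = 0, (0, 0)
    while lo <= hi:
        mid = (lo + hi) // 2
        hit = find(mid)
        if hit is not None:
            best_k, best_pos = mid, hit
            lo = mid + 1
        else:
            hi = mid - 1
    if best_k == 0:
        return 0, 0, 0
    return best_k, best_pos[0] + 1, best_pos[1] + 1


def longest_internal_repeat(s: str) -> tuple[int, int, int]:
    """Longest substring occurring at two distinct positions of ``s``
    (direct internal repeat), with 1-based starts; (0,0,0) if none."""
    s = str(s)
    n = len(s)

    def find(k: int) -> Optional[tuple[int, int]]:
        if k == 0 or k > n - 1:
            return None
        seen: dict[str, int] = {}
        best: Optional[tuple[int, int]] = None
        for i in range(n - k + 1):
            kmer = s[i : i + k]
            if kmer in seen:
                cand = (seen[kmer], i)
                if best is None or cand < best:
                    best = cand
            else:
                seen[kmer] = i
        return best

    lo, hi = 1, n - 1
    best_k, best_pos = 0, (0, 0)
    while lo <= hi:
        mid = (lo + hi) // 2
        hit = find(mid)
        if hit is not None:
            best_k, best_pos = mid, hit
            lo = mid + 1
        else:
            hi = mid - 1
    if best_k == 0:
        return 0, 0, 0
    return best_k, best_pos[0] + 1, best_pos[1] + 1


def _element_sequences(plan: AssemblyPlan) -> list[tuple[str, NucSeq]]:
    out = []
    for el in plan.elements:
        seq = plan.library[el.part_id].seq
        if el.flipped:
            seq = reverse_complement(seq)
        out.append((el.part_id, seq))
    return out


def check_identical_regions(
    plan: AssemblyPlan, threshold: int = DEFAULT_IDENTITY_THRESHOLD
) -> list[Finding]:
    """Error for every identity stretch strictly longer than ``threshold``.

    Screens all unordered element pairs (forward and reverse-complement),
    plus each element against itself for internal direct repeats and
    against its own reverse complement for inverted repeats.
    """
    findings: list[Finding] = []
    seqs = _element_sequences(plan)
    for i, (id_a, a) in enumerate(seqs):
        # self: internal direct repeat (excluding the trivial full match)
        k, pa, pb = longest_internal_repeat(a)
        if k > threshold:
            findings.append(
                Finding(
                    "identical_region",
                    "error",
                    f"internal direct repeat of {k} nt in {id_a} "
                    f"(positions {pa} and {pb}); more than {threshold} identical "
                    "bases will be spliced out during assembly",
                    locus=id_a,
                    measured=k,
                )
            )
        # self vs reverse complement: inverted repeat
        k, pa, pb = longest_common_substring(a, reverse_complement(a))
        if k > threshold:
            findings.append(
                Finding(
                    "identical_region_rc",
                    "error",
                    f"inverted repeat of {k} nt within {id_a} "
                    f"(position {pa} vs rc position {pb})",
                    locus=id_a,
                    measured=k,
                )
            )
        for id_b, b in seqs[i + 1 :]:
            k, pa, pb = longest_common_substring(a, b)
            krc, pa_rc, pb_rc = longest_common_substring(a, reverse_complement(b))
            if krc > k:
                k, pa, pb, strand = krc, pa_rc, pb_rc, " (reverse complement)"
            else:
                strand = ""
            if k > threshold:
                findings.append(
                    Finding(
                        "identical_region",
                        "error",
                        f"{id_a} and {id_b} share {k} identical bases{strand} "
                        f"({id_a} position {pa}, {id_b} position {pb}); limit is "
                        f"{threshold}",
                        locus=f"{id_a}|{id_b}",
                        measured=k,
                    )
                )
    return findings


def check_repeated_parts(plan: AssemblyPlan) -> list[Finding]:
    """Error if any part id occurs more than once in the arrangement."""
    findings: list[Finding] = []
    seen: dict[str, int] = {}
    for idx, el in enumerate(plan.elements, start=1):
        if el.part_id in seen:
            note = ""
            if el.flipped or plan.elements[seen[el.part_id] - 1].flipped:
                note = (
                    " (one copy is flipped: its reverse complement is still "
                    ">40 nt identical on the opposite strand, see "
                    "identical-region findings)"
                )
            findings.append(
                Finding(
                    "repeated_part",
                    "error",
                    f"part {el.part_id!r} appears at positions {seen[el.part_id]} "
                    f"and {idx}; assemblies cannot contain repetitive parts{note}",
                    locus=el.part_id,
                )
            )
        else:
            seen[el.part_id] = idx
    return findings


def check_overhang_fidelity(plan: AssemblyPlan) -> list[Finding]:
    """Seam-collision and cross-ligation screening of the plan's half-Clips.

    A downstream internal overhang equal to the seam (either strand) is an
    error — the trimming rule makes this unreachable, so hitting it signals
    a design defect. An upstream internal overhang equal to the seam is a
    warning (it could ligate to a seam overhang in the same tube), as is a
    mutually complementary pair of internal overhangs within one ligation
    tube (the two half-Clips could join at the wrong end).
    """
    findings: list[Finding] = []
    seam = plan.seam
    seam_set = {str(seam.top), str(seam.bottom)}
    for idx, el in enumerate(plan.elements, start=1):
        part = plan.library[el.part_id]
        up, down = _half_clips_for(part, el.flipped, seam)
        d_int = str(down.internal_overhang.sequence)
        u_int = str(up.internal_overhang.sequence)
        if d_int in seam_set:
            findings.append(
                Finding(
                    "seam_internal_overhang",
                    "error",
                    f"downstream internal overhang {d_int} of {el.part_id} is "
                    "seam-valued despite trimming (design defect)",
                    locus=el.part_id,
                )
            )
        if u_int in seam_set:
            findings.append(
                Finding(
                    "seam_internal_overhang_upstream",
                    "warning",
                    f"upstream internal overhang {u_int} of {el.part_id} equals a "
                    "seam overhang and could ligate to seam ends in the same tube",
                    locus=el.part_id,
                )
            )
    # per ligation tube: the downstream half of element i meets the upstream
    # half of element i+1; complementary internal overhangs would let the
    # tube's two half-Clips ligate internally-to-internally.
    n = len(plan.elements)
    for i, el in enumerate(plan.elements):
        nxt = plan.elements[(i + 1) % n]
        _, down = _half_clips_for(plan.library[el.part_id], el.flipped, seam)
        up, _ = _half_clips_for(plan.library[nxt.part_id], nxt.flipped, seam)
        d_int = down.internal_overhang.sequence
        u_int = up.internal_overhang.sequence
        if str(reverse_complement(d_int)) == str(u_int):
            findings.append(
                Finding(
                    "complementary_internal_overhangs",
                    "warning",
                    f"internal overhangs {d_int}/{u_int} in the "
                    f"{el.part_id}--{nxt.part_id} ligation tube are mutually "
                    "complementary and could mis-ligate",
                    locus=f"{el.part_id}|{nxt.part_id}",
                )
            )
    return findings


def check_reading_frame(plan: AssemblyPlan) -> list[Finding]:
    """Frame bookkeeping for runs of consecutive CDS parts.

    Each seam between two CDS parts inserts one codon (GCC → Ala, CTA → Leu)
    provided it lands in frame: the cumulative length of the upstream CDS
    parts in the run must be a multiple of 3 (seams contribute 3 each, so
    they never shift the frame). A seam codon that is a stop is flagged.
    """
    findings: list[Finding] = []
    seam_codon = str(plan.seam.top)
    aa = str(Seq(seam_codon).translate())
    n = len(plan.elements)
    run_len = 0  # cumulative CDS bases since the run started
    for i, el in enumerate(plan.elements):
        part = plan.library[el.part_id]
        if not part.is_cds:
            run_len = 0
            continue
        nxt = plan.elements[(i + 1) % n]
        next_part = plan.library[nxt.part_id]
        run_len += len(part.seq)
        if not next_part.is_cds or (i + 1) >= n:
            continue
        locus = f"{el.part_id}|{nxt.part_id}"
        if el.intervening_after is not None:
            findings.append(
                Finding(
                    "cds_junction_intervening",
                    "info",
                    "CDS-CDS junction carries an intervening sequence; frame "
                    "depends on its length and is not checked here",
                    locus=locus,
                )
            )
            continue
        if run_len % 3 != 0:
            findings.append(
                Finding(
                    "seam_frame_shift",
                    "warning",
                    f"upstream CDS length {run_len} is not a multiple of 3: the "
                    f"{seam_codon} seam codon is out of frame at this junction",
                    locus=locus,
                    measured=run_len,
                )
            )
            continue
        if aa == "*":
            findings.append(
                Finding(
                    "seam_stop_codon",
                    "warning",
                    f"in-frame seam codon {seam_codon} is a stop codon",
                    locus=locus,
                )
            )
        else:
            findings.append(
                Finding(
                    "seam_codon_inserted",
                    "info",
                    f"in-frame seam inserts one {aa} "
                    f"({seam_codon}) codon at this CDS-CDS junction",
                    locus=locus,
                )
            )
    return findings


def validate_design(
    plan: AssemblyPlan, identity_threshold: int = DEFAULT_IDENTITY_THRESHOLD
) -> ValidationReport:
    """Run every check and aggregate into a deterministic report.

    Findings are ordered by the index of the first element they concern,
    then by code; the report passes iff no error-severity finding exists.
    """
    element_index = {el.part_id: i for i, el in enumerate(plan.elements)}

    def sort_key(f: Finding) -> tuple[int, str, str]:
        first = f.locus.split("|")[0]
        return (element_index.get(first, len(plan.elements)), f.code, f.locus)

    findings = [
        *check_repeated_parts(plan),
        *check_identical_regions(plan, identity_threshold),
        *check_overhang_fidelity(plan),
        *check_reading_frame(plan),
    ]
    return ValidationReport(tuple(sorted(findings, key=sort_key)))
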