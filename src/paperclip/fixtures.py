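"""Synthetic part generation for examples and tests.

Two hand-sized toy parts are defined as module constants: TOY1, a 60-nt
open reading frame whose downstream window needs no trimming, and TOY2,
44 nt whose 40-nt suffix begins with GCC and therefore exercises the
seam-collision trimming rule exactly once. Random libraries are produced
reproducibly from a seed, with optional "planted" pathologies (seam-valued
suffixes, shared identical regions, CDS frame structures) so that every
validation path can be driven without external data.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional, Sequence

from .clip_design import Part
from .seqcore import NucSeq, PAPERCLIP_SEAM, SeamSpec, reverse_complement

__all__ = [
    "TOY1",
    "TOY2",
    "toy_parts",
    "PlantSpec",
    "generate_fixture_parts",
    "random_nucseq",
]

#: 60-nt toy ORF (starts ATG, ends TAA; length divisible by 3).
TOY1 = NucSeq("ATGAAAGTTCTGACCGAAGATCAGCGTAAAGCACTGGCAGAAGTTCTGCGTGAAACCTAA")
#: 44-nt toy part whose 40-nt suffix begins GCC (triggers one trim step).
TOY2 = NucSeq("ATGAGCCTTTACCGGTAAACCCGGGTTTAAACCATGGAGCTCAA")


def toy_parts(is_cds: bool = False, allow_flip: bool = False) -> dict[str, Part]:
    return {
        "TOY1": Part("TOY1", TOY1, is_cds=is_cds, allow_flip=allow_flip),
        "TOY2": Part("TOY2", TOY2, is_cds=is_cds, allow_flip=allow_flip),
    }


def random_nucseq(rng: random.Random, length: int) -> NucSeq:
    return NucSeq("".join(rng.choice("ACGT") for _ in range(length)))


@dataclass(frozen=True)
class PlantSpec:
    """Pathologies to plant into a generated library.

    ``seam_collision_part`` makes that part's 40-nt suffix begin with the
    seam so downstream design must trim. ``shared_region_len`` plants an
    identical region of that length into the first two parts (for identity
    screening). ``cds_parts`` marks those indices as CDS; each CDS part's
    length is rounded to the stated frame remainder.
    """

    seam_collision_part: Optional[int] = None
    shared_region_len: Optional[int] = None
    cds_parts: Sequence[int] = ()
    cds_frame_remainder: int = 0


def generate_fixture_parts(
    n: int,
    length_range: tuple[int, int] = (200, 400),
    seed: int = 0,
    planted: Optional[PlantSpec] = None,
    seam: SeamSpec = PAPERCLIP_SEAM,
    prefix: str = "P",
) -> dict[str, Part]:
    """Reproducible random part library.

    The same ``seed`` always yields a byte-identical library. Generated
    sequences are rejection-sampled so that, unless a collision is
    deliberately planted, no downstream window begins with the seam on
    either strand (keeping trim = 0 the baseline condition).
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    lo, hi = length_range
    if lo < 40:
        raise ValueError("minimum part length is 40 nt")
    planted = planted or PlantSpec()
    rng = random.Random(seed)
    forbidden = {str(seam.top), str(seam.bottom)}
    parts: dict[str, Part] = {}
    seqs: list[str] = []
    for i in range(n):
        length = rng.randint(lo, hi)
        if i in planted.cds_parts:
            length -= (length - planted.cds_frame_remainder) % 3
        while True:
            seq = random_nucseq(rng, length)
            if seq[len(seq) - 40 :][:3] not in forbidden:
                break
        seqs.append(str(seq))

    if planted.seam_collision_part is not None:
        idx = planted.seam_collision_part
        if not 0 <= idx < n:
            raise ValueError("seam_collision_part index out of range")
        s = seqs[idx]
        seqs[idx] = s[:-40] + str(seam.top) + s[-37:]

    if planted.shared_region_len is not None:
        k = planted.shared_region_len
        if n < 2:
            raise ValueError("shared region needs at least two parts")
        if k > min(len(seqs[0]), len(seqs[1])) - 45:
            raise ValueError(
                f"cannot plant a {k}-nt shared region into parts of length "
                f"{len(seqs[0])}/{len(seqs[1])}"
            )
        region = random_nucseq(rng, k)
        # plant mid-sequence so design windows stay untouched
        positions = []
        for j in (0, 1):
            pos = (len(seqs[j]) - k) // 2
            seqs[j] = seqs[j][:pos] + str(region) + seqs[j][pos + k :]
            positions.append(pos)
        # pin the plant boundaries: force the bases flanking the region in
        # the second part to mismatch the first part's flanks, so the shared
        # region is exactly k nt and boundary tests are exact
        p0, p1 = positions
        s0, s1 = seqs[0], list(seqs[1])
        for off0, off1 in ((p0 - 1, p1 - 1), (p0 + k, p1 + k)):
            if 0 <= off0 < len(s0) and 0 <= off1 < len(s1):
                choices = [b for b in "ACGT" if b != s0[off0]]
                s1[off1] = rng.choice(choices)
        seqs[1] = "".join(s1)

    for i, s in enumerate(seqs):
        pid = f"{prefix}{i + 1}"
        parts[pid] = Part(
            id=pid,
            seq=NucSeq(s),
            is_cds=i in planted.cds_parts,
            description="synthetic fixture part",
        )
    return parts
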