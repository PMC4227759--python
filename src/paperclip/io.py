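"""Reading part libraries and writing oligo sheets and predicted constructs.

Part libraries come in as FASTA (metadata as ``key=value`` tokens in the
description line, e.g. ``>gfp is_cds=true allow_flip=true``) or GenBank
(metadata from ``misc_feature``-level qualifiers or the record annotations).
Oligo order sheets go out as plain CSV; predicted constructs as FASTA and as
annotated GenBank with circular topology.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .assembly import PredictedConstruct
from .clip_design import Oligo, Part, design_part_oligos
from .seqcore import NucSeq, PAPERCLIP_SEAM, SeamSpec

__all__ = [
    "read_parts",
    "write_oligo_sheet",
    "oligo_sheet_frame",
    "read_oligo_sheet",
    "write_construct",
]

PathLike = Union[str, Path]

_TRUE = {"true", "1", "yes"}


def _parse_bool(value: str) -> bool:
    return value.strip().lower() in _TRUE


def _metadata_from_description(description: str) -> tuple[dict, str]:
    meta = {"is_cds": False, "allow_flip": False}
    free_text: list[str] = []
    tokens = description.split()[1:]  # first token is the id
    for tok in tokens:
        if "=" in tok:
            key, _, value = tok.partition("=")
            if key in ("is_cds", "allow_flip"):
                meta[key] = _parse_bool(value)
                continue
        free_text.append(tok)
    return meta, " ".join(free_text)


def read_parts(path: PathLike, fmt: str = "fasta") -> dict[str, Part]:
    """Read a part library from FASTA or GenBank.

    Sequences are validated (strict A/C/G/T; lowercase uppercased) and
    duplicate ids rejected. Raises ``ValueError`` naming the offending
    record on any invalid sequence.
    """
    fmt = fmt.lower()
    if fmt not in ("fasta", "genbank", "gb"):
        raise ValueError(f"unsupported format {fmt!r} (use fasta or genbank)")
    fmt = "genbank" if fmt in ("genbank", "gb") else "fasta"
    library: dict[str, Part] = {}
    for record in SeqIO.parse(str(path), fmt):
        if record.id in library:
            raise ValueError(f"duplicate part id {record.id!r} in {path}")
        try:
            seq = NucSeq(str(record.seq))
        except ValueError as exc:
            raise ValueError(f"record {record.id!r}: {exc}") from exc
        if fmt == "fasta":
            meta, description = _metadata_from_description(record.description)
        else:
            ann = record.annotations
            meta = {
                "is_cds": _parse_bool(str(ann.get("is_cds", "false"))),
                "allow_flip": _parse_bool(str(ann.get("allow_flip", "false"))),
            }
            # qualifiers on whole-record source/misc features override
            for feat in record.features:
                for key in ("is_cds", "allow_flip"):
                    if key in feat.qualifiers:
                        meta[key] = _parse_bool(str(feat.qualifiers[key][0]))
            description = record.description
        library[record.id] = Part(
            id=record.id,
            seq=seq,
            is_cds=meta["is_cds"],
            allow_flip=meta["allow_flip"],
            description=description,
        )
    if not library:
        raise ValueError(f"no records parsed from {path}")
    return library


_SHEET_COLUMNS = [
    "oligo_name",
    "role",
    "part_id",
    "sequence",
    "length",
    "phosphorylation_5prime",
    "notes",
]
_ROLE_ORDER = {r: i for i, r in enumerate(["UF", "UR", "DF", "DR", "UFx", "DRx"])}


def oligo_sheet_frame(
    library: Mapping[str, Part], seam: SeamSpec = PAPERCLIP_SEAM
) -> pd.DataFrame:
    """Deterministic order sheet: one row per oligo, sorted by part id then role."""
    rows = []
    for part_id in sorted(library):
        for oligo in design_part_oligos(library[part_id], seam):
            notes = ""
            if oligo.role in ("UF", "DR"):
                notes = "also serves as PCR amplification primer"
            rows.append(
                {
                    "oligo_name": oligo.name,
                    "role": oligo.role,
                    "part_id": part_id,
                    "sequence": str(oligo.seq),
                    "length": len(oligo.seq),
                    "phosphorylation_5prime": oligo.phosphorylated,
                    "notes": notes,
                }
            )
    frame = pd.DataFrame(rows, columns=_SHEET_COLUMNS)
    frame["_role_rank"] = frame["role"].map(_ROLE_ORDER)
    frame = frame.sort_values(["part_id", "_role_rank"], kind="stable").drop(
        columns="_role_rank"
    )
    return frame.reset_index(drop=True)


def write_oligo_sheet(
    library: Mapping[str, Part], path: PathLike, seam: SeamSpec = PAPERCLIP_SEAM
) -> pd.DataFrame:
    frame = oligo_sheet_frame(library, seam)
    frame.to_csv(path, index=False)
    return frame


def read_oligo_sheet(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(
        path, dtype={"sequence": str}, keep_default_na=False
    )


def _construct_record(construct: PredictedConstruct) -> SeqRecord:
    record = SeqRecord(
        Seq(str(construct.seq)),
        id=construct.name,
        name=construct.name[:16],
        description=f"predicted circular assembly, {construct.length} bp",
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular"
    for feat in construct.features:
        record.features.append(
            SeqFeature(
                FeatureLocation(feat.start - 1, feat.end, strand=feat.strand),
                type={"part": "misc_feature", "seam": "misc_feature", "intervening": "misc_feature"}[feat.kind],
                qualifiers={"label": [feat.label], "note": [feat.kind]},
            )
        )
    return record


def write_construct(
    construct: PredictedConstruct, fasta_path: PathLike, genbank_path: PathLike
) -> None:
    """Write the predicted construct as FASTA and annotated circular GenBank.

    Both files carry the same sequence at the canonical rotation (backbone
    base 1 first); the GenBank has one feature per part, per seam, and per
    intervening element.
    """
    record = _construct_record(construct)
    SeqIO.write([record], str(fasta_path), "fasta")
    SeqIO.write([record], str(genbank_path), "genbank")
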