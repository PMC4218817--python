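"""Protein FASTA input, normalization and longest-isoform-per-gene reduction.

A proteome arrives as one FASTA file per species.  Headers may carry only a
protein identifier, or (Ensembl-style ``pep`` dumps) ``gene:``/``transcript:``
tags plus biotype annotations, or generic ``key=value`` pairs.  Sequences are
uppercased, a single trailing stop symbol ``*`` is stripped, and anything
else outside ``A``–``Z`` (internal stops, ``.``, digits, whitespace) rejects
the record: curated proteomes should not contain them, and silently dropping
characters would corrupt every downstream length denominator.

Transcript-level proteomes are reduced to one protein per gene by keeping
the longest isoform; equal-length ties keep the lexicographically smallest
protein id so the reduction is deterministic under any input ordering.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "FastaFormatError",
    "HEADER_SCHEMAS",
    "read_fasta",
    "read_gene_map",
    "apply_gene_map",
    "select_longest_per_gene",
    "write_fasta",
]

#: Header dialects understood by :func:`read_fasta`.
HEADER_SCHEMAS = ("plain", "ensembl", "keyvalue")

#: Biotype substrings that flag an entry as a pseudogene/transposon product.
_EXCLUDED_BIOTYPES = ("pseudogene", "transposon", "transposable")

_VALID_SEQ = re.compile(r"^[A-Z]+$")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA entries, naming the offending record."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its protein/gene/transcript identity.

    ``sequence`` is a normalized uppercase amino-acid string over the 20
    standard letters plus placeholder letters (X, B, Z, U, O ...); its
    character count is the protein length used everywhere downstream.
    """

    protein_id: str
    sequence: str
    gene_id: str = ""
    transcript_id: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise FastaFormatError("protein record with empty identifier")
        if not self.sequence:
            raise FastaFormatError(f"empty sequence for protein {self.protein_id!r}")
        if not _VALID_SEQ.match(self.sequence):
            bad = sorted(set(self.sequence) - set(map(chr, range(65, 91))))
            raise FastaFormatError(
                f"protein {self.protein_id!r}: sequence contains invalid "
                f"characters {bad} (internal stop symbols or non-letters)"
            )
        if not self.gene_id:
            object.__setattr__(self, "gene_id", self.protein_id)

    def __len__(self) -> int:
        return len(self.sequence)


def _normalize_sequence(raw: str, protein_id: str) -> str:
    seq = str(raw).upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    if not seq:
        raise FastaFormatError(f"empty sequence for protein {protein_id!r}")
    return seq


def _parse_tagged(description: str, sep: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for token in description.split():
        if sep in token:
            key, _, value = token.partition(sep)
            if key and key not in out:
                out[key] = value
    return out


def _record_from_entry(entry, schema: str) -> ProteinRecord | None:
    protein_id = entry.id
    desc = entry.description
    if desc.startswith(protein_id):
        desc = desc[len(protein_id):].strip()
    gene_id = ""
    transcript_id = ""
    if schema == "ensembl":
        tags = _parse_tagged(desc, ":")
        for key in ("gene_biotype", "transcript_biotype", "biotype"):
            biotype = tags.get(key, "").lower()
            if any(flag in biotype for flag in _EXCLUDED_BIOTYPES):
                return None
        gene_id = tags.get("gene", "")
        transcript_id = tags.get("transcript", "")
    elif schema == "keyvalue":
        tags = _parse_tagged(desc, "=")
        biotype = tags.get("biotype", "").lower()
        if any(flag in biotype for flag in _EXCLUDED_BIOTYPES):
            return None
        gene_id = tags.get("gene", "")
        transcript_id = tags.get("transcript", "")
    sequence = _normalize_sequence(str(entry.seq), protein_id)
    return ProteinRecord(
        protein_id=protein_id,
        sequence=sequence,
        gene_id=gene_id,
        transcript_id=transcript_id,
        description=desc,
    )


def read_fasta(path: str | Path, header_schema: str = "plain") -> list[ProteinRecord]:
    """Read a protein FASTA file into validated :class:`ProteinRecord` objects.

    Parameters
    ----------
    path:
        FASTA file, multi-line wrapped or single-line sequences.
    header_schema:
        ``"plain"`` (first word is the protein id, no gene mapping),
        ``"ensembl"`` (``gene:``/``transcript:``/``*_biotype:`` tags;
        pseudogene/transposon biotypes are dropped), or ``"keyvalue"``
        (``gene=``/``transcript=``/``biotype=`` pairs).

    Raises
    ------
    FastaFormatError
        On an empty sequence, invalid sequence characters, or a duplicated
        protein id; the message names the offending entry.
    ValueError
        On an unknown ``header_schema``.
    """
    if header_schema not in HEADER_SCHEMAS:
        raise ValueError(
            f"unknown header schema {header_schema!r}; expected one of {HEADER_SCHEMAS}"
        )
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        record = _record_from_entry(entry, header_schema)
        if record is None:  # filtered biotype
            continue
        if record.protein_id in seen:
            raise FastaFormatError(
                f"duplicate protein identifier {record.protein_id!r} in {path.name}"
            )
        seen.add(record.protein_id)
        records.append(record)
    return records


def read_gene_map(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a protein→gene (and optional transcript) mapping TSV.

    The file must have a header row with at least ``protein_id`` and
    ``gene_id`` columns; a ``transcript_id`` column is optional.
    """
    path = Path(path)
    mapping: dict[str, tuple[str, str]] = {}
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"protein_id", "gene_id"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"{path.name}: gene map requires a header with columns "
                f"protein_id and gene_id (got {reader.fieldnames})"
            )
        for row in reader:
            mapping[row["protein_id"]] = (
                row["gene_id"],
                row.get("transcript_id") or "",
            )
    return mapping


def apply_gene_map(
    records: Iterable[ProteinRecord], mapping: Mapping[str, tuple[str, str]]
) -> list[ProteinRecord]:
    """Attach gene/transcript ids from a mapping table.

    Proteins absent from the mapping keep ``gene_id == protein_id``.
    """
    out = []
    for record in records:
        if record.protein_id in mapping:
            gene_id, transcript_id = mapping[record.protein_id]
            record = replace(record, gene_id=gene_id, transcript_id=transcript_id)
        out.append(record)
    return out


def select_longest_per_gene(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Keep the single longest protein per gene, ties broken by protein id.

    The returned list contains exactly one record per distinct ``gene_id``,
    ordered by ``gene_id``.  Idempotent.
    """
    best: dict[str, ProteinRecord] = {}
    for record in records:
        incumbent = best.get(record.gene_id)
        if incumbent is None:
            best[record.gene_id] = record
            continue
        key_new = (-len(record.sequence), record.protein_id)
        key_old = (-len(incumbent.sequence), incumbent.protein_id)
        if key_new < key_old:
            best[record.gene_id] = record
    return [best[gene] for gene in sorted(best)]


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with fixed-width sequence wrapping."""
    path = Path(path)
    with path.open("w") as handle:
        for record in records:
            header = record.protein_id
            if record.description:
                header = f"{header} {record.description}"
            handle.write(f">{header}\n")
            seq = record.sequence
            for start in range(0, len(seq), width):
                handle.write(seq[start : start + width] + "\n")
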