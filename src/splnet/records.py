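"""Sequence record containers and FASTA round-trip helpers.

Transcripts are stored on one canonical DNA alphabet (T, not U); circRNAs are
stored as a linearised circle with the back-splice join recorded as a 1-based
position (the base immediately upstream of the join).  Metadata rides on the
FASTA description line as ``key=value`` tokens so fixtures stay plain text.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError

DNA_ALPHABET = frozenset("ACGT")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

BIOTYPES = ("mrna", "lncrna", "circrna", "mirna")


def normalize_rna(seq: str) -> str:
    """Uppercase and map U->T so every caller sees one alphabet."""
    return seq.upper().replace("U", "T")


def check_nucleotide(seq: str) -> str:
    seq = normalize_rna(seq)
    for i, ch in enumerate(seq):
        if ch not in DNA_ALPHABET:
            raise ValidationError(
                f"invalid nucleotide {ch!r} at position {i + 1}"
            )
    return seq


def check_protein(seq: str) -> str:
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in PROTEIN_ALPHABET:
            raise ValidationError(
                f"invalid amino-acid residue {ch!r} at position {i + 1}"
            )
    return seq


def reverse_complement(seq: str) -> str:
    return str(Seq(normalize_rna(seq)).reverse_complement())


@dataclass
class TranscriptRecord:
    """One transcript: sequence plus biotype/locus/junction metadata."""

    id: str
    seq: str
    biotype: str
    locus: Optional[str] = None
    junction: Optional[int] = None  # circRNA only; 1-based, join after this base

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValidationError(
                f"unknown biotype {self.biotype!r} for {self.id}"
            )
        self.seq = check_nucleotide(self.seq)
        if self.biotype == "circrna":
            if self.junction is None:
                self.junction = len(self.seq)
            if not 1 <= self.junction <= len(self.seq):
                raise ValidationError(
                    f"junction {self.junction} outside sequence of {self.id}"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ProteinRecord:
    """One protein: sequence plus the locus id used for isoform grouping."""

    id: str
    seq: str
    locus: Optional[str] = None
    description: str = ""

    def __post_init__(self) -> None:
        self.seq = check_protein(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


def _meta_string(pairs: dict) -> str:
    return " ".join(f"{k}={v}" for k, v in pairs.items() if v is not None)


def _parse_meta(description: str) -> dict:
    meta = {}
    for token in description.split():
        if "=" in token:
            key, _, value = token.partition("=")
            meta[key] = value
    return meta


def write_transcript_fasta(records: Iterable[TranscriptRecord], path) -> None:
    out = []
    for rec in records:
        meta = {"biotype": rec.biotype, "locus": rec.locus,
                "junction": rec.junction}
        out.append(SeqRecord(Seq(rec.seq), id=rec.id,
                             description=_meta_string(meta)))
    SeqIO.write(out, path, "fasta")


def read_transcript_fasta(path, default_biotype: str = "mrna"):
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        meta = _parse_meta(rec.description)
        junction = meta.get("junction")
        records.append(TranscriptRecord(
            id=rec.id,
            seq=str(rec.seq),
            biotype=meta.get("biotype", default_biotype),
            locus=meta.get("locus"),
            junction=int(junction) if junction is not None else None,
        ))
    return records


def write_protein_fasta(records: Iterable[ProteinRecord], path) -> None:
    out = []
    for rec in records:
        meta = {"locus": rec.locus}
        out.append(SeqRecord(Seq(rec.seq), id=rec.id,
                             description=_meta_string(meta)))
    SeqIO.write(out, path, "fasta")


def read_protein_fasta(path):
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        meta = _parse_meta(rec.description)
        records.append(ProteinRecord(
            id=rec.id, seq=str(rec.seq), locus=meta.get("locus"),
            description=rec.description,
        ))
    return records
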