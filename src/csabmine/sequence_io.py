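"""Sequence and annotation I/O.

Reads and writes the plain-text formats the mining pipeline consumes:
multi-record FASTA (via Biopython), Phobius short-format secretion
predictions, and the flat result tables the pipeline emits (TSV/JSON).
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")

#: Fixed column order of the result table (documented in the README).
TABLE_COLUMNS = (
    "id",
    "class",
    "mature_length",
    "net_charge",
    "gamma_core",
    "kcxn",
    "conserved_gly",
    "cluster",
)


class SequenceIOError(ValueError):
    """Malformed sequence data or prediction file."""


class FastaParseError(SequenceIOError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    """One protein or nucleotide entry.

    ``residues`` is uppercased on construction and validated against the
    declared alphabet (protein: 20 amino acids plus X; nucleotide: ACGTN).
    ``id`` is the first whitespace-delimited header token; the full header
    is kept in ``description``.
    """

    id: str
    residues: str
    kind: str = "protein"
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("protein", "nucleotide"):
            raise SequenceIOError(f"unknown sequence kind {self.kind!r}")
        if not self.id or re.search(r"\s", self.id):
            raise SequenceIOError(f"invalid record id {self.id!r}")
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise SequenceIOError(f"record {self.id!r}: empty sequence")
        alphabet = PROTEIN_ALPHABET if self.kind == "protein" else NUCLEOTIDE_ALPHABET
        bad = set(self.residues) - alphabet
        if bad:
            raise SequenceIOError(
                f"record {self.id!r}: residues {sorted(bad)} outside "
                f"{self.kind} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SecretionAnnotation:
    """Signal-peptide / transmembrane call for one sequence.

    ``cleavage_site`` is the 1-based index of the last signal-peptide
    residue and is only present when a signal peptide was predicted.
    """

    id: str
    has_signal_peptide: bool
    has_transmembrane: bool
    cleavage_site: int | None = None

    def __post_init__(self) -> None:
        if self.cleavage_site is not None:
            if not self.has_signal_peptide:
                raise SequenceIOError(
                    f"{self.id}: cleavage site without signal peptide"
                )
            if self.cleavage_site < 1:
                raise SequenceIOError(f"{self.id}: cleavage site must be >= 1")


def read_fasta(path: str | Path, kind: str = "protein") -> list[SequenceRecord]:
    """Read a multi-record FASTA file.

    Order is preserved, lowercase residues are normalised to uppercase and
    every record is alphabet-validated. Malformed entries raise
    :class:`FastaParseError` naming the offending record.
    """
    path = Path(path)
    with open(path) as handle:
        head = handle.read(1)
        if head and head not in (">", ";", "\n"):
            raise FastaParseError(f"{path}: line 1 does not start a FASTA header")
    records: list[SequenceRecord] = []
    for index, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if not rec.id:
            raise FastaParseError(f"{path}: entry {index} has an empty header")
        if len(rec.seq) == 0:
            raise FastaParseError(
                f"{path}: entry {index} ({rec.id!r}) has an empty sequence"
            )
        try:
            records.append(
                SequenceRecord(
                    id=rec.id,
                    residues=str(rec.seq),
                    kind=kind,
                    description=rec.description,
                )
            )
        except SequenceIOError as exc:
            raise FastaParseError(f"{path}: entry {index}: {exc}") from exc
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description or "")
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


_CLEAVAGE_RE = re.compile(r"[cC](\d+)[-/](\d+)")


def read_phobius_short(path: str | Path) -> list[SecretionAnnotation]:
    """Parse Phobius "short" tabular output.

    Columns: sequence id, transmembrane segment count, signal-peptide flag
    (Y / N / 0), prediction string. The cleavage site is taken from the
    ``c<i>/<j>`` part of the prediction string (last signal residue = i).
    """
    annotations: list[SecretionAnnotation] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        tokens = line.split()
        if "PREDICTION" in line.upper() and not tokens[1].isdigit():
            continue  # header row
        if len(tokens) < 3:
            raise SequenceIOError(
                f"{path}: line {lineno}: expected >=3 columns, got {len(tokens)}"
            )
        seq_id, tm_token, sp_token = tokens[0], tokens[1], tokens[2]
        try:
            tm_count = int(tm_token)
        except ValueError as exc:
            raise SequenceIOError(
                f"{path}: line {lineno}: transmembrane count {tm_token!r} "
                "is not an integer (unknown column layout?)"
            ) from exc
        if sp_token not in ("Y", "N", "0"):
            raise SequenceIOError(
                f"{path}: line {lineno}: signal flag {sp_token!r} not in Y/N/0"
            )
        has_sp = sp_token == "Y"
        cleavage = None
        if has_sp and len(tokens) >= 4:
            m = _CLEAVAGE_RE.search(tokens[3])
            if m:
                cleavage = int(m.group(1))
        annotations.append(
            SecretionAnnotation(
                id=seq_id,
                has_signal_peptide=has_sp,
                has_transmembrane=tm_count > 0,
                cleavage_site=cleavage,
            )
        )
    return annotations


def write_phobius_short(
    annotations: Iterable[SecretionAnnotation], path: str | Path
) -> None:
    """Write annotations back out in Phobius short format (for fixtures)."""
    lines = ["SEQENCE ID                     TM SP PREDICTION"]
    for a in annotations:
        tm = 1 if a.has_transmembrane else 0
        sp = "Y" if a.has_signal_peptide else "0"
        if a.has_signal_peptide and a.cleavage_site is not None:
            pred = f"n4-11c{a.cleavage_site}/{a.cleavage_site + 1}o"
        elif a.has_transmembrane:
            pred = "i41-60o"
        else:
            pred = "o"
        lines.append(f"{a.id} {tm} {sp} {pred}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_table(
    rows: Sequence[Mapping[str, object]], path: str | Path, format: str = "tsv"
) -> None:
    """Write one row per annotated record in the fixed column order.

    JSON mode round-trips losslessly through :func:`read_table`.
    """
    path = Path(path)
    if format == "tsv":
        with open(path, "w", newline="") as handle:
            writer = csv.DictWriter(
                handle, fieldnames=TABLE_COLUMNS, delimiter="\t", extrasaction="ignore"
            )
            writer.writeheader()
            for row in rows:
                writer.writerow({k: row.get(k, "") for k in TABLE_COLUMNS})
    elif format == "json":
        payload = [{k: row.get(k) for k in TABLE_COLUMNS} for row in rows]
        path.write_text(json.dumps(payload, indent=1, sort_keys=False) + "\n")
    else:
        raise SequenceIOError(f"unknown table format {format!r}")


def read_table(path: str | Path, format: str = "json") -> list[dict]:
    path = Path(path)
    if format == "json":
        return json.loads(path.read_text())
    if format == "tsv":
        with open(path) as handle:
            return list(csv.DictReader(handle, delimiter="\t"))
    raise SequenceIOError(f"unknown table format {format!r}")
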