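"""Reading and writing the formats the pipeline touches.

Clone sequences arrive as FASTA (one or many records per file) or as GFF3
files carrying their sequences in an embedded ``##FASTA`` section.  Continuous
methylation measurements (e.g. from array platforms) come as TSV tables and
are binarised by thresholding.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: IUPAC nucleotide alphabet (concrete bases, ambiguity codes, N, gap-free)
IUPAC_CODES = set("ACGTRYSWKMBDHVN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SequenceRecord:
    """A named nucleotide sequence, uppercase-normalised.

    Parameters
    ----------
    id:
        FASTA header token (first whitespace-delimited word).
    bases:
        Sequence over the IUPAC alphabet.
    source_file:
        Path of the file the record was read from ("" for in-memory records).
    """

    id: str
    bases: str
    source_file: str = ""

    def __post_init__(self) -> None:
        if not self.bases:
            raise FormatError(f"record {self.id!r}: empty sequence")
        self.bases = self.bases.upper()
        bad = set(self.bases) - IUPAC_CODES
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class ContinuousTable:
    """Rectangular table of real-valued measurements (rows x columns)."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise FormatError("table not rectangular with given ids")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise FormatError("duplicate row ids")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise FormatError("duplicate column ids")


def _records_from_handle(handle, source: str) -> list[SequenceRecord]:
    try:
        bio_records = list(SeqIO.parse(handle, "fasta"))
    except ValueError as exc:  # Biopython signals malformed FASTA
        raise FormatError(f"{source}: {exc}") from exc
    if not bio_records:
        raise FormatError(f"{source}: no FASTA records found")
    records = []
    seen: set[str] = set()
    for rec in bio_records:
        if not rec.id:
            raise FormatError(f"{source}: record with empty header")
        if rec.id in seen:
            raise FormatError(f"{source}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq), source))
    return records


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read all records from a FASTA file, preserving file order.

    Lowercase bases are uppercased; duplicate ids and non-IUPAC characters
    raise :class:`FormatError`.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty file")
    if not text.lstrip().startswith(">"):
        raise FormatError(f"{path}: does not start with a FASTA header line")
    return _records_from_handle(_io.StringIO(text), str(path))


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as FASTA with fixed line wrap."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i:i + width] + "\n")


def read_gff_sequences(path: str | Path) -> list[SequenceRecord]:
    """Extract sequences from the ``##FASTA`` section of a GFF3 file.

    Only the GFF3 dialect with an embedded FASTA payload is accepted; a GFF
    without one raises :class:`FormatError`.
    """
    path = Path(path)
    text = path.read_text()
    marker = "##FASTA"
    idx = text.find(marker)
    if idx < 0:
        raise FormatError(f"{path}: GFF3 file has no ##FASTA section")
    fasta_part = text[idx + len(marker):].lstrip("\n")
    if not fasta_part.strip():
        raise FormatError(f"{path}: ##FASTA section is empty")
    return _records_from_handle(_io.StringIO(fasta_part), str(path))


def read_continuous_table(path: str | Path) -> ContinuousTable:
    """Read a TSV table: first row column ids, first column row ids."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"{path}: non-numeric cell(s) in table body")
    return ContinuousTable(
        [str(r) for r in df.index], [str(c) for c in df.columns], values
    )


def binarize(table: ContinuousTable, threshold: float) -> np.ndarray:
    """Threshold a continuous table into {0,1}; ties (== threshold) map to 1.

    Missing values (NaN) propagate as NaN.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    values = table.values
    out = np.where(values >= threshold, 1.0, 0.0)
    out[np.isnan(values)] = np.nan
    return out


_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)


def complement(bases: str) -> str:
    """Base-wise complement (IUPAC-aware), same order."""
    return bases.translate(_COMPLEMENT)


def reverse_complement(bases: str) -> str:
    return complement(bases)[::-1]


def to_bio_record(rec: SequenceRecord) -> _BioSeqRecord:
    return _BioSeqRecord(Seq(rec.bases), id=rec.id, description="")
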