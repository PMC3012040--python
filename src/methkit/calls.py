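"""CpG site discovery and the clone x CpG methylation matrix.

After bisulfite conversion a CpG cytosine that survives as C was protected by
methylation; one read as T was unmethylated.  Each aligned clone therefore
contributes one ternary row over the reference's CpG sites:
1 = methylated (C), 0 = unmethylated (T), missing = not covered, gapped, or
any other base (which evidences sequencing error, not methylation state).

The assembled :class:`MethylationDataset` is the central object downstream
statistics and plots consume; it serialises to a self-describing JSON
container and to TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import CloneAlignment
from .io import SequenceRecord

#: sentinel for a missing call in the float matrix
MISSING = np.nan

_SCHEMA_VERSION = 1


@dataclass
class ReferenceSequence:
    """Reference bases plus derived CpG coordinates (1-based C positions)."""

    id: str
    bases: str
    cpg_positions: list[int]

    def __post_init__(self) -> None:
        for p in self.cpg_positions:
            if self.bases[p - 1: p + 1] != "CG":
                raise ValueError(f"position {p} is not the C of a CpG")
        if list(self.cpg_positions) != sorted(set(self.cpg_positions)):
            raise ValueError("cpg_positions must be strictly increasing")


def find_cpg_sites(ref: SequenceRecord) -> ReferenceSequence:
    """Locate every forward-strand CG dinucleotide; returns C positions."""
    bases = ref.bases
    positions = [
        i + 1 for i in range(len(bases) - 1) if bases[i: i + 2] == "CG"
    ]
    return ReferenceSequence(id=ref.id, bases=bases, cpg_positions=positions)


def call_methylation(aln: CloneAlignment,
                     ref: ReferenceSequence) -> np.ndarray:
    """One clone's ternary call row over the reference CpG sites.

    Clone C at a CpG column -> 1 (methylated); T -> 0 (unmethylated); gap, N
    or any other base -> missing; CpG positions outside the clone's aligned
    span -> missing.
    """
    wanted = {p: i for i, p in enumerate(ref.cpg_positions)}
    row = np.full(len(ref.cpg_positions), MISSING)
    for pos, ref_base, clone_base in aln.columns():
        if pos is None:
            continue
        idx = wanted.get(pos)
        if idx is None:
            continue
        if clone_base == "C":
            row[idx] = 1.0
        elif clone_base == "T":
            row[idx] = 0.0
    return row


@dataclass
class MethylationDataset:
    """Clone x CpG ternary matrix with genomic positions and spans.

    ``calls`` is a float matrix over {1.0, 0.0, NaN}; NaN is the first-class
    missing state and is excluded pairwise from downstream statistics.
    """

    clone_ids: list[str]
    cpg_positions: list[int]
    calls: np.ndarray = field(repr=False)
    spans: list[tuple[int, int]]
    reference_id: str = ""

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.clone_ids), len(self.cpg_positions)):
            raise ValueError("calls shape does not match ids/positions")
        if len(self.spans) != len(self.clone_ids):
            raise ValueError("one span per clone required")

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    @property
    def n_sites(self) -> int:
        return len(self.cpg_positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.clone_ids,
                            columns=self.cpg_positions)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "schema_version": _SCHEMA_VERSION,
            "reference_id": self.reference_id,
            "clone_ids": self.clone_ids,
            "cpg_positions": self.cpg_positions,
            "spans": [list(s) for s in self.spans],
            "calls": [
                [None if np.isnan(v) else int(v) for v in row]
                for row in self.calls
            ],
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MethylationDataset":
        obj = json.loads(Path(path).read_text())
        calls = np.array(
            [[MISSING if v is None else float(v) for v in row]
             for row in obj["calls"]]
        ).reshape(len(obj["clone_ids"]), len(obj["cpg_positions"]))
        return cls(
            clone_ids=list(obj["clone_ids"]),
            cpg_positions=list(obj["cpg_positions"]),
            calls=calls,
            spans=[tuple(s) for s in obj["spans"]],
            reference_id=obj.get("reference_id", ""),
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", na_rep="NA",
                               index_label="clone_id")


def assemble_dataset(alignments: list[CloneAlignment],
                     ref: ReferenceSequence) -> MethylationDataset:
    """Stack per-clone call rows in input order into a dataset."""
    rows = [call_methylation(a, ref) for a in alignments]
    calls = (np.vstack(rows) if rows
             else np.empty((0, len(ref.cpg_positions))))
    return MethylationDataset(
        clone_ids=[a.clone_id for a in alignments],
        cpg_positions=list(ref.cpg_positions),
        calls=calls,
        spans=[(a.ref_start, a.ref_end) for a in alignments],
        reference_id=ref.id,
    )
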