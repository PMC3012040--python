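"""Synthetic references and bisulfite clones with known ground truth.

The generator emulates a single-locus bisulfite cloning-and-sequencing
experiment: a reference with CG dinucleotides at chosen positions plus
planted non-CpG cytosines (the denominators of the conversion-ratio QC
statistic) on an A/G/T background, and per-clone reads derived by applying a
known methylation pattern, an incomplete-conversion probability, a
substitution-error rate and an orientation transform.  Every stochastic draw
is recorded in the ground-truth object, so each upstream contract can be
checked against what was planted.

One seeded :class:`numpy.random.Generator` drives a simulation; the same
seed reproduces byte-identical FASTA output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .calls import ReferenceSequence, find_cpg_sites
from .io import SequenceRecord, complement, reverse_complement, write_fasta

#: the demonstration geometry: 5 CpG sites in a 100 bp reference
TOY_CPG_POSITIONS = (7, 32, 48, 55, 73)

#: the demonstration methylation profile: clones 1-2 methylated at sites 1-2,
#: clone 3 at sites 3-4, clone 4 at sites 3-5
TOY_PATTERN = (
    (1, 1, 0, 0, 0),
    (1, 1, 0, 0, 0),
    (0, 0, 1, 1, 0),
    (0, 0, 1, 1, 1),
)


@dataclass
class SimulationConfig:
    """Parameters of one simulated bisulfite experiment.

    Defaults describe a clean small-scale experiment: a 100 bp locus with the
    demonstration CpG geometry, 10 planted non-CpG cytosines, complete
    conversion, error-free sequencing, forward-oriented clones.
    """

    ref_length: int = 100
    cpg_positions: tuple[int, ...] = TOY_CPG_POSITIONS
    n_noncpg_c: int = 10
    methylation_pattern: tuple = TOY_PATTERN
    conversion_failure_p: float = 0.0
    seq_error_p: float = 0.0
    orientations: tuple[str, ...] | None = None  # default: all identity
    clean_calls: bool = True  # keep errors away from C positions
    seed: int = 0

    def __post_init__(self) -> None:
        pos = sorted(self.cpg_positions)
        if pos and pos[-1] + 1 > self.ref_length:
            raise ValueError("CpG positions do not fit in ref_length")
        for a, b in zip(pos, pos[1:]):
            if b <= a + 1:
                raise ValueError(
                    f"CpG positions {a},{b} adjacent/overlapping: ambiguous"
                )
        if not 0.0 <= self.conversion_failure_p <= 1.0:
            raise ValueError("conversion_failure_p must be in [0,1]")
        if not 0.0 <= self.seq_error_p <= 1.0:
            raise ValueError("seq_error_p must be in [0,1]")


@dataclass
class GroundTruth:
    """What the simulator planted, per clone."""

    cpg_positions: list[int]
    noncpg_c_positions: list[int]
    methylation_pattern: list[list[int]]
    orientations: list[str]
    unconverted_positions: list[list[int]]  # non-CpG Cs left unconverted
    error_positions: list[list[int]]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def make_reference(cfg: SimulationConfig,
                   rng: np.random.Generator | None = None
                   ) -> tuple[SequenceRecord, ReferenceSequence, list[int]]:
    """Build a reference with exactly the requested CpG sites.

    Background is drawn from A/G/T (so no cytosine exists except where
    planted); CG dinucleotides sit exactly at ``cfg.cpg_positions`` and
    ``cfg.n_noncpg_c`` additional cytosines are planted outside CpG context
    (never followed by G).  Returns the record, the scanned
    :class:`ReferenceSequence` and the planted non-CpG C positions (1-based).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    length = cfg.ref_length
    bases = list(rng.choice(list("AGT"), size=length))
    blocked = set()
    for p in cfg.cpg_positions:  # 1-based C position
        bases[p - 1] = "C"
        bases[p] = "G"
        blocked.update((p - 1, p, p + 1))

    candidates = [
        i for i in range(1, length + 1)
        if i not in blocked and i + 1 <= length and i + 1 not in blocked
    ]
    # a planted C must not be followed by G (would create a CpG) and must not
    # precede a requested CpG's C
    candidates = [i for i in candidates if bases[i] != "G"]
    if len(candidates) < cfg.n_noncpg_c:
        raise ValueError("reference too short for requested non-CpG Cs")
    picked = sorted(
        rng.choice(candidates, size=cfg.n_noncpg_c, replace=False).tolist()
    )
    for i in picked:
        bases[i - 1] = "C"
        if bases[i] == "G":  # cannot happen by construction, guard anyway
            bases[i] = "A"

    record = SequenceRecord(id="ref", bases="".join(bases))
    ref = find_cpg_sites(record)
    if list(ref.cpg_positions) != sorted(cfg.cpg_positions):
        raise AssertionError("CpG placement failed")  # infeasible geometry
    return record, ref, picked


def make_clones(ref_record: SequenceRecord, cfg: SimulationConfig,
                noncpg_c_positions: list[int],
                rng: np.random.Generator | None = None
                ) -> tuple[list[SequenceRecord], GroundTruth]:
    """Derive bisulfite clone reads from the reference per the config."""
    rng = rng or np.random.default_rng(cfg.seed + 1)
    pattern = np.asarray(cfg.methylation_pattern, dtype=int)
    n_clones = pattern.shape[0]
    if pattern.shape[1] != len(cfg.cpg_positions):
        raise ValueError("pattern width != number of CpG sites")
    orientations = (list(cfg.orientations) if cfg.orientations
                    else ["identity"] * n_clones)
    if len(orientations) != n_clones:
        raise ValueError("one orientation per clone required")

    cpg_sorted = sorted(cfg.cpg_positions)
    protected = set()  # positions errors must avoid in clean-call mode
    if cfg.clean_calls:
        for p in cpg_sorted:
            protected.update((p, p + 1))
        protected.update(noncpg_c_positions)

    records = []
    unconverted_all, errors_all = [], []
    for k in range(n_clones):
        bases = list(ref_record.bases)
        # methylation: keep C where pattern=1, convert to T otherwise
        for site_idx, p in enumerate(cpg_sorted):
            if pattern[k, site_idx] == 0:
                bases[p - 1] = "T"
        # non-CpG Cs convert, except conversion failures
        unconverted = []
        for p in noncpg_c_positions:
            if rng.random() < cfg.conversion_failure_p:
                unconverted.append(p)
            else:
                bases[p - 1] = "T"
        # substitution errors
        errors = []
        if cfg.seq_error_p > 0:
            for i in range(len(bases)):
                pos = i + 1
                if pos in protected:
                    continue
                if rng.random() < cfg.seq_error_p:
                    alternatives = [b for b in "ACGT" if b != bases[i]]
                    bases[i] = str(rng.choice(alternatives))
                    errors.append(pos)
        seq = "".join(bases)
        orient = orientations[k]
        if orient == "reverse":
            seq = seq[::-1]
        elif orient == "complement":
            seq = complement(seq)
        elif orient == "reverse_complement":
            seq = reverse_complement(seq)
        elif orient != "identity":
            raise ValueError(f"unknown orientation {orient!r}")
        records.append(SequenceRecord(id=f"clone{k + 1}", bases=seq))
        unconverted_all.append(unconverted)
        errors_all.append(errors)

    truth = GroundTruth(
        cpg_positions=cpg_sorted,
        noncpg_c_positions=list(noncpg_c_positions),
        methylation_pattern=pattern.tolist(),
        orientations=orientations,
        unconverted_positions=unconverted_all,
        error_positions=errors_all,
    )
    return records, truth


def simulate_experiment(cfg: SimulationConfig
                        ) -> tuple[SequenceRecord, ReferenceSequence,
                                   list[SequenceRecord], GroundTruth]:
    """Reference + clones + ground truth from one seeded stream."""
    rng = np.random.default_rng(cfg.seed)
    ref_record, ref, noncpg = make_reference(cfg, rng)
    clones, truth = make_clones(ref_record, cfg, noncpg, rng)
    return ref_record, ref, clones, truth


def write_experiment(cfg: SimulationConfig, outdir: str | Path) -> dict:
    """Simulate and write reference FASTA, clones FASTA, ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref_record, ref, clones, truth = simulate_experiment(cfg)
    write_fasta([ref_record], outdir / "reference.fasta")
    write_fasta(clones, outdir / "clones.fasta")
    truth.to_json(outdir / "ground_truth.json")
    return {
        "reference": str(outdir / "reference.fasta"),
        "clones": str(outdir / "clones.fasta"),
        "ground_truth": str(outdir / "ground_truth.json"),
        "n_clones": len(clones),
        "n_cpg": len(ref.cpg_positions),
    }
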