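"""Per-clone quality control: bisulfite conversion ratio and identity rate.

The conversion ratio is the fraction of reference cytosines OUTSIDE CpG
context that the clone still reads as C — unconverted cytosines, i.e. a
bisulfite-treatment FAILURE rate (lower is better).  Non-CpG cytosines are
essentially never methylated in vertebrates, so any retained C there marks
incomplete conversion rather than biology.

The identity rate measures sequence agreement between clone and reference in
a local alignment restricted to A, G and T: reference-C columns are excluded
because conversion legitimately rewrites them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .align import CloneAlignment, SubstitutionScheme, local_align_agt


@dataclass
class QCReport:
    """Quality-control summary for one clone."""

    clone_id: str
    orientation: str
    score: float
    conversion_ratio: float | None  # None when no non-CpG C covered
    identity_rate: float | None     # None when 0 matches + 0 mismatches
    n_nonCpG_C: int
    n_unconverted: int
    n_matches: int
    n_mismatches: int
    passed: bool = True
    failed_gates: list[str] = field(default_factory=list)

    @property
    def conversion_success(self) -> float | None:
        """1 - conversion_ratio, the conventional 'conversion rate'."""
        if self.conversion_ratio is None:
            return None
        return 1.0 - self.conversion_ratio


def conversion_ratio(aln: CloneAlignment,
                     cpg_positions) -> tuple[float | None, int, int]:
    """Unconverted fraction of non-CpG reference cytosines in one clone.

    Walks alignment columns whose reference base is C at a position NOT in
    ``cpg_positions``; a clone C there is unconverted.  Gap and clone-N
    columns are excluded from numerator and denominator.  Returns
    ``(ratio, n_unconverted, n_nonCpG_C)``; ratio is None when the
    denominator is zero (clone flagged downstream).
    """
    cpg = set(cpg_positions)
    n_total = 0
    n_unconv = 0
    for pos, ref_base, clone_base in aln.columns():
        if pos is None or ref_base != "C" or pos in cpg:
            continue
        if clone_base in ("-", "N"):
            continue
        n_total += 1
        if clone_base == "C":
            n_unconv += 1
    ratio = (n_unconv / n_total) if n_total > 0 else None
    return ratio, n_unconv, n_total


def identity_rate(matches: int, mismatches: int) -> float | None:
    """A/G/T-restricted identity: matches / (matches + mismatches)."""
    if matches < 0 or mismatches < 0:
        raise ValueError("negative counts")
    total = matches + mismatches
    if total == 0:
        return None
    return matches / total


def qc_clone(aln: CloneAlignment, ref_bases: str, cpg_positions,
             scheme: SubstitutionScheme | None = None) -> QCReport:
    """Compute both QC statistics for one orientation-resolved clone."""
    scheme = scheme or SubstitutionScheme()
    ratio, n_unconv, n_total = conversion_ratio(aln, cpg_positions)
    clone_seq = aln.aligned_clone.replace("-", "")
    matches, mismatches = local_align_agt(ref_bases, clone_seq, scheme)
    return QCReport(
        clone_id=aln.clone_id,
        orientation=aln.orientation,
        score=aln.score,
        conversion_ratio=ratio,
        identity_rate=identity_rate(matches, mismatches),
        n_nonCpG_C=n_total,
        n_unconverted=n_unconv,
        n_matches=matches,
        n_mismatches=mismatches,
    )


def apply_gates(reports: list[QCReport],
                max_conversion_ratio: float = 0.1,
                min_identity: float = 0.8,
                min_score: float = float("-inf")
                ) -> tuple[list[QCReport], list[QCReport]]:
    """Partition reports into (passed, failed) by configurable gates.

    A clone with an undefined statistic (no non-CpG C covered, or an empty
    A/G/T comparison) fails that gate: it cannot demonstrate quality.
    Each failed report lists the specific gate(s) violated.
    """
    for t in (max_conversion_ratio, min_identity):
        if not math.isfinite(t):
            raise ValueError("gate thresholds must be finite")
    passed, failed = [], []
    for rep in reports:
        gates = []
        if rep.conversion_ratio is None or rep.conversion_ratio > max_conversion_ratio:
            gates.append("conversion_ratio")
        if rep.identity_rate is None or rep.identity_rate < min_identity:
            gates.append("identity_rate")
        if rep.score < min_score:
            gates.append("score")
        rep.failed_gates = gates
        rep.passed = not gates
        (passed if rep.passed else failed).append(rep)
    return passed, failed


def reports_to_frame(reports: list[QCReport]) -> pd.DataFrame:
    """One row per clone, suitable for TSV export."""
    return pd.DataFrame(
        [
            {
                "clone_id": r.clone_id,
                "orientation": r.orientation,
                "score": r.score,
                "conversion_ratio": r.conversion_ratio,
                "conversion_success": r.conversion_success,
                "identity_rate": r.identity_rate,
                "n_nonCpG_C": r.n_nonCpG_C,
                "n_unconverted": r.n_unconverted,
                "n_matches": r.n_matches,
                "n_mismatches": r.n_mismatches,
                "passed": r.passed,
                "failed_gates": ",".join(r.failed_gates),
            }
            for r in reports
        ]
    )


def summary_text(reports: list[QCReport]) -> str:
    """Human-readable QC summary."""
    lines = [f"{len(reports)} clone(s); "
             f"{sum(r.passed for r in reports)} passed QC"]
    for r in reports:
        conv = "NA" if r.conversion_ratio is None else f"{r.conversion_ratio:.3f}"
        ident = "NA" if r.identity_rate is None else f"{r.identity_rate:.3f}"
        status = "PASS" if r.passed else "FAIL(" + ",".join(r.failed_gates) + ")"
        lines.append(
            f"  {r.clone_id}: orientation={r.orientation} score={r.score:.1f} "
            f"conversion_ratio={conv} identity={ident} {status}"
        )
    return "\n".join(lines)
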