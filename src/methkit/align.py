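"""Bisulfite-tolerant pairwise alignment and orientation control.

Bisulfite treatment converts unmethylated cytosine to uracil, read as T, so a
clone T aligned to a reference C is expected biology, not a mismatch.  The
substitution scheme here is therefore DIRECTIONAL: clone T vs reference C
scores as tolerated, while clone C vs reference T is an ordinary mismatch.

Sequencer output may also arrive reversed, complemented or
reverse-complemented relative to the reference.  ``orient_clone`` scores all
four orientation candidates by global Needleman-Wunsch alignment and keeps
the best, so a correctly oriented clone is never transformed.

Coordinates are 1-based, fully closed, on the forward strand of the
reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .io import SequenceRecord, complement, reverse_complement

NEG_INF = float("-inf")

#: IUPAC code -> set of concrete bases it stands for
_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

ORIENTATIONS = ("identity", "reverse", "complement", "reverse_complement")


@dataclass
class SubstitutionScheme:
    """Scoring parameters for bisulfite clone-vs-reference alignment.

    ``bisulfite_tc_score`` is the score for clone T aligned to reference C
    (the conversion-tolerated pairing); it must not be penalised as an
    ordinary mismatch.  N scores 0 against anything; other ambiguity codes
    score ``match_score`` when the two codes' base sets intersect.
    Gap costs are affine: a gap of length L costs
    ``gap_open + (L-1) * gap_extend``.
    """

    match_score: float = 1.0
    mismatch_score: float = -1.0
    bisulfite_tc_score: float = 1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if self.match_score <= self.mismatch_score:
            raise ValueError("match_score must exceed mismatch_score")
        if self.bisulfite_tc_score < self.mismatch_score:
            raise ValueError("bisulfite_tc_score below mismatch_score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")

    def score(self, ref_base: str, clone_base: str) -> float:
        """Score one reference/clone base pairing (directional)."""
        if ref_base == "C" and clone_base == "T":
            return self.bisulfite_tc_score
        if ref_base == "N" or clone_base == "N":
            return 0.0
        if set(_IUPAC_SETS[ref_base]) & set(_IUPAC_SETS[clone_base]):
            return self.match_score
        return self.mismatch_score


@dataclass
class CloneAlignment:
    """Best-orientation global alignment of one clone to the reference.

    ``aligned_ref``/``aligned_clone`` are equal-length gapped strings with no
    all-gap column; ungapping ``aligned_ref`` reproduces
    ``reference[ref_start..ref_end]`` (1-based, closed).  ``flagged`` marks
    clones for which no orientation produced a credible alignment.
    """

    clone_id: str
    orientation: str
    score: float
    aligned_ref: str
    aligned_clone: str
    ref_start: int
    ref_end: int
    flagged: bool = False

    def __post_init__(self) -> None:
        if len(self.aligned_ref) != len(self.aligned_clone):
            raise ValueError("aligned strings differ in length")

    def columns(self):
        """Yield (ref_position or None, ref_base, clone_base) per column.

        ``ref_position`` is 1-based on the forward reference strand and None
        for columns where the reference is gapped.
        """
        pos = self.ref_start - 1
        for rb, cb in zip(self.aligned_ref, self.aligned_clone):
            if rb != "-":
                pos += 1
                yield pos, rb, cb
            else:
                yield None, rb, cb


# DP pointer codes: which matrix a cell's best path came from
_M, _X, _Y, _NONE = 0, 1, 2, 3


def _affine_dp(ref: str, clone: str, scheme: SubstitutionScheme,
               local: bool = False):
    """Gotoh affine-gap DP over ref (rows) x clone (columns).

    Returns (M, X, Y, pointers) where X holds paths ending with a gap in the
    clone (reference base consumed) and Y paths ending with a gap in the
    reference.  Pointer tie-break prefers diagonal over up (X) over left (Y),
    giving a deterministic traceback.
    """
    n, m = len(ref), len(clone)
    go, ge = scheme.gap_open, scheme.gap_extend
    width = m + 1
    M = [[NEG_INF] * width for _ in range(n + 1)]
    X = [[NEG_INF] * width for _ in range(n + 1)]
    Y = [[NEG_INF] * width for _ in range(n + 1)]
    ptr = [[(0, 0, 0)] * width for _ in range(n + 1)]

    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0 if local else go + (i - 1) * ge
        M[i][0] = 0.0 if local else NEG_INF
    for j in range(1, m + 1):
        Y[0][j] = 0.0 if local else go + (j - 1) * ge
        M[0][j] = 0.0 if local else NEG_INF
    if local:
        for i in range(n + 1):
            M[i][0] = 0.0
        for j in range(m + 1):
            M[0][j] = 0.0

    score = scheme.score
    for i in range(1, n + 1):
        rb = ref[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mu, Xu, Yu = M[i - 1], X[i - 1], Y[i - 1]
        row_ptr = ptr[i]
        for j in range(1, m + 1):
            s = score(rb, clone[j - 1])
            # M: diagonal step from any matrix; tie-break M > X > Y
            a, b, c = Mu[j - 1], Xu[j - 1], Yu[j - 1]
            if a >= b and a >= c:
                best, src = a, _M
            elif b >= c:
                best, src = b, _X
            else:
                best, src = c, _Y
            mval = best + s
            if local and mval < 0.0:
                mval, src = 0.0, _NONE
            Mi[j] = mval
            # X: gap in clone (consume ref base i); open from M/Y, extend X
            a, b, c = Mu[j] + go, Xu[j] + ge, Yu[j] + go
            if a >= b and a >= c:
                xval, xsrc = a, _M
            elif b >= c:
                xval, xsrc = b, _X
            else:
                xval, xsrc = c, _Y
            Xi[j] = xval
            # Y: gap in reference (consume clone base j)
            a, b, c = Mi[j - 1] + go, Xi[j - 1] + go, Yi[j - 1] + ge
            if a >= b and a >= c:
                yval, ysrc = a, _M
            elif b >= c:
                yval, ysrc = b, _X
            else:
                yval, ysrc = c, _Y
            Yi[j] = yval
            row_ptr[j] = (src, xsrc, ysrc)
    return M, X, Y, ptr


def _nw_score(ref: str, clone: str, scheme: SubstitutionScheme) -> float:
    M, X, Y, _ = _affine_dp(ref, clone, scheme)
    n, m = len(ref), len(clone)
    return max(M[n][m], X[n][m], Y[n][m])


def needleman_wunsch(ref: str, clone: str, scheme: SubstitutionScheme,
                     clone_id: str = "clone",
                     orientation: str = "identity") -> CloneAlignment:
    """Optimal global alignment of clone to reference under the scheme.

    Traceback tie-break: diagonal over up (gap in clone) over left (gap in
    reference), so output is deterministic.  Reference-only overhangs (clone
    gapped at either end) are trimmed and ``ref_start``/``ref_end`` record
    the reference span under the clone's first and last aligned base.
    """
    if not ref or not clone:
        raise ValueError("empty sequence")
    ref, clone = ref.upper(), clone.upper()
    M, X, Y, ptr = _affine_dp(ref, clone, scheme)
    n, m = len(ref), len(clone)
    finals = (M[n][m], X[n][m], Y[n][m])
    best = max(finals)
    state = (_M, _X, _Y)[finals.index(best)]  # index() prefers M > X > Y

    ra, ca = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if state == _M:
            if i == 0 or j == 0:  # boundary: only gaps remain
                state = _X if i > 0 else _Y
                continue
            ra.append(ref[i - 1])
            ca.append(clone[j - 1])
            state = ptr[i][j][0]
            i -= 1
            j -= 1
        elif state == _X:
            ra.append(ref[i - 1])
            ca.append("-")
            state = ptr[i][j][1] if j > 0 else _X
            i -= 1
        else:  # _Y
            ra.append("-")
            ca.append(clone[j - 1])
            state = ptr[i][j][2] if i > 0 else _Y
            j -= 1
    ra.reverse()
    ca.reverse()

    # trim reference-only overhangs so the span reflects clone coverage
    lo = 0
    while lo < len(ca) and ca[lo] == "-":
        lo += 1
    hi = len(ca)
    while hi > lo and ca[hi - 1] == "-":
        hi -= 1
    ref_start = 1 + sum(1 for b in ra[:lo] if b != "-")
    ref_end = ref_start - 1 + sum(1 for b in ra[lo:hi] if b != "-")
    return CloneAlignment(
        clone_id=clone_id,
        orientation=orientation,
        score=best,
        aligned_ref="".join(ra[lo:hi]),
        aligned_clone="".join(ca[lo:hi]),
        ref_start=ref_start,
        ref_end=ref_end,
    )


def orientation_variants(clone: str) -> dict[str, str]:
    """The four orientation candidates of a clone sequence."""
    return {
        "identity": clone,
        "reverse": clone[::-1],
        "complement": complement(clone),
        "reverse_complement": reverse_complement(clone),
    }


def orient_clone(ref: str, clone: str, scheme: SubstitutionScheme,
                 clone_id: str = "clone",
                 unalignable_floor: float = 0.0) -> CloneAlignment:
    """Resolve clone orientation by global alignment score.

    All four candidates (as-given, reverse, complement, reverse-complement)
    are scored; the highest-scoring alignment is returned with its
    orientation recorded.  Ties prefer the earlier orientation in
    ``ORIENTATIONS`` (identity first), so good input is never transformed.
    If all four scores are equal and at or below ``unalignable_floor`` the
    returned alignment carries ``flagged=True``.
    """
    if not ref or not clone:
        raise ValueError("empty sequence")
    variants = orientation_variants(clone.upper())
    scores = {
        name: _nw_score(ref.upper(), seq, scheme)
        for name, seq in variants.items()
    }
    best_name = max(ORIENTATIONS, key=lambda o: scores[o])
    aln = needleman_wunsch(ref, variants[best_name], scheme,
                           clone_id=clone_id, orientation=best_name)
    values = list(scores.values())
    if math.isclose(min(values), max(values)) and values[0] <= unalignable_floor:
        aln.flagged = True
    return aln


def local_align_agt(ref: str, clone: str,
                    scheme: SubstitutionScheme) -> tuple[int, int]:
    """Match/mismatch counts from a local alignment, restricted to A/G/T.

    Smith-Waterman local alignment of the (orientation-resolved) clone to the
    reference; columns where the reference base is C, either side is gapped,
    or the clone base is not a concrete A/C/G/T are excluded.  Bisulfite
    conversion makes reference-C columns uninformative about sequence
    identity, hence the restriction to the three untouched bases.
    """
    if not ref or not clone:
        raise ValueError("empty sequence")
    ref, clone = ref.upper(), clone.upper()
    M, X, Y, ptr = _affine_dp(ref, clone, scheme, local=True)
    n, m = len(ref), len(clone)
    best, bi, bj = 0.0, 0, 0
    for i in range(n + 1):
        Mi = M[i]
        for j in range(m + 1):
            if Mi[j] > best:
                best, bi, bj = Mi[j], i, j
    if best <= 0.0:
        return (0, 0)

    matches = mismatches = 0
    state = _M
    i, j = bi, bj
    while i > 0 and j > 0:
        if state == _M:
            if M[i][j] == 0.0 and ptr[i][j][0] == _NONE:
                break
            rb, cb = ref[i - 1], clone[j - 1]
            if rb != "C" and cb in "ACGT":
                if rb == cb:
                    matches += 1
                else:
                    mismatches += 1
            state = ptr[i][j][0]
            if state == _NONE:
                i -= 1
                j -= 1
                break
            i -= 1
            j -= 1
        elif state == _X:
            state = ptr[i][j][1]
            i -= 1
        else:
            state = ptr[i][j][2]
            j -= 1
    return (matches, mismatches)


def align_clones(ref_record: SequenceRecord,
                 clones: list[SequenceRecord],
                 scheme: SubstitutionScheme | None = None) -> list[CloneAlignment]:
    """Orient and globally align every clone against one reference."""
    scheme = scheme or SubstitutionScheme()
    return [
        orient_clone(ref_record.bases, rec.bases, scheme, clone_id=rec.id)
        for rec in clones
    ]


def alignments_to_tsv(alignments: list[CloneAlignment], path) -> None:
    """Tabular export: clone_id, orientation, score, ref_start, ref_end."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "clone_id": a.clone_id,
                "orientation": a.orientation,
                "score": a.score,
                "ref_start": a.ref_start,
                "ref_end": a.ref_end,
                "flagged": a.flagged,
            }
            for a in alignments
        ]
    ).to_csv(path, sep="\t", index=False)


def alignments_to_fasta(alignments: list[CloneAlignment], path) -> None:
    """Pairwise FASTA export (ref row then clone row per alignment)."""
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(f">ref|{a.clone_id}|{a.ref_start}-{a.ref_end}\n")
            fh.write(a.aligned_ref + "\n")
            fh.write(f">{a.clone_id}|{a.orientation}\n")
            fh.write(a.aligned_clone + "\n")
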