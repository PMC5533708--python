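"""Global pairwise alignment of paralogs and coordinate mapping."""

from __future__ import annotations

import dataclasses

from Bio import Align
from Bio.Align import substitution_matrices

from ..records import ProteinRecord, SequenceError

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0


@dataclasses.dataclass(frozen=True)
class ParalogAlignment:
    protein_a: str
    protein_b: str
    aligned_a: str
    aligned_b: str
    identity_pct: float
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise SequenceError("aligned rows differ in length")

    def columns(self):
        """Yield (pos_a, pos_b, char_a, char_b); gap positions are None."""
        ia = ib = 0
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            pa = pb = None
            if ca != "-":
                ia += 1
                pa = ia
            if cb != "-":
                ib += 1
                pb = ib
            yield pa, pb, ca, cb

    @property
    def coordinate_map(self) -> dict[int, int]:
        """pos in A -> pos in B for aligned (non-gap-pair) columns."""
        return {
            pa: pb for pa, pb, ca, cb in self.columns() if pa is not None and pb is not None
        }


def align_paralogs(
    a: ProteinRecord,
    b: ProteinRecord,
    substitution_matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> ParalogAlignment:
    """Global affine-gap alignment; identity over aligned (non-gap) columns.

    Full-length identity figures are parameter-dependent; defaults follow
    common BLAST-style protein scoring (BLOSUM62, 11/1).
    """
    if not a.sequence or not b.sequence:
        raise SequenceError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(substitution_matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    alignment = aligner.align(a.sequence, b.sequence)[0]
    aligned_a, aligned_b = str(alignment[0]), str(alignment[1])
    pairs = [
        (ca, cb) for ca, cb in zip(aligned_a, aligned_b) if ca != "-" and cb != "-"
    ]
    identical = sum(1 for ca, cb in pairs if ca == cb)
    identity = 100.0 * identical / len(pairs) if pairs else 0.0
    result = ParalogAlignment(
        protein_a=a.accession,
        protein_b=b.accession,
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        identity_pct=identity,
        score=float(alignment.score),
    )
    if result.aligned_a.replace("-", "") != a.sequence or result.aligned_b.replace(
        "-", ""
    ) != b.sequence:
        raise SequenceError("alignment does not round-trip input sequences")
    return result


def map_position(aln: ParalogAlignment, protein: str, position: int) -> int | None:
    """Map a residue position through the alignment; None in partner gaps."""
    if protein == aln.protein_a:
        forward = True
        length = len(aln.aligned_a.replace("-", ""))
    elif protein == aln.protein_b:
        forward = False
        length = len(aln.aligned_b.replace("-", ""))
    else:
        raise SequenceError(f"unknown accession {protein!r} for this alignment")
    if not (1 <= position <= length):
        raise SequenceError(f"position {position} outside {protein}")
    if forward:
        return aln.coordinate_map.get(position)
    reverse = {pb: pa for pa, pb in aln.coordinate_map.items()}
    return reverse.get(position)


def recompute_score(
    aln: ParalogAlignment,
    substitution_matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Affine-gap score recomputed directly from the emitted alignment."""
    matrix = substitution_matrices.load(substitution_matrix)
    # PairwiseAligner semantics: the first gapped column costs gap_open,
    # each further column of the same gap costs gap_extend.
    score = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca == "-":
            score -= abs(gap_extend) if in_gap_a else abs(gap_open)
            in_gap_a, in_gap_b = True, False
        elif cb == "-":
            score -= abs(gap_extend) if in_gap_b else abs(gap_open)
            in_gap_a, in_gap_b = False, True
        else:
            score += matrix[ca, cb]
            in_gap_a = in_gap_b = False
    return score
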