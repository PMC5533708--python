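"""Ortholog-alignment conservation scoring and the SLiM validation gate.

A candidate motif is *accepted* when it sits in a disordered region and is
conserved among orthologs.  Conservation is operationalised two ways and
both are reported: mean per-column conservation over the hit, and the
fraction of ortholog rows in which the motif regex still matches.  Overlap
with an alternatively used isoform region is recorded as supporting
evidence but is not part of the gate.
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .records import ProteinRecord, IsoformDiff, SequenceError
from .seqfeatures.disorder import DisorderProfile
from .seqfeatures.motifs import MotifHit, MotifPattern

DEFAULT_C_MIN = 0.6
DEFAULT_F_MIN = 0.7
GAP_COLUMN_FRACTION = 0.5


class AlignmentFormatError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class OrthologAlignment:
    """An ortholog MSA with a designated reference row."""

    family_id: str
    rows: tuple[tuple[str, str], ...]  # (accession, gapped sequence)
    reference_row: str

    def __post_init__(self) -> None:
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise AlignmentFormatError(f"{self.family_id}: ragged alignment rows")
        if self.reference_row not in {acc for acc, _ in self.rows}:
            raise AlignmentFormatError(
                f"{self.family_id}: reference row {self.reference_row!r} absent"
            )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def reference_gapped(self) -> str:
        return dict(self.rows)[self.reference_row]

    @property
    def reference_sequence(self) -> str:
        return self.reference_gapped.replace("-", "")

    @property
    def column_map(self) -> dict[int, int]:
        """MSA column (1-based) -> reference residue position (1-based)."""
        out: dict[int, int] = {}
        pos = 0
        for col, c in enumerate(self.reference_gapped, start=1):
            if c != "-":
                pos += 1
                out[col] = pos
        return out

    def reference_columns(self) -> list[int]:
        """0-based MSA column index for each reference residue, in order."""
        return [
            i for i, c in enumerate(self.reference_gapped) if c != "-"
        ]


def read_alignment_fasta(
    path: str | Path, reference_row: str, family_id: str | None = None
) -> OrthologAlignment:
    rows = [(rec.id.split("|")[1] if "|" in rec.id else rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise AlignmentFormatError(f"no alignment rows in {path}")
    return OrthologAlignment(
        family_id=family_id or Path(path).stem, rows=tuple(rows), reference_row=reference_row
    )


@dataclasses.dataclass(frozen=True)
class ConservationProfile:
    reference: str
    score: np.ndarray  # per reference residue, in [0, 1]
    gap_fraction: np.ndarray
    gappy: np.ndarray  # True where the column exceeded the gap-fraction cap

    def mean_over(self, start: int, end: int) -> float:
        return float(np.mean(self.score[start - 1 : end]))


def score_columns(
    msa: OrthologAlignment, method: str = "identity_fraction"
) -> ConservationProfile:
    """Per-reference-residue conservation over non-gap rows.

    ``identity_fraction`` is the modal-residue fraction; ``normalized_entropy``
    is 1 - H/log20.  Columns with more than half gaps score 0 and are
    flagged ``gappy``.
    """
    if method not in ("identity_fraction", "normalized_entropy"):
        raise ValueError(f"unknown conservation method {method!r}")
    n_rows = len(msa.rows)
    scores, gaps, gappy = [], [], []
    for col in msa.reference_columns():
        residues = [seq[col] for _, seq in msa.rows if seq[col] != "-"]
        gap_frac = 1 - len(residues) / n_rows
        is_gappy = gap_frac > GAP_COLUMN_FRACTION
        if is_gappy or not residues:
            score = 0.0
        elif method == "identity_fraction":
            score = Counter(residues).most_common(1)[0][1] / len(residues)
        else:
            counts = Counter(residues)
            h = -sum(
                (c / len(residues)) * math.log(c / len(residues)) for c in counts.values()
            )
            score = 1.0 - h / math.log(20)
        scores.append(score)
        gaps.append(gap_frac)
        gappy.append(is_gappy)
    return ConservationProfile(
        reference=msa.reference_row,
        score=np.array(scores),
        gap_fraction=np.array(gaps),
        gappy=np.array(gappy),
    )


def motif_ortholog_support(
    hit: MotifHit,
    pattern: MotifPattern,
    msa: OrthologAlignment,
    flank: int = 3,
) -> float:
    """Fraction of non-reference rows whose aligned segment still matches.

    Each ortholog contributes the ungapped sequence aligned to the hit window
    extended by ``flank`` residues; rows that are all-gap across the window
    are excluded from the denominator.  For C-terminally anchored patterns
    the window runs to the end of the alignment so the anchor is meaningful.
    """
    ref_len = len(msa.reference_sequence)
    if not (1 <= hit.start <= hit.end <= ref_len):
        raise SequenceError(f"hit {hit.start}-{hit.end} outside reference row")
    ref_cols = msa.reference_columns()
    lo = ref_cols[max(hit.start - 1 - flank, 0)]
    if pattern.anchored_c_terminal and hit.end == ref_len:
        hi = msa.n_columns - 1
    else:
        hi = ref_cols[min(hit.end - 1 + flank, ref_len - 1)]
    matching = 0
    considered = 0
    for acc, seq in msa.rows:
        if acc == msa.reference_row:
            continue
        segment = seq[lo : hi + 1].replace("-", "")
        if not segment:
            continue
        considered += 1
        if pattern.compiled.search(segment):
            matching += 1
    return matching / considered if considered else 0.0


@dataclasses.dataclass(frozen=True)
class ValidatedMotif:
    hit: MotifHit
    mean_conservation: float
    ortholog_match_fraction: float
    disordered: bool
    overlaps_isoform_diff: bool
    accepted: bool


def validate_motifs(
    hits: Sequence[MotifHit],
    disorder: DisorderProfile,
    cons: ConservationProfile,
    support: Mapping[tuple[str, int, int], float],
    isoform_diffs: Sequence[IsoformDiff] = (),
    c_min: float = DEFAULT_C_MIN,
    f_min: float = DEFAULT_F_MIN,
    disorder_fraction: float = 0.5,
) -> list[ValidatedMotif]:
    """Apply the acceptance gate: disordered AND conserved (both measures).

    ``support`` maps (motif_id, start, end) to the ortholog match fraction.
    A hit counts as disordered when at least ``disorder_fraction`` of its
    residues are called disordered.
    """
    out: list[ValidatedMotif] = []
    for hit in hits:
        if hit.protein != disorder.protein or disorder.protein != cons.reference:
            raise SequenceError(
                f"mismatched accessions: hit {hit.protein}, disorder "
                f"{disorder.protein}, conservation {cons.reference}"
            )
        disordered = disorder.fraction_disordered(hit.start, hit.end) >= disorder_fraction
        mean_cons = cons.mean_over(hit.start, hit.end)
        frac = support.get((hit.motif_id, hit.start, hit.end), 0.0)
        overlaps = any(d.overlaps(hit.start, hit.end) for d in isoform_diffs)
        out.append(
            ValidatedMotif(
                hit=hit,
                mean_conservation=mean_cons,
                ortholog_match_fraction=frac,
                disordered=disordered,
                overlaps_isoform_diff=overlaps,
                accepted=disordered and mean_cons >= c_min and frac >= f_min,
            )
        )
    return out


def validate_protein_motifs(
    protein: ProteinRecord,
    hits: Sequence[MotifHit],
    patterns: Sequence[MotifPattern],
    disorder: DisorderProfile,
    msa: OrthologAlignment,
    method: str = "identity_fraction",
    flank: int = 3,
    c_min: float = DEFAULT_C_MIN,
    f_min: float = DEFAULT_F_MIN,
) -> list[ValidatedMotif]:
    """Convenience wrapper: score the MSA, compute per-hit ortholog support
    and run the gate in one call."""
    by_id = {p.motif_id: p for p in patterns}
    cons = score_columns(msa, method=method)
    support = {
        (h.motif_id, h.start, h.end): motif_ortholog_support(
            h, by_id[h.motif_id], msa, flank=flank
        )
        for h in hits
    }
    return validate_motifs(
        hits, disorder, cons, support, protein.isoform_diffs, c_min=c_min, f_min=f_min
    )
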