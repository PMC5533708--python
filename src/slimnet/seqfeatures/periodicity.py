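"""Residue periodicity detection via adjacent-spacing histograms.

Used to flag regularly spaced residue signatures (e.g. a tyrosine every ~12
residues in a repeat-like tail) without running a full repeat decomposition.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

from ..records import ProteinRecord, SequenceError


@dataclasses.dataclass(frozen=True)
class PeriodicitySignal:
    protein: str
    residue: str
    region: tuple[int, int]
    occurrence_count: int
    dominant_period: int | None
    period_score: float | None
    spacing_histogram: tuple[tuple[int, int], ...] = ()


def detect_periodicity(
    protein: ProteinRecord,
    residue: str,
    region: tuple[int, int],
    period_range: tuple[int, int] = (2, 50),
    tolerance: int = 1,
) -> PeriodicitySignal:
    """Dominant spacing of ``residue`` occurrences within ``region``.

    The dominant period is the mode of the adjacent-spacing histogram
    restricted to ``period_range`` (smallest period wins ties); the score is
    the fraction of all adjacent spacings within ``tolerance`` of it.  Fewer
    than 3 occurrences yield a null-period signal.
    """
    start, end = region
    if not (1 <= start <= end <= len(protein)):
        raise SequenceError(f"region {region} outside {protein.accession}")
    if period_range[0] < 2:
        raise ValueError("minimum period must be >= 2")
    if len(residue) != 1:
        raise ValueError("residue must be a single letter")
    positions = [
        i for i in range(start, end + 1) if protein.sequence[i - 1] == residue
    ]
    if len(positions) < 3:
        return PeriodicitySignal(
            protein.accession, residue, region, len(positions), None, None
        )
    spacings = [b - a for a, b in zip(positions, positions[1:])]
    hist = Counter(spacings)
    in_range = {p: c for p, c in hist.items() if period_range[0] <= p <= period_range[1]}
    if not in_range:
        return PeriodicitySignal(
            protein.accession, residue, region, len(positions), None, None,
            tuple(sorted(hist.items())),
        )
    dominant = min(in_range, key=lambda p: (-in_range[p], p))
    score = sum(1 for s in spacings if abs(s - dominant) <= tolerance) / len(spacings)
    return PeriodicitySignal(
        protein=protein.accession,
        residue=residue,
        region=region,
        occurrence_count=len(positions),
        dominant_period=dominant,
        period_score=score,
        spacing_histogram=tuple(sorted(hist.items())),
    )
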