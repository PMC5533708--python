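"""Compositionally biased region detection.

Two detectors cover the feature classes seen in scaffold-protein termini:

* :func:`detect_bias_regions` — windowed enrichment for an arbitrary residue
  set (serine-rich regions and similar), where every length-``window``
  sub-window inside a reported region must reach ``min_fraction``.
* :func:`detect_homopolymer_runs` — poly-amino-acid runs (poly-Q, poly-P)
  defined as runs of one residue of a minimum length with a bounded number
  of single-residue interruptions.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

from ..records import ProteinRecord

DEFAULT_SERINE_RICH = dict(residue_set=frozenset("S"), window=30, min_fraction=0.33, min_length=20)
DEFAULT_HOMOPOLYMER = dict(min_length=8, max_interruptions=1)


class BiasConfigError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class BiasRegion:
    protein: str
    bias_type: str
    start: int
    end: int
    fraction: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _member_mask(seq: str, residue_set: frozenset[str]) -> list[bool]:
    return [c in residue_set for c in seq]


def detect_bias_regions(
    protein: ProteinRecord,
    residue_set: Iterable[str],
    window: int,
    min_fraction: float,
    min_length: int,
    bias_type: str | None = None,
) -> list[BiasRegion]:
    """Maximal non-overlapping regions of local residue-set enrichment.

    A region is a maximal run of qualifying sliding windows (fraction of
    member residues >= ``min_fraction``), trimmed so it starts and ends on a
    member residue; regions shorter than ``min_length`` are dropped.  When
    two runs of qualifying windows would produce overlapping spans the later
    region is truncated to start after the earlier one, which preserves the
    every-sub-window guarantee (its window starts remain qualifying).
    """
    residue_set = frozenset(residue_set)
    if not residue_set:
        raise BiasConfigError("residue_set is empty")
    if not (0 < min_fraction <= 1):
        raise BiasConfigError(f"min_fraction must be in (0, 1], got {min_fraction}")
    if window < 1:
        raise BiasConfigError(f"window must be >= 1, got {window}")
    label = bias_type or "+".join(sorted(residue_set))
    seq = protein.sequence
    n = len(seq)
    # sequences shorter than the window are scanned with one full-length
    # window, which keeps the detector idempotent on its own output regions
    window = min(window, n)
    member = _member_mask(seq, residue_set)
    counts = [0] * (n - window + 1)
    running = sum(member[:window])
    counts[0] = running
    for i in range(1, n - window + 1):
        running += member[i + window - 1] - member[i - 1]
        counts[i] = running
    qualifying = [c / window >= min_fraction for c in counts]

    regions: list[BiasRegion] = []
    prev_end0 = -1  # 0-based inclusive end of previous reported region
    i = 0
    while i < len(qualifying):
        if not qualifying[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(qualifying) and qualifying[j + 1]:
            j += 1
        s0, e0 = i, j + window - 1
        s0 = max(s0, prev_end0 + 1)
        # trim to member residues at both ends
        while s0 <= e0 and not member[s0]:
            s0 += 1
        while e0 >= s0 and not member[e0]:
            e0 -= 1
        if e0 - s0 + 1 >= min_length:
            frac = sum(member[s0 : e0 + 1]) / (e0 - s0 + 1)
            regions.append(
                BiasRegion(protein.accession, label, s0 + 1, e0 + 1, frac)
            )
            prev_end0 = e0
        i = j + 1
    return regions


def detect_homopolymer_runs(
    protein: ProteinRecord,
    residue: str,
    min_length: int = 8,
    max_interruptions: int = 1,
    bias_type: str | None = None,
) -> list[BiasRegion]:
    """Poly-residue runs of length >= ``min_length`` tolerating up to
    ``max_interruptions`` single non-member residues, greedily left to right."""
    if len(residue) != 1:
        raise BiasConfigError("homopolymer detector takes a single residue")
    label = bias_type or f"poly{residue}"
    seq = protein.sequence
    n = len(seq)
    regions: list[BiasRegion] = []
    i = 0
    while i < n:
        if seq[i] != residue:
            i += 1
            continue
        j = i
        interruptions = 0
        last_member = i
        while j + 1 < n:
            nxt = seq[j + 1]
            if nxt == residue:
                j += 1
                last_member = j
            elif interruptions < max_interruptions and j + 2 < n and seq[j + 2] == residue:
                interruptions += 1
                j += 2
                last_member = j
            else:
                break
        length = last_member - i + 1
        if length >= min_length:
            frac = sum(1 for c in seq[i : last_member + 1] if c == residue) / length
            regions.append(BiasRegion(protein.accession, label, i + 1, last_member + 1, frac))
        i = last_member + 1
    return regions
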