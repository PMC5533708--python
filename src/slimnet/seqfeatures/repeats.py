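"""Tandem-repeat unit scanning against a position-weighted consensus.

A :class:`RepeatProfile` holds per-position residue weights derived from a
curated repeat consensus: the consensus residue scores 1.0, chemically
similar residues 0.5, everything else 0.  TPR-style profiles additionally
score a small/large residue size pattern at 0.5 per matching position.
Packaged profiles encode the canonical 33-residue ankyrin and 34-residue
TPR consensus units; both are reconstructions of published consensus rows
and are exposed as data so they can be replaced.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

from ..records import ProteinRecord

SMALL_RESIDUES = frozenset("AGSCP")
LARGE_RESIDUES = frozenset("FWYLIMRK")

# residues scoring 0.5 against each consensus residue
_SIMILAR: dict[str, str] = {
    "A": "GS", "G": "AS", "S": "ATG", "T": "S", "C": "",
    "D": "EN", "E": "DQ", "N": "DQH", "Q": "ENH",
    "K": "R", "R": "K", "H": "NQ",
    "L": "IVMF", "I": "LVM", "V": "ILM", "M": "LIV",
    "F": "YWL", "Y": "FW", "W": "FY", "P": "",
}


class RepeatConfigError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class RepeatProfile:
    repeat_name: str
    unit_length: int
    position_weights: tuple[Mapping[str, float], ...]
    size_pattern: tuple[str, ...] | None = None  # 'S' small, 'L' large, '.' any
    size_weight: float = 0.5

    def __post_init__(self) -> None:
        if len(self.position_weights) != self.unit_length:
            raise RepeatConfigError("position_weights length != unit_length")
        if self.size_pattern is not None and len(self.size_pattern) != self.unit_length:
            raise RepeatConfigError("size_pattern length != unit_length")

    @property
    def max_score(self) -> float:
        total = sum(max(w.values(), default=0.0) for w in self.position_weights)
        if self.size_pattern is not None:
            total += self.size_weight * sum(1 for c in self.size_pattern if c != ".")
        return total

    def score_window(self, window: str) -> float:
        if len(window) != self.unit_length:
            raise RepeatConfigError(
                f"window length {len(window)} != unit length {self.unit_length}"
            )
        score = 0.0
        for aa, weights in zip(window, self.position_weights):
            score += weights.get(aa, 0.0)
        if self.size_pattern is not None:
            for aa, cls in zip(window, self.size_pattern):
                if (cls == "S" and aa in SMALL_RESIDUES) or (
                    cls == "L" and aa in LARGE_RESIDUES
                ):
                    score += self.size_weight
        return score

    def consensus_string(self) -> str:
        """A maximal-scoring unit string (ties broken alphabetically)."""
        out = []
        for i, weights in enumerate(self.position_weights):
            if weights:
                best = max(sorted(weights), key=lambda a: weights[a])
            elif self.size_pattern is not None and self.size_pattern[i] == "S":
                best = "A"
            elif self.size_pattern is not None and self.size_pattern[i] == "L":
                best = "L"
            else:
                best = "A"
            out.append(best)
        return "".join(out)


@dataclasses.dataclass(frozen=True)
class RepeatHit:
    protein: str
    repeat_name: str
    unit_index: int
    start: int
    end: int
    score: float


def profile_from_consensus(
    name: str,
    consensus: str,
    size_pattern: str | None = None,
    unscored: str = "x",
) -> RepeatProfile:
    """Build a profile from a consensus row.

    Lowercase / ``unscored`` positions carry no residue weight (they may
    still contribute through ``size_pattern``).
    """
    weights: list[dict[str, float]] = []
    for aa in consensus:
        if aa == unscored or aa.islower():
            weights.append({})
            continue
        w = {aa: 1.0}
        for sim in _SIMILAR.get(aa, ""):
            w[sim] = 0.5
        weights.append(w)
    return RepeatProfile(
        repeat_name=name,
        unit_length=len(consensus),
        position_weights=tuple(weights),
        size_pattern=tuple(size_pattern) if size_pattern is not None else None,
    )


# Canonical 33-residue ankyrin unit (idealised consensus; 'x' = variable).
ANK_CONSENSUS = "DxxGxTPLHLAAxxGHLEIVxVLLKxGADVNAx"
# Canonical 34-residue TPR unit with its small/large signature.
TPR_CONSENSUS = "AEAWYNLGNAYYKQGDYDEAIEYYQKALELDPRS"
TPR_SIZE_PATTERN = "...L..LS..L........S...L..S......."


def ank_profile() -> RepeatProfile:
    return profile_from_consensus("ANK", ANK_CONSENSUS)


def tpr_profile() -> RepeatProfile:
    return profile_from_consensus("TPR", TPR_CONSENSUS, size_pattern=TPR_SIZE_PATTERN)


def scan_repeats(
    protein: ProteinRecord,
    profile: RepeatProfile,
    threshold: float | None = None,
    loop_slack: int = 0,
) -> list[RepeatHit]:
    """Greedy left-to-right selection of non-overlapping repeat units.

    The first qualifying window is locally refined: while a strictly
    higher-scoring window starts inside the current candidate's span the
    candidate moves there (leftmost on ties), so no accepted unit hides a
    better unit strictly inside its own span.  ``loop_slack`` is accepted for
    interface compatibility; unit placements are fixed-length and inter-unit
    loops are skipped naturally by the scan.
    """
    if threshold is None:
        threshold = 0.5 * profile.max_score
    if not (0 <= threshold <= profile.max_score):
        raise RepeatConfigError(
            f"threshold {threshold} outside score range [0, {profile.max_score}]"
        )
    seq = protein.sequence
    L = profile.unit_length
    n = len(seq)
    if L > n:
        return []
    scores = [profile.score_window(seq[i : i + L]) for i in range(n - L + 1)]
    hits: list[RepeatHit] = []
    i = 0
    while i < len(scores):
        if scores[i] < threshold:
            i += 1
            continue
        j = i
        while True:
            inside = range(j + 1, min(j + L, len(scores)))
            better = None
            best = scores[j]
            for k in inside:
                if scores[k] > best:
                    best = scores[k]
                    better = k
            if better is None:
                break
            j = better
        hits.append(
            RepeatHit(
                protein=protein.accession,
                repeat_name=profile.repeat_name,
                unit_index=len(hits) + 1,
                start=j + 1,
                end=j + L,
                score=scores[j],
            )
        )
        i = j + L
    return hits


def scan_repeats_bruteforce(
    protein: ProteinRecord, profile: RepeatProfile, threshold: float | None = None
) -> list[tuple[int, float]]:
    """All qualifying window placements (start, score) — diagnostic helper."""
    if threshold is None:
        threshold = 0.5 * profile.max_score
    seq = protein.sequence
    L = profile.unit_length
    return [
        (i + 1, profile.score_window(seq[i : i + L]))
        for i in range(len(seq) - L + 1)
        if profile.score_window(seq[i : i + L]) >= threshold
    ]
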