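"""Missense variant parsing, region mapping and predictor-vote aggregation.

Only three-letter HGVS-p missense labels (``p.Arg760Cys``) are supported;
synonymous, nonsense and indel descriptions are rejected.  Pathogenicity
predictors are never executed here — their calls arrive as a table and are
tallied into a simple majority consensus.
"""

from __future__ import annotations

import csv
import dataclasses
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Data.IUPACData import protein_letters_3to1

from .records import ProteinRecord, SequenceError
from .seqfeatures.bias import BiasRegion
from .seqfeatures.motifs import MotifHit
from .seqfeatures.repeats import RepeatHit

_THREE_TO_ONE = {k.capitalize(): v for k, v in protein_letters_3to1.items()}
_HGVS_P = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")

DEFAULT_MAJORITY = 0.75

VOTE_VALUES = ("damaging", "tolerated", "missing")
CONSENSUS_LABELS = ("pathogenic-leaning", "uncertain", "benign-leaning")


class HgvsParseError(ValueError):
    pass


class VoteTableError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class Variant:
    protein: str
    position: int
    ref_aa: str
    alt_aa: str
    label: str

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise HgvsParseError(f"{self.label}: not a missense change")


@dataclasses.dataclass(frozen=True)
class RegionAnnotation:
    protein: str
    name: str
    start: int
    end: int

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclasses.dataclass(frozen=True)
class VariantAnnotation:
    variant: Variant
    region: str  # containing region name, or "none"
    motifs: tuple[MotifHit, ...]
    bias_regions: tuple[BiasRegion, ...]
    repeat_units: tuple[RepeatHit, ...]
    damaging: int | None = None
    total: int | None = None
    consensus: str | None = None


def parse_hgvs_p(label: str, protein: str = "") -> Variant:
    """Decode ``p.<Aaa><pos><Bbb>`` into a one-letter missense variant."""
    m = _HGVS_P.match(label.strip())
    if m is None:
        raise HgvsParseError(
            f"{label!r}: expected a three-letter missense HGVS-p label like p.Arg760Cys"
        )
    ref3, pos, alt3 = m.groups()
    for aaa in (ref3, alt3):
        if aaa not in _THREE_TO_ONE:
            raise HgvsParseError(f"{label!r}: unknown amino-acid code {aaa!r}")
    return Variant(
        protein=protein,
        position=int(pos),
        ref_aa=_THREE_TO_ONE[ref3],
        alt_aa=_THREE_TO_ONE[alt3],
        label=label.strip(),
    )


def load_region_table(path: str | Path) -> list[RegionAnnotation]:
    """Read region annotations (columns: accession, region, start, end) and
    reject overlapping regions within one protein."""
    regions: list[RegionAnnotation] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"accession", "region", "start", "end"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise VoteTableError(f"region table {path} missing columns {required}")
        for row in reader:
            regions.append(
                RegionAnnotation(
                    protein=row["accession"],
                    name=row["region"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                )
            )
    validate_regions(regions)
    return regions


def validate_regions(regions: Sequence[RegionAnnotation]) -> None:
    by_protein: dict[str, list[RegionAnnotation]] = {}
    for r in regions:
        if r.start > r.end:
            raise VoteTableError(f"region {r.name}: start > end")
        by_protein.setdefault(r.protein, []).append(r)
    for protein, rs in by_protein.items():
        ordered = sorted(rs, key=lambda r: r.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:
                raise VoteTableError(
                    f"{protein}: regions {a.name} and {b.name} overlap"
                )


def map_variant(
    variant: Variant,
    regions: Sequence[RegionAnnotation],
    motifs: Sequence[MotifHit] = (),
    bias_regions: Sequence[BiasRegion] = (),
    repeat_units: Sequence[RepeatHit] = (),
    sequence: ProteinRecord | None = None,
) -> VariantAnnotation:
    """Locate the variant in the region map and list overlapping features."""
    if sequence is not None:
        if variant.position > len(sequence):
            raise SequenceError(
                f"{variant.label}: position beyond {sequence.accession} length"
            )
        if sequence.sequence[variant.position - 1] != variant.ref_aa:
            raise SequenceError(
                f"{variant.label}: reference residue mismatch at {variant.position}"
            )
    validate_regions(regions)
    containing = "none"
    for r in sorted(regions, key=lambda r: r.start):
        if r.protein == variant.protein and r.contains(variant.position):
            containing = r.name
            break
    pos = variant.position
    return VariantAnnotation(
        variant=variant,
        region=containing,
        motifs=tuple(m for m in motifs if m.start <= pos <= m.end),
        bias_regions=tuple(b for b in bias_regions if b.start <= pos <= b.end),
        repeat_units=tuple(u for u in repeat_units if u.start <= pos <= u.end),
    )


def aggregate_votes(
    calls: Mapping[str, str] | Iterable[tuple[str, str]],
    majority_rule: float = DEFAULT_MAJORITY,
) -> tuple[int, int, str]:
    """Tally per-tool calls into (damaging, total, consensus).

    ``missing`` calls are excluded from the total.  Consensus is
    pathogenic-leaning at or above ``majority_rule``, benign-leaning at or
    below its complement, otherwise uncertain.
    """
    items = list(calls.items()) if isinstance(calls, Mapping) else list(calls)
    if not items:
        raise VoteTableError("empty vote table")
    for tool, call in items:
        if call not in VOTE_VALUES:
            raise VoteTableError(f"tool {tool}: unknown call {call!r}")
    scored = [(t, c) for t, c in items if c != "missing"]
    if not scored:
        raise VoteTableError("no non-missing votes")
    damaging = sum(1 for _, c in scored if c == "damaging")
    total = len(scored)
    ratio = damaging / total
    if ratio >= majority_rule:
        consensus = "pathogenic-leaning"
    elif ratio <= 1 - majority_rule:
        consensus = "benign-leaning"
    else:
        consensus = "uncertain"
    return damaging, total, consensus


def load_vote_table(path: str | Path) -> dict[str, dict[str, str]]:
    """Read predictor votes (columns: variant, tool, call) keyed by variant."""
    out: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"variant", "tool", "call"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise VoteTableError(f"vote table {path} missing columns {required}")
        for row in reader:
            out.setdefault(row["variant"], {})[row["tool"]] = row["call"]
    return out
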