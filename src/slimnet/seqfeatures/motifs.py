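"""Short linear motif (SLiM) scanning.

Motif patterns are data, not code: they ship as a TSV table of ELM-style
class names with a regex in the standard Python dialect restricted to
character classes, ``.``, bounded repeats ``{m,n}``, alternation and
anchors.  The packaged table is a *reconstruction* of the published ELM
classes (the originating resource does not version-pin its regexes), so
treat it as a starting point and override with ``--patterns`` where exact
class definitions matter.
"""

from __future__ import annotations

import csv
import dataclasses
import re
from pathlib import Path
from typing import Iterable, Sequence

from ..records import ProteinRecord, SequenceError

MOTIF_KINDS = ("LIG", "DOC", "DEG", "MOD", "TRG")


class PatternError(ValueError):
    """Raised when a motif pattern is malformed (configuration error)."""


@dataclasses.dataclass(frozen=True)
class MotifPattern:
    """One ELM-style motif class: a named regex plus binder-domain metadata."""

    motif_id: str
    regex: str
    kind: str
    anchored_c_terminal: bool = False
    binder_domain_classes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        try:
            compiled = re.compile(self.regex)
        except re.error as exc:
            raise PatternError(f"motif {self.motif_id}: regex does not compile: {exc}")
        ends_anchored = self.regex.rstrip(")").endswith("$")
        if ends_anchored != self.anchored_c_terminal:
            raise PatternError(
                f"motif {self.motif_id}: anchored_c_terminal={self.anchored_c_terminal} "
                f"inconsistent with regex {self.regex!r}"
            )
        if self.kind not in MOTIF_KINDS:
            raise PatternError(f"motif {self.motif_id}: unknown kind {self.kind!r}")
        object.__setattr__(self, "_compiled", compiled)

    @property
    def compiled(self) -> re.Pattern:
        return self._compiled  # type: ignore[attr-defined]


@dataclasses.dataclass(frozen=True)
class MotifHit:
    """A single regex match on a protein, 1-based inclusive coordinates."""

    protein: str
    motif_id: str
    start: int
    end: int
    matched: str


def scan_motifs(
    protein: ProteinRecord, patterns: Sequence[MotifPattern]
) -> list[MotifHit]:
    """Report every match of every pattern on ``protein``.

    All distinct start positions are reported, so overlapping matches of the
    same pattern and of different patterns co-exist; downstream validation is
    responsible for filtering.  Order is deterministic: by start, then
    motif_id.
    """
    seq = protein.sequence
    if not seq:
        raise SequenceError(f"{protein.accession}: empty sequence")
    hits: list[MotifHit] = []
    for pat in patterns:
        rx = pat.compiled
        for i in range(len(seq)):
            m = rx.match(seq, i)
            if m is None or m.end() == m.start():
                continue
            hits.append(
                MotifHit(
                    protein=protein.accession,
                    motif_id=pat.motif_id,
                    start=m.start() + 1,
                    end=m.end(),
                    matched=m.group(0),
                )
            )
    hits.sort(key=lambda h: (h.start, h.motif_id, h.end))
    return hits


def load_pattern_table(path: str | Path) -> list[MotifPattern]:
    """Read the motif-pattern TSV.

    Columns: motif_id, regex, kind, anchored (0/1), binder_domain_classes
    (semicolon separated, may be empty).
    """
    patterns: list[MotifPattern] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"motif_id", "regex", "kind", "anchored", "binder_domain_classes"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise PatternError(f"pattern table {path} missing columns {required}")
        for lineno, row in enumerate(reader, start=2):
            binders = tuple(
                b.strip() for b in row["binder_domain_classes"].split(";") if b.strip()
            )
            try:
                patterns.append(
                    MotifPattern(
                        motif_id=row["motif_id"],
                        regex=row["regex"],
                        kind=row["kind"],
                        anchored_c_terminal=row["anchored"].strip() in ("1", "true", "True"),
                        binder_domain_classes=binders,
                    )
                )
            except PatternError as exc:
                raise PatternError(f"{path}:{lineno}: {exc}") from exc
    seen: set[str] = set()
    for pat in patterns:
        if pat.motif_id in seen:
            raise PatternError(f"duplicate motif_id {pat.motif_id} in {path}")
        seen.add(pat.motif_id)
    return patterns


def write_hits_tsv(hits: Iterable[MotifHit], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["protein", "motif_id", "start", "end", "matched"])
        for h in hits:
            writer.writerow([h.protein, h.motif_id, h.start, h.end, h.matched])
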