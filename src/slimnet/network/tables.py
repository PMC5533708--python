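"""Curated interaction and motif-placement tables.

The packaged fixtures transcribe a published manual curation: an
interaction table (one row per interactor of the two paralog members,
``T1``/``T2``/``both``), a motif-placement table (which motif or domain is
predicted to mediate each interaction, and on which member), a per-member
accepted-site table, and a YAML compatibility map pairing binder domain
classes with the motif classes they recognise.
"""

from __future__ import annotations

import csv
import dataclasses
import re
from pathlib import Path
from typing import Iterable, Mapping

import yaml

MEMBERS = ("T1", "T2")
MEMBER_TOKENS = {"T1": ("T1",), "T2": ("T2",), "both": MEMBERS}
UNKNOWN_REGION = "unknown"
SLIM = "slim"
DOMAIN = "domain"


class TableError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class Interactor:
    name: str
    tanc_member: str  # "T1", "T2" or "both"
    evidence_method: str
    known_binding_region: tuple[str, ...]  # empty = unknown
    domain_architecture: tuple[str, ...]
    pathway: str

    @property
    def members(self) -> tuple[str, ...]:
        return MEMBER_TOKENS[self.tanc_member]

    @property
    def evidence_class(self) -> str:
        # high-throughput evidence is flagged by an HTS-prefixed method
        return "HTP" if self.evidence_method.startswith("HTS") else "LTP"

    @property
    def has_experimental_region(self) -> bool:
        return bool(self.known_binding_region)


def _split(field: str) -> tuple[str, ...]:
    return tuple(part.strip() for part in field.split(";") if part.strip())


def load_interaction_table(path: str | Path) -> list[Interactor]:
    """Read and validate the curated interaction TSV.

    Columns: name, member, method, binding_region, domain_architecture,
    pathway.  Rows with unknown member tokens or duplicate (name, member)
    pairs are rejected with row-numbered messages.
    """
    interactors: list[Interactor] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {
            "name", "member", "method", "binding_region", "domain_architecture", "pathway",
        }
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise TableError(f"interaction table {path} missing columns {required}")
        for lineno, row in enumerate(reader, start=2):
            member = row["member"].strip()
            if member not in MEMBER_TOKENS:
                raise TableError(f"{path}:{lineno}: unknown member token {member!r}")
            name = row["name"].strip()
            if not name:
                raise TableError(f"{path}:{lineno}: empty interactor name")
            if name in {n for n, _ in seen}:
                raise TableError(f"{path}:{lineno}: duplicate row for {name!r}")
            seen.add((name, member))
            region = row["binding_region"].strip()
            interactors.append(
                Interactor(
                    name=name,
                    tanc_member=member,
                    evidence_method=row["method"].strip(),
                    known_binding_region=() if region in ("", UNKNOWN_REGION) else _split(region),
                    domain_architecture=_split(row["domain_architecture"]),
                    pathway=row["pathway"].strip(),
                )
            )
    return interactors


@dataclasses.dataclass(frozen=True)
class MotifPlacement:
    """One transcribed prediction row: sites predicted to mediate binding of
    ``interactor`` on ``member`` ('both' rows describe novel interactor
    classes proposed for both members)."""

    member: str
    interactor: str
    sites: tuple[str, ...]
    site_kind: str  # "slim" or "domain"


def load_placement_table(path: str | Path) -> list[MotifPlacement]:
    out: list[MotifPlacement] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"member", "interactor", "sites", "site_kind"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise TableError(f"placement table {path} missing columns {required}")
        for lineno, row in enumerate(reader, start=2):
            member = row["member"].strip()
            if member not in MEMBER_TOKENS:
                raise TableError(f"{path}:{lineno}: unknown member token {member!r}")
            kind = row["site_kind"].strip()
            if kind not in (SLIM, DOMAIN):
                raise TableError(f"{path}:{lineno}: unknown site kind {kind!r}")
            out.append(
                MotifPlacement(
                    member=member,
                    interactor=row["interactor"].strip(),
                    sites=_split(row["sites"]),
                    site_kind=kind,
                )
            )
    return out


@dataclasses.dataclass(frozen=True)
class SiteInventory:
    """Accepted motifs and present domains per member."""

    motifs: Mapping[str, frozenset[str]]
    domains: Mapping[str, frozenset[str]]

    def motif_accepted(self, member: str, motif_id: str) -> bool:
        return motif_id in self.motifs.get(member, frozenset())

    def domain_present(self, member: str, domain: str) -> bool:
        return domain in self.domains.get(member, frozenset())


def load_acceptance_table(path: str | Path) -> SiteInventory:
    """Read the per-member accepted-site TSV (member, site, site_kind)."""
    motifs: dict[str, set[str]] = {m: set() for m in MEMBERS}
    domains: dict[str, set[str]] = {m: set() for m in MEMBERS}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"member", "site", "site_kind"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise TableError(f"acceptance table {path} missing columns {required}")
        for lineno, row in enumerate(reader, start=2):
            member = row["member"].strip()
            if member not in MEMBER_TOKENS:
                raise TableError(f"{path}:{lineno}: unknown member token {member!r}")
            target = motifs if row["site_kind"].strip() == SLIM else domains
            for m in MEMBER_TOKENS[member]:
                target[m].add(row["site"].strip())
    return SiteInventory(
        motifs={m: frozenset(v) for m, v in motifs.items()},
        domains={m: frozenset(v) for m, v in domains.items()},
    )


def inventory_from_validated(
    validated_per_member: Mapping[str, Iterable],
    domains_per_member: Mapping[str, Iterable[str]],
) -> SiteInventory:
    """Build a :class:`SiteInventory` from ValidatedMotif lists (recompute
    mode) instead of the transcribed fixture."""
    motifs = {
        m: frozenset(v.hit.motif_id for v in vs if v.accepted)
        for m, vs in validated_per_member.items()
    }
    return SiteInventory(
        motifs=motifs,
        domains={m: frozenset(ds) for m, ds in domains_per_member.items()},
    )


_LEADING_COUNT = re.compile(r"^\d+\s+")


def _normalise_domain(item: str) -> str:
    return _LEADING_COUNT.sub("", item.strip()).lower()


@dataclasses.dataclass(frozen=True)
class CompatibilityMap:
    """Binder domain class -> motif classes it recognises."""

    pairs: Mapping[str, tuple[str, ...]]

    def motifs_for_architecture(self, architecture: Iterable[str]) -> frozenset[str]:
        normalised = {_normalise_domain(item) for item in architecture}
        hits: set[str] = set()
        for domain_class, motif_ids in self.pairs.items():
            if _normalise_domain(domain_class) in normalised:
                hits.update(motif_ids)
        return frozenset(hits)

    def compatible(self, architecture: Iterable[str], motif_id: str) -> bool:
        return motif_id in self.motifs_for_architecture(architecture)


def load_compatibility(path: str | Path) -> CompatibilityMap:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise TableError(f"compatibility map {path} must be a mapping")
    return CompatibilityMap(
        pairs={str(k): tuple(v) for k, v in raw.items()}
    )
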