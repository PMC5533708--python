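"""Binding-site assignment, paralog-transfer inference and network summary.

Two operating modes share one rule set:

* *placement mode* — predictions transcribed from the published curation
  are validated against the compatibility map and the accepted-site
  inventory and turned into assignments/edges (``--use-placement-table``);
* *rule mode* — assignments and edges are derived from the tables alone
  (used on synthetic data, ``--recompute-motifs``).

The transfer rule: an interactor curated to exactly one member whose
(known or predicted) site is available on the other member — an accepted
motif (``shared_slim``) or a present globular domain (``shared_domain``,
flagged lower confidence) — is inferred to bind that other member too.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

from .tables import (
    DOMAIN,
    MEMBERS,
    CompatibilityMap,
    Interactor,
    MotifPlacement,
    SiteInventory,
    SLIM,
)

EXPERIMENTAL = "experimental"
COMPATIBILITY_PREDICTED = "compatibility_predicted"


@dataclasses.dataclass(frozen=True)
class BindingSiteAssignment:
    interactor: str
    member: str
    site: str
    site_kind: str  # slim | domain
    rationale: str  # experimental | compatibility_predicted


@dataclasses.dataclass(frozen=True)
class InferredEdge:
    interactor: str
    from_member: str
    to_member: str
    basis: str  # shared_slim | shared_domain
    sites: tuple[str, ...]
    low_confidence: bool

    def __post_init__(self) -> None:
        if self.from_member == self.to_member:
            raise ValueError("inferred edge must cross members")


def _other(member: str) -> str:
    return MEMBERS[1] if member == MEMBERS[0] else MEMBERS[0]


def _site_kind(site: str, inventory: SiteInventory) -> str:
    all_domains = set().union(*inventory.domains.values()) if inventory.domains else set()
    return DOMAIN if site in all_domains else SLIM


def assign_binding_sites(
    interactors: Sequence[Interactor],
    inventory: SiteInventory,
    compatibility: CompatibilityMap,
    placements: Sequence[MotifPlacement] | None = None,
) -> list[BindingSiteAssignment]:
    """Experimental assignments plus compatibility-predicted ones.

    Experimental sites are copied from the curated binding region, on every
    member the interactor is known to bind.  Predicted assignments are
    emitted only for interactors whose curated region is unknown, on the
    member(s) they are known to bind, when the interactor's architecture is
    compatible with the motif, the motif is accepted on that member, and the
    motif is not already experimentally occupied on that member (a
    single-site interaction already explained by a curated binder is not
    re-assigned).  In placement mode the transcribed rows propose the
    candidate (interactor, member, motif) triples; in rule mode every
    compatible pair is considered.
    """
    by_name = {i.name: i for i in interactors}
    assignments: list[BindingSiteAssignment] = []
    experimental_occupancy: set[tuple[str, str]] = set()  # (member, site)
    for interactor in interactors:
        for site in interactor.known_binding_region:
            for member in interactor.members:
                assignments.append(
                    BindingSiteAssignment(
                        interactor=interactor.name,
                        member=member,
                        site=site,
                        site_kind=_site_kind(site, inventory),
                        rationale=EXPERIMENTAL,
                    )
                )
                experimental_occupancy.add((member, site))

    def predict(interactor: Interactor, member: str, motif_id: str) -> None:
        if interactor.has_experimental_region:
            return
        if member not in interactor.members:
            return
        if not inventory.motif_accepted(member, motif_id):
            return
        if not compatibility.compatible(interactor.domain_architecture, motif_id):
            return
        if (member, motif_id) in experimental_occupancy:
            return
        assignments.append(
            BindingSiteAssignment(
                interactor=interactor.name,
                member=member,
                site=motif_id,
                site_kind=SLIM,
                rationale=COMPATIBILITY_PREDICTED,
            )
        )

    if placements is not None:
        for row in placements:
            interactor = by_name.get(row.interactor)
            if interactor is None or row.site_kind != SLIM:
                continue
            for member in (row.member,) if row.member in MEMBERS else MEMBERS:
                for site in row.sites:
                    predict(interactor, member, site)
    else:
        for interactor in interactors:
            candidates = compatibility.motifs_for_architecture(
                interactor.domain_architecture
            )
            for member in interactor.members:
                for motif_id in sorted(candidates):
                    predict(interactor, member, motif_id)

    unique = sorted(set(assignments), key=lambda a: (a.interactor, a.member, a.site, a.rationale))
    return unique


def infer_paralog_edges(
    interactors: Sequence[Interactor],
    assignments: Sequence[BindingSiteAssignment],
    inventory: SiteInventory,
    compatibility: CompatibilityMap | None = None,
    placements: Sequence[MotifPlacement] | None = None,
) -> list[InferredEdge]:
    """Infer cross-paralog edges for single-member interactors.

    Besides the assignment-driven rule, placement mode also honours
    transcribed transfer rows for interactors without any assignment on
    their curated member (a motif accepted on the *other* member that is
    compatible with the interactor's architecture supports the transfer on
    its own).  Known edges are never duplicated and the operation is
    idempotent.
    """
    by_name = {i.name: i for i in interactors}
    proposals: dict[tuple[str, str, str], set[str]] = {}

    def propose(interactor: Interactor, to_member: str, site: str, kind: str) -> None:
        if len(interactor.members) != 1 or to_member in interactor.members:
            return
        if kind == SLIM:
            if not inventory.motif_accepted(to_member, site):
                return
            if compatibility is not None and not compatibility.compatible(
                interactor.domain_architecture, site
            ):
                return
            basis = "shared_slim"
        else:
            if not inventory.domain_present(to_member, site):
                return
            basis = "shared_domain"
        proposals.setdefault((interactor.name, to_member, basis), set()).add(site)

    for a in assignments:
        interactor = by_name.get(a.interactor)
        if interactor is None or len(interactor.members) != 1:
            continue
        propose(interactor, _other(a.member), a.site, a.site_kind)

    if placements is not None:
        for row in placements:
            interactor = by_name.get(row.interactor)
            if interactor is None or row.member not in MEMBERS:
                continue
            if row.member in interactor.members:
                continue
            for site in row.sites:
                propose(interactor, row.member, site, row.site_kind)

    edges = [
        InferredEdge(
            interactor=name,
            from_member=by_name[name].members[0],
            to_member=to_member,
            basis=basis,
            sites=tuple(sorted(sites)),
            low_confidence=(basis == "shared_domain"),
        )
        for (name, to_member, basis), sites in proposals.items()
    ]
    edges.sort(key=lambda e: (e.to_member, e.basis, e.interactor))
    return edges


def find_mutually_exclusive(
    assignments: Sequence[BindingSiteAssignment],
    single_copy_sites: Iterable[str],
) -> list[tuple[str, frozenset[str]]]:
    """Group interactors competing for the same single-copy site.

    ``single_copy_sites`` names the motifs that occur once per protein
    (e.g. C-terminally anchored motifs); interactors assigned to such a
    site — on either member — cannot bind simultaneously.  Groups of size
    >= 2 are reported as (site, names).
    """
    single = set(single_copy_sites)
    groups: dict[str, set[str]] = {}
    for a in assignments:
        if a.site in single:
            groups.setdefault(a.site, set()).add(a.interactor)
    return sorted(
        (site, frozenset(names)) for site, names in groups.items() if len(names) >= 2
    )


@dataclasses.dataclass(frozen=True)
class NetworkReport:
    known_interactors: dict[str, int]
    experimental_region: dict[str, int]
    predicted_site: dict[str, int]
    inferred_edges: dict[str, dict[str, int]]  # basis -> to_member -> count
    mutually_exclusive: tuple[tuple[str, frozenset[str]], ...]

    def as_dict(self) -> dict:
        return {
            "known_interactors": dict(self.known_interactors),
            "experimental_region": dict(self.experimental_region),
            "predicted_site": dict(self.predicted_site),
            "inferred_edges": {b: dict(v) for b, v in self.inferred_edges.items()},
            "mutually_exclusive": [
                {"site": site, "interactors": sorted(names)}
                for site, names in self.mutually_exclusive
            ],
        }


def summarize(
    interactors: Sequence[Interactor],
    assignments: Sequence[BindingSiteAssignment],
    inferred: Sequence[InferredEdge],
    mutually_exclusive: Sequence[tuple[str, frozenset[str]]] = (),
) -> NetworkReport:
    """All printed-count style tallies, recomputable from the raw lists.

    Interactors bound to both members count once per member.
    """
    known = {m: sum(1 for i in interactors if m in i.members) for m in MEMBERS}
    experimental = {
        m: len(
            {
                a.interactor
                for a in assignments
                if a.member == m and a.rationale == EXPERIMENTAL
            }
        )
        for m in MEMBERS
    }
    predicted = {
        m: len(
            {
                a.interactor
                for a in assignments
                if a.member == m and a.rationale == COMPATIBILITY_PREDICTED
            }
        )
        for m in MEMBERS
    }
    inferred_counts: dict[str, dict[str, int]] = {
        basis: {m: 0 for m in MEMBERS} for basis in ("shared_slim", "shared_domain")
    }
    for e in inferred:
        inferred_counts[e.basis][e.to_member] += 1
    return NetworkReport(
        known_interactors=known,
        experimental_region=experimental,
        predicted_site=predicted,
        inferred_edges=inferred_counts,
        mutually_exclusive=tuple(mutually_exclusive),
    )
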