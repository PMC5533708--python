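"""Deterministic synthetic data with a machine-readable truth manifest.

Every generated object draws from its own pseudo-random stream keyed by
``(seed, object id)``, so adding an object to a scenario never perturbs the
others.  The generator emulates the statistical structure the validation
gate assumes — conserved motifs planted inside disordered blocks, ordered
decoys, tandem repeat arrays, ortholog families with per-site noise and
per-motif retention — and records exact coordinates and outcomes in a
JSON-serialisable manifest.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from typing import Mapping, Sequence

import numpy as np

from .conservation import OrthologAlignment
from .network.tables import (
    DOMAIN,
    MEMBERS,
    Interactor,
    SLIM,
    SiteInventory,
)
from .records import ProteinRecord

ORDERED = "ordered"
DISORDERED = "disordered"

# background compositions; disorder-promoting residues dominate IDR blocks
_ORDERED_POOL = "ILVFMWYACGTND"
_ORDERED_WEIGHTS = np.array([4, 4, 3, 4, 2, 2, 2, 1, 1, 1, 1, 1, 1], dtype=float)
_DISORDERED_POOL = "PSEKQGRDTANH"
_DISORDERED_WEIGHTS = np.array([3, 3, 3, 3, 3, 2, 2, 2, 1, 1, 1, 1], dtype=float)

_ALL_AA = "ACDEFGHIKLMNPQRSTVWY"


class GeneratorError(ValueError):
    pass


def rng_for(seed: int, object_id: str) -> np.random.Generator:
    """One documented stream per generated object: keyed by (seed, crc32(id))."""
    return np.random.default_rng([seed, zlib.crc32(object_id.encode())])


@dataclasses.dataclass(frozen=True)
class PlantedMotif:
    motif_id: str
    start: int  # 1-based
    instance: str
    retention: float = 1.0

    @property
    def end(self) -> int:
        return self.start + len(self.instance) - 1


@dataclasses.dataclass(frozen=True)
class PlantedRepeat:
    consensus: str
    copies: int
    start: int

    @property
    def end(self) -> int:
        return self.start + self.copies * len(self.consensus) - 1


@dataclasses.dataclass(frozen=True)
class PlantedBias:
    residue: str
    start: int
    end: int
    density: float = 1.0


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    seed: int
    accession: str
    length: int
    blocks: tuple[tuple[int, int, str], ...]  # (start, end, ordered|disordered)
    motifs: tuple[PlantedMotif, ...] = ()
    repeats: tuple[PlantedRepeat, ...] = ()
    bias_regions: tuple[PlantedBias, ...] = ()

    def __post_init__(self) -> None:
        spans = []
        pos = 1
        for start, end, kind in self.blocks:
            if kind not in (ORDERED, DISORDERED):
                raise GeneratorError(f"unknown block kind {kind!r}")
            if start != pos or end < start:
                raise GeneratorError("blocks must tile the sequence without gaps")
            pos = end + 1
        if self.blocks and pos != self.length + 1:
            raise GeneratorError("blocks do not cover the full length")
        for m in self.motifs:
            spans.append((m.start, m.end, f"motif {m.motif_id}"))
        for r in self.repeats:
            spans.append((r.start, r.end, "repeat array"))
        for b in self.bias_regions:
            spans.append((b.start, b.end, f"bias poly{b.residue}"))
        spans.sort()
        for (s1, e1, w1), (s2, e2, w2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise GeneratorError(f"planted elements overlap: {w1} and {w2}")
        for s, e, what in spans:
            if not (1 <= s <= e <= self.length):
                raise GeneratorError(f"{what} outside sequence 1-{self.length}")

    def block_kind(self, position: int) -> str:
        for start, end, kind in self.blocks:
            if start <= position <= end:
                return kind
        return DISORDERED


def generate_protein(config: GeneratorConfig) -> tuple[ProteinRecord, dict]:
    """Background sequence per block composition with elements planted verbatim."""
    rng = rng_for(config.seed, f"protein:{config.accession}")
    letters = []
    for pos in range(1, config.length + 1):
        if config.block_kind(pos) == ORDERED:
            pool, weights = _ORDERED_POOL, _ORDERED_WEIGHTS
        else:
            pool, weights = _DISORDERED_POOL, _DISORDERED_WEIGHTS
        letters.append(pool[rng.choice(len(pool), p=weights / weights.sum())])
    for r in config.repeats:
        unit = r.consensus
        for c in range(r.copies):
            offset = r.start - 1 + c * len(unit)
            letters[offset : offset + len(unit)] = list(unit)
    for b in config.bias_regions:
        sub_rng = rng_for(config.seed, f"bias:{config.accession}:{b.start}")
        for i in range(b.start - 1, b.end):
            if sub_rng.random() < b.density:
                letters[i] = b.residue
    for m in config.motifs:
        letters[m.start - 1 : m.end] = list(m.instance)
    record = ProteinRecord(
        accession=config.accession, name=config.accession, sequence="".join(letters)
    )
    manifest = {
        "accession": config.accession,
        "length": config.length,
        "blocks": [list(b) for b in config.blocks],
        "motifs": [
            {
                "motif_id": m.motif_id,
                "start": m.start,
                "end": m.end,
                "instance": m.instance,
                "retention": m.retention,
                "block": config.block_kind(m.start),
            }
            for m in config.motifs
        ],
        "repeats": [
            {"consensus": r.consensus, "copies": r.copies, "start": r.start, "end": r.end}
            for r in config.repeats
        ],
        "bias_regions": [
            {"residue": b.residue, "start": b.start, "end": b.end, "density": b.density}
            for b in config.bias_regions
        ],
    }
    return record, manifest


def generate_ortholog_family(
    reference: ProteinRecord,
    config: GeneratorConfig,
    family_size: int = 10,
    substitution_rate: float = 0.05,
    indel_rate: float = 0.0,
    family_id: str | None = None,
) -> tuple[OrthologAlignment, dict]:
    """Derive orthologs by per-site noise outside planted motifs.

    Each planted motif is kept intact with its ``retention`` probability and
    otherwise ablated by randomising its window (geometry preserved, so the
    emitted alignment needs no motif-local gaps).  Deletions become gap
    columns in the affected row; insertions add columns gapped in all other
    rows.  The manifest records the per-ortholog retention outcome.
    """
    if not (0 <= substitution_rate < 1 and 0 <= indel_rate < 1):
        raise GeneratorError("substitution and indel rates must be in [0, 1)")
    family_id = family_id or f"{reference.accession}_family"
    length = len(reference)
    motif_mask = np.zeros(length, dtype=bool)
    for m in config.motifs:
        motif_mask[m.start - 1 : m.end] = True

    base_rows: list[tuple[str, list[str]]] = [(reference.accession, list(reference.sequence))]
    insertions: dict[tuple[str, int], str] = {}
    outcomes: dict[str, dict[str, bool]] = {}
    for k in range(family_size):
        acc = f"{reference.accession}_ort{k + 1}"
        rng = rng_for(config.seed, f"ortholog:{family_id}:{k}")
        row = list(reference.sequence)
        for i in range(length):
            if motif_mask[i]:
                continue
            roll = rng.random()
            if roll < substitution_rate:
                row[i] = _ALL_AA[rng.integers(len(_ALL_AA))]
            elif roll < substitution_rate + indel_rate:
                if rng.random() < 0.5:
                    row[i] = "-"
                else:
                    ins_len = int(rng.integers(1, 4))
                    insertions[(acc, i)] = "".join(
                        _ALL_AA[rng.integers(len(_ALL_AA))] for _ in range(ins_len)
                    )
        outcomes[acc] = {}
        for m in config.motifs:
            retained = bool(rng.random() < m.retention)
            outcomes[acc][f"{m.motif_id}@{m.start}"] = retained
            if not retained:
                for i in range(m.start - 1, m.end):
                    row[i] = _ALL_AA[rng.integers(len(_ALL_AA))]
        base_rows.append((acc, row))

    insert_points: dict[int, int] = {}
    for (_, i), ins in insertions.items():
        insert_points[i] = max(insert_points.get(i, 0), len(ins))
    aligned_rows: list[tuple[str, str]] = []
    for acc, row in base_rows:
        out = []
        for i, c in enumerate(row):
            out.append(c)
            if i in insert_points:
                ins = insertions.get((acc, i), "")
                out.append(ins + "-" * (insert_points[i] - len(ins)))
        aligned_rows.append((acc, "".join(out)))

    msa = OrthologAlignment(
        family_id=family_id,
        rows=tuple(aligned_rows),
        reference_row=reference.accession,
    )
    manifest = {
        "family_id": family_id,
        "family_size": family_size,
        "substitution_rate": substitution_rate,
        "indel_rate": indel_rate,
        "retention_outcomes": outcomes,
        "expected_support": {
            f"{m.motif_id}@{m.start}": (
                sum(outcomes[acc][f"{m.motif_id}@{m.start}"] for acc in outcomes)
                / family_size
                if family_size
                else 0.0
            )
            for m in config.motifs
        },
    }
    return msa, manifest


@dataclasses.dataclass(frozen=True)
class InteractionPlan:
    name: str
    member: str  # "T1", "T2" or "both"
    site: str
    site_kind: str = SLIM
    experimental: bool = True


def generate_interaction_table(
    plans: Sequence[InteractionPlan],
    inventory: SiteInventory,
    binder_class_for_motif: Mapping[str, str] | None = None,
) -> tuple[list[Interactor], dict]:
    """Interaction rows plus the expected inferred-edge set.

    An interactor is transferable iff it is curated to a single member and
    its site is available on the other member (accepted motif or present
    domain).  ``binder_class_for_motif`` supplies the architecture entry that
    makes rule-mode compatibility succeed for motif sites.
    """
    interactors: list[Interactor] = []
    expected_edges: list[dict] = []
    occupancy = {
        (member, plan.site)
        for plan in plans
        if plan.experimental
        for member in (MEMBERS if plan.member == "both" else (plan.member,))
    }
    for plan in plans:
        if plan.member not in ("both", *MEMBERS):
            raise GeneratorError(f"unknown member {plan.member!r}")
        if plan.site_kind == SLIM and binder_class_for_motif is not None:
            architecture = (binder_class_for_motif.get(plan.site, plan.site + "_binder"),)
        else:
            architecture = (plan.site + "_binder",)
        interactors.append(
            Interactor(
                name=plan.name,
                tanc_member=plan.member,
                evidence_method="Co-IP" if plan.experimental else "HTS synthetic",
                known_binding_region=(plan.site,) if plan.experimental else (),
                domain_architecture=architecture,
                pathway="synthetic",
            )
        )
        if plan.member in MEMBERS:
            other = MEMBERS[1] if plan.member == MEMBERS[0] else MEMBERS[0]
            # does the interactor get a site on its own member under the rules?
            if plan.experimental:
                has_site = True
            elif plan.site_kind == SLIM:
                has_site = (
                    inventory.motif_accepted(plan.member, plan.site)
                    and (plan.member, plan.site) not in occupancy
                )
            else:
                has_site = False  # domain sites are never compatibility-predicted
            if plan.site_kind == SLIM:
                available = inventory.motif_accepted(other, plan.site)
                basis = "shared_slim"
            else:
                available = inventory.domain_present(other, plan.site)
                basis = "shared_domain"
            if has_site and available:
                expected_edges.append(
                    {
                        "interactor": plan.name,
                        "from_member": plan.member,
                        "to_member": other,
                        "basis": basis,
                    }
                )
    manifest = {"expected_edges": expected_edges}
    return interactors, manifest


def manifest_roundtrip(manifest: dict) -> dict:
    """JSON round-trip helper (the manifest contract requires it)."""
    return json.loads(json.dumps(manifest))


# default planted instances matching the packaged pattern table
DEFAULT_INSTANCES = {
    "DOC_PP1_RVXF_1": "KSVTF",
    "LIG_14-3-3_2": "RSYSVP",
    "DEG_SCF_TRCP1_1": "DSGYES",
    "MOD_LATS_1": "HARVVS",
}


@dataclasses.dataclass(frozen=True)
class ParalogScenario:
    """A two-member scenario exercising the full pipeline offline."""

    seed: int
    records: dict[str, ProteinRecord]
    configs: dict[str, GeneratorConfig]
    manifests: dict[str, dict]
    families: dict[str, OrthologAlignment]
    family_manifests: dict[str, dict]
    plans: tuple[InteractionPlan, ...]


def default_paralog_scenario(
    seed: int,
    family_size: int = 12,
    substitution_rate: float = 0.05,
    retention: float = 1.0,
) -> ParalogScenario:
    """Two paralogs with shared and private motifs in disordered blocks plus
    ordered-block decoys, each with an ortholog family and an interaction
    plan containing transferable and non-transferable entries."""
    blocks = ((1, 100, DISORDERED), (101, 220, ORDERED), (221, 320, DISORDERED))
    shared = (
        PlantedMotif("DOC_PP1_RVXF_1", 20, DEFAULT_INSTANCES["DOC_PP1_RVXF_1"], retention),
        PlantedMotif("LIG_14-3-3_2", 60, DEFAULT_INSTANCES["LIG_14-3-3_2"], retention),
    )
    decoy = PlantedMotif("DEG_SCF_TRCP1_1", 150, DEFAULT_INSTANCES["DEG_SCF_TRCP1_1"], retention)
    private = {
        "T1": PlantedMotif("DEG_SCF_TRCP1_1", 250, DEFAULT_INSTANCES["DEG_SCF_TRCP1_1"], retention),
        "T2": PlantedMotif("MOD_LATS_1", 250, DEFAULT_INSTANCES["MOD_LATS_1"], retention),
    }
    records, configs, manifests, families, family_manifests = {}, {}, {}, {}, {}
    for member in MEMBERS:
        config = GeneratorConfig(
            seed=seed,
            accession=f"SYN_{member}",
            length=320,
            blocks=blocks,
            motifs=(*shared, decoy, private[member]),
        )
        record, manifest = generate_protein(config)
        msa, family_manifest = generate_ortholog_family(
            record, config, family_size=family_size, substitution_rate=substitution_rate
        )
        records[member] = record
        configs[member] = config
        manifests[member] = manifest
        families[member] = msa
        family_manifests[member] = family_manifest
    plans = (
        InteractionPlan("EXP_SHARED", "T1", "DOC_PP1_RVXF_1", SLIM, True),
        InteractionPlan("PRED_SHARED", "T2", "LIG_14-3-3_2", SLIM, False),
        InteractionPlan("PRIVATE_T2", "T1", "MOD_LATS_1", SLIM, False),
        InteractionPlan("BOTH_MEMBER", "both", "DOC_PP1_RVXF_1", SLIM, True),
        InteractionPlan("DOMAIN_ONLY", "T1", "SYNDOM", DOMAIN, True),
    )
    return ParalogScenario(
        seed=seed,
        records=records,
        configs=configs,
        manifests=manifests,
        families=families,
        family_manifests=family_manifests,
        plans=plans,
    )
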