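"""Accessors for the packaged data fixtures.

The motif-pattern table is a documented reconstruction of the published
ELM-style classes; the interaction, placement and acceptance tables
transcribe the curated tables of the source analysis; the region table for
the second paralog reflects the narrative domain boundaries (exact
boundaries were published only in supplementary material and remain a
user-supplied input).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .network.tables import (
    CompatibilityMap,
    Interactor,
    MotifPlacement,
    SiteInventory,
    load_acceptance_table,
    load_compatibility,
    load_interaction_table,
    load_placement_table,
)
from .seqfeatures.motifs import MotifPattern, load_pattern_table
from .variants import RegionAnnotation, load_region_table


def data_path(name: str) -> Path:
    return Path(str(resources.files("slimnet.data").joinpath(name)))


def packaged_patterns() -> list[MotifPattern]:
    return load_pattern_table(data_path("motif_patterns.tsv"))


def packaged_interactions() -> list[Interactor]:
    return load_interaction_table(data_path("interactions.tsv"))


def packaged_placements() -> list[MotifPlacement]:
    return load_placement_table(data_path("motif_placements.tsv"))


def packaged_site_inventory() -> SiteInventory:
    return load_acceptance_table(data_path("site_acceptance.tsv"))


def packaged_compatibility() -> CompatibilityMap:
    return load_compatibility(data_path("compatibility.yaml"))


def packaged_tanc2_regions() -> list[RegionAnnotation]:
    return load_region_table(data_path("regions_tanc2.tsv"))


def single_copy_sites() -> list[str]:
    """Motifs occurring at most once per protein: the C-terminally anchored
    classes of the packaged pattern table."""
    return [p.motif_id for p in packaged_patterns() if p.anchored_c_terminal]
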