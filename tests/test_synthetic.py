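import json

import numpy as np
import pytest

from slimnet import datafiles
from slimnet.network import assign_binding_sites, infer_paralog_edges
from slimnet.network.tables import SiteInventory
from slimnet.seqfeatures import scan_motifs, score_disorder
from slimnet.conservation import motif_ortholog_support, score_columns
from slimnet.synthetic import (
    DEFAULT_INSTANCES,
    GeneratorConfig,
    GeneratorError,
    InteractionPlan,
    PlantedMotif,
    PlantedRepeat,
    default_paralog_scenario,
    generate_interaction_table,
    generate_ortholog_family,
    generate_protein,
    manifest_roundtrip,
)


def base_config(seed=1, motifs=(), repeats=(), length=200):
    return GeneratorConfig(
        seed=seed,
        accession="SYN",
        length=length,
        blocks=((1, 100, "disordered"), (101, length, "ordered")),
        motifs=motifs,
        repeats=repeats,
    )


class TestGenerateProtein:
    def test_same_seed_identical(self):
        config = base_config()
        rec1, man1 = generate_protein(config)
        rec2, man2 = generate_protein(config)
        assert rec1.sequence == rec2.sequence
        assert man1 == man2

    def test_different_seed_differs(self):
        rec1, _ = generate_protein(base_config(seed=1))
        rec2, _ = generate_protein(base_config(seed=2))
        assert rec1.sequence != rec2.sequence

    def test_planted_motifs_located_by_scanner(self, patterns_by_id):
        motifs = tuple(
            PlantedMotif(mid, start, DEFAULT_INSTANCES[mid])
            for mid, start in [
                ("DOC_PP1_RVXF_1", 10),
                ("LIG_14-3-3_2", 30),
                ("DEG_SCF_TRCP1_1", 50),
                ("MOD_LATS_1", 70),
                ("DOC_PP1_RVXF_1", 90),
            ]
        )
        config = base_config(motifs=motifs)
        record, manifest = generate_protein(config)
        assert len(manifest["motifs"]) == 5
        for entry in manifest["motifs"]:
            pattern = patterns_by_id[entry["motif_id"]]
            hits = scan_motifs(record, [pattern])
            assert any(h.start == entry["start"] for h in hits)

    def test_overlapping_plants_rejected(self):
        with pytest.raises(GeneratorError):
            base_config(
                motifs=(
                    PlantedMotif("A", 10, "KSVTF"),
                    PlantedMotif("B", 12, "KSVTF"),
                )
            )

    def test_motif_across_repeat_rejected(self):
        with pytest.raises(GeneratorError):
            base_config(
                motifs=(PlantedMotif("A", 110, "KSVTF"),),
                repeats=(PlantedRepeat("TPLHLAAK", 3, 101),),
            )

    def test_blocks_must_tile(self):
        with pytest.raises(GeneratorError):
            GeneratorConfig(
                seed=1, accession="SYN", length=100,
                blocks=((1, 40, "ordered"), (45, 100, "disordered")),
            )

    def test_block_compositions_differ(self):
        record, _ = generate_protein(base_config(seed=5, length=400))
        disorder = score_disorder(record)
        assert disorder.smoothed[:90].mean() > 0
        assert disorder.smoothed[110:].mean() < 0

    def test_manifest_json_roundtrip(self):
        _, manifest = generate_protein(base_config())
        assert manifest_roundtrip(manifest) == manifest


class TestGenerateFamily:
    def test_full_retention_full_support(self, patterns_by_id):
        motifs = (PlantedMotif("DOC_PP1_RVXF_1", 20, "KSVTF", retention=1.0),)
        config = base_config(motifs=motifs)
        record, _ = generate_protein(config)
        msa, manifest = generate_ortholog_family(record, config, family_size=10)
        pattern = patterns_by_id["DOC_PP1_RVXF_1"]
        hits = scan_motifs(record, [pattern])
        hit = next(h for h in hits if h.start == 20)
        assert motif_ortholog_support(hit, pattern, msa) == 1.0
        assert manifest["expected_support"]["DOC_PP1_RVXF_1@20"] == 1.0

    def test_partial_retention_binomial(self, patterns_by_id):
        # n=50, p=0.8: 4 sigma = 4*sqrt(0.8*0.2/50) ~ 0.23 (documented tolerance)
        motifs = (PlantedMotif("DOC_PP1_RVXF_1", 20, "KSVTF", retention=0.8),)
        config = base_config(seed=13, motifs=motifs)
        record, _ = generate_protein(config)
        msa, manifest = generate_ortholog_family(record, config, family_size=50)
        pattern = patterns_by_id["DOC_PP1_RVXF_1"]
        hit = next(h for h in scan_motifs(record, [pattern]) if h.start == 20)
        support = motif_ortholog_support(hit, pattern, msa, flank=0)
        assert abs(support - 0.8) <= 0.23
        # support can only exceed the manifest through chance re-creation
        assert support >= manifest["expected_support"]["DOC_PP1_RVXF_1@20"] - 1e-9

    def test_zero_substitution_perfect_conservation(self):
        config = base_config()
        record, _ = generate_protein(config)
        msa, _ = generate_ortholog_family(record, config, family_size=6, substitution_rate=0.0)
        profile = score_columns(msa)
        np.testing.assert_allclose(profile.score, 1.0)

    def test_indels_preserve_reference_roundtrip(self):
        config = base_config(seed=21)
        record, _ = generate_protein(config)
        msa, _ = generate_ortholog_family(
            record, config, family_size=6, substitution_rate=0.05, indel_rate=0.05
        )
        assert msa.reference_sequence == record.sequence
        lengths = {len(row) for _, row in msa.rows}
        assert len(lengths) == 1

    def test_deterministic_under_seed(self):
        config = base_config(seed=33)
        record, _ = generate_protein(config)
        msa1, man1 = generate_ortholog_family(record, config, family_size=5)
        msa2, man2 = generate_ortholog_family(record, config, family_size=5)
        assert msa1.rows == msa2.rows
        assert man1 == man2

    def test_bad_rates_rejected(self):
        config = base_config()
        record, _ = generate_protein(config)
        with pytest.raises(GeneratorError):
            generate_ortholog_family(record, config, substitution_rate=1.5)


class TestGenerateInteractionTable:
    def rule_oracle(self, plans, inventory):
        """Brute-force application of the transfer rule."""
        occupied = {
            (m, p.site)
            for p in plans if p.experimental
            for m in (("T1", "T2") if p.member == "both" else (p.member,))
        }
        edges = set()
        for p in plans:
            if p.member not in ("T1", "T2"):
                continue
            other = "T2" if p.member == "T1" else "T1"
            if p.experimental:
                has_site = True
            elif p.site_kind == "slim":
                has_site = (
                    inventory.motif_accepted(p.member, p.site)
                    and (p.member, p.site) not in occupied
                )
            else:
                has_site = False
            if not has_site:
                continue
            if p.site_kind == "slim" and inventory.motif_accepted(other, p.site):
                edges.add((p.name, other, "shared_slim"))
            elif p.site_kind == "domain" and inventory.domain_present(other, p.site):
                edges.add((p.name, other, "shared_domain"))
        return edges

    @pytest.fixture
    def toy_inventory(self):
        return SiteInventory(
            motifs={
                "T1": frozenset({"M_SHARED", "M_T1"}),
                "T2": frozenset({"M_SHARED"}),
            },
            domains={"T1": frozenset({"D1"}), "T2": frozenset({"D1"})},
        )

    def test_planted_transferable_count(self, toy_inventory):
        plans = [
            InteractionPlan("A", "T1", "M_SHARED", "slim", True),
            InteractionPlan("B", "T1", "M_SHARED", "slim", True),
            InteractionPlan("C", "T2", "M_SHARED", "slim", True),
            InteractionPlan("D", "T1", "M_T1", "slim", True),
            InteractionPlan("E", "T1", "D_MISSING", "domain", True),
        ]
        _, manifest = generate_interaction_table(plans, toy_inventory)
        assert len(manifest["expected_edges"]) == 3

    def test_both_member_plan_never_transfers(self, toy_inventory):
        plans = [InteractionPlan("X", "both", "M_SHARED", "slim", True)]
        _, manifest = generate_interaction_table(plans, toy_inventory)
        assert manifest["expected_edges"] == []

    def test_random_plans_match_rule_oracle(self, toy_inventory):
        rng = np.random.default_rng(29)
        sites = [("M_SHARED", "slim"), ("M_T1", "slim"), ("D1", "domain"), ("D_X", "domain")]
        for _ in range(25):
            plans = []
            for j in range(int(rng.integers(1, 10))):
                site, kind = sites[rng.integers(len(sites))]
                plans.append(
                    InteractionPlan(
                        f"I{j}",
                        ["T1", "T2", "both"][rng.integers(3)],
                        site,
                        kind,
                        bool(rng.integers(2)),
                    )
                )
            _, manifest = generate_interaction_table(plans, toy_inventory)
            got = {
                (e["interactor"], e["to_member"], e["basis"])
                for e in manifest["expected_edges"]
            }
            assert got == self.rule_oracle(plans, toy_inventory)


class TestScenarioClosedLoop:
    def test_inference_recovers_planted_edges(self, compatibility):
        scenario = default_paralog_scenario(seed=3)
        inventory = SiteInventory(
            motifs={
                member: frozenset(
                    m["motif_id"]
                    for m in scenario.manifests[member]["motifs"]
                    if m["block"] == "disordered"
                )
                for member in ("T1", "T2")
            },
            domains={"T1": frozenset({"SYNDOM"}), "T2": frozenset({"SYNDOM"})},
        )
        binder_for = {
            motif: cls for cls, motifs in compatibility.pairs.items() for motif in motifs
        }
        interactors, manifest = generate_interaction_table(
            scenario.plans, inventory, binder_for
        )
        assignments = assign_binding_sites(interactors, inventory, compatibility, None)
        inferred = infer_paralog_edges(interactors, assignments, inventory, compatibility)
        got = {(e.interactor, e.to_member, e.basis) for e in inferred}
        expected = {
            (e["interactor"], e["to_member"], e["basis"])
            for e in manifest["expected_edges"]
        }
        assert got == expected  # precision = recall = 1
        assert ("EXP_SHARED", "T2", "shared_slim") in got
        assert ("DOMAIN_ONLY", "T2", "shared_domain") in got
        assert not any(e.interactor == "PRIVATE_T2" for e in inferred)
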