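import networkx as nx
import pytest

from slimnet import datafiles
from slimnet.network import (
    COMPATIBILITY_PREDICTED,
    EXPERIMENTAL,
    TableError,
    assign_binding_sites,
    build_network,
    export_network,
    find_mutually_exclusive,
    infer_paralog_edges,
    load_interaction_table,
    load_network_tsv,
    summarize,
)
from slimnet.network.tables import CompatibilityMap, Interactor, SiteInventory


@pytest.fixture
def pipeline(interactors, placements, inventory, compatibility):
    assignments = assign_binding_sites(interactors, inventory, compatibility, placements)
    inferred = infer_paralog_edges(interactors, assignments, inventory, compatibility, placements)
    groups = find_mutually_exclusive(assignments, datafiles.single_copy_sites())
    return assignments, inferred, groups


class TestLoadInteractionTable:
    def test_packaged_fixture_counts(self, interactors):
        assert sum(1 for i in interactors if "T1" in i.members) == 24
        assert sum(1 for i in interactors if "T2" in i.members) == 20

    def test_empty_table(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("name\tmember\tmethod\tbinding_region\tdomain_architecture\tpathway\n")
        assert load_interaction_table(path) == []

    def test_duplicate_row_rejected_with_row_number(self, tmp_path):
        path = tmp_path / "dup.tsv"
        header = "name\tmember\tmethod\tbinding_region\tdomain_architecture\tpathway"
        row = "X\tT1\tCo-IP\tunknown\tPDZ\tp"
        path.write_text("\n".join([header, row, row]) + "\n")
        with pytest.raises(TableError, match="3"):
            load_interaction_table(path)

    def test_unknown_member_token_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        header = "name\tmember\tmethod\tbinding_region\tdomain_architecture\tpathway"
        path.write_text(header + "\nX\tT3\tCo-IP\tunknown\tPDZ\tp\n")
        with pytest.raises(TableError, match="T3"):
            load_interaction_table(path)

    def test_evidence_class_derivation(self, interactors):
        by_name = {i.name: i for i in interactors}
        assert by_name["CDC5L"].evidence_class == "HTP"
        assert by_name["PSD-95"].evidence_class == "LTP"
        assert by_name["XPO1"].evidence_class == "LTP"  # "Pull down" is low throughput


class TestAssignBindingSites:
    def test_ppp1ca_predicted_on_t2(self, pipeline):
        assignments, _, _ = pipeline
        predicted = [
            a for a in assignments
            if a.interactor == "PPP1CA" and a.rationale == COMPATIBILITY_PREDICTED
        ]
        assert [(a.member, a.site) for a in predicted] == [("T2", "DOC_PP1_RVXF_1")]

    def test_incompatible_architecture_gets_nothing(self, pipeline):
        assignments, _, _ = pipeline
        assert not any(
            a.interactor == "CAMKIIa" and a.rationale == COMPATIBILITY_PREDICTED
            for a in assignments
        )

    def test_predicted_site_counts(self, pipeline):
        assignments, _, _ = pipeline
        for member, expected in [("T1", 1), ("T2", 5)]:
            names = {
                a.interactor for a in assignments
                if a.member == member and a.rationale == COMPATIBILITY_PREDICTED
            }
            assert len(names) == expected, names
        t1 = {a.interactor for a in assignments
              if a.member == "T1" and a.rationale == COMPATIBILITY_PREDICTED}
        assert t1 == {"FBXW11"}

    def test_experimental_assignments_copied(self, pipeline):
        assignments, _, _ = pipeline
        experimental = {
            (a.interactor, a.member) for a in assignments if a.rationale == EXPERIMENTAL
        }
        assert ("Fodrin", "T1") in experimental
        assert ("PSD-95", "T1") in experimental and ("PSD-95", "T2") in experimental


class TestInferParalogEdges:
    def test_scrib_shared_slim_edge(self, pipeline):
        _, inferred, _ = pipeline
        edge = next(e for e in inferred if e.interactor == "SCRIB")
        assert (edge.from_member, edge.to_member, edge.basis) == ("T1", "T2", "shared_slim")
        assert edge.sites == ("LIG_PDZ_Class_1",)
        assert not edge.low_confidence

    def test_fodrin_shared_domain_edge_flagged(self, pipeline):
        _, inferred, _ = pipeline
        edge = next(e for e in inferred if e.interactor == "Fodrin")
        assert edge.basis == "shared_domain"
        assert edge.low_confidence
        assert set(edge.sites) == {"ANK", "TPR"}

    def test_both_member_interactor_gets_no_edge(self, pipeline):
        _, inferred, _ = pipeline
        assert not any(e.interactor in ("PSD-95", "SAP97", "PRICKLE1") for e in inferred)

    def test_counts_to_t2(self, pipeline):
        _, inferred, _ = pipeline
        slim = {e.interactor for e in inferred if e.to_member == "T2" and e.basis == "shared_slim"}
        domain = {e.interactor for e in inferred if e.to_member == "T2" and e.basis == "shared_domain"}
        assert slim == {"FBXW11", "SCRIB", "Homer"}
        assert domain == {"Fodrin", "MINK", "TNIK"}

    def test_no_inferred_edge_duplicates_known(self, pipeline, interactors):
        _, inferred, _ = pipeline
        known = {(i.name, m) for i in interactors for m in i.members}
        assert not any((e.interactor, e.to_member) in known for e in inferred)

    def test_idempotent(self, interactors, placements, inventory, compatibility):
        assignments = assign_binding_sites(interactors, inventory, compatibility, placements)
        once = infer_paralog_edges(interactors, assignments, inventory, compatibility, placements)
        twice = infer_paralog_edges(interactors, assignments, inventory, compatibility, placements)
        assert once == twice

    def test_provenance_dependency(self, interactors, placements, inventory, compatibility):
        # deleting an interactor's known edge removes its inferred edge
        without_scrib = [i for i in interactors if i.name != "SCRIB"]
        assignments = assign_binding_sites(without_scrib, inventory, compatibility, placements)
        inferred = infer_paralog_edges(
            without_scrib, assignments, inventory, compatibility, placements
        )
        assert not any(e.interactor == "SCRIB" for e in inferred)


class TestMutuallyExclusive:
    def test_pdz_group(self, pipeline):
        _, _, groups = pipeline
        assert len(groups) == 1
        site, names = groups[0]
        assert site == "LIG_PDZ_Class_1"
        assert names == frozenset({"PSD-95", "SAP97", "SCRIB"})

    def test_all_distinct_sites_no_groups(self):
        assert find_mutually_exclusive([], ["LIG_PDZ_Class_1"]) == []

    def test_planted_group_of_k(self, inventory, compatibility):
        k = 4
        interactors = [
            Interactor(f"I{j}", "T1", "Y2H", ("SITE_X",), ("PDZ",), "p") for j in range(k)
        ]
        assignments = assign_binding_sites(interactors, inventory, compatibility, None)
        groups = find_mutually_exclusive(assignments, ["SITE_X"])
        assert len(groups) == 1
        assert len(groups[0][1]) == k


class TestSummarize:
    def test_packaged_counts(self, interactors, pipeline):
        assignments, inferred, groups = pipeline
        report = summarize(interactors, assignments, inferred, groups)
        assert report.known_interactors == {"T1": 24, "T2": 20}
        assert report.experimental_region == {"T1": 6, "T2": 2}
        assert report.predicted_site == {"T1": 1, "T2": 5}
        assert report.inferred_edges["shared_slim"]["T2"] == 3
        assert report.inferred_edges["shared_domain"]["T2"] == 3

    def test_empty_inputs_zero_report(self):
        report = summarize([], [], [], [])
        assert report.known_interactors == {"T1": 0, "T2": 0}
        assert report.experimental_region == {"T1": 0, "T2": 0}
        assert sum(sum(v.values()) for v in report.inferred_edges.values()) == 0

    def test_counts_recomputable(self, interactors, pipeline):
        assignments, inferred, groups = pipeline
        report = summarize(interactors, assignments, inferred, groups)
        for member in ("T1", "T2"):
            assert report.known_interactors[member] == sum(
                1 for i in interactors if member in i.members
            )


class TestExport:
    def test_empty_network(self, tmp_path):
        graph = build_network([], [])
        assert set(graph.nodes) == {"TANC1", "TANC2"}
        assert graph.number_of_edges() == 0
        export_network(graph, tmp_path / "net.tsv", "tsv")
        assert load_network_tsv(tmp_path / "net.tsv").number_of_edges() == 0

    def test_edge_count_arithmetic(self, interactors, pipeline):
        assignments, inferred, _ = pipeline
        graph = build_network(interactors, inferred, assignments)
        known_edges = sum(len(i.members) for i in interactors)  # 24 + 20
        assert graph.number_of_edges() == known_edges + len(inferred)
        assert known_edges == 44

    def test_tsv_roundtrip(self, tmp_path, interactors, pipeline):
        assignments, inferred, _ = pipeline
        graph = build_network(interactors, inferred, assignments)
        export_network(graph, tmp_path / "net.tsv", "tsv")
        loaded = load_network_tsv(tmp_path / "net.tsv")
        assert nx.utils.graphs_equal(graph, loaded)

    def test_graphml_and_sif_writable(self, tmp_path, interactors, pipeline):
        assignments, inferred, _ = pipeline
        graph = build_network(interactors, inferred, assignments)
        export_network(graph, tmp_path / "net.graphml", "graphml")
        export_network(graph, tmp_path / "net.sif", "sif")
        assert nx.read_graphml(tmp_path / "net.graphml").number_of_edges() == graph.number_of_edges()
        assert (tmp_path / "net.sif").read_text().count("\n") >= graph.number_of_edges()

    def test_unknown_format_rejected(self, tmp_path):
        from slimnet.network.export import ExportError

        with pytest.raises(ExportError):
            export_network(build_network([], []), tmp_path / "x", "xml")
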