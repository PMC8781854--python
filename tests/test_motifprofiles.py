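"""Edge partitioning, per-unit normalization, position profiles, consensus SS."""

import networkx as nx
import numpy as np
import pytest

from ankanet.contactnet import (
    ContactNetwork,
    NetworkParams,
    betweenness,
    build_network,
    eigenvector_centrality,
)
from ankanet.io_formats import ProteinRecord
from ankanet.motifprofiles import (
    classify_edges,
    cluster_consensus_profile,
    consensus_secondary_structure,
    normalize_per_unit,
    position_profile,
    profile_from_analysis,
)


def record_for_solenoid(spec):
    """Annotation record matching a generated solenoid (no flanks)."""
    L = spec.repeat_length
    n = spec.n_copies * L
    return ProteinRecord(
        "SYN", "A" * n, [(c * L + 1, (c + 1) * L) for c in range(spec.n_copies)]
    )


def toy_network(edges, nodes=None):
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return ContactNetwork(sorted(g.nodes), g, NetworkParams())


class TestClassifyEdges:
    def test_intra_inter_cross_labels(self):
        # copies at 1-10 and 11-20; residue 25 is outside any copy
        rec = ProteinRecord("P", "A" * 30, [(1, 10), (11, 20)])
        net = toy_network([(5, 9), (10, 11), (20, 25)])
        part = classify_edges(net, rec)
        assert part.intra[5] == 1 and part.intra[9] == 1
        assert part.inter[10] == 1 and part.inter[11] == 1
        assert part.cross[20] == 1 and part.cross[25] == 1

    def test_helix_packing_edge_is_intra(self):
        # positions 5 and 21 of copy 2 (copies 1-33, 34-66)
        rec = ProteinRecord("P", "A" * 70, [(1, 33), (34, 66)])
        net = toy_network([(38, 54)])  # 38 -> copy 2 pos 5; 54 -> copy 2 pos 21
        part = classify_edges(net, rec)
        assert part.intra[38] == 1 and part.intra[54] == 1
        assert part.inter[38] == 0

    def test_unmappable_node_names_residue(self):
        rec = ProteinRecord("P", "A" * 10, [(1, 10)])
        net = toy_network([(5, 99)])
        with pytest.raises(ValueError, match="99"):
            classify_edges(net, rec)

    def test_conservation_law_on_solenoid(self, solenoid, solenoid_spec):
        rec = record_for_solenoid(solenoid_spec)
        net = build_network(solenoid)
        part = classify_edges(net, rec)
        deg = net.degree()
        for u in net.nodes:
            assert part.intra[u] + part.inter[u] + part.cross[u] == deg[u]
            assert part.cross[u] == 0  # generator has no non-repeat residues


class TestNormalizePerUnit:
    def test_scales_to_unit_maximum(self):
        rec = ProteinRecord("P", "A" * 3, [(1, 3)])
        out = normalize_per_unit({1: 2.0, 2: 4.0, 3: 8.0}, rec)
        assert out == {1: 0.25, 2: 0.5, 3: 1.0}

    def test_all_zero_copy_stays_zero(self):
        rec = ProteinRecord("P", "A" * 3, [(1, 3)])
        out = normalize_per_unit({1: 0.0, 2: 0.0, 3: 0.0}, rec)
        assert out == {1: 0.0, 2: 0.0, 3: 0.0}

    def test_per_unit_not_global(self):
        rec = ProteinRecord("P", "A" * 4, [(1, 2), (3, 4)])
        out = normalize_per_unit({1: 1.0, 2: 2.0, 3: 5.0, 4: 10.0}, rec)
        assert out == {1: 0.5, 2: 1.0, 3: 0.5, 4: 1.0}

    def test_node_outside_copies_rejected(self):
        rec = ProteinRecord("P", "A" * 9, [(1, 3)])
        with pytest.raises(ValueError):
            normalize_per_unit({1: 1.0, 7: 1.0}, rec)


class TestPositionProfile:
    def test_mean_over_copies(self):
        rec = ProteinRecord("P", "A" * 9, [(1, 3), (4, 6), (7, 9)])
        deg = {i: 4.0 for i in range(1, 10)}
        deg[2] = deg[5] = deg[8] = 6.0
        prof = position_profile({"degree": deg}, rec, l_max=3)
        assert prof.mean("degree", 1) == 4.0
        assert prof.mean("degree", 2) == 6.0
        assert list(prof.table["n_copies"]) == [3, 3, 3]

    def test_ragged_copies_average_where_covered(self):
        rec = ProteinRecord("P", "A" * 63, [(1, 30), (31, 63)])
        values = {i: 1.0 for i in range(1, 64)}
        prof = position_profile({"v": values}, rec, l_max=33)
        assert prof.table["n_copies"].tolist()[:30] == [2] * 30
        assert prof.table["n_copies"].tolist()[30:] == [1] * 3
        assert prof.mean("v", 33) == 1.0

    def test_uniform_metric_gives_flat_profile(self):
        rec = ProteinRecord("P", "A" * 66, [(1, 33), (34, 66)])
        prof = position_profile(
            {"v": {i: 2.5 for i in range(1, 67)}}, rec
        )
        assert np.allclose(prof.table["mean_v"], 2.5)

    def test_copy_order_invariance(self, solenoid, solenoid_spec):
        rec = record_for_solenoid(solenoid_spec)
        net = build_network(solenoid)
        deg = {u: float(d) for u, d in net.degree().items()}
        prof = position_profile({"degree": deg}, rec)
        # feeding the copies in reversed annotation order changes nothing:
        # position mapping depends on each copy's own start only
        rec2 = ProteinRecord(rec.accession, rec.sequence, rec.repeats)
        prof2 = position_profile({"degree": deg}, rec2)
        assert prof.table.equals(prof2.table)


class TestClusterConsensusProfile:
    def _profile(self, values, n_copies, l_max=1):
        rec = ProteinRecord("P", "A" * n_copies, [(i, i) for i in range(1, n_copies + 1)])
        return position_profile(
            {"v": {i: values for i in range(1, n_copies + 1)}}, rec, l_max=l_max
        )

    def test_identical_members_unchanged(self):
        p = self._profile(0.5, 3)
        merged = cluster_consensus_profile([p, p])
        assert merged.mean("v", 1) == pytest.approx(0.5)

    def test_copy_weighted_mean(self):
        a = self._profile(0.0, 1)
        b = self._profile(1.0, 3)
        merged = cluster_consensus_profile([a, b])
        assert merged.mean("v", 1) == pytest.approx(0.75)

    def test_single_member_identity(self):
        p = self._profile(0.3, 2)
        merged = cluster_consensus_profile([p])
        assert merged.table["mean_v"].equals(p.table["mean_v"])


class TestConsensusSS:
    def test_identical_copies(self):
        ss = ["HHHTTTCCC"] * 4
        assert consensus_secondary_structure(ss, l_max=9) == "HHHTTTCCC"

    def test_majority_vote(self):
        ss = ["H", "H", "H", "C", "C"]
        assert consensus_secondary_structure(ss, l_max=1) == "H"

    def test_tie_break_prefers_helix(self):
        assert consensus_secondary_structure(["H", "C"], l_max=1) == "H"
        assert consensus_secondary_structure(["T", "C"], l_max=1) == "T"

    def test_uncovered_positions_dashed(self):
        assert consensus_secondary_structure(["H"], l_max=3) == "H--"

    def test_solenoid_helix_spans_recovered(self, solenoid_spec):
        from ankanet.synthgen import generate_ss_and_plddt

        ss, _ = generate_ss_and_plddt(solenoid_spec, seed=1)
        L = solenoid_spec.repeat_length
        copies = [ss[c * L:(c + 1) * L] for c in range(solenoid_spec.n_copies)]
        cons = consensus_secondary_structure(copies, l_max=L)
        helix = {p for p in range(1, L + 1) if cons[p - 1] == "H"}
        assert helix == set(range(5, 12)) | set(range(15, 24))


class TestFullProfile:
    def test_normalized_centralities_bounded_with_unit_peak(
        self, solenoid, solenoid_spec
    ):
        rec = record_for_solenoid(solenoid_spec)
        net = build_network(solenoid)
        prof = profile_from_analysis(
            net, rec, betweenness(net), eigenvector_centrality(net).values
        )
        for col in ("mean_norm_betweenness", "mean_norm_eigenvector"):
            v = prof.table[col].dropna()
            assert ((v >= 0) & (v <= 1)).all()

    def test_terminal_positions_dominate_inter_edges(
        self, solenoid, solenoid_spec
    ):
        rec = record_for_solenoid(solenoid_spec)
        net = build_network(solenoid)
        prof = profile_from_analysis(
            net, rec, betweenness(net), eigenvector_centrality(net).values
        )
        L = solenoid_spec.repeat_length
        terminal = [1, 2, L - 1, L]
        a2, b2 = solenoid_spec.helix2_span
        mid_helix2 = list(range(a2 + 2, b2 - 1))
        t = np.mean([prof.mean("inter", p) for p in terminal])
        m = np.mean([prof.mean("inter", p) for p in mid_helix2])
        assert t > m
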