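"""Topology encoding, validation, IO round-trips, and cycle enumeration."""

import itertools

import pytest

from csf1r_grn.network import (
    Component, Cycle, NetworkDefinition, NetworkValidationError, Regulation,
    default_network, feedback_loops, load_network, write_network, write_sif,
)


class TestPackagedNetwork:
    def test_component_census(self, net):
        assert len(net.components) == 11
        roles = [c.role for c in net.components]
        assert roles.count("ligand") == 1
        assert roles.count("transcription_factor") == 6
        assert roles.count("receptor") == 4

    def test_active_form_set(self, net):
        active = {c.name for c in net.components if c.has_active_form}
        assert active == {"STAT1", "STAT3", "CSF1R", "NFKB", "CEBPA"}

    def test_regulation_ids_cover_table(self, net):
        assert sorted(r.id for r in net.regulations) == list(range(1, 43))

    def test_inhibitory_edges(self, net):
        inhib = {(r.source, r.target, r.level)
                 for r in net.regulations if r.sign == "inhibition"}
        assert inhib == {("IRF8", "STAT1", "transcriptional"),
                         ("LPS", "CEBPA", "transcriptional")}

    def test_post_translational_targets_have_active_form(self, net):
        for r in net.regulations:
            if r.level == "post_translational":
                assert net.component(r.target).has_active_form


class TestValidation:
    def _doc(self, net):
        return net.to_dict()

    def test_unknown_component_rejected(self, net, tmp_path):
        doc = self._doc(net)
        doc["regulations"][0]["target"] = "FOO"
        import json
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(NetworkValidationError, match="FOO"):
            load_network(path)

    def test_duplicate_edge_rejected(self, net):
        regs = list(net.regulations)
        regs.append(Regulation(43, regs[2].source, regs[2].target, "activation",
                               regs[2].level, "dup"))
        with pytest.raises(NetworkValidationError, match="duplicate"):
            NetworkDefinition(net.components, regs)

    def test_post_translational_needs_active_target(self, net):
        regs = list(net.regulations)
        regs.append(Regulation(43, "STAT1", "PU1", "activation",
                               "post_translational", "bad level"))
        with pytest.raises(NetworkValidationError, match="active form"):
            NetworkDefinition(net.components, regs)

    def test_lps_cannot_be_target(self, net):
        regs = [Regulation(1, "STAT1", "LPS", "activation", "transcriptional", "")]
        with pytest.raises(NetworkValidationError):
            NetworkDefinition(net.components, regs)


class TestRoundTrip:
    def test_json_round_trip(self, net, tmp_path):
        path = tmp_path / "net.json"
        write_network(net, path)
        assert load_network(path) == net

    def test_minimal_network_round_trip(self, tmp_path):
        tiny = NetworkDefinition([Component("CSF1", "ligand", False)], [])
        path = tmp_path / "tiny.json"
        write_network(tiny, path)
        assert load_network(path) == tiny

    def test_sif_export(self, net, tmp_path):
        path = tmp_path / "net.sif"
        write_sif(net, path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 42
        fields = lines[0].split("\t")
        assert len(fields) == 3 and fields[1] in ("activation", "inhibition")


def _brute_force_cycles(net: NetworkDefinition, max_length: int):
    """Oracle: enumerate simple cycles by checking every node permutation."""
    signs = {}
    for r in net.regulations:
        if r.source != "LPS":
            signs.setdefault((r.source, r.target), set()).add(r.sign)
    nodes = net.names
    out = set()
    for k in range(1, max_length + 1):
        for perm in itertools.permutations(nodes, k):
            edges = [(perm[i], perm[(i + 1) % k]) for i in range(k)]
            if all(e in signs for e in edges):
                n_inh = sum("inhibition" in signs[e] for e in edges)
                i0 = min(range(k), key=lambda i: perm[i])
                rot = tuple(perm[i0:] + perm[:i0])
                out.add((rot, n_inh % 2 == 0))
    return out


class TestFeedbackLoops:
    def test_il6r_stat1_loop_positive(self, net):
        loops = feedback_loops(net, 2)
        assert Cycle(("IL6R", "STAT1"), positive=True) in loops

    def test_nfkb_stat1_stat3_cebpa_loop_positive(self, net):
        loops = feedback_loops(net, 4)
        target = {"NFKB", "STAT1", "STAT3", "CEBPA"}
        hits = [c for c in loops if set(c.nodes) == target and len(c) == 4]
        assert any(c.positive for c in hits)

    def test_stat3_cebpa_pu1_csf3r_loop_positive(self, net):
        # the STAT3 self-reinforcing loop closes through CSF3R's activation
        # of STAT3 protein: STAT3 -> CEBPA -> PU1 -> CSF3R -> STAT3
        loops = feedback_loops(net, 4)
        target = {"STAT3", "CEBPA", "PU1", "CSF3R"}
        assert any(set(c.nodes) == target and c.positive for c in loops)

    def test_empty_network(self):
        empty = NetworkDefinition([Component("CSF1", "ligand", False)], [])
        assert feedback_loops(empty, 5) == []

    @pytest.mark.parametrize("max_length", [1, 2, 3, 4, 5])
    def test_agrees_with_brute_force_on_subnetwork(self, net, max_length):
        # restrict to 6 nodes so permutation enumeration stays feasible
        keep = {"STAT1", "STAT3", "NFKB", "CEBPA", "PU1", "IL6R"}
        comps = [c for c in net.components if c.name in keep]
        regs = [r for r in net.regulations
                if r.source in keep | {"LPS"} and r.target in keep]
        # drop duplicate (source,target) pairs at different levels for the oracle
        sub = NetworkDefinition(comps, regs)
        got = {(c.nodes, c.positive) for c in feedback_loops(sub, max_length)}
        assert got == _brute_force_cycles(sub, max_length)

    def test_mixed_sign_toy_cycle_is_negative(self):
        comps = [Component("A", "transcription_factor", False),
                 Component("B", "transcription_factor", False)]
        regs = [Regulation(1, "A", "B", "activation", "transcriptional", ""),
                Regulation(2, "B", "A", "inhibition", "transcriptional", "")]
        toy = NetworkDefinition(comps, regs)
        loops = feedback_loops(toy, 2)
        assert loops == [Cycle(("A", "B"), positive=False)]
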