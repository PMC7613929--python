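"""Interface detection, classification, local C2 and filament graphs."""

import copy

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from filageom import synthetic
from filageom.rigid import RigidTransform
from filageom.structure import Structure, apply_transform
from filageom.topology import (build_filament_graph, classify_interface,
                               classify_interfaces, detect_c2,
                               find_interfaces, interface_report,
                               polar_contacts)


def truth_edge_labels(truth):
    return {tuple(sorted(pair)): label
            for pair, label in truth.params["interfaces"]}


class TestFindInterfaces:
    def test_distant_chains_have_no_interface(self, protomer):
        far = copy.deepcopy(protomer)
        far.chain_id = "Q"
        for res in far.residues:
            for atom in res.atoms:
                atom.coords = atom.coords + np.array([100.0, 0.0, 0.0])
        s = Structure(id="far", chains=[protomer, far])
        assert find_interfaces(s) == []

    def test_single_chain_warns_and_returns_empty(self, protomer):
        s = Structure(id="one", chains=[protomer])
        with pytest.warns(UserWarning, match="fewer than 2"):
            assert find_interfaces(s) == []

    def test_generator_truth_recovered_exactly(self, double_filament):
        s, truth = double_filament
        detected = {tuple(sorted(i.chain_pair)) for i in find_interfaces(s)}
        assert detected == set(truth_edge_labels(truth))

    def test_both_lateral_registries_present(self, double_filament):
        labels = set(truth_edge_labels(double_filament[1]).values())
        assert {"lateral_i_istar", "lateral_i_istar_minus1"} <= labels

    def test_invariant_under_rigid_motion(self, double_filament, rng):
        s, _ = double_filament
        t = RigidTransform(Rotation.random(random_state=rng).as_matrix(),
                           rng.normal(scale=30, size=3))
        a = {(i.chain_pair, i.n_residue_pairs) for i in find_interfaces(s)}
        b = {(i.chain_pair, i.n_residue_pairs)
             for i in find_interfaces(apply_transform(s, t))}
        assert a == b

    def test_count_monotone_in_cutoff(self, double_filament):
        s, _ = double_filament
        n = [sum(i.n_residue_pairs for i in find_interfaces(s, cutoff))
             for cutoff in (4.0, 4.5, 5.5)]
        assert n[0] <= n[1] <= n[2]


class TestClassification:
    def test_double_filament_labels_match_truth(self, double_filament,
                                                pseudo_domains):
        s, truth = double_filament
        ifaces = find_interfaces(s)
        classes = classify_interfaces(s, ifaces, pseudo_domains)
        expected = truth_edge_labels(truth)
        for pair, cls in classes.items():
            want = expected[tuple(sorted(pair))]
            if want == "longitudinal":
                assert cls.label.startswith("longitudinal")
            else:
                assert cls.label == want

    def test_parallel_dimer_is_longitudinal(self, protomer, pseudo_domains):
        s, _ = synthetic.build_helical_filament(
            protomer, rise=48.0, twist_deg=5.0, n=2)
        ifaces = find_interfaces(s)
        assert len(ifaces) == 1
        cls = classify_interface(s, ifaces[0], pseudo_domains)
        assert cls.label.startswith("longitudinal")
        assert cls.relative_twist_deg == pytest.approx(5.0, abs=1e-6)

    def test_recovery_with_coordinate_noise(self, double_filament,
                                            pseudo_domains):
        """Graph recovery stays exact for sigma <= 0.3 A."""
        s, truth = double_filament
        expected = truth_edge_labels(truth)
        for seed, sigma in [(3, 0.3), (7, 0.3), (11, 0.2)]:
            noisy = synthetic.perturb(s, sigma, seed=seed)
            ifaces = find_interfaces(noisy)
            detected = {tuple(sorted(i.chain_pair)) for i in ifaces}
            assert detected == set(expected)
            classes = classify_interfaces(noisy, ifaces, pseudo_domains)
            for pair, cls in classes.items():
                want = expected[tuple(sorted(pair))]
                assert cls.label == want or (
                    want == "longitudinal"
                    and cls.label.startswith("longitudinal"))


class TestDetectC2:
    def test_exact_c2_dimer(self, double_filament):
        s, truth = double_filament
        pairs = {tuple(sorted(p)) for p in truth.params["c2_pairs"]}
        for iface in find_interfaces(s):
            if tuple(sorted(iface.chain_pair)) in pairs:
                a = detect_c2(s, iface)
                assert a.has_c2
                assert a.angle_dev_deg == pytest.approx(0.0, abs=1e-9)
                assert a.rise_abs == pytest.approx(0.0, abs=1e-9)
                assert a.mapping_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_axis_shift_violates_c2(self, double_filament):
        """Translating one chain along the would-be axis by 5 A shows up
        as a 5 A rise and breaks the verdict."""
        s, truth = double_filament
        s = s.copy()
        axis_dir = np.asarray(truth.params["c2_axis_direction"], dtype=float)
        pair = truth.params["c2_pairs"][0]
        chain = s.chain(pair[1])
        for res in chain.residues:
            for atom in res.atoms:
                atom.coords = atom.coords + 5.0 * axis_dir
        iface = next(i for i in find_interfaces(s, contact_cutoff=9.0,
                                                min_pairs=1)
                     if set(i.chain_pair) == set(pair))
        a = detect_c2(s, iface)
        assert a.rise_abs == pytest.approx(5.0, abs=1e-6)
        assert not a.has_c2

    def test_translation_related_dimer_is_not_c2(self, protomer):
        s, _ = synthetic.build_helical_filament(
            protomer, rise=48.0, twist_deg=0.0, n=2)
        ifaces = find_interfaces(s)
        a = detect_c2(s, ifaces[0])
        assert abs(a.axis.twist_deg) < 1e-6
        assert not a.has_c2


class TestPolarContacts:
    def test_cutoff_monotonicity(self, double_filament):
        s, _ = double_filament
        iface = find_interfaces(s)[0]
        n_tight = len(polar_contacts(s, iface, 3.0))
        n_loose = len(polar_contacts(s, iface, 3.5))
        assert n_tight <= n_loose
        for _, _, d in polar_contacts(s, iface, 3.5):
            assert d <= 3.5

    def test_known_pair_inside_and_outside_cutoff(self):
        from filageom.structure import Atom, Chain, Residue
        mk = lambda cid, x: Chain(cid, [Residue(1, "SER", [
            Atom("N", "N", [x, 0, 0]), Atom("CA", "C", [x + 1.2, 0.1, 0]),
            Atom("C", "C", [x + 2.0, 1.2, 0]),
            Atom("OG", "O", [x + 0.3, 2.0, 1.0])])])
        s = Structure(id="p", chains=[mk("A", 0.0), mk("B", 3.2)])
        iface = find_interfaces(s, contact_cutoff=6.0, min_pairs=1)[0]
        close = polar_contacts(s, iface, 3.5)
        assert any(d == pytest.approx(3.2, abs=1e-6) for _, _, d in close)
        assert not any(d <= 3.0 for _, _, d in polar_contacts(s, iface, 3.0))


class TestFilamentGraph:
    def test_constructed_tetramer(self, double_filament, pseudo_domains):
        s, truth = double_filament
        ifaces = find_interfaces(s)
        classes = classify_interfaces(s, ifaces, pseudo_domains)
        graph = build_filament_graph(ifaces, classes)
        assert sorted(map(sorted, graph.protofilaments)) == \
            sorted(map(sorted, truth.params["protofilaments"]))
        assert len(graph.components) == 1
        assert len(graph.components[0]) == 2 * truth.params[
            "n_per_protofilament"]
        assert graph.is_double_filament()

    def test_two_dimer_protofilaments(self, protomer, pseudo_domains):
        s, _ = synthetic.build_double_filament(protomer,
                                               n_per_protofilament=2)
        ifaces = find_interfaces(s)
        classes = classify_interfaces(s, ifaces, pseudo_domains)
        graph = build_filament_graph(ifaces, classes)
        assert len(graph.components[0]) == 4
        assert sorted(len(p) for p in graph.protofilaments) == [2, 2]

    def test_closed_ring_of_13(self, protomer, pseudo_domains):
        """13 subunits closing a full circle form a cyclic protofilament,
        reported as a ring rather than an error."""
        import math
        radius_nm = 13 * 48.0 / (2 * math.pi) / 10.0
        s, _ = synthetic.build_arc_filament(protomer, radius_nm, 48.0, n=13)
        ifaces = find_interfaces(s)
        classes = classify_interfaces(s, ifaces, pseudo_domains)
        graph = build_filament_graph(ifaces, classes)
        assert graph.protofilaments == []
        assert len(graph.closed_rings) == 1
        assert len(graph.closed_rings[0]) == 13

    def test_report_table_columns(self, double_filament, pseudo_domains):
        s, _ = double_filament
        ifaces = find_interfaces(s)
        classes = classify_interfaces(s, ifaces, pseudo_domains)
        c2 = {i.chain_pair: detect_c2(s, i) for i in ifaces}
        table = interface_report(ifaces, classes, c2)
        assert len(table) == len(ifaces)
        assert {"chain_a", "chain_b", "label", "relative_twist_deg",
                "has_c2"} <= set(table.columns)
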