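"""Cysteine cross-link candidate scanning and background screening."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from filageom import synthetic
from filageom.crosslink import (BMOE, LinkerSpec, MissingResidueError,
                                background_check, c2_self_pairs,
                                candidate_table, cbeta_distance,
                                scan_crosslink_pairs)
from filageom.rigid import RigidTransform
from filageom.structure import (Atom, Chain, Residue, Structure,
                                apply_transform)
from filageom.topology import (build_filament_graph, classify_interfaces,
                               detect_c2, find_interfaces)


@pytest.fixture(scope="module")
def filament_with_graph(protomer, pseudo_domains):
    s, truth = synthetic.build_double_filament(protomer,
                                               n_per_protofilament=3)
    ifaces = find_interfaces(s)
    classes = classify_interfaces(s, ifaces, pseudo_domains)
    graph = build_filament_graph(ifaces, classes)
    return s, truth, graph


def two_residue_structure(distance: float) -> Structure:
    def residue(x):
        return Residue(1, "ASP", [Atom("N", "N", [x, 0, 1.4]),
                                  Atom("CA", "C", [x, 0.2, 0]),
                                  Atom("CB", "C", [x, 0, -1.5])])
    return Structure(id="pair", chains=[
        Chain("A", [residue(0.0)]), Chain("B", [residue(distance)])])


class TestCbetaDistance:
    def test_constructed_5_angstrom_pair(self):
        s = two_residue_structure(5.0)
        assert cbeta_distance(s, ("A", 1), ("B", 1)) \
            == pytest.approx(5.0, abs=1e-9)

    def test_symmetric_and_rigid_motion_invariant(self, rng):
        s = two_residue_structure(7.3)
        d1 = cbeta_distance(s, ("A", 1), ("B", 1))
        d2 = cbeta_distance(s, ("B", 1), ("A", 1))
        assert d1 == d2
        t = RigidTransform(Rotation.random(random_state=rng).as_matrix(),
                           rng.normal(scale=20, size=3))
        d3 = cbeta_distance(apply_transform(s, t), ("A", 1), ("B", 1))
        assert d3 == pytest.approx(d1, abs=1e-9)

    def test_glycine_skipped_with_warning(self):
        s = two_residue_structure(5.0)
        s.chain("A").residues[0].name = "GLY"
        s.chain("A").residues[0].atoms = [
            a for a in s.chain("A").residues[0].atoms if a.name != "CB"]
        with pytest.warns(UserWarning, match="glycine"):
            assert cbeta_distance(s, ("A", 1), ("B", 1)) is None
        with pytest.raises(ValueError, match="glycine"):
            cbeta_distance(s, ("A", 1), ("B", 1), strict=True)

    def test_missing_residue_is_lookup_error(self):
        s = two_residue_structure(5.0)
        with pytest.raises(MissingResidueError):
            cbeta_distance(s, ("A", 99), ("B", 1))


class TestScan:
    def test_zero_max_distance_gives_empty(self, filament_with_graph):
        s, _, graph = filament_with_graph
        with pytest.warns(UserWarning, match="no cross-link"):
            assert scan_crosslink_pairs(s, graph, max_distance=0.0) == []

    def test_monotone_in_max_distance(self, filament_with_graph):
        s, _, graph = filament_with_graph
        small = scan_crosslink_pairs(s, graph, max_distance=6.0)
        large = scan_crosslink_pairs(s, graph, max_distance=10.0)
        key = lambda c: (c.site1.chain, c.site1.seq_id,
                         c.site2.chain, c.site2.seq_id)
        assert {key(c) for c in small} <= {key(c) for c in large}

    def test_sorted_ascending_by_distance(self, filament_with_graph):
        s, _, graph = filament_with_graph
        cands = scan_crosslink_pairs(s, graph, max_distance=12.0)
        dists = [c.cbeta_distance for c in cands]
        assert dists == sorted(dists)

    def test_restricted_candidate_set_single_pair(self, filament_with_graph):
        """Restricting to one residue number yields only pairs among those
        positions, with correct linker annotation."""
        s, _, graph = filament_with_graph
        cands = scan_crosslink_pairs(s, graph, candidate_residues=[13],
                                     linkers=[BMOE], max_distance=20.0)
        assert cands
        for c in cands:
            assert c.site1.seq_id == 13 and c.site2.seq_id == 13
            assert c.symmetry_self_pair
            if c.cbeta_distance <= BMOE.span + BMOE.tolerance:
                assert "BMOE" in c.compatible_linkers
            if c.cbeta_distance < BMOE.span - BMOE.tolerance:
                assert "BMOE" in c.short_for_linkers

    def test_linker_compatibility_windows(self):
        bmoe = LinkerSpec("BMOE", 8.0, 3.0)
        assert bmoe.compatible(3.7) and bmoe.shorter_than_span(3.7)
        assert bmoe.compatible(10.5)
        assert not bmoe.compatible(12.6)


class TestBackground:
    def test_constructed_decoy_cysteine(self, protomer, pseudo_domains):
        """A decoy cysteine placed on the partner chain is found as the
        nearest endogenous background and flagged when close."""
        s, truth, = None, None
        s_t = synthetic.build_double_filament(
            synthetic.make_protomer(120, seed=1, cys_positions=(14,)),
            n_per_protofilament=3)
        s, truth = s_t
        ifaces = find_interfaces(s)
        classes = classify_interfaces(s, ifaces, pseudo_domains)
        graph = build_filament_graph(ifaces, classes)
        cands = scan_crosslink_pairs(s, graph, candidate_residues=[13],
                                     max_distance=20.0)
        cands = background_check(s, graph, cands, endogenous_cys=[14])
        for c in cands:
            assert math.isfinite(c.background_min_distance)
            # residue 14 is adjacent to 13 on the partner chain
            assert c.background_min_distance < 12.0
            assert c.background_flagged

    def test_empty_endogenous_list_leaves_infinite(self,
                                                   filament_with_graph):
        s, _, graph = filament_with_graph
        cands = scan_crosslink_pairs(s, graph, candidate_residues=[13],
                                     max_distance=20.0)
        cands = background_check(s, graph, cands, endogenous_cys=[])
        assert all(math.isinf(c.background_min_distance) for c in cands)


class TestC2SelfPairs:
    def test_self_pairs_on_c2_interface(self, filament_with_graph):
        s, truth, graph = filament_with_graph
        pair = tuple(truth.params["c2_pairs"][1])
        iface = next(i for i in find_interfaces(s)
                     if set(i.chain_pair) == set(pair))
        c2 = detect_c2(s, iface)
        assert c2.has_c2
        cands = c2_self_pairs(s, iface.chain_pair, c2, residues=range(1, 31))
        assert cands and all(c.symmetry_self_pair for c in cands)
        # distances invariant under chain swap
        swapped = c2_self_pairs(s, iface.chain_pair[::-1], c2,
                                residues=range(1, 31))
        a = sorted(round(c.cbeta_distance, 9) for c in cands)
        b = sorted(round(c.cbeta_distance, 9) for c in swapped)
        assert a == b

    def test_warns_without_c2(self, protomer, filament_with_graph):
        s, truth, graph = filament_with_graph
        iface = next(i for i in find_interfaces(s)
                     if i.chain_pair == ("A0", "A1"))
        c2 = detect_c2(s, iface)
        assert not c2.has_c2
        with pytest.warns(UserWarning, match="lacks local C2"):
            cands = c2_self_pairs(s, iface.chain_pair, c2,
                                  residues=range(1, 31))
        assert cands  # still computed


def test_candidate_table_roundtrip(filament_with_graph):
    s, _, graph = filament_with_graph
    cands = scan_crosslink_pairs(s, graph, max_distance=8.0)
    table = candidate_table(cands)
    assert len(table) == len(cands)
    assert {"chain1", "resi1", "cbeta_distance_A", "interface",
            "self_pair"} <= set(table.columns)
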