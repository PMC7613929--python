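"""Inter-subunit interface detection, classification and filament graphs.

Actin-like double filaments have two kinds of interface:

* **longitudinal** — head-to-tail contacts between consecutive subunits of
  one protofilament (for FtsA between the IIA/IIB surfaces of one subunit
  and the nucleotide face of the next), subdivided into *tight* and *loose*
  by how many residue pairs the IIA/IIB surfaces contribute;
* **lateral** — contacts between the two antiparallel protofilaments,
  mediated by the IC domain, in two registries: FtsA_i-FtsA_i* (subunits in
  register) and FtsA_i-FtsA_i*-1 (offset by about one longitudinal repeat).

Both lateral interfaces carry approximate local two-fold (C2) symmetry: a
180-degree rotation that swaps the two chains while mapping the dimer onto
itself.  The classified interfaces assemble into a graph whose maximal
longitudinal paths are the protofilaments.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .rigid import RigidTransform, ScrewAxis, screw_decompose, superpose
from .structure import Chain, Structure, transform_between_subunits

logger = logging.getLogger(__name__)

#: default contact definition (standard quaternary-contact practice)
CONTACT_CUTOFF_A = 4.5
MIN_RESIDUE_PAIRS = 5
POLAR_CUTOFF_A = 3.5

#: classifier thresholds
LONGITUDINAL_TWIST_MAX_DEG = 60.0
LATERAL_TWIST_MIN_DEG = 150.0
TIGHT_MIN_PAIRS = 3

#: local-C2 acceptance tolerances ("local" crystal symmetry is approximate)
C2_TOL_ANGLE_DEG = 5.0
C2_TOL_RISE_A = 1.5
C2_TOL_RMSD_A = 2.0

LABELS = ("longitudinal_tight", "longitudinal_loose",
          "lateral_i_istar", "lateral_i_istar_minus1", "other")


@dataclasses.dataclass
class InterfaceContact:
    """All residue-level contacts between one unordered chain pair."""
    chain_pair: tuple[str, str]
    contact_pairs: list[tuple[tuple[int, str], tuple[int, str], float]]
    polar_contacts: list[tuple[tuple[int, str, str], tuple[int, str, str], float]] \
        = dataclasses.field(default_factory=list)

    @property
    def n_residue_pairs(self) -> int:
        return len(self.contact_pairs)


@dataclasses.dataclass
class InterfaceClass:
    """Classifier verdict for one interface."""
    label: str
    relative_twist_deg: float
    evidence: dict = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class C2Assessment:
    """Local two-fold symmetry test of a two-chain interface."""
    has_c2: bool
    axis: ScrewAxis
    angle_dev_deg: float
    rise_abs: float
    mapping_rmsd: float


@dataclasses.dataclass
class FilamentGraph:
    """Subunits as nodes, classified interfaces as edges."""
    graph: nx.Graph
    protofilaments: list[list[str]]
    closed_rings: list[list[str]]
    components: list[list[str]]

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edges(self, label_prefix: str | None = None):
        out = []
        for a, b, data in self.graph.edges(data=True):
            cls: InterfaceClass = data["cls"]
            if label_prefix is None or cls.label.startswith(label_prefix):
                out.append(((a, b), cls))
        return out

    def is_double_filament(self) -> bool:
        """Two protofilaments joined by >= 1 lateral edge per subunit on
        average."""
        if len(self.protofilaments) + len(self.closed_rings) != 2:
            return False
        n_sub = self.graph.number_of_nodes()
        n_lat = len(self.edges("lateral"))
        return n_lat * 2 >= n_sub


# ---------------------------------------------------------------------------
# contact detection


def _heavy_atom_table(chain: Chain) -> tuple[np.ndarray, list]:
    coords, info = [], []
    for res in chain.residues:
        for atom in res.atoms:
            coords.append(atom.coords)
            info.append((res.seq_id, res.name, atom.name, atom.element))
    return np.asarray(coords, dtype=float).reshape(-1, 3), info


def find_interfaces(s: Structure, contact_cutoff: float = CONTACT_CUTOFF_A,
                    min_pairs: int = MIN_RESIDUE_PAIRS,
                    polar_cutoff: float = POLAR_CUTOFF_A
                    ) -> list[InterfaceContact]:
    """Detect chain-chain interfaces by heavy-atom proximity.

    An interface is a chain pair with at least ``min_pairs`` residue pairs
    whose minimum heavy-atom distance is within ``contact_cutoff``.  The
    result is independent of chain order within each pair and sorted by
    chain ids for determinism.
    """
    chains = s.polymer_chains()
    if len(chains) < 2:
        warnings.warn("structure has fewer than 2 polymer chains; "
                      "no interfaces possible", stacklevel=2)
        return []
    tables = {c.chain_id: _heavy_atom_table(c) for c in chains}
    trees = {cid: cKDTree(xyz) for cid, (xyz, _) in tables.items()
             if len(xyz)}
    out: list[InterfaceContact] = []
    for ca, cb in itertools.combinations(sorted(trees), 2):
        xyz_a, info_a = tables[ca]
        xyz_b, info_b = tables[cb]
        pairs = trees[ca].query_ball_tree(trees[cb], contact_cutoff)
        res_min: dict[tuple, float] = {}
        polar = []
        for ia, hits in enumerate(pairs):
            for ib in hits:
                d = float(np.linalg.norm(xyz_a[ia] - xyz_b[ib]))
                seq_a, name_a, atom_a, el_a = info_a[ia]
                seq_b, name_b, atom_b, el_b = info_b[ib]
                key = ((seq_a, name_a), (seq_b, name_b))
                if key not in res_min or d < res_min[key]:
                    res_min[key] = d
                if d <= polar_cutoff and el_a in ("N", "O") \
                        and el_b in ("N", "O"):
                    polar.append(((seq_a, name_a, atom_a),
                                  (seq_b, name_b, atom_b), d))
        if len(res_min) >= min_pairs:
            contact_pairs = sorted(
                [(ra, rb, d) for (ra, rb), d in res_min.items()])
            out.append(InterfaceContact((ca, cb), contact_pairs,
                                        sorted(polar)))
    return out


def polar_contacts(s: Structure, iface: InterfaceContact,
                   polar_cutoff: float = POLAR_CUTOFF_A) -> list:
    """Inter-chain N/O-N/O atom pairs within ``polar_cutoff``.

    Donor/acceptor chemistry is approximated by element (N or O on both
    sides); no angle term.  Counts are comparable across structures, which
    is how hydrogen bonds "lost" upon filament bending are quantified.
    """
    ca, cb = iface.chain_pair
    xyz_a, info_a = _heavy_atom_table(s.chain(ca))
    xyz_b, info_b = _heavy_atom_table(s.chain(cb))
    mask_a = [i for i, t in enumerate(info_a) if t[3] in ("N", "O")]
    mask_b = [i for i, t in enumerate(info_b) if t[3] in ("N", "O")]
    if not mask_a or not mask_b:
        return []
    tree_b = cKDTree(xyz_b[mask_b])
    out = []
    for i in mask_a:
        for j_local in tree_b.query_ball_point(xyz_a[i], polar_cutoff):
            j = mask_b[j_local]
            d = float(np.linalg.norm(xyz_a[i] - xyz_b[j]))
            out.append(((info_a[i][0], info_a[i][1], info_a[i][2]),
                        (info_b[j][0], info_b[j][1], info_b[j][2]), d))
    return sorted(out)


# ---------------------------------------------------------------------------
# C2 symmetry


def detect_c2(s: Structure, iface: InterfaceContact,
              tol_angle_deg: float = C2_TOL_ANGLE_DEG,
              tol_rise: float = C2_TOL_RISE_A,
              tol_rmsd: float = C2_TOL_RMSD_A) -> C2Assessment:
    """Test an interface for local two-fold symmetry.

    The transform mapping chain 1 onto chain 2 (atoms matched by residue
    number and atom name) is the candidate symmetry operation: swapping the
    chains maps the dimer onto itself exactly when that transform is an
    involution, i.e. a 180-degree rotation with no translation along its
    axis.  Local C2 holds when the twist is within ``tol_angle_deg`` of
    180 degrees, the rise within ``tol_rise`` of zero and the superposition
    RMSD (the conformational difference between the chains) within
    ``tol_rmsd``.
    """
    ca, cb = iface.chain_pair
    A, B = _matched_coords(s.chain(ca), s.chain(cb))
    transform, rmsd = superpose(A, B)
    axis = screw_decompose(transform)
    angle_dev = abs(180.0 - abs(axis.twist_deg))
    rise_abs = abs(axis.rise)
    has_c2 = (angle_dev <= tol_angle_deg and rise_abs <= tol_rise
              and rmsd <= tol_rmsd)
    return C2Assessment(has_c2, axis, angle_dev, rise_abs, rmsd)


def _matched_coords(chain_a: Chain, chain_b: Chain
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of atoms common to both chains, matched by
    (seq_id, icode, atom name)."""
    index_b = {(r.seq_id, r.icode, a.name): a.coords
               for r in chain_b.residues for a in r.atoms}
    A, B = [], []
    for r in chain_a.residues:
        for a in r.atoms:
            key = (r.seq_id, r.icode, a.name)
            if key in index_b:
                A.append(a.coords)
                B.append(index_b[key])
    if len(A) < 3:
        raise ValueError(
            f"chains {chain_a.chain_id}/{chain_b.chain_id}: fewer than 3 "
            "matched atoms")
    return np.asarray(A), np.asarray(B)


# ---------------------------------------------------------------------------
# classification


def _domain_residues(domains, names) -> set[int]:
    out: set[int] = set()
    for name in names:
        for lo, hi in domains.ranges.get(name, []):
            out.update(range(lo, hi + 1))
    return out


def _pair_count_in(iface: InterfaceContact, set_a: set[int],
                   set_b: set[int]) -> int:
    """Residue pairs with residue1 in set_a and residue2 in set_b, either
    orientation."""
    n = 0
    for (seq_a, _), (seq_b, _), _ in iface.contact_pairs:
        if (seq_a in set_a and seq_b in set_b) \
                or (seq_a in set_b and seq_b in set_a):
            n += 1
    return n


def classify_interface(s: Structure, iface: InterfaceContact, domains,
                       longitudinal_axis=None,
                       longitudinal_repeat: float | None = None,
                       longitudinal_twist_max: float = LONGITUDINAL_TWIST_MAX_DEG,
                       lateral_twist_min: float = LATERAL_TWIST_MIN_DEG,
                       tight_min_pairs: int = TIGHT_MIN_PAIRS
                       ) -> InterfaceClass:
    """Classify one interface as longitudinal (tight/loose), lateral
    (i-i* / i-i*-1) or other.

    The discriminator is the relative twist between the two subunits
    (rotation angle of the chain-to-chain superposition): near-parallel
    subunits (twist < ``longitudinal_twist_max``) are longitudinal,
    antiparallel subunits (twist >= ``lateral_twist_min``) lateral.
    Longitudinal interfaces are *tight* when at least ``tight_min_pairs``
    residue pairs connect one subunit's IIA/IIB ranges to the other's
    nucleotide face (IA/IIA), else *loose*.  Lateral sub-types are split by
    the registry offset: the projection of the inter-centroid vector onto
    the protofilament axis, compared against a quarter of the longitudinal
    repeat (offsets below -> i-i*, above -> i-i*-1; without axis/repeat
    information the offset defaults to 0, i.e. i-i*).

    ``domains`` is a :class:`~filageom.domains.DomainDefinition`; missing
    IIA/IIB/IA ranges are a configuration error for longitudinal calls.
    """
    ca, cb = iface.chain_pair
    transform, rmsd = transform_between_subunits(s, ca, cb)
    twist = transform.angle_deg
    evidence: dict = {"superposition_rmsd": rmsd,
                      "n_residue_pairs": iface.n_residue_pairs}

    if twist < longitudinal_twist_max:
        need = {"IIA", "IIB", "IA"}
        if not need.issubset(domains.ranges):
            raise KeyError(
                f"domain definition lacks ranges for {sorted(need - set(domains.ranges))}")
        head = _domain_residues(domains, ("IIA", "IIB"))
        nucleotide_face = _domain_residues(domains, ("IA", "IIA"))
        n_tight = _pair_count_in(iface, head, nucleotide_face)
        evidence["iia_iib_to_nucleotide_face_pairs"] = n_tight
        label = "longitudinal_tight" if n_tight >= tight_min_pairs \
            else "longitudinal_loose"
        return InterfaceClass(label, twist, evidence)

    if twist >= lateral_twist_min:
        ic = _domain_residues(domains, ("IC",))
        if ic:
            n_ic = sum(1 for (sa, _), (sb, _), _ in iface.contact_pairs
                       if sa in ic and sb in ic)
            evidence["ic_ic_pairs"] = n_ic
            evidence["ic_fraction"] = n_ic / max(iface.n_residue_pairs, 1)
        offset = 0.0
        if longitudinal_axis is not None:
            axis = np.asarray(longitudinal_axis, dtype=float)
            axis = axis / np.linalg.norm(axis)
            delta = s.chain(cb).centroid() - s.chain(ca).centroid()
            offset = abs(float(delta @ axis))
        evidence["registry_offset_A"] = offset
        if longitudinal_repeat and offset > longitudinal_repeat / 4.0:
            label = "lateral_i_istar_minus1"
        else:
            label = "lateral_i_istar"
        return InterfaceClass(label, twist, evidence)

    return InterfaceClass("other", twist, evidence)


def classify_interfaces(s: Structure, interfaces: list[InterfaceContact],
                        domains, **kwargs) -> dict[tuple[str, str], InterfaceClass]:
    """Classify every interface, bootstrapping the protofilament axis.

    Longitudinal interfaces are identified first (by relative twist); the
    mean inter-centroid displacement across them provides the
    protofilament axis and longitudinal repeat needed to split the lateral
    sub-types.  (The displacement, not the screw axis, is used: for
    near-pure translations the screw axis direction is dominated by
    whatever tiny rotation the coordinates carry.)
    """
    axes, rises = [], []
    for iface in interfaces:
        t, _ = transform_between_subunits(s, *iface.chain_pair)
        if t.angle_deg < kwargs.get("longitudinal_twist_max",
                                    LONGITUDINAL_TWIST_MAX_DEG):
            ca, cb = iface.chain_pair
            delta = s.chain(cb).centroid() - s.chain(ca).centroid()
            norm = np.linalg.norm(delta)
            if norm == 0:
                continue
            d = delta / norm
            if axes and np.dot(axes[0], d) < 0:
                d = -d
            axes.append(d)
            rises.append(norm)
    axis = None
    repeat = None
    if axes:
        axis = np.mean(axes, axis=0)
        axis /= np.linalg.norm(axis)
        repeat = float(np.mean(rises))
    out = {}
    for iface in interfaces:
        out[iface.chain_pair] = classify_interface(
            s, iface, domains, longitudinal_axis=axis,
            longitudinal_repeat=repeat, **kwargs)
    return out


# ---------------------------------------------------------------------------
# graph assembly


def build_filament_graph(interfaces: list[InterfaceContact],
                         classes: dict[tuple[str, str], InterfaceClass],
                         nodes=None) -> FilamentGraph:
    """Assemble classified interfaces into a filament graph.

    Protofilaments are the maximal simple paths over longitudinal edges;
    a cyclic longitudinal path is reported as a closed ring, not an error.
    Connected components (over all edges) give the oligomer grouping,
    e.g. the four FtsA tetramers of the peptide co-crystal.
    """
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    for iface in interfaces:
        cls = classes[iface.chain_pair]
        g.add_edge(*iface.chain_pair, cls=cls, iface=iface)

    longi = nx.Graph()
    longi.add_nodes_from(g.nodes)
    for a, b, data in g.edges(data=True):
        if data["cls"].label.startswith("longitudinal"):
            longi.add_edge(a, b)

    protofilaments, closed_rings = [], []
    for comp in nx.connected_components(longi):
        sub = longi.subgraph(comp)
        if sub.number_of_nodes() == 1:
            protofilaments.append(sorted(comp))
            continue
        degrees = dict(sub.degree())
        ends = sorted(n for n, d in degrees.items() if d == 1)
        if not ends and all(d == 2 for d in degrees.values()):
            # cyclic protofilament: closed ring
            start = sorted(comp)[0]
            ring = [start]
            prev = None
            while True:
                nxt = [n for n in sub.neighbors(ring[-1]) if n != prev]
                prev = ring[-1]
                if nxt[0] == start:
                    break
                ring.append(nxt[0])
            closed_rings.append(ring)
        elif len(ends) == 2 and all(d <= 2 for d in degrees.values()):
            path = [ends[0]]
            prev = None
            while path[-1] != ends[1]:
                nxt = [n for n in sub.neighbors(path[-1]) if n != prev]
                prev = path[-1]
                path.append(nxt[0])
            protofilaments.append(path)
        else:
            # branched longitudinal subgraph: report longest simple path
            logger.warning("branched longitudinal subgraph over %s", comp)
            best: list = []
            for u in ends or list(comp):
                for v in ends or list(comp):
                    if u >= v:
                        continue
                    for p in nx.all_simple_paths(sub, u, v):
                        if len(p) > len(best):
                            best = p
            protofilaments.append(best or sorted(comp))

    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: (-len(c), c))
    return FilamentGraph(g, protofilaments, closed_rings, components)


def interface_report(interfaces, classes, c2: dict | None = None
                     ) -> pd.DataFrame:
    """Tab-ready summary table: one row per classified interface."""
    rows = []
    for iface in interfaces:
        cls = classes[iface.chain_pair]
        row = {"chain_a": iface.chain_pair[0],
               "chain_b": iface.chain_pair[1],
               "label": cls.label,
               "relative_twist_deg": round(cls.relative_twist_deg, 3),
               "n_residue_pairs": iface.n_residue_pairs,
               "n_polar_contacts": len(iface.polar_contacts)}
        if c2 and iface.chain_pair in c2:
            a = c2[iface.chain_pair]
            row.update(has_c2=a.has_c2,
                       c2_angle_dev_deg=round(a.angle_dev_deg, 3),
                       c2_rise_A=round(a.rise_abs, 3),
                       c2_rmsd_A=round(a.mapping_rmsd, 3))
        rows.append(row)
    return pd.DataFrame(rows)
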