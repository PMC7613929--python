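"""Domain orientation (principal axes) and hinge-rotation analysis.

FtsA is an actin-fold protein whose IC subdomain (the one unique among
actin homologues) swings relative to the IA/IIA/IIB core.  Two measures are
implemented:

* **principal axes** of a domain's main-chain (N, CA, C) atoms — the
  eigenvectors of the unit-mass second-moment (covariance) tensor of the
  centred coordinates, ordered by descending spatial extent.  The first
  axis, drawn as an arrow from the domain centroid, summarises domain
  orientation across structures;
* **hinge rotation** between two conformers — superpose on a fixed domain
  set, then measure the residual rigid rotation of the mobile domain (a
  simplified fixed/mobile two-body analysis; the open-vs-closed FtsA IC
  rotation measured this way is compared to the published 13.8 degrees).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .rigid import DegeneracyError, screw_decompose, superpose
from .structure import Selector, Structure, select_atoms

MAIN_CHAIN = ("N", "CA", "C")


@dataclasses.dataclass
class DomainDefinition:
    """Residue ranges (author numbering, inclusive) for each subdomain.

    ``ranges`` maps a domain name (IA, IB, IC, IIA, IIB) to a list of
    (first, last) residue-number ranges; ranges must not overlap between
    domains of the same definition.
    """
    ranges: dict[str, list[tuple[int, int]]]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: dict[int, str] = {}
        for name, ranges in self.ranges.items():
            self.ranges[name] = [(int(lo), int(hi)) for lo, hi in ranges]
            for lo, hi in self.ranges[name]:
                if hi < lo:
                    raise ValueError(f"{name}: inverted range {lo}-{hi}")
                for seq in range(lo, hi + 1):
                    if seq in seen:
                        raise ValueError(
                            f"residue {seq} assigned to both {seen[seq]} "
                            f"and {name}")
                    seen[seq] = name

    def residues(self, *names: str) -> list[int]:
        out: list[int] = []
        for name in names:
            if name not in self.ranges:
                raise KeyError(f"no domain named {name!r} "
                               f"(have {sorted(self.ranges)})")
            for lo, hi in self.ranges[name]:
                out.extend(range(lo, hi + 1))
        return sorted(set(out))

    def selector(self, chain_id: str, *names: str,
                 atom_names=MAIN_CHAIN) -> Selector:
        return Selector(chains=[chain_id],
                        residue_ranges=[(lo, hi)
                                        for n in names
                                        for lo, hi in self.ranges[n]],
                        atom_names=list(atom_names))


@dataclasses.dataclass
class PrincipalAxesResult:
    centroid: np.ndarray
    axes: np.ndarray       # rows, ordered by descending spatial extent
    moments: np.ndarray    # matching variances, descending
    degenerate: bool


@dataclasses.dataclass
class HingeResult:
    angle_deg: float
    axis: np.ndarray
    translation_A: float    # screw translation along the hinge axis
    fixed_domains: tuple[str, ...]
    mobile_domain: str
    rmsd_fixed: float
    n_fixed_atoms: int
    n_mobile_atoms: int


def principal_axes(coords: np.ndarray,
                   degeneracy_rtol: float = 0.01) -> PrincipalAxesResult:
    """Principal axes of a coordinate set under unit atom masses.

    Eigen-decomposition of the covariance of the centred coordinates; the
    first axis has the largest spatial extent.  Axis signs are fixed
    canonically (largest-magnitude component positive) — callers needing a
    sequence-anchored sign apply it on top (see :func:`domain_orientation`).
    Two moments within ``degeneracy_rtol`` of each other (or both
    vanishing, as for collinear points, whose transverse axes are
    arbitrary) set the degenerate flag.
    """
    X = np.asarray(coords, dtype=float).reshape(-1, 3)
    if len(X) < 3:
        raise DegeneracyError("principal_axes needs at least 3 points")
    centroid = X.mean(axis=0)
    Xc = X - centroid
    cov = Xc.T @ Xc / len(Xc)
    evals, evecs = np.linalg.eigh(cov)      # ascending
    order = np.argsort(evals)[::-1]
    moments = np.maximum(evals[order], 0.0)
    axes = evecs[:, order].T
    if moments[0] <= 0.0:
        raise DegeneracyError("all points coincide: principal axes "
                              "undefined")
    for i in range(3):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    # right-handed frame
    if np.dot(np.cross(axes[0], axes[1]), axes[2]) < 0:
        axes[2] = -axes[2]
    pairs = [(moments[0], moments[1]), (moments[1], moments[2])]
    degenerate = any(
        abs(a - b) <= degeneracy_rtol * max(a, b)
        or max(a, b) <= 1e-12 * moments[0]
        for a, b in pairs)
    return PrincipalAxesResult(centroid, axes, moments, degenerate)


def domain_orientation(s: Structure, chain_id: str,
                       domains: DomainDefinition, domain_name: str
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Oriented arrow (centroid, signed first principal axis) of a domain.

    Main-chain atoms only.  The axis sign is sequence-anchored: it points
    so that its dot product with (centroid of the C-terminal half of the
    domain's residues minus centroid of the N-terminal half) is
    non-negative, making arrows comparable across structures after
    whole-chain superposition.
    """
    residues = domains.residues(domain_name)
    chain = s.chain(chain_id)
    present = [r for r in residues if chain.residue(r) is not None]
    missing = sorted(set(residues) - set(present))
    if missing:
        raise KeyError(f"chain {chain_id}: domain {domain_name} residues "
                       f"missing: {missing}")
    cs = select_atoms(s, Selector(chains=[chain_id],
                                  residue_ranges=[(r, r) for r in present],
                                  atom_names=list(MAIN_CHAIN)))
    result = principal_axes(cs.coords)
    axis = result.axes[0].copy()
    half = len(present) // 2
    n_half = [r for r in present[:half]]
    c_half = [r for r in present[half:]]
    cen = {}
    for tag, nums in (("n", n_half), ("c", c_half)):
        mask = cs.table["seq_id"].isin(nums).to_numpy()
        cen[tag] = cs.coords[mask].mean(axis=0)
    if np.dot(axis, cen["c"] - cen["n"]) < 0:
        axis = -axis
    return result.centroid, axis


def hinge_rotation(s_a: Structure, chain_a: str, s_b: "Structure | None",
                   chain_b: str, domains: DomainDefinition,
                   fixed: tuple[str, ...], mobile: str,
                   atom_names=MAIN_CHAIN) -> HingeResult:
    """Hinge rotation of ``mobile`` between two conformers.

    Chain_b (from ``s_b``, or from ``s_a`` when ``s_b`` is None) is
    superposed onto chain_a over the main-chain atoms of the ``fixed``
    domains; the transform that then maps the (already fixed-aligned)
    mobile-domain atoms onto their counterparts is the hinge motion, whose
    rotation angle (in [0, 180]) and screw axis are reported.

    Only residues/atoms present in both chains are used; fewer than 3
    common atoms in either set is an error.
    """
    if s_b is None:
        s_b = s_a
    fixed_a, fixed_b = _matched_domain_coords(
        s_a, chain_a, s_b, chain_b, domains, fixed, atom_names)
    mob_a, mob_b = _matched_domain_coords(
        s_a, chain_a, s_b, chain_b, domains, (mobile,), atom_names)
    align, rmsd_fixed = superpose(fixed_b, fixed_a)
    hinge, _ = superpose(align.apply(mob_b), mob_a)
    screw = screw_decompose(hinge)
    return HingeResult(abs(screw.twist_deg), screw.direction,
                       abs(screw.rise), tuple(fixed), mobile, rmsd_fixed,
                       len(fixed_a), len(mob_a))


def _matched_domain_coords(s_a, chain_a, s_b, chain_b, domains,
                           names, atom_names):
    res = domains.residues(*names)
    A, B = [], []
    ch_a, ch_b = s_a.chain(chain_a), s_b.chain(chain_b)
    for seq in res:
        ra, rb = ch_a.residue(seq), ch_b.residue(seq)
        if ra is None or rb is None:
            continue
        for name in atom_names:
            aa, ab = ra.atom(name), rb.atom(name)
            if aa is not None and ab is not None:
                A.append(aa.coords)
                B.append(ab.coords)
    if len(A) < 3:
        raise DegeneracyError(
            f"domains {names}: only {len(A)} common atoms between "
            f"{chain_a} and {chain_b}")
    return np.asarray(A), np.asarray(B)
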