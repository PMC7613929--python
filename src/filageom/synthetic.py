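"""Synthetic ground-truth generators for every pipeline stage.

Pseudo-protomers (rigid, asymmetric arrangements of pseudo-residues
carrying standard N/CA/C/CB atom names) are placed on helices, rings, arcs
and antiparallel double filaments with exactly known screw parameters,
curvature and interface lists, so every analysis operation can be tested
against construction-time truth.  Gaussian coordinate noise and
binding-isotherm noise are seeded and reproducible.

Default construction parameters emulate the FtsA systems the analyses are
aimed at: a longitudinal repeat of 48 A (actin-like protofilament spacing),
mini-ring geometry of 13 subunits at ~100 A helical radius (a ~20 nm
centroid-path diameter), filament curvature radius 16.3 nm, and isotherm
truths of Kd 0.8 uM (single-site) and 0.016/11 uM (two-step) at 2 percent
response noise.
"""

from __future__ import annotations

import dataclasses
import json
import math

import numpy as np

from .binding import Isotherm, fp_anisotropy, spr_response
from .rigid import RigidTransform
from .structure import Atom, Chain, Residue, Structure

#: FtsA-like defaults (see module docstring)
DEFAULT_RISE_A = 48.0
RING_TWIST_DEG = 360.0 / 13.0
RING_RADIUS_A = 100.0
CURVATURE_RADIUS_NM = 16.3
SPR_TRUTH = {"Kd": 0.8, "Rmax": 100.0, "B": 5.0}
FP_TRUTH = {"F0": 0.05, "F_Lo": 0.08, "Kd_Lo": 0.016,
            "F_Hi": 0.06, "Kd_Hi": 11.0}
NOISE_FRACTION = 0.02

#: local atom offsets (A) from the CA position within each pseudo-residue;
#: chiral and irregular so protomers are never accidentally symmetric
_ATOM_OFFSETS = {
    "N": np.array([1.20, 0.45, -0.35]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([-0.95, 1.05, 0.25]),
    "CB": np.array([0.55, -1.15, 0.85]),
}
_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "CB": "C"}


@dataclasses.dataclass
class TruthRecord:
    """Everything needed to rebuild a synthetic input bit-exactly and to
    check any analysis of it."""
    kind: str
    seed: int
    params: dict

    def to_json(self, **kwargs) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, RigidTransform):
                return o.as_matrix34().tolist()
            raise TypeError(type(o))
        return json.dumps(dataclasses.asdict(self), default=default,
                          **kwargs)


def make_protomer(n_atoms: int = 120, seed: int = 0,
                  length: float = 58.0, width: float = 13.0,
                  depth: float = 7.5, cys_positions=()) -> Chain:
    """A rigid asymmetric pseudo-protomer of ``n_atoms // 4`` residues.

    Residues are threaded along a smooth, closed-ended 3-D curve spanning
    ``length`` A along z (the protofilament direction) whose transverse
    amplitudes ``width`` (y) and ``depth`` (x) differ from each other and
    from the length, guaranteeing pairwise-distinct principal moments.
    Both curve ends return to the z axis so that consecutive subunits of a
    filament with rise slightly below ``length`` make head-to-tail contact.
    The +y face carries two distinct contact patches (Gaussian ridges at
    43 and 84 percent of the length), emulating the two lateral contact
    surfaces of a filament subunit that touch the in-register (i*) and the
    offset (i*-1) subunit of an opposing protofilament.
    Every pseudo-residue carries N, CA, C and CB atoms (names chosen so all
    real-structure selectors work unchanged); ``cys_positions`` residues
    are named CYS (decoy endogenous cysteines), the rest ALA.
    """
    if n_atoms < 4:
        raise ValueError("make_protomer needs n_atoms >= 4")
    n_res = n_atoms // 4
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_res)
    # closed-ended asymmetric backbone curve with two lateral ridges
    x = depth * np.sin(np.pi * t) * (1.0 + 0.35 * np.sin(3 * np.pi * t))
    y = width * (np.exp(-((t - 0.431) / 0.12) ** 4)
                 + np.exp(-((t - 0.845) / 0.12) ** 4))
    z = length * t
    # small rigid per-residue jitter, fixed by the seed
    jitter = rng.normal(scale=0.35, size=(n_res, 3))
    backbone = np.column_stack([x, y, z]) + jitter

    cys = set(cys_positions)
    residues = []
    for i, ca in enumerate(backbone, start=1):
        name = "CYS" if i in cys else "ALA"
        atoms = [Atom(a, _ELEMENTS[a], ca + _ATOM_OFFSETS[a])
                 for a in ("N", "CA", "C", "CB")]
        residues.append(Residue(i, name, atoms))
    chain = Chain("P", residues)

    coords = chain.coords()
    cov = np.cov((coords - coords.mean(axis=0)).T)
    moments = np.sort(np.linalg.eigvalsh(cov))[::-1]
    if moments[0] - moments[1] < 0.05 * moments[0] \
            or moments[1] - moments[2] < 0.05 * moments[1]:
        raise RuntimeError("protomer construction produced near-degenerate "
                           "principal moments; change dimensions")
    return chain


def _place_chain(chain: Chain, transform: RigidTransform,
                 chain_id: str) -> Chain:
    import copy
    new = copy.deepcopy(chain)
    new.chain_id = chain_id
    for res in new.residues:
        for atom in res.atoms:
            atom.coords = transform.apply(atom.coords)
    return new


def screw_operator(twist_deg: float, rise: float,
                   axis=(0.0, 0.0, 1.0), point=(0.0, 0.0, 0.0)
                   ) -> RigidTransform:
    """The screw transform: rotate ``twist_deg`` about the axis through
    ``point`` along ``axis``, then translate ``rise`` along it."""
    d = np.asarray(axis, dtype=float)
    d = d / np.linalg.norm(d)
    from scipy.spatial.transform import Rotation
    R = Rotation.from_rotvec(d * math.radians(twist_deg)).as_matrix()
    p = np.asarray(point, dtype=float)
    t = rise * d + (np.eye(3) - R) @ p
    return RigidTransform(R, t)


def build_helical_filament(protomer: Chain, rise: float = DEFAULT_RISE_A,
                           twist_deg: float = RING_TWIST_DEG,
                           helical_radius: float = 0.0, n: int = 6,
                           seed: int = 0
                           ) -> tuple[Structure, TruthRecord]:
    """Place n copies of the protomer on a helix about the z axis.

    Subunit k sits at azimuth ``k*twist``, height ``k*rise``; the protomer
    centroid is first moved to ``(helical_radius, 0, 0)`` relative to its
    own centroid so the recovered helical radius equals the requested one
    exactly.  Chain ids are S0..S{n-1}.
    """
    if n < 2:
        raise ValueError("build_helical_filament needs n >= 2")
    centroid = protomer.coords().mean(axis=0)
    to_radius = RigidTransform(
        np.eye(3), np.array([helical_radius, 0.0, 0.0]) - centroid
        + np.array([0.0, 0.0, centroid[2]]))
    base = _place_chain(protomer, to_radius, "S0")
    op = screw_operator(twist_deg, rise)
    chains = [base]
    for k in range(1, n):
        chains.append(_place_chain(base, op.power(k), f"S{k}"))
    s = Structure(id="synthetic_helix", chains=chains)
    truth = TruthRecord("helical_filament", seed, {
        "twist_deg": twist_deg, "rise": rise,
        "helical_radius": helical_radius, "n": n,
        "axis_direction": [0.0, 0.0, 1.0], "axis_point": [0.0, 0.0, 0.0],
        "operator": op, "chain_order": [c.chain_id for c in chains],
        "longitudinal_pairs": [(f"S{k}", f"S{k+1}") for k in range(n - 1)],
    })
    return s, truth


def _brute_force_contacts(chain_a: Chain, chain_b: Chain,
                          cutoff: float = 4.5, min_pairs: int = 5) -> int:
    """Residue pairs within cutoff, by direct pairwise comparison (the
    slow, obviously-correct oracle used to enumerate true interfaces)."""
    n = 0
    for ra in chain_a.residues:
        xa = np.array([a.coords for a in ra.atoms])
        for rb in chain_b.residues:
            xb = np.array([a.coords for a in rb.atoms])
            d2 = ((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=2)
            if d2.min() <= cutoff * cutoff:
                n += 1
    return n


def build_double_filament(protomer: Chain, rise: float = DEFAULT_RISE_A,
                          n_per_protofilament: int = 3,
                          contact_gap: float = 2.6,
                          registry_shift: float = -8.0,
                          contact_cutoff: float = 4.5,
                          min_pairs: int = 5, seed: int = 0
                          ) -> tuple[Structure, TruthRecord]:
    """An antiparallel double filament with exact local C2 interfaces.

    Protofilament A is a straight stack (pure translation ``rise`` along
    z) of chains A0..A{n-1}; protofilament B is the exact 180-degree
    rotation of A about an axis parallel to x — so every chain pair swapped
    by that rotation has *exact* local C2 symmetry by construction.  The
    axis height centres B on A shifted by ``registry_shift`` A along z
    (the registry offset); its y position is tuned so the closest
    inter-protofilament atom gap equals ``contact_gap`` A, guaranteeing
    lateral contacts.  With the default shift the protomer's two lateral
    ridges engage both opposing registries, so each inner subunit contacts
    two subunits of the opposing protofilament (an in-register i-i* and an
    offset i-i*-1 interface), as in the FtsA double filament.

    The TruthRecord lists every true interface with its class, enumerated
    by brute-force residue-pair counting at construction time (independent
    of the detection pipeline's spatial indexing).
    """
    if n_per_protofilament < 2:
        raise ValueError("need n_per_protofilament >= 2")
    n = n_per_protofilament
    centroid = protomer.coords().mean(axis=0)
    center = RigidTransform(np.eye(3),
                            np.array([-centroid[0], -centroid[1], 0.0]))
    base = _place_chain(protomer, center, "A0")
    op = screw_operator(0.0, rise)
    chains_a = [base] + [_place_chain(base, op.power(k), f"A{k}")
                         for k in range(1, n)]

    coords_a = np.vstack([c.coords() for c in chains_a])
    z_min, z_max = coords_a[:, 2].min(), coords_a[:, 2].max()
    zc = (z_min + z_max) / 2.0 + registry_shift / 2.0
    y_max = coords_a[:, 1].max()

    def c2_about(y0: float) -> RigidTransform:
        # 180 deg about the x-parallel axis through (*, y0, zc)
        R = np.diag([1.0, -1.0, -1.0])
        t = np.array([0.0, 2 * y0, 2 * zc])
        return RigidTransform(R, t)

    # choose the axis height so the nearest A-B atom gap equals contact_gap;
    # a shift dy of the axis moves B rigidly by 2*dy in y
    y0 = y_max + contact_gap / 2.0
    for _ in range(4):
        c2 = c2_about(y0)
        chains_b = [_place_chain(c, c2, c.chain_id.replace("A", "B"))
                    for c in chains_a]
        gap = _min_gap(chains_a, chains_b)
        if abs(gap - contact_gap) < 1e-9:
            break
        y0 += (contact_gap - gap) / 2.0
    c2 = c2_about(y0)
    chains_b = [_place_chain(c, c2, c.chain_id.replace("A", "B"))
                for c in chains_a]

    s = Structure(id="synthetic_double_filament",
                  chains=chains_a + chains_b)

    # construction-time truth: brute-force interface enumeration
    interfaces = []
    for k in range(n - 1):
        interfaces.append(((f"A{k}", f"A{k+1}"), "longitudinal"))
        interfaces.append(((f"B{k}", f"B{k+1}"), "longitudinal"))
    all_chains = {c.chain_id: c for c in s.chains}
    lateral = []
    for i in range(n):
        for j in range(n):
            npairs = _brute_force_contacts(all_chains[f"A{i}"],
                                           all_chains[f"B{j}"],
                                           contact_cutoff, min_pairs)
            if npairs >= min_pairs:
                # registry offset along z between the two centroids
                za = all_chains[f"A{i}"].centroid()[2]
                zb = all_chains[f"B{j}"].centroid()[2]
                offset = abs(za - zb)
                sub = "lateral_i_istar" if offset <= rise / 4.0 \
                    else "lateral_i_istar_minus1"
                lateral.append(((f"A{i}", f"B{j}"), sub))
    interfaces.extend(lateral)
    # C2-swapped partners: Bk is the image of Ak, so its z-order is
    # reversed and the in-register (contacting) partner of Ai is B{n-1-i};
    # each such dimer is exactly C2-symmetric under the involution
    # c2 o (longitudinal shift)
    truth = TruthRecord("double_filament", seed, {
        "rise": rise, "n_per_protofilament": n,
        "contact_gap": contact_gap, "registry_shift": registry_shift,
        "c2_axis_direction": [1.0, 0.0, 0.0],
        "c2_axis_point": [0.0, y0, zc],
        "c2_operator": c2,
        "protofilaments": [[f"A{k}" for k in range(n)],
                           [f"B{k}" for k in range(n)]],
        "c2_pairs": [(f"A{k}", f"B{n-1-k}") for k in range(n)],
        "interfaces": interfaces,
    })
    return s, truth


def _min_gap(chains_a, chains_b) -> float:
    xa = np.vstack([c.coords() for c in chains_a])
    xb = np.vstack([c.coords() for c in chains_b])
    from scipy.spatial import cKDTree
    d, _ = cKDTree(xb).query(xa, k=1)
    return float(d.min())


def build_arc_filament(protomer: Chain,
                       curvature_radius_nm: float = CURVATURE_RADIUS_NM,
                       spacing: float = DEFAULT_RISE_A, n: int = 6,
                       seed: int = 0) -> tuple[Structure, TruthRecord]:
    """Subunits whose centroids lie exactly on a circular arc.

    The circle of radius ``curvature_radius_nm`` lies in the xy plane,
    centred at the origin; subunit k is the protomer rotated rigidly about
    the circle axis by ``k * spacing / R`` radians, with its centroid on
    the circle.  Models a filament bent along its axis.
    """
    if n < 3:
        raise ValueError("build_arc_filament needs n >= 3")
    R = curvature_radius_nm * 10.0
    if spacing >= 2 * math.pi * R:
        raise ValueError("spacing exceeds the circumference")
    centroid = protomer.coords().mean(axis=0)
    # centroid on the circle, long axis (local z) along the tangent (global
    # y at the starting point), ridges (local y) out of plane
    align = RigidTransform(
        np.array([[-1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [0.0, 1.0, 0.0]]),
        np.zeros(3))
    shifted = RigidTransform(np.eye(3),
                             np.array([R, 0.0, 0.0]) - align.apply(centroid))
    base = _place_chain(protomer, shifted.compose(align), "S0")
    dtheta = math.degrees(spacing / R)
    chains = [base]
    for k in range(1, n):
        rot = screw_operator(k * dtheta, 0.0, axis=(0, 0, 1))
        chains.append(_place_chain(base, rot, f"S{k}"))
    s = Structure(id="synthetic_arc", chains=chains)
    truth = TruthRecord("arc_filament", seed, {
        "curvature_radius_nm": curvature_radius_nm, "spacing": spacing,
        "n": n, "center": [0.0, 0.0, 0.0], "plane_normal": [0.0, 0.0, 1.0],
        "arc_step_deg": dtheta,
    })
    return s, truth


def perturb(s: Structure, sigma: float, seed: int = 0) -> Structure:
    """Add i.i.d. Gaussian displacement (std ``sigma`` A per coordinate)
    to every atom; deterministic under the seed."""
    rng = np.random.default_rng(seed)
    out = s.copy()
    for chain in out.chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom.coords = atom.coords + rng.normal(scale=sigma, size=3)
    return out


def simulate_isotherm(model: str, params: dict | None = None,
                      concentrations=None, noise_sigma: float | None = None,
                      seed: int = 0) -> tuple[Isotherm, TruthRecord]:
    """Draw a binding isotherm from the single-site (``eq1``) or two-step
    (``eq3``) forward model with additive Gaussian response noise.

    Defaults reproduce the titration designs of the source experiments:
    12-point 1:2 dilution series from 10 uM (single-site) or from 40 uM
    (two-step), truths ``SPR_TRUTH`` / ``FP_TRUTH``, noise 2 percent of
    the response range.
    """
    rng = np.random.default_rng(seed)
    if model == "eq1":
        p = dict(SPR_TRUTH) if params is None else dict(params)
        if concentrations is None:
            concentrations = 10.0 / 2.0 ** np.arange(12)[::-1]
        y = spr_response(np.asarray(concentrations, dtype=float), **p)
    elif model == "eq3":
        p = dict(FP_TRUTH) if params is None else dict(params)
        if concentrations is None:
            concentrations = 40.0 / 2.0 ** np.arange(16)[::-1]
        y = fp_anisotropy(np.asarray(concentrations, dtype=float), **p)
    else:
        raise ValueError(f"unknown model {model!r} (use eq1/eq3)")
    x = np.asarray(concentrations, dtype=float)
    sigma = noise_sigma
    if sigma is None:
        sigma = NOISE_FRACTION * float(np.ptp(y))
    y_noisy = y + rng.normal(scale=sigma, size=len(y)) if sigma > 0 else y
    truth = TruthRecord(model, seed, {
        "params": p, "noise_sigma": sigma,
        "concentrations": list(map(float, x)),
    })
    return Isotherm(x, y_noisy), truth
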