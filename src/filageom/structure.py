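"""Atomic coordinate models: reading, writing, selection and transformation.

A thin hierarchy (Structure -> Chain -> Residue -> Atom) tailored to
quaternary-geometry analysis.  File I/O is delegated to gemmi; the hierarchy
here keeps only what the downstream geometry needs: author numbering,
heavy-atom coordinates in Angstrom, per-chain polymer flags and any symmetry
operators carried by the file.

Conventions applied on reading:

* hydrogens (and deuteriums) are dropped;
* waters are dropped;
* alternate locations are resolved by keeping the highest-occupancy
  conformer (ties broken by the lexicographically first altloc tag).
"""

from __future__ import annotations

import dataclasses
import logging
import re
import warnings
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .rigid import DegeneracyError, RigidTransform, superpose

logger = logging.getLogger(__name__)

#: canonical intra-residue atom ordering used for deterministic output
_ATOM_ORDER = {"N": 0, "CA": 1, "C": 2, "O": 3, "CB": 4}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class ParseError(ValueError):
    """Raised when a coordinate file cannot be read."""


class FormatError(ValueError):
    """Raised for an unknown or unsupported file format."""


class LookupError_(KeyError):
    """Raised when a selection references an absent chain or residue."""


class SelectionError(ValueError):
    """Raised for a malformed selection expression."""


class ChainLimitError(ValueError):
    """Raised when a structure cannot be represented in the target format."""


@dataclasses.dataclass
class Atom:
    """A heavy atom: name (e.g. ``CA``), element, coordinates in Angstrom."""
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")


@dataclasses.dataclass
class Residue:
    """A residue identified by author number + insertion code."""
    seq_id: int
    name: str
    atoms: list[Atom] = dataclasses.field(default_factory=list)
    icode: str = ""

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def label(self) -> str:
        return f"{self.seq_id}{self.icode}"


@dataclasses.dataclass
class Chain:
    """An ordered run of residues under one author chain id."""
    chain_id: str
    residues: list[Residue] = dataclasses.field(default_factory=list)
    is_polymer: bool = True

    def residue(self, seq_id: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.seq_id == seq_id and r.icode == icode:
                return r
        return None

    @property
    def seq_ids(self) -> list[int]:
        return [r.seq_id for r in self.residues]

    def coords(self, atom_names=None) -> np.ndarray:
        out = []
        for r in self.residues:
            for a in r.atoms:
                if atom_names is None or a.name in atom_names:
                    out.append(a.coords)
        return np.array(out).reshape(-1, 3)

    def centroid(self, atom_names=None) -> np.ndarray:
        c = self.coords(atom_names)
        if len(c) == 0:
            raise ValueError(f"chain {self.chain_id}: no atoms for centroid")
        return c.mean(axis=0)


@dataclasses.dataclass
class Structure:
    """A collection of chains plus any symmetry operators from the file."""
    id: str = ""
    chains: list[Chain] = dataclasses.field(default_factory=list)
    symmetry_ops: list[RigidTransform] = dataclasses.field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise LookupError_(f"no chain {chain_id!r} in structure {self.id!r}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def polymer_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.is_polymer]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def copy(self) -> "Structure":
        import copy as _copy
        return _copy.deepcopy(self)


@dataclasses.dataclass
class CoordSet:
    """A coordinate matrix with per-row provenance.

    ``table`` has columns chain, seq_id, icode, res_name, atom_name, element
    aligned row-for-row with ``coords``.
    """
    coords: np.ndarray
    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.coords)

    def transformed(self, t: RigidTransform) -> "CoordSet":
        return CoordSet(t.apply(self.coords), self.table.copy())


# ---------------------------------------------------------------------------
# reading


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep, per atom name, the highest-occupancy altloc (ties: first tag)."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name in order:
        group = sorted(by_name[name], key=lambda a: (-a.occupancy, a.altloc))
        out.append(group[0])
    return out


def _is_amino(res_name: str) -> bool:
    info = gemmi.find_tabulated_residue(res_name)
    if info is not None and info.is_amino_acid():
        return True
    # unknown three-letter codes (e.g. UNK poly-Ala stand-ins) count as polymer
    return res_name == "UNK"


def _transform_from_gemmi(tr: gemmi.Transform) -> RigidTransform:
    return RigidTransform(np.array(tr.mat.tolist()), np.array(tr.vec.tolist()))


def _collect_symmetry_ops(st: gemmi.Structure) -> list[RigidTransform]:
    ops: list[RigidTransform] = []
    for ncs in st.ncs:
        ops.append(_transform_from_gemmi(ncs.tr))
    for assembly in st.assemblies:
        for gen in assembly.generators:
            for oper in gen.operators:
                t = _transform_from_gemmi(oper.transform)
                if not (np.allclose(t.rotation, np.eye(3), atol=1e-9)
                        and np.allclose(t.translation, 0, atol=1e-9)):
                    ops.append(t)
        break  # first (author-preferred) assembly only
    return ops


def read_structure(path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Hydrogens and waters are dropped and altlocs resolved; symmetry
    operators present in the file header (NCS or first-assembly generators)
    are retained in ``symmetry_ops``.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file does not exist")
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: empty file")
    fmt = format.lower()
    if fmt == "auto":
        suffix = path.suffix.lower()
        if suffix in {".pdb", ".ent"}:
            fmt = "pdb"
        elif suffix in {".cif", ".mmcif"}:
            fmt = "mmcif"
        else:
            raise FormatError(f"cannot infer format from suffix {suffix!r}")
    if fmt not in {"pdb", "mmcif"}:
        raise FormatError(f"unknown format {format!r} (use pdb/mmcif/auto)")

    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc

    st.setup_entities()
    model = st[0]
    out = Structure(id=st.name or path.stem,
                    symmetry_ops=_collect_symmetry_ops(st))
    for gchain in model:
        residues: list[Residue] = []
        any_amino = False
        for gres in gchain:
            if gres.name in _WATER_NAMES:
                continue
            atoms = [Atom(a.name, a.element.name, [a.pos.x, a.pos.y, a.pos.z],
                          float(a.occ), a.altloc or "")
                     for a in gres if a.element.name not in ("H", "D")]
            atoms = _resolve_altlocs(atoms)
            if not atoms:
                continue
            residues.append(Residue(gres.seqid.num, gres.name, atoms,
                                    gres.seqid.icode.strip()))
            any_amino = any_amino or _is_amino(gres.name)
        if residues:
            out.chains.append(Chain(gchain.name, residues,
                                    is_polymer=any_amino))
    if not out.chains:
        raise ParseError(f"{path}: no non-water atoms found")
    return out


# ---------------------------------------------------------------------------
# selection

_RANGE_RE = re.compile(r"^(-?\d+)(?:-(-?\d+))?$")


def _parse_ranges(text: str) -> list[tuple[int, int]]:
    ranges = []
    for part in text.split(","):
        m = _RANGE_RE.match(part.strip())
        if not m:
            raise SelectionError(f"bad residue range {part!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) is not None else lo
        if hi < lo:
            raise SelectionError(f"inverted residue range {part!r}")
        ranges.append((lo, hi))
    return ranges


@dataclasses.dataclass
class Selector:
    """A structured selection: chains, residue ranges and atom names.

    ``None`` means "no restriction".  The equivalent string syntax accepted
    by :func:`select_atoms` joins clauses with ``and``::

        "chain A and resi 10-50,60 and name N,CA,C"
    """
    chains: list[str] | None = None
    residue_ranges: list[tuple[int, int]] | None = None
    atom_names: list[str] | None = None

    @classmethod
    def parse(cls, expr: str) -> "Selector":
        sel = cls()
        expr = expr.strip()
        if not expr or expr.lower() == "all":
            return sel
        for clause in re.split(r"\s+and\s+", expr):
            clause = clause.strip()
            m = re.match(r"^(chain|resi|name)\s+(.+)$", clause)
            if not m:
                raise SelectionError(f"cannot parse clause {clause!r}")
            key, val = m.group(1), m.group(2)
            if key == "chain":
                sel.chains = [c.strip() for c in val.split(",") if c.strip()]
            elif key == "resi":
                sel.residue_ranges = _parse_ranges(val)
            else:
                sel.atom_names = [a.strip().upper() for a in val.split(",")
                                  if a.strip()]
        return sel

    def _residue_ok(self, seq_id: int) -> bool:
        if self.residue_ranges is None:
            return True
        return any(lo <= seq_id <= hi for lo, hi in self.residue_ranges)


def select_atoms(s: Structure, selector: "Selector | str | None" = None,
                 polymer_only: bool = True) -> CoordSet:
    """Select atoms into a :class:`CoordSet`.

    Rows come out ordered by (chain, seq_id, insertion code, canonical atom
    order), so the same selector on the same structure always yields the
    same rows in the same order.  An empty selection is allowed but warned
    about.  Referencing an absent chain raises a lookup error.
    """
    if selector is None:
        sel = Selector()
    elif isinstance(selector, str):
        sel = Selector.parse(selector)
    else:
        sel = selector

    if sel.chains is not None:
        known = set(s.chain_ids)
        missing = [c for c in sel.chains if c not in known]
        if missing:
            raise LookupError_(
                f"selection references absent chain(s) {missing} "
                f"(structure has {sorted(known)})")

    rows, coords = [], []
    for chain in sorted(s.chains, key=lambda c: c.chain_id):
        if polymer_only and not chain.is_polymer:
            continue
        if sel.chains is not None and chain.chain_id not in sel.chains:
            continue
        for res in sorted(chain.residues, key=lambda r: (r.seq_id, r.icode)):
            if not sel._residue_ok(res.seq_id):
                continue
            atoms = sorted(res.atoms,
                           key=lambda a: (_ATOM_ORDER.get(a.name, 99), a.name))
            for atom in atoms:
                if sel.atom_names is not None and atom.name not in sel.atom_names:
                    continue
                rows.append((chain.chain_id, res.seq_id, res.icode,
                             res.name, atom.name, atom.element))
                coords.append(atom.coords)
    if not rows:
        warnings.warn("selection matched no atoms", stacklevel=2)
    table = pd.DataFrame(rows, columns=["chain", "seq_id", "icode",
                                        "res_name", "atom_name", "element"])
    return CoordSet(np.array(coords, dtype=float).reshape(-1, 3), table)


# ---------------------------------------------------------------------------
# transforms and assembly expansion


def apply_transform(obj, t: RigidTransform):
    """Apply a proper rigid transform to a Structure or CoordSet.

    Returns a new object of the same shape; all pairwise distances are
    preserved (the transform constructor rejects improper rotations).
    """
    if isinstance(obj, CoordSet):
        return obj.transformed(t)
    if isinstance(obj, Structure):
        out = obj.copy()
        for chain in out.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    atom.coords = t.apply(atom.coords)
        out.symmetry_ops = list(obj.symmetry_ops)
        return out
    raise TypeError(f"cannot transform object of type {type(obj).__name__}")


def expand_assembly(s: Structure, ops: list[RigidTransform],
                    copies: int = 1) -> Structure:
    """Generate symmetry copies of every chain.

    For each operator ``ops[j]`` and each power ``c`` in ``1..copies`` the
    cumulative operator ``ops[j]**c`` is applied to every original chain.
    Generated chains get deterministic ids ``{source}~{j}.{c}`` recording
    (source chain, operator index, copy index); originals are untouched.
    Chain-id collisions are renamed (never silently overwritten) and logged.
    """
    if not ops:
        raise ValueError("expand_assembly: empty operator list")
    if copies < 1:
        raise ValueError("expand_assembly: copies must be >= 1")
    out = s.copy()
    existing = set(out.chain_ids)
    for j, op in enumerate(ops):
        cumulative = RigidTransform.identity()
        for c in range(1, copies + 1):
            cumulative = op.compose(cumulative)
            for chain in s.chains:
                new_id = f"{chain.chain_id}~{j}.{c}"
                while new_id in existing:
                    renamed = new_id + "'"
                    logger.warning("chain id collision: %s renamed to %s",
                                   new_id, renamed)
                    new_id = renamed
                existing.add(new_id)
                import copy as _copy
                new_chain = _copy.deepcopy(chain)
                new_chain.chain_id = new_id
                for res in new_chain.residues:
                    for atom in res.atoms:
                        atom.coords = cumulative.apply(atom.coords)
                out.chains.append(new_chain)
    return out


def matched_coordinates(s: Structure, chain_a: str, chain_b: str,
                        selector: "Selector | str | None" = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of the selected atoms common to two chains, matched on
    (seq_id, icode, atom name).  Fewer than 3 common atoms is an error."""
    sel_a = _restrict_selector(selector, chain_a)
    sel_b = _restrict_selector(selector, chain_b)
    ca = select_atoms(s, sel_a)
    cb = select_atoms(s, sel_b)
    key_cols = ["seq_id", "icode", "atom_name"]
    ta = ca.table.assign(_row=np.arange(len(ca.table)))
    tb = cb.table.assign(_row=np.arange(len(cb.table)))
    merged = ta.merge(tb, on=key_cols, suffixes=("_a", "_b"))
    logger.info("chains %s/%s: %d common selected atoms",
                chain_a, chain_b, len(merged))
    if len(merged) < 3:
        raise DegeneracyError(
            f"chains {chain_a}/{chain_b}: only {len(merged)} common atoms")
    return (ca.coords[merged["_row_a"].to_numpy()],
            cb.coords[merged["_row_b"].to_numpy()])


def transform_between_subunits(s: Structure, chain_a: str, chain_b: str,
                               selector: "Selector | str | None" = None
                               ) -> tuple[RigidTransform, float]:
    """Rigid transform mapping chain_a onto chain_b over common residues.

    The selected atoms of both chains are matched on (seq_id, icode,
    atom name); the intersection is used and its size logged.
    """
    A, B = matched_coordinates(s, chain_a, chain_b, selector)
    return superpose(A, B)


def filament_screw(s: Structure, chain_order: list[str],
                   selector: "Selector | str | None" = None,
                   refine: bool = True) -> tuple[RigidTransform, float]:
    """The common subunit-to-subunit operator of a filament, estimated
    jointly from the whole filament.

    All matched (chain k, chain k+1) coordinate pairs are first stacked
    into a single superposition.  With ``refine`` (default) the estimate
    is then polished by nonlinear least squares over all ordered chain
    pairs (j, k) under the power constraint ``chain_k ~ g**(k-j)
    (chain_j)``, which pins the screw axis with the full filament as the
    lever arm — with noisy coordinates this is far more stable than any
    single neighbour transform, especially for the axis direction and
    position.  Returns the operator and the RMSD of the stacked
    consecutive-pair superposition.
    """
    if len(chain_order) < 2:
        raise ValueError("filament_screw needs at least 2 chains")
    A, B = [], []
    for a, b in zip(chain_order, chain_order[1:]):
        xa, xb = matched_coordinates(s, a, b, selector)
        A.append(xa)
        B.append(xb)
    g0, rmsd = superpose(np.vstack(A), np.vstack(B))
    if not refine or len(chain_order) == 2:
        return g0, rmsd

    from scipy.optimize import least_squares
    from scipy.spatial.transform import Rotation
    pairs = []
    for j in range(len(chain_order)):
        for k in range(j + 1, len(chain_order)):
            xa, xb = matched_coordinates(s, chain_order[j], chain_order[k],
                                         selector)
            pairs.append((k - j, xa, xb))

    def residuals(x):
        g = RigidTransform(Rotation.from_rotvec(x[:3]).as_matrix(), x[3:])
        return np.concatenate([(g.power(step).apply(xa) - xb).ravel()
                               for step, xa, xb in pairs])

    x0 = np.concatenate([Rotation.from_matrix(g0.rotation).as_rotvec(),
                         g0.translation])
    fit = least_squares(residuals, x0, method="lm")
    g = RigidTransform(Rotation.from_rotvec(fit.x[:3]).as_matrix(),
                       fit.x[3:])
    return g, rmsd


def _restrict_selector(selector, chain_id: str) -> Selector:
    if selector is None:
        sel = Selector()
    elif isinstance(selector, str):
        sel = Selector.parse(selector)
    else:
        sel = dataclasses.replace(selector)
    sel.chains = [chain_id]
    return sel


# ---------------------------------------------------------------------------
# writing

_PDB_CHAIN_ALPHABET = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
                       "abcdefghijklmnopqrstuvwxyz0123456789")


def _to_gemmi(s: Structure, chain_id_map: dict[str, str] | None = None
              ) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.id or "model"
    model = gemmi.Model("1")
    for chain in s.chains:
        name = chain.chain_id if chain_id_map is None else chain_id_map[chain.chain_id]
        gchain = gemmi.Chain(name)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, res.icode or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = atom.occupancy
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(s: Structure, path, format: str = "auto",
                    strict_chain_limit: bool = True) -> dict[str, str]:
    """Write a structure to PDB or mmCIF.

    PDB chain ids are single characters; long derived ids are remapped
    deterministically and the mapping returned.  More than 62 chains cannot
    be written as PDB: with ``strict_chain_limit`` this raises, otherwise
    the format silently switches to mmCIF.

    Returns the chain-id mapping used ({original: written}).
    """
    if not s.chains:
        raise ValueError("refusing to write an empty structure")
    path = Path(path)
    fmt = format.lower()
    if fmt == "auto":
        fmt = "pdb" if path.suffix.lower() in {".pdb", ".ent"} else "mmcif"
    if fmt not in {"pdb", "mmcif"}:
        raise FormatError(f"unknown format {format!r}")

    mapping = {c: c for c in s.chain_ids}
    if fmt == "pdb":
        needs_map = any(len(c) != 1 for c in s.chain_ids) \
            or len(s.chains) > len(set(s.chain_ids))
        if len(s.chains) > 62:
            if strict_chain_limit:
                raise ChainLimitError(
                    f"{len(s.chains)} chains exceed the 62-chain PDB limit; "
                    "write mmCIF instead")
            fmt = "mmcif"
        elif needs_map:
            mapping = {c: _PDB_CHAIN_ALPHABET[i]
                       for i, c in enumerate(s.chain_ids)}

    st = _to_gemmi(s, mapping)
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        doc = st.make_mmcif_document()
        doc.write_file(str(path))
    return mapping
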