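"""Rigid-body geometry: least-squares superposition and screw decomposition.

Any proper rigid transform ``x -> R x + t`` is equivalent to a rotation by a
twist angle about a unique axis in space combined with a translation (rise)
along that axis.  Repeated application of such a screw operator traces a
helix, which is why the decomposition is the workhorse of filament analysis:
the subunit-to-subunit operator of a protofilament immediately yields its
helical twist and rise.

Sign convention
---------------
The pair ``(direction, twist)`` is only defined up to a simultaneous flip
``(d, theta, rise) -> (-d, -theta, -rise)``.  We resolve the ambiguity
deterministically: the axis direction is chosen so that the rise is
non-negative whenever it is non-zero; for pure rotations (rise ~ 0) the
direction is chosen so that the twist is non-negative.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.transform import Rotation

#: below these magnitudes a twist / rise is treated as exactly zero
TWIST_ZERO_TOL_DEG = 1e-6
RISE_ZERO_TOL_A = 1e-6


class DegeneracyError(ValueError):
    """Raised when a superposition problem is geometrically degenerate."""


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """A proper rigid-body transform ``x -> rotation @ x + translation``.

    Parameters
    ----------
    rotation : (3, 3) ndarray
        Proper orthogonal matrix (determinant +1).
    translation : (3,) ndarray
        Translation vector in Angstrom.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("non-finite entries in rigid transform")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("improper rotation (determinant -1): reflections "
                             "are not rigid-body transforms")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec_deg, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from an axis-angle rotation vector given in degrees."""
        R = Rotation.from_rotvec(np.asarray(rotvec_deg, dtype=float),
                                 degrees=True).as_matrix()
        return cls(R, np.asarray(translation, dtype=float))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) coordinate array (or a single 3-vector)."""
        xyz = np.asarray(coords, dtype=float)
        return xyz @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self o other`` (apply *other* first, then *self*)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def power(self, n: int) -> "RigidTransform":
        """n-fold repeated application (n >= 0)."""
        out = RigidTransform.identity()
        for _ in range(int(n)):
            out = self.compose(out)
        return out

    @property
    def angle_deg(self) -> float:
        """Magnitude of the rotation angle in degrees, in [0, 180]."""
        return float(np.degrees(
            Rotation.from_matrix(self.rotation).magnitude()))

    def as_matrix34(self) -> np.ndarray:
        return np.hstack([self.rotation, self.translation[:, None]])

    @classmethod
    def from_matrix34(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float).reshape(3, 4)
        return cls(m[:, :3], m[:, 3])


@dataclasses.dataclass(frozen=True)
class ScrewAxis:
    """Screw decomposition of a rigid transform.

    Attributes
    ----------
    direction : unit 3-vector along the screw axis.
    point : a point on the axis (the one closest to the origin), Angstrom.
    twist_deg : rotation about the axis in degrees, in (-180, 180].
    rise : signed translation along the axis in Angstrom.
    pure_translation : True when the twist is below tolerance; the axis
        direction is then taken along the translation and ``point`` is
        arbitrary (the origin's perpendicular projection).
    """

    direction: np.ndarray
    point: np.ndarray
    twist_deg: float
    rise: float
    pure_translation: bool = False

    @property
    def subunits_per_turn(self) -> float:
        if abs(self.twist_deg) < TWIST_ZERO_TOL_DEG:
            return float("inf")
        return 360.0 / abs(self.twist_deg)

    def to_transform(self) -> RigidTransform:
        """Recompose the screw parameters into the rigid transform."""
        d = np.asarray(self.direction, dtype=float)
        R = Rotation.from_rotvec(d * np.radians(self.twist_deg)).as_matrix()
        p = np.asarray(self.point, dtype=float)
        t = self.rise * d + (np.eye(3) - R) @ p
        return RigidTransform(R, t)

    def distance_to_axis(self, xyz: np.ndarray) -> np.ndarray:
        """Perpendicular distance of point(s) from the screw axis, Angstrom."""
        v = np.atleast_2d(np.asarray(xyz, dtype=float)) - self.point
        perp = v - np.outer(v @ self.direction, self.direction)
        dist = np.linalg.norm(perp, axis=1)
        return dist if np.asarray(xyz).ndim > 1 else float(dist[0])


def _canonical_direction(d: np.ndarray) -> np.ndarray:
    """Fix the sign of an ambiguous axis: largest-|component| made positive."""
    i = int(np.argmax(np.abs(d)))
    return -d if d[i] < 0 else d


def screw_decompose(t: RigidTransform,
                    twist_tol_deg: float = TWIST_ZERO_TOL_DEG,
                    rise_tol: float = RISE_ZERO_TOL_A) -> ScrewAxis:
    """Decompose a rigid transform into screw (axis, twist, rise) form.

    Degenerate cases are flagged, never raised: the identity and pure
    translations come back with ``pure_translation=True`` and zero twist.
    """
    rot = Rotation.from_matrix(t.rotation)
    rotvec = rot.as_rotvec()
    theta = float(np.linalg.norm(rotvec))
    trans = t.translation

    if np.degrees(theta) < twist_tol_deg:
        # no rotation: axis along the translation (or z for the identity)
        norm = float(np.linalg.norm(trans))
        if norm < rise_tol:
            return ScrewAxis(np.array([0.0, 0.0, 1.0]), np.zeros(3),
                             0.0, 0.0, pure_translation=True)
        d = trans / norm
        return ScrewAxis(d, np.zeros(3), 0.0, norm, pure_translation=True)

    d = rotvec / theta
    twist = float(np.degrees(theta))  # in (0, 180]
    rise = float(trans @ d)

    # sign convention: rise >= 0 when nonzero, else twist >= 0
    if rise < -rise_tol:
        d, twist, rise = -d, -twist, -rise
    elif abs(rise) <= rise_tol:
        rise = abs(rise) if rise > 0 else 0.0
        if twist < 0:
            d, twist = -d, -twist
        if twist > 180.0 - 1e-12:
            # 180-degree rotations: both directions give twist 180
            d = _canonical_direction(d)
    if twist <= -180.0:
        twist += 360.0

    # axis point: minimal-norm solution of (I - R) p = t_perp, p _|_ d
    t_perp = trans - rise * d
    p, *_ = np.linalg.lstsq(np.eye(3) - t.rotation, t_perp, rcond=None)
    p = p - (p @ d) * d
    return ScrewAxis(d, p, twist, rise, pure_translation=False)


def superpose(moving: np.ndarray, fixed: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition (Kabsch) of *moving* onto *fixed*.

    Returns the proper rigid transform minimising the RMSD between
    ``transform.apply(moving)`` and ``fixed``, together with that RMSD.

    Raises
    ------
    DegeneracyError
        For mismatched row counts, fewer than 3 points, or collinear points.
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(fixed, dtype=float)
    if P.ndim != 2 or Q.ndim != 2 or P.shape[1] != 3 or Q.shape[1] != 3:
        raise DegeneracyError("coordinate sets must be (n, 3) arrays")
    if P.shape[0] != Q.shape[0]:
        raise DegeneracyError(
            f"row-count mismatch: {P.shape[0]} vs {Q.shape[0]}")
    if P.shape[0] < 3:
        raise DegeneracyError("need at least 3 points for superposition")

    cm, cf = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cm, Q - cf
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2:
        raise DegeneracyError("moving points are collinear")

    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum(
        (transform.apply(P) - Q) ** 2, axis=1))))
    return transform, rmsd


def read_operators(path) -> list[RigidTransform]:
    """Read rigid transforms from a plain-text operator file.

    Each operator is a 3x4 block (rotation | translation), rows on separate
    lines, 4 whitespace-separated numbers each; blocks separated by blank
    lines or ``#`` comment lines.
    """
    ops: list[RigidTransform] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                if len(rows) == 3:
                    ops.append(RigidTransform.from_matrix34(np.array(rows)))
                    rows = []
                elif rows:
                    raise ValueError(
                        f"operator block with {len(rows)} rows (expected 3)")
                continue
            vals = [float(x) for x in line.split()]
            if len(vals) != 4:
                raise ValueError(f"expected 4 numbers per row, got: {line!r}")
            rows.append(vals)
    if len(rows) == 3:
        ops.append(RigidTransform.from_matrix34(np.array(rows)))
    elif rows:
        raise ValueError(f"trailing operator block with {len(rows)} rows")
    return ops


def write_operators(ops, path) -> None:
    """Write rigid transforms as 3x4 text blocks (inverse of read_operators)."""
    with open(path, "w") as fh:
        for op in ops:
            for row in op.as_matrix34():
                fh.write(" ".join(f"{v: .9f}" for v in row) + "\n")
            fh.write("\n")
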