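"""Helical parameters, ring closure, symmetry expansion and curvature.

The subunit-to-subunit screw operator of a protofilament defines its helical
lattice: twist (rotation per subunit), rise (axial translation per subunit)
and helical radius (distance of a subunit centroid from the screw axis).
When an integer number of subunits n brings the accumulated twist to ~360
degrees with negligible accumulated rise, repeated application closes into a
ring of n subunits ("mini-rings": 12-13 subunits for FtsA); otherwise it
traces an open helix.  Filament bending is quantified separately by fitting
a circle to subunit centroids (radius of curvature).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy.optimize import least_squares

from .rigid import RISE_ZERO_TOL_A, TWIST_ZERO_TOL_DEG, RigidTransform, \
    ScrewAxis, screw_decompose
from .structure import Structure, expand_assembly

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class HelicalParams:
    """Helical lattice parameters of a subunit-to-subunit operator."""
    twist_deg: float
    rise: float              # Angstrom
    helical_radius: float    # Angstrom, centroid distance from the axis
    axis: ScrewAxis
    degenerate: bool = False  # identity / pure-translation operator

    @property
    def subunits_per_turn(self) -> float:
        if abs(self.twist_deg) < TWIST_ZERO_TOL_DEG:
            return float("inf")
        return 360.0 / abs(self.twist_deg)

    @property
    def handedness(self) -> str:
        if abs(self.twist_deg) < TWIST_ZERO_TOL_DEG \
                or abs(self.rise) < RISE_ZERO_TOL_A:
            return "none"
        return "right" if self.twist_deg * self.rise > 0 else "left"


@dataclasses.dataclass(frozen=True)
class RingClosure:
    """Verdict on whether a screw operator closes into an n-subunit ring."""
    is_ring: bool
    n_subunits: int | None
    closure_angle_dev_deg: float
    closure_rise: float


@dataclasses.dataclass(frozen=True)
class CurvatureEstimate:
    """Least-squares circle fit through filament subunit centroids."""
    radius_nm: float          # inf when the points are collinear
    center: np.ndarray        # Angstrom, in the original frame
    plane_normal: np.ndarray
    residual_rmsd: float      # Angstrom, in-plane radial residuals
    n_points: int

    @property
    def is_straight(self) -> bool:
        return not np.isfinite(self.radius_nm)


def helical_parameters(t: RigidTransform,
                       reference_centroid) -> HelicalParams:
    """Helical parameters of the screw operator *t*.

    ``reference_centroid`` is the centroid of the reference subunit; its
    perpendicular distance from the screw axis is the helical radius.  Pure
    translations and the identity are flagged degenerate, not errors.
    """
    axis = screw_decompose(t)
    centroid = np.asarray(reference_centroid, dtype=float).reshape(3)
    if axis.pure_translation:
        return HelicalParams(0.0, axis.rise, float("nan"), axis,
                             degenerate=True)
    radius = float(axis.distance_to_axis(centroid))
    return HelicalParams(axis.twist_deg, axis.rise, radius, axis)


def predict_ring_closure(p: "HelicalParams | float", tol_angle_deg: float = 3.0,
                         tol_rise: float = 5.0, n_max: int = 100,
                         rise: float | None = None) -> RingClosure:
    """Find the subunit count n (3..n_max) at which the helix closes.

    The best n minimises ``|360 - n*|twist||`` (ties -> smaller n); the
    operator closes a ring iff that deviation and the accumulated rise
    ``|n*rise|`` are both within tolerance.  A float may be passed instead
    of HelicalParams as a bare twist in degrees (with ``rise=``).
    """
    if isinstance(p, HelicalParams):
        twist, rise_val = p.twist_deg, p.rise
    else:
        twist, rise_val = float(p), float(rise if rise is not None else 0.0)
    if abs(twist) < TWIST_ZERO_TOL_DEG:
        return RingClosure(False, None, float("inf"), 0.0)
    ns = np.arange(3, n_max + 1)
    devs = np.abs(360.0 - ns * abs(twist))
    best = int(np.argmin(devs))  # argmin returns the first (smallest n) tie
    n = int(ns[best])
    angle_dev = float(devs[best])
    closure_rise = abs(n * rise_val)
    is_ring = angle_dev <= tol_angle_deg and closure_rise <= tol_rise
    return RingClosure(is_ring, n if is_ring else None, angle_dev,
                       closure_rise)


def expand_helix(s: Structure, chain_id: str, t: RigidTransform,
                 n: int, clash_cutoff: float = 1.0) -> Structure:
    """Expand one protomer chain by n applications of the screw operator.

    Returns a structure of n+1 subunits: subunit k is ``t**k`` applied to
    the protomer.  Severe steric overlap (any inter-subunit CA-CA pair
    closer than ``clash_cutoff``) is warned about, never raised.
    """
    if n < 1:
        raise ValueError("expand_helix: n must be >= 1")
    chain = s.chain(chain_id)
    protomer = Structure(id=f"{s.id}:{chain_id}", chains=[chain])
    expanded = expand_assembly(protomer, [t], copies=n)
    ca0 = chain.coords(("CA",))
    if len(ca0):
        from scipy.spatial import cKDTree
        for other in expanded.chains[1:]:
            d, _ = cKDTree(other.coords(("CA",))).query(ca0, k=1)
            if np.min(d) < clash_cutoff:
                warnings.warn(
                    f"severe steric overlap between subunits "
                    f"(min CA-CA {np.min(d):.2f} A)", stacklevel=2)
                break
    return expanded


def fit_curvature(centroids, collinear_tol: float = 1e-9) -> CurvatureEstimate:
    """Radius of curvature from >= 3 points along a filament path.

    The points are projected onto their principal plane (the two largest
    principal components) and a circle is fitted there: an algebraic
    (Kasa) fit refined by geometric least squares.  Collinear inputs get an
    infinite-radius flag.  The radius is reported in nm (input in Angstrom).
    """
    pts = np.asarray(centroids, dtype=float).reshape(-1, 3)
    if len(pts) < 3:
        raise ValueError("fit_curvature needs at least 3 points")
    center0 = pts.mean(axis=0)
    X = pts - center0
    # principal plane of the points
    _, svals, Vt = np.linalg.svd(X, full_matrices=False)
    normal = Vt[2]
    uv = X @ Vt[:2].T  # in-plane 2D coordinates

    # collinearity: second singular value vanishes relative to the first
    if svals[0] <= 0 or svals[1] / svals[0] < collinear_tol:
        return CurvatureEstimate(float("inf"), center0, normal,
                                 0.0, len(pts))

    # Kasa algebraic fit: solve u^2+v^2 = 2a u + 2b v + c
    A = np.column_stack([2 * uv, np.ones(len(uv))])
    b = (uv ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    a0, b0 = sol[0], sol[1]
    r0 = float(np.sqrt(sol[2] + a0 ** 2 + b0 ** 2))

    def residuals(params):
        cu, cv, r = params
        return np.hypot(uv[:, 0] - cu, uv[:, 1] - cv) - r

    fit = least_squares(residuals, x0=[a0, b0, r0], method="lm")
    cu, cv, radius = fit.x
    radius = abs(float(radius))
    rmsd = float(np.sqrt(np.mean(fit.fun ** 2)))
    center3d = center0 + cu * Vt[0] + cv * Vt[1]
    return CurvatureEstimate(radius / 10.0, center3d, normal, rmsd, len(pts))


def filament_diameter(expanded: Structure, axis: ScrewAxis
                      ) -> tuple[float, float]:
    """(centroid-path diameter, envelope diameter) of a filament, in nm.

    The centroid-path diameter is twice the mean perpendicular distance of
    subunit centroids from the screw axis (the quantity compared to the
    ~20 nm mini-ring diameter); the envelope diameter is twice the maximum
    perpendicular atom distance, so envelope >= centroid path always.
    """
    chains = expanded.polymer_chains()
    if len(chains) < 2:
        logger.warning("filament_diameter on %d subunit(s)", len(chains))
    centroids = np.array([c.centroid() for c in chains])
    centroid_d = 2.0 * float(np.mean(axis.distance_to_axis(centroids)))
    all_xyz = np.vstack([c.coords() for c in chains])
    envelope_d = 2.0 * float(np.max(axis.distance_to_axis(all_xyz)))
    return centroid_d / 10.0, envelope_d / 10.0
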