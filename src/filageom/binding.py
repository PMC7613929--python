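"""Equilibrium binding-isotherm models and their least-squares fits.

Two models:

* **single-site** (SPR equilibrium response)::

      R_eq(C) = C * Rmax / (C + Kd) + B

  with analyte concentration C (uM), maximum response at saturation Rmax,
  dissociation constant Kd (uM) and background resonance B;

* **two-step** (fluorescence polarisation of a labelled peptide titrated
  with protein)::

      F([P_T]) = F0 + F_Lo * [P_T] / (Kd_Lo + [P_T])
                    + F_Hi * [P_T] / (Kd_Hi + [P_T])

  the sum of two saturable transitions: F0 is the anisotropy without
  titrating protein, F_Lo/F_Hi the anisotropy changes at saturation of the
  low- and high-affinity step (Kd_Lo <= Kd_Hi by labelling convention).
  For FtsA-FtsN the two steps correspond to peptide binding and
  peptide-induced polymerisation.

Fits are ordinary (unweighted) nonlinear least squares with positivity
bounds, restarted from a few jittered initialisations (deterministic seed)
to avoid shallow local minima.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.optimize import least_squares

N_RESTARTS = 5
_RESTART_SEED = 20220831  # fixed: fits are deterministic


class FitError(RuntimeError):
    """Raised when a fit cannot converge or the data are degenerate."""


@dataclasses.dataclass
class Isotherm:
    """A titration: concentrations x (uM) and responses y (same length).

    Concentrations must be non-negative; rows are sorted by x on
    construction.  Replicates (repeated x) are allowed.
    """
    x: np.ndarray
    y: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be equal-length 1-D arrays")
        if np.any(x < 0):
            raise ValueError("concentrations must be non-negative")
        order = np.argsort(x, kind="stable")
        self.x, self.y = x[order], y[order]
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate)[order]

    @property
    def n_distinct(self) -> int:
        return len(np.unique(self.x))


@dataclasses.dataclass
class SPRFit:
    Kd: float
    Rmax: float
    B: float
    stderr: dict
    rss: float
    n: int

    def predict(self, C) -> np.ndarray:
        return spr_response(C, self.Kd, self.Rmax, self.B)


@dataclasses.dataclass
class TwoStepFit:
    F0: float
    F_Lo: float
    Kd_Lo: float
    F_Hi: float
    Kd_Hi: float
    stderr: dict
    rss: float
    n: int
    flags: list = dataclasses.field(default_factory=list)

    def predict(self, PT) -> np.ndarray:
        return fp_anisotropy(PT, self.F0, self.F_Lo, self.Kd_Lo,
                             self.F_Hi, self.Kd_Hi)


def spr_response(C, Kd: float, Rmax: float, B: float = 0.0):
    """Single-site equilibrium response: ``C*Rmax/(C+Kd) + B``."""
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("analyte concentration must be >= 0")
    if Kd <= 0:
        raise ValueError("Kd must be positive")
    return C * Rmax / (C + Kd) + B


def fp_anisotropy(PT, F0: float, F_Lo: float, Kd_Lo: float,
                  F_Hi: float, Kd_Hi: float):
    """Two-step saturation model: ``F0 + F_Lo*PT/(Kd_Lo+PT) +
    F_Hi*PT/(Kd_Hi+PT)``."""
    PT = np.asarray(PT, dtype=float)
    if np.any(PT < 0):
        raise ValueError("total protein concentration must be >= 0")
    if Kd_Lo <= 0 or Kd_Hi <= 0:
        raise ValueError("dissociation constants must be positive")
    return F0 + F_Lo * PT / (Kd_Lo + PT) + F_Hi * PT / (Kd_Hi + PT)


def _jittered_fits(residuals, x0, bounds, rng):
    best = None
    starts = [np.asarray(x0, dtype=float)]
    for _ in range(N_RESTARTS - 1):
        starts.append(starts[0] * rng.lognormal(0.0, 0.4, len(x0)))
    lo, hi = bounds
    for start in starts:
        start = np.clip(start, np.asarray(lo) + 1e-12, hi)
        try:
            fit = least_squares(residuals, start, bounds=bounds,
                                method="trf", max_nfev=20000)
        except (ValueError, FloatingPointError):
            continue
        if fit.success and (best is None or fit.cost < best.cost):
            best = fit
    return best


def _stderr(fit, names) -> dict:
    n, p = len(fit.fun), len(fit.x)
    if n <= p:
        return {k: float("nan") for k in names}
    s2 = 2 * fit.cost / (n - p)
    J = fit.jac
    try:
        cov = np.linalg.inv(J.T @ J) * s2
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return dict(zip(names, (float(v) for v in se)))


def fit_spr(data: Isotherm) -> SPRFit:
    """Fit the single-site model to an equilibrium-response titration.

    Initials: Kd at the concentration whose response is nearest the
    half-range, Rmax from the response range, B from the minimum response.
    Raises :class:`FitError` for degenerate (flat) data or non-convergence.
    """
    if data.n_distinct < 4:
        raise FitError("need at least 4 distinct concentrations")
    x, y = data.x, data.y
    span = float(np.ptp(y))
    if span <= 0 or span < 1e-12 * max(abs(y).max(), 1.0):
        raise FitError("degenerate fit: responses are constant")
    half = y.min() + span / 2
    kd0 = max(float(x[np.argmin(np.abs(y - half))]), x[x > 0].min())
    x0 = [kd0, span, float(y.min())]
    lo = [1e-12, 1e-12, -np.inf]
    hi = [np.inf, np.inf, np.inf]

    def residuals(p):
        return spr_response(x, p[0], p[1], p[2]) - y

    rng = np.random.default_rng(_RESTART_SEED)
    fit = _jittered_fits(residuals, x0, (lo, hi), rng)
    if fit is None:
        raise FitError(f"single-site fit failed to converge "
                       f"(initials {x0})")
    kd, rmax, b = (float(v) for v in fit.x)
    return SPRFit(kd, rmax, b, _stderr(fit, ("Kd", "Rmax", "B")),
                  float(2 * fit.cost), len(x))


def fit_fp(data: Isotherm, identifiability_ratio: float = 10.0) -> TwoStepFit:
    """Fit the two-step model to a titration spanning both transitions.

    The two Kd labels are assigned so that ``Kd_Lo <= Kd_Hi``.  Flags:
    ``poorly_separated`` when the fitted Kd ratio is below
    ``identifiability_ratio`` (the two steps are then barely
    distinguishable), ``kd_hi_unbounded`` when Kd_Hi lands above the
    titrated range (the data do not cover the second transition) — the
    latter also raises unless the fit is otherwise sound.
    """
    if data.n_distinct < 6:
        raise FitError("need at least 6 distinct concentrations")
    x, y = data.x, data.y
    span = float(np.ptp(y))
    if span <= 0:
        raise FitError("degenerate fit: responses are constant")
    xpos = x[x > 0]
    # initial Kds a decade apart inside the titrated range
    kd_lo0 = float(np.quantile(xpos, 0.2))
    kd_hi0 = float(np.quantile(xpos, 0.8))
    x0 = [float(y.min()), span / 2, kd_lo0, span / 2, kd_hi0]
    lo = [-np.inf, 1e-12, 1e-12, 1e-12, 1e-12]
    hi = [np.inf, np.inf, np.inf, np.inf, np.inf]

    def residuals(p):
        return fp_anisotropy(x, *p) - y

    rng = np.random.default_rng(_RESTART_SEED)
    fit = _jittered_fits(residuals, x0, (lo, hi), rng)
    if fit is None:
        raise FitError(f"two-step fit failed to converge (initials {x0})")
    f0, a1, k1, a2, k2 = (float(v) for v in fit.x)
    if k1 > k2:
        a1, k1, a2, k2 = a2, k2, a1, k1
    flags = []
    if k2 / k1 < identifiability_ratio:
        flags.append("poorly_separated")
        warnings.warn(
            f"two-step fit: Kd ratio {k2 / k1:.2f} below "
            f"{identifiability_ratio}; the transitions are poorly "
            "identifiable", stacklevel=2)
    if k2 > x.max():
        flags.append("kd_hi_unbounded")
        warnings.warn(
            f"two-step fit: Kd_Hi {k2:.3g} uM exceeds the highest titrated "
            f"concentration {x.max():.3g} uM; second transition not covered",
            stacklevel=2)
    return TwoStepFit(f0, a1, k1, a2, k2,
                      _stderr(fit, ("F0", "F_Lo", "Kd_Lo", "F_Hi", "Kd_Hi")),
                      float(2 * fit.cost), len(x), flags)


def dilution_series(top: float, n: int, factor: float = 2.0,
                    include_zero: bool = False) -> np.ndarray:
    """A 1:factor dilution series from ``top`` (uM), ascending."""
    conc = top / factor ** np.arange(n)[::-1]
    if include_zero:
        conc = np.concatenate([[0.0], conc])
    return conc
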