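"""Closed-form two-region model of cilia-driven bidirectional flow.

The central canal is idealized as a 2D channel of height ``d`` (dorso-ventral)
that is infinite along the rostro-caudal axis ``x``.  Motile cilia line the
ventral wall and are homogenized into a constant axial volume force density
``fv`` acting on the fluid in the ventral layer ``0 <= y <= h``; the dorsal
region ``h <= y <= d`` is passive.  In the Stokes regime the axial momentum
balance in each region reads

    ventral:  dP/dx - fv = mu * v''(y)
    dorsal:   dP/dx      = mu * v''(y)

with no slip at both walls, continuity of velocity and shear rate at ``y = h``,
and a closed canal that imposes zero net flux through every cross-section.
Those five conditions determine the two parabolas and the axial pressure
gradient uniquely.  For ``h = d/2`` the solution is the symmetric biparabola
with ``dP/dx = fv/2`` and extremal speeds ``fv d^2 / (64 mu)``: caudal flow in
the ventral half, rostral return flow in the dorsal half.

Coordinates: ``y = 0`` ventral wall, ``y = d`` dorsal wall; positive velocity
is rostral-to-caudal.  All quantities are SI (m, s, Pa.s, N/m^3).

Dimensional analysis of the ciliary forcing gives ``fv = alpha * mu * f / h``
where ``f`` is the mean beat frequency and ``alpha`` a dimensionless factor of
order unity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelParams",
    "AnalyticalProfile",
    "ProfileFeatures",
    "cilia_force_density",
    "solve_two_region",
    "evaluate_profile",
    "profile_features",
    "net_flux",
]

#: relative margin keeping h away from the degenerate limits 0 and d
_H_MARGIN = 1e-6


def cilia_force_density(alpha: float, mu: float, f: float, h: float) -> float:
    """Volume force density ``fv = alpha * mu * f / h`` (N/m^3).

    Parameters
    ----------
    alpha : dimensionless force factor (order unity).
    mu : dynamic viscosity (Pa s).
    f : mean cilia beat frequency (Hz); ``f = 0`` gives ``fv = 0``.
    h : ciliated-layer height (m).
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if mu <= 0:
        raise ValueError(f"mu must be positive, got {mu}")
    if f < 0:
        raise ValueError(f"f must be non-negative, got {f}")
    if h <= 0:
        raise ValueError(f"h must be positive, got {h}")
    return alpha * mu * f / h


@dataclass(frozen=True)
class ModelParams:
    """Inputs of the two-region model.

    ``fv`` may be given directly; if omitted it is derived as
    ``alpha * mu * f / h``.
    """

    mu: float
    d: float
    h: float
    alpha: float = 0.5
    f: float = 40.0
    fv: float | None = None

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if self.d <= 0:
            raise ValueError(f"d must be positive, got {self.d}")
        lo, hi = _H_MARGIN * self.d, (1 - _H_MARGIN) * self.d
        if not (lo < self.h < hi):
            raise ValueError(
                f"h must lie strictly inside (0, d); got h={self.h}, d={self.d}"
            )
        if self.fv is None:
            object.__setattr__(
                self, "fv", cilia_force_density(self.alpha, self.mu, self.f, self.h)
            )
        elif self.fv < 0:
            raise ValueError(f"fv must be non-negative, got {self.fv}")


@dataclass(frozen=True)
class AnalyticalProfile:
    """Solved piecewise-parabolic velocity profile.

    The two regions are stored as quadratic coefficients
    ``v(y) = c2 y^2 + c1 y + c0`` (``*_ventral`` valid on [0, h],
    ``*_dorsal`` on [h, d]).  ``yA``/``yB`` are the classical integration
    constants of the textbook form ``v = (G - fv)/mu (y^2/2 - yA y)`` and
    ``v = G/mu (y^2/2 - yB y - d^2/2 + yB d)``; they are NaN when the
    corresponding prefactor vanishes (e.g. ``fv = 0``).
    """

    d: float
    h: float
    mu: float
    fv: float
    dPdx: float
    coef_ventral: tuple[float, float, float]
    coef_dorsal: tuple[float, float, float]
    yA: float = field(default=np.nan)
    yB: float = field(default=np.nan)


def solve_two_region(params: ModelParams) -> AnalyticalProfile:
    """Solve the two-region model with the zero-net-flux closure.

    The unknowns are the linear velocity coefficients A (ventral), B (dorsal)
    and the pressure gradient G = dP/dx, determined by the 3x3 linear system
    expressing velocity continuity, shear-rate continuity and zero net flux.
    For ``h = d/2`` the solution reduces to ``yA = d/4``, ``yB = 3d/4`` and
    ``dP/dx = fv/2``.
    """
    mu, d, h, fv = params.mu, params.d, params.h, params.fv
    # v_ventral = (G-fv)/(2mu) y^2 + A y         (no slip at y=0 built in)
    # v_dorsal  = G/(2mu) y^2 + B y + C,  C = -G d^2/(2mu) - B d  (no slip at d)
    # rows: velocity continuity at h, shear continuity at h, zero net flux
    M = np.array(
        [
            [h, d - h, d**2 / (2 * mu)],
            [1.0, -1.0, 0.0],
            [h**2 / 2, -((d - h) ** 2) / 2, d**2 * (3 * h - 2 * d) / (6 * mu)],
        ]
    )
    rhs = np.array([fv * h**2 / (2 * mu), fv * h / mu, fv * h**3 / (6 * mu)])
    try:
        A, B, G = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:  # cannot occur for 0 < h < d
        raise ArithmeticError(f"two-region system is singular: {exc}") from exc

    C = -G * d**2 / (2 * mu) - B * d
    cv = ((G - fv) / (2 * mu), A, 0.0)
    cd = (G / (2 * mu), B, C)
    yA = -A * mu / (G - fv) if G != fv else np.nan
    yB = -B * mu / G if G != 0 else np.nan
    return AnalyticalProfile(
        d=d, h=h, mu=mu, fv=fv, dPdx=G,
        coef_ventral=cv, coef_dorsal=cd, yA=yA, yB=yB,
    )


def evaluate_profile(profile: AnalyticalProfile, y):
    """Axial velocity v(y) in m/s (positive = caudal) for y in [0, d]."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y > profile.d):
        raise ValueError(f"y must lie in [0, d={profile.d}]")
    c2v, c1v, c0v = profile.coef_ventral
    c2d, c1d, c0d = profile.coef_dorsal
    ventral = c2v * y**2 + c1v * y + c0v
    dorsal = c2d * y**2 + c1d * y + c0d
    out = np.where(y <= profile.h, ventral, dorsal)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ProfileFeatures:
    """Extrema and zero crossing of a solved profile.

    Positions are absolute (m) and relative to the diameter (in [0, 1]).
    ``defined`` is False (all values NaN) when the profile is identically
    zero and the features are meaningless.
    """

    vmax: float
    y_vmax: float
    vmin: float
    y_vmin: float
    y_zero: float
    rel_vmax: float
    rel_zero: float
    rel_vmin: float
    defined: bool = True


def _region_extrema(coef, lo, hi):
    """Candidate (y, v) extrema of one quadratic piece on [lo, hi]."""
    c2, c1, c0 = coef
    ys = [lo, hi]
    if c2 != 0:
        vtx = -c1 / (2 * c2)
        if lo < vtx < hi:
            ys.append(vtx)
    return [(y, c2 * y**2 + c1 * y + c0) for y in ys]


def profile_features(profile: AnalyticalProfile) -> ProfileFeatures:
    """Locate vmax, vmin and the zero crossing in closed form."""
    if profile.fv == 0:
        nan = float("nan")
        return ProfileFeatures(nan, nan, nan, nan, nan, nan, nan, nan, defined=False)

    d, h = profile.d, profile.h
    cands = _region_extrema(profile.coef_ventral, 0.0, h)
    cands += _region_extrema(profile.coef_dorsal, h, d)
    y_vmax, vmax = max(cands, key=lambda t: t[1])
    y_vmin, vmin = min(cands, key=lambda t: t[1])

    # interior zero crossing: roots of each parabola within its open region
    roots = []
    eps = 1e-9 * d
    for coef, lo, hi in ((profile.coef_ventral, 0.0, h), (profile.coef_dorsal, h, d)):
        for r in np.roots(coef):
            if abs(r.imag) < 1e-12 * d:
                r = float(r.real)
                if lo - eps <= r <= hi + eps and eps < r < d - eps:
                    roots.append(r)
    y_zero = min(roots) if roots else float("nan")

    return ProfileFeatures(
        vmax=float(vmax), y_vmax=float(y_vmax),
        vmin=float(vmin), y_vmin=float(y_vmin),
        y_zero=y_zero,
        rel_vmax=float(y_vmax / d), rel_zero=float(y_zero / d),
        rel_vmin=float(y_vmin / d),
    )


def net_flux(profile: AnalyticalProfile) -> float:
    """Exact flux per unit depth, ``int_0^d v(y) dy`` (m^2/s).

    Zero (to rounding) for any profile produced by :func:`solve_two_region`;
    useful as a diagnostic for manually perturbed profiles.
    """
    def _piece(coef, lo, hi):
        p = np.polyint(np.array(coef))
        return np.polyval(p, hi) - np.polyval(p, lo)

    return float(
        _piece(profile.coef_ventral, 0.0, profile.h)
        + _piece(profile.coef_dorsal, profile.h, profile.d)
    )
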