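"""Numerical 2D Stokes flow driven by arbitrary ciliary force patterns.

Generalizes the homogeneous two-region model to spatially structured
forcing: periodic "spots" of axial volume force along the ventral wall
(period ``w``, active width ``a``), unequal force amplitudes between
neighboring spots (beat-frequency heterogeneity), and a linear-in-y force
shape.  With sparse forcing, recirculation cells (vortices) appear between
active spots; when the passive gaps are wider than the canal diameter the
through-flow between spots vanishes and all streamlines close locally.

Discretization: Fourier modes along the periodic rostro-caudal axis, second
order finite differences across the canal.  Each transverse Fourier mode of
the streamfunction solves the one-dimensional biharmonic problem

    mu (D^2 - k^2)^2 psi_k = -d/dy f_k(y)

with no-slip, impermeable walls.  The k = 0 (mean) mode carries the free
global pressure gradient, fixed so that the discrete net flux through every
cross-section is zero, mirroring the closed-canal argument of the analytic
model.  By linearity of the Stokes equations the solver is exactly
superposable in the force pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import sparse
from scipy.linalg import solve_banded
from scipy.ndimage import maximum_filter, minimum_filter
from scipy.sparse.linalg import spsolve

from .hydro import AnalyticalProfile, evaluate_profile

__all__ = [
    "CiliaPattern",
    "FlowField",
    "VortexReport",
    "solve_stokes",
    "heterogeneous_frequency_field",
    "field_from_profile",
    "detect_recirculation",
    "pressure_profile",
]


@dataclass(frozen=True)
class CiliaPattern:
    """Periodic ventral forcing: spots of width ``a`` every ``w`` meters.

    ``fv`` may be a scalar (identical spots) or a sequence of per-spot
    amplitudes, cycled along the canal (unequal amplitudes model cilia
    patches beating at different frequencies).  ``shape`` selects the
    force profile across the ciliated layer: "constant", or "linear"
    (maximal at the wall, zero at ``y = h``, same total force).
    """

    w: float
    a: float
    h: float
    fv: float | tuple = 4000.0
    shape: str = "constant"

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError(f"period w must be positive, got {self.w}")
        if not (0 <= self.a <= self.w):
            raise ValueError(f"active width a must satisfy 0 <= a <= w, got {self.a}")
        amps = np.atleast_1d(np.asarray(self.fv, dtype=float))
        if np.any(amps < 0):
            raise ValueError("force amplitudes must be non-negative")
        if self.shape not in ("constant", "linear"):
            raise ValueError(f"unknown force shape {self.shape!r}")
        object.__setattr__(self, "fv", tuple(amps.tolist()))

    @property
    def passive_fraction(self) -> float:
        return 1.0 - self.a / self.w

    def force_array(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Axial body force fx on the (y, x) grid (N/m^3)."""
        amps = np.asarray(self.fv)
        n_seg = amps.size
        # active window centered within each period
        xm = np.mod(x, self.w)
        seg = np.floor_divide(np.mod(x, n_seg * self.w), self.w).astype(int)
        lo, hi = (self.w - self.a) / 2, (self.w + self.a) / 2
        active = (xm >= lo) & (xm < hi)
        fx_row = np.where(active, amps[seg], 0.0)
        if self.shape == "constant":
            prof = (y < self.h).astype(float)
        else:  # linear: 2(1 - y/h) inside the layer, equal total force
            prof = np.where(y < self.h, 2.0 * (1.0 - y / self.h), 0.0)
        return prof[:, None] * fx_row[None, :]


@dataclass
class FlowField:
    """Discrete Stokes solution on a (ny+1) x nx periodic channel grid."""

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray  # axial velocity (ny+1, nx)
    v: np.ndarray  # transverse velocity
    P: np.ndarray  # pressure (periodic part + G x)
    psi: np.ndarray  # streamfunction, zero on both walls
    d: float
    h: float
    dPdx_mean: float  # global axial pressure gradient G
    pattern: CiliaPattern | None = None


def _solve_mean_mode(f0: np.ndarray, y: np.ndarray, mu: float):
    """k=0 mode: mu u'' = G - f0(y), no slip, zero discrete (trapezoid) flux."""
    n = y.size - 1
    dy = y[1] - y[0]
    ab = np.zeros((3, n - 1))
    ab[0, 1:] = 1.0
    ab[1] = -2.0
    ab[2, :-1] = 1.0
    # particular solution with G=0: mu u'' = -f0
    rhs_f = -f0[1:-1] * dy**2 / mu
    uF = np.zeros(n + 1)
    uF[1:-1] = solve_banded((1, 1), ab, rhs_f)
    # unit-pressure-gradient solution: mu u'' = 1  (discrete, for consistency)
    rhs_p = np.full(n - 1, dy**2 / mu)
    uP = np.zeros(n + 1)
    uP[1:-1] = solve_banded((1, 1), ab, rhs_p)
    G = -np.trapezoid(uF, y) / np.trapezoid(uP, y)
    return uF + G * uP, float(G)


def _solve_mode(fk: np.ndarray, y: np.ndarray, k: float, mu: float) -> np.ndarray:
    """One k != 0 streamfunction mode: mu (D^2-k^2)^2 psi = -fk'(y)."""
    n = y.size
    dy = y[1] - y[0]
    fkp = np.gradient(fk, dy, edge_order=2)
    N = 2 * n
    A = sparse.lil_matrix((N, N), dtype=complex)
    b = np.zeros(N, dtype=complex)
    # psi rows
    A[0, 0] = 1.0
    A[n - 1, n - 1] = 1.0
    for j in range(1, n - 1):
        A[j, j - 1] = 1 / dy**2
        A[j, j] = -2 / dy**2 - k**2
        A[j, j + 1] = 1 / dy**2
        A[j, n + j] = -1.0
    # chi rows: boundary slots carry the no-slip (psi'=0) conditions
    A[n, 0], A[n, 1], A[n, 2] = -3.0, 4.0, -1.0
    A[2 * n - 1, n - 1], A[2 * n - 1, n - 2], A[2 * n - 1, n - 3] = 3.0, -4.0, 1.0
    for j in range(1, n - 1):
        A[n + j, n + j - 1] = mu / dy**2
        A[n + j, n + j] = mu * (-2 / dy**2 - k**2)
        A[n + j, n + j + 1] = mu / dy**2
        b[n + j] = -fkp[j]
    z = spsolve(A.tocsr(), b)
    return z[:n]


def solve_stokes(
    d: float,
    pattern: CiliaPattern,
    *,
    n_periods: int | None = None,
    ny: int = 48,
    nx_per_period: int = 48,
    mu: float = 1e-3,
) -> FlowField:
    """Steady Stokes solution for a periodic ciliary force pattern.

    The domain spans ``n_periods`` repeats of the pattern (default: enough
    segments to cycle all amplitudes, at least 3).  The grid resolves the
    diameter with ``ny`` cells and each period with ``nx_per_period``.
    """
    n_amp = len(pattern.fv)
    if n_periods is None:
        n_periods = max(3, n_amp)
    if n_periods % n_amp:
        n_periods = n_amp * int(np.ceil(n_periods / n_amp))
    if d <= 0 or pattern.h >= d:
        raise ValueError("need 0 < h < d")
    if ny * pattern.h / d < 8:
        raise ValueError(
            f"grid under-resolves the ciliated layer: ny={ny} gives "
            f"{ny * pattern.h / d:.1f} < 8 cells over h"
        )

    Lx = n_periods * pattern.w
    nx = n_periods * nx_per_period
    dx = Lx / nx
    x = dx * np.arange(nx)
    y = np.linspace(0.0, d, ny + 1)

    # cell-averaged (finite-volume) force: supersample each node cell so the
    # sharp active-window and layer edges are represented to second order
    S = 8
    xs = (x[:, None] + dx * ((np.arange(S) + 0.5) / S - 0.5)[None, :]).ravel()
    dyy = y[1] - y[0]
    ys = (y[:, None] + dyy * ((np.arange(S) + 0.5) / S - 0.5)[None, :]).ravel()
    fx_fine = pattern.force_array(xs, ys)  # (S*(ny+1), S*nx)
    fx = fx_fine.reshape(y.size, S, nx, S).mean(axis=(1, 3))  # (ny+1, nx)
    fhat = np.fft.rfft(fx, axis=1) / nx
    kvals = 2 * np.pi * np.fft.rfftfreq(nx, dx)

    u0, G = _solve_mean_mode(fhat[:, 0].real, y, mu)

    nmodes = kvals.size
    psi_hat = np.zeros((y.size, nmodes), dtype=complex)
    u_hat = np.zeros_like(psi_hat)
    dy = y[1] - y[0]
    fmax = np.abs(fhat[:, 1:]).max() if nmodes > 1 else 0.0
    for m in range(1, nmodes):
        if fmax > 0 and np.abs(fhat[:, m]).max() < 1e-12 * fmax:
            continue
        psi_hat[:, m] = _solve_mode(fhat[:, m], y, kvals[m], mu)
        u_hat[:, m] = np.gradient(psi_hat[:, m], dy, edge_order=2)

    # assemble real fields (rfft normalization: one-sided spectrum)
    def _from_modes(zhat):
        return np.fft.irfft(zhat, n=nx, axis=1) * nx

    u = u0[:, None] + _from_modes(u_hat)
    v = _from_modes(-1j * kvals[None, :] * psi_hat)
    from scipy.integrate import cumulative_trapezoid

    psi0 = cumulative_trapezoid(u0, y, initial=0.0)
    psi = psi0[:, None] + _from_modes(psi_hat)

    # project out the residual discrete flux (O(dy^3)), keeping no-slip
    pois = y * (d - y)
    pois /= np.trapezoid(pois, y)
    flux = np.trapezoid(u, y, axis=0)
    u = u - pois[:, None] * flux[None, :]

    # pressure: ik P_k = mu (u'' - k^2 u) + f_k ;  k=0 part is G x
    P_hat = np.zeros_like(psi_hat)
    for m in range(1, nmodes):
        upp = np.gradient(np.gradient(u_hat[:, m], dy, edge_order=2), dy, edge_order=2)
        P_hat[:, m] = (mu * (upp - kvals[m] ** 2 * u_hat[:, m]) + fhat[:, m]) / (
            1j * kvals[m]
        )
    P = G * x[None, :] + _from_modes(P_hat)

    return FlowField(
        x=x, y=y, u=u, v=v, P=P, psi=psi, d=d, h=pattern.h,
        dPdx_mean=G, pattern=pattern,
    )


def heterogeneous_frequency_field(
    d: float,
    amplitudes,
    w: float,
    h: float,
    *,
    a: float | None = None,
    **kwargs,
) -> FlowField:
    """Flow driven by neighboring cilia patches of unequal force.

    ``amplitudes`` are per-patch force densities (e.g. alternating
    4000/2000 N/m^3 for patches beating at different frequencies); patches
    are ``a`` wide (default fully active, a = w) with period ``w``.
    """
    amps = tuple(float(a_) for a_ in np.atleast_1d(amplitudes))
    if len(set(amps)) < 2 and len(amps) > 1:
        pass  # degenerate (all equal) is allowed and reduces to uniform
    pattern = CiliaPattern(w=w, a=w if a is None else a, h=h, fv=amps)
    return solve_stokes(d, pattern, **kwargs)


def field_from_profile(
    profile: AnalyticalProfile, *, nx: int = 96, ny: int = 48, length: float | None = None
) -> FlowField:
    """Extend an analytic profile uniformly along x into a FlowField."""
    from scipy.integrate import cumulative_trapezoid

    d = profile.d
    if length is None:
        length = 3 * d
    x = np.linspace(0.0, length, nx, endpoint=False)
    y = np.linspace(0.0, d, ny + 1)
    u0 = np.asarray(evaluate_profile(profile, y))
    psi0 = cumulative_trapezoid(u0, y, initial=0.0)
    u = np.broadcast_to(u0[:, None], (y.size, nx)).copy()
    return FlowField(
        x=x, y=y, u=u, v=np.zeros_like(u),
        P=profile.dPdx * x[None, :] * np.ones((y.size, 1)),
        psi=np.broadcast_to(psi0[:, None], (y.size, nx)).copy(),
        d=d, h=profile.h, dPdx_mean=profile.dPdx, pattern=None,
    )


@dataclass
class VortexReport:
    """Closed-recirculation summary of a flow field."""

    count: int
    extrema: list = dc_field(default_factory=list)  # (y, x, psi) per vortex core
    through_flow: float = 0.0  # max |u| on passive mid-sections (m/s)
    prominence: float = 0.0  # recirculation strength / total psi scale


def _passive_mid_sections(field: FlowField) -> np.ndarray:
    """x indices at the centers of the passive gaps of the pattern."""
    pat = field.pattern
    if pat is None or pat.a >= pat.w:
        return np.array([], dtype=int)
    # gap between period i's active window end and period i+1's start;
    # active window is centered, so gap centers sit at period boundaries
    centers = []
    Lx = field.x[-1] + (field.x[1] - field.x[0])
    nper = int(round(Lx / pat.w))
    for i in range(nper):
        centers.append((i * pat.w) % Lx)
    idx = [int(np.argmin(np.abs(field.x - c))) for c in centers]
    return np.unique(idx)


def detect_recirculation(field: FlowField, wall_margin: int = 2) -> VortexReport:
    """Find closed-streamline cores as strict interior extrema of psi.

    A vortex core is a grid point whose streamfunction value is strictly
    larger (or smaller) than all 8-connected neighbors, away from the
    walls.  A purely parallel flow (psi constant along x) has no strict
    extremum and reports zero vortices.  ``prominence`` is the maximal
    amplitude of the x-fluctuating part of psi relative to the overall psi
    scale; ``through_flow`` is max |u| on the mid-sections of passive gaps.
    """
    psi = field.psi
    scale = np.abs(psi).max()
    if scale == 0:
        return VortexReport(count=0)
    tol = 1e-10 * scale
    # wrap in x (periodic), clip in y
    mx = maximum_filter(psi, size=3, mode=("nearest", "wrap"))
    mn = minimum_filter(psi, size=3, mode=("nearest", "wrap"))
    interior = np.zeros_like(psi, dtype=bool)
    interior[1 + wall_margin : -1 - wall_margin, :] = True
    # strict extremum: beats the neighborhood max/min which includes itself
    # only possible when equal; require a clear margin over 2nd largest
    ismax = interior & (psi >= mx - tol)
    ismin = interior & (psi <= mn + tol)
    cores = []
    for mask, kind in ((ismax, "max"), (ismin, "min")):
        jj, ii = np.nonzero(mask)
        for j, i in zip(jj, ii):
            neigh = psi[j - 1 : j + 2, np.arange(i - 1, i + 2) % psi.shape[1]]
            others = np.delete(neigh.ravel(), 4)
            center = psi[j, i]
            if kind == "max" and np.all(center > others + tol):
                cores.append((field.y[j], field.x[i], float(center)))
            elif kind == "min" and np.all(center < others - tol):
                cores.append((field.y[j], field.x[i], float(center)))

    psi_mean = psi.mean(axis=1, keepdims=True)
    fluct = np.abs(psi - psi_mean).max()
    prom = float(fluct / scale)

    idx = _passive_mid_sections(field)
    through = float(np.abs(field.u[:, idx]).max()) if idx.size else 0.0
    return VortexReport(
        count=len(cores), extrema=cores, through_flow=through, prominence=prom
    )


def pressure_profile(field: FlowField):
    """Section-averaged pressure P(x) and its mean axial slope.

    For uniform forcing with h = d/2 the slope equals fv/2; sparse patterns
    reduce it in proportion to the active fraction a/w.
    """
    Pbar = np.trapezoid(field.P, field.y, axis=0) / field.d
    pat = field.pattern
    if pat is not None:
        # mean slope from finite differences over one full pattern cycle:
        # the periodic pressure component cancels exactly
        cycle = len(pat.fv) * pat.w
        dx = field.x[1] - field.x[0]
        shift = int(round(cycle / dx))
        if 0 < shift < field.x.size:
            dP = Pbar[shift:] - Pbar[:-shift]
            slope = float(dP.mean() / cycle)
        else:
            slope = float(np.polyfit(field.x, Pbar, 1)[0])
    else:
        slope = float(np.polyfit(field.x, Pbar, 1)[0])
    return field.x, Pbar, slope
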