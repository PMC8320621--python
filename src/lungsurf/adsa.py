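"""Axisymmetric drop shape analysis (ADSA) for the constrained-drop geometry.

Forward problem: integrate the axisymmetric Young-Laplace equation from the
drop apex to the knife-edge pedestal, producing a meridian contour for given
surface tension, density difference and apex curvature. Inverse problem:
recover surface tension from an observed contour by least-squares shape
fitting, which is how the instrument turns drop images into the assay's
surface-tension readout.

The meridian profile (r(s), z(s), phi(s)) parametrized by arc length s obeys
the Bashforth-Adams system

    dphi/ds = 2/R0 + (drho * g / gamma) * z - sin(phi) / r
    dr/ds   = cos(phi)
    dz/ds   = sin(phi)

with apex conditions r = z = phi = 0 and the apex limit dphi/ds = 1/R0.
z is measured from the apex toward the pedestal, so the hydrostatic term is
positive for a sessile drop and flattens the profile as the Bond number
beta = drho * g * R0^2 / gamma grows. Units are mm, mN/m, kg/m^3 and m/s^2
throughout; `capillary_constant` centralizes the conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares, minimize
from scipy.spatial import cKDTree

from lungsurf.errors import (
    FitFailureError,
    GeometryError,
    IdentifiabilityError,
    InsufficientDataError,
    ParameterError,
)

STANDARD_GRAVITY = 9.81  # m/s^2

# Arc length budget, in units of max(R0, pedestal_radius), before the
# integration is declared unable to reach the pedestal.
_MAX_ARC_FACTOR = 60.0


def capillary_constant(delta_rho: float, g: float, gamma: float) -> float:
    """Hydrostatic coefficient drho*g/gamma in 1/mm^2.

    delta_rho in kg/m^3, g in m/s^2, gamma in mN/m; lengths in mm.
    """
    return delta_rho * g * 1e-3 / gamma


@dataclass(frozen=True)
class PhysicalParams:
    """Physical parameters of a constrained sessile drop.

    Attributes
    ----------
    surface_tension : float
        gamma in mN/m, > 0.
    density_difference : float
        drho between drop liquid and surrounding gas, kg/m^3, >= 0.
    apex_radius : float
        R0, radius of curvature at the apex, mm, > 0.
    pedestal_radius : float
        Radius of the knife-edge pedestal that pins the contact line, mm.
    gravity : float
        m/s^2.
    """

    surface_tension: float
    density_difference: float
    apex_radius: float
    pedestal_radius: float
    gravity: float = STANDARD_GRAVITY

    def __post_init__(self) -> None:
        if not self.surface_tension > 0:
            raise ParameterError(f"surface_tension must be > 0, got {self.surface_tension}")
        if self.density_difference < 0:
            raise ParameterError(f"density_difference must be >= 0, got {self.density_difference}")
        if not self.apex_radius > 0:
            raise ParameterError(f"apex_radius must be > 0, got {self.apex_radius}")
        if not self.pedestal_radius > 0:
            raise ParameterError(f"pedestal_radius must be > 0, got {self.pedestal_radius}")
        if not np.isfinite(self.bond_number):
            raise ParameterError("Bond number is not finite")

    @property
    def bond_number(self) -> float:
        """beta = drho * g * R0^2 / gamma (dimensionless)."""
        return capillary_constant(self.density_difference, self.gravity, self.surface_tension) * self.apex_radius**2


@dataclass
class DropProfile:
    """Axisymmetric meridian contour from the apex to the pedestal.

    Arrays are aligned per point; the first point is the apex
    (r = 0, z = 0, phi = 0) and arc length s is strictly increasing.
    ``params`` is None for observed (imaged) contours.
    """

    s: np.ndarray  # mm
    r: np.ndarray  # mm
    z: np.ndarray  # mm
    phi: np.ndarray  # radians
    params: PhysicalParams | None = field(default=None)

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        n = len(self.s)
        if not (len(self.r) == len(self.z) == len(self.phi) == n):
            raise ParameterError("profile arrays must have equal length")
        if n and not (self.r >= -1e-12).all():
            raise ParameterError("profile has negative radial coordinates")
        if n > 1 and not (np.diff(self.s) > 0).all():
            raise ParameterError("arc length must be strictly increasing")

    def __len__(self) -> int:
        return len(self.s)

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of (r, z) coordinates."""
        return np.column_stack([self.r, self.z])


def _apex_series(s0: float, inv_r0: float, c: float) -> tuple[float, float, float]:
    """Series expansion of (phi, r, z) at small arc length s0.

    Regularizes the sin(phi)/r singularity: phi = s/R0 + c s^3/(8 R0) + O(s^5),
    r = s - s^3/(6 R0^2) + O(s^5), z = s^2/(2 R0) + O(s^4).
    """
    phi0 = s0 * inv_r0 + c * s0**3 * inv_r0 / 8.0
    r0 = s0 - s0**3 * inv_r0**2 / 6.0
    z0 = s0**2 * inv_r0 / 2.0
    return phi0, r0, z0


def integrate_drop_profile(
    params: PhysicalParams,
    step: float = 0.01,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> DropProfile:
    """Integrate the Young-Laplace shape from apex until r reaches the pedestal.

    Parameters
    ----------
    params : PhysicalParams
    step : float
        Output sampling interval along the arc, mm (the integrator itself is
        adaptive; `step` only controls the returned grid).

    Returns
    -------
    DropProfile
        Contour sampled every `step` mm of arc length, beginning at the apex
        and ending exactly where r first equals ``params.pedestal_radius``.

    Raises
    ------
    ParameterError
        Non-positive step.
    GeometryError
        The profile never reaches the pedestal radius within the arc-length
        budget (pedestal wider than the drop can bulge).
    """
    if not step > 0:
        raise ParameterError(f"step must be > 0, got {step}")
    inv_r0 = 1.0 / params.apex_radius
    c = capillary_constant(params.density_difference, params.gravity, params.surface_tension)
    r_ped = params.pedestal_radius

    def rhs(s, y):
        phi, r, z = y
        dphi = 2.0 * inv_r0 + c * z - np.sin(phi) / r
        return (dphi, np.cos(phi), np.sin(phi))

    def hit_pedestal(s, y):
        return y[1] - r_ped

    hit_pedestal.terminal = True
    hit_pedestal.direction = 0

    s0 = 1e-4 * params.apex_radius
    y0 = _apex_series(s0, inv_r0, c)
    s_max = _MAX_ARC_FACTOR * max(params.apex_radius, r_ped)

    def drop_closes(s, y):
        # r returning toward the axis: the drop closes on itself before
        # reaching the pedestal (pedestal wider than the drop can bulge)
        return y[1] - 10.0 * s0

    drop_closes.terminal = True
    drop_closes.direction = -1

    def overturns(s, y):
        # phi past 180 deg: beyond the pinning limit of a knife-edge
        # pedestal, the solution would self-intersect
        return y[0] - np.pi

    overturns.terminal = True

    sol = solve_ivp(
        rhs,
        (s0, s_max),
        y0,
        method="RK45",
        events=(hit_pedestal, drop_closes, overturns),
        dense_output=True,
        rtol=rtol,
        atol=atol,
    )
    if sol.status != 1 or len(sol.t_events[0]) == 0:
        raise GeometryError(
            f"profile never reached pedestal_radius={r_ped} mm "
            f"(beta={params.bond_number:.3g}, arc budget {s_max:.3g} mm)"
        )
    s_end = sol.t_events[0][0]

    s_grid = np.arange(step, s_end, step)
    if len(s_grid) and s_end - s_grid[-1] < 0.25 * step:
        s_grid = s_grid[:-1]
    interior = sol.sol(s_grid) if len(s_grid) else np.empty((3, 0))
    y_end = sol.sol(s_end)

    s = np.concatenate([[0.0], s_grid, [s_end]])
    phi = np.concatenate([[0.0], interior[0], [y_end[0]]])
    r = np.concatenate([[0.0], interior[1], [y_end[1]]])
    z = np.concatenate([[0.0], interior[2], [y_end[2]]])
    r[-1] = r_ped  # event location is exact to solver tolerance
    return DropProfile(s=s, r=r, z=z, phi=phi, params=params)


def profile_area_volume(profile: DropProfile) -> tuple[float, float]:
    """Surface area and volume of the contour as a surface of revolution.

    area = 2*pi * integral r ds (mm^2); volume = pi * integral r^2 dz,
    reported in uL (1 mm^3 = 1 uL). Trapezoidal quadrature on the stored grid.
    """
    if len(profile) < 3:
        raise InsufficientDataError(f"need >= 3 contour points, got {len(profile)}")
    area = 2.0 * np.pi * np.trapezoid(profile.r, profile.s)
    volume = np.pi * np.trapezoid(profile.r**2, profile.z)
    return float(area), float(volume)


def _forward_curve(gamma: float, r0: float, delta_rho: float, g: float, s_end: float, n_dense: int = 4000) -> np.ndarray:
    """Candidate contour densely sampled out to arc length s_end.

    Integrating to a fixed arc length (stopping early only if the drop
    closes on itself) keeps the fit residuals smooth in the parameters;
    a radial stopping condition would jump discontinuously whenever the
    candidate's equatorial bulge grazes the target radius.
    """
    inv_r0 = 1.0 / r0
    c = capillary_constant(delta_rho, g, gamma)

    def rhs(s, y):
        phi, r, z = y
        return (2.0 * inv_r0 + c * z - np.sin(phi) / r, np.cos(phi), np.sin(phi))

    s0 = 1e-4 * r0

    def closes(s, y):
        return y[1] - 10.0 * s0

    closes.terminal = True
    closes.direction = -1

    def overturns(s, y):
        return y[0] - np.pi

    overturns.terminal = True

    y0 = _apex_series(s0, inv_r0, c)
    sol = solve_ivp(
        rhs, (s0, s_end), y0, method="RK45", events=(closes, overturns), dense_output=True, rtol=1e-9, atol=1e-11
    )
    if len(sol.t_events[0]):
        stop = sol.t_events[0][0]
    elif len(sol.t_events[1]):
        stop = sol.t_events[1][0]
    else:
        stop = sol.t[-1]
    s_grid = np.linspace(s0, stop, n_dense)
    y = sol.sol(s_grid)
    pts = np.column_stack([y[1], y[2]])
    return np.vstack([[0.0, 0.0], pts])


def _point_to_polyline(pts: np.ndarray, curve: np.ndarray) -> np.ndarray:
    """Distance from each point to the polyline, by projection onto the
    segments adjacent to the nearest vertex (exact to polyline resolution)."""
    _, idx = cKDTree(curve).query(pts)
    best = np.full(len(pts), np.inf)
    for offset in (-1, 0):
        i0 = np.clip(idx + offset, 0, len(curve) - 2)
        a = curve[i0]
        ab = curve[i0 + 1] - a
        denom = np.einsum("ij,ij->i", ab, ab)
        t = np.clip(np.einsum("ij,ij->i", pts - a, ab) / np.maximum(denom, 1e-300), 0.0, 1.0)
        d = np.linalg.norm(pts - (a + t[:, None] * ab), axis=1)
        best = np.minimum(best, d)
    return best


def fit_surface_tension(
    observed: DropProfile,
    delta_rho: float,
    g: float = STANDARD_GRAVITY,
    gamma_init: float = 30.0,
    r0_init: float | None = None,
) -> tuple[float, float, float]:
    """Recover surface tension from an observed contour by shape fitting.

    Minimizes the sum of squared point-to-curve nearest-neighbor distances
    between the observed (r, z) points and a densely sampled forward profile,
    over (gamma, R0) in log space with the apex fixed at the origin (contours
    are assumed apex-registered upstream).

    Parameters
    ----------
    observed : DropProfile
        >= 20 apex-registered contour points.
    delta_rho : float
        Density difference, kg/m^3; must be > 0 for identifiability.

    Returns
    -------
    (gamma_hat, r0_hat, residual_rms) : mN/m, mm, mm

    Raises
    ------
    IdentifiabilityError
        delta_rho = 0: a zero-Bond drop is spherical at every gamma.
    FitFailureError
        Optimizer did not converge; diagnostics carried on the exception.
    """
    if len(observed) < 20:
        raise InsufficientDataError(f"need >= 20 contour points, got {len(observed)}")
    if delta_rho <= 0:
        raise IdentifiabilityError(
            "delta_rho must be > 0: at zero Bond number the drop is spherical "
            "and its shape carries no surface-tension information"
        )

    pts = observed.points
    r_max = float(pts[:, 0].max())
    # candidate curves extend a little past the data's arc length so every
    # observed point projects onto the interior of the curve
    s_end = 1.15 * float(observed.s[-1])

    if r0_init is None:
        # near the apex z ~ r^2 / (2 R0); use the apex-local part of the contour
        inner = pts[(pts[:, 1] > 0) & (pts[:, 0] < 0.4 * r_max)]
        if len(inner) >= 3:
            r0_init = float(np.median(inner[:, 0] ** 2 / (2.0 * inner[:, 1])))
        else:
            r0_init = r_max
        r0_init = min(max(r0_init, 0.5 * r_max), 10.0 * r_max)

    span = float(np.ptp(pts[:, 0]) + np.ptp(pts[:, 1]))

    def residuals(x):
        gamma, r0 = np.exp(x)
        curve = _forward_curve(gamma, r0, delta_rho, g, s_end)
        return _point_to_polyline(pts, curve)

    # multi-start in gamma: the shape response saturates at both Bond-number
    # extremes, so a single distant start can stall on a flat cost region
    starts = [gamma_init] + [gi for gi in (10.0, 100.0, 3.0, 300.0) if gi != gamma_init]
    result = None
    for gi in starts:
        x0 = np.log([gi, r0_init])
        # diff_step large enough that finite-difference shape changes clear
        # the forward integrator's tolerance, else the jacobian is noise
        res = least_squares(
            residuals,
            x0,
            method="lm",
            x_scale="jac",
            diff_step=1e-3,
            xtol=1e-11,
            ftol=1e-11,
            gtol=1e-11,
            max_nfev=120,
        )
        if result is None or res.cost < result.cost:
            result = res
        if np.sqrt(np.mean(res.fun**2)) < 0.01 * span:
            result = res
            break

    # derivative-free polish: the (gamma, R0) valley is nearly degenerate at
    # low Bond number and LM can stall a fraction of a percent from its floor
    polish = minimize(
        lambda x: float(np.sum(residuals(x) ** 2)),
        result.x,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-16, "maxfev": 400},
    )
    x_best = polish.x if polish.fun <= 2.0 * result.cost else result.x
    final = residuals(x_best)

    gamma_hat, r0_hat = np.exp(x_best)
    rms = float(np.sqrt(np.mean(final**2)))

    if not np.isfinite(gamma_hat) or rms >= 0.5 * span:
        raise FitFailureError(
            "surface-tension fit did not converge",
            diagnostics={
                "status": result.status,
                "message": result.message,
                "gamma": float(gamma_hat),
                "r0": float(r0_hat),
                "residual_rms_mm": rms,
                "nfev": result.nfev,
            },
        )
    return float(gamma_hat), float(r0_hat), rms
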