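"""Analytic one-dimensional theory of bilayer-mediated wedge interactions.

An amphipathic helix ("wedge") partially inserted into the upper leaflet of a
lipid bilayer locally compresses the leaflet hydrophobic thickness.  With the
lower-leaflet thickness deformation frozen out (``u^- = 0``), the elastic
energy of the remaining upper-leaflet height field ``h(r)`` and thickness
deformation field ``u(r)`` is, per unit length of helix,

    g = 1/2 { K_b [ h''^2 - h'' u'' + u''^2 / 2 ]
              + (K_t/2) (u/a)^2 + tau (u/a)
              + tau [ h'^2 - h' u' + u'^2 / 2 ] },

where ``r`` is the coordinate perpendicular to the (parallel) helix axes.
The substitution ``ubar = u + tau a / K_t`` and ``p = h - ubar / 2``
decouples the functional into

    g = 1/2 { K_b [ ubar''^2 / 4 + p''^2 ] + (K_t / 2 a^2) ubar^2
              + tau [ ubar'^2 / 4 + p'^2 ] }  -  tau^2 / (4 K_t).

The constant background ``-tau^2/(4 K_t)`` (the energy density of the
uniformly relaxed membrane under tension) is excluded from all energies
reported here; it cancels identically in interaction quantities.

The Euler-Lagrange equation for ``ubar`` is fourth order with inverse-square
decay constants ``nu_pm = (lambda_t^-2 +/- sqrt(lambda_t^-4 - lambda_s^-4))/2``
where ``lambda_t = sqrt(K_b/tau)`` and ``lambda_s = (K_b a^2 / 8 K_t)^(1/4)``.
At zero tension the roots are purely imaginary conjugates and the thickness
profile decays as an exponentially damped oscillation.  The auxiliary height
field ``p`` satisfies ``K_b p'''' = tau p''``; at ``tau = 0`` its general
solution is a cubic polynomial.

Boundary conditions at each bilayer-wedge contact, measured along the
outward normal ``n`` from the wedge (mirror-symmetric wedge cross section):

* ``u = U``            (imposed immersion depth),
* ``du/dn = slope_u``  (default 0),
* ``dh/dn = slope_h``  (default ``-tan 9 deg``).

The wedges are free to ride vertically; minimising the energy over the
height difference of the two wedges ("zero vertical force") eliminates the
odd cubic branch of ``p`` and is built into the solutions below.

Interaction potentials are differences of solved-region energies:
``G_int(d) = E_interior(d) - E_exterior(wedge_a) - E_exterior(wedge_b)``,
each scaled by the helix length ``L``.  Negative values are favourable.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq, minimize_scalar

from .errors import (
    BracketError,
    DegenerateParametersError,
    OverlapError,
    ParameterError,
    StateError,
)

#: Default contact slope of the height field, -tan(9 degrees).
DEFAULT_SLOPE_H = -math.tan(math.radians(9.0))

__all__ = [
    "DEFAULT_SLOPE_H",
    "BilayerParameters",
    "WedgeParameters",
    "DecayConstants",
    "DeformationProfile1D",
    "InteractionCurve",
    "decay_constants",
    "solve_pair_profile",
    "solve_isolated_profile",
    "profile_energy",
    "profile_energy_quadrature",
    "pair_interaction_energy",
    "interaction_curve",
    "dimerization_energy",
    "contact_cost",
    "critical_immersion_depth",
]


@dataclass(frozen=True)
class BilayerParameters:
    """Material constants of the lipid bilayer.

    Parameters
    ----------
    K_b : float
        Bending rigidity (k_BT).  Default 20.
    K_t : float
        Thickness deformation modulus (k_BT/nm^2).  Default 60.
    a : float
        Unperturbed monolayer hydrophobic thickness (nm).  Default 2.0.
    tau : float
        Membrane tension (k_BT/nm^2).  Default 0 (tensionless).
    """

    K_b: float = 20.0
    K_t: float = 60.0
    a: float = 2.0
    tau: float = 0.0

    def __post_init__(self) -> None:
        if not (self.K_b > 0):
            raise ParameterError(f"K_b must be positive, got {self.K_b}")
        if not (self.K_t > 0):
            raise ParameterError(f"K_t must be positive, got {self.K_t}")
        if not (self.a > 0):
            raise ParameterError(f"a must be positive, got {self.a}")
        if self.tau < 0:
            raise ParameterError(f"tau must be non-negative, got {self.tau}")

    @property
    def lambda_s(self) -> float:
        """Thickness-deformation decay length (K_b a^2 / 8 K_t)^(1/4), nm."""
        return (self.K_b * self.a**2 / (8.0 * self.K_t)) ** 0.25

    @property
    def lambda_t(self) -> float:
        """Tension length sqrt(K_b/tau), nm; infinite at tau = 0."""
        return math.inf if self.tau == 0.0 else math.sqrt(self.K_b / self.tau)

    @property
    def u_shift(self) -> float:
        """Shift tau*a/K_t relating ubar = u + u_shift (nm)."""
        return self.tau * self.a / self.K_t


@dataclass(frozen=True)
class WedgeParameters:
    """Geometry and contact conditions of one amphipathic wedge.

    ``U`` is the membrane immersion depth (nm, <= 0 for leaflet compression;
    0 is the shallow state, -0.9 the deep state measured for N-BAR H0
    helices).  ``L`` is the helix length (nm) and ``r0`` the wedge
    cross-sectional radius (nm).  ``slope_h`` and ``slope_u`` are the contact
    slopes of the height and thickness fields along the outward normal.
    """

    U: float = 0.0
    L: float = 3.0
    r0: float = 0.6
    slope_h: float = DEFAULT_SLOPE_H
    slope_u: float = 0.0

    def __post_init__(self) -> None:
        if not (self.r0 > 0):
            raise ParameterError(f"r0 must be positive, got {self.r0}")
        if not (self.L > 0):
            raise ParameterError(f"L must be positive, got {self.L}")


@dataclass(frozen=True)
class DecayConstants:
    """Characteristic scales of the thickness-deformation solution.

    ``nu_plus`` and ``nu_minus`` are the (generally complex) inverse-square
    decay lengths; at ``tau = 0`` they are purely imaginary conjugates.
    ``k_plus = sqrt(nu_plus)`` and ``k_minus`` are the decay roots chosen
    with non-negative real part so that decaying branches exist.
    """

    lambda_t: float
    lambda_s: float
    nu_plus: complex
    nu_minus: complex

    @property
    def k_plus(self) -> complex:
        k = cmath.sqrt(self.nu_plus)
        return -k if k.real < 0 else k

    @property
    def k_minus(self) -> complex:
        k = cmath.sqrt(self.nu_minus)
        return -k if k.real < 0 else k


def decay_constants(bilayer: BilayerParameters) -> DecayConstants:
    """Compute the decay constants of the 1D thickness-deformation solution."""
    lam_s = bilayer.lambda_s
    lam_t = bilayer.lambda_t
    inv_t2 = 0.0 if math.isinf(lam_t) else 1.0 / lam_t**2
    disc = cmath.sqrt(complex(inv_t2**2 - 1.0 / lam_s**4))
    nu_p = 0.5 * (inv_t2 + disc)
    nu_m = 0.5 * (inv_t2 - disc)
    return DecayConstants(lambda_t=lam_t, lambda_s=lam_s, nu_plus=nu_p, nu_minus=nu_m)


_IMAG_TOL = 1e-6  # conjugate pairing keeps residuals far below this


def _real(z: complex, what: str) -> float:
    if abs(z.imag) > _IMAG_TOL + 1e-8 * abs(z.real):
        raise StateError(f"{what} has non-negligible imaginary part: {z}")
    return z.real


@dataclass
class DeformationProfile1D:
    """A solved 1D deformation profile on one membrane region.

    ``kind`` is ``"interior"`` (the span between the facing edges of two
    wedges, domain ``[r_left, r_right]``) or ``"exterior"`` (the semi-infinite
    region outside one wedge, domain ``[0, inf)`` with ``r`` measured outward
    from the wedge edge).  The thickness part is stored as complex
    coefficients of exponent branches anchored at the region edges (well
    conditioned for wide spans); the auxiliary height part ``p = h - ubar/2``
    is polynomial at ``tau = 0`` and a combination of tension branches
    otherwise.  Evaluators return real values; conjugate pairing of the
    coefficients guarantees this to machine precision.
    """

    kind: str
    bilayer: BilayerParameters
    wedges: tuple[WedgeParameters, ...]
    r_left: float
    r_right: float  # inf for exterior
    roots: tuple[complex, complex]
    ubar_coeff: np.ndarray  # complex, 4 (interior) or 2 (exterior)
    p_poly: tuple[float, float, float]  # b0 + b1 r + b2 r^2 (polynomial mode)
    p_exp: tuple[float, float]  # c1 e^{(r-rR)/lt} + c2 e^{-(r-rL)/lt}
    p_mode: str = "poly"  # "poly" (tensionless limit) or "exp"

    # -- raw field evaluation -------------------------------------------------
    def _ubar(self, r: float, n: int = 0) -> float:
        k1, k2 = self.roots
        if self.kind == "interior":
            rl, rr = self.r_left, self.r_right
            basis = np.array(
                [
                    (-k1) ** n * cmath.exp(-k1 * (r - rl)),
                    (k1) ** n * cmath.exp(-k1 * (rr - r)),
                    (-k2) ** n * cmath.exp(-k2 * (r - rl)),
                    (k2) ** n * cmath.exp(-k2 * (rr - r)),
                ]
            )
        else:
            basis = np.array(
                [
                    (-k1) ** n * cmath.exp(-k1 * r),
                    (-k2) ** n * cmath.exp(-k2 * r),
                ]
            )
        return _real(complex(np.dot(self.ubar_coeff, basis)), "ubar")

    def _p(self, r: float, n: int = 0) -> float:
        if self.p_mode == "poly":
            b0, b1, b2 = self.p_poly
            if n == 0:
                return b0 + b1 * r + b2 * r * r
            if n == 1:
                return b1 + 2.0 * b2 * r
            if n == 2:
                return 2.0 * b2
            return 0.0
        lt = self.bilayer.lambda_t
        c1, c2 = self.p_exp
        if self.kind == "interior":
            e1 = math.exp((r - self.r_right) / lt)
            e2 = math.exp(-(r - self.r_left) / lt)
        else:
            e1 = 0.0
            e2 = math.exp(-r / lt)
        return (c1 * e1 + c2 * e2 * (-1.0) ** n) / lt**n

    # -- public evaluators ----------------------------------------------------
    def u_plus(self, r: float) -> float:
        """Thickness deformation u(r) in nm."""
        return self._ubar(r) - self.bilayer.u_shift

    def h_plus(self, r: float) -> float:
        """Height field h(r) in nm (reference level zero)."""
        return 0.5 * self._ubar(r) + self._p(r)

    def du_plus(self, r: float, n: int = 1) -> float:
        """n-th derivative of u(r)."""
        return self._ubar(r, n)

    def dh_plus(self, r: float, n: int = 1) -> float:
        """n-th derivative of h(r)."""
        return 0.5 * self._ubar(r, n) + self._p(r, n)


def _interior_p_part(
    bilayer: BilayerParameters,
    wedge_a: WedgeParameters,
    wedge_b: WedgeParameters,
    rl: float,
    rr: float,
) -> tuple[tuple[float, float, float], tuple[float, float], str]:
    """Height-field part of the interior solution.

    Contact slopes of p follow from dh/dn = slope_h and du/dn = slope_u with
    the outward normal +r at the left edge and -r at the right edge.  The
    zero-vertical-force (free wedge height) condition removes the cubic
    branch at tau = 0 and the linear branch at tau > 0.
    """
    s_l = wedge_a.slope_h - 0.5 * wedge_a.slope_u
    s_r = -wedge_b.slope_h + 0.5 * wedge_b.slope_u
    w = rr - rl
    lt = bilayer.lambda_t
    # the tension branches e^{±r/lambda_t} degenerate with {1, r} when the
    # span is tiny against lambda_t; use the tensionless quadratic there
    if bilayer.tau == 0.0 or w / lt < 1e-6:
        b2 = (s_r - s_l) / (2.0 * w)
        b1 = s_l - 2.0 * b2 * rl
        return (0.0, b1, b2), (0.0, 0.0), "poly"
    # p = c1 e^{(r-rr)/lt} + c2 e^{-(r-rl)/lt}
    e = math.exp(-w / lt)
    mat = np.array([[e / lt, -1.0 / lt], [1.0 / lt, -e / lt]])
    try:
        c1, c2 = np.linalg.solve(mat, [s_l, s_r])
    except np.linalg.LinAlgError as exc:  # pragma: no cover - tiny lt only
        raise DegenerateParametersError(str(exc)) from exc
    return (0.0, 0.0, 0.0), (float(c1), float(c2)), "exp"


def solve_pair_profile(
    bilayer: BilayerParameters,
    wedge_a: WedgeParameters,
    wedge_b: WedgeParameters,
    d: float,
) -> DeformationProfile1D:
    """Solve the interior region between two parallel wedges.

    ``d`` is the axis-to-axis separation (nm); the contact edges sit at
    ``-d/2 + r0_a`` and ``d/2 - r0_b``.  The six boundary conditions (three
    per edge) determine the four thickness coefficients exactly and the
    height part up to the wedge-height freedom, which is removed by energy
    minimisation.  Immersion depths may differ (asymmetric pair).
    """
    if d < wedge_a.r0 + wedge_b.r0:
        raise OverlapError(
            f"wedges overlap: d={d} < r0_a + r0_b = {wedge_a.r0 + wedge_b.r0}"
        )
    rl = -0.5 * d + wedge_a.r0
    rr = 0.5 * d - wedge_b.r0
    if rr - rl < 1e-3:
        raise DegenerateParametersError(
            f"interior span {rr - rl:.2e} nm at d={d} is too narrow to resolve"
        )
    dc = decay_constants(bilayer)
    k1, k2 = dc.k_plus, dc.k_minus
    if abs(k1 - k2) < 1e-12:
        raise DegenerateParametersError("degenerate decay roots (lambda_t = lambda_s)")
    shift = bilayer.u_shift
    # basis rows: value and first derivative at each edge
    def val_row(r: float) -> np.ndarray:
        return np.array(
            [
                cmath.exp(-k1 * (r - rl)),
                cmath.exp(-k1 * (rr - r)),
                cmath.exp(-k2 * (r - rl)),
                cmath.exp(-k2 * (rr - r)),
            ]
        )

    def der_row(r: float) -> np.ndarray:
        return np.array([-k1, k1, -k2, k2]) * val_row(r)

    mat = np.array([val_row(rl), der_row(rl), val_row(rr), der_row(rr)])
    rhs = np.array(
        [
            wedge_a.U + shift,
            wedge_a.slope_u,  # outward normal +r at left edge
            wedge_b.U + shift,
            -wedge_b.slope_u,  # outward normal -r at right edge
        ],
        dtype=complex,
    )
    try:
        coeff = np.linalg.solve(mat, rhs)
    except np.linalg.LinAlgError as exc:
        raise DegenerateParametersError(str(exc)) from exc
    p_poly, p_exp, p_mode = _interior_p_part(bilayer, wedge_a, wedge_b, rl, rr)
    return DeformationProfile1D(
        kind="interior",
        bilayer=bilayer,
        wedges=(wedge_a, wedge_b),
        r_left=rl,
        r_right=rr,
        roots=(k1, k2),
        ubar_coeff=coeff,
        p_poly=p_poly,
        p_exp=p_exp,
        p_mode=p_mode,
    )


def solve_isolated_profile(
    bilayer: BilayerParameters, wedge: WedgeParameters
) -> DeformationProfile1D:
    """Solve the semi-infinite exterior region on one side of a single wedge.

    Only decaying branches are kept, so ``u -> u_eq`` and the height field
    flattens far from the wedge.  Twice this region's energy is the
    large-separation reference of the pair problem.
    """
    dc = decay_constants(bilayer)
    k1, k2 = dc.k_plus, dc.k_minus
    if abs(k1 - k2) < 1e-12:
        raise DegenerateParametersError("degenerate decay roots (lambda_t = lambda_s)")
    shift = bilayer.u_shift
    mat = np.array([[1.0, 1.0], [-k1, -k2]])
    rhs = np.array([wedge.U + shift, wedge.slope_u], dtype=complex)
    try:
        coeff = np.linalg.solve(mat, rhs)
    except np.linalg.LinAlgError as exc:
        raise DegenerateParametersError(str(exc)) from exc
    s = wedge.slope_h - 0.5 * wedge.slope_u
    # a membrane-scale-irrelevant tension (lambda_t beyond ~1 mm) is treated
    # as tensionless to avoid overflowing tension-branch coefficients
    if bilayer.tau == 0.0 or bilayer.lambda_t > 1e6:
        p_poly, p_exp, p_mode = (0.0, s, 0.0), (0.0, 0.0), "poly"
    else:
        # p = c2 e^{-r/lambda_t}; p'(0) = -c2/lambda_t = s
        p_poly, p_exp, p_mode = (0.0, 0.0, 0.0), (0.0, -s * bilayer.lambda_t), "exp"
    return DeformationProfile1D(
        kind="exterior",
        bilayer=bilayer,
        wedges=(wedge,),
        r_left=0.0,
        r_right=math.inf,
        roots=(k1, k2),
        ubar_coeff=coeff,
        p_poly=p_poly,
        p_exp=p_exp,
        p_mode=p_mode,
    )


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------


def _boundary_bracket(profile: DeformationProfile1D, r: float) -> float:
    """Antiderivative of the on-shell energy density (total-derivative form).

    On solutions of the Euler-Lagrange equations the energy density is a
    total derivative; the bracket below, evaluated at the region endpoints,
    yields the region energy per unit helix length.  The tension background
    is excluded.
    """
    b = profile.bilayer
    h = profile.h_plus(r)
    h1 = profile.dh_plus(r, 1)
    h2 = profile.dh_plus(r, 2)
    h3 = profile.dh_plus(r, 3)
    u = profile._ubar(r, 0)
    u1 = profile._ubar(r, 1)
    u2 = profile._ubar(r, 2)
    u3 = profile._ubar(r, 3)
    kb_part = (
        h1 * h2
        - h * h3
        - 0.5 * h1 * u2
        + 0.5 * h * u3
        + 0.5 * u1 * u2
        - 0.5 * u * u3
        + 0.5 * u * h3
        - 0.5 * u1 * h2
    )
    tau_part = h * h1 - 0.5 * h * u1 + 0.5 * u * u1 - 0.5 * u * h1
    return 0.5 * b.K_b * kb_part + 0.5 * b.tau * tau_part


def profile_energy(
    profile: DeformationProfile1D, bilayer: BilayerParameters, L: float
) -> float:
    """Region energy (k_BT) from the boundary-term form, scaled by length L.

    Valid on solved (on-shell) profiles only; excludes the constant tension
    background.  Invariant under uniform shifts of the height field.
    """
    if profile.bilayer != bilayer:
        raise StateError("profile was solved with different bilayer parameters")
    if profile.kind == "interior":
        return L * (
            _boundary_bracket(profile, profile.r_right)
            - _boundary_bracket(profile, profile.r_left)
        )
    # exterior: bracket vanishes at infinity (decaying branches only)
    return -L * _boundary_bracket(profile, 0.0)


def _density(profile: DeformationProfile1D, r: float) -> float:
    """Background-subtracted energy density of the raw two-field functional."""
    b = profile.bilayer
    u = profile.u_plus(r)
    u1 = profile.du_plus(r, 1)
    u2 = profile.du_plus(r, 2)
    h1 = profile.dh_plus(r, 1)
    h2 = profile.dh_plus(r, 2)
    g = 0.5 * (
        b.K_b * (h2 * h2 - h2 * u2 + 0.5 * u2 * u2)
        + 0.5 * b.K_t * (u / b.a) ** 2
        + b.tau * (u / b.a)
        + b.tau * (h1 * h1 - h1 * u1 + 0.5 * u1 * u1)
    )
    return g + b.tau**2 / (4.0 * b.K_t)


def profile_energy_quadrature(
    profile: DeformationProfile1D, bilayer: BilayerParameters, L: float
) -> float:
    """Region energy by direct numerical quadrature of the energy density.

    Independent oracle for :func:`profile_energy`: integrates the raw
    height/thickness density (same background-subtraction convention) with
    adaptive quadrature instead of using the on-shell boundary form.
    """
    if profile.bilayer != bilayer:
        raise StateError("profile was solved with different bilayer parameters")
    if profile.kind == "interior":
        lo, hi = profile.r_left, profile.r_right
        val, _ = quad(lambda r: _density(profile, r), lo, hi, limit=400)
        return L * val
    # exterior: integrate to infinity; split at a few decay lengths for
    # accuracy of the oscillatory integrand
    lam = max(profile.bilayer.lambda_s, 1.0)
    split = 20.0 * lam
    v1, _ = quad(lambda r: _density(profile, r), 0.0, split, limit=400)
    v2, _ = quad(lambda r: _density(profile, r), split, np.inf, limit=200)
    return L * (v1 + v2)


def pair_interaction_energy(
    bilayer: BilayerParameters,
    wedge_a: WedgeParameters,
    wedge_b: WedgeParameters,
    d: float,
) -> float:
    """Interaction potential G_int(d) in k_BT for one pair of wedges.

    The large-separation reference is the closed-form sum of the two
    isolated semi-infinite exterior energies, so no numerical extrapolation
    enters.  Negative values are favourable.
    """
    if wedge_a.L != wedge_b.L:
        raise ParameterError("wedges in a pair must share the helix length L")
    L = wedge_a.L
    e_int = profile_energy(solve_pair_profile(bilayer, wedge_a, wedge_b, d), bilayer, L)
    e_a = profile_energy(solve_isolated_profile(bilayer, wedge_a), bilayer, L)
    e_b = profile_energy(solve_isolated_profile(bilayer, wedge_b), bilayer, L)
    return e_int - e_a - e_b


@dataclass
class InteractionCurve:
    """G_int versus axis-to-axis separation for a fixed wedge pair."""

    d_grid: np.ndarray
    g_int: np.ndarray
    bilayer: BilayerParameters
    wedge_a: WedgeParameters
    wedge_b: WedgeParameters

    def to_frame(self):
        """Two-column table (d_nm, G_int_kBT)."""
        import pandas as pd

        return pd.DataFrame({"d_nm": self.d_grid, "G_int_kBT": self.g_int})


def interaction_curve(
    bilayer: BilayerParameters,
    wedge_a: WedgeParameters,
    wedge_b: WedgeParameters,
    d_grid: np.ndarray,
) -> InteractionCurve:
    """Evaluate G_int on a grid of separations (all must exceed contact)."""
    d_grid = np.asarray(d_grid, dtype=float)
    contact = wedge_a.r0 + wedge_b.r0
    if np.any(d_grid < contact):
        raise OverlapError(f"all separations must be >= {contact} nm")
    g = np.array(
        [pair_interaction_energy(bilayer, wedge_a, wedge_b, d) for d in d_grid]
    )
    return InteractionCurve(d_grid, g, bilayer, wedge_a, wedge_b)


def dimerization_energy(
    bilayer: BilayerParameters,
    wedge_a: WedgeParameters,
    wedge_b: WedgeParameters,
    d_min: float | None = None,
    d_max: float = 10.0,
    n_grid: int = 400,
) -> tuple[float, float]:
    """Depth and location of the G_int minimum over ``[d_min, d_max]``.

    Returns ``(gain, d_star)`` where ``gain = -min G_int`` (positive when a
    bound dimer is favourable) and ``d_star`` is the optimal axis-to-axis
    separation.  ``d_min`` defaults to just outside wedge contact.
    """
    contact = wedge_a.r0 + wedge_b.r0
    if d_min is None:
        d_min = contact + 0.01
    if d_min < contact:
        raise ParameterError(f"d_min={d_min} is inside the hard core {contact}")
    if d_max <= d_min:
        raise ParameterError("empty separation bracket")
    ds = np.linspace(d_min, d_max, n_grid)
    g = np.array([pair_interaction_energy(bilayer, wedge_a, wedge_b, d) for d in ds])
    i = int(np.argmin(g))
    lo = ds[max(i - 1, 0)]
    hi = ds[min(i + 1, len(ds) - 1)]
    if hi > lo:
        res = minimize_scalar(
            lambda d: pair_interaction_energy(bilayer, wedge_a, wedge_b, d),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-6},
        )
        d_star, g_min = float(res.x), float(res.fun)
        if g_min > g[i]:
            d_star, g_min = float(ds[i]), float(g[i])
    else:  # pragma: no cover
        d_star, g_min = float(ds[i]), float(g[i])
    return -g_min, d_star


def contact_cost(
    bilayer: BilayerParameters,
    wedge_a: WedgeParameters,
    wedge_b: WedgeParameters,
    d_hi: float = 2.0,
    n_grid: int = 120,
) -> float:
    """Repulsive contact cost: min of G_int over the dimer-contact window.

    For shallow immersion the curve is repulsive everywhere; this reports
    the smallest repulsion a dimer at near-contact separation
    (``2 r0 <= d <= d_hi``) must pay.
    """
    contact = wedge_a.r0 + wedge_b.r0
    ds = np.linspace(contact + 0.01, d_hi, n_grid)
    g = np.array([pair_interaction_energy(bilayer, wedge_a, wedge_b, d) for d in ds])
    return float(np.min(g))


def critical_immersion_depth(
    bilayer: BilayerParameters,
    wedge_template: WedgeParameters,
    U_bracket: tuple[float, float] = (-0.7, -0.2),
    d_max: float = 10.0,
) -> float:
    """Immersion depth at which the minimal G_int over separation changes sign.

    Bisects ``U -> min_d G_int(U, d)`` within ``U_bracket`` to an absolute
    tolerance below 1e-3 nm.  Raises :class:`BracketError` when the bracket
    does not straddle the crossover.
    """

    def min_g(U: float) -> float:
        w = replace(wedge_template, U=U)
        gain, _ = dimerization_energy(bilayer, w, w, d_max=d_max)
        return -gain

    g_lo, g_hi = min_g(U_bracket[0]), min_g(U_bracket[1])
    if g_lo * g_hi > 0:
        raise BracketError(
            f"min_d G_int has no sign change on {U_bracket}: ({g_lo}, {g_hi})"
        )
    return float(brentq(min_g, U_bracket[0], U_bracket[1], xtol=1e-4))
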