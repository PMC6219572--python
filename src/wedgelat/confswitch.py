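"""Statistical mechanics of the concerted H0 immersion-depth switch.

A pair of membrane-bound N-BAR proteins diffuses on the membrane; each
protein is in the shallow (``s = 0``, U ~ 0 nm) or deep (``s = 1``,
U ~ -0.9 nm) H0 immersion state.  The pair energy splits into a
non-interacting part ``G_non(s1, s2) = (s1 + s2) eps_d`` (``eps_d`` is the
single-protein deep-shallow energy difference at infinite separation) and
the bilayer-mediated interaction ``G_int(s1, s2, r)`` obtained from the
analytic 1D solver with the face-on helices at axis-to-axis separation
``r`` (isotropic reduction).

Sampling over the separation within a disc of cutoff radius ``r_c`` gives
the configurational weight of a state pair

    z(s1, s2) = exp(-G_non) [ 1 + c pi Int_{2 r0}^{r_c} f12 r dr ],

with the Mayer function ``f12 = exp(-G_int) - 1`` and ``c = 2/A`` the
concentration of membrane-bound proteins (per nm^2).  The probability that
the pair is jointly deep is

    P_d = z(1,1) / [ z(0,0) + 2 z(0,1) + z(1,1) ].

In the dilute limit ``c -> 0`` this reduces to ``1/(1 + e^{eps_d})^2``.
All energies are dimensionless multiples of k_BT.

The weights are linear in ``c``: the Mayer integrals are computed once per
state pair (adaptive quadrature on a dense interpolant of ``G_int``, with
the near-contact region where ``exp(-G_int)`` underflows handled in closed
form), after which weights, probabilities and whole phase diagrams are
closed-form evaluations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import PchipInterpolator

from .elastic1d import (
    BilayerParameters,
    WedgeParameters,
    pair_interaction_energy,
)
from .errors import ParameterError, RangeError

__all__ = [
    "ConformationalModel",
    "PhaseDiagram",
    "state_interaction",
    "mayer_integral",
    "boltzmann_weight",
    "deep_state_probability",
    "phase_diagram",
]


@dataclass
class ConformationalModel:
    """Two-state conformational model of an N-BAR pair.

    ``epsilon_d`` (k_BT) is the deep-minus-shallow energy of one protein at
    infinite separation; ``U_map`` is implied by ``U_shallow``/``U_deep``;
    ``r_c`` is the pair-interaction cutoff (nm).  The wedge template fixes
    helix length, radius and contact slopes for both states.
    """

    epsilon_d: float = 2.0
    bilayer: BilayerParameters = field(default_factory=BilayerParameters)
    wedge_template: WedgeParameters = field(default_factory=WedgeParameters)
    U_shallow: float = 0.0
    U_deep: float = -0.9
    r_c: float = 40.0
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.r_min >= self.r_c:
            raise ParameterError("need r_min = 2 r0 < r_c")

    @property
    def r_min(self) -> float:
        return 2.0 * self.wedge_template.r0

    def wedge(self, s: int) -> WedgeParameters:
        U = self.U_deep if s else self.U_shallow
        return replace(self.wedge_template, U=U)

    def g_non(self, s1: int, s2: int) -> float:
        return (s1 + s2) * self.epsilon_d


def state_interaction(model: ConformationalModel, s1: int, s2: int, r: float) -> float:
    """G_int(s1, s2, r) in k_BT for one separation (exact solver call)."""
    if r < model.r_min:
        raise RangeError(f"separation {r} below the hard core {model.r_min}")
    return pair_interaction_energy(
        model.bilayer, model.wedge(s1), model.wedge(s2), r
    )


def _interpolant(model: ConformationalModel, s1: int, s2: int):
    """Dense monotone-cubic interpolant of G_int(r), cached per state pair."""
    key = tuple(sorted((s1, s2)))
    if key in model._cache:
        return model._cache[key]
    # below w = 0.01 nm span the repulsion exceeds ~300 k_BT, so the Mayer
    # function is -1 there to machine precision (handled in closed form)
    r_lo = model.r_min + 1e-2
    # dense near contact where G varies fastest, linear farther out
    r_grid = np.unique(
        np.concatenate(
            [
                r_lo + np.geomspace(1e-2, 3.0, 160) - 1e-2,
                np.linspace(r_lo + 3.0, model.r_c, 240),
            ]
        )
    )
    g = np.array(
        [
            pair_interaction_energy(model.bilayer, model.wedge(s1), model.wedge(s2), r)
            for r in r_grid
        ]
    )
    spline = PchipInterpolator(r_grid, g, extrapolate=False)
    i_min = int(np.argmin(g))
    model._cache[key] = (spline, r_lo, float(r_grid[i_min]))
    return model._cache[key]


def mayer_integral(model: ConformationalModel, s1: int, s2: int) -> float:
    """``Int_{2 r0}^{r_c} (exp(-G_int) - 1) r dr`` for one state pair (nm^2).

    Between the hard core and the first interpolation knot the repulsion
    diverges, so the Mayer function is -1 there (closed form); the rest is
    adaptive quadrature split at the potential minimum to resolve the deep
    attractive well.
    """
    spline, r_lo, r_star = _interpolant(model, s1, s2)

    def f(r: float) -> float:
        return (math.exp(-float(spline(r))) - 1.0) * r

    g_lo = float(spline(r_lo))
    if g_lo > 50.0:
        # divergent repulsive core: f = -1 below the first knot
        i_core = -0.5 * (r_lo**2 - model.r_min**2)
    else:
        # degenerate (weak) contact: treat G as constant over the thin band
        i_core = (math.exp(-g_lo) - 1.0) * 0.5 * (r_lo**2 - model.r_min**2)
    pieces = sorted({r_lo, r_star, model.r_c})
    total = i_core
    for a, b in zip(pieces[:-1], pieces[1:]):
        if b > a:
            val, _ = quad(f, a, b, epsrel=1e-6, epsabs=1e-9, limit=400)
            total += val
    return total


def boltzmann_weight(model: ConformationalModel, s1: int, s2: int, c: float) -> float:
    """Configurational weight z(s1, s2) at concentration c (proteins/nm^2).

    Raises :class:`RangeError` when the dilute-pair bracket
    ``1 + c pi I`` turns non-positive (the virial-type expansion has left
    its range of validity at this concentration).
    """
    if c <= 0.0:
        raise ParameterError(f"concentration must be positive, got {c}")
    bracket = 1.0 + c * math.pi * mayer_integral(model, s1, s2)
    if bracket <= 0.0:
        raise RangeError(
            f"weight bracket non-positive for state ({s1},{s2}) at c={c} nm^-2; "
            "concentration too high for the dilute-pair expansion"
        )
    return math.exp(-model.g_non(s1, s2)) * bracket


def deep_state_probability(model: ConformationalModel, c: float) -> float:
    """Probability that both proteins are in the deep immersion state."""
    z00 = boltzmann_weight(model, 0, 0, c)
    z01 = boltzmann_weight(model, 0, 1, c)
    z11 = boltzmann_weight(model, 1, 1, c)
    return z11 / (z00 + 2.0 * z01 + z11)


@dataclass
class PhaseDiagram:
    """P_d over a (concentration, epsilon_d) grid with its P_d = 1/2 contour."""

    c_grid: np.ndarray
    eps_grid: np.ndarray
    P_d: np.ndarray  # (n_eps, n_c)
    contour: list[tuple[float, float]]  # (c, eps) points where P_d = 1/2

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.P_d,
            index=pd.Index(self.eps_grid, name="epsilon_d_kBT"),
            columns=pd.Index(self.c_grid, name="c_per_nm2"),
        )


def phase_diagram(
    model: ConformationalModel,
    c_grid: np.ndarray,
    eps_grid: np.ndarray,
) -> PhaseDiagram:
    """Deep-state probability over the concentration/energy-difference plane.

    The Mayer integrals do not depend on ``epsilon_d``, so the whole matrix
    is closed-form once the three integrals are known.  The ``P_d = 1/2``
    contour is located by linear interpolation in ``c`` along each
    ``epsilon_d`` row (P_d is monotone in ``c`` for favourable deep
    interactions).
    """
    c_grid = np.asarray(c_grid, dtype=float)
    eps_grid = np.asarray(eps_grid, dtype=float)
    if c_grid.size == 0 or eps_grid.size == 0 or np.any(c_grid <= 0):
        raise ParameterError("grids must be non-empty with positive concentrations")
    i00 = mayer_integral(model, 0, 0)
    i01 = mayer_integral(model, 0, 1)
    i11 = mayer_integral(model, 1, 1)
    b00 = 1.0 + math.pi * c_grid * i00
    b01 = 1.0 + math.pi * c_grid * i01
    b11 = 1.0 + math.pi * c_grid * i11
    if np.any(b00 <= 0) or np.any(b01 <= 0) or np.any(b11 <= 0):
        bad = c_grid[(b00 <= 0) | (b01 <= 0) | (b11 <= 0)].min()
        raise RangeError(
            f"weight bracket non-positive from c={bad} nm^-2; reduce the c grid"
        )
    P = np.empty((eps_grid.size, c_grid.size))
    for i, eps in enumerate(eps_grid):
        e1 = math.exp(-eps)
        z00 = b00
        z01 = e1 * b01
        z11 = e1 * e1 * b11
        P[i] = z11 / (z00 + 2.0 * z01 + z11)
    contour: list[tuple[float, float]] = []
    for i, eps in enumerate(eps_grid):
        row = P[i]
        for j in range(len(c_grid) - 1):
            lo, hi = row[j] - 0.5, row[j + 1] - 0.5
            if lo == 0.0:
                contour.append((float(c_grid[j]), float(eps)))
            elif lo * hi < 0.0:
                t = -lo / (hi - lo)
                contour.append(
                    (float(c_grid[j] + t * (c_grid[j + 1] - c_grid[j])), float(eps))
                )
    return PhaseDiagram(c_grid=c_grid, eps_grid=eps_grid, P_d=P, contour=contour)
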