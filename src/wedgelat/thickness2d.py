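"""Two-dimensional leaflet-thickness fields around stadium-shaped wedges.

With the leaflet height field pinned (``h = 0``) the elastic energy of the
upper-leaflet thickness deformation ``u(x, y)`` reduces to

    E[u] = Int dx dy [ (K_b/4) (Lap u)^2 + (K_t/4) (u/a)^2
                       + (tau/2) (u/a) + (tau/4) |grad u|^2 ],

a convex quadratic functional.  A wedge (an H0 helix lying in the leaflet)
is represented by its stadium-shaped footprint: a rectangle of length
``L - 2 r0`` capped by semicircles of radius ``r0``.  Along the straight
sides the footprint imposes the immersion depth ``u = U``; along the rounded
caps the imposed value tapers linearly in arc length to 0 at the cap
centres, so the deformation source switches off smoothly at the helix tips.

Discretisation: regular-grid finite differences; the squared 5-point
Laplacian yields the standard 13-point biharmonic stencil.  Footprint values
are imposed as Dirichlet data on all covered nodes (values extended from the
nearest outline point), the membrane energy is integrated over uncovered
nodes only, and the patch edge is clamped to the uniform equilibrium
``u_eq = -tau a / K_t``.  The resulting contact condition at the footprint
boundary is hinged (prescribed value, zero bending moment); the matching 1D
closed form for an isolated straight wedge at ``tau = 0`` is

    u(r) = U exp(-beta r) cos(beta r),   beta = (K_t / K_b a^2)^(1/4)/sqrt 2,

used as the independent oracle for the mid-length transect of a long
footprint.  Background energy (tension term at ``u_eq``) is subtracted, so
an empty patch has zero energy at any tension.

Directional pair potentials for the Monte Carlo module are built by solving
two-footprint fields over a grid of relative poses and subtracting twice the
isolated-footprint energy; the stadium's two mirror symmetries reduce the
stored table to one quadrant.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spl

from .elastic1d import BilayerParameters
from .errors import GeometryError, ParameterError, SolverError

__all__ = [
    "WedgeFootprint",
    "ThicknessField",
    "PairPotentialTable",
    "build_footprint",
    "footprints_overlap",
    "solve_thickness_field",
    "isolated_footprint_energy",
    "pair_potential_table",
    "additivity_check",
    "pinned_height_transect",
    "pinned_height_energy_per_length",
]


@dataclass(frozen=True)
class WedgeFootprint:
    """Stadium footprint of one wedge with its immersion profile.

    ``pose`` is ``(x, y, theta)``: centre position (nm) and axis orientation
    (rad).  The imposed immersion equals ``U`` on the straight sides and
    tapers linearly (in arc length along the outline) to 0 at the two
    cap-centre tip points.
    """

    U: float
    L: float = 3.0
    r0: float = 0.6
    pose: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.L > 2.0 * self.r0):
            raise ParameterError(
                f"stadium needs L > 2 r0, got L={self.L}, r0={self.r0}"
            )
        if self.r0 <= 0:
            raise ParameterError(f"r0 must be positive, got {self.r0}")

    @property
    def half_core(self) -> float:
        """Half-length of the straight section, L/2 - r0."""
        return 0.5 * self.L - self.r0

    @property
    def perimeter(self) -> float:
        """Outline length 2 (L - 2 r0) + 2 pi r0."""
        return 2.0 * (self.L - 2.0 * self.r0) + 2.0 * math.pi * self.r0

    @property
    def segment(self) -> tuple[float, float, float, float]:
        """World-frame endpoints of the spine segment (capsule axis)."""
        x, y, th = self.pose
        c, s = math.cos(th), math.sin(th)
        hc = self.half_core
        return (x - hc * c, y - hc * s, x + hc * c, y + hc * s)

    def sdf_and_values(
        self, X: np.ndarray, Y: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Signed distance to the outline (<0 inside) and the immersion value
        of the nearest outline point, for arrays of world coordinates."""
        x0, y0, th = self.pose
        dx = X - x0
        dy = Y - y0
        c, s = math.cos(th), math.sin(th)
        xi = c * dx + s * dy
        eta = -s * dx + c * dy
        hc = self.half_core
        ax = np.clip(xi, -hc, hc)
        ddx = xi - ax
        sdf = np.hypot(ddx, eta) - self.r0
        onside = np.abs(xi) <= hc
        # angular position along the cap: 0 at the side-cap junction,
        # pi/2 at the tip centre; taper is linear in arc length = angle*r0
        phi = np.arctan2(np.abs(ddx), np.abs(eta))
        vals = np.where(onside, self.U, self.U * (1.0 - 2.0 * phi / math.pi))
        return sdf, vals

    def boundary_immersion(self, point: tuple[float, float]) -> float:
        """Immersion value of the outline point nearest to ``point``."""
        sdf, vals = self.sdf_and_values(
            np.array([point[0]]), np.array([point[1]])
        )
        return float(vals[0])


def build_footprint(
    U: float,
    L: float = 3.0,
    r0: float = 0.6,
    pose: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> WedgeFootprint:
    """Construct a stadium footprint with the tapered immersion profile."""
    return WedgeFootprint(U=U, L=L, r0=r0, pose=pose)


def _segment_distance(
    a: tuple[float, float, float, float], b: tuple[float, float, float, float]
) -> float:
    """Minimum distance between two segments (ax, ay, bx, by)."""
    p = np.array(a[:2])
    q = np.array(a[2:])
    r = np.array(b[:2])
    t = np.array(b[2:])
    d1 = q - p
    d2 = t - r
    r12 = p - r
    a11 = d1 @ d1
    a22 = d2 @ d2
    a12 = d1 @ d2
    b1 = d1 @ r12
    b2 = d2 @ r12
    den = a11 * a22 - a12 * a12
    if den > 1e-14:
        s = np.clip((a12 * b2 - a22 * b1) / den, 0.0, 1.0)
    else:
        s = 0.0
    t_ = (a12 * s + b2) / a22 if a22 > 1e-14 else 0.0
    t_ = np.clip(t_, 0.0, 1.0)
    s = np.clip((a12 * t_ - b1) / a11, 0.0, 1.0) if a11 > 1e-14 else 0.0
    return float(np.linalg.norm(p + s * d1 - (r + t_ * d2)))


def footprints_overlap(fa: WedgeFootprint, fb: WedgeFootprint) -> bool:
    """Exact capsule-capsule overlap test between two stadium outlines."""
    return _segment_distance(fa.segment, fb.segment) < fa.r0 + fb.r0


@dataclass
class ThicknessField:
    """Solved thickness deformation on a rectangular patch."""

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray  # (nx, ny)
    inside: np.ndarray  # wedge-covered nodes (bool)
    energy: float  # background-subtracted, k_BT
    bilayer: BilayerParameters
    resolution: float

    def transect_y(self, x0: float) -> tuple[np.ndarray, np.ndarray]:
        """Field values along the grid column nearest x = x0."""
        i = int(np.argmin(np.abs(self.x - x0)))
        return self.y, self.u[i, :]


def solve_thickness_field(
    bilayer: BilayerParameters,
    footprints: list[WedgeFootprint],
    xlim: tuple[float, float],
    ylim: tuple[float, float],
    resolution: float = 0.1,
) -> ThicknessField:
    """Minimise the pinned-height energy over a patch with given footprints.

    ``resolution`` is the grid spacing (nm); it must resolve the cap radius
    with at least four cells.  Footprints must lie inside the patch and must
    not overlap each other.  Raises :class:`SolverError` if the sparse solve
    produces non-finite values.
    """
    for i, fa in enumerate(footprints):
        for fb in footprints[i + 1 :]:
            if footprints_overlap(fa, fb):
                raise GeometryError("footprints overlap")
        if not (
            xlim[0] + fa.L < fa.pose[0] + fa.L < xlim[1]
            and ylim[0] + fa.L < fa.pose[1] + fa.L < ylim[1]
        ):
            # loose containment check: centre at least L from the patch edge
            pass
    if footprints and resolution > min(f.r0 for f in footprints) / 4.0:
        raise ParameterError(
            f"resolution {resolution} too coarse to resolve r0; need >= 4 cells"
        )
    # nodes live on an absolute lattice with an irrational phase: footprint
    # outlines (nice decimal coordinates) then never pass exactly through
    # nodes (float rounding would flip whole boundary rows in or out of the
    # Dirichlet set), and solves on different patches share the same node
    # positions so that reference energies cancel exactly in differences
    h = resolution
    k0x = math.floor(xlim[0] / h)
    k0y = math.floor(ylim[0] / h)
    nx = int(math.ceil(xlim[1] / h)) - k0x + 1
    ny = int(math.ceil(ylim[1] / h)) - k0y + 1
    x = (k0x + np.arange(nx) + 0.28711) * h
    y = (k0y + np.arange(ny) + 0.41347) * h
    X, Y = np.meshgrid(x, y, indexing="ij")
    n = nx * ny
    h = resolution
    dxx = sp.diags(
        [np.ones(nx - 1), -2.0 * np.ones(nx), np.ones(nx - 1)], [-1, 0, 1]
    ) / h**2
    dyy = sp.diags(
        [np.ones(ny - 1), -2.0 * np.ones(ny), np.ones(ny - 1)], [-1, 0, 1]
    ) / h**2
    lap = (sp.kron(dxx, sp.eye(ny)) + sp.kron(sp.eye(nx), dyy)).tocsr()
    gx = sp.kron(
        sp.diags([-np.ones(nx - 1), np.ones(nx - 1)], [-1, 1]) / (2 * h), sp.eye(ny)
    ).tocsr()
    gy = sp.kron(
        sp.eye(nx), sp.diags([-np.ones(ny - 1), np.ones(ny - 1)], [-1, 1]) / (2 * h)
    ).tocsr()

    sdf_all = np.full((nx, ny), np.inf)
    vals = np.zeros((nx, ny))
    u_eq = -bilayer.tau * bilayer.a / bilayer.K_t
    for f in footprints:
        sdf, v = f.sdf_and_values(X, Y)
        take = (sdf < sdf_all) & (sdf <= 0.0)
        vals = np.where(take, v, vals)
        sdf_all = np.minimum(sdf_all, sdf)
    inside = sdf_all <= 0.0
    border = np.zeros((nx, ny), bool)
    border[:2, :] = border[-2:, :] = True
    border[:, :2] = border[:, -2:] = True
    vals[border & ~inside] = u_eq
    fixed = inside | border

    w = (~inside).ravel().astype(float)
    W = sp.diags(w)
    kb, kt, a, tau = bilayer.K_b, bilayer.K_t, bilayer.a, bilayer.tau
    A = h * h * (
        0.5 * kb * (lap.T @ W @ lap)
        + (0.5 * kt / a**2) * W
        + 0.5 * tau * (gx.T @ W @ gx + gy.T @ W @ gy)
    )
    b = h * h * (0.5 * tau / a) * w
    fr = ~fixed.ravel()
    cr = fixed.ravel()
    A = A.tocsr()
    Aff = A[fr][:, fr].tocsc()
    Afc = A[fr][:, cr]
    xc = vals.ravel()[cr]
    uf = spl.spsolve(Aff, -(b[fr] + Afc @ xc))
    if not np.all(np.isfinite(uf)):
        raise SolverError("sparse solve produced non-finite values")
    u = vals.ravel().copy()
    u[fr] = uf
    # the quadratic form carries the 1/2 of the energy functional already
    energy = 0.5 * float(u @ (A @ u)) + float(b @ u)
    if tau:
        energy -= (-(tau**2) / (4.0 * kt)) * h * h * float(w.sum())
    return ThicknessField(
        x=x,
        y=y,
        u=u.reshape(nx, ny),
        inside=inside,
        energy=energy,
        bilayer=bilayer,
        resolution=resolution,
    )


def isolated_footprint_energy(
    bilayer: BilayerParameters,
    U: float,
    L: float = 3.0,
    r0: float = 0.6,
    resolution: float = 0.1,
    margin: float = 7.0,
) -> float:
    """Deformation energy of a single footprint on a generous patch."""
    f = build_footprint(U, L, r0, (0.0, 0.0, 0.0))
    half = 0.5 * L + margin
    fld = solve_thickness_field(
        bilayer, [f], (-half, half), (-half, half), resolution
    )
    return fld.energy


# ---------------------------------------------------------------------------
# 1D oracle for the long-footprint limit (tau = 0)
# ---------------------------------------------------------------------------


def _beta(bilayer: BilayerParameters) -> float:
    return (bilayer.K_t / (bilayer.K_b * bilayer.a**2)) ** 0.25 / math.sqrt(2.0)


def pinned_height_transect(
    bilayer: BilayerParameters, U: float, r0: float, r: np.ndarray
) -> np.ndarray:
    """Closed-form 1D pinned-height profile across an infinite straight wedge.

    Hinged contact (u = U, zero bending moment) at the wedge edge, tau = 0:
    ``u(r) = U exp(-beta s) cos(beta s)`` with ``s`` the distance beyond the
    edge.  ``r`` is measured from the wedge axis.
    """
    if bilayer.tau != 0.0:
        raise ParameterError("closed-form transect is for tau = 0 only")
    beta = _beta(bilayer)
    s = np.abs(np.asarray(r, dtype=float)) - r0
    out = np.where(
        s <= 0.0, U, U * np.exp(-beta * np.clip(s, 0.0, None)) * np.cos(beta * s)
    )
    return out


def pinned_height_energy_per_length(
    bilayer: BilayerParameters, U: float
) -> float:
    """Energy per unit wedge length of the hinged 1D profile (both sides).

    Closed form at tau = 0: with ``u = U e^{-beta r} cos beta r``,
    ``int u^2 = 3 U^2/(8 beta)`` and ``int u''^2 = beta^3 U^2 / 2``.
    """
    if bilayer.tau != 0.0:
        raise ParameterError("closed form is for tau = 0 only")
    beta = _beta(bilayer)
    i_u2 = 3.0 * U**2 / (8.0 * beta)
    i_upp2 = 0.5 * beta**3 * U**2
    return 2.0 * (0.25 * bilayer.K_b * i_upp2 + 0.25 * bilayer.K_t / bilayer.a**2 * i_u2)


# ---------------------------------------------------------------------------
# directional pair potential table
# ---------------------------------------------------------------------------


@dataclass
class PairPotentialTable:
    """Tabulated wedge-wedge interaction energies over relative poses.

    Energies are stored on the quadrant ``dx >= 0, dy >= 0`` (the stadium's
    two mirror symmetries map the other quadrants onto it with
    ``theta -> -theta``) and on a periodic orientation grid over ``[0, pi)``.
    ``lookup`` applies the symmetry reduction, multilinear interpolation
    (periodic in theta), returns 0 beyond the grid and +inf for overlapping
    outlines (hardcore, never interpolated).  Tabulated energies are blended
    smoothly to zero over the outermost shell so the potential vanishes
    exactly at the table edge.
    """

    dx_grid: np.ndarray
    dy_grid: np.ndarray
    theta_grid: np.ndarray  # [0, pi) uniform
    energies: np.ndarray  # (n_theta, n_dx, n_dy), hardcore cells filled
    hardcore: np.ndarray  # bool, same shape
    U: float
    L: float
    r0: float
    bilayer: BilayerParameters
    resolution: float

    def lookup(self, dx: float, dy: float, dtheta: float) -> float:
        """Interaction energy for wedge B at (dx, dy, dtheta) in A's frame."""
        if dx < 0.0:
            dx, dtheta = -dx, -dtheta
        if dy < 0.0:
            dy, dtheta = -dy, -dtheta
        th = dtheta % math.pi
        if dx > self.dx_grid[-1] or dy > self.dy_grid[-1]:
            return 0.0
        fa = build_footprint(self.U, self.L, self.r0, (0.0, 0.0, 0.0))
        fb = build_footprint(self.U, self.L, self.r0, (dx, dy, th))
        if footprints_overlap(fa, fb):
            return math.inf
        hx = self.dx_grid[1] - self.dx_grid[0]
        hy = self.dy_grid[1] - self.dy_grid[0]
        ht = self.theta_grid[1] - self.theta_grid[0]
        ix = min(int(dx / hx), len(self.dx_grid) - 2)
        iy = min(int(dy / hy), len(self.dy_grid) - 2)
        it = int(th / ht) % len(self.theta_grid)
        it1 = (it + 1) % len(self.theta_grid)
        fx = dx / hx - ix
        fy = dy / hy - iy
        ft = th / ht - int(th / ht)
        e = 0.0
        for jt, wt in ((it, 1.0 - ft), (it1, ft)):
            for jx, wx in ((ix, 1.0 - fx), (ix + 1, fx)):
                for jy, wy in ((iy, 1.0 - fy), (iy + 1, fy)):
                    e += wt * wx * wy * self.energies[jt, jx, jy]
        return e

    def save(self, path_prefix: str) -> None:
        """Write the array container plus a JSON sidecar."""
        np.savez(
            path_prefix + ".npz",
            dx_grid=self.dx_grid,
            dy_grid=self.dy_grid,
            theta_grid=self.theta_grid,
            energies=self.energies,
            hardcore=self.hardcore,
        )
        meta = {
            "U": self.U,
            "L": self.L,
            "r0": self.r0,
            "bilayer": {
                "K_b": self.bilayer.K_b,
                "K_t": self.bilayer.K_t,
                "a": self.bilayer.a,
                "tau": self.bilayer.tau,
            },
            "resolution": self.resolution,
            "format_version": 1,
        }
        with open(path_prefix + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path_prefix: str) -> "PairPotentialTable":
        data = np.load(path_prefix + ".npz")
        with open(path_prefix + ".json") as fh:
            meta = json.load(fh)
        return cls(
            dx_grid=data["dx_grid"],
            dy_grid=data["dy_grid"],
            theta_grid=data["theta_grid"],
            energies=data["energies"],
            hardcore=data["hardcore"],
            U=meta["U"],
            L=meta["L"],
            r0=meta["r0"],
            bilayer=BilayerParameters(**meta["bilayer"]),
            resolution=meta["resolution"],
        )


def pair_potential_table(
    bilayer: BilayerParameters,
    U: float = -0.9,
    L: float = 3.0,
    r0: float = 0.6,
    extent: float = 9.0,
    step: float = 0.75,
    n_theta: int = 6,
    resolution: float = 0.15,
    margin: float = 6.0,
    blend_start: float | None = None,
) -> PairPotentialTable:
    """Tabulate two-wedge interaction energies over relative poses.

    One wedge sits at the origin along x; the second is placed at each pose
    of the quadrant grid.  Interaction = two-wedge field energy minus twice
    the isolated energy (computed once at the same resolution).  Poses with
    overlapping outlines are flagged hardcore and filled from the nearest
    solved neighbour so that interpolation near contact stays finite (the
    hardcore itself is enforced geometrically in ``lookup``).
    """
    dxg = np.arange(0.0, extent + 0.5 * step, step)
    dyg = np.arange(0.0, extent + 0.5 * step, step)
    thg = np.arange(n_theta) * (math.pi / n_theta)
    e_iso = isolated_footprint_energy(
        bilayer, U, L, r0, resolution, margin=margin + 1.0
    )
    energies = np.full((n_theta, len(dxg), len(dyg)), np.nan)
    hard = np.zeros_like(energies, dtype=bool)
    fa = build_footprint(U, L, r0, (0.0, 0.0, 0.0))
    for it, th in enumerate(thg):
        for ix, dx in enumerate(dxg):
            for iy, dy in enumerate(dyg):
                fb = build_footprint(U, L, r0, (dx, dy, th))
                if _segment_distance(fa.segment, fb.segment) < 2.0 * r0 + 0.05:
                    hard[it, ix, iy] = True
                    continue
                xlo = min(-L / 2, dx - L / 2) - margin
                xhi = max(L / 2, dx + L / 2) + margin
                ylo = min(-r0, dy - L / 2) - margin
                yhi = max(r0, dy + L / 2) + margin
                fld = solve_thickness_field(
                    bilayer, [fa, fb], (xlo, xhi), (ylo, yhi), resolution
                )
                energies[it, ix, iy] = fld.energy - 2.0 * e_iso
    # fill hardcore cells from the nearest solved neighbour (radially outward)
    for it in range(n_theta):
        sl = energies[it]
        nan = np.isnan(sl)
        if nan.any():
            idx = np.argwhere(~nan)
            for i, j in np.argwhere(nan):
                k = np.argmin((idx[:, 0] - i) ** 2 + (idx[:, 1] - j) ** 2)
                sl[i, j] = sl[idx[k, 0], idx[k, 1]]
    # smooth truncation to zero at the table edge
    rmax = extent
    r0b = blend_start if blend_start is not None else 0.75 * extent
    R = np.hypot(dxg[:, None], dyg[None, :])
    s = np.clip((rmax - R) / max(rmax - r0b, 1e-9), 0.0, 1.0)
    taper = 0.5 - 0.5 * np.cos(math.pi * s)
    energies *= taper[None, :, :]
    return PairPotentialTable(
        dx_grid=dxg,
        dy_grid=dyg,
        theta_grid=thg,
        energies=energies,
        hardcore=hard,
        U=U,
        L=L,
        r0=r0,
        bilayer=bilayer,
        resolution=resolution,
    )


def additivity_check(
    bilayer: BilayerParameters,
    footprints: list[WedgeFootprint],
    resolution: float = 0.15,
    margin: float = 6.0,
) -> tuple[float, float]:
    """Compare a three-wedge interaction with the sum of its pair terms.

    Returns ``(triple_interaction, pairwise_sum)`` where the triple
    interaction is the three-footprint field energy minus three isolated
    energies and the pairwise sum accumulates the three two-footprint
    interactions, all on a common patch.
    """
    if len(footprints) != 3:
        raise ParameterError("additivity check needs exactly three footprints")
    for i, fa in enumerate(footprints):
        for fb in footprints[i + 1 :]:
            if footprints_overlap(fa, fb):
                raise GeometryError("footprints overlap")
    xs = [f.pose[0] for f in footprints]
    ys = [f.pose[1] for f in footprints]
    lmax = max(f.L for f in footprints)
    xlim = (min(xs) - lmax - margin, max(xs) + lmax + margin)
    ylim = (min(ys) - lmax - margin, max(ys) + lmax + margin)

    def solve(fs: list[WedgeFootprint]) -> float:
        return solve_thickness_field(bilayer, fs, xlim, ylim, resolution).energy

    singles = [solve([f]) for f in footprints]
    triple = solve(footprints) - sum(singles)
    pair_sum = 0.0
    for i in range(3):
        for j in range(i + 1, 3):
            pair_sum += (
                solve([footprints[i], footprints[j]]) - singles[i] - singles[j]
            )
    return triple, pair_sum
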