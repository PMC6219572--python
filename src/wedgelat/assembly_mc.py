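"""Rigid-body simulated annealing of N-BAR proteins in a periodic box.

An N-BAR protein is modelled as a rigid 2D body: a crescent backbone (the
BAR domain, a chain of capsules) with one H0 helix footprint near each tip.
Proteins interact through

* hardcore sterics (capsule-capsule, exact segment distances),
* the tabulated bilayer-thickness-mediated H0-H0 pair potential
  (:class:`~wedgelat.thickness2d.PairPotentialTable`, four H0 pairs per
  protein pair; intra-protein H0 pairs are rigid and excluded), and
* optionally a modified Lennard-Jones BAR-BAR potential
  ``eps [ (r_m/r)^12 - 2 (r_m/r)^6 (1 - |2 th1 - pi|/2pi - |2 th2 - pi|/2pi) ]``
  between protein centres, with the orientations ``th_i`` of the BAR axes
  measured against the centre-connecting line modulo pi (face-on pairs,
  th1 = th2 = pi/2, attract most strongly).

Energies are in units of k_B T_rm (room temperature); the Monte Carlo
temperature is dimensionless in units of T_rm.  One Monte Carlo step
performs one translation trial (±delta_r) and one rotation trial
(±delta_theta) per protein in a freshly shuffled order, accepted by the
Metropolis rule; annealing runs a hot phase at constant T followed by a
linear ramp to T = 0.  Trajectories are reproducible functions of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _mc
from .errors import DensityError, ParameterError, StateError
from .thickness2d import PairPotentialTable

__all__ = [
    "NBARShape",
    "Configuration",
    "AnnealSchedule",
    "ChainStats",
    "bar_pair_potential",
    "random_configuration",
    "total_energy",
    "metropolis_sweep",
    "anneal",
    "chain_statistics",
]

T_ROOM_K = 298.0  # room temperature, the unit of the dimensionless T


@dataclass(frozen=True)
class NBARShape:
    """Rigid geometry of one N-BAR protein (nm, body frame).

    The backbone is a crescent polyline of capsules bowing towards +y; the
    two H0 footprints protrude axially past the backbone tips, with helix
    axes along ±x (directions outward, matching the C2 symmetry of the
    N-BAR dimer) and a slight offset towards the -y "outer" side.  With
    near-axial H0 helices, lateral face-to-face pairing of two proteins
    would force their backbones closer than one backbone diameter and is
    sterically excluded, so H0 dimerisation happens tip-to-tail as observed.
    The BAR-BAR pair potential acts between the backbone centroids
    (``bar_center``, offset towards the concave side), which lifts the
    outer/inner degeneracy of dimer links.  All dimensions are free
    parameters; the defaults give a backbone span comparable to the BAR-BAR
    potential minimum distance r_m = 10 nm.
    """

    backbone: tuple[tuple[float, float], ...] = (
        (-4.3, 0.0),
        (-1.8, 1.1),
        (1.8, 1.1),
        (4.3, 0.0),
    )
    bar_radius: float = 0.9
    h0_x: float = 5.7
    h0_y: float = -0.14
    h0_L: float = 3.0
    h0_r0: float = 0.6
    bar_center: tuple[float, float] = (0.0, 0.8)

    def __post_init__(self) -> None:
        if 2.0 * self.h0_x < self.h0_L:
            raise ParameterError("the two H0 footprints of one protein overlap")

    @property
    def capsules(self) -> np.ndarray:
        """(K, 5) array of steric capsules [ax, ay, bx, by, radius]."""
        rows = []
        pts = self.backbone
        for (ax, ay), (bx, by) in zip(pts[:-1], pts[1:]):
            rows.append((ax, ay, bx, by, self.bar_radius))
        hc = 0.5 * self.h0_L - self.h0_r0
        for sgn in (+1.0, -1.0):
            cx = sgn * self.h0_x
            rows.append((cx - hc, self.h0_y, cx + hc, self.h0_y, self.h0_r0))
        return np.array(rows, dtype=np.float64)

    @property
    def h0_frames(self) -> np.ndarray:
        """(2, 3) array [centre_x, centre_y, axis_angle] of the H0 helices.

        The helix direction points outward along the protein axis (the two
        H0 helices of the rigid dimer run antiparallel to each other).
        """
        return np.array(
            [
                [self.h0_x, self.h0_y, 0.0],
                [-self.h0_x, self.h0_y, math.pi],
            ],
            dtype=np.float64,
        )

    @property
    def reach(self) -> float:
        """Radius of the smallest origin-centred disc containing the body."""
        caps = self.capsules
        r = 0.0
        for ax, ay, bx, by, rad in caps:
            r = max(r, math.hypot(ax, ay) + rad, math.hypot(bx, by) + rad)
        return r


@dataclass
class Configuration:
    """Poses of N proteins in a periodic square box."""

    box: float
    poses: np.ndarray  # (N, 3): x, y, theta
    shape: NBARShape = field(default_factory=NBARShape)
    seed: int | None = None  # provenance of the generating RNG

    def __post_init__(self) -> None:
        self.poses = np.ascontiguousarray(self.poses, dtype=np.float64)
        if self.poses.ndim != 2 or self.poses.shape[1] != 3:
            raise ParameterError("poses must be an (N, 3) array")

    @property
    def n(self) -> int:
        return self.poses.shape[0]

    def copy(self) -> "Configuration":
        return Configuration(self.box, self.poses.copy(), self.shape, self.seed)


@dataclass(frozen=True)
class AnnealSchedule:
    """Simulated-annealing protocol.

    Full-scale defaults: 1e7 steps at constant T = 2 (units of room
    temperature) followed by a linear ramp to T = 0 over 5e6 steps, with
    0.1 nm translation and 1 degree rotation trials.  Scaled-down runs are
    produced with :func:`dataclasses.replace` and recorded in run metadata.
    """

    n_hot: int = 10_000_000
    n_cool: int = 5_000_000
    t_hot: float = 2.0
    delta_r: float = 0.1
    delta_theta: float = math.pi / 180.0
    seed: int = 0


def bar_pair_potential(
    r: float, theta1: float, theta2: float, eps: float = 10.0, r_m: float = 10.0
) -> float:
    """Modified Lennard-Jones BAR-BAR pair potential (k_BT).

    ``r`` is the centre-to-centre distance (nm); ``theta1``, ``theta2`` are
    the BAR orientations against the centre line, reduced modulo pi.  At
    ``r = r_m`` with both proteins face-on the energy is exactly ``-eps``.
    """
    if r <= 0.0:
        raise ParameterError("BAR pair potential diverges at r = 0")
    t1 = theta1 % math.pi
    t2 = theta2 % math.pi
    ang = 1.0 - abs(2.0 * t1 - math.pi) / (2.0 * math.pi) - abs(
        2.0 * t2 - math.pi
    ) / (2.0 * math.pi)
    sr6 = (r_m / r) ** 6
    return eps * (sr6 * sr6 - 2.0 * sr6 * ang)


def _table_args(table: PairPotentialTable | None):
    if table is None:
        # zero-energy table spanning nothing: every lookup returns 0
        en = np.zeros((2, 2, 2), dtype=np.float64)
        return en, 1.0, 1.0, math.pi / 2.0, 0.0, 0.0
    en = np.ascontiguousarray(table.energies, dtype=np.float64)
    hx = float(table.dx_grid[1] - table.dx_grid[0])
    hy = float(table.dy_grid[1] - table.dy_grid[0])
    ht = float(table.theta_grid[1] - table.theta_grid[0])
    return en, hx, hy, ht, float(table.dx_grid[-1]), float(table.dy_grid[-1])


def _mc_args(config: Configuration, table, bar_on, eps, r_m):
    en, hx, hy, ht, xmax, ymax = _table_args(table)
    shape = config.shape
    caps = shape.capsules
    h0s = shape.h0_frames
    reach = shape.reach
    h0_cut = xmax + 2.0 * math.hypot(shape.h0_x, shape.h0_y) + shape.h0_L
    return (
        caps, h0s, float(shape.bar_center[0]), float(shape.bar_center[1]),
        en, hx, hy, ht, xmax, ymax,
        bool(bar_on), float(eps), float(r_m),
        float(config.box), reach, h0_cut,
    )


def total_energy(
    config: Configuration,
    h0_table: PairPotentialTable | None,
    bar_on: bool = False,
    eps: float = 10.0,
    r_m: float = 10.0,
) -> float:
    """Total pair energy of a configuration (k_BT); inf on steric overlap."""
    if h0_table is None and not bar_on:
        pass  # sterics-only energy is still well defined (0 or inf)
    e = _mc._total_energy(config.poses, *_mc_args(config, h0_table, bar_on, eps, r_m))
    return math.inf if e >= _mc.BIG else float(e)


def random_configuration(
    n: int,
    box: float,
    shape: NBARShape | None = None,
    seed: int = 0,
    max_tries: int = 2000,
) -> Configuration:
    """Rejection-sample an overlap-free random configuration."""
    shape = shape or NBARShape()
    rng = np.random.default_rng(seed)
    caps = shape.capsules
    placed: list[tuple[float, float, float]] = []
    zero_tab = _table_args(None)
    for _ in range(n):
        for attempt in range(max_tries):
            x = rng.uniform(0.0, box)
            y = rng.uniform(0.0, box)
            th = rng.uniform(0.0, 2.0 * math.pi)
            ok = True
            for (px, py, pth) in placed:
                e = _mc._pair_energy(
                    x, y, th, px, py, pth,
                    caps, shape.h0_frames, 0.0, 0.0, *zero_tab,
                    False, 0.0, 1.0, box, shape.reach, 0.0,
                )
                if e >= _mc.BIG:
                    ok = False
                    break
            if ok:
                placed.append((x, y, th))
                break
        else:
            raise DensityError(
                f"could not place protein {len(placed) + 1}/{n} in box {box} nm "
                f"after {max_tries} tries"
            )
    return Configuration(box, np.array(placed), shape, seed)


def metropolis_sweep(
    config: Configuration,
    schedule: AnnealSchedule,
    T: float,
    n_steps: int,
    h0_table: PairPotentialTable | None = None,
    bar_on: bool = False,
    eps: float = 10.0,
    r_m: float = 10.0,
    trace_every: int | None = None,
) -> tuple[Configuration, dict]:
    """Run n_steps Metropolis steps at constant temperature T (T_rm units)."""
    if T < 0:
        raise ParameterError("temperature must be non-negative")
    out = config.copy()
    te = trace_every or max(1, n_steps // 100)
    steps, temps, ens = _mc.run_mc(
        out.poses, n_steps, float(T), float(T),
        schedule.delta_r, schedule.delta_theta,
        *_mc_args(config, h0_table, bar_on, eps, r_m),
        schedule.seed, te,
    )
    return out, {"step": steps, "T": temps, "energy": ens}


def anneal(
    config0: Configuration,
    h0_table: PairPotentialTable | None,
    bar_on: bool,
    schedule: AnnealSchedule,
    eps: float = 10.0,
    r_m: float = 10.0,
) -> tuple[Configuration, dict]:
    """Simulated annealing: hot phase then linear cooling to T = 0.

    Returns the final configuration and an energy trace dict with keys
    ``step``, ``T``, ``energy`` (total energy sampled periodically).
    """
    out = config0.copy()
    args = _mc_args(config0, h0_table, bar_on, eps, r_m)
    te_hot = max(1, schedule.n_hot // 100)
    s1, t1, e1 = _mc.run_mc(
        out.poses, schedule.n_hot, schedule.t_hot, schedule.t_hot,
        schedule.delta_r, schedule.delta_theta, *args,
        schedule.seed % 2**31, te_hot,
    )
    te_cool = max(1, schedule.n_cool // 100)
    s2, t2, e2 = _mc.run_mc(
        out.poses, schedule.n_cool, schedule.t_hot, 0.0,
        schedule.delta_r, schedule.delta_theta, *args,
        (schedule.seed + 1000003) % 2**31, te_cool,
    )
    trace = {
        "step": np.concatenate([s1, s2 + schedule.n_hot]),
        "T": np.concatenate([t1, t2]),
        "energy": np.concatenate([e1, e2]),
    }
    return out, trace


@dataclass
class ChainStats:
    """Dimer/chain order parameters of a configuration.

    ``dimers`` lists inter-protein H0 pairs (i, a, j, b) closer than the
    distance gate; ``chains`` are the connected components of the protein
    set under the dimer relation; ``alignment_angles`` are the angles
    between the paired H0 helix directions (antiparallel pairing gives
    angles near pi); ``outer_fraction`` is the fraction of dimer links made
    on the outer (away-from-backbone) side of the H0 helices.
    """

    dimers: list[tuple[int, int, int, int]]
    chains: list[list[int]]
    alignment_angles: np.ndarray
    outer_fraction: float

    @property
    def n_dimers(self) -> int:
        return len(self.dimers)

    @property
    def chain_length_histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for c in self.chains:
            hist[len(c)] = hist.get(len(c), 0) + 1
        return hist


def chain_statistics(
    config: Configuration,
    gate_distance: float = 2.5,
    gate_angle: float | None = None,
) -> ChainStats:
    """Identify H0 dimers, chains and alignment angles in a configuration.

    A dimer is an inter-protein pair of H0 helices whose centre separation
    (minimum image) is at most ``gate_distance`` nm; if ``gate_angle`` is
    given, the pair must additionally be antiparallel to within that angle
    (radians) of pi.
    """
    if gate_distance <= 0:
        raise ParameterError("gate distance must be positive")
    shape = config.shape
    box = config.box
    n = config.n
    h0s = shape.h0_frames
    centres = np.empty((n, 2, 2))
    angles = np.empty((n, 2))
    for i in range(n):
        x, y, th = config.poses[i]
        c, s = math.cos(th), math.sin(th)
        for a in range(2):
            centres[i, a, 0] = x + c * h0s[a, 0] - s * h0s[a, 1]
            centres[i, a, 1] = y + s * h0s[a, 0] + c * h0s[a, 1]
            angles[i, a] = th + h0s[a, 2]
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    dimers = []
    align = []
    outer_votes = []
    for i in range(n):
        for j in range(i + 1, n):
            for a in range(2):
                for bb in range(2):
                    dx = centres[j, bb, 0] - centres[i, a, 0]
                    dy = centres[j, bb, 1] - centres[i, a, 1]
                    dx -= box * round(dx / box)
                    dy -= box * round(dy / box)
                    if math.hypot(dx, dy) > gate_distance:
                        continue
                    ang = math.acos(
                        max(-1.0, min(1.0, math.cos(angles[i, a] - angles[j, bb])))
                    )
                    if gate_angle is not None and abs(ang - math.pi) > gate_angle:
                        continue
                    dimers.append((i, a, j, bb))
                    align.append(ang)
                    # outer-side vote: partner H0 centre expressed in each
                    # protein's body frame; the link is "outer" when it lies
                    # beyond that protein's own H0 row (further from the
                    # backbone, y_body < h0_y)
                    for (pi_, ai, dxx, dyy) in (
                        (i, a, dx, dy),
                        (j, bb, -dx, -dy),
                    ):
                        th = config.poses[pi_, 2]
                        c, s = math.cos(th), math.sin(th)
                        wx = centres[pi_, ai, 0] + dxx - config.poses[pi_, 0]
                        wy = centres[pi_, ai, 1] + dyy - config.poses[pi_, 1]
                        yb = -s * wx + c * wy
                        outer_votes.append(1.0 if yb < shape.h0_y else 0.0)
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[ri] = rj
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    chains = sorted(comps.values(), key=len, reverse=True)
    return ChainStats(
        dimers=dimers,
        chains=chains,
        alignment_angles=np.array(align),
        outer_fraction=float(np.mean(outer_votes)) if outer_votes else float("nan"),
    )
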