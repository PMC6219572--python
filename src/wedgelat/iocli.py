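"""Run configuration, scenario dispatch, result serialisation and fixtures.

Every run is a pure function of a validated :class:`RunConfig` plus a seed:
outputs (CSV/JSON-lines tables) carry a JSON sidecar embedding the fully
resolved configuration, the seed and the package version, so any artifact
can be regenerated exactly.  Unknown configuration keys are rejected.
"""

from __future__ import annotations

import dataclasses
import json
import math
import time
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .assembly_mc import (
    AnnealSchedule,
    Configuration,
    NBARShape,
    anneal,
    chain_statistics,
    random_configuration,
)
from .confswitch import ConformationalModel, phase_diagram
from .elastic1d import (
    DEFAULT_SLOPE_H,
    BilayerParameters,
    WedgeParameters,
    critical_immersion_depth,
    interaction_curve,
)
from .errors import ParameterError
from .thickness2d import (
    build_footprint,
    pair_potential_table,
    solve_thickness_field,
)

__all__ = ["RunConfig", "load_config", "save_config", "run_scenario", "make_fixture"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BilayerConfig(_Block):
    K_b: float = Field(20.0, gt=0)
    K_t: float = Field(60.0, gt=0)
    a: float = Field(2.0, gt=0)
    tau: float = Field(0.0, ge=0)

    def build(self) -> BilayerParameters:
        return BilayerParameters(self.K_b, self.K_t, self.a, self.tau)


class WedgeConfig(_Block):
    U: float = -0.9
    L: float = Field(3.0, gt=0)
    r0: float = Field(0.6, gt=0)
    slope_h: float = DEFAULT_SLOPE_H
    slope_u: float = 0.0

    def build(self) -> WedgeParameters:
        return WedgeParameters(self.U, self.L, self.r0, self.slope_h, self.slope_u)


class PotentialBlock(_Block):
    U_a: float = -0.9
    U_b: float = -0.9
    d_min: float = Field(1.25, gt=0)
    d_max: float = Field(10.0, gt=0)
    n_points: int = Field(200, ge=2)


class UcritBlock(_Block):
    U_lo: float = -0.7
    U_hi: float = -0.2
    d_max: float = 10.0


class Field2DBlock(_Block):
    U: float = -0.9
    L: float = 3.0
    half_width: float = Field(8.0, gt=0)
    resolution: float = Field(0.15, gt=0)


class PairTableBlock(_Block):
    U: float = -0.9
    extent: float = Field(6.0, gt=0)
    step: float = Field(0.5, gt=0)
    n_theta: int = Field(6, ge=1)
    resolution: float = Field(0.15, gt=0)
    margin: float = Field(5.0, gt=0)


class AnnealBlock(_Block):
    n_proteins: int = Field(16, ge=1)
    box: float = Field(60.0, gt=0)
    n_hot: int = Field(100_000, ge=0)
    n_cool: int = Field(50_000, ge=0)
    t_hot: float = Field(2.0, ge=0)
    delta_r: float = Field(0.1, gt=0)
    delta_theta_deg: float = Field(1.0, gt=0)
    bar_on: bool = False
    eps: float = Field(10.0)
    r_m: float = Field(10.0, gt=0)
    table: PairTableBlock = Field(default_factory=PairTableBlock)


class PhaseBlock(_Block):
    c_min: float = Field(1e-5, gt=0)
    c_max: float = Field(1e-3, gt=0)
    n_c: int = Field(30, ge=2)
    eps_min: float = 0.0
    eps_max: float = 6.0
    n_eps: int = Field(25, ge=2)
    U_shallow: float = 0.0
    U_deep: float = -0.9
    r_c: float = Field(40.0, gt=0)


Scenario = Literal[
    "potential-curve",
    "critical-depth",
    "field-2d",
    "pair-table",
    "anneal",
    "phase-diagram",
]


class RunConfig(_Block):
    scenario: Scenario
    bilayer: BilayerConfig = Field(default_factory=BilayerConfig)
    wedge: WedgeConfig = Field(default_factory=WedgeConfig)
    potential: PotentialBlock = Field(default_factory=PotentialBlock)
    ucrit: UcritBlock = Field(default_factory=UcritBlock)
    field2d: Field2DBlock = Field(default_factory=Field2DBlock)
    pairtable: PairTableBlock = Field(default_factory=PairTableBlock)
    anneal: AnnealBlock = Field(default_factory=AnnealBlock)
    phase: PhaseBlock = Field(default_factory=PhaseBlock)
    seed: int = 0
    out_dir: str = "results"
    format_version: int = 1


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    Defaults are filled for absent keys; unknown keys and out-of-range
    values are rejected with the offending field named in the error.
    """
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"config file not found: {path}")
    text = path.read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if data is None:
        data = {}
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ParameterError(f"invalid config field '{loc}': {first['msg']}") from exc
    except TypeError as exc:
        raise ParameterError(f"invalid config structure: {exc}") from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))


def _sidecar(config: RunConfig, seed: int, outputs: list[str], t0: float) -> dict:
    return {
        "config": config.model_dump(),
        "seed": seed,
        "package_version": __version__,
        "format_version": config.format_version,
        "runtime_s": round(time.time() - t0, 3),
        "outputs": outputs,
    }


def run_scenario(config: RunConfig, seed: int | None = None, out_dir: str | None = None) -> list[Path]:
    """Execute one scenario and write its result files.

    Returns the list of written paths; the last entry is always the JSON
    metadata sidecar.
    """
    t0 = time.time()
    seed = config.seed if seed is None else seed
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bil = config.bilayer.build()
    written: list[Path] = []

    if config.scenario == "potential-curve":
        p = config.potential
        wa = dataclasses.replace(config.wedge.build(), U=p.U_a)
        wb = dataclasses.replace(config.wedge.build(), U=p.U_b)
        ds = np.linspace(p.d_min, p.d_max, p.n_points)
        curve = interaction_curve(bil, wa, wb, ds)
        f = out / "potential_curve.csv"
        curve.to_frame().to_csv(f, index=False)
        written.append(f)

    elif config.scenario == "critical-depth":
        u = config.ucrit
        uc = critical_immersion_depth(
            bil, config.wedge.build(), (u.U_lo, u.U_hi), d_max=u.d_max
        )
        f = out / "critical_depth.json"
        f.write_text(json.dumps({"U_c_nm": uc}, indent=1))
        written.append(f)

    elif config.scenario == "field-2d":
        fb = config.field2d
        fp = build_footprint(fb.U, fb.L, config.wedge.r0)
        hw = fb.half_width
        fld = solve_thickness_field(bil, [fp], (-hw, hw), (-hw, hw), fb.resolution)
        df = pd.DataFrame(fld.u, index=pd.Index(fld.x, name="x_nm"), columns=fld.y)
        f = out / "thickness_field.csv"
        df.to_csv(f)
        g = out / "thickness_field_energy.json"
        g.write_text(json.dumps({"energy_kBT": fld.energy}, indent=1))
        written += [f, g]

    elif config.scenario == "pair-table":
        tb = config.pairtable
        tab = pair_potential_table(
            bil, U=tb.U, L=config.wedge.L, r0=config.wedge.r0,
            extent=tb.extent, step=tb.step, n_theta=tb.n_theta,
            resolution=tb.resolution, margin=tb.margin,
        )
        prefix = str(out / "pair_table")
        tab.save(prefix)
        written += [Path(prefix + ".npz"), Path(prefix + ".json")]

    elif config.scenario == "anneal":
        an = config.anneal
        tb = an.table
        tab = pair_potential_table(
            bil, U=tb.U, L=config.wedge.L, r0=config.wedge.r0,
            extent=tb.extent, step=tb.step, n_theta=tb.n_theta,
            resolution=tb.resolution, margin=tb.margin,
        )
        cfg0 = random_configuration(an.n_proteins, an.box, seed=seed)
        sched = AnnealSchedule(
            n_hot=an.n_hot, n_cool=an.n_cool, t_hot=an.t_hot,
            delta_r=an.delta_r,
            delta_theta=math.radians(an.delta_theta_deg), seed=seed,
        )
        final, trace = anneal(cfg0, tab, an.bar_on, sched, eps=an.eps, r_m=an.r_m)
        f = out / "trajectory.jsonl"
        with f.open("w") as fh:
            for s, T, e in zip(trace["step"], trace["T"], trace["energy"]):
                fh.write(json.dumps({"step": int(s), "T": float(T), "energy": float(e)}) + "\n")
        g = out / "final_state.csv"
        pd.DataFrame(
            {
                "id": np.arange(final.n),
                "x_nm": final.poses[:, 0],
                "y_nm": final.poses[:, 1],
                "theta_rad": final.poses[:, 2],
            }
        ).to_csv(g, index=False)
        stats = chain_statistics(final)
        h = out / "chain_stats.json"
        h.write_text(
            json.dumps(
                {
                    "n_dimers": stats.n_dimers,
                    "chain_lengths": sorted(
                        (len(c) for c in stats.chains), reverse=True
                    ),
                    "median_alignment_deg": (
                        float(np.degrees(np.median(stats.alignment_angles)))
                        if stats.n_dimers
                        else None
                    ),
                    "outer_fraction": (
                        None
                        if math.isnan(stats.outer_fraction)
                        else stats.outer_fraction
                    ),
                },
                indent=1,
            )
        )
        written += [f, g, h]

    elif config.scenario == "phase-diagram":
        ph = config.phase
        model = ConformationalModel(
            bilayer=bil,
            wedge_template=config.wedge.build(),
            U_shallow=ph.U_shallow,
            U_deep=ph.U_deep,
            r_c=ph.r_c,
        )
        pdg = phase_diagram(
            model,
            np.linspace(ph.c_min, ph.c_max, ph.n_c),
            np.linspace(ph.eps_min, ph.eps_max, ph.n_eps),
        )
        f = out / "phase_diagram.csv"
        pdg.to_frame().to_csv(f)
        g = out / "phase_contour.json"
        g.write_text(
            json.dumps(
                {"P_d=1/2": [{"c_per_nm2": c, "epsilon_d_kBT": e} for c, e in pdg.contour]},
                indent=1,
            )
        )
        written += [f, g]
    else:  # pragma: no cover - pydantic forbids other literals
        raise ParameterError(f"unknown scenario {config.scenario}")

    side = out / "run_metadata.json"
    side.write_text(
        json.dumps(_sidecar(config, seed, [p.name for p in written], t0), indent=1)
    )
    written.append(side)
    return written


def make_fixture(kind: str, seed: int = 0, **kwargs):
    """Deterministic fixtures for tests and examples.

    Kinds: ``random-config`` (overlap-free random N-BAR poses),
    ``dimer`` (two proteins hand-built into one antiparallel tip-to-tail
    H0 dimer), ``chain`` (n proteins in a tip-to-tail chain) and
    ``parameter-sweep`` (a list of bilayer/wedge parameter draws for
    solver property tests).
    """
    shape = kwargs.pop("shape", None) or NBARShape()
    if kind == "random-config":
        n = kwargs.pop("n", 16)
        box = kwargs.pop("box", 60.0)
        return random_configuration(n, box, shape, seed=seed, **kwargs)
    if kind == "dimer":
        box = kwargs.pop("box", 60.0)
        gap = kwargs.pop("gap", 1.6)
        x0 = box / 2.0
        dx = 2.0 * shape.h0_x
        dy = 2.0 * shape.h0_y - gap
        poses = np.array(
            [[x0, x0, 0.0], [x0 + dx, x0 + dy, math.pi]]
        )
        return Configuration(box, poses, shape, seed)
    if kind == "chain":
        n = kwargs.pop("n", 4)
        box = kwargs.pop("box", 90.0)
        gap = kwargs.pop("gap", 1.6)
        poses = []
        x, y = 10.0, box / 2.0
        for i in range(n):
            th = 0.0 if i % 2 == 0 else math.pi
            poses.append([x, y, th])
            x += 2.0 * shape.h0_x
            y += (2.0 * shape.h0_y - gap) * (1 if i % 2 == 0 else -1)
        return Configuration(box, np.array(poses), shape, seed)
    if kind == "parameter-sweep":
        n = kwargs.pop("n", 20)
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n):
            draws.append(
                {
                    "bilayer": BilayerParameters(
                        K_b=rng.uniform(10, 40),
                        K_t=rng.uniform(30, 120),
                        a=rng.uniform(1.5, 2.5),
                        tau=float(rng.choice([0.0, rng.uniform(0.0, 0.3)])),
                    ),
                    "wedge": WedgeParameters(
                        U=rng.uniform(-1.2, 0.3),
                        L=3.0,
                        r0=rng.uniform(0.4, 0.8),
                        slope_h=rng.uniform(-0.3, 0.1),
                        slope_u=rng.uniform(-0.1, 0.1),
                    ),
                    "d": rng.uniform(1.7, 12.0),
                }
            )
        return draws
    raise ParameterError(f"unknown fixture kind: {kind}")
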