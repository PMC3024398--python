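"""Named scenario presets and file-backed configuration.

Each preset encodes exactly the deviations from the baseline parameter set
that its study calls for: trajectory runs under constant or switching
allocation, the equilibrium-abundance sweep over u, and the period/statistic
sweep tables.  ``run_scenario`` executes a preset (with optional overrides)
and writes deterministic CSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .allocation import equilibrium_sweep_u, v_star
from .analysis import estimate_period, parameter_sweep, summary_stats
from .integrate import AllocationPolicy, SolverSettings, simulate
from .params import ParameterSet, baseline

__all__ = ["ScenarioSpec", "PRESETS", "run_scenario", "load_config", "save_config"]

_FORCED = {"d_r": 0.45, "d_s": 0.45}


def _preset(**kw) -> dict[str, Any]:
    d: dict[str, Any] = {
        "kind": "trajectory",
        "variant": "cr3",
        "params": {},
        "policy": {"mode": "constant", "u_const": 0.5},
        "init": None,
        "t_span": 300.0,
        "window": None,
        "rho": None,
    }
    d.update(kw)
    return d


#: Preset registry.  Policy directions follow the behaviour each figure
#: reports: the stabilising peak-clipping rule is 'grow_below'
#: (u = u_max while X <= X_switch); the lag-phase rule is 'quality_below'.
PRESETS: dict[str, dict[str, Any]] = {
    # equilibrium-abundance sweep over constant u (fixed resource background)
    "fig1": _preset(
        kind="sweep_u", variant="fixed", u_step=0.001, horizon=600.0,
    ),
    # 300-month trajectories, constant u = v = 0.5
    "fig2a": _preset(),
    "fig2b": _preset(params={"d_r": 0.45}),
    "fig2c": _preset(params={"d_s": 0.45}),
    "fig2d": _preset(params=dict(_FORCED)),
    "fig2e": _preset(params={"delta": 5.5}, t_span=2400.0),
    "fig2f": _preset(params={"delta": 5.5, **_FORCED}),
    # threshold switching under strong forcing, delta = 7; years 80-100 stats
    **{
        name: _preset(
            params={"delta": 7.0, **_FORCED},
            policy={
                "mode": "threshold",
                "u_min": umin,
                "u_max": umax,
                "X_switch": xsw,
                "direction": "grow_below",
            },
            t_span=1200.0,
            window=(960.0, 1200.0),
        )
        for name, (umin, umax, xsw) in {
            "fig3a": (0.0, 1.0, 29_300.0),
            "fig3b": (0.0, 1.0, 15_000.0),
            "fig3c": (0.0, 1.0, 7_000.0),
            "fig3d": (0.0, 1.0, 4_000.0),
            "fig3e": (0.1, 0.9, 4_000.0),
            "fig3f": (0.3, 0.7, 4_000.0),
        }.items()
    },
    # mean/sigma scans of the switching rule (delta = 7, forced).
    "fig4a": _preset(
        kind="sweep_du", params={"delta": 7.0, **_FORCED, "v_set": 0.5},
        X_switch=4_000.0, du_step=0.01, horizon=1200.0,
    ),
    "fig4b": _preset(
        kind="sweep_du", params={"delta": 7.0, **_FORCED, "v_set": 0.5},
        X_switch=6_000.0, du_step=0.01, horizon=1200.0,
    ),
    "fig4c": _preset(
        kind="sweep_xswitch", params={"delta": 7.0, **_FORCED, "v_set": 0.5},
        du=0.5, x_step=500.0, horizon=1200.0,
    ),
    "fig4d": _preset(
        kind="sweep_xswitch", params={"delta": 7.0, **_FORCED, "v_set": 0.5},
        du=0.3, x_step=500.0, horizon=1200.0,
    ),
    "fig4e": _preset(
        kind="sweep_w", params={"delta": 7.0, **_FORCED, "v_set": 0.70},
        du=0.5, X_switch=4_000.0, w_step=0.1, horizon=1200.0,
    ),
    "fig4f": _preset(
        kind="sweep_w", params={"delta": 7.0, **_FORCED, "v_set": 0.70},
        du=0.3, X_switch=4_000.0, w_step=0.1, horizon=1200.0,
    ),
    # microbial-style growth phases on a constant, abundant resource
    "fig5": _preset(
        variant="fixed",
        rho=500_000.0 / 30_000.0,
        params={"alpha": 0.001, "mu": 0.01, "c_bias": 0.6, "w_cost": 1.0},
        policy={
            "mode": "threshold",
            "u_min": 0.07,
            "u_max": 0.85,
            "X_switch": 1_000.0,
            "direction": "quality_below",
        },
        init={"X": 100.0, "Q_X": 0.05},
        t_span=600.0,
    ),
    # oscillation-period tables
    "table3a": _preset(
        kind="table3", sweep_param="r",
        grid=[0.18, 0.19, 0.20, 0.21, 0.25, 0.30, 0.35, 0.40, 0.45, 0.47, 0.48, 0.49, 0.50],
        cases={"case1_no_seasonality": {}, "case2_seasonal_forcing": dict(_FORCED)},
    ),
    "table3b": _preset(
        kind="table3", sweep_param="a",
        grid=[0.02, 0.03, 0.05, 0.06, 0.08, 0.10, 0.15, 0.25, 0.50, 1.00],
        cases={
            "case1_r0.5": {"r": 0.5, **_FORCED},
            "case2_r0.3": {"r": 0.3, **_FORCED},
        },
    ),
}


@dataclass
class ScenarioSpec:
    """A runnable scenario: preset id plus validated overrides."""

    name: str
    overrides: dict[str, Any] = field(default_factory=dict)
    output: str | None = None

    def __post_init__(self) -> None:
        if self.name not in PRESETS:
            raise ValueError(
                f"unknown preset {self.name!r}; valid ids: {', '.join(sorted(PRESETS))}"
            )
        allowed = {"params", "policy", "t_span", "init", "horizon"}
        unknown = set(self.overrides) - allowed
        if unknown:
            raise ValueError(f"unknown override section(s): {sorted(unknown)}")
        # validate eagerly so bad values fail at construction
        self.resolve()

    def resolve(self) -> dict[str, Any]:
        """Preset merged with overrides; parameters and policy validated."""
        cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in PRESETS[self.name].items()}
        ov = self.overrides
        cfg["params"] = {**cfg["params"], **ov.get("params", {})}
        if "policy" in ov:
            cfg["policy"] = {**cfg["policy"], **ov["policy"]}
        for key in ("t_span", "init", "horizon"):
            if key in ov:
                cfg[key] = ov[key]
        cfg["params_obj"] = baseline().with_(**cfg["params"])
        cfg["policy_obj"] = AllocationPolicy(**cfg["policy"])
        return cfg


# --------------------------------------------------------------------------
# execution
# --------------------------------------------------------------------------


def _summary_base(spec: ScenarioSpec, cfg: dict[str, Any]) -> dict[str, Any]:
    return {
        "scenario": spec.name,
        "version": __version__,
        "variant": cfg["variant"],
        "params": cfg["params_obj"].to_dict(),
        "policy": dataclasses.asdict(cfg["policy_obj"]),
        "solver": dataclasses.asdict(SolverSettings()),
    }


def run_scenario(spec: ScenarioSpec, log=None) -> dict[str, Any]:
    """Execute a scenario and write its result bundle.

    Writes trajectory/sweep CSVs plus a ``summary.json`` echoing every
    effective setting into ``spec.output`` (no files are written when output
    is None).  Rerunning produces byte-identical numeric outputs.
    """
    log = log or (lambda msg: None)
    cfg = spec.resolve()
    p: ParameterSet = cfg["params_obj"]
    outdir = Path(spec.output) if spec.output else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    summary = _summary_base(spec, cfg)
    kind = cfg["kind"]
    log(f"scenario {spec.name}: kind={kind}, variant={cfg['variant']}")

    if kind == "trajectory":
        traj = simulate(
            cfg["variant"], p, cfg["policy_obj"], cfg["init"], cfg["t_span"],
            rho=cfg["rho"],
        )
        est = estimate_period(traj, cfg["window"])
        summary["period_years"] = est.rounded
        summary["extinct_at"] = traj.extinct_at
        summary["equilibrated"] = traj.equilibrated
        if cfg["window"] or not traj.extinct:
            st = summary_stats(traj, cfg["window"])
            summary["stats"] = dataclasses.asdict(st)
        if outdir:
            traj.save(outdir / "trajectory")
        result: dict[str, Any] = {"trajectory": traj, "summary": summary}

    elif kind == "sweep_u":
        grid = np.round(np.arange(0.0, 1.0 + 1e-12, cfg["u_step"]), 6)
        grid = grid[(grid > 0) & (grid < 1)]
        sw = equilibrium_sweep_u(
            p, grid, cfg["variant"], horizon=cfg["horizon"], rho=cfg["rho"]
        )
        vs = v_star(p)
        summary.update(
            max_abundance=sw.max, argmax_u=sw.argmax,
            v_plus=vs.v_plus, v_minus=vs.v_minus,
        )
        nz = sw.grid[sw.metric > 0]
        summary["min_nonzero_u"] = float(nz[0]) if len(nz) else None
        if outdir:
            sw.save(outdir / "sweep_u")
        result = {"sweep": sw, "summary": summary}

    elif kind in ("sweep_du", "sweep_xswitch", "sweep_w"):
        result = _run_switch_scan(spec, cfg, p, summary, outdir, log)

    elif kind == "table3":
        frames = {}
        for case, overrides in cfg["cases"].items():
            pp = p.with_(**overrides)
            sw = parameter_sweep(cfg["variant"], pp, cfg["sweep_param"], cfg["grid"], "period")
            ext = parameter_sweep(cfg["variant"], pp, cfg["sweep_param"], cfg["grid"], "extinction")
            frames[case] = [
                "Extinction" if np.isfinite(e) else
                ("Equilibrium" if not np.isfinite(v) else f"Period ~{round(v, 1)}")
                for v, e in zip(sw.metric, ext.metric)
            ]
            log(f"  case {case} done")
        table = pd.DataFrame({cfg["sweep_param"]: cfg["grid"], **frames})
        summary["table"] = table.to_dict(orient="list")
        if outdir:
            table.to_csv(outdir / "table.csv", index=False)
        result = {"table": table, "summary": summary}

    else:  # pragma: no cover - registry is closed
        raise ValueError(f"unhandled scenario kind {kind}")

    if outdir:
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return result


def _run_switch_scan(spec, cfg, p, summary, outdir, log):
    """Mean/sigma of X as one switching-rule setting varies."""
    horizon = cfg["horizon"]
    window = (960.0, horizon)
    kind = cfg["kind"]
    if kind == "sweep_du":
        grid = np.round(np.arange(0.0, 0.5 + 1e-9, cfg["du_step"]), 6)
        make = lambda g: AllocationPolicy.threshold(
            max(0.5 - g, 0.0), min(0.5 + g, 1.0), cfg["X_switch"], "grow_below"
        )
        pname = "delta_u"
        pp = p
    elif kind == "sweep_xswitch":
        grid = np.arange(0.0, 32_000.0 + 1e-9, cfg["x_step"])
        make = lambda g: AllocationPolicy.threshold(
            0.5 - cfg["du"], 0.5 + cfg["du"], g, "grow_below"
        )
        pname = "X_switch"
        pp = p
    else:  # sweep_w
        grid = np.round(np.arange(0.0, 5.0 + 1e-9, cfg["w_step"]), 6)
        pname = "w_cost"
        pp = p

    means, sigmas = np.empty(len(grid)), np.empty(len(grid))
    flags = []
    for i, g in enumerate(grid):
        if kind == "sweep_w":
            pi = pp.with_(w_cost=float(g))
            pol = AllocationPolicy.threshold(
                0.5 - cfg["du"], 0.5 + cfg["du"], cfg["X_switch"], "grow_below"
            )
        else:
            pi = pp
            pol = make(float(g))
        try:
            traj = simulate(cfg["variant"], pi, pol, None, (0.0, horizon),
                            SolverSettings(rtol=1e-7, atol=1e-9))
            if traj.extinct_at is not None:
                means[i], sigmas[i] = 0.0, 0.0
                flags.append("extinct")
            else:
                st = summary_stats(traj, window)
                means[i], sigmas[i] = st.mean, st.sigma
                flags.append("ok")
        except RuntimeError as exc:
            means[i] = sigmas[i] = np.nan
            flags.append(f"failed: {exc}")
        if i % 10 == 0:
            log(f"  {pname}={g:g} -> mean={means[i]:.0f}")
    df = pd.DataFrame({pname: grid, "mean_X": means, "sigma_X": sigmas, "flag": flags})
    summary["argmax_mean"] = float(grid[int(np.nanargmax(means))])
    alive = np.array([f != "extinct" for f in flags])
    summary["first_collapse"] = (
        float(grid[~alive][0]) if (~alive).any() else None
    )
    if outdir:
        df.to_csv(outdir / "scan.csv", index=False, float_format="%.10g")
    return {"scan": df, "summary": summary}


# --------------------------------------------------------------------------
# configuration files
# --------------------------------------------------------------------------

_CONFIG_KEYS = {"name", "overrides", "output"}


def load_config(path) -> ScenarioSpec:
    """Parse a YAML scenario configuration (strict: unknown keys rejected)."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError("configuration must be a mapping")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    if "name" not in data:
        raise ValueError("configuration must name a scenario preset")
    return ScenarioSpec(
        name=data["name"],
        overrides=data.get("overrides", {}) or {},
        output=data.get("output"),
    )


def save_config(spec: ScenarioSpec, path) -> None:
    """Serialise a ScenarioSpec back to YAML (round-trips with load_config)."""
    data = {"name": spec.name, "overrides": spec.overrides, "output": spec.output}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
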