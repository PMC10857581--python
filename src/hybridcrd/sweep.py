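"""Parameter sweeps over the (r, p) plane and tabular grid I/O.

The scenarios of interest fix the group composition (N = 6, M = 3 with
a ∈ {2, 3, 4} fixed agents) and the population constants (Z = 100,
mu = 0.01, beta = 2, b = 1, c = 0.1), then scan the risk probability r
and the agent cooperativeness p over [0, 1].  Presets named after the
figure panels they regenerate (fig1a .. fig6c) bundle the composition
with the metric each figure plots:

====== =========================== ==========
preset scenario                    metric
====== =========================== ==========
fig1*  hybrid success              group_success
fig2*  hybrid cooperation          coop_level
fig3*  substitution success delta  delta_success_substitution
fig4*  addition success delta      delta_success_addition
fig5*  substitution coop delta     delta_coop_substitution
fig6*  addition coop delta         delta_coop_addition
====== =========================== ==========

with panel a/b/c mapping to a = 2/3/4.  Controls in delta sweeps do not
depend on p, so each control column is solved once per r value.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import ModelSpec, PopulationParams, TransitionsMode, stationary_distribution
from .game import GameParams, HybridConfig
from .metrics import ControlMode, MetricReport, control_spec, metric_report

logger = logging.getLogger(__name__)

METRICS = (
    "coop_level",
    "group_success",
    "delta_coop_substitution",
    "delta_success_substitution",
    "delta_coop_addition",
    "delta_success_addition",
)

_BASE = dict(N=6, M=3, Z=100, mu=0.01, beta=2.0, b=1.0, c=0.1)
_PANEL_A = {"a": 2, "b": 3, "c": 4}
_FIG_METRIC = {
    "1": "group_success",
    "2": "coop_level",
    "3": "delta_success_substitution",
    "4": "delta_success_addition",
    "5": "delta_coop_substitution",
    "6": "delta_coop_addition",
}

PRESETS: dict[str, dict] = {
    f"fig{fig}{panel}": {**_BASE, "a": a, "metric": metric}
    for fig, metric in _FIG_METRIC.items()
    for panel, a in _PANEL_A.items()
}

__all__ = ["SweepGrid", "PRESETS", "METRICS", "make_spec", "evaluate_point", "run_sweep",
           "write_grid", "read_grid", "plot_heatmap"]


@dataclass(frozen=True)
class SweepGrid:
    """Dense metric values over an (r × p) lattice for one scenario."""

    r_values: np.ndarray
    p_values: np.ndarray
    metric: str
    values: np.ndarray  # shape (len(r_values), len(p_values))
    base: dict = field(default_factory=dict)  # N, M, a, Z, mu, beta, b, c
    transitions: str = "with-mutation"

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.r_values), len(self.p_values)):
            raise ValueError("values matrix shape must be |r_values| x |p_values|")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; choose from {METRICS}")


def make_spec(base: Mapping, r: float, p: float) -> ModelSpec:
    """Assemble a ModelSpec from a scenario base dict plus the swept (r, p)."""
    return ModelSpec(
        game=GameParams(N=base["N"], M=base["M"], r=r, b=base.get("b", 1.0), c=base.get("c", 0.1)),
        hybrid=HybridConfig(a=base["a"], p=p),
        pop=PopulationParams(Z=base["Z"], mu=base["mu"], beta=base["beta"]),
    )


def evaluate_point(
    spec: ModelSpec,
    controls: Iterable[ControlMode] = (),
    mode: TransitionsMode = "with-mutation",
) -> dict:
    """One stationary solve per involved spec; returns a flat report dict."""
    stat = stationary_distribution(spec, mode=mode)
    rep = metric_report(spec, stat)
    out = {
        "coop_level": rep.coop_level,
        "group_success": rep.group_success,
        "method": stat.method,
        "residual": stat.residual,
        "transitions": mode,
    }
    for ctrl in controls:
        c_rep = metric_report(control_spec(spec, ctrl))
        short = "substitution" if ctrl == "substitution" else "addition"
        out[f"delta_coop_{short}"] = rep.coop_level - c_rep.coop_level
        out[f"delta_success_{short}"] = rep.group_success - c_rep.group_success
    return out


def _control_reports(base: Mapping, mode_metric: str, r: float) -> MetricReport:
    ctrl: ControlMode = "substitution" if mode_metric.endswith("substitution") else "addition"
    hybrid_spec = make_spec(base, r=r, p=0.0)
    return metric_report(control_spec(hybrid_spec, ctrl))


def run_sweep(
    preset: str | None = None,
    metric: str | None = None,
    base: Mapping | None = None,
    grid_n: int = 51,
    r_values: np.ndarray | None = None,
    p_values: np.ndarray | None = None,
    transitions: TransitionsMode = "with-mutation",
) -> SweepGrid:
    """Compute a metric over an (r, p) grid for a preset or explicit scenario.

    Deterministic (no randomness anywhere in the analytical path); logs
    per-row progress at INFO.  Default grid is 51 x 51 over [0, 1]^2.
    """
    if preset is not None:
        if preset not in PRESETS:
            raise ValueError(
                f"unknown preset {preset!r}; available: {', '.join(sorted(PRESETS))}"
            )
        cfg = dict(PRESETS[preset])
        base = {k: v for k, v in cfg.items() if k != "metric"}
        metric = metric or cfg["metric"]
    if base is None or metric is None:
        raise ValueError("provide either a preset or both base and metric")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")

    r_values = np.linspace(0.0, 1.0, grid_n) if r_values is None else np.asarray(r_values, float)
    p_values = np.linspace(0.0, 1.0, grid_n) if p_values is None else np.asarray(p_values, float)
    if len(r_values) < 2 or len(p_values) < 2:
        raise ValueError("grid needs at least 2 values per axis")

    is_delta = metric.startswith("delta")
    want_coop = "coop" in metric
    values = np.empty((len(r_values), len(p_values)))
    for ir, r in enumerate(r_values):
        ctrl_val = 0.0
        if is_delta:
            c_rep = _control_reports(base, metric, r)
            ctrl_val = c_rep.coop_level if want_coop else c_rep.group_success
        for ip, p in enumerate(p_values):
            rep = metric_report(make_spec(base, r=r, p=p))
            hybrid_val = rep.coop_level if want_coop else rep.group_success
            values[ir, ip] = hybrid_val - ctrl_val if is_delta else hybrid_val
        logger.info("sweep %s: row r=%.3f done (%d/%d)", metric, r, ir + 1, len(r_values))
    return SweepGrid(
        r_values=r_values,
        p_values=p_values,
        metric=metric,
        values=values,
        base=dict(base),
        transitions=transitions,
    )


def write_grid(grid: SweepGrid, path: str | Path, format: str | None = None) -> None:
    """Write a grid as long-form CSV (r, p, metric, value) or JSON.

    CSV carries full round-trip float precision; JSON additionally stores
    the axes, the scenario parameters, the transitions mode and the
    package version.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix == ".json" else "csv")
    try:
        if fmt == "csv":
            df = pd.DataFrame(
                {
                    "r": np.repeat(grid.r_values, len(grid.p_values)),
                    "p": np.tile(grid.p_values, len(grid.r_values)),
                    "metric": grid.metric,
                    "value": grid.values.ravel(),
                }
            )
            df.to_csv(path, index=False, float_format="%.17g")
        elif fmt == "json":
            payload = {
                "r_values": grid.r_values.tolist(),
                "p_values": grid.p_values.tolist(),
                "metric": grid.metric,
                "values": grid.values.tolist(),
                "base": grid.base,
                "transitions": grid.transitions,
                "version": __version__,
            }
            path.write_text(json.dumps(payload, indent=2))
        else:
            raise ValueError(f"unknown format {fmt!r}; use 'csv' or 'json'")
    except OSError as exc:
        raise OSError(f"cannot write grid to {path}: {exc}") from exc


def read_grid(path: str | Path) -> SweepGrid:
    """Read a grid previously written by :func:`write_grid` (bit-exact)."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        return SweepGrid(
            r_values=np.array(payload["r_values"]),
            p_values=np.array(payload["p_values"]),
            metric=payload["metric"],
            values=np.array(payload["values"]),
            base=payload.get("base", {}),
            transitions=payload.get("transitions", "with-mutation"),
        )
    df = pd.read_csv(path, float_precision="round_trip")
    r_values = df["r"].unique()
    p_values = df["p"].unique()
    values = df["value"].to_numpy().reshape(len(r_values), len(p_values))
    return SweepGrid(
        r_values=r_values,
        p_values=p_values,
        metric=df["metric"].iloc[0],
        values=values,
    )


def plot_heatmap(grid: SweepGrid, path: str | Path) -> None:
    """Quick-look heatmap of a sweep (diagnostic, not publication styling)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    mesh = ax.pcolormesh(grid.p_values, grid.r_values, grid.values, shading="auto")
    fig.colorbar(mesh, ax=ax, label=grid.metric)
    ax.set_xlabel("agent cooperation probability p")
    ax.set_ylabel("risk probability r")
    a = grid.base.get("a")
    if a is not None:
        ax.set_title(f"{grid.metric} (a={a})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
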