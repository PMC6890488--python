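"""Named initial curves, exact solutions, error norms and study drivers.

The study drivers reproduce the standard benchmark suite for curve
shortening flow: temporal and spatial convergence of the enclosed-area
error on the circle (exact solution), the ellipse and a nonconvex curve,
mesh-monitor comparisons, semi-implicit stepping through the singularity of
a self-intersecting curve, and forced flow (``V = kappa + beta``) of a unit
``l_p``-ball measured against a self-computed gold standard.

Under classical curve shortening flow the enclosed area of *any* closed
curve decreases at exactly ``2 pi`` per unit time, so
``A(t) = A(0) - 2 pi t`` serves as the exact reference for every unforced
study; the initial unit circle additionally has the exact radius
``r(t) = sqrt(1 - 2 t)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .equidistribute import ParametricCurve, generate_initial_curve
from .geometry import ClosedCurve
from .monitor import MonitorSpec
from .solver import CSF, Forcing, SchemeConfig, SimulationResult, evolve

# ---------------------------------------------------------------------------
# named parametric curves


def _circle(u: np.ndarray) -> np.ndarray:
    a = 2.0 * np.pi * np.asarray(u, dtype=float)
    return np.column_stack([np.cos(a), np.sin(a)])


def _circle_deriv(u: np.ndarray) -> np.ndarray:
    a = 2.0 * np.pi * np.asarray(u, dtype=float)
    return 2.0 * np.pi * np.column_stack([-np.sin(a), np.cos(a)])


def _ellipse(u: np.ndarray) -> np.ndarray:
    a = 2.0 * np.pi * np.asarray(u, dtype=float)
    return np.column_stack([3.0 * np.cos(a), np.sin(a)])


def _ellipse_deriv(u: np.ndarray) -> np.ndarray:
    a = 2.0 * np.pi * np.asarray(u, dtype=float)
    return 2.0 * np.pi * np.column_stack([-3.0 * np.sin(a), np.cos(a)])


def _nonconvex(u: np.ndarray) -> np.ndarray:
    a = 2.0 * np.pi * np.asarray(u, dtype=float)
    s, c = np.sin(a), np.cos(a)
    s6 = np.sin(6.0 * np.pi * np.asarray(u, dtype=float))
    y = 0.5 * s + np.sin(c) + s * (0.2 + s * s6**2)
    return np.column_stack([c, y])


def _selfintersect(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    a2, a4 = 2.0 * np.pi * u, 4.0 * np.pi * u
    return np.column_stack([np.cos(a4) * np.cos(a2), np.cos(a4) * np.sin(a2)])


def _lp_ball(u: np.ndarray, p: float) -> np.ndarray:
    a = 2.0 * np.pi * np.asarray(u, dtype=float)
    c, s = np.cos(a), np.sin(a)
    r = (np.abs(c) ** p + np.abs(s) ** p) ** (-1.0 / p)
    return np.column_stack([r * c, r * s])


def named_curve(name: str, **params) -> ParametricCurve:
    """Parametric generator for a named initial curve.

    ``circle`` (unit), ``ellipse`` (semi-axes 3 and 1), ``nonconvex``
    (multi-lobed test curve), ``selfintersect`` (self-intersecting,
    develops a singularity in finite time), ``lpball`` (unit ``l_p``-ball,
    keyword ``p``, default 10).
    """
    if name == "circle":
        return ParametricCurve(_circle, _circle_deriv, name="circle")
    if name == "ellipse":
        return ParametricCurve(_ellipse, _ellipse_deriv, name="ellipse")
    if name == "nonconvex":
        return ParametricCurve(_nonconvex, name="nonconvex")
    if name == "selfintersect":
        return ParametricCurve(_selfintersect, name="selfintersect")
    if name == "lpball":
        p = float(params.get("p", 10.0))
        return ParametricCurve(lambda u: _lp_ball(u, p), name=f"lpball(p={p:g})")
    raise ValueError(f"unknown curve {name!r}")


CURVE_NAMES = ("circle", "ellipse", "nonconvex", "selfintersect", "lpball")


def make_curve(
    name: str,
    n_nodes: int,
    mesh: str = "equidistributed",
    monitor_spec: Optional[MonitorSpec] = None,
    tol: float = 1e-10,
    max_iter: int = 100,
    **params,
) -> ClosedCurve:
    """Sample a named curve to ``n_nodes`` nodes.

    ``mesh="uniform_u"`` samples the printed parameterization at uniform
    parameter values; ``mesh="equidistributed"`` (default) runs the de Boor
    algorithm so that the initial mesh equidistributes ``monitor_spec``
    (uniform arc length when no spec is given).
    """
    pc = named_curve(name, **params)
    if mesh == "uniform_u":
        return ClosedCurve(pc.map(np.arange(n_nodes) / n_nodes))
    if mesh != "equidistributed":
        raise ValueError(f"unknown mesh mode {mesh!r}")
    if monitor_spec is None:
        monitor_spec = MonitorSpec(kind="uniform")
    return generate_initial_curve(pc, monitor_spec, n_nodes, tol=tol, max_iter=max_iter)


# ---------------------------------------------------------------------------
# exact solutions and error measures


def exact_circle_radius(t: float) -> float:
    """Radius ``sqrt(1 - 2t)`` of the shrinking unit circle (``t <= 0.5``)."""
    if t > 0.5:
        raise ValueError(f"circle has vanished by t = {t} (> 0.5)")
    return math.sqrt(1.0 - 2.0 * t)


def exact_csf_area(a0: float, t) -> np.ndarray:
    """Exact enclosed area ``A(0) - 2 pi t`` under curve shortening flow."""
    return a0 - 2.0 * np.pi * np.asarray(t, dtype=float)


@dataclass(frozen=True)
class ErrorReport:
    """Enclosed-area error of a run against a reference area series.

    ``l2_norm`` is ``sqrt(sum_n e_h(t_n)^2 dt)`` over the completed steps
    ``n = 1..N_T``; ``abs_final`` is ``|e_h(T)|``; ``series`` holds
    ``e_h(t_n) = A_h(t_n) - A_ref(t_n)`` for every recorded time.
    """

    l2_norm: float
    abs_final: float
    times: np.ndarray
    series: np.ndarray


def _error_report(result: SimulationResult, a_ref: np.ndarray) -> ErrorReport:
    series = result.areas - a_ref
    dt = result.config.dt if result.config is not None else float(np.diff(result.times).mean())
    return ErrorReport(
        l2_norm=float(np.sqrt(np.sum(series[1:] ** 2) * dt)),
        abs_final=float(abs(series[-1])),
        times=result.times.copy(),
        series=series,
    )


def area_error_l2(result: SimulationResult, a_ref=None) -> ErrorReport:
    """Error of a completed run against a reference area map ``t -> A(t)``.

    ``a_ref`` defaults to the exact curve-shortening area
    ``A(0) - 2 pi t``.
    """
    if not result.completed:
        raise ValueError(
            f"run did not complete (status {result.status!r} at "
            f"t = {result.failure_time})"
        )
    if a_ref is None:
        ref = exact_csf_area(result.areas[0], result.times)
    else:
        ref = np.asarray([a_ref(t) for t in result.times], dtype=float)
    return _error_report(result, ref)


def gold_standard_error(result: SimulationResult, gold: SimulationResult) -> ErrorReport:
    """Error of ``result`` against a finer self-computed reference run.

    The gold standard's time step must divide the run's time step so that
    the coarse time grid is a subset of the fine one.
    """
    if not (result.completed and gold.completed):
        raise ValueError("both runs must be completed")
    dt_c, dt_f = result.config.dt, gold.config.dt
    stride = int(round(dt_c / dt_f))
    if stride < 1 or abs(stride * dt_f - dt_c) > 1e-9 * dt_c:
        raise ValueError("gold-standard dt must divide the run's dt")
    ref = gold.areas[::stride]
    if ref.shape[0] != result.areas.shape[0]:
        raise ValueError("incompatible time grids")
    return _error_report(result, ref)


def convergence_order(resolutions: Sequence[float], errors: Sequence[float]) -> float:
    """Least-squares slope of ``log(error)`` against ``log(resolution)``.

    Positive when the error decreases under refinement (e.g. 2.0 for a
    second-order method).
    """
    res = np.asarray(resolutions, dtype=float)
    err = np.asarray(errors, dtype=float)
    if res.shape[0] < 2:
        raise ValueError("need at least two (resolution, error) pairs")
    if np.any(err <= 0.0) or np.any(res <= 0.0):
        raise ValueError("resolutions and errors must be positive")
    slope = np.polyfit(np.log(res), np.log(err), 1)[0]
    return float(-slope)


def picard_stats(result: SimulationResult) -> Tuple[int, int]:
    """(max, min) of the per-step Picard iteration counts."""
    if not result.picard_counts:
        raise ValueError("no completed steps")
    return max(result.picard_counts), min(result.picard_counts)


# ---------------------------------------------------------------------------
# study drivers


def run_named(
    curve: str = "circle",
    n_nodes: int = 128,
    n_steps: int = 100,
    t_final: float = 0.25,
    scheme: str = "CNBE",
    monitor: str = "uniform",
    tau: float = 0.1,
    p_mode: str = "identity",
    forcing: Forcing = CSF,
    picard_cap: Optional[int] = None,
    mesh: str = "equidistributed",
    snapshot_stride: int = 0,
    verbose: bool = False,
    **curve_params,
) -> SimulationResult:
    """Generate a named initial curve and evolve it; the generic driver."""
    spec = MonitorSpec(kind=monitor)
    x0 = make_curve(curve, n_nodes, mesh=mesh, monitor_spec=spec, **curve_params)
    cfg = SchemeConfig(
        scheme=scheme,
        dt=t_final / n_steps,
        t_final=t_final,
        tau=tau,
        p_mode=p_mode,
        picard_cap=picard_cap,
        snapshot_stride=snapshot_stride,
    )
    return evolve(x0, cfg, spec, forcing, verbose=verbose)


def _study_error(
    result: SimulationResult, reference: str, gold: Optional[SimulationResult]
) -> float:
    if reference == "exact":
        return area_error_l2(result).l2_norm
    return gold_standard_error(result, gold).abs_final


def temporal_study(
    curve: str = "circle",
    n_nodes: int = 10**4,
    n_steps_list: Sequence[int] = (10, 20, 40, 80, 160),
    t_final: float = 0.25,
    schemes: Sequence[str] = ("BE", "CNBE"),
    monitor: str = "uniform",
    tau: float = 0.1,
    p_mode: str = "identity",
    forcing: Forcing = CSF,
    reference: str = "exact",
    mesh: str = "equidistributed",
    **curve_params,
) -> pd.DataFrame:
    """Refine the time step at fixed ``N``; one row per (scheme, N_T).

    ``reference="exact"`` measures the L2-in-time enclosed-area error
    against ``A(0) - 2 pi t``; ``reference="gold"`` measures the final-time
    error against a self-computed gold standard (same ``N``, CNBE, time
    step ten times smaller than the finest run compared).
    """
    gold = None
    if reference == "gold":
        gold = run_named(
            curve, n_nodes, 10 * max(n_steps_list), t_final, "CNBE",
            monitor, tau, p_mode, forcing, mesh=mesh, **curve_params,
        )
    rows = []
    for scheme in schemes:
        for nt in n_steps_list:
            result = run_named(
                curve, n_nodes, nt, t_final, scheme,
                monitor, tau, p_mode, forcing, mesh=mesh, **curve_params,
            )
            pmax, pmin = picard_stats(result)
            rows.append(
                {
                    "scheme": scheme,
                    "n_nodes": n_nodes,
                    "n_steps": nt,
                    "error": _study_error(result, reference, gold),
                    "picard_max": pmax,
                    "picard_min": pmin,
                }
            )
    return pd.DataFrame(rows)


def spatial_study(
    curve: str = "circle",
    n_nodes_list: Sequence[int] = (160, 320, 640, 1280, 2560),
    n_steps: int = 10**4,
    t_final: float = 0.25,
    schemes: Sequence[str] = ("CNBE",),
    monitor: str = "uniform",
    tau: float = 0.1,
    p_mode: str = "identity",
    forcing: Forcing = CSF,
    reference: str = "exact",
    mesh: str = "equidistributed",
    **curve_params,
) -> pd.DataFrame:
    """Refine the mesh at fixed ``N_T``; one row per (scheme, N)."""
    rows = []
    for scheme in schemes:
        for n_nodes in n_nodes_list:
            gold = None
            if reference == "gold":
                gold = run_named(
                    curve, n_nodes, 10 * n_steps, t_final, "CNBE",
                    monitor, tau, p_mode, forcing, mesh=mesh, **curve_params,
                )
            result = run_named(
                curve, n_nodes, n_steps, t_final, scheme,
                monitor, tau, p_mode, forcing, mesh=mesh, **curve_params,
            )
            pmax, pmin = picard_stats(result)
            rows.append(
                {
                    "scheme": scheme,
                    "n_nodes": n_nodes,
                    "n_steps": n_steps,
                    "error": _study_error(result, reference, gold),
                    "picard_max": pmax,
                    "picard_min": pmin,
                }
            )
    return pd.DataFrame(rows)


def fitted_orders(table: pd.DataFrame, axis: str) -> Dict[str, float]:
    """Per-scheme convergence orders fitted from a study table.

    ``axis`` is ``"n_steps"`` (temporal order) or ``"n_nodes"`` (spatial).
    """
    return {
        scheme: convergence_order(sub[axis], sub["error"])
        for scheme, sub in table.groupby("scheme", sort=False)
    }


def singularity_run(
    n_nodes: int = 1000,
    dt: float = 1e-5,
    t_final: float = 0.086,
    tau: float = 1e-3,
    picard_cap: Optional[int] = None,
    scheme: str = "CNBE",
    p_mode: str = "balanced",
) -> SimulationResult:
    """Evolve the self-intersecting curve up to / through its singularity.

    Fully implicit (``picard_cap=None``) the run is expected to stop with
    ``status="singularity"`` shortly after ``t = 0.0829``; with a small cap
    (semi-implicit mode, 2 for CNBE) it steps across the singular time.
    """
    return run_named(
        "selfintersect",
        n_nodes,
        n_steps=int(round(t_final / dt)),
        t_final=t_final,
        scheme=scheme,
        monitor="uniform",
        tau=tau,
        p_mode=p_mode,
        picard_cap=picard_cap,
    )
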