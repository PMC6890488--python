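"""Initial mesh generation by iterated de Boor equidistribution.

Given a closed parametric curve :math:`x(u)`, ``u in [0, 1]``, and a monitor
function ``M``, the goal is a partition ``0 = u_0 < ... < u_N = 1`` with

.. math:: \\int_0^{u_i} M(u)\\,|x_u|\\,du = \\frac{i}{N} \\int_0^1 M(u)\\,|x_u|\\,du.

One de Boor step approximates the density :math:`\\rho = M |x_u|` by a
piecewise-constant function on the current partition (midpoint values per
cell), forms its cumulative integral ``R``, and places the new break points
at ``R^{-1}(k R(1) / N)`` by inverse linear interpolation.  Iterating the
step (the monitor is re-evaluated on the re-sampled curve each time)
converges to an approximately equidistributing partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .geometry import ClosedCurve
from .monitor import MonitorSpec, evaluate_monitor


@dataclass(frozen=True)
class ParametricCurve:
    """Closed curve given by a periodic map ``u in [0, 1] -> R^2``.

    Parameters
    ----------
    map
        Vectorized map; for an array ``u`` of shape ``(n,)`` returns points of
        shape ``(n, 2)``, with ``map(0) == map(1)``.
    derivative
        Optional analytic derivative ``x_u`` of the same signature.  When
        absent, ``|x_u|`` is approximated by central differences on a refined
        parameter sample.
    name
        Optional label used in logs and CSV output.
    """

    map: Callable[[np.ndarray], np.ndarray]
    derivative: Optional[Callable[[np.ndarray], np.ndarray]] = None
    name: str = ""

    def speed(self, u: np.ndarray, h: float = 1e-7) -> np.ndarray:
        """``|x_u|`` at parameter values ``u`` (analytic or central-difference)."""
        u = np.asarray(u, dtype=float)
        if self.derivative is not None:
            d = np.asarray(self.derivative(u), dtype=float)
        else:
            d = (self.map(u + h) - self.map(u - h)) / (2.0 * h)
        return np.hypot(d[:, 0], d[:, 1])


@dataclass(frozen=True)
class EquidistributionResult:
    """Outcome of the iterated de Boor mesh generation."""

    curve: ClosedCurve
    partition: np.ndarray  # shape (N+1,), endpoints 0 and 1
    iterations: int
    converged: bool
    final_update: float
    update_history: np.ndarray = None  # max |u_new - u_old| per iteration


def deboor_step(old: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """One de Boor equidistribution step.

    Parameters
    ----------
    old
        Current partition, shape ``(N+1,)``, strictly increasing with
        ``old[0] = 0`` and ``old[-1] = 1``.
    rho
        Positive piecewise-constant density, one value per cell of ``old``,
        shape ``(N,)``.

    Returns
    -------
    ndarray
        New partition exactly equidistributing ``rho`` over the old cells;
        endpoints unchanged.
    """
    old = np.asarray(old, dtype=float)
    rho = np.asarray(rho, dtype=float)
    n = rho.shape[0]
    if old.shape[0] != n + 1:
        raise ValueError("rho must have one value per cell of the partition")
    if np.any(np.diff(old) <= 0.0):
        raise ValueError("partition must be strictly increasing")
    if np.any(rho <= 0.0):
        bad = int(np.flatnonzero(rho <= 0.0)[0])
        raise ValueError(f"nonpositive density in cell {bad}")

    # cumulative integral of the piecewise-constant density; R is
    # piecewise-linear and strictly increasing, so inverse linear
    # interpolation is exact.
    r = np.concatenate([[0.0], np.cumsum(rho * np.diff(old))])
    targets = np.arange(n + 1) * (r[-1] / n)
    new = np.interp(targets, r, old)
    new[0], new[-1] = old[0], old[-1]
    return new


def generate_initial_curve(
    pc: ParametricCurve,
    spec: MonitorSpec,
    n_nodes: int,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ClosedCurve:
    """Sample ``pc`` on a partition that equidistributes the monitor.

    Iterates: sample the curve on the current partition, evaluate the monitor
    on the sampled polygon, build the per-cell density
    ``rho_j = M(u_{j+1/2}) |x_u|(u_{j+1/2})`` and take a de Boor step; stops
    when the partition update ``max_k |u_k_new - u_k_old|`` drops below
    ``tol``.  Non-convergence within ``max_iter`` raises a warning, not an
    error — the last partition is still returned.
    """
    return equidistribute_curve(pc, spec, n_nodes, tol=tol, max_iter=max_iter).curve


def equidistribute_curve(
    pc: ParametricCurve,
    spec: MonitorSpec,
    n_nodes: int,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> EquidistributionResult:
    """Full-information variant of :func:`generate_initial_curve`."""
    if n_nodes < 4:
        raise ValueError("need at least 4 nodes")
    if tol <= 0.0:
        raise ValueError("tol must be positive")

    from .geometry import compute_frame

    u = np.linspace(0.0, 1.0, n_nodes + 1)
    update = np.inf
    updates = []
    iterations = 0
    for iterations in range(1, max_iter + 1):
        curve = ClosedCurve(pc.map(u[:-1]))
        m_nodes = evaluate_monitor(compute_frame(curve), spec)
        # monitor at cell midpoints by linear interpolation between the
        # node values (node i sits at u_i; node N wraps to node 0)
        m_ext = np.concatenate([m_nodes, m_nodes[:1]])
        m_mid = 0.5 * (m_ext[:-1] + m_ext[1:])
        u_mid = 0.5 * (u[:-1] + u[1:])
        rho = m_mid * pc.speed(u_mid)
        u_new = deboor_step(u, rho)
        update = float(np.max(np.abs(u_new - u)))
        updates.append(update)
        u = u_new
        if update < tol:
            break
    converged = update < tol
    if not converged:
        warnings.warn(
            f"de Boor equidistribution did not converge in {max_iter} "
            f"iterations (last update {update:.3e})",
            RuntimeWarning,
        )
    return EquidistributionResult(
        curve=ClosedCurve(pc.map(u[:-1])),
        partition=u,
        iterations=iterations,
        converged=converged,
        final_update=update,
        update_history=np.asarray(updates),
    )
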