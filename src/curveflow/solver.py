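"""Implicit time stepping for the coupled normal/tangential mesh equations.

Each node of the polygonal curve moves with normal velocity
:math:`V = \\alpha \\kappa + \\beta` (the geometric law) and with a tangential
velocity derived from a moving-mesh PDE that relaxes the mesh toward
equidistribution of a monitor function ``M`` at rate ``1/tau``.  One time
step solves, by Picard iteration, a nonlinear system of ``2N`` scalar
equations: at every node, the three-point stencil equation for the normal
motion is projected onto the (lagged) unit normal and the stencil equation
for the tangential motion onto the (lagged) unit tangent.

Two temporal schemes are available:

``BE``
    backward Euler for both the normal and tangential equations
    (first-order in time);
``CNBE``
    Crank-Nicolson for the normal equation combined with backward Euler for
    the tangential equation (second-order in the enclosed-area error).  The
    Crank-Nicolson projection uses the *unnormalized* averaged normal
    ``(n^{n+1,m} + n^n)/2``.

Within a Picard sweep the geometric coefficients (chords, tangents, normals)
are taken from the previous iterate, which makes each sweep a linear solve
with a cyclic banded matrix; the monitor ``M`` and the spatial balancing
operator ``P`` are always evaluated at the previous *time level* (treated
explicitly).  Iteration stops when the maximal nodal displacement between
successive iterates falls below ``picard_tol`` (default ``1e-6``), or after
exactly ``picard_cap`` sweeps in semi-implicit mode — capping at 1 (BE) or 2
(CNBE) sweeps lets the integration step across a geometric singularity that
a fully implicit solve cannot converge through.

The tangential stencil weight is
:math:`\\nu_i = 4 \\Delta t\\, M_i P_i / (\\tau (M_i |x_{i+1} - x_{i-1}|)^2)`
and the drive term on the right-hand side is
:math:`\\Delta t\\, P_i (M_{i+1} - M_{i-1}) /
(\\tau M_i^2 |x_{i+1} - x_{i-1}|)`; the latter follows from writing the
tangential equation in the form
:math:`(\\dot x - \\frac{PM}{\\tau (M|x_\\xi|)^2} x_{\\xi\\xi}) \\cdot t
= \\frac{P M_\\xi |x_\\xi|}{\\tau (M|x_\\xi|)^2}` before discretizing, so the
central-difference chord in ``M_xi |x_xi|`` cancels one chord power of the
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Tuple, Union

import numpy as np
import scipy.linalg

from .geometry import (
    ClosedCurve,
    DegenerateGeometryError,
    GeometryFrame,
    compute_frame,
    enclosed_area,
)
from .monitor import MonitorSpec, evaluate_monitor

ForcingTerm = Union[float, Callable[[np.ndarray, float], np.ndarray]]


class PicardNonConvergenceError(RuntimeError):
    """The Picard solver exhausted its iteration budget.

    For curve shortening flow this typically signals a geometric singularity:
    past the singular time no fully implicit solve can converge.
    """

    def __init__(self, time: float, update: float, iterations: int):
        super().__init__(
            f"Picard iteration did not converge at t = {time:.6g} "
            f"({iterations} iterations, last update {update:.3e})"
        )
        self.time = time
        self.update = update
        self.iterations = iterations


@dataclass(frozen=True)
class Forcing:
    """Normal-velocity coefficients in ``V = alpha * kappa + beta``.

    ``alpha`` (nonnegative) and ``beta`` may be constants or callables
    ``f(points, t) -> values`` with ``points`` of shape ``(N, 2)``.
    """

    alpha: ForcingTerm = 1.0
    beta: ForcingTerm = 0.0

    def alpha_at(self, points: np.ndarray, t: float) -> np.ndarray:
        a = self._eval(self.alpha, points, t)
        if np.any(a < 0.0):
            raise ValueError(f"alpha must be nonnegative (at t = {t:.6g})")
        return a

    def beta_at(self, points: np.ndarray, t: float) -> np.ndarray:
        return self._eval(self.beta, points, t)

    @staticmethod
    def _eval(term: ForcingTerm, points: np.ndarray, t: float) -> np.ndarray:
        if callable(term):
            return np.broadcast_to(
                np.asarray(term(points, t), dtype=float), (points.shape[0],)
            ).copy()
        return np.full(points.shape[0], float(term))


CSF = Forcing(alpha=1.0, beta=0.0)
"""Classical curve shortening flow, ``V = kappa``."""


@dataclass(frozen=True)
class SchemeConfig:
    """Time integration and mesh-relaxation parameters.

    Parameters
    ----------
    scheme
        ``"BE"`` or ``"CNBE"``.
    dt
        Time step size.
    t_final
        Final time ``T``; the number of steps is ``round(T / dt)``.
    tau
        Mesh relaxation time of the tangential moving-mesh equation.
    p_mode
        Spatial balancing operator: ``"identity"`` (``P = 1``, steepest
        descent) or ``"balanced"`` (``P = M |x_xi|^2``, which makes the
        relaxation rate more uniform along the curve and less sensitive to
        ``tau``).
    p_dxi_scaling
        For ``balanced``: approximate ``|x_xi|`` by the scaled central
        difference ``|x_{i+1} - x_{i-1}| / (2 dxi)`` (default) instead of the
        bare chord.  Retaining the ``dxi`` scaling keeps the meaning of
        ``tau`` independent of the resolution ``N``.
    picard_tol
        Stopping tolerance on the maximal nodal displacement between
        successive Picard iterates.
    picard_max
        Iteration budget; exhausting it raises
        :class:`PicardNonConvergenceError`.
    picard_cap
        Semi-implicit mode: perform exactly this many sweeps per step,
        skipping the tolerance test (1 for BE, 2 for CNBE).
    snapshot_stride
        Store a curve snapshot every this many steps (first and last are
        always stored); 0 keeps only first and last.
    """

    scheme: str = "CNBE"
    dt: float = 1e-3
    t_final: float = 0.25
    tau: float = 1.0
    p_mode: str = "identity"
    p_dxi_scaling: bool = True
    picard_tol: float = 1e-6
    picard_max: int = 200
    picard_cap: Optional[int] = None
    snapshot_stride: int = 0

    def __post_init__(self):
        if self.scheme not in ("BE", "CNBE"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.p_mode not in ("identity", "balanced"):
            raise ValueError(f"unknown p_mode {self.p_mode!r}")
        if self.dt <= 0.0 or self.t_final <= 0.0 or self.tau <= 0.0:
            raise ValueError("dt, t_final and tau must be positive")
        if self.picard_cap is not None and self.picard_cap > self.picard_max:
            raise ValueError("picard_cap must not exceed picard_max")

    @property
    def n_steps(self) -> int:
        n = int(round(self.t_final / self.dt))
        if abs(n * self.dt - self.t_final) > 1e-8 * self.t_final:
            raise ValueError("t_final must be an integer multiple of dt")
        return n


@dataclass(frozen=True)
class AssembledSystem:
    """Linear ``2N x 2N`` cyclic banded system of one Picard sweep.

    Unknowns are interleaved ``(x_0, y_0, x_1, y_1, ...)``.  Every row
    couples the three-node stencil ``{i-1, i, i+1}``; the periodic wrap
    appears as two ``2 x 2`` corner blocks held separately from the band.
    """

    band: np.ndarray  # (7, 2N), diagonal-ordered form, l = u = 3
    corner_top: np.ndarray  # rows 0:2, cols 2N-2:2N
    corner_bot: np.ndarray  # rows 2N-2:2N, cols 0:2
    rhs: np.ndarray  # (2N,)

    @property
    def dim(self) -> int:
        return self.rhs.shape[0]

    def to_dense(self) -> np.ndarray:
        """Full matrix (for testing and small problems)."""
        n2 = self.dim
        a = np.zeros((n2, n2))
        for d in range(-3, 4):
            idx = np.arange(max(0, -d), min(n2, n2 - d))
            a[idx + d, idx] = self.band[3 + d, idx]
        a[0:2, n2 - 2 : n2] = self.corner_top
        a[n2 - 2 : n2, 0:2] = self.corner_bot
        return a

    def solve(self) -> np.ndarray:
        """Solve for the next iterate; returns nodes of shape ``(N, 2)``.

        The band is factorized by LAPACK (partial pivoting) and the two
        periodic corner blocks are folded in with a rank-4 Woodbury update,
        so the cost is linear in ``N``.
        """
        n2 = self.dim
        u_cols = np.zeros((n2, 4))
        u_cols[0:2, 0:2] = self.corner_top
        u_cols[n2 - 2 : n2, 2:4] = self.corner_bot
        pick = np.array([n2 - 2, n2 - 1, 0, 1])  # rows selected by V^T

        b = np.column_stack([self.rhs, u_cols])
        try:
            y = scipy.linalg.solve_banded((3, 3), self.band, b)
            cap = np.eye(4) + y[pick, 1:5]
            z = np.linalg.solve(cap, y[pick, 0])
            x = y[:, 0] - y[:, 1:5] @ z
        except np.linalg.LinAlgError:
            x = self._solve_sparse()
        if not np.all(np.isfinite(x)):
            x = self._solve_sparse()
        return x.reshape(-1, 2)

    def _solve_sparse(self) -> np.ndarray:
        import scipy.sparse
        import scipy.sparse.linalg

        a = scipy.sparse.csc_matrix(self.to_dense())
        return scipy.sparse.linalg.spsolve(a, self.rhs)


def _node_coefficients(
    x_prev: np.ndarray,
    x_it: np.ndarray,
    frame_prev: GeometryFrame,
    frame_it: GeometryFrame,
    m_vals: np.ndarray,
    p_vals: np.ndarray,
    forcing: Forcing,
    cfg: SchemeConfig,
    t_next: float,
):
    """Stencil weights, projection vectors and right-hand sides per node.

    Returns ``(a_n, b_n, w_n, rhs_n, a_t, b_t, w_t, rhs_t)`` where the
    normal equation at node ``i`` reads
    ``(a_n x_{i-1} + b_n x_i + a_n x_{i+1}) . w_n = rhs_n`` and likewise for
    the tangential equation with ``w_t``.
    """
    dt = cfg.dt
    t_prev = t_next - dt
    chord_it = frame_it.chord_len

    alpha_it = forcing.alpha_at(x_it, t_next)
    beta_it = forcing.beta_at(x_it, t_next)
    mu_it = 4.0 * dt * alpha_it / chord_it**2

    if cfg.scheme == "BE":
        w_n = frame_it.normal
        a_n = -mu_it
        b_n = 1.0 + 2.0 * mu_it
        rhs_n = np.einsum("ij,ij->i", x_prev, w_n) + dt * beta_it
    else:  # CNBE
        w_n = 0.5 * (frame_it.normal + frame_prev.normal)  # not re-normalized
        a_n = -0.5 * mu_it
        b_n = 1.0 + mu_it
        alpha_prev = forcing.alpha_at(x_prev, t_prev)
        beta_prev = forcing.beta_at(x_prev, t_prev)
        mu_prev = 4.0 * dt * alpha_prev / frame_prev.chord_len**2
        second_prev = np.roll(x_prev, 1, axis=0) - 2.0 * x_prev + np.roll(x_prev, -1, axis=0)
        rhs_n = (
            0.5 * mu_prev * np.einsum("ij,ij->i", second_prev, w_n)
            + np.einsum("ij,ij->i", x_prev, w_n)
            + 0.5 * dt * (beta_it + beta_prev)
        )

    nu = 4.0 * dt * p_vals / (cfg.tau * m_vals * chord_it**2)
    w_t = frame_it.tangent
    a_t = -nu
    b_t = 1.0 + 2.0 * nu
    m_diff = np.roll(m_vals, -1) - np.roll(m_vals, 1)
    rhs_t = np.einsum("ij,ij->i", x_prev, w_t) + dt * p_vals * m_diff / (
        cfg.tau * m_vals**2 * chord_it
    )
    return a_n, b_n, w_n, rhs_n, a_t, b_t, w_t, rhs_t


def assemble_system(
    x_prev: ClosedCurve,
    x_iter: ClosedCurve,
    m_vals: np.ndarray,
    p_vals: np.ndarray,
    forcing: Forcing,
    cfg: SchemeConfig,
    t_next: float,
    frame_prev: Optional[GeometryFrame] = None,
    frame_iter: Optional[GeometryFrame] = None,
) -> AssembledSystem:
    """Assemble one Picard sweep's linear system.

    ``x_prev`` is the accepted curve at the previous time level, ``x_iter``
    the current Picard iterate (geometry lag), ``m_vals`` and ``p_vals`` the
    monitor and balancing-operator values at the previous time level.
    """
    if frame_prev is None:
        frame_prev = compute_frame(x_prev)
    if frame_iter is None:
        frame_iter = compute_frame(x_iter)
    n = x_prev.n_nodes
    a_n, b_n, w_n, rhs_n, a_t, b_t, w_t, rhs_t = _node_coefficients(
        x_prev.nodes,
        x_iter.nodes,
        frame_prev,
        frame_iter,
        m_vals,
        p_vals,
        forcing,
        cfg,
        t_next,
    )

    band = np.zeros((7, 2 * n))
    corner_top = np.zeros((2, 2))
    corner_bot = np.zeros((2, 2))
    n2 = 2 * n
    # Rows 2i hold the normal equation, rows 2i+1 the tangential one; in
    # diagonal-ordered form band[3 + row - col, col] each (equation,
    # neighbour offset, coordinate) combination lands on a fixed diagonal
    # with stride-2 columns.  The i = 0 / i = N-1 wrap entries go to the
    # periodic corner blocks instead of the band.
    for e, (a_c, b_c, w) in enumerate([(a_n, b_n, w_n), (a_t, b_t, w_t)]):
        for c in range(2):
            v_diag = b_c * w[:, c]
            v_off = a_c * w[:, c]
            band[3 - c + e, c::2] = v_diag  # coupling to x_i
            band[5 - c + e, c : n2 - 2 : 2] = v_off[1:]  # to x_{i-1}
            band[1 - c + e, 2 + c :: 2] = v_off[:-1]  # to x_{i+1}
            corner_top[e, c] = v_off[0]
            corner_bot[e, c] = v_off[n - 1]

    rhs = np.empty(2 * n)
    rhs[0::2] = rhs_n
    rhs[1::2] = rhs_t
    return AssembledSystem(band=band, corner_top=corner_top, corner_bot=corner_bot, rhs=rhs)


def _monitor_and_p(
    frame: GeometryFrame, spec: MonitorSpec, cfg: SchemeConfig
) -> Tuple[np.ndarray, np.ndarray]:
    """Monitor and balancing-operator values at a time level (explicit)."""
    n = frame.curvature.shape[0]
    if spec.kind == "uniform":
        m_vals = np.ones(n)
    else:
        m_vals = evaluate_monitor(frame, spec)
    if cfg.p_mode == "identity":
        p_vals = np.ones(n)
    else:
        x_xi = frame.chord_len * (0.5 * n) if cfg.p_dxi_scaling else frame.chord_len
        p_vals = m_vals * x_xi**2
    return m_vals, p_vals


def picard_step(
    x_prev: ClosedCurve,
    cfg: SchemeConfig,
    spec: MonitorSpec,
    forcing: Forcing,
    t_next: float,
) -> Tuple[ClosedCurve, int]:
    """Advance the curve by one time step; returns the curve and sweep count.

    Raises
    ------
    PicardNonConvergenceError
        Fully implicit mode only: the budget ``picard_max`` was exhausted
        with the update still above ``picard_tol``.
    DegenerateGeometryError
        An iterate developed a zero chord or edge.
    """
    frame_prev = compute_frame(x_prev)
    m_vals, p_vals = _monitor_and_p(frame_prev, spec, cfg)

    x_it = x_prev
    frame_it = frame_prev
    budget = cfg.picard_cap if cfg.picard_cap is not None else cfg.picard_max
    update = np.inf
    for m in range(1, budget + 1):
        system = assemble_system(
            x_prev,
            x_it,
            m_vals,
            p_vals,
            forcing,
            cfg,
            t_next,
            frame_prev=frame_prev,
            frame_iter=frame_it,
        )
        new_nodes = system.solve()
        if not np.all(np.isfinite(new_nodes)):
            raise PicardNonConvergenceError(t_next, np.inf, m)
        update = float(np.max(np.hypot(*(new_nodes - x_it.nodes).T)))
        x_it = ClosedCurve(new_nodes)
        if cfg.picard_cap is None and update < cfg.picard_tol:
            return x_it, m
        if m < budget:
            frame_it = compute_frame(x_it)
    if cfg.picard_cap is not None:
        return x_it, budget
    raise PicardNonConvergenceError(t_next, update, budget)


@dataclass
class SimulationResult:
    """Time-marching output.

    ``times`` and ``areas`` have one entry per completed step plus the
    initial state; ``picard_counts`` one entry per completed step.
    ``snapshots`` is a list of ``(step, curve)`` pairs, always containing the
    first and the last available state.  ``status`` is ``"completed"``,
    ``"singularity"`` (Picard failure or degenerate geometry, with
    ``failure_time`` set) or ``"diverged"``.
    """

    times: np.ndarray
    areas: np.ndarray
    picard_counts: List[int]
    snapshots: List[Tuple[int, ClosedCurve]]
    status: str
    failure_time: Optional[float] = None
    config: Optional[SchemeConfig] = None
    monitor_spec: Optional[MonitorSpec] = None

    @property
    def completed(self) -> bool:
        return self.status == "completed"

    @property
    def final_curve(self) -> ClosedCurve:
        return self.snapshots[-1][1]


def evolve(
    x0: ClosedCurve,
    cfg: SchemeConfig,
    spec: MonitorSpec = MonitorSpec(kind="uniform"),
    forcing: Forcing = CSF,
    verbose: bool = False,
) -> SimulationResult:
    """March the curve from ``t = 0`` to ``t = t_final``.

    On Picard failure or degenerate geometry the partial history up to the
    last completed step is returned with ``status = "singularity"``.
    """
    n_steps = cfg.n_steps
    times = [0.0]
    areas = [enclosed_area(x0)]
    counts: List[int] = []
    snapshots: List[Tuple[int, ClosedCurve]] = [(0, x0)]
    status = "completed"
    failure_time = None

    x = x0
    for n in range(n_steps):
        t_next = (n + 1) * cfg.dt
        try:
            x, iters = picard_step(x, cfg, spec, forcing, t_next)
        except (PicardNonConvergenceError, DegenerateGeometryError) as exc:
            status = "singularity"
            failure_time = t_next if not isinstance(exc, PicardNonConvergenceError) else exc.time
            break
        area = enclosed_area(x)
        if not np.isfinite(area):
            status = "diverged"
            failure_time = t_next
            break
        times.append(t_next)
        areas.append(area)
        counts.append(iters)
        if cfg.snapshot_stride and (n + 1) % cfg.snapshot_stride == 0:
            snapshots.append((n + 1, x))
        if verbose:
            from .geometry import edge_length_ratio

            print(
                f"step {n + 1:6d}  t = {t_next:.6f}  A_h = {area:.8f}  "
                f"picard = {iters}  edge ratio = {edge_length_ratio(x):.4f}"
            )

    last_step = len(times) - 1
    if snapshots[-1][0] != last_step:
        snapshots.append((last_step, x))
    return SimulationResult(
        times=np.asarray(times),
        areas=np.asarray(areas),
        picard_counts=counts,
        snapshots=snapshots,
        status=status,
        failure_time=failure_time,
        config=cfg,
        monitor_spec=spec,
    )
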