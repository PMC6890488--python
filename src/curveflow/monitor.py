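"""Monitor functions driving tangential mesh adaptivity.

The monitor :math:`M > 0` is the weight whose equidistribution
(:math:`M\\,ds` constant between neighbouring nodes) defines the target mesh.
Two kinds are supported:

``uniform``
    :math:`M = 1`: equidistribution of arc length.
``curvature``
    :math:`M_i = \\tfrac12 M_{floor} + \\tfrac12 |\\kappa_i|^{\\gamma}` with the
    adaptive floor
    :math:`M_{floor} = |\\Gamma_h|^{-1} \\sum_j
    \\tfrac12 (|\\kappa_{j+1}|^\\gamma + |\\kappa_j|^\\gamma)\\, h_j`
    (trapezoid quadrature of the mean of :math:`|\\kappa|^\\gamma` over the
    curve).  The floor keeps the monitor positive on flat arcs so no part of
    the curve is starved of nodes, and it needs no a-priori parameter: it
    adapts to the evolving curve length.

The exponent defaults to :math:`\\gamma = 1/2`, which minimizes the maximal
distance between the curve and its polygonal interpolant; :math:`\\gamma=1/3`
(area discrepancy) and :math:`\\gamma=2/3` (length discrepancy) are the other
standard choices.

Monitor values are smoothed by a periodic weighted average with weights
:math:`(q/(q+1))^{|k|}`, ``|k| <= p`` (defaults ``p=2, q=3``) to make the
mesh dynamics robust.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ClosedCurve, GeometryFrame


@dataclass(frozen=True)
class MonitorSpec:
    """Choice and parameters of the mesh-adaptivity monitor function.

    Parameters
    ----------
    kind
        ``"uniform"`` (arc length) or ``"curvature"``.
    exponent
        Curvature exponent ``gamma`` in ``(0, 1]``; ignored for ``uniform``.
    smooth_p
        Half-width of the smoothing stencil (nonnegative integer).
    smooth_q
        Smoothing decay parameter (positive); weight of offset ``k`` is
        ``(q/(q+1))**|k|``.
    smoothing_enabled
        Apply smoothing whenever the monitor is evaluated.
    """

    kind: str = "curvature"
    exponent: float = 0.5
    smooth_p: int = 2
    smooth_q: float = 3.0
    smoothing_enabled: bool = True

    def __post_init__(self):
        if self.kind not in ("uniform", "curvature"):
            raise ValueError(f"unknown monitor kind {self.kind!r}")
        if self.kind == "curvature" and not 0.0 < self.exponent <= 1.0:
            raise ValueError("exponent must lie in (0, 1]")
        if self.smooth_p < 0:
            raise ValueError("smooth_p must be nonnegative")
        if self.smooth_q <= 0.0:
            raise ValueError("smooth_q must be positive")


def monitor_floor(frame: GeometryFrame, spec: MonitorSpec) -> float:
    """Adaptive floor: mean of ``|kappa|**gamma`` over the polygon.

    Trapezoid quadrature
    ``sum_j ((|k_{j+1}|^g + |k_j|^g)/2) h_j / |Gamma_h|``; recomputed from
    the current frame at every evaluation, so it tracks the evolving curve.
    """
    kappa = frame.curvature
    if not np.all(np.isfinite(kappa)):
        bad = int(np.flatnonzero(~np.isfinite(kappa))[0])
        raise ValueError(f"non-finite curvature at node {bad}")
    a = np.abs(kappa) ** spec.exponent
    # trapezoid rule over edges: edge j joins nodes j and j+1
    return float(np.sum(0.5 * (np.roll(a, -1) + a) * frame.edge_len) / frame.length)


def raw_monitor(frame: GeometryFrame, spec: MonitorSpec) -> np.ndarray:
    """Evaluate the (unsmoothed) monitor at every node of ``frame``."""
    n = frame.curvature.shape[0]
    if spec.kind == "uniform":
        return np.ones(n)
    floor = monitor_floor(frame, spec)
    return 0.5 * floor + 0.5 * np.abs(frame.curvature) ** spec.exponent


def smooth_monitor(values: np.ndarray, spec: MonitorSpec) -> np.ndarray:
    """Periodic weighted moving average of monitor values.

    ``M~_i = sum_{|k|<=p} M_{i+k} w_k / sum w_k`` with
    ``w_k = (q/(q+1))**|k|`` and indices mod ``N``.  The output is a convex
    combination of the input, so it preserves positivity and bounds.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    p, q = spec.smooth_p, spec.smooth_q
    if p >= n / 2:
        raise ValueError(f"smoothing half-width p={p} too large for N={n}")
    offsets = np.arange(-p, p + 1)
    weights = (q / (q + 1.0)) ** np.abs(offsets)
    out = np.zeros_like(values)
    for k, w in zip(offsets, weights):
        out += w * np.roll(values, -k)
    return out / weights.sum()


def evaluate_monitor(frame: GeometryFrame, spec: MonitorSpec) -> np.ndarray:
    """Monitor values at the nodes, smoothed when the spec asks for it."""
    m = raw_monitor(frame, spec)
    if spec.smoothing_enabled and spec.kind != "uniform":
        m = smooth_monitor(m, spec)
    return m


def equidistribution_ratio(curve: ClosedCurve, values: np.ndarray) -> float:
    """Measure how far the mesh is from equidistributing ``values``.

    Per edge ``j``, the discrete weighted arc length is
    ``w_j = ((M_j + M_{j+1})/2) h_j``.  Returns ``max_j w_j / min_j w_j``;
    the value is 1 exactly when the monitor is discretely equidistributed.
    """
    from .geometry import compute_frame

    values = np.asarray(values, dtype=float)
    h = compute_frame(curve).edge_len
    if values.shape[0] != h.shape[0]:
        raise ValueError("monitor values not aligned with curve nodes")
    w = 0.5 * (values + np.roll(values, -1)) * h
    if np.any(w == 0.0):
        raise ValueError("zero weighted edge length")
    return float(w.max() / w.min())
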