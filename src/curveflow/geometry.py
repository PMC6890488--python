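"""Discrete differential geometry of closed polygonal plane curves.

A curve is represented by ``N`` unique nodes :math:`x_i \\in \\mathbb{R}^2`,
``i = 0..N-1``, joined into a closed polygon with periodic indexing
(:math:`x_N \\equiv x_0`, :math:`x_{-1} \\equiv x_{N-1}`).  The nodes are the
images of a uniform partition of the parameter interval ``[0, 1]`` with step
:math:`\\Delta\\xi = 1/N`.

All differential quantities use central differences over the periodic index:

* unit tangent   :math:`t_i = (x_{i+1} - x_{i-1}) / |x_{i+1} - x_{i-1}|`
* unit normal    :math:`n_i = (t_{i,2}, -t_{i,1})`
* signed curvature
  :math:`\\kappa_i = 4 (x_{i-1} - 2 x_i + x_{i+1}) \\cdot n_i
  / |x_{i+1} - x_{i-1}|^2`

With this convention a counterclockwise convex curve has an *outward* normal
and negative curvature, so the flow :math:`V = \\kappa` moves it inward, in
agreement with the shrinking-circle solution :math:`r(t) = \\sqrt{1 - 2t}`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np


class DegenerateGeometryError(ValueError):
    """A chord or edge of the polygon has collapsed to zero length."""

    def __init__(self, message: str, node: int):
        super().__init__(f"{message} (node {node})")
        self.node = node


@dataclass(frozen=True)
class ClosedCurve:
    """Closed polygonal curve: ``N`` unique plane nodes, periodic indexing.

    Parameters
    ----------
    nodes
        Array of shape ``(N, 2)``, ``N >= 4``.  The closing node
        ``x_N = x_0`` is implicit and never stored.
    """

    nodes: np.ndarray

    def __post_init__(self):
        nodes = np.asarray(self.nodes, dtype=float)
        if nodes.ndim != 2 or nodes.shape[1] != 2:
            raise ValueError(f"nodes must have shape (N, 2), got {nodes.shape}")
        if nodes.shape[0] < 4:
            raise ValueError(f"need at least 4 nodes, got {nodes.shape[0]}")
        if not np.all(np.isfinite(nodes)):
            raise ValueError("non-finite node coordinates")
        object.__setattr__(self, "nodes", nodes)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def dxi(self) -> float:
        """Uniform parameter step :math:`\\Delta\\xi = 1/N`."""
        return 1.0 / self.n_nodes


@dataclass(frozen=True)
class GeometryFrame:
    """Per-node discrete frame of a :class:`ClosedCurve`.

    Attributes
    ----------
    tangent, normal
        Unit vectors, shape ``(N, 2)``.
    curvature
        Signed curvature :math:`\\kappa_i`, shape ``(N,)``.
    edge_len
        :math:`h_i = |x_{i+1} - x_i|`, shape ``(N,)``; edge ``i`` joins node
        ``i`` to node ``i+1`` (periodic).
    chord_len
        Central chord :math:`|x_{i+1} - x_{i-1}|`, shape ``(N,)``.
    length
        Polygon length :math:`|\\Gamma_h| = \\sum_i h_i`.
    """

    tangent: np.ndarray
    normal: np.ndarray
    curvature: np.ndarray
    edge_len: np.ndarray
    chord_len: np.ndarray
    length: float = field(default=0.0)


def compute_frame(curve: ClosedCurve) -> GeometryFrame:
    """Compute tangents, normals, curvature and lengths of ``curve``.

    Raises
    ------
    DegenerateGeometryError
        If any central chord :math:`|x_{i+1} - x_{i-1}|` or edge vanishes.
    """
    x = curve.nodes
    xp = np.roll(x, -1, axis=0)  # x_{i+1}
    xm = np.roll(x, +1, axis=0)  # x_{i-1}

    chord = xp - xm
    chord_len = np.hypot(chord[:, 0], chord[:, 1])
    bad = np.flatnonzero(chord_len == 0.0)
    if bad.size:
        raise DegenerateGeometryError("degenerate central chord", int(bad[0]))

    tangent = chord / chord_len[:, None]
    normal = np.column_stack([tangent[:, 1], -tangent[:, 0]])

    second_diff = xm - 2.0 * x + xp
    curvature = 4.0 * np.einsum("ij,ij->i", second_diff, normal) / chord_len**2

    edge = xp - x
    edge_len = np.hypot(edge[:, 0], edge[:, 1])
    bad = np.flatnonzero(edge_len == 0.0)
    if bad.size:
        raise DegenerateGeometryError("degenerate edge", int(bad[0]))

    return GeometryFrame(
        tangent=tangent,
        normal=normal,
        curvature=curvature,
        edge_len=edge_len,
        chord_len=chord_len,
        length=float(edge_len.sum()),
    )


def enclosed_area(curve: ClosedCurve) -> float:
    """Signed polygon (shoelace) area; positive for counterclockwise curves.

    :math:`A_h = \\tfrac12 \\sum_{i=0}^{N-1} (x_i y_{i+1} - x_{i+1} y_i)`
    """
    x, y = curve.nodes[:, 0], curve.nodes[:, 1]
    xp, yp = np.roll(x, -1), np.roll(y, -1)
    return float(0.5 * np.sum(x * yp - xp * y))


def edge_length_ratio(curve: ClosedCurve) -> float:
    """Mesh-quality diagnostic ``max_i h_i / min_i h_i`` (>= 1).

    A uniform-arc-length mesh has ratio 1; tangential mesh relaxation with a
    uniform monitor drives the ratio toward 1 over time.
    """
    h = compute_frame(curve).edge_len
    return float(h.max() / h.min())


def read_polygon_csv(path: Union[str, Path, io.TextIOBase]) -> ClosedCurve:
    """Read a polygon from CSV with header ``x,y``, one node per row.

    Closure is implicit: the last row must differ from the first.
    """
    import pandas as pd

    df = pd.read_csv(path)
    if not {"x", "y"} <= set(df.columns):
        raise ValueError("polygon CSV must have columns 'x' and 'y'")
    nodes = df[["x", "y"]].to_numpy(dtype=float)
    if nodes.shape[0] >= 2 and np.allclose(nodes[0], nodes[-1]):
        raise ValueError(
            "polygon CSV closes explicitly (last row equals first); "
            "closure must be implicit"
        )
    return ClosedCurve(nodes)


def write_polygon_csv(curve: ClosedCurve, path: Union[str, Path, io.TextIOBase]) -> None:
    """Write the nodes of ``curve`` as a CSV with header ``x,y``."""
    import pandas as pd

    pd.DataFrame(curve.nodes, columns=["x", "y"]).to_csv(path, index=False)
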