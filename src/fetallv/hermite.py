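"""Cubic-Hermite tensor-product interpolation on a structured quadrilateral grid.

The ventricular meshes in this package are structured grids of bicubic
Hermite elements in the (longitudinal, transmural) parameter plane, with an
analytic (linear) circumferential sweep.  Every scalar field carries four
degrees of freedom per node: the nodal value and its first and mixed
derivatives with respect to the *global* parametric coordinates
``xi1, xi2 in [0, 1]``.  Sharing global derivatives between neighbouring
elements makes the interpolation C1-continuous across element boundaries by
construction.
"""

from __future__ import annotations

import numpy as np

__all__ = ["HermiteGrid", "hermite_shape", "hermite_shape_d", "gauss_legendre_01"]


def hermite_shape(s: np.ndarray) -> np.ndarray:
    """Cubic Hermite shape functions on [0, 1].

    Returns an array ``(..., 4)`` with ``[h0, h1, g0, g1]`` where ``h`` weight
    end values and ``g`` weight end derivatives (with respect to ``s``).
    """
    s = np.asarray(s, dtype=float)
    s2, s3 = s * s, s * s * s
    return np.stack(
        [2 * s3 - 3 * s2 + 1, -2 * s3 + 3 * s2, s3 - 2 * s2 + s, s3 - s2], axis=-1
    )


def hermite_shape_d(s: np.ndarray) -> np.ndarray:
    """First derivatives of :func:`hermite_shape` with respect to ``s``."""
    s = np.asarray(s, dtype=float)
    s2 = s * s
    return np.stack(
        [6 * s2 - 6 * s, -6 * s2 + 6 * s, 3 * s2 - 4 * s + 1, 3 * s2 - 2 * s], axis=-1
    )


def gauss_legendre_01(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre points/weights mapped from [-1, 1] to [0, 1]."""
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


class HermiteGrid:
    """Structured bicubic-Hermite element grid on the unit square.

    Parameters
    ----------
    n1, n2 : int
        Number of elements along ``xi1`` (longitudinal, apex to base) and
        ``xi2`` (transmural, endocardium to epicardium).

    Scalar fields on the grid are stored as arrays of shape
    ``(n1 + 1, n2 + 1, 4)`` — per node ``[v, dv/dxi1, dv/dxi2, d2v/dxi1 dxi2]``
    — or equivalently as flat vectors of length ``n_dof = 4 (n1+1)(n2+1)``.
    """

    def __init__(self, n1: int, n2: int):
        self.n1 = int(n1)
        self.n2 = int(n2)
        self.n_nodes = (self.n1 + 1) * (self.n2 + 1)
        self.n_dof = 4 * self.n_nodes
        self.n_elements = self.n1 * self.n2

    # -- indexing ---------------------------------------------------------
    def node_index(self, i, j):
        """Flat node index of grid node (i, j)."""
        return np.asarray(i) * (self.n2 + 1) + np.asarray(j)

    def element_nodes(self, e1, e2):
        """The four corner (i, j) pairs of element (e1, e2)."""
        return [(e1, e2), (e1 + 1, e2), (e1, e2 + 1), (e1 + 1, e2 + 1)]

    def flatten(self, nodal: np.ndarray) -> np.ndarray:
        return np.asarray(nodal, dtype=float).reshape(self.n_dof)

    def unflatten(self, flat: np.ndarray) -> np.ndarray:
        return np.asarray(flat, dtype=float).reshape(self.n1 + 1, self.n2 + 1, 4)

    # -- operator assembly ------------------------------------------------
    def operator(self, e1, e2, s, t, d1: int = 0, d2: int = 0) -> np.ndarray:
        """Row matrix evaluating a field (or its global derivative) at points.

        ``e1, e2, s, t`` are broadcastable arrays of element indices and local
        coordinates in [0, 1].  ``d1, d2`` in {0, 1} select differentiation with
        respect to ``xi1`` / ``xi2``.  Returns ``(npts, n_dof)`` such that
        ``op @ field_flat`` evaluates the field at the points.
        """
        e1, e2, s, t = np.broadcast_arrays(
            np.atleast_1d(e1), np.atleast_1d(e2), np.atleast_1d(s), np.atleast_1d(t)
        )
        npts = e1.size
        e1 = e1.ravel().astype(int)
        e2 = e2.ravel().astype(int)
        s = s.ravel().astype(float)
        t = t.ravel().astype(float)
        if np.any((s < -1e-12) | (s > 1 + 1e-12) | (t < -1e-12) | (t > 1 + 1e-12)):
            raise ValueError("local coordinates must lie in [0, 1]")

        S = hermite_shape_d(s) if d1 else hermite_shape(s)
        T = hermite_shape_d(t) if d2 else hermite_shape(t)
        # local->global derivative scale factors
        w1, w2 = 1.0 / self.n1, 1.0 / self.n2
        scale_s = self.n1 if d1 else 1.0
        scale_t = self.n2 if d2 else 1.0

        op = np.zeros((npts, self.n_dof))
        rows = np.arange(npts)
        for a in (0, 1):  # corner along xi1
            for b in (0, 1):  # corner along xi2
                node = self.node_index(e1 + a, e2 + b)
                base = 4 * node
                # dof order: value, d/dxi1, d/dxi2, d2/dxi1dxi2
                op[rows, base + 0] += scale_s * scale_t * S[:, a] * T[:, b]
                op[rows, base + 1] += scale_s * scale_t * w1 * S[:, 2 + a] * T[:, b]
                op[rows, base + 2] += scale_s * scale_t * w2 * S[:, a] * T[:, 2 + b]
                op[rows, base + 3] += (
                    scale_s * scale_t * w1 * w2 * S[:, 2 + a] * T[:, 2 + b]
                )
        return op

    def quadrature(self, ngauss: int = 3):
        """In-plane Gauss quadrature over all elements.

        Returns ``(e1, e2, s, t, w)`` flat arrays; ``w`` includes the element
        area measure in (xi1, xi2) so that ``sum(w * f)`` approximates
        ``integral over the unit square of f``.
        """
        gp, gw = gauss_legendre_01(ngauss)
        e1g, e2g, sg, tg = np.meshgrid(
            np.arange(self.n1), np.arange(self.n2), gp, gp, indexing="ij"
        )
        wg = np.einsum("a,b->ab", gw, gw)[None, None, :, :] * np.ones_like(sg)
        w = wg / (self.n1 * self.n2)
        return (
            e1g.ravel(),
            e2g.ravel(),
            sg.ravel(),
            tg.ravel(),
            w.ravel(),
        )

    def boundary_quadrature(self, edge_xi2: float, ngauss: int = 4):
        """Quadrature along a ``xi2 = const`` grid line (element edges).

        Returns ``(e1, e2, s, t, w)`` with ``w`` the xi1 line measure.
        """
        gp, gw = gauss_legendre_01(ngauss)
        if edge_xi2 in (0.0, 0):
            e2, t = 0, 0.0
        elif edge_xi2 in (1.0, 1):
            e2, t = self.n2 - 1, 1.0
        else:
            raise ValueError("edge must be xi2 = 0 or 1")
        e1 = np.repeat(np.arange(self.n1), ngauss)
        s = np.tile(gp, self.n1)
        w = np.tile(gw, self.n1) / self.n1
        return e1, np.full_like(e1, e2), s, np.full_like(s, t), w
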