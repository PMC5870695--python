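"""Trilinear hexahedral element geometry: corner ordering, shape-function
gradients on the reference cube [-1, 1]^3, Jacobians and Gauss rules.

Local corner ordering is the right-handed unit-cube order (VTK hexahedron):

    0:(0,0,0) 1:(1,0,0) 2:(1,1,0) 3:(0,1,0)
    4:(0,0,1) 5:(1,0,1) 6:(1,1,1) 7:(0,1,1)
"""
from __future__ import annotations

import numpy as np

#: Corner offsets of the unit cube in local node order.
CORNER_OFFSETS = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [1, 1, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 0, 1],
        [1, 1, 1],
        [0, 1, 1],
    ],
    dtype=np.int64,
)

# Corner signs on the reference cube [-1, 1]^3.
_SIGNS = 2.0 * CORNER_OFFSETS - 1.0

#: Element faces as local corner quadruples, outward-oriented.
HEX_FACES = np.array(
    [
        [0, 3, 2, 1],  # z-
        [4, 5, 6, 7],  # z+
        [0, 1, 5, 4],  # y-
        [2, 3, 7, 6],  # y+
        [1, 2, 6, 5],  # x+
        [0, 4, 7, 3],  # x-
    ],
    dtype=np.int64,
)


def gauss_rule(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Tensor-product Gauss-Legendre rule on [-1, 1]^3.

    Returns (points (G,3), weights (G,)) with G = order**3.
    """
    x, w = np.polynomial.legendre.leggauss(order)
    pts = np.array(np.meshgrid(x, x, x, indexing="ij")).reshape(3, -1).T
    wts = (w[:, None, None] * w[None, :, None] * w[None, None, :]).ravel()
    return pts, wts


def shape_functions(xi: np.ndarray) -> np.ndarray:
    """Trilinear shape functions N_a(xi) for points xi (G,3) -> (G,8)."""
    xi = np.atleast_2d(np.asarray(xi, dtype=float))
    terms = 1.0 + xi[:, None, :] * _SIGNS[None, :, :]  # (G,8,3)
    return terms.prod(axis=2) / 8.0


def shape_gradients(xi: np.ndarray) -> np.ndarray:
    """Reference-space gradients dN_a/dxi_d at points xi (G,3) -> (G,8,3)."""
    xi = np.atleast_2d(np.asarray(xi, dtype=float))
    terms = 1.0 + xi[:, None, :] * _SIGNS[None, :, :]  # (G,8,3)
    out = np.empty((xi.shape[0], 8, 3))
    for d in range(3):
        e0, e1 = [e for e in range(3) if e != d]
        out[:, :, d] = _SIGNS[None, :, d] / 8.0 * terms[:, :, e0] * terms[:, :, e1]
    return out


def jacobians(coords: np.ndarray, grads: np.ndarray) -> np.ndarray:
    """Jacobians J[de] = d x_e / d xi_d for element corner coords.

    coords: (..., 8, 3); grads: (G, 8, 3) -> J: (..., G, 3, 3).
    """
    coords = np.asarray(coords, dtype=float)
    return np.einsum("gad,...ae->...gde", grads, coords)


def jacobian_determinants(coords: np.ndarray, order: int = 2) -> np.ndarray:
    """det J at the order^3 Gauss points for elements (..., 8, 3)."""
    pts, _ = gauss_rule(order)
    return np.linalg.det(jacobians(coords, shape_gradients(pts)))
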