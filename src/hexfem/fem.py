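"""FEM solution of the quasi-static EEG forward problem.

The electric potential u in the head volume conductor satisfies the Poisson
problem  div(sigma grad u) = div j^p  with homogeneous Neumann boundary
conditions (no current leaves the head).  Discretizing with trilinear
Lagrange elements on the hexahedral mesh gives the sparse system A u = b with

    A_ij = integral  < sigma grad h_i , grad h_j >  dx,

assembled by 2x2x2 Gauss quadrature (exact for axis-aligned voxels).  A point
current dipole j^p = m delta_{x0} is represented by the St. Venant approach:
a patch of monopole loads on the nodes around x0 whose net current vanishes
and whose first moment equals m exactly; second-order moments and the load
magnitudes are minimized under a relative Tikhonov weight.

The pure-Neumann system is singular (constant null space); uniqueness is
restored by a Dirichlet constraint at one reference node (row/column
elimination keeps the matrix SPD).  Systems are solved with conjugate
gradients preconditioned by incomplete Cholesky with zero fill-in (IC(0)-CG).
Because A is symmetric, one solve per electrode yields a transfer matrix
T^eeg mapping any load vector to referenced electrode potentials, from which
leadfields for whole source grids follow at one sparse product per source.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import cg

from ._element import gauss_rule, jacobians, shape_gradients
from ._ic0 import IC0Preconditioner
from .mesh import ElectrodeSet, HexMesh

logger = logging.getLogger("hexfem")

_GAUSS_PTS, _GAUSS_WTS = gauss_rule(2)
_GRADS = shape_gradients(_GAUSS_PTS)  # (8, 8, 3)


class ConvergenceError(RuntimeError):
    """CG failed to reach the requested residual; carries the final residual."""

    def __init__(self, residual: float, rel_tol: float):
        super().__init__(
            f"PCG did not converge: final relative residual {residual:.3e} "
            f"> rel_tol {rel_tol:.3e}"
        )
        self.residual = residual


@dataclass
class Dipole:
    """Current dipole: position (mm) and moment vector (source-strength units)."""

    position: np.ndarray
    moment: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.moment = np.asarray(self.moment, dtype=float).reshape(3)


@dataclass
class LoadVector:
    """Sparse St. Venant load vector: monopole currents on a node patch."""

    node_indices: np.ndarray
    values: np.ndarray
    n_nodes: int

    def toarray(self) -> np.ndarray:
        out = np.zeros(self.n_nodes)
        out[self.node_indices] = self.values
        return out


def element_stiffness(corner_coords: np.ndarray, sigma: float) -> np.ndarray:
    """8x8 stiffness matrix of one trilinear hexahedron (2x2x2 Gauss).

    Raises ValueError on a non-positive Jacobian (inverted element).
    """
    coords = np.asarray(corner_coords, dtype=float).reshape(8, 3)
    J = jacobians(coords, _GRADS)  # (8, 3, 3)
    det = np.linalg.det(J)
    if np.any(det <= 0.0):
        raise ValueError("non-positive Jacobian: inverted element")
    invJT = np.linalg.inv(J).transpose(0, 2, 1)  # (8, 3, 3)
    gradx = np.einsum("gad,gde->gae", _GRADS, invJT)
    Ke = np.einsum("g,g,gae,gbe->ab", _GAUSS_WTS, det, gradx, gradx)
    return float(sigma) * Ke


@dataclass
class StiffnessMatrix:
    """Sparse symmetric FEM system matrix (pure-Neumann, PSD, rowsums 0)."""

    matrix: sparse.csr_matrix

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def assemble_stiffness(mesh: HexMesh, chunk: int = 20000) -> StiffnessMatrix:
    """Assemble the global stiffness matrix from all element contributions."""
    n = mesh.n_nodes
    rows, cols, vals = [], [], []
    for start in range(0, mesh.n_elements, chunk):
        sl = slice(start, min(start + chunk, mesh.n_elements))
        coords = mesh.element_coords(sl)  # (C, 8, 3)
        J = jacobians(coords, _GRADS)  # (C, 8, 3, 3)
        det = np.linalg.det(J)
        if np.any(det <= 0.0):
            raise ValueError("non-positive Jacobian: inverted element in mesh")
        invJT = np.linalg.inv(J).transpose(0, 1, 3, 2)
        gradx = np.einsum("gad,cgde->cgae", _GRADS, invJT)
        Ke = np.einsum(
            "g,cg,cgae,cgbe->cab", _GAUSS_WTS, det, gradx, gradx
        ) * mesh.element_conductivity[sl, None, None]
        el = mesh.elements[sl]
        rows.append(np.repeat(el, 8, axis=1).ravel())
        cols.append(np.tile(el, (1, 8)).ravel())
        vals.append(Ke.ravel())
    A = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    A = (A + A.T) * 0.5  # enforce exact symmetry against roundoff
    ncomp, _ = connected_components(A, directed=False)
    if ncomp > 1:
        warnings.warn(
            f"mesh is disconnected ({ncomp} components); stiffness null space "
            "contains one constant per component",
            stacklevel=2,
        )
    return StiffnessMatrix(A.tocsr())


# ---------------------------------------------------------------------------
# St. Venant right-hand side
# ---------------------------------------------------------------------------

def _locate_element(mesh: HexMesh, x0: np.ndarray) -> int:
    """Element containing x0, via the voxel raster of a voxel-derived mesh."""
    if mesh.voxel_index is None or mesh.voxel_size is None:
        d2 = np.sum((mesh.element_coords().mean(axis=1) - x0) ** 2, axis=1)
        return int(np.argmin(d2))
    try:
        return mesh.element_at(x0)
    except ValueError:
        raise ValueError("source outside mesh") from None


def venant_rhs(
    mesh: HexMesh,
    dipole: Dipole,
    admissible_labels: set[int] | None = None,
    reg_weight: float = 1e-6,
) -> LoadVector:
    """St. Venant load vector for a current dipole.

    The patch is the mesh node nearest to the dipole plus every node sharing
    an element with it.  The loads q solve

        min  || M2 q ||^2 + eps || q ||^2
        s.t. sum q = 0           (monopole / charge conservation, exact)
             sum q (x - x0) = m  (dipole-moment reproduction, exact)

    where M2 holds the second-order monomials of the scaled node offsets and
    eps is ``reg_weight`` relative to the problem scale.
    """
    el = _locate_element(mesh, dipole.position)
    if admissible_labels is not None and int(mesh.element_label[el]) not in admissible_labels:
        raise ValueError(
            f"source in non-admissible compartment (label {mesh.element_label[el]})"
        )
    enodes = mesh.elements[el]
    d2 = np.sum((mesh.nodes[enodes] - dipole.position) ** 2, axis=1)
    center = int(enodes[np.argmin(d2)])
    patch = np.unique(mesh.elements[mesh.elements_of_node(center)])
    if patch.size < 4:
        raise ValueError("degenerate Venant patch")

    scale = float(np.mean(mesh.voxel_size)) if mesh.voxel_size is not None else float(
        np.sqrt(d2.max())
    )
    d = (mesh.nodes[patch] - dipole.position) / scale  # (P, 3)
    P = patch.size

    # equality constraints: zeroth and first moments
    C = np.vstack([np.ones((1, P)), d.T])  # (4, P)
    t = np.concatenate([[0.0], dipole.moment / scale])

    # penalized second-order monomials
    M2 = np.vstack(
        [
            d[:, 0] ** 2,
            d[:, 1] ** 2,
            d[:, 2] ** 2,
            d[:, 0] * d[:, 1],
            d[:, 0] * d[:, 2],
            d[:, 1] * d[:, 2],
        ]
    )  # (6, P)
    H = M2.T @ M2
    eps = reg_weight * max(np.trace(H) / P, 1.0)
    H[np.diag_indices(P)] += eps

    kkt = np.zeros((P + 4, P + 4))
    kkt[:P, :P] = H
    kkt[:P, P:] = C.T
    kkt[P:, :P] = C
    rhs = np.zeros(P + 4)
    rhs[P:] = t
    sol = np.linalg.solve(kkt, rhs)
    q = sol[:P]  # loads carry units of moment / length

    return LoadVector(node_indices=patch, values=q, n_nodes=mesh.n_nodes)


# ---------------------------------------------------------------------------
# Reference constraint and solver
# ---------------------------------------------------------------------------

@dataclass
class ReferencedSystem:
    """Stiffness system with one Dirichlet (reference) node eliminated."""

    matrix: sparse.csr_matrix  # (N-1, N-1), SPD
    ref_node: int
    n_full: int
    preconditioner: IC0Preconditioner | None = field(default=None, repr=False)

    def reduce(self, v: np.ndarray) -> np.ndarray:
        return np.delete(np.asarray(v, dtype=float), self.ref_node)

    def expand(self, u: np.ndarray) -> np.ndarray:
        return np.insert(np.asarray(u, dtype=float), self.ref_node, 0.0)

    def reduced_index(self, node: int) -> int:
        if node == self.ref_node:
            raise ValueError("reference node has no reduced index")
        return node - 1 if node > self.ref_node else node


def apply_reference(
    A: StiffnessMatrix, ref_node: int, b: np.ndarray | LoadVector | None = None
):
    """Eliminate one node (Dirichlet u = 0) from the pure-Neumann system.

    Returns the SPD :class:`ReferencedSystem`, or ``(system, reduced_b)``
    when a load vector is supplied.
    """
    n = A.n
    if not (0 <= ref_node < n):
        raise IndexError(f"reference node {ref_node} out of range")
    keep = np.ones(n, dtype=bool)
    keep[ref_node] = False
    Ared = A.matrix[keep][:, keep].tocsr()
    sys = ReferencedSystem(matrix=Ared, ref_node=int(ref_node), n_full=n)
    if b is None:
        return sys
    bfull = b.toarray() if isinstance(b, LoadVector) else np.asarray(b, dtype=float)
    return sys, sys.reduce(bfull)


def solve_pcg(
    system: ReferencedSystem | sparse.spmatrix,
    b: np.ndarray,
    rel_tol: float = 1e-8,
    max_iter: int = 5000,
) -> np.ndarray:
    """IC(0)-CG solve of an SPD system to a relative residual ``rel_tol``.

    Accepts a :class:`ReferencedSystem` (preconditioner cached on it) or a
    raw SPD sparse matrix.  Deterministic; raises :class:`ConvergenceError`
    carrying the final residual on failure.
    """
    if isinstance(system, ReferencedSystem):
        A = system.matrix
        if system.preconditioner is None:
            system.preconditioner = IC0Preconditioner(A)
        M = system.preconditioner
    else:
        A = sparse.csr_matrix(system)
        M = IC0Preconditioner(A)
    b = np.asarray(b, dtype=float).ravel()
    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:
        return np.zeros_like(b)
    u, _ = cg(A, b, rtol=rel_tol, atol=0.0, maxiter=max_iter, M=M)
    res = float(np.linalg.norm(A @ u - b) / bnorm)
    if res > rel_tol:
        raise ConvergenceError(res, rel_tol)
    return u


def solve_forward(
    A: StiffnessMatrix,
    b: LoadVector | np.ndarray,
    ref_node: int,
    rel_tol: float = 1e-8,
    system: ReferencedSystem | None = None,
) -> np.ndarray:
    """Full forward solve: node potentials with u[ref_node] = 0."""
    if system is None:
        system = apply_reference(A, ref_node)
    bfull = b.toarray() if isinstance(b, LoadVector) else np.asarray(b, dtype=float)
    u = solve_pcg(system, system.reduce(bfull), rel_tol=rel_tol)
    return system.expand(u)


# ---------------------------------------------------------------------------
# Transfer matrix and leadfield
# ---------------------------------------------------------------------------

@dataclass
class TransferMatrix:
    """S x N operator mapping load vectors to referenced electrode potentials.

    Row s solves A t_s = e_{node(s)} - e_{node(ref)}; the reference row is 0.
    ``T @ b`` equals the electrode potential differences of a direct solve.
    """

    matrix: np.ndarray  # (S, N)
    electrodes: ElectrodeSet
    ref_index: int

    def apply(self, b: LoadVector | np.ndarray) -> np.ndarray:
        if isinstance(b, LoadVector):
            return self.matrix[:, b.node_indices] @ b.values
        return self.matrix @ np.asarray(b, dtype=float)


def transfer_matrix(
    A: StiffnessMatrix,
    electrodes: ElectrodeSet,
    ref_electrode: int | str | None = None,
    rel_tol: float = 1e-8,
) -> TransferMatrix:
    """Compute T^eeg by one IC(0)-CG solve per non-reference electrode.

    Because A is symmetric, the adjoint solves coincide with direct solves:
    row s of T satisfies A t_s = e_s - e_ref with the reference node grounded.
    """
    if electrodes.node_index is None:
        raise ValueError("electrodes must be projected to mesh nodes first")
    if ref_electrode is None:
        ref = electrodes.n - 1
    elif isinstance(ref_electrode, str):
        ref = electrodes.index_of(ref_electrode)
    else:
        ref = int(ref_electrode)
    nodes = electrodes.node_index
    if len(np.unique(nodes)) < len(nodes):
        warnings.warn("duplicate electrode nodes after projection", stacklevel=2)

    system = apply_reference(A, int(nodes[ref]))
    T = np.zeros((electrodes.n, A.n))
    for s in range(electrodes.n):
        if s == ref:
            continue
        rhs = np.zeros(A.n - 1)
        rhs[system.reduced_index(int(nodes[s]))] = 1.0
        T[s] = system.expand(solve_pcg(system, rhs, rel_tol=rel_tol))
        logger.debug("transfer row %d/%d done", s + 1, electrodes.n)
    return TransferMatrix(matrix=T, electrodes=electrodes, ref_index=ref)


@dataclass
class Leadfield:
    """S x (3 n) gain matrix: electrode potentials of unit x/y/z moments."""

    matrix: np.ndarray
    positions: np.ndarray  # (n, 3) kept source positions
    electrodes: ElectrodeSet
    average_referenced: bool
    skipped: list[int] = field(default_factory=list)

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]

    def gain(self, k: int) -> np.ndarray:
        """S x 3 gain block of source k."""
        return self.matrix[:, 3 * k : 3 * k + 3]

    def potentials(self, k: int, moment: np.ndarray) -> np.ndarray:
        return self.gain(k) @ np.asarray(moment, dtype=float)


def average_reference(u: np.ndarray) -> np.ndarray:
    """Subtract the mean over electrodes (axis 0): average-reference gauge."""
    u = np.asarray(u, dtype=float)
    return u - u.mean(axis=0, keepdims=True) if u.ndim > 1 else u - u.mean()


def compute_leadfield(
    T: TransferMatrix,
    mesh: HexMesh,
    positions: np.ndarray,
    admissible_labels: set[int] | None = None,
    to_average_reference: bool = True,
) -> Leadfield:
    """Leadfield over a source grid: columns T . venant_rhs(x_k, e_axis).

    Sources whose Venant construction fails (outside the mesh or in a
    non-admissible compartment) are skipped and recorded.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    cols, kept, skipped = [], [], []
    for k, x in enumerate(positions):
        try:
            block = np.empty((T.matrix.shape[0], 3))
            for ax in range(3):
                m = np.zeros(3)
                m[ax] = 1.0
                b = venant_rhs(mesh, Dipole(x, m), admissible_labels)
                block[:, ax] = T.apply(b)
        except ValueError as exc:
            logger.info("leadfield: skipping source %d at %s (%s)", k, x, exc)
            skipped.append(k)
            continue
        cols.append(block)
        kept.append(k)
    if not cols:
        raise ValueError("no admissible sources for leadfield")
    L = np.concatenate(cols, axis=1)
    if to_average_reference:
        L = average_reference(L)
    return Leadfield(
        matrix=L,
        positions=positions[kept],
        electrodes=T.electrodes,
        average_referenced=to_average_reference,
        skipped=skipped,
    )
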