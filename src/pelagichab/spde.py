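"""Sparse precision matrices for the Matérn GMRF and the cyclic month effect.

The spatial field is a Matérn (nu = 1 in 2-D, alpha = 2) Gaussian field
approximated on the triangulation by linear finite elements, which turns it
into a Gaussian Markov random field with sparse precision

    Q = tau^2 (kappa^4 C + 2 kappa^2 G + G C^{-1} G)

with C the mass-lumped (diagonal) mass matrix and G the stiffness matrix.
Range and marginal standard deviation relate to (kappa, tau) by
rho = sqrt(8) / kappa and sigma = 1 / (sqrt(4 pi) kappa tau).

The seasonal effect is a first-order cyclic random walk over the 12 months:
structure matrix circulant(2, -1, 0, ..., 0, -1), rank n - 1, used with a
precision hyperparameter and a sum-to-zero constraint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

__all__ = ["SpdeParams", "fem_matrices", "spde_precision", "cyclic_rw1_structure"]


@dataclass(frozen=True)
class SpdeParams:
    """Matérn GMRF hyperparameters (kappa: inverse range scale, tau: precision scale)."""

    kappa: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.kappa > 0 and self.tau > 0):
            raise ValueError("kappa and tau must be positive")

    @property
    def range(self) -> float:
        """Distance at which Matérn(nu=1) correlation drops to ~0.13."""
        return float(np.sqrt(8.0) / self.kappa)

    @property
    def marginal_sd(self) -> float:
        return float(1.0 / (np.sqrt(4.0 * np.pi) * self.kappa * self.tau))

    @classmethod
    def from_range_sd(cls, spatial_range: float, marginal_sd: float) -> "SpdeParams":
        kappa = np.sqrt(8.0) / spatial_range
        tau = 1.0 / (np.sqrt(4.0 * np.pi) * kappa * marginal_sd)
        return cls(kappa=float(kappa), tau=float(tau))


def fem_matrices(mesh) -> tuple[sparse.dia_matrix, sparse.csr_matrix]:
    """Lumped mass matrix C (diagonal) and stiffness matrix G for P1 elements."""
    verts = mesh.vertices
    tris = mesh.triangles
    n = mesh.n_vertices
    p = verts[tris]  # (m, 3, 2)
    # edge vectors opposite each vertex
    e = p[:, [2, 0, 1], :] - p[:, [1, 2, 0], :]  # (m, 3, 2)
    areas = 0.5 * np.abs(e[:, 0, 0] * e[:, 1, 1] - e[:, 0, 1] * e[:, 1, 0])
    # local stiffness K_ab = (e_a . e_b) / (4 A)
    dots = np.einsum("mad,mbd->mab", e, e)
    K = dots / (4.0 * areas)[:, None, None]
    rows = np.repeat(tris, 3, axis=1).ravel()
    cols = np.tile(tris, (1, 3)).ravel()
    G = sparse.csr_matrix((K.ravel(), (rows, cols)), shape=(n, n))
    c_diag = np.zeros(n)
    np.add.at(c_diag, tris.ravel(), np.repeat(areas / 3.0, 3))
    C = sparse.diags(c_diag)
    return C, G.tocsr()


def spde_precision(mesh, params: SpdeParams) -> sparse.csc_matrix:
    """Sparse SPD precision of the Matérn(nu=1) GMRF on the mesh vertices."""
    C, G = fem_matrices(mesh)
    c = C.diagonal()
    if np.any(c <= 0):
        raise ValueError("mesh has a vertex with zero mass (isolated vertex)")
    Cinv = sparse.diags(1.0 / c)
    k2 = params.kappa**2
    Q = params.tau**2 * (k2**2 * C + 2.0 * k2 * G + G @ Cinv @ G)
    Q = ((Q + Q.T) * 0.5).tocsc()
    if not np.all(np.isfinite(Q.data)):
        raise ValueError("non-finite entries in SPDE precision")
    return Q


def cyclic_rw1_structure(n: int = 12) -> sparse.csr_matrix:
    """Circulant RW1 structure matrix: diagonal 2, -1 on cyclic neighbors.

    Rank n - 1 with null space span{1}; month n is adjacent to month 1.
    """
    if n < 3:
        raise ValueError("cyclic RW1 needs n >= 3")
    i = np.arange(n)
    rows = np.r_[i, i, i]
    cols = np.r_[i, (i + 1) % n, (i - 1) % n]
    vals = np.r_[2.0 * np.ones(n), -np.ones(n), -np.ones(n)]
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
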