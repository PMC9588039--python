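"""Chebyshev-polynomial spectral filtering on graphs.

A spectral filter is a polynomial of the graph Laplacian, g_theta(L) =
sum_k theta_k T_k(L~), where L~ = 2L/lambda_max - I maps the spectrum into
[-1, 1] (the interval on which Chebyshev polynomials of the first kind are
stable) and T_k follows the three-term recurrence T_k = 2 L~ T_{k-1} - T_{k-2}
with T_0 = I, T_1 = L~.  The filter is K-localized: the output at a vertex
depends only on its (K-1)-hop neighborhood, and a layer with F_in input and
F_out output channels has F_in * F_out * K trainable coefficients.

``cheb_filter`` evaluates the filter with sparse matrix products and never
materializes T_k(L~); ``spectral_oracle`` is a dense eigendecomposition
reference used only in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graph_hierarchy import Laplacian

__all__ = ["ScaledLaplacian", "ChebFilterSpec", "scale_laplacian", "cheb_filter",
           "spectral_oracle", "cheb_basis_apply"]

_ORACLE_MAX_N = 500  # dense eigendecomposition path, tests only


@dataclass
class ScaledLaplacian:
    """L~ = 2 L / lambda_max - I, with spectrum in [-1, 1]."""

    matrix: sp.csr_matrix
    kind: str
    lambda_max: float


@dataclass
class ChebFilterSpec:
    """Chebyshev coefficients theta of shape (F_in, F_out, K)."""

    theta: np.ndarray
    bias: np.ndarray | None = None  # (F_out,), optional

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=np.float64)
        if self.theta.ndim != 3:
            raise ValueError("theta must have shape (F_in, F_out, K)")
        if not np.isfinite(self.theta).all():
            raise ValueError("theta contains non-finite coefficients")
        if self.bias is not None:
            self.bias = np.asarray(self.bias, dtype=np.float64)
            if self.bias.shape != (self.theta.shape[1],):
                raise ValueError("bias must have shape (F_out,)")

    @property
    def f_in(self) -> int:
        return self.theta.shape[0]

    @property
    def f_out(self) -> int:
        return self.theta.shape[1]

    @property
    def order(self) -> int:
        return self.theta.shape[2]

    @property
    def n_parameters(self) -> int:
        """Trainable coefficient count F_in * F_out * K (bias excluded)."""
        return int(np.prod(self.theta.shape))


def scale_laplacian(lap: Laplacian) -> ScaledLaplacian:
    """Rescale so the spectrum fits [-1, 1]: L~ = 2 L / lambda_max - I.

    Edgeless graphs use the convention lambda_max = 2 (giving L~ = -I).
    """
    lmax = lap.lambda_max
    if lap.matrix.nnz == 0:
        lmax = 2.0
    if lmax <= 0:
        raise ValueError(f"lambda_max must be positive, got {lmax}")
    n = lap.matrix.shape[0]
    scaled = sp.csr_matrix(lap.matrix * (2.0 / lmax) - sp.identity(n))
    return ScaledLaplacian(matrix=scaled, kind=lap.kind, lambda_max=lmax)


def cheb_basis_apply(scaled: ScaledLaplacian | sp.spmatrix, x: np.ndarray,
                     order: int) -> np.ndarray:
    """Stack [T_0(L~) x, ..., T_{K-1}(L~) x] along a new leading axis.

    ``x`` is (n, ...) — trailing axes (features, batch) ride along through the
    sparse matvecs.  This is the shared kernel of the filter forward pass and
    of backpropagation (L~ is symmetric, so the same stack serves both).
    """
    mat = scaled.matrix if isinstance(scaled, ScaledLaplacian) else scaled
    x = np.asarray(x)
    n = mat.shape[0]
    if x.shape[0] != n:
        raise ValueError(f"x has {x.shape[0]} rows, Laplacian is {n}x{n}")
    flat = x.reshape(n, -1)
    out = np.empty((order,) + flat.shape, dtype=flat.dtype)
    out[0] = flat
    if order > 1:
        out[1] = mat @ flat
    for k in range(2, order):
        out[k] = 2.0 * (mat @ out[k - 1]) - out[k - 2]
    return out.reshape((order,) + x.shape)


def cheb_filter(x: np.ndarray, scaled: ScaledLaplacian,
                spec: ChebFilterSpec) -> np.ndarray:
    """Apply the K-localized filter: y = sum_k T_k(L~) x theta_k (+ bias).

    ``x`` is (n, F_in) or batched (B, n, F_in); the output replaces F_in with
    F_out.  Batched subjects share one L~ and are filtered independently.
    """
    x = np.asarray(x, dtype=np.float64)
    batched = x.ndim == 3
    if not batched:
        x = x[None]
    if x.shape[2] != spec.f_in:
        raise ValueError(f"x has {x.shape[2]} features, filter expects {spec.f_in}")
    # (K, n, B*F_in) via the recurrence, then contract with theta.
    xt = np.moveaxis(x, 1, 0)  # (n, B, F_in)
    basis = cheb_basis_apply(scaled, xt, spec.order)  # (K, n, B, F_in)
    y = np.einsum("knbf,fgk->bng", basis, spec.theta, optimize=True)
    if spec.bias is not None:
        y = y + spec.bias
    return y if batched else y[0]


def spectral_oracle(x: np.ndarray, lap: Laplacian, spec: ChebFilterSpec,
                    return_transforms: bool = False):
    """Dense spectral-domain reference: filter via the graph Fourier transform.

    Eigendecomposes L = U diag(lambda) U^T, evaluates the scalar Chebyshev
    polynomial g(lambda~) on the scaled eigenvalues, and returns
    U g(Lambda~) U^T x per (input, output) channel pair.  Intended as an
    independent test oracle only; refuses graphs above a small size bound.
    With ``return_transforms`` the forward transform U^T x and U are returned
    alongside.
    """
    n = lap.matrix.shape[0]
    if n > _ORACLE_MAX_N:
        raise ValueError(f"spectral_oracle is a test-only dense path (n <= {_ORACLE_MAX_N})")
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] != n or x.shape[1] != spec.f_in:
        raise ValueError("x must be (n, F_in)")
    dense = lap.matrix.toarray()
    evals, u = np.linalg.eigh(dense)
    lmax = lap.lambda_max if lap.matrix.nnz else 2.0
    lam_scaled = 2.0 * evals / lmax - 1.0

    # scalar Chebyshev polynomials of the scaled eigenvalues, shape (K, n)
    tk = np.empty((spec.order, n))
    tk[0] = 1.0
    if spec.order > 1:
        tk[1] = lam_scaled
    for k in range(2, spec.order):
        tk[k] = 2.0 * lam_scaled * tk[k - 1] - tk[k - 2]

    x_hat = u.T @ x  # graph Fourier transform
    # response per output channel: g_fg(lambda) = sum_k theta[f,g,k] tk[k]
    y = np.empty((n, spec.f_out))
    for g in range(spec.f_out):
        acc = np.zeros(n)
        for f in range(spec.f_in):
            gain = spec.theta[f, g] @ tk  # (n,) spectral response
            acc += u @ (gain * x_hat[:, f])
        y[:, g] = acc
    if spec.bias is not None:
        y = y + spec.bias
    if return_transforms:
        return y, x_hat, u
    return y
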