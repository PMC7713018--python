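"""Gauss–Hermite rules and adaptive-centering state for random-effect integrals.

Marginal likelihoods integrate a conditional density against a Gaussian
random-effect density.  The integrals are evaluated with tensor-product
Gauss–Hermite quadrature, *adaptively* recentered per subject: nodes are
placed at the mode of the log-integrand and scaled by the inverse curvature
there, i.e. for subject i

    ∫ g(b) db ≈ 2^{d/2} |C_i| Σ_q w_q exp(‖u_q‖²) g(m_i + √2 C_i u_q),

with C_i C_i' = (−H_i)⁻¹ the inverse negative Hessian at the mode m_i.
The mode search itself lives with the likelihood code (it needs model
internals); this module provides the rules and the per-subject centering
container.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np


@dataclass(frozen=True)
class QuadratureRule:
    """Tensor-product Gauss–Hermite rule for weight exp(−‖u‖²) in d dims.

    ``logw`` already includes the exp(‖u_q‖²) reweighting used by the
    adaptive transform, so an integral of g against Lebesgue measure is
    ``2^{d/2} |C| Σ_q exp(logw_q) g(m + √2 C u_q)``.
    """

    Q: int
    dim: int
    u: np.ndarray     # (M, d) node coordinates
    logw: np.ndarray  # (M,) log w_q + ‖u_q‖²

    @property
    def n_nodes(self) -> int:
        return self.u.shape[0]


def gauss_hermite(Q: int):
    """1-D Gauss–Hermite nodes/weights (physicists' weight exp(−x²))."""
    return np.polynomial.hermite.hermgauss(Q)


def tensor_rule(Q: int, dim: int) -> QuadratureRule:
    x, w = gauss_hermite(Q)
    logw1 = np.log(w)
    if dim == 1:
        u = x[:, None]
        logw = logw1 + x ** 2
    else:
        grids = list(product(range(Q), repeat=dim))
        u = np.array([[x[i] for i in g] for g in grids])
        logw = np.array([sum(logw1[i] for i in g) for g in grids])
        logw = logw + np.sum(u ** 2, axis=1)
    return QuadratureRule(Q=Q, dim=dim, u=u, logw=logw)


@dataclass
class Centering:
    """Per-subject adaptive centering: modes, scale factors and log-dets."""

    m: np.ndarray        # (N, d) integrand modes
    C: np.ndarray        # (N, d, d) with C C' = (−H)⁻¹ at the mode
    logdetC: np.ndarray  # (N,)
    adaptive: bool = True

    def nodes(self, rule: QuadratureRule) -> np.ndarray:
        """Transformed nodes b = m_i + √2 C_i u_q, shape (N, M, d)."""
        return self.m[:, None, :] + np.sqrt(2.0) * np.matmul(
            rule.u[None, :, :], np.transpose(self.C, (0, 2, 1)))


def whitening_from_cov(D: np.ndarray, n: int) -> Centering:
    """Non-adaptive centering at 0 scaled by the prior covariance D."""
    L = np.linalg.cholesky(D)
    C = np.broadcast_to(L, (n,) + L.shape).copy()
    logdet = np.full(n, np.log(np.diag(L)).sum())
    return Centering(m=np.zeros((n, D.shape[0])), C=C, logdetC=logdet,
                     adaptive=False)
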