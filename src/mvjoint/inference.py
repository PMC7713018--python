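"""Hypothesis tests and human-readable summaries of combined fits."""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import EstimationError
from .estimation import CombinedFit


def wald_joint_association(fit: CombinedFit, L=None):
    """Multivariate Wald test of H0: Lθ = 0 on the association parameters.

    W² = (Lθ̂)' (L Cov(θ̂) L')⁻¹ (Lθ̂) ~ χ²_rank(L).  With L the identity this
    tests the joint null of no longitudinal–survival association.  Returns
    (W², df, p).
    """
    theta, cov, _ = fit.block("theta")
    return wald_test(theta, cov, L)


def wald_test(theta, cov, L=None):
    theta = np.atleast_1d(np.asarray(theta, float))
    cov = np.atleast_2d(np.asarray(cov, float))
    L = np.eye(len(theta)) if L is None else np.atleast_2d(np.asarray(L, float))
    df = np.linalg.matrix_rank(L)
    if df < L.shape[0]:
        raise EstimationError("L must have full row rank")
    mid = L @ cov @ L.T
    try:
        sol = np.linalg.solve(mid, L @ theta)
    except np.linalg.LinAlgError:
        raise EstimationError("L Cov L' is singular") from None
    w2 = float((L @ theta) @ sol)
    return w2, int(df), float(stats.chi2.sf(w2, df))


def effect_multiplier(coef: float):
    """Multiplicative survival-time factor e^coef and its complement 1−e^coef.

    On the accelerated scale a coefficient of −0.9204 means survival times
    are multiplied by e^{−0.9204} ≈ 0.3984, i.e. about 60% shorter.
    """
    m = float(np.exp(coef))
    return m, 1.0 - m


def summarize(fit: CombinedFit) -> str:
    """Deterministic plain-text estimate(SE) table by submodel block."""
    blocks = (("Longitudinal", ("beta", "sigma", "d", "rho_within")),
              ("Survival", ("xi", "theta", "alpha")),
              ("Correlation", ("rho",)))
    width = max((len(l) for l in fit.labels), default=10) + 2
    out = [f"Combined joint model fit over responses: "
           f"{', '.join(map(str, fit.responses))}",
           f"pairs fitted: {fit.n_pairs}, converged: {fit.n_converged_pairs}"]
    for title, kinds in blocks:
        idx = [i for i, k in enumerate(fit.keys) if k[0] in kinds]
        if not idx:
            continue
        out.append(title)
        for i in idx:
            out.append(f"  {fit.labels[i]:<{width}}"
                       f"{fit.estimates[i]: .4f} ({fit.se[i]:.4f})"
                       f"   z={fit.z[i]: .3f}  p={fit.p[i]:.4f}")
    if fit.keys and any(k[0] == "rho" for k in fit.keys):
        out.append("Random-intercept correlation matrix")
        for row in fit.corr_matrix:
            out.append("  " + "  ".join(f"{v: .4f}" for v in row))
    for note in fit.notes:
        out.append(f"note: {note}")
    return "\n".join(out) + "\n"
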