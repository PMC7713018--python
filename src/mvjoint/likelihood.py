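"""Conditional and marginal log-likelihoods of the joint model.

The joint model couples, for each response ℓ, a Gaussian linear mixed
submodel

    y_ℓij = x'_1ij β_ℓ + z'_1ij b_ℓi + ε_ℓij,   ε ~ N(0, σ_ℓ²),

with a Weibull (shape α_ℓ; exponential when α_ℓ = 1) submodel whose
log-hazard-scale linear predictor is η_ℓi = x'_2i ξ_ℓ + θ'_ℓ b_ℓi, so that
the conditional survival density is

    f(t|b) = [α t^{α−1} e^η]^δ exp(−t^α e^η).

The random effects b_i = (b_1i, …) are multivariate normal with covariance
D; marginal likelihoods integrate them out with adaptive tensor-product
Gauss–Hermite quadrature.  A plain Monte-Carlo integrator is provided as an
independent oracle for tests.

Implementation note: per-subject longitudinal data enter only through the
sufficient statistics (y'y, X'y, X'X, Z'y, Z'X, Z'Z), which makes one
likelihood evaluation a handful of dense numpy contractions over
(subject × node) grids; all parameter derivatives are analytic.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.special import logsumexp

from .data_io import JointDataset, ModelSpec, build_design, resolve_response
from .errors import DomainError, UnsupportedDimensionError
from .parameters import ParameterVector, ParamSchema, ResponseParams
from .quadrature import Centering, QuadratureRule, tensor_rule, whitening_from_cov

logger = logging.getLogger(__name__)

LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# elementary densities

def longitudinal_loglik(y, X, Z, beta, b, sigma) -> float:
    """Log-density of y ~ N(Xβ + Zb, σ²I) for one subject."""
    if not sigma > 0:
        raise DomainError(f"sigma must be > 0, got {sigma}")
    y = np.asarray(y, float)
    resid = y - np.asarray(X, float) @ np.asarray(beta, float) \
        - np.asarray(Z, float) @ np.atleast_1d(np.asarray(b, float))
    n = y.size
    return float(-0.5 * n * (LOG2PI + 2.0 * np.log(sigma))
                 - 0.5 * resid @ resid / sigma ** 2)


def survival_loglik(t, delta, alpha, eta):
    """Weibull log-likelihood contribution δ·log f(t) + (1−δ)·log S(t).

    Equals δ[log α + (α−1) log t + η] − t^α e^η; with α = 1 this is exactly
    the exponential model.  Vectorized over its arguments.
    """
    t = np.asarray(t, float)
    if np.any(t <= 0):
        raise DomainError("survival time must be > 0")
    if not np.all(np.asarray(alpha) > 0):
        raise DomainError("alpha must be > 0")
    delta = np.asarray(delta, float)
    eta = np.asarray(eta, float)
    logt = np.log(t)
    out = delta * (np.log(alpha) + (alpha - 1.0) * logt + eta) \
        - np.exp(alpha * logt + eta)
    return out if out.ndim else float(out)


def joint_conditional_loglik(y, X, Z, t, delta, x2, params: ResponseParams,
                             b, sign_convention: str = "log_hazard") -> float:
    """Joint conditional log-density f(y, t | b) for one subject, one response.

    The survival predictor is η = ±(x'_2 ξ + θ'b) with the sign set by the
    convention; the default implements the hazard-scale form literally.
    """
    b = np.atleast_1d(np.asarray(b, float))
    sign = 1.0 if sign_convention == "log_hazard" else -1.0
    eta = sign * (float(np.asarray(x2, float) @ params.xi) + float(params.theta @ b))
    return longitudinal_loglik(y, X, Z, params.beta, b, params.sigma) + \
        float(survival_loglik(t, delta, params.alpha, eta))


# ---------------------------------------------------------------------------
# compiled data blocks

class _CompiledResponse:
    """Sufficient statistics for one response over a common subject list."""

    def __init__(self, block, subject_index):
        pos = {s: i for i, s in enumerate(block.subjects)}
        order = [pos[s] for s in subject_index]
        X = [block.X[i] for i in order]
        Z = [block.Z[i] for i in order]
        y = [block.y[i] for i in order]
        self.response = block.response
        self.n = np.array([len(v) for v in y], float)
        self.yy = np.array([v @ v for v in y])
        self.Xy = np.stack([x.T @ v for x, v in zip(X, y)])
        self.XX = np.stack([x.T @ x for x in X])
        self.Zy = np.stack([z.T @ v for z, v in zip(Z, y)])
        self.ZX = np.stack([z.T @ x for z, x in zip(Z, X)])
        self.ZZ = np.stack([z.T @ z for z in Z])
        self.t = block.t[order]
        self.logt = np.log(self.t)
        self.delta = block.delta[order]
        self.x2 = block.x2[order]
        self.dz = Z[0].shape[1]
        self.p = X[0].shape[1]


class JointLikelihood:
    """Marginal log-likelihood machinery for a subset of responses.

    Handles one response (univariate joint model, random intercept or
    intercept+slope), a pair (the bivariate composite-likelihood factor) or
    all k ≤ 3 responses (the full multivariate model).
    """

    def __init__(self, dataset: JointDataset, spec: ModelSpec, responses=None):
        if responses is None:
            responses = spec.responses
        responses = tuple(resolve_response(spec, r) for r in responses)
        self.spec = spec
        self.responses = responses
        blocks = [build_design(dataset, spec, r) for r in responses]
        sets = [set(b.subjects) for b in blocks]
        self.subjects = tuple(s for s in dataset.subjects
                              if all(s in ss for ss in sets))
        dropped = dataset.n_subjects - len(self.subjects)
        if dropped:
            logger.info("model over %s: %d subjects excluded (missing a response)",
                        responses, dropped)
        self.blocks = [_CompiledResponse(b, self.subjects) for b in blocks]
        self.dims = tuple(b.dz for b in self.blocks)
        offs = np.concatenate([[0], np.cumsum(self.dims)])
        self.slices = [slice(int(offs[i]), int(offs[i + 1]))
                       for i in range(len(self.blocks))]
        self.dtot = int(offs[-1])
        if self.dtot > 3:
            raise UnsupportedDimensionError(
                f"tensor quadrature supports at most 3 random-effect "
                f"dimensions, got {self.dtot}; use the pairwise route")
        self.rule = tensor_rule(spec.quad_nodes, self.dtot)
        self.sign = 1.0 if spec.sign_convention == "log_hazard" else -1.0
        self.N = len(self.subjects)

    # -- parameter-dependent per-subject quantities -------------------------

    def _prep(self, pv: ParameterVector):
        pv.validate()
        D = pv.subset(self.responses).D()
        try:
            L = np.linalg.cholesky(D)
        except np.linalg.LinAlgError:
            raise DomainError("random-effect covariance not positive definite") \
                from None
        prep = {"D": D, "Dinv": np.linalg.inv(D),
                "logdetD": 2.0 * np.log(np.diag(L)).sum(), "per": []}
        for blk in self.blocks:
            p = pv.responses[blk.response]
            beta, xi = p.beta, p.xi
            c = blk.yy - 2.0 * blk.Xy @ beta + (blk.XX @ beta) @ beta
            S = blk.Zy - np.einsum("ndp,p->nd", blk.ZX, beta)
            lam = blk.x2 @ xi
            prep["per"].append({
                "p": p, "c": c, "S": S, "lam": lam,
                "alogt": p.alpha * blk.logt,
            })
        return prep

    def _log_integrand(self, prep, B, parts=False):
        """Log joint conditional density × RE prior at nodes B (N, M, d)."""
        # small random-effect dimensions: explicit loops over d beat einsum
        total = 0.0
        per_parts = []
        for i, (blk, pr) in enumerate(zip(self.blocks, prep["per"])):
            p = pr["p"]
            sl = self.slices[i]
            dz = self.dims[i]
            b = B[:, :, sl]
            Qq = np.broadcast_to(pr["c"][:, None], b.shape[:2]).copy()
            theta_b = 0.0
            for a in range(dz):
                ba = b[:, :, a]
                Qq -= 2.0 * ba * pr["S"][:, a][:, None]
                theta_b = theta_b + p.theta[a] * ba
                for e in range(dz):
                    Qq += blk.ZZ[:, a, e][:, None] * ba * b[:, :, e]
            ll_long = (-0.5 * blk.n * (LOG2PI + 2.0 * np.log(p.sigma)))[:, None] \
                - Qq / (2.0 * p.sigma ** 2)
            eta = self.sign * (pr["lam"][:, None] + theta_b)
            cum = np.exp(eta + pr["alogt"][:, None])
            ll_surv = blk.delta[:, None] * (
                np.log(p.alpha) + (p.alpha - 1.0) * blk.logt[:, None] + eta) - cum
            total = total + ll_long + ll_surv
            if parts:
                per_parts.append({"Qq": Qq, "A": blk.delta[:, None] - cum,
                                  "cum": cum, "b": b})
        Dinv = prep["Dinv"]
        Ainv = B @ Dinv  # batched matmul: D⁻¹ b per node
        quad = 0.0
        for a in range(self.dtot):
            quad = quad + Ainv[:, :, a] * B[:, :, a]
        total = total + (-0.5 * self.dtot * LOG2PI
                         - 0.5 * prep["logdetD"] - 0.5 * quad)
        if parts:
            return total, per_parts, Ainv
        return total

    # -- adaptive centering --------------------------------------------------

    def _mode_grad_hess(self, prep, b):
        """Gradient and Hessian of the log-integrand in b, shapes (N,d), (N,d,d)."""
        N, d = b.shape
        g = -(b @ prep["Dinv"])
        H = -np.broadcast_to(prep["Dinv"], (N, d, d)).copy()
        for i, (blk, pr) in enumerate(zip(self.blocks, prep["per"])):
            p = pr["p"]
            sl = self.slices[i]
            bl = b[:, sl]
            eta = self.sign * (pr["lam"] + bl @ p.theta)
            cum = np.exp(eta + pr["alogt"])
            g[:, sl] += (pr["S"] - (bl[:, None, :] @ blk.ZZ)[:, 0, :]) \
                / p.sigma ** 2 \
                + self.sign * (blk.delta - cum)[:, None] * p.theta[None, :]
            H[:, sl, sl] += -blk.ZZ / p.sigma ** 2 \
                - cum[:, None, None] * np.outer(p.theta, p.theta)
        return g, H

    def _logg_scalar(self, prep, b):
        return self._log_integrand(prep, b[:, None, :])[:, 0]

    def centering(self, pv: ParameterVector, warm: Centering | None = None
                  ) -> Centering:
        """Per-subject Newton search for the integrand mode and curvature.

        Falls back to non-adaptive (prior-whitened) centering for subjects
        whose mode search fails, with a logged warning.
        """
        prep = self._prep(pv)
        b = warm.m.copy() if warm is not None and warm.adaptive \
            else np.zeros((self.N, self.dtot))
        f = self._logg_scalar(prep, b)
        converged = np.zeros(self.N, bool)
        for _ in range(self.spec.mode_max_iter):
            g, H = self._mode_grad_hess(prep, b)
            converged = np.abs(g).max(axis=1) < self.spec.mode_tol
            if converged.all():
                break
            step = np.linalg.solve(-H, g[:, :, None])[:, :, 0]
            scale = np.ones(self.N)
            for _ in range(12):  # backtracking: log-integrand is concave
                cand = b + scale[:, None] * step
                fc = self._logg_scalar(prep, cand)
                bad = (fc < f - 1e-12) & ~converged
                if not bad.any():
                    break
                scale[bad] *= 0.5
            move = ~converged
            b[move] = cand[move]
            f[move] = fc[move]
        g, H = self._mode_grad_hess(prep, b)
        converged = np.abs(g).max(axis=1) < max(self.spec.mode_tol, 1e-6)
        A = -H
        try:
            L = np.linalg.cholesky(A)
            ok = converged
        except np.linalg.LinAlgError:
            ok = np.zeros(self.N, bool)
            L = np.broadcast_to(np.eye(self.dtot), A.shape).copy()
        C = np.transpose(
            np.linalg.solve(L, np.broadcast_to(np.eye(self.dtot),
                                               (self.N, self.dtot, self.dtot))),
            (0, 2, 1))
        logdetC = -np.log(np.einsum("ndd->nd", L)).sum(axis=1)
        if not ok.all():
            n_bad = int((~ok).sum())
            logger.warning("mode search failed for %d subjects; using "
                           "non-adaptive centering there", n_bad)
            fb = whitening_from_cov(prep["D"], self.N)
            bad = ~ok
            b[bad] = 0.0
            C[bad] = fb.C[bad]
            logdetC[bad] = fb.logdetC[bad]
        return Centering(m=b, C=C, logdetC=logdetC, adaptive=True)

    # -- marginal log-likelihood and analytic score -------------------------

    def loglik_by_subject(self, pv: ParameterVector,
                          centering: Centering | None = None,
                          rule: QuadratureRule | None = None) -> np.ndarray:
        rule = rule or self.rule
        if centering is None:
            centering = self.centering(pv)
        prep = self._prep(pv)
        B = centering.nodes(rule)
        logg = self._log_integrand(prep, B)
        return (0.5 * self.dtot * np.log(2.0) + centering.logdetC
                + logsumexp(rule.logw[None, :] + logg, axis=1))

    def loglik(self, pv, centering=None, rule=None) -> float:
        return float(self.loglik_by_subject(pv, centering, rule).sum())

    def loglik_and_score(self, schema: ParamSchema, pv: ParameterVector,
                         centering: Centering):
        """Total log-likelihood, natural-scale gradient, per-subject scores.

        The centering is treated as fixed (refresh happens in an outer loop),
        which makes objective and gradient exactly consistent.
        """
        prep = self._prep(pv)
        B = centering.nodes(self.rule)
        logg, parts, Ainv = self._log_integrand(prep, B, parts=True)
        lw = self.rule.logw[None, :] + logg
        mx = lw.max(axis=1, keepdims=True)
        w = np.exp(lw - mx)
        sw = w.sum(axis=1)
        ll = float((0.5 * self.dtot * np.log(2.0) + centering.logdetC
                    + np.log(sw) + mx[:, 0]).sum())
        P = w / sw[:, None]  # posterior node weights, (N, M)

        scores = {}
        for i, (blk, pr, part) in enumerate(
                zip(self.blocks, prep["per"], parts)):
            p, r = pr["p"], blk.response
            b, A = part["b"], part["A"]
            dz = self.dims[i]
            # beta: (1/σ²)(X'y − X'Xβ − (Z'X)'b), posterior-averaged over nodes
            base = blk.Xy - (blk.XX @ p.beta)
            pb = [(P * b[:, :, a]).sum(axis=1) for a in range(dz)]
            zxb = 0.0
            for a in range(dz):
                zxb = zxb + blk.ZX[:, a, :] * pb[a][:, None]
            scores[("beta", r)] = (base - zxb) / p.sigma ** 2
            scores[("sigma", r)] = (P * part["Qq"]).sum(axis=1) / p.sigma ** 3 \
                - blk.n / p.sigma
            PA = P * A
            pa = PA.sum(axis=1)
            scores[("xi", r)] = self.sign * blk.x2 * pa[:, None]
            scores[("theta", r)] = self.sign * np.stack(
                [(PA * b[:, :, a]).sum(axis=1) for a in range(dz)], axis=1)
            scores[("alpha", r)] = blk.delta / p.alpha + blk.logt * (
                blk.delta - (P * part["cum"]).sum(axis=1))
        # random-effect covariance parameters, via A = D⁻¹ b per node
        dvec = np.concatenate([pv.responses[r].d for r in self.responses])
        dscore = np.stack(
            [(P * Ainv[:, :, a] * B[:, :, a]).sum(axis=1) for a in
             range(self.dtot)], axis=1)
        dscore = (dscore - 1.0) / dvec[None, :]
        Dinv = prep["Dinv"]
        rho_scores = {}
        for a in range(self.dtot):
            for bq in range(a + 1, self.dtot):
                val = dvec[a] * dvec[bq] * (
                    (P * Ainv[:, :, a] * Ainv[:, :, bq]).sum(axis=1)
                    - Dinv[a, bq])
                rho_scores[(a, bq)] = val

        # map to schema order
        S = np.zeros((self.N, schema.n))
        resp_re_offset = {}
        off = 0
        for i, r in enumerate(self.responses):
            resp_re_offset[r] = off
            off += self.dims[i]
        for j, key in enumerate(schema.keys):
            kind = key[0]
            if kind == "beta":
                S[:, j] = scores[("beta", key[1])][:, key[2]]
            elif kind == "sigma":
                S[:, j] = scores[("sigma", key[1])]
            elif kind == "xi":
                S[:, j] = scores[("xi", key[1])][:, key[2]]
            elif kind == "theta":
                S[:, j] = scores[("theta", key[1])][:, key[2]]
            elif kind == "alpha":
                S[:, j] = scores[("alpha", key[1])]
            elif kind == "d":
                S[:, j] = dscore[:, resp_re_offset[key[1]] + key[2]]
            elif kind == "rho_within":
                o = resp_re_offset[key[1]]
                S[:, j] = rho_scores[(o, o + 1)]
            elif kind == "rho":
                S[:, j] = rho_scores[(resp_re_offset[key[1]],
                                      resp_re_offset[key[2]])]
            else:  # pragma: no cover
                raise KeyError(key)
        return ll, S.sum(axis=0), S


# ---------------------------------------------------------------------------
# public marginal-likelihood entry points

def pair_marginal_loglik(dataset, r, s, pv: ParameterVector, spec: ModelSpec,
                         centering: Centering | None = None) -> float:
    """Bivariate composite-likelihood factor for responses (r, s).

    Each factor of the pair carries its own survival contribution (the
    composite construction); in shared survival mode both factors contain
    the same observed time.
    """
    r, s = resolve_response(spec, r), resolve_response(spec, s)
    lik = JointLikelihood(dataset, spec, (r, s))
    return lik.loglik(pv.subset((r, s)), centering)


def full_marginal_loglik(dataset, pv: ParameterVector, spec: ModelSpec) -> float:
    """Full multivariate marginal log-likelihood (k ≤ 3 responses)."""
    lik = JointLikelihood(dataset, spec)  # raises UnsupportedDimensionError if d > 3
    return lik.loglik(pv.subset(spec.responses))


def mc_marginal_loglik(dataset, pv: ParameterVector, spec: ModelSpec,
                       n_draws: int = 10_000, seed: int = 0,
                       responses=None):
    """Plain Monte-Carlo estimate of the marginal log-likelihood (test oracle).

    Samples the random effects from their Gaussian prior, averages the
    conditional density per subject, and reports a delta-method standard
    error for the summed log-likelihood.
    """
    if n_draws < 1000:
        raise DomainError("n_draws must be >= 1000 for a usable oracle")
    lik = JointLikelihood(dataset, spec, responses)
    pv_sub = pv.subset(lik.responses)
    prep = lik._prep(pv_sub)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(prep["D"])
    B = rng.standard_normal((lik.N, n_draws, lik.dtot)) @ L.T
    logg = lik._log_integrand(prep, B)
    # remove the prior factor: sampling measure is the prior itself
    quad = np.einsum("nmd,de,nme->nm", B, prep["Dinv"], B)
    logcond = logg + 0.5 * lik.dtot * LOG2PI + 0.5 * prep["logdetD"] + 0.5 * quad
    mx = logcond.max(axis=1, keepdims=True)
    w = np.exp(logcond - mx)
    mean_w = w.mean(axis=1)
    ll = float((np.log(mean_w) + mx[:, 0]).sum())
    se_i = w.std(axis=1, ddof=1) / np.sqrt(n_draws) / mean_w
    return ll, float(np.sqrt((se_i ** 2).sum()))
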