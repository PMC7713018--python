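"""Maximum-likelihood fitting: single joint models, bivariate pairs, and the
pairwise composite-likelihood estimator with sandwich covariance.

The pairwise route fits all P = k(k−1)/2 bivariate joint models, averages
the k−1 copies of every response-specific parameter, and combines the
per-pair observed-information matrices and per-subject scores into an
asymptotic covariance for the averaged estimates:

    Cov(Λ̂′) = J⁻¹ K J⁻¹,     Cov(Λ̂) = A Cov(Λ̂′) A′,

with J block-diagonal in the per-pair observed information, K the empirical
cross-product (over subjects) of the concatenated per-pair scores — which
captures between-pair dependence because pairs share subjects — and A the
averaging matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import optimize, stats

from .data_io import JointDataset, ModelSpec, build_design, resolve_response
from .errors import EstimationError, InitializationError
from .likelihood import JointLikelihood
from .parameters import ParameterVector, ParamSchema, ResponseParams, key_label

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# results containers

@dataclass(eq=False)
class PairFit:
    """One maximized joint model (univariate, bivariate pair, or full)."""

    responses: tuple
    keys: tuple                  # parameter keys, natural-scale order
    labels: tuple
    pv: ParameterVector          # estimates, structured
    estimates: np.ndarray        # natural-scale vector aligned with keys
    info: np.ndarray             # observed information (natural scale)
    scores: np.ndarray           # (N, P) per-subject scores at the optimum
    subjects: tuple
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    flat_directions: tuple = ()  # labels with (numerically) zero curvature

    @property
    def pair(self):
        return self.responses


@dataclass(eq=False)
class CombinedFit:
    """Averaged pairwise estimates with combined sandwich covariance."""

    responses: tuple
    keys: tuple
    labels: tuple
    estimates: np.ndarray
    cov: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    n_copies: np.ndarray
    corr_matrix: np.ndarray      # k×k random-intercept correlations (NaN if lost)
    pair_fits: list
    n_pairs: int
    n_converged_pairs: int
    converged: bool
    notes: tuple = ()

    def __getitem__(self, key):
        return float(self.estimates[self.keys.index(tuple(key))])

    def block(self, kind: str):
        """Estimates, covariance submatrix and labels for one parameter kind."""
        idx = [i for i, k in enumerate(self.keys) if k[0] == kind]
        return (self.estimates[idx], self.cov[np.ix_(idx, idx)],
                tuple(self.labels[i] for i in idx))

    def as_table(self):
        import pandas as pd
        return pd.DataFrame({
            "parameter": self.labels, "estimate": self.estimates,
            "se": self.se, "z": self.z, "p": self.p,
            "n_pairs": self.n_copies,
        })


# ---------------------------------------------------------------------------
# initial values

def _moment_lmm(block):
    """Moment-based random-intercept fit: OLS β, variance decomposition."""
    X = np.vstack(block.X)
    y = np.concatenate(block.y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n_i = np.array([len(v) for v in block.y])
    idx = np.repeat(np.arange(len(n_i)), n_i)
    mbar = np.bincount(idx, weights=resid) / n_i
    within = resid - mbar[idx]
    denom = max(int((n_i - 1).sum()), 1)
    sigma2 = float(within @ within) / denom
    between = float(np.var(mbar, ddof=1)) - sigma2 * float(np.mean(1.0 / n_i))
    d2 = max(between, 0.05 * sigma2)
    return beta, np.sqrt(sigma2), np.sqrt(d2), mbar


def fit_weibull_regression(t, delta, X, alpha_fixed=False, sign=1.0,
                           gtol=1e-8):
    """MLE of a plain Weibull regression with η = ±Xcoef (no random effects)."""
    t = np.asarray(t, float)
    delta = np.asarray(delta, float)
    X = np.asarray(X, float)
    logt = np.log(t)

    def negll(par):
        coef, la = par[:-1], par[-1]
        alpha = 1.0 if alpha_fixed else np.exp(la)
        eta = sign * (X @ coef)
        cum = np.exp(alpha * logt + eta)
        ll = np.sum(delta * (np.log(alpha) + (alpha - 1.0) * logt + eta) - cum)
        g_coef = sign * X.T @ (delta - cum)
        g_la = 0.0 if alpha_fixed else float(
            np.sum(delta * (1.0 + alpha * logt) - alpha * logt * cum))
        return -ll, -np.concatenate([g_coef, [g_la]])

    x0 = np.zeros(X.shape[1] + 1)
    with np.errstate(over="ignore", divide="ignore"):
        x0[0] = sign * np.log(max(delta.sum(), 0.5) / t.sum())
    res = optimize.minimize(negll, x0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 500, "gtol": gtol,
                                     "ftol": 1e-14})
    coef = res.x[:-1]
    alpha = 1.0 if alpha_fixed else float(np.exp(res.x[-1]))
    return coef, alpha, bool(res.success), -float(res.fun)


def initialize_params(dataset: JointDataset, spec: ModelSpec,
                      responses=None) -> ParameterVector:
    """Derive starting values.

    β, σ, d from per-response moment random-intercept fits; ξ, α from a
    survival-only Weibull regression; θ = 0; ρ_rs from the correlation of
    per-subject mean residuals, clipped to (−0.9, 0.9).
    """
    if responses is None:
        responses = spec.responses
    responses = tuple(resolve_response(spec, r) for r in responses)
    per, mbars, subj_sets = {}, {}, {}
    sign = 1.0 if spec.sign_convention == "log_hazard" else -1.0
    for r in responses:
        block = build_design(dataset, spec, r)
        if len(block.subjects) < 2 or np.ptp(np.concatenate(block.y)) == 0:
            raise InitializationError(
                f"response {r}: degenerate data (too few subjects or "
                f"constant response)")
        beta, sigma, d, mbar = _moment_lmm(block)
        xi, alpha, ok, _ = fit_weibull_regression(
            block.t, block.delta, block.x2, alpha_fixed=spec.alpha_fixed,
            sign=sign)
        if not ok:
            logger.warning("response %s: survival-only init fit did not "
                           "fully converge", r)
        slope = spec.random_effects == "intercept_slope"
        if slope:
            ints, slops = _per_subject_lines(block)
            d0 = max(np.std(ints, ddof=1), 0.05 * sigma)
            d1 = max(np.std(slops, ddof=1), 1e-2)
            rho_w = float(np.clip(np.corrcoef(ints, slops)[0, 1], -0.9, 0.9)) \
                if len(ints) > 2 else 0.0
            per[r] = ResponseParams(beta=beta, sigma=sigma, d=[d0, d1],
                                    xi=xi, theta=[0.0, 0.0], alpha=alpha,
                                    rho_within=rho_w)
        else:
            per[r] = ResponseParams(beta=beta, sigma=sigma, d=[d], xi=xi,
                                    theta=[0.0], alpha=alpha)
        mbars[r] = dict(zip(block.subjects, mbar))
    rho = {}
    for r, s in combinations(responses, 2):
        common = [u for u in mbars[r] if u in mbars[s]]
        a = np.array([mbars[r][u] for u in common])
        b = np.array([mbars[s][u] for u in common])
        raw = float(np.corrcoef(a, b)[0, 1]) if len(common) > 2 else 0.0
        rho[(r, s)] = float(np.clip(raw, -0.9, 0.9))
    return ParameterVector({r: per[r] for r in responses}, rho)


def _per_subject_lines(block):
    ints, slops = [], []
    X = np.vstack(block.X)
    y = np.concatenate(block.y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    for Xi, Zi, yi in zip(block.X, block.Z, block.y):
        if len(yi) >= 2 and np.ptp(Zi[:, 1]) > 0:
            coef, *_ = np.linalg.lstsq(Zi, yi - Xi @ beta, rcond=None)
            ints.append(coef[0])
            slops.append(coef[1])
    return np.array(ints), np.array(slops)


# ---------------------------------------------------------------------------
# core fitter

_PENALTY = 1e10


def _fit_model(dataset, spec, responses, init=None, fixed=None,
               compute_info=True) -> PairFit:
    lik = JointLikelihood(dataset, spec, responses)
    responses = lik.responses
    pv0 = (init.subset(responses) if init is not None
           else initialize_params(dataset, spec, responses))
    schema = ParamSchema.for_model(pv0, alpha_fixed=spec.alpha_fixed,
                                   fixed=fixed)
    schema.apply_fixed(pv0)
    nat = schema.pack(pv0)
    z = schema.to_unconstrained(nat)
    centering = lik.centering(pv0)
    ll0 = lik.loglik(pv0, centering)
    if not np.isfinite(ll0):
        raise InitializationError(
            f"log-likelihood non-finite at initial values for {responses}")

    cell = [centering]

    def negll(zv, refresh=True):
        natv = schema.from_unconstrained(zv)
        pv = schema.unpack(natv, pv0)
        try:
            if refresh:
                cell[0] = lik.centering(pv, warm=cell[0])
            ll, g, _ = lik.loglik_and_score(schema, pv, cell[0])
        except (np.linalg.LinAlgError, ValueError):
            return _PENALTY, np.zeros_like(zv)
        if not np.isfinite(ll):
            return _PENALTY, np.zeros_like(zv)
        return -ll, -(g * schema.dnat_dz(natv))

    # main pass: quadrature centering tracks the parameters (self-adaptive)
    res = optimize.minimize(negll, z, jac=True, method="BFGS",
                            options={"maxiter": spec.max_iter,
                                     "gtol": spec.gtol})
    z = res.x
    n_iter = int(res.nit)
    # polish with centering frozen at the optimum: objective and gradient
    # are then exactly consistent, so the final gradient norm is meaningful
    cell[0] = lik.centering(schema.unpack(schema.from_unconstrained(z), pv0),
                            warm=cell[0])
    res2 = optimize.minimize(lambda zv: negll(zv, refresh=False), z, jac=True,
                             method="BFGS",
                             options={"maxiter": 100, "gtol": spec.gtol})
    if -res2.fun >= -res.fun:
        z = res2.x
        n_iter += int(res2.nit)
    centering = lik.centering(schema.unpack(schema.from_unconstrained(z), pv0),
                              warm=cell[0])

    nat = schema.from_unconstrained(z)
    pv_hat = schema.unpack(nat, pv0)
    ll_final, grad, scores = lik.loglik_and_score(schema, pv_hat, centering)
    grad_z = grad * schema.dnat_dz(nat)
    grad_norm = float(np.abs(grad_z).max()) if schema.n else 0.0
    scale = 1.0 + abs(ll_final) / 1e4
    converged = bool(grad_norm < max(100 * spec.gtol * scale, 1e-3 * scale))

    if compute_info:
        info = _observed_information(lik, schema, pv_hat, nat, centering)
        flat = _flat_directions(info, schema.labels)
        if flat:
            logger.warning("model %s: flat likelihood directions detected: %s",
                           responses, flat)
    else:
        info = np.full((schema.n, schema.n), np.nan)
        flat = ()
    return PairFit(responses=responses, keys=schema.keys, labels=schema.labels,
                   pv=pv_hat, estimates=nat, info=info, scores=scores,
                   subjects=lik.subjects, loglik=float(ll_final),
                   converged=converged, n_iter=n_iter, grad_norm=grad_norm,
                   flat_directions=flat)


def _observed_information(lik, schema, pv_hat, nat, centering):
    """Central differences of the analytic natural-scale score."""
    P = schema.n
    J = np.zeros((P, P))
    for j in range(P):
        h = 1e-5 * max(1.0, abs(nat[j]))
        gg = []
        for sgn in (1.0, -1.0):
            natp = nat.copy()
            natp[j] += sgn * h
            pvp = schema.unpack(natp, pv_hat)
            _, g, _ = lik.loglik_and_score(schema, pvp, centering)
            gg.append(g)
        J[:, j] = -(gg[0] - gg[1]) / (2.0 * h)
    return 0.5 * (J + J.T)


def _flat_directions(info, labels, rel_tol=1e-8):
    if info.size == 0:
        return ()
    w, V = np.linalg.eigh(0.5 * (info + info.T))
    wmax = max(w.max(), 1e-300)
    flat = []
    for i in np.where(w < rel_tol * wmax)[0]:
        j = int(np.argmax(np.abs(V[:, i])))
        flat.append(labels[j])
    return tuple(flat)


def fit_pair(dataset, r, s, spec: ModelSpec, init: ParameterVector | None = None,
             fixed: dict | None = None, compute_info: bool = True) -> PairFit:
    """Maximize the bivariate composite-likelihood factor for responses (r, s).

    Non-convergence is recorded on the returned :class:`PairFit`, not raised.
    """
    r, s = resolve_response(spec, r), resolve_response(spec, s)
    if spec.responses.index(r) >= spec.responses.index(s):
        r, s = s, r
    return _fit_model(dataset, spec, (r, s), init=init, fixed=fixed,
                      compute_info=compute_info)


def fit_univariate_joint(dataset, response, spec: ModelSpec,
                         init: ParameterVector | None = None,
                         fixed: dict | None = None) -> CombinedFit:
    """Single-response joint model (random intercept, or intercept+slope)."""
    response = resolve_response(spec, response)
    fit = _fit_model(dataset, spec, (response,), init=init, fixed=fixed)
    return _combined_from_single(fit, (response,))


def n_pairs(k: int) -> int:
    """Number of bivariate models for k responses: P = k(k−1)/2."""
    return k * (k - 1) // 2


def all_pairs(spec: ModelSpec):
    return list(combinations(spec.responses, 2))


# ---------------------------------------------------------------------------
# pairwise loop, averaging and combined covariance

def pairwise_fit(dataset: JointDataset, spec: ModelSpec,
                 init: ParameterVector | None = None,
                 compute_cov: bool = True) -> CombinedFit:
    """Fit all P pairs, average duplicate estimates, combine covariances.

    Pairs are independent (their fitting order is irrelevant); a pair that
    fails to converge is excluded from every average with a logged warning.
    If a response-specific parameter loses all its copies the fit aborts
    with :class:`EstimationError`; a correlation whose single source pair
    failed is reported as NaN in the correlation matrix.
    """
    k = spec.k
    if k < 2:
        raise EstimationError("pairwise fitting requires k >= 2 responses")
    if init is None:
        init = initialize_params(dataset, spec)
    pair_fits = [fit_pair(dataset, r, s, spec, init=init,
                          compute_info=compute_cov)
                 for r, s in all_pairs(spec)]
    return combine_pairs(pair_fits, spec, compute_cov=compute_cov)


def combine_pairs(pair_fits, spec: ModelSpec,
                  compute_cov: bool = True) -> CombinedFit:
    good = [f for f in pair_fits if f.converged]
    bad = [f for f in pair_fits if not f.converged]
    for f in bad:
        logger.warning("pair %s did not converge; its estimates are excluded "
                       "from averaging", f.responses)
    if not good:
        raise EstimationError("no pair converged")

    # global key list in canonical order
    keys, copies = [], {}
    for r in spec.responses:
        tmpl = None
        for f in pair_fits:
            if r in f.responses:
                tmpl = f
                break
        for key in tmpl.keys:
            if key[0] != "rho" and key[1] == r:
                keys.append(key)
    for r, s in combinations(spec.responses, 2):
        keys.append(("rho", r, s))
    offsets, off = [], 0
    for f in good:
        offsets.append(off)
        off += len(f.keys)
    for key in keys:
        cps = []
        for f, o in zip(good, offsets):
            if key in f.keys:
                cps.append((f, o, f.keys.index(key)))
        copies[key] = cps
    lost_resp = [key_label(key) for key in keys
                 if not copies[key] and key[0] != "rho"]
    if lost_resp:
        raise EstimationError(
            f"parameters lost all converged copies: {lost_resp}")

    est_keys = [key for key in keys if copies[key]]
    A = np.zeros((len(est_keys), off))
    estimates = np.zeros(len(est_keys))
    n_copies = np.zeros(len(est_keys), int)
    for i, key in enumerate(est_keys):
        cps = copies[key]
        n_copies[i] = len(cps)
        for f, o, local in cps:
            A[i, o + local] = 1.0 / len(cps)
            estimates[i] += f.estimates[local] / len(cps)

    cov = (combine_covariance(good, A) if compute_cov
           else np.full((len(est_keys), len(est_keys)), np.nan))
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = estimates / se
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))

    corr = np.full((spec.k, spec.k), np.nan)
    np.fill_diagonal(corr, 1.0)
    est_map = dict(zip(map(tuple, est_keys), estimates))
    for a, r in enumerate(spec.responses):
        for b in range(a + 1, spec.k):
            s = spec.responses[b]
            v = est_map.get(("rho", r, s), np.nan)
            corr[a, b] = corr[b, a] = v
    notes = []
    if np.isnan(corr).any():
        notes.append("correlation matrix incomplete: source pair failed")
    else:
        w = np.linalg.eigvalsh(corr)
        if w.min() < -1e-10:
            notes.append("assembled correlation matrix is not positive "
                         "semidefinite (reported as is)")

    return CombinedFit(
        responses=spec.responses, keys=tuple(map(tuple, est_keys)),
        labels=tuple(key_label(key) for key in est_keys),
        estimates=estimates, cov=cov, se=se, z=zstat, p=pvals,
        n_copies=n_copies, corr_matrix=corr, pair_fits=list(pair_fits),
        n_pairs=len(pair_fits), n_converged_pairs=len(good),
        converged=not bad, notes=tuple(notes))


def combine_covariance(fits, A) -> np.ndarray:
    """Sandwich covariance A J⁻¹ K J⁻¹ A′ for stacked converged pair fits.

    J is block-diagonal in the per-pair observed information; K sums, over
    the union of subjects, the outer products of concatenated per-subject
    scores (zero-padded where a subject is absent from a pair).
    """
    sizes = [len(f.keys) for f in fits]
    off = np.concatenate([[0], np.cumsum(sizes)])
    P = int(off[-1])
    subjects = []
    seen = set()
    for f in fits:
        for s in f.subjects:
            if s not in seen:
                seen.add(s)
                subjects.append(s)
    pos = {s: i for i, s in enumerate(subjects)}
    S = np.zeros((len(subjects), P))
    Jinv = np.zeros((P, P))
    for f, o, sz in zip(fits, off, sizes):
        rows = [pos[s] for s in f.subjects]
        S[rows, o:o + sz] = f.scores
        try:
            Jinv[o:o + sz, o:o + sz] = np.linalg.inv(f.info)
        except np.linalg.LinAlgError:
            raise EstimationError(
                f"singular observed information for pair {f.responses}") \
                from None
    K = S.T @ S
    cov = A @ Jinv @ K @ Jinv @ A.T
    return 0.5 * (cov + cov.T)


def _combined_from_single(fit: PairFit, responses) -> CombinedFit:
    A = np.eye(len(fit.keys))
    cov = combine_covariance([fit], A)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = fit.estimates / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    responses = tuple(responses)
    corr = np.eye(len(responses))
    est_map = dict(zip(fit.keys, fit.estimates))
    for a, r in enumerate(responses):
        for b in range(a + 1, len(responses)):
            v = est_map.get(("rho", r, responses[b]), np.nan)
            corr[a, b] = corr[b, a] = v
    return CombinedFit(
        responses=tuple(responses), keys=fit.keys, labels=fit.labels,
        estimates=fit.estimates.copy(), cov=cov, se=se, z=z, p=p,
        n_copies=np.ones(len(fit.keys), int), corr_matrix=corr,
        pair_fits=[fit], n_pairs=1, n_converged_pairs=int(fit.converged),
        converged=fit.converged,
        notes=(("flat directions: " + ", ".join(fit.flat_directions),)
               if fit.flat_directions else ()))


# ---------------------------------------------------------------------------
# baseline-values-only Weibull comparator

@dataclass
class BaselineWeibullFit:
    """Plain Weibull survival fit using each subject's earliest longitudinal
    value as a fixed baseline covariate (no random effects, no integral)."""

    response: str
    coef_names: tuple
    coef: np.ndarray          # (intercept, covariates..., theta)
    alpha: float
    theta: float
    converged: bool
    inestimable: tuple = ()
    loglik: float = np.nan


def fit_baseline_weibull(dataset, response, spec: ModelSpec) -> BaselineWeibullFit:
    """Fit the comparator model μ = ξ0 + ξ'x + θ·y_baseline, Weibull(α, μ)."""
    response = resolve_response(spec, response)
    block = build_design(dataset, spec, response)
    y_base = []
    lon = dataset.longitudinal
    lon = lon.loc[lon["response"] == response]
    grouped = lon.sort_values("time").groupby("subject_id", sort=False)
    first = grouped.first()["value"]
    missing = [s for s in block.subjects if s not in first.index]
    if missing:
        raise EstimationError(
            f"subjects without a baseline observation for {response}: "
            f"{missing[:5]}")
    y_base = first.loc[list(block.subjects)].to_numpy(float)
    X = np.column_stack([block.x2, y_base])
    names = block.x2_names + (f"baseline_{response}",)
    bad = tuple(names[j] for j in range(1, X.shape[1])
                if np.ptp(X[:, j]) == 0.0)
    if bad:
        logger.warning("baseline Weibull fit for %s: constant covariates %s "
                       "are inestimable", response, bad)
        return BaselineWeibullFit(response=response, coef_names=names,
                                  coef=np.full(X.shape[1], np.nan),
                                  alpha=np.nan, theta=np.nan,
                                  converged=False, inestimable=bad)
    sign = 1.0 if spec.sign_convention == "log_hazard" else -1.0
    coef, alpha, ok, ll = fit_weibull_regression(
        block.t, block.delta, X, alpha_fixed=spec.alpha_fixed, sign=sign)
    return BaselineWeibullFit(response=response, coef_names=names, coef=coef,
                              alpha=alpha, theta=float(coef[-1]),
                              converged=ok, loglik=ll)
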