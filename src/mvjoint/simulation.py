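"""Synthetic-data generation and the Monte-Carlo replication study.

The generator draws from the multivariate joint model itself: correlated
random intercepts b_i ~ MVN(0, D); Gaussian trajectories

    y_ℓij = β_ℓ0 + β_ℓ1·time_ij + β_ℓ2·male_i + b_ℓi + ε_ℓij

observed at every visit time (trajectories are not truncated at the event);
and event times from the Weibull survival function S(t) = exp(−e^η t^α)
with η_ℓi = ξ_ℓ0 + ξ_ℓ1·male_i + θ_ℓ·b_ℓi, drawn by inversion

    T = (−log U · e^{−η})^{1/α}.

The default design is the package's reference study: k = 3 responses,
N = 1000 subjects, visits at 0..6 years, β₁ = (3.7, −1, 0.5),
β₂ = (4, 1, −0.5), β₃ = (5, 1, −0.5), ξ = (5, −0.5), θ = (−0.8, 0.6, −0.5),
α = 0.5, σ = (0.8, 1, 1), d = (0.7, 0.5, 0.5), ρ₁₂ = −0.5, ρ₁₃ = 0.6,
ρ₂₃ = 0.3, no censoring (δ = 1 everywhere), 1000 replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_io import JointDataset, ModelSpec, SHARED
from .errors import ConfigError, EstimationError
from .estimation import (fit_baseline_weibull, initialize_params,
                         pairwise_fit, _fit_model)
from .parameters import ParameterVector, ParamSchema, ResponseParams, key_label

logger = logging.getLogger(__name__)

_DEFAULT_BETA = {"y1": (3.7, -1.0, 0.5), "y2": (4.0, 1.0, -0.5),
                 "y3": (5.0, 1.0, -0.5)}


@dataclass(frozen=True)
class SimulationDesign:
    """True parameter values and sampling layout for the replication study."""

    n_subjects: int = 1000
    times: tuple = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    responses: tuple = ("y1", "y2", "y3")
    beta: dict = field(default_factory=lambda: dict(_DEFAULT_BETA))
    sigma: dict = field(default_factory=lambda: {"y1": 0.8, "y2": 1.0, "y3": 1.0})
    d: dict = field(default_factory=lambda: {"y1": 0.7, "y2": 0.5, "y3": 0.5})
    rho: dict = field(default_factory=lambda: {("y1", "y2"): -0.5,
                                               ("y1", "y3"): 0.6,
                                               ("y2", "y3"): 0.3})
    xi: tuple = (5.0, -0.5)
    theta: dict = field(default_factory=lambda: {"y1": -0.8, "y2": 0.6,
                                                 "y3": -0.5})
    alpha: float = 0.5
    male_prob: float = 0.5
    survival_time_mode: str = "per_response"
    censoring_time: float | None = None
    n_replicates: int = 1000
    base_seed: int = 0
    sign_convention: str = "log_hazard"
    quad_nodes: int = 9

    def __post_init__(self):
        for r in self.responses:
            for dic, what in ((self.beta, "beta"), (self.sigma, "sigma"),
                              (self.d, "d"), (self.theta, "theta")):
                if r not in dic:
                    raise ConfigError(f"design lacks {what} for response {r!r}")
        np.linalg.cholesky(self.true_params().D())  # PD check; raises if not

    @property
    def k(self) -> int:
        return len(self.responses)

    def true_params(self) -> ParameterVector:
        per = {r: ResponseParams(
            beta=np.asarray(self.beta[r], float), sigma=float(self.sigma[r]),
            d=[float(self.d[r])], xi=np.asarray(self.xi, float),
            theta=[float(self.theta[r])], alpha=float(self.alpha))
            for r in self.responses}
        rho = {k: float(v) for k, v in self.rho.items()}
        return ParameterVector(per, rho)

    def model_spec(self, **overrides) -> ModelSpec:
        kw = dict(
            responses=self.responses,
            fixed_effects={r: ("time", "male") for r in self.responses},
            survival_covariates=("male",),
            distribution="weibull",
            survival_time_mode=self.survival_time_mode,
            sign_convention=self.sign_convention,
            quad_nodes=self.quad_nodes,
        )
        kw.update(overrides)
        return ModelSpec(**kw)

    def with_(self, **kw) -> "SimulationDesign":
        return replace(self, **kw)


def simulate_dataset(design: SimulationDesign, seed: int,
                     return_latent: bool = False):
    """Draw one dataset from the joint model; reproducible from ``seed``."""
    rng = np.random.default_rng(seed)
    N, k = design.n_subjects, design.k
    pv = design.true_params()
    male = (rng.random(N) < design.male_prob).astype(float)
    L = np.linalg.cholesky(pv.D())
    b = rng.standard_normal((N, k)) @ L.T
    times = np.asarray(design.times, float)
    sign = 1.0 if design.sign_convention == "log_hazard" else -1.0

    long_rows = []
    surv_rows = []
    subj = np.arange(1, N + 1)
    for j, r in enumerate(design.responses):
        p = pv.responses[r]
        mean = (p.beta[0] + p.beta[1] * times[None, :]
                + (p.beta[2] * male)[:, None] + b[:, j][:, None])
        y = mean + p.sigma * rng.standard_normal((N, len(times)))
        long_rows.append(pd.DataFrame({
            "subject_id": np.repeat(subj, len(times)),
            "response": r,
            "time": np.tile(times, N),
            "value": y.ravel(),
            "male": np.repeat(male, len(times)),
        }))
        if design.survival_time_mode != SHARED:
            eta = sign * (p.xi[0] + p.xi[1] * male + p.theta[0] * b[:, j])
            E = rng.exponential(size=N)
            T = (E * np.exp(-eta)) ** (1.0 / p.alpha)
            t_obs, delta = _apply_censoring(T, design.censoring_time)
            surv_rows.append(pd.DataFrame({
                "subject_id": subj, "response": r, "time": t_obs,
                "event": delta, "male": male}))
    if design.survival_time_mode == SHARED:
        # one event time per subject, every association term in one hazard
        theta_vec = np.array([pv.responses[r].theta[0]
                              for r in design.responses])
        eta = sign * (pv.responses[design.responses[0]].xi[0]
                      + pv.responses[design.responses[0]].xi[1] * male
                      + b @ theta_vec)
        E = rng.exponential(size=N)
        T = (E * np.exp(-eta)) ** (1.0 / design.alpha)
        t_obs, delta = _apply_censoring(T, design.censoring_time)
        surv = pd.DataFrame({"subject_id": subj, "time": t_obs,
                             "event": delta, "male": male})
    else:
        surv = pd.concat(surv_rows, ignore_index=True)
    lon = pd.concat(long_rows, ignore_index=True)
    ds = JointDataset(lon, surv, design.responses,
                      survival_time_mode=design.survival_time_mode)
    if return_latent:
        return ds, {"b": b, "male": male}
    return ds


def _apply_censoring(T, c):
    if c is None:
        return T, np.ones_like(T, dtype=int)
    return np.minimum(T, c), (T <= c).astype(int)


# ---------------------------------------------------------------------------
# replication study

METHODS = ("pairwise", "full", "baseline_weibull")


def true_value_map(design: SimulationDesign) -> dict:
    """Label -> true value for every model parameter of the design."""
    pv = design.true_params()
    schema = ParamSchema.for_model(pv)
    return dict(zip(schema.labels, schema.pack(pv)))


def run_replicate(design: SimulationDesign, rep: int, methods=METHODS,
                  init_at_truth: bool = False) -> list:
    """Simulate replicate ``rep`` and fit it by each requested method.

    Returns tidy rows (replicate, method, parameter, value, converged);
    replicate seeds are base_seed + rep (mod 2³¹).
    """
    seed = int((design.base_seed + rep) % (2 ** 31))
    ds = simulate_dataset(design, seed)
    spec = design.model_spec()
    rows = []
    init = None
    if any(m in ("pairwise", "full") for m in methods):
        try:
            init = (design.true_params() if init_at_truth
                    else initialize_params(ds, spec))
        except EstimationError:
            init = design.true_params()
    pair_pv = None
    for method in methods:
        if method == "pairwise":
            try:
                fit = pairwise_fit(ds, spec, init=init, compute_cov=False)
                ok = fit.converged
                est = dict(zip(fit.labels, fit.estimates))
                if ok:  # warm start for the full-likelihood arm
                    pair_pv = init.copy()
                    for key, val in zip(fit.keys, fit.estimates):
                        pair_pv.set(key, float(val))
            except EstimationError as e:
                logger.warning("replicate %d pairwise fit failed: %s", rep, e)
                ok, est = False, {}
        elif method == "full":
            try:
                fit = _fit_model(ds, spec, spec.responses,
                                 init=pair_pv if pair_pv is not None else init,
                                 compute_info=False)
                ok = fit.converged
                est = dict(zip(fit.labels, fit.estimates))
            except Exception as e:  # noqa: BLE001 -- booked as non-convergence
                logger.warning("replicate %d full fit failed: %s", rep, e)
                ok, est = False, {}
        elif method == "baseline_weibull":
            ok, est = True, {}
            for r in design.responses:
                bf = fit_baseline_weibull(ds, r, spec)
                ok = ok and bf.converged
                if bf.converged:
                    est[key_label(("xi", r, 0))] = bf.coef[0]
                    est[key_label(("xi", r, 1))] = bf.coef[1]
                    est[key_label(("alpha", r))] = bf.alpha
                    est[key_label(("theta", r, 0))] = bf.theta
        else:
            raise ConfigError(f"unknown method {method!r}")
        for label, val in est.items():
            rows.append({"replicate": rep, "method": method,
                         "parameter": label, "value": float(val),
                         "converged": bool(ok)})
        if not est:
            rows.append({"replicate": rep, "method": method,
                         "parameter": None, "value": np.nan,
                         "converged": False})
    return rows


@dataclass
class StudyResult:
    """Tidy per-replicate estimates plus summary-table builders."""

    design: SimulationDesign
    estimates: pd.DataFrame   # replicate, method, parameter, value, converged
    methods: tuple

    def converged_ids(self, method) -> set:
        df = self.estimates
        df = df[df["method"] == method]
        return set(df.loc[df["converged"], "replicate"].unique())

    def matched_ids(self) -> set:
        """Replicate IDs converged under every fitted likelihood method.

        Mirrors the matched-by-ID comparison rule: when both the pairwise
        and full methods ran, only replicates successful under both enter
        the summaries.
        """
        ids = None
        for m in self.methods:
            if m in ("pairwise", "full"):
                s = self.converged_ids(m)
                ids = s if ids is None else ids & s
        if ids is None:
            ids = self.converged_ids(self.methods[0])
        return ids

    def summary(self, method, ids=None) -> pd.DataFrame:
        """Mean and Monte-Carlo SE (SD across replicates) per parameter."""
        ids = self.matched_ids() if ids is None else set(ids)
        df = self.estimates
        df = df[(df["method"] == method) & df["replicate"].isin(ids)
                & df["converged"] & df["parameter"].notna()]
        g = df.groupby("parameter")["value"]
        out = pd.DataFrame({"mean": g.mean(), "mc_se": g.std(ddof=1),
                            "n_reps": g.count()})
        truth = true_value_map(self.design)
        out.insert(0, "true", [truth.get(p, np.nan) for p in out.index])
        return out.reset_index()

    def mean_table(self) -> pd.DataFrame:
        """True value and per-method means, one row per parameter."""
        base = None
        for m in self.methods:
            if m == "baseline_weibull":
                continue
            s = self.summary(m)[["parameter", "true", "mean"]].rename(
                columns={"mean": f"mean_{m}"})
            base = s if base is None else base.merge(
                s.drop(columns="true"), on="parameter", how="outer")
        return base

    def mc_se_table(self) -> pd.DataFrame:
        """Monte-Carlo SEs per likelihood method, with pairwise/full ratio."""
        base = None
        for m in self.methods:
            if m == "baseline_weibull":
                continue
            s = self.summary(m)[["parameter", "mc_se"]].rename(
                columns={"mc_se": f"mc_se_{m}"})
            base = s if base is None else base.merge(s, on="parameter",
                                                     how="outer")
        if base is not None and {"mc_se_pairwise", "mc_se_full"} <= \
                set(base.columns):
            base["ratio"] = base["mc_se_pairwise"] / base["mc_se_full"]
        return base

    def baseline_table(self) -> pd.DataFrame:
        """Baseline-values-only Weibull comparator means vs true values."""
        ids = self.converged_ids("baseline_weibull")
        return self.summary("baseline_weibull", ids=ids)

    def convergence_rate(self, method) -> float:
        df = self.estimates[self.estimates["method"] == method]
        per = df.groupby("replicate")["converged"].first()
        return float(per.mean())


def replicate_study(design: SimulationDesign, methods=METHODS,
                    n_replicates: int | None = None, skip_ids=(),
                    prior_rows=None) -> StudyResult:
    """Run the full simulate-and-refit study.

    ``skip_ids``/``prior_rows`` support resuming: already-completed
    replicate IDs are not recomputed and their stored rows are merged in.
    The result is deterministic given the design's base seed regardless of
    interruption, because replicate seeds depend only on the replicate ID.
    """
    R = design.n_replicates if n_replicates is None else int(n_replicates)
    if R < 1:
        raise ConfigError("need at least one replicate")
    rows = list(prior_rows) if prior_rows is not None else []
    skip = set(skip_ids)
    for rep in range(R):
        if rep in skip:
            continue
        rows.extend(run_replicate(design, rep, methods))
    est = pd.DataFrame(rows)
    est = est.sort_values(["replicate", "method", "parameter"],
                          kind="stable").reset_index(drop=True)
    return StudyResult(design=design, estimates=est, methods=tuple(methods))
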