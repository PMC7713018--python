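"""Parameter containers and the free-parameter schema used by the fitters.

A :class:`ParameterVector` holds, per response ℓ: fixed effects β_ℓ, residual
SD σ_ℓ, random-effect SD(s) d_ℓ, survival coefficients ξ_ℓ, association
parameter(s) θ_ℓ and Weibull shape α_ℓ; plus the cross-response correlations
ρ_rs of the random intercepts (or, for the single-response intercept+slope
model, the within-response correlation ρ between intercept and slope).

Optimization happens on an unconstrained scale (log σ, log d, log α,
atanh ρ); a :class:`ParamSchema` maps between the structured container, the
natural-scale flat vector, and the unconstrained vector, and can hold any
subset of parameters fixed (e.g. θ = 0, ρ = 0 for oracle comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, DomainError


@dataclass
class ResponseParams:
    """All parameters specific to one longitudinal response."""

    beta: np.ndarray
    sigma: float
    d: np.ndarray            # random-effect SDs, shape (1,) or (2,)
    xi: np.ndarray
    theta: np.ndarray        # association coefficients, same shape as d
    alpha: float = 1.0
    rho_within: float = 0.0  # intercept-slope correlation; used iff len(d) == 2

    def __post_init__(self):
        self.beta = np.asarray(self.beta, float)
        self.d = np.atleast_1d(np.asarray(self.d, float))
        self.xi = np.asarray(self.xi, float)
        self.theta = np.atleast_1d(np.asarray(self.theta, float))
        if self.theta.shape != self.d.shape:
            raise ConfigError("theta and d must have the same length")

    def validate(self):
        if not self.sigma > 0:
            raise DomainError(f"sigma must be > 0, got {self.sigma}")
        if not np.all(self.d > 0):
            raise DomainError(f"random-effect SDs must be > 0, got {self.d}")
        if not self.alpha > 0:
            raise DomainError(f"alpha must be > 0, got {self.alpha}")
        if len(self.d) == 2 and not abs(self.rho_within) < 1:
            raise DomainError(f"|rho| must be < 1, got {self.rho_within}")

    def copy(self) -> "ResponseParams":
        return ResponseParams(self.beta.copy(), self.sigma, self.d.copy(),
                              self.xi.copy(), self.theta.copy(), self.alpha,
                              self.rho_within)


@dataclass
class ParameterVector:
    """Full parameter set Λ for a model over one or more responses."""

    responses: dict                      # name -> ResponseParams, ordered
    rho: dict = field(default_factory=dict)  # (r, s) with r before s -> ρ_rs

    def copy(self) -> "ParameterVector":
        return ParameterVector({n: p.copy() for n, p in self.responses.items()},
                               dict(self.rho))

    @property
    def names(self):
        return tuple(self.responses)

    def subset(self, names) -> "ParameterVector":
        names = tuple(names)
        rho = {(r, s): v for (r, s), v in self.rho.items()
               if r in names and s in names}
        return ParameterVector({n: self.responses[n].copy() for n in names}, rho)

    def rho_between(self, r, s) -> float:
        if (r, s) in self.rho:
            return self.rho[(r, s)]
        if (s, r) in self.rho:
            return self.rho[(s, r)]
        return 0.0

    def re_dims(self):
        return tuple(len(p.d) for p in self.responses.values())

    def D(self) -> np.ndarray:
        """Covariance matrix of the stacked random effects.

        For intercept-only responses the blocks are scalars d_ℓ² with
        off-diagonals ρ_rs d_r d_s; the single intercept+slope response uses
        its 2×2 block with within-response correlation.
        """
        names = self.names
        dims = self.re_dims()
        idx = np.concatenate([[0], np.cumsum(dims)])
        dtot = idx[-1]
        D = np.zeros((dtot, dtot))
        for a, n in enumerate(names):
            p = self.responses[n]
            i0 = idx[a]
            if dims[a] == 1:
                D[i0, i0] = p.d[0] ** 2
            else:
                d0, d1 = p.d
                off = p.rho_within * d0 * d1
                D[i0:i0 + 2, i0:i0 + 2] = [[d0 ** 2, off], [off, d1 ** 2]]
        for a, r in enumerate(names):
            for b in range(a + 1, len(names)):
                s = names[b]
                if dims[a] == 1 and dims[b] == 1:
                    v = self.rho_between(r, s) * \
                        self.responses[r].d[0] * self.responses[s].d[0]
                    D[idx[a], idx[b]] = D[idx[b], idx[a]] = v
        return D

    def validate(self):
        for p in self.responses.values():
            p.validate()
        for v in self.rho.values():
            if not abs(v) < 1:
                raise DomainError(f"|rho| must be < 1, got {v}")
        # the full random-effect covariance must be positive definite
        try:
            np.linalg.cholesky(self.D())
        except np.linalg.LinAlgError:
            raise DomainError("random-effect covariance matrix is not "
                              "positive definite") from None

    # -- flat access by key -------------------------------------------------

    def get(self, key):
        kind = key[0]
        if kind == "rho":
            return self.rho_between(key[1], key[2])
        p = self.responses[key[1]]
        if kind == "beta":
            return p.beta[key[2]]
        if kind == "sigma":
            return p.sigma
        if kind == "d":
            return p.d[key[2]]
        if kind == "xi":
            return p.xi[key[2]]
        if kind == "theta":
            return p.theta[key[2]]
        if kind == "alpha":
            return p.alpha
        if kind == "rho_within":
            return p.rho_within
        raise KeyError(key)

    def set(self, key, value):
        kind = key[0]
        if kind == "rho":
            r, s = key[1], key[2]
            self.rho[(r, s) if (s, r) not in self.rho else (s, r)] = value
            return
        p = self.responses[key[1]]
        if kind == "beta":
            p.beta[key[2]] = value
        elif kind == "sigma":
            p.sigma = value
        elif kind == "d":
            p.d[key[2]] = value
        elif kind == "xi":
            p.xi[key[2]] = value
        elif kind == "theta":
            p.theta[key[2]] = value
        elif kind == "alpha":
            p.alpha = value
        elif kind == "rho_within":
            p.rho_within = value
        else:
            raise KeyError(key)


def key_label(key) -> str:
    kind = key[0]
    if kind == "rho":
        return f"rho[{key[1]},{key[2]}]"
    if kind in ("sigma", "alpha", "rho_within"):
        return f"{kind}[{key[1]}]"
    return f"{kind}[{key[1]}][{key[2]}]"


_LOG = ("sigma", "d", "alpha")
_ATANH = ("rho", "rho_within")


class ParamSchema:
    """Ordered list of free parameter keys plus natural/unconstrained maps."""

    def __init__(self, keys, fixed=None):
        self.keys = tuple(tuple(k) for k in keys)
        self.fixed = dict(fixed or {})
        self.labels = tuple(key_label(k) for k in self.keys)
        self._kinds = tuple(k[0] for k in self.keys)

    @property
    def n(self) -> int:
        return len(self.keys)

    @classmethod
    def for_model(cls, pv: ParameterVector, alpha_fixed: bool = False,
                  fixed: dict | None = None) -> "ParamSchema":
        """Canonical schema for a model over the responses of ``pv``.

        ``fixed`` maps keys (see :func:`key_label` structure) to values held
        constant during optimization; exponential models fix every α at 1.
        """
        fixed = dict(fixed or {})
        keys = []
        names = pv.names
        for n in names:
            p = pv.responses[n]
            keys += [("beta", n, j) for j in range(len(p.beta))]
            keys.append(("sigma", n))
            keys += [("d", n, j) for j in range(len(p.d))]
            if len(p.d) == 2:
                keys.append(("rho_within", n))
            keys += [("xi", n, j) for j in range(len(p.xi))]
            keys += [("theta", n, j) for j in range(len(p.theta))]
            if not alpha_fixed:
                keys.append(("alpha", n))
            else:
                fixed.setdefault(("alpha", n), 1.0)
        for a, r in enumerate(names):
            for s in names[a + 1:]:
                if len(pv.responses[r].d) == 1 and len(pv.responses[s].d) == 1:
                    keys.append(("rho", r, s))
        keys = [k for k in keys if k not in fixed]
        return cls(keys, fixed)

    def apply_fixed(self, pv: ParameterVector):
        for key, val in self.fixed.items():
            pv.set(key, val)

    def pack(self, pv: ParameterVector) -> np.ndarray:
        return np.array([pv.get(k) for k in self.keys], float)

    def unpack(self, vec, template: ParameterVector) -> ParameterVector:
        pv = template.copy()
        for k, v in zip(self.keys, np.asarray(vec, float)):
            pv.set(k, float(v))
        self.apply_fixed(pv)
        return pv

    def to_unconstrained(self, nat: np.ndarray) -> np.ndarray:
        z = np.asarray(nat, float).copy()
        for i, kind in enumerate(self._kinds):
            if kind in _LOG:
                z[i] = np.log(z[i])
            elif kind in _ATANH:
                z[i] = np.arctanh(z[i])
        return z

    def from_unconstrained(self, z: np.ndarray) -> np.ndarray:
        nat = np.asarray(z, float).copy()
        for i, kind in enumerate(self._kinds):
            if kind in _LOG:
                nat[i] = np.exp(nat[i])
            elif kind in _ATANH:
                nat[i] = np.tanh(nat[i])
        return nat

    def dnat_dz(self, nat: np.ndarray) -> np.ndarray:
        """Diagonal Jacobian ∂natural/∂unconstrained at ``nat``."""
        jac = np.ones(self.n)
        for i, kind in enumerate(self._kinds):
            if kind in _LOG:
                jac[i] = nat[i]
            elif kind in _ATANH:
                jac[i] = 1.0 - nat[i] ** 2
        return jac
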