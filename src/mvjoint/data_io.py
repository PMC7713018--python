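"""Datasets, model specifications, delimited-file I/O and design matrices.

The package works on two tidy tables:

* a *longitudinal* table with one row per measurement:
  ``subject_id, response, time, value, <covariates...>``
* a *survival* table with one row per subject (``shared`` mode) or one row
  per (subject, response) pair (``per_response`` mode):
  ``subject_id[, response], time, event, <covariates...>``

Measurement time is expressed in years from each subject's own baseline
(0-based); calendar dates are never parsed.  Longitudinal values are on the
model (e.g. log-transformed) scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ConsistencyError, DataFormatError

logger = logging.getLogger(__name__)

SHARED = "shared"

LONG_REQUIRED = ("subject_id", "response", "time", "value")
SURV_REQUIRED = ("subject_id", "time", "event")


@dataclass(frozen=True)
class LongitudinalObservation:
    """One longitudinal measurement: response ``response`` of a subject at ``time``."""

    subject_id: object
    response: str
    time: float
    value: float
    covariates: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SurvivalRecord:
    """Observed follow-up time and event indicator (1 = event, 0 = censored)."""

    subject_id: object
    response: str  # a response label, or data_io.SHARED
    time: float
    event: int
    covariates: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ModelSpec:
    """Model configuration: designs, distributions and fitting options.

    Parameters
    ----------
    fixed_effects
        Per-response list of longitudinal mean covariates *after* the
        intercept (the intercept column is always added first).  The name
        ``"time"`` refers to the measurement-time column; any other name
        must be a column of the longitudinal table.
    survival_covariates
        Baseline covariate names for the log-hazard-scale linear predictor
        (after its intercept); columns of the survival table.
    distribution
        ``"weibull"`` (free shape α per response) or ``"exponential"``
        (α fixed at 1).
    random_effects
        ``"intercept_only"`` for any k; ``"intercept_slope"`` only for k=1.
    survival_time_mode
        ``"shared"``: one event time per subject, entering every response's
        factor; ``"per_response"``: one event time per (subject, response).
    sign_convention
        ``"log_hazard"``: the linear predictor enters the hazard as
        exp(+η), so larger η means shorter survival.  ``"negated"`` flips
        the sign of η everywhere (generator and fitter always share the
        convention, so recovery is convention-invariant).
    """

    responses: tuple
    fixed_effects: dict
    survival_covariates: tuple = ()
    distribution: str = "weibull"
    random_effects: str = "intercept_only"
    survival_time_mode: str = "per_response"
    sign_convention: str = "log_hazard"
    quad_nodes: int = 9
    gtol: float = 1e-6
    max_iter: int = 500
    mode_tol: float = 1e-8
    mode_max_iter: int = 50
    seed: int | None = None

    def __post_init__(self):
        if self.distribution not in ("weibull", "exponential"):
            raise ConfigError(f"unknown distribution {self.distribution!r}")
        if self.random_effects not in ("intercept_only", "intercept_slope"):
            raise ConfigError(f"unknown random_effects {self.random_effects!r}")
        if self.random_effects == "intercept_slope" and len(self.responses) != 1:
            raise ConfigError("intercept_slope random effects require k=1")
        if self.survival_time_mode not in (SHARED, "per_response"):
            raise ConfigError(
                f"unknown survival_time_mode {self.survival_time_mode!r}")
        if self.sign_convention not in ("log_hazard", "negated"):
            raise ConfigError(f"unknown sign_convention {self.sign_convention!r}")
        missing = [r for r in self.responses if r not in self.fixed_effects]
        if missing:
            raise ConfigError(f"fixed_effects missing for responses {missing}")
        if self.quad_nodes < 1:
            raise ConfigError("quad_nodes must be >= 1")

    @property
    def k(self) -> int:
        return len(self.responses)

    @property
    def alpha_fixed(self) -> bool:
        return self.distribution == "exponential"

    def with_(self, **kw) -> "ModelSpec":
        return replace(self, **kw)


class JointDataset:
    """Longitudinal observations plus survival records for N subjects.

    Data are held as two pandas DataFrames validated on construction;
    ``subjects`` fixes a deterministic subject order used by every
    design-matrix and likelihood routine.
    """

    def __init__(self, longitudinal: pd.DataFrame, survival: pd.DataFrame,
                 responses, survival_time_mode: str = "per_response",
                 validate: bool = True):
        self.longitudinal = longitudinal.reset_index(drop=True)
        self.survival = survival.reset_index(drop=True)
        self.responses = tuple(responses)
        self.survival_time_mode = survival_time_mode
        self.subjects = tuple(pd.unique(self.survival["subject_id"]))
        if validate:
            self._validate()

    @property
    def k(self) -> int:
        return len(self.responses)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def _validate(self):
        lon, sur = self.longitudinal, self.survival
        for c in LONG_REQUIRED:
            if c not in lon.columns:
                raise DataFormatError(f"longitudinal table lacks column {c!r}")
        for c in SURV_REQUIRED:
            if c not in sur.columns:
                raise DataFormatError(f"survival table lacks column {c!r}")
        unknown = set(lon["response"]) - set(self.responses)
        if unknown:
            raise ConsistencyError(
                f"longitudinal responses {sorted(map(str, unknown))} not declared")
        t = lon["time"].to_numpy(float)
        if not np.all(np.isfinite(t)) or (t < 0).any():
            raise DataFormatError("longitudinal times must be finite and >= 0")
        if lon.duplicated(["subject_id", "response", "time"]).any():
            raise DataFormatError(
                "duplicate (subject, response, time) rows in longitudinal table")
        ts = sur["time"].to_numpy(float)
        if not np.all(np.isfinite(ts)) or (ts <= 0).any():
            raise DataFormatError("survival times must be finite and > 0")
        ev = sur["event"].to_numpy()
        if not np.isin(ev, (0, 1)).all():
            raise DataFormatError("event indicator must be 0 or 1")
        if self.survival_time_mode == SHARED:
            if sur["subject_id"].duplicated().any():
                raise DataFormatError(
                    "shared mode requires exactly one survival row per subject")
        else:
            if "response" not in sur.columns:
                raise DataFormatError(
                    "per_response mode requires a 'response' column in the "
                    "survival table")
            if sur.duplicated(["subject_id", "response"]).any():
                raise DataFormatError(
                    "per_response mode requires one survival row per "
                    "(subject, response)")
        orphan = set(sur["subject_id"]) - set(lon["subject_id"])
        if orphan:
            raise ConsistencyError(
                f"survival subjects absent from longitudinal table: "
                f"{sorted(map(str, orphan))[:5]} ...")

    def subjects_with_response(self, response: str) -> tuple:
        have = set(self.longitudinal.loc[
            self.longitudinal["response"] == response, "subject_id"])
        if self.survival_time_mode != SHARED:
            have &= set(self.survival.loc[
                self.survival["response"] == response, "subject_id"])
        return tuple(s for s in self.subjects if s in have)


def resolve_response(spec_or_ds, response) -> str:
    """Accept a response label or a 1-based index and return the label."""
    responses = spec_or_ds.responses
    if isinstance(response, (int, np.integer)):
        if not 1 <= response <= len(responses):
            raise ConfigError(f"response index {response} outside 1..{len(responses)}")
        return responses[response - 1]
    if response not in responses:
        raise ConfigError(f"unknown response {response!r}")
    return response


def read_joint_dataset(longitudinal_path, survival_path, spec: ModelSpec) -> JointDataset:
    """Read the two CSV tables and return a validated :class:`JointDataset`.

    Rows with non-finite time/value entries are dropped with a logged count.
    """
    lon = pd.read_csv(longitudinal_path)
    sur = pd.read_csv(survival_path)
    for c in LONG_REQUIRED:
        if c not in lon.columns:
            raise DataFormatError(
                f"{longitudinal_path}: missing required column {c!r}")
    for c in SURV_REQUIRED:
        if c not in sur.columns:
            raise DataFormatError(f"{survival_path}: missing required column {c!r}")
    ok = np.isfinite(lon["time"].to_numpy(float)) & np.isfinite(
        lon["value"].to_numpy(float))
    if not ok.all():
        logger.warning("dropping %d longitudinal rows with non-finite entries",
                       int((~ok).sum()))
        lon = lon.loc[ok]
    oks = np.isfinite(sur["time"].to_numpy(float))
    if not oks.all():
        logger.warning("dropping %d survival rows with non-finite times",
                       int((~oks).sum()))
        sur = sur.loc[oks]
    lon = lon.copy()
    lon["response"] = lon["response"].astype(str)
    if "response" in sur.columns:
        sur = sur.copy()
        sur["response"] = sur["response"].astype(str)
    return JointDataset(lon, sur, spec.responses, spec.survival_time_mode)


def write_joint_dataset(dataset: JointDataset, longitudinal_path, survival_path):
    """Write the two tables as CSV (inverse of :func:`read_joint_dataset`)."""
    dataset.longitudinal.to_csv(longitudinal_path, index=False)
    dataset.survival.to_csv(survival_path, index=False)


@dataclass
class DesignBlock:
    """Per-subject design matrices for one response.

    ``X`` rows are ordered by measurement time and the intercept column is
    always first; ``Z`` is a column of ones (intercept_only) or
    ``[1, t_ij]`` (intercept_slope).
    """

    response: str
    subjects: tuple
    X: list            # list of (n_i, p) arrays
    Z: list            # list of (n_i, dz) arrays
    y: list            # list of (n_i,) arrays
    x2: np.ndarray     # (N, q) survival design, intercept first
    t: np.ndarray      # (N,) observed times
    delta: np.ndarray  # (N,) event indicators
    x_names: tuple
    x2_names: tuple


def build_design(dataset: JointDataset, spec: ModelSpec, response) -> DesignBlock:
    """Build per-subject matrices (X_1i, z_1i, y_i) and (x_2i, t_i, δ_i).

    Subjects lacking any longitudinal (or, in per_response mode, survival)
    record for this response are excluded with a logged count.
    """
    response = resolve_response(spec, response)
    subjects = dataset.subjects_with_response(response)
    n_excluded = dataset.n_subjects - len(subjects)
    if n_excluded:
        logger.info("response %s: excluding %d subjects with no data",
                    response, n_excluded)
    lon = dataset.longitudinal
    lon = lon.loc[lon["response"] == response].sort_values(["subject_id", "time"])
    covs = tuple(spec.fixed_effects[response])
    for c in covs:
        if c != "time" and c not in lon.columns:
            raise ConfigError(
                f"longitudinal covariate {c!r} not found in data columns")
    grouped = dict(tuple(lon.groupby("subject_id", sort=False)))
    X, Z, y = [], [], []
    slope = spec.random_effects == "intercept_slope"
    for s in subjects:
        g = grouped[s]
        tcol = g["time"].to_numpy(float)
        cols = [np.ones(len(g))]
        for c in covs:
            cols.append(tcol if c == "time" else g[c].to_numpy(float))
        X.append(np.column_stack(cols))
        Z.append(np.column_stack([np.ones(len(g)), tcol]) if slope
                 else np.ones((len(g), 1)))
        y.append(g["value"].to_numpy(float))

    sur = dataset.survival
    if dataset.survival_time_mode != SHARED:
        sur = sur.loc[sur["response"] == response]
    for c in spec.survival_covariates:
        if c not in sur.columns:
            raise ConfigError(f"survival covariate {c!r} not found in data columns")
    sur = sur.set_index("subject_id").loc[list(subjects)]
    x2 = np.column_stack(
        [np.ones(len(subjects))] +
        [sur[c].to_numpy(float) for c in spec.survival_covariates])
    return DesignBlock(
        response=response, subjects=subjects, X=X, Z=Z, y=y, x2=x2,
        t=sur["time"].to_numpy(float), delta=sur["event"].to_numpy(float),
        x_names=("intercept",) + covs,
        x2_names=("intercept",) + tuple(spec.survival_covariates),
    )


# ---------------------------------------------------------------------------
# configuration files

def load_config(path) -> dict:
    """Load a YAML (or JSON, a YAML subset) key-value configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    return cfg


def model_spec_from_config(cfg: dict) -> ModelSpec:
    """Build a :class:`ModelSpec` from a configuration mapping."""
    try:
        responses = tuple(cfg["responses"])
        fixed = {r: tuple(v) for r, v in cfg["fixed_effects"].items()}
    except KeyError as e:
        raise ConfigError(f"config missing required key {e.args[0]!r}") from None
    keys = ("distribution", "random_effects", "survival_time_mode",
            "sign_convention", "quad_nodes", "gtol", "max_iter", "seed")
    extra = {k: cfg[k] for k in keys if k in cfg}
    return ModelSpec(
        responses=responses, fixed_effects=fixed,
        survival_covariates=tuple(cfg.get("survival_covariates", ())), **extra)
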