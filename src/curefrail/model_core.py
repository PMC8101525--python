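"""Core distributions and likelihood for the mixture cure rate frailty model.

The population is a two-component mixture: a cured (long-term survivor)
fraction that never experiences the event, and an uncured (short-term)
fraction whose event time follows a Weibull proportional-hazards model with
a multiplicative gamma frailty.

* Incidence part (cure probability): ``pi(x) = expit(b0 + x . b)`` — the
  probability of belonging to the cured fraction, so ``exp(b_j)`` is the
  odds ratio of being cured.
* Latency part: conditional on frailty ``w``, the uncured hazard is
  ``w * h0(t) * exp(x . beta)`` with Weibull baseline cumulative hazard
  ``H0(t) = scale * t**shape``.
* Frailty: ``w ~ Gamma(theta, theta)`` (shape = rate), mean 1 and variance
  ``1/theta``. Marginalising the frailty analytically gives the uncured
  survival ``S_u(t|x) = (1 + H0(t) e^{x.beta} / theta)**(-theta)``.

Population survival is ``S_pop(t) = pi + (1 - pi) * S_u(t)``, whose
``t -> inf`` limit is the cure fraction (the Kaplan-Meier plateau).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

__all__ = [
    "SubjectRecord",
    "Dataset",
    "CureModelParams",
    "LinkedProbability",
    "ParamTransform",
    "weibull_cumhaz",
    "weibull_hazard",
    "cure_probability",
    "latency_survival",
    "latency_density",
    "population_survival",
    "log_likelihood",
    "read_dataset_csv",
    "write_dataset_csv",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectRecord:
    """One right-censored subject: follow-up time (months), event indicator
    (1 = event, 0 = censored) and a dummy-coded covariate vector."""

    time: float
    event: int
    covariates: np.ndarray

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"time must be non-negative, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")
        if self.event == 1 and self.time == 0:
            raise ValueError("event recorded at time 0 is not representable "
                             "(the event-time density is degenerate there)")


@dataclass
class LinkedProbability:
    """A probability strictly inside (0, 1), as produced by the logistic link."""

    value: float

    def __post_init__(self) -> None:
        if not 0.0 < self.value < 1.0:
            raise ValueError(f"probability must lie in (0,1), got {self.value}")

    def __float__(self) -> float:
        return float(self.value)


class Dataset:
    """A right-censored cohort with dummy-coded covariates.

    Parameters
    ----------
    time, event : arrays of length n
        Follow-up time in months and the event indicator.
    covariates : (n, p) array
        Dummy-coded design matrix (no intercept column; the incidence
        intercept lives in the parameters).
    covariate_names : list of str
    incidence_columns, latency_columns : sequences of column indices
        Which covariates enter the incidence (cure) and latency
        (time-to-event) parts. Default: all columns in both.
    reference_levels : optional dict
        Metadata recording the reference level of each dummy-coded
        categorical.
    """

    def __init__(
        self,
        time,
        event,
        covariates,
        covariate_names=None,
        incidence_columns=None,
        latency_columns=None,
        reference_levels=None,
    ):
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=int)
        self.covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if self.covariates.shape[0] != self.time.shape[0]:
            self.covariates = self.covariates.reshape(self.time.shape[0], -1)
        n, p = self.covariates.shape
        if n == 0:
            raise ValueError("dataset must be nonempty")
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time, event and covariates have inconsistent lengths")
        if np.any(self.time < 0):
            raise ValueError("negative follow-up times")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event indicator must be 0/1")
        if np.any((self.event == 1) & (self.time == 0)):
            raise ValueError("event recorded at time 0: the likelihood is "
                             "degenerate; correct or drop these records")
        if np.any(~np.isfinite(self.time)) or np.any(~np.isfinite(self.covariates)):
            raise ValueError("non-finite values in dataset (missing values are "
                             "rejected; no imputation rule is defined)")
        self.covariate_names = (
            list(covariate_names) if covariate_names is not None
            else [f"x{j}" for j in range(p)]
        )
        if len(self.covariate_names) != p:
            raise ValueError("covariate_names length mismatch")
        self.incidence_columns = (
            list(range(p)) if incidence_columns is None else list(incidence_columns)
        )
        self.latency_columns = (
            list(range(p)) if latency_columns is None else list(latency_columns)
        )
        for idx in (*self.incidence_columns, *self.latency_columns):
            if not 0 <= idx < p:
                raise ValueError(f"covariate column index {idx} out of range")
        self.reference_levels = dict(reference_levels or {})

    # -- convenience views ---------------------------------------------------

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def x_incidence(self) -> np.ndarray:
        return self.covariates[:, self.incidence_columns]

    @property
    def x_latency(self) -> np.ndarray:
        return self.covariates[:, self.latency_columns]

    @property
    def incidence_names(self) -> list[str]:
        return [self.covariate_names[j] for j in self.incidence_columns]

    @property
    def latency_names(self) -> list[str]:
        return [self.covariate_names[j] for j in self.latency_columns]

    def records(self):
        """Iterate over :class:`SubjectRecord` views of the rows."""
        for i in range(self.n):
            yield SubjectRecord(float(self.time[i]), int(self.event[i]),
                                self.covariates[i].copy())

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.time, "event": self.event})
        for j, name in enumerate(self.covariate_names):
            df[name] = self.covariates[:, j]
        return df

    def subset(self, idx) -> "Dataset":
        return Dataset(
            self.time[idx], self.event[idx], self.covariates[idx],
            self.covariate_names, self.incidence_columns, self.latency_columns,
            self.reference_levels,
        )


@dataclass(frozen=True)
class CureModelParams:
    """Full parameter set of the mixture cure rate frailty model.

    b0
        incidence intercept (logit of the cure probability at the
        reference covariate profile).
    b
        incidence (long-term) coefficients; ``exp(b_j)`` = cure odds ratio.
    beta
        latency (short-term) log hazard ratios.
    shape, scale
        Weibull baseline, ``H0(t) = scale * t**shape``.
    theta
        gamma frailty shape (= rate); frailty variance is ``1/theta``.
    """

    b0: float
    b: np.ndarray = field(default_factory=lambda: np.array([]))
    beta: np.ndarray = field(default_factory=lambda: np.array([]))
    shape: float = 1.0
    scale: float = 1.0
    theta: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "b", np.atleast_1d(np.asarray(self.b, dtype=float)))
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, dtype=float)))
        for name in ("shape", "scale", "theta"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a positive finite real, got {v}")

    def param_names(self, incidence_names=None, latency_names=None) -> list[str]:
        inc = incidence_names or [f"x{j}" for j in range(len(self.b))]
        lat = latency_names or [f"x{j}" for j in range(len(self.beta))]
        return (["intercept"] + [f"incidence:{s}" for s in inc]
                + [f"latency:{s}" for s in lat] + ["shape", "scale", "theta"])


# ---------------------------------------------------------------------------
# Parameter packing: natural <-> unconstrained (optimisation / sampling) scale
# ---------------------------------------------------------------------------


class ParamTransform:
    """Maps :class:`CureModelParams` to a flat unconstrained vector.

    Layout: ``[b0, b..., beta..., log shape, log scale, log theta]``.
    Positive parameters are log-transformed so optimisers and random-walk
    samplers operate on an unconstrained space. ``fixed_theta`` pins the
    frailty parameter (used for the no-frailty reduced model) and removes
    it from the vector.
    """

    def __init__(self, n_incidence: int, n_latency: int,
                 fixed_theta: float | None = None):
        self.n_incidence = int(n_incidence)
        self.n_latency = int(n_latency)
        self.fixed_theta = fixed_theta

    @property
    def n_params(self) -> int:
        return 1 + self.n_incidence + self.n_latency + (2 if self.fixed_theta else 3)

    def names(self, incidence_names=None, latency_names=None) -> list[str]:
        inc = incidence_names or [f"x{j}" for j in range(self.n_incidence)]
        lat = latency_names or [f"x{j}" for j in range(self.n_latency)]
        base = (["intercept"] + [f"incidence:{s}" for s in inc]
                + [f"latency:{s}" for s in lat] + ["shape", "scale"])
        return base if self.fixed_theta else base + ["theta"]

    # indices of log-scale entries within the vector
    @property
    def log_scale_idx(self) -> list[int]:
        k = 1 + self.n_incidence + self.n_latency
        return list(range(k, self.n_params))

    def pack(self, params: CureModelParams) -> np.ndarray:
        if len(params.b) != self.n_incidence or len(params.beta) != self.n_latency:
            raise ValueError("parameter dimensions do not match transform")
        head = np.concatenate(([params.b0], params.b, params.beta,
                               [np.log(params.shape), np.log(params.scale)]))
        if self.fixed_theta is None:
            head = np.concatenate((head, [np.log(params.theta)]))
        return head

    def unpack(self, vec: np.ndarray) -> CureModelParams:
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (self.n_params,):
            raise ValueError(f"expected vector of length {self.n_params}, "
                             f"got shape {vec.shape}")
        i = 1 + self.n_incidence
        j = i + self.n_latency
        theta = self.fixed_theta if self.fixed_theta is not None else np.exp(vec[j + 2])
        return CureModelParams(
            b0=vec[0], b=vec[1:i], beta=vec[i:j],
            shape=np.exp(vec[j]), scale=np.exp(vec[j + 1]), theta=theta,
        )

    @classmethod
    def for_dataset(cls, data: Dataset, fixed_theta: float | None = None):
        return cls(len(data.incidence_columns), len(data.latency_columns),
                   fixed_theta=fixed_theta)


# ---------------------------------------------------------------------------
# Model functions
# ---------------------------------------------------------------------------


def _check_weibull(shape: float, scale: float) -> None:
    if shape <= 0 or scale <= 0:
        raise ValueError(f"Weibull shape and scale must be positive, "
                         f"got shape={shape}, scale={scale}")


def weibull_cumhaz(t, shape: float, scale: float):
    """Baseline cumulative hazard ``H0(t) = scale * t**shape``."""
    _check_weibull(shape, scale)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = scale * np.power(t, shape)
    return out if out.ndim else float(out)

def weibull_hazard(t, shape: float, scale: float):
    """Baseline hazard ``h0(t) = shape * scale * t**(shape-1)``, for t > 0."""
    _check_weibull(shape, scale)
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("hazard requires t > 0")
    out = shape * scale * np.power(t, shape - 1.0)
    return out if out.ndim else float(out)


def cure_probability(x, b0: float, b) -> LinkedProbability:
    """Logistic cure probability ``pi(x) = expit(b0 + x . b)``."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if x.shape[-1] != b.shape[0]:
        raise ValueError(f"covariate/coefficient dimension mismatch: "
                         f"{x.shape[-1]} vs {b.shape[0]}")
    eta = b0 + x @ b
    if np.ndim(eta) == 0 or eta.shape == ():
        return LinkedProbability(float(expit(eta)))
    return expit(eta)  # vectorised use returns a plain array


def _log_latency_survival(t, eta_lat, params: CureModelParams):
    """log S_u(t | x) with the gamma frailty marginalised analytically."""
    h0 = weibull_cumhaz(t, params.shape, params.scale)
    return -params.theta * np.log1p(np.asarray(h0) * np.exp(eta_lat) / params.theta)


def latency_survival(t, x, params: CureModelParams):
    """Marginal (frailty-integrated) survival of the uncured,
    ``S_u(t|x) = (1 + H0(t) e^{x.beta} / theta)**(-theta)``."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    eta = float(x @ params.beta)
    out = np.exp(_log_latency_survival(t, eta, params))
    return float(out) if np.ndim(out) == 0 else out


def latency_density(t, x, params: CureModelParams):
    """Marginal event-time density of the uncured (negative derivative of
    :func:`latency_survival`):

    ``f_u(t|x) = h0(t) e^{x.beta} (1 + H0(t) e^{x.beta}/theta)**(-theta-1)``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("latency density requires t > 0")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    eta = float(x @ params.beta)
    h0 = weibull_hazard(t_arr, params.shape, params.scale)
    big_h = weibull_cumhaz(t_arr, params.shape, params.scale)
    log_f = (np.log(h0) + eta
             - (params.theta + 1.0) * np.log1p(np.asarray(big_h) * np.exp(eta) / params.theta))
    out = np.exp(log_f)
    return float(out) if np.ndim(out) == 0 else out


def population_survival(t, x_inc, x_lat, params: CureModelParams):
    """Mixture survival ``S_pop(t) = pi + (1 - pi) S_u(t | x)``."""
    x_inc = np.atleast_1d(np.asarray(x_inc, dtype=float))
    pi = float(expit(params.b0 + x_inc @ params.b))
    s_u = latency_survival(t, x_lat, params)
    return pi + (1.0 - pi) * s_u


def log_likelihood(data: Dataset, params: CureModelParams) -> float:
    """Observed-data log-likelihood with frailty and cure status
    marginalised analytically.

    Events contribute ``log[(1 - pi) f_u(t)]``; censored records contribute
    ``log[pi + (1 - pi) S_u(t)]``.
    """
    if len(params.b) != len(data.incidence_columns):
        raise ValueError("incidence coefficient dimension mismatch")
    if len(params.beta) != len(data.latency_columns):
        raise ValueError("latency coefficient dimension mismatch")

    t = data.time
    event = data.event.astype(bool)
    eta_inc = params.b0 + data.x_incidence @ params.b
    eta_lat = data.x_latency @ params.beta

    log_pi = log_expit(eta_inc)          # log pi(x)
    log_1mpi = log_expit(-eta_inc)       # log (1 - pi(x))

    # shared pieces; t == 0 only occurs for censored records (validated on load)
    big_h = weibull_cumhaz(t, params.shape, params.scale)
    log_ratio = np.log1p(big_h * np.exp(eta_lat) / params.theta)
    log_s_u = -params.theta * log_ratio

    ll = 0.0
    if event.any():
        te = t[event]
        log_h0 = np.log(params.shape * params.scale) + (params.shape - 1.0) * np.log(te)
        log_f = log_h0 + eta_lat[event] - (params.theta + 1.0) * log_ratio[event]
        ll += np.sum(log_1mpi[event] + log_f)
    if (~event).any():
        ll += np.sum(np.logaddexp(log_pi[~event],
                                  log_1mpi[~event] + log_s_u[~event]))
    return float(ll)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def read_dataset_csv(
    path,
    incidence=None,
    latency=None,
    reference_levels: dict[str, str] | None = None,
) -> Dataset:
    """Read a cohort CSV with columns ``time``, ``event``, then covariates.

    Non-numeric covariate columns are dummy-coded against a reference level
    (``reference_levels[name]`` if given, else the lexicographically first
    level); the chosen references are recorded in ``Dataset.reference_levels``.
    Missing values are rejected. ``incidence``/``latency`` select covariate
    subsets by (dummy-coded) name for the two model parts.
    """
    df = pd.read_csv(path)
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"input CSV is missing required column '{col}'")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"missing value at data row {bad + 1}; "
                         "records must be complete")
    refs = dict(reference_levels or {})
    cov_cols = [c for c in df.columns if c not in ("time", "event")]
    pieces, names = [], []
    for c in cov_cols:
        col = df[c]
        if pd.api.types.is_numeric_dtype(col):
            pieces.append(col.to_numpy(dtype=float))
            names.append(c)
        else:
            levels = sorted(col.astype(str).unique())
            ref = str(refs.get(c, levels[0]))
            if ref not in levels:
                raise ValueError(f"reference level '{ref}' not found in column '{c}'")
            refs[c] = ref
            for lev in levels:
                if lev == ref:
                    continue
                pieces.append((col.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{c}:{lev}")
    cov = np.column_stack(pieces) if pieces else np.empty((len(df), 0))

    def _select(sel):
        if sel is None:
            return None
        idx = []
        for s in sel:
            matches = [j for j, nm in enumerate(names)
                       if nm == s or nm.split(":")[0] == s]
            if not matches:
                raise ValueError(f"unknown covariate '{s}' (available: {names})")
            idx.extend(matches)
        return sorted(set(idx))

    return Dataset(
        df["time"].to_numpy(dtype=float),
        df["event"].to_numpy(),
        cov,
        covariate_names=names,
        incidence_columns=_select(incidence),
        latency_columns=_select(latency),
        reference_levels=refs,
    )


def write_dataset_csv(data: Dataset, path) -> None:
    data.to_dataframe().to_csv(path, index=False)
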