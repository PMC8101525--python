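"""Maximum-likelihood estimation of the mixture cure rate frailty model.

Positive parameters (Weibull shape/scale, frailty theta) are optimised on
the log scale; standard errors come from the numerically differentiated
observed information at the optimum, with the delta method used to report
them on the natural scale. Mixture cure likelihoods can be multimodal, so
the fit uses several jittered starting points and keeps the best mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import logit
from statsmodels.tools.numdiff import approx_fprime, approx_hess

from .model_core import CureModelParams, Dataset, ParamTransform, log_likelihood
from .km_cure import km_estimate, plateau_cure_fraction

__all__ = ["MLEResult", "fit_mle", "wald_ci", "default_init"]

_Z975 = 1.959963984540054


@dataclass
class MLEResult:
    """MLE point estimates with Wald inference.

    ``se`` and ``ci`` are on the natural (reporting) scale: plain for the
    coefficients, delta-method / back-transformed for shape, scale, theta.
    ``vector``, ``cov`` and ``transform`` retain the unconstrained-scale
    internals for downstream use (information criteria, proposal tuning).
    """

    params_hat: CureModelParams
    param_names: list[str]
    estimate: dict[str, float]
    se: dict[str, float]
    ci: dict[str, tuple[float, float]]
    loglik: float
    converged: bool
    n_iter: int
    vector: np.ndarray = field(repr=False, default=None)
    cov: np.ndarray = field(repr=False, default=None)
    transform: ParamTransform = field(repr=False, default=None)
    n_obs: int = 0

    @property
    def n_params(self) -> int:
        return len(self.param_names)


def default_init(data: Dataset, fixed_theta: float | None = None) -> CureModelParams:
    """Data-driven starting point.

    Incidence intercept = logit of the Kaplan-Meier plateau estimate
    (clipped away from 0/1), coefficients 0; Weibull scale from a
    censoring-ignored exponential moment match on the event times with
    shape 1; theta = 1.
    """
    curve = km_estimate(data.time, data.event)
    plateau = plateau_cure_fraction(curve).cure_estimate
    pi0 = float(np.clip(plateau, 0.02, 0.98))
    event_times = data.time[data.event == 1]
    if event_times.size:
        scale0 = max(1.0 / float(np.mean(event_times)), 1e-6)
    else:
        scale0 = 0.1
    return CureModelParams(
        b0=float(logit(pi0)),
        b=np.zeros(len(data.incidence_columns)),
        beta=np.zeros(len(data.latency_columns)),
        shape=1.0,
        scale=scale0,
        theta=fixed_theta if fixed_theta is not None else 1.0,
    )


def _neg_loglik(vec, data, transform):
    try:
        params = transform.unpack(vec)
    except (ValueError, FloatingPointError, OverflowError):
        return np.inf
    with np.errstate(over="ignore"):
        ll = log_likelihood(data, params)
    return -ll if np.isfinite(ll) else np.inf


def fit_mle(
    data: Dataset,
    init: CureModelParams | None = None,
    *,
    fixed_theta: float | None = None,
    n_starts: int = 5,
    jitter_sd: float = 0.5,
    max_iter: int = 500,
    tol: float = 1e-9,
    seed: int = 0,
) -> MLEResult:
    """Maximise the observed-data log-likelihood.

    Runs ``n_starts`` quasi-Newton (L-BFGS-B) optimisations from the
    default (or supplied) starting point plus Gaussian-jittered copies and
    keeps the best mode. ``fixed_theta`` fits the no-frailty reduced model
    with theta pinned at the given value.
    """
    if data.n_events == 0:
        raise ValueError("all records censored: the cure fraction and latency "
                         "parameters are not identifiable without events")
    if data.n_events == data.n:
        raise ValueError("all records are events: a cure fraction cannot be "
                         "identified without censored follow-up")

    transform = ParamTransform.for_dataset(data, fixed_theta=fixed_theta)
    x0 = transform.pack(init if init is not None else default_init(data, fixed_theta))
    f0 = _neg_loglik(x0, data, transform)
    if not np.isfinite(f0):
        raise ValueError("log-likelihood is not finite at the starting values; "
                         "check the data and initial parameters")

    rng = np.random.default_rng(seed)
    starts = [x0] + [x0 + rng.normal(0.0, jitter_sd, size=x0.shape)
                     for _ in range(max(n_starts - 1, 0))]

    best = None
    total_iter = 0
    any_converged = False
    for s in starts:
        res = optimize.minimize(
            _neg_loglik, s, args=(data, transform), method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
        )
        total_iter += int(res.nit)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
        any_converged = any_converged or bool(res.success)
    if best is None:
        raise RuntimeError("all optimiser starts failed to produce a finite "
                           "likelihood")

    vec_hat, hess = _newton_polish(np.asarray(best.x, dtype=float), data, transform)
    params_hat = transform.unpack(vec_hat)
    loglik = float(log_likelihood(data, params_hat))
    names = transform.names(data.incidence_names, data.latency_names)
    cov, weak = _pseudo_covariance(hess, names)
    if weak:
        warnings.warn(
            "observed information is flat in: " + ", ".join(weak)
            + "; standard errors for these parameters are reported as "
            "infinite (expected when the frailty variance estimate sits at "
            "the no-frailty boundary)", stacklevel=2)
    se_unc = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

    estimate, se_nat, ci = _natural_scale_summaries(
        vec_hat, se_unc, transform, names, level=0.95)

    return MLEResult(
        params_hat=params_hat,
        param_names=names,
        estimate=estimate,
        se=se_nat,
        ci=ci,
        loglik=loglik,
        converged=any_converged and bool(best.success or best.fun <= f0),
        n_iter=total_iter,
        vector=vec_hat,
        cov=cov,
        transform=transform,
        n_obs=data.n,
    )


def _newton_polish(vec, data, transform, max_steps: int = 15,
                   grad_tol: float = 1e-7):
    """A few damped Newton steps with the numerical Hessian, to drive the
    score to (near) zero after the quasi-Newton search. Returns the refined
    point and the Hessian evaluated there."""
    f_cur = _neg_loglik(vec, data, transform)
    hess = approx_hess(vec, _neg_loglik, args=(data, transform))
    for _ in range(max_steps):
        grad = approx_fprime(vec, _neg_loglik, args=(data, transform),
                             centered=True)
        if np.linalg.norm(grad) < grad_tol:
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        accepted = False
        t = 1.0
        while t > 1e-4:
            cand = vec - t * step
            f_new = _neg_loglik(cand, data, transform)
            if f_new <= f_cur + 1e-10:
                vec, f_cur, accepted = cand, f_new, True
                break
            t /= 2.0
        if not accepted:
            break
        hess = approx_hess(vec, _neg_loglik, args=(data, transform))
    return vec, hess


def _pseudo_covariance(hess: np.ndarray, names: list[str]):
    """Invert the observed information, tolerating flat directions.

    Parameters dominating near-null eigendirections (typically theta at
    the no-frailty boundary) get an infinite variance; the remaining
    block is inverted normally. Returns ``(cov, weak_parameter_names)``.
    """
    eigvals, vecs = np.linalg.eigh(hess)
    floor = 1e-9 * max(float(np.max(np.abs(eigvals))), 1.0)
    weak_cols = vecs[:, eigvals <= floor]
    weak_idx = sorted({int(np.argmax(np.abs(col))) for col in weak_cols.T})
    p = hess.shape[0]
    strong_idx = [k for k in range(p) if k not in weak_idx]
    cov = np.zeros((p, p))
    if strong_idx:
        sub = hess[np.ix_(strong_idx, strong_idx)]
        sub_eigs = np.linalg.eigvalsh(sub)
        if np.min(sub_eigs) <= floor:
            culprits = sorted({names[k] for k in weak_idx} | {"(mixed)"})
            raise np.linalg.LinAlgError(
                "observed information matrix is singular or indefinite; "
                f"non-identified parameter(s): {', '.join(culprits)}")
        cov[np.ix_(strong_idx, strong_idx)] = np.linalg.inv(sub)
    for k in weak_idx:
        cov[k, k] = np.inf
    return cov, [names[k] for k in weak_idx]


def _natural_scale_summaries(vec, se_unc, transform: ParamTransform, names,
                             level: float):
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    log_idx = set(transform.log_scale_idx)
    estimate, se_nat, ci = {}, {}, {}
    for k, name in enumerate(names):
        if k in log_idx:
            est = float(np.exp(vec[k]))
            estimate[name] = est
            se_nat[name] = est * float(se_unc[k])  # delta method
            ci[name] = (float(np.exp(vec[k] - z * se_unc[k])),
                        float(np.exp(vec[k] + z * se_unc[k])))
        else:
            estimate[name] = float(vec[k])
            se_nat[name] = float(se_unc[k])
            ci[name] = (float(vec[k] - z * se_unc[k]),
                        float(vec[k] + z * se_unc[k]))
    return estimate, se_nat, ci


def wald_ci(result: MLEResult, level: float = 0.95) -> dict[str, tuple[float, float]]:
    """Wald intervals at the given level, built on the optimisation scale
    and back-transformed for log-scale parameters (hence asymmetric and
    strictly positive for shape/scale/theta)."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0,1)")
    diag = np.diag(result.cov)
    if not np.all(np.isfinite(diag)):
        bad = [nm for nm, v in zip(result.param_names, diag) if not np.isfinite(v)]
        raise np.linalg.LinAlgError(
            "observed information is singular; non-identified "
            f"parameter(s): {', '.join(bad)}")
    se_unc = np.sqrt(np.clip(diag, 0.0, np.inf))
    _, _, ci = _natural_scale_summaries(
        result.vector, se_unc, result.transform, result.param_names, level)
    return ci


def score_norm(result: MLEResult, data: Dataset) -> float:
    """Euclidean norm of the log-likelihood gradient at the optimum, on the
    optimisation scale (a convergence diagnostic)."""
    g = approx_fprime(result.vector, _neg_loglik, args=(data, result.transform),
                      centered=True)
    return float(np.linalg.norm(g))
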