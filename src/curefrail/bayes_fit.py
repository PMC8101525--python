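"""Random-walk Metropolis-Hastings inference for the mixture cure model.

The sampler works on the unconstrained scale (coefficients as-is; Weibull
shape/scale and frailty theta on the log scale) with block Gaussian
random-walk proposals. Proposal scales are adapted during burn-in toward a
20-40% acceptance rate and frozen afterwards, so the post-burn-in kernel
is an exact Metropolis-Hastings kernel. Priors are weakly informative
normals: Normal(0, sd^2) on the coefficients and on the logs of the
positive parameters; because the positive parameters are sampled on the
log scale and the prior is placed directly on the log, no extra Jacobian
term is needed.

Summaries are reported on the natural scale (draws of shape/scale/theta
are exponentiated before taking means, SDs and equal-tailed 95%
percentile intervals).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .model_core import CureModelParams, Dataset, ParamTransform, log_likelihood
from .classical_fit import default_init

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "PosteriorChain",
    "PosteriorSummary",
    "DiagnosticsReport",
    "log_posterior",
    "mh_sample",
    "posterior_summary",
    "diagnostics",
    "random_walk_metropolis",
    "save_chain",
    "load_chain",
]


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PriorSpec:
    """Independent normal priors on the unconstrained scale.

    ``coefficient_sd`` applies to the incidence intercept and all
    incidence/latency coefficients; ``log_positive_sd`` to log(shape),
    log(scale) and log(theta). Both zero-mean.
    """

    coefficient_sd: float = 10.0
    log_positive_sd: float = 10.0

    def __post_init__(self):
        if self.coefficient_sd <= 0 or self.log_positive_sd <= 0:
            raise ValueError("prior SDs must be positive")

    def sds(self, transform: ParamTransform) -> np.ndarray:
        out = np.full(transform.n_params, self.coefficient_sd)
        out[transform.log_scale_idx] = self.log_positive_sd
        return out

    def log_density(self, vec: np.ndarray, transform: ParamTransform) -> float:
        sds = self.sds(transform)
        return float(-0.5 * np.sum((vec / sds) ** 2)
                     - np.sum(np.log(sds)) - 0.5 * len(vec) * np.log(2 * np.pi))

    def sample(self, transform: ParamTransform, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(0.0, self.sds(transform))


@dataclass
class MCMCConfig:
    n_iter: int = 30_000
    burn_in: int = 10_000
    thin: int = 5
    n_chains: int = 4
    seed: int = 0
    proposal_sds: np.ndarray | None = None
    adapt_interval: int = 100
    target_accept: float = 0.3

    def __post_init__(self):
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")


# ---------------------------------------------------------------------------
# Chains
# ---------------------------------------------------------------------------


@dataclass
class PosteriorChain:
    """One MH chain on the unconstrained scale, with burn-in/thinning
    metadata. ``draws`` holds every iteration; ``kept`` applies burn-in
    and thinning."""

    draws: np.ndarray
    param_names: list[str]
    burn_in: int
    thin: int
    seed: int
    acceptance_rate: float
    log_scale_idx: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.draws.shape[0] <= self.burn_in:
            raise ValueError("chain shorter than burn-in")
        if not 0.0 <= self.acceptance_rate <= 1.0:
            raise ValueError("acceptance rate must lie in [0,1]")

    @property
    def kept(self) -> np.ndarray:
        return self.draws[self.burn_in::self.thin]

    def natural_draws(self) -> np.ndarray:
        """Kept draws with log-scale columns back-transformed."""
        out = self.kept.copy()
        if self.log_scale_idx:
            out[:, self.log_scale_idx] = np.exp(out[:, self.log_scale_idx])
        return out


@dataclass
class PosteriorSummary:
    """Per-parameter posterior mean, SD and equal-tailed 95% interval
    (natural scale)."""

    param_names: list[str]
    mean: dict[str, float]
    sd: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    n_draws: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mean": self.mean,
            "sd": self.sd,
            "ci_low": {k: v[0] for k, v in self.ci95.items()},
            "ci_high": {k: v[1] for k, v in self.ci95.items()},
        }).loc[self.param_names]


# ---------------------------------------------------------------------------
# Targets
# ---------------------------------------------------------------------------


def _make_log_target(data: Dataset | None, priors: PriorSpec,
                     transform: ParamTransform, likelihood_off: bool = False):
    def log_target(vec: np.ndarray) -> float:
        lp = priors.log_density(vec, transform)
        if data is None or likelihood_off:
            return lp
        try:
            params = transform.unpack(vec)
        except (ValueError, OverflowError):
            return -np.inf
        with np.errstate(over="ignore"):
            ll = log_likelihood(data, params)
        return ll + lp if np.isfinite(ll) else -np.inf

    return log_target


def log_posterior(params: CureModelParams, data: Dataset | None,
                  priors: PriorSpec | None = None, *,
                  fixed_theta: float | None = None) -> float:
    """Log posterior density (up to a constant) at the given parameters.

    With ``data=None`` the likelihood term is absent and the value is the
    log prior. Out-of-support parameter vectors map to ``-inf`` rather
    than raising, so rejection in the sampler is automatic.
    """
    priors = priors or PriorSpec()
    transform = ParamTransform(len(params.b), len(params.beta),
                               fixed_theta=fixed_theta)
    try:
        vec = transform.pack(params)
    except (ValueError, FloatingPointError):
        return -np.inf
    return _make_log_target(data, priors, transform)(vec)


# ---------------------------------------------------------------------------
# Generic random-walk MH core
# ---------------------------------------------------------------------------


def random_walk_metropolis(
    log_target,
    x0: np.ndarray,
    proposal_sds: np.ndarray,
    n_iter: int,
    rng: np.random.Generator,
    *,
    burn_in: int = 0,
    adapt_interval: int = 100,
    target_accept: float = 0.3,
):
    """Block Gaussian random-walk Metropolis with burn-in scale adaptation.

    During burn-in a global proposal multiplier is tuned toward
    ``target_accept`` and the proposal shape is refreshed from the
    empirical covariance of the chain so far (adaptive Metropolis); after
    burn-in both are frozen, preserving the exact MH kernel. Returns
    ``(draws, post-burn-in acceptance rate)``.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    sds = np.atleast_1d(np.asarray(proposal_sds, dtype=float)).copy()
    if np.any(sds <= 0):
        raise ValueError("proposal SDs must be strictly positive")
    lp = log_target(x0)
    if not np.isfinite(lp):
        raise ValueError("log target is not finite at the initial point")

    p = x0.size
    draws = np.empty((n_iter, p))
    x = x0.copy()
    scale = 1.0
    chol = np.diag(sds)          # proposal shape; refreshed during burn-in
    acc_window = 0
    acc_post = 0
    n_post = 0
    for i in range(n_iter):
        prop = x + scale * (chol @ rng.standard_normal(p))
        lp_prop = log_target(prop)
        if np.log(rng.uniform()) < lp_prop - lp:
            x, lp = prop, lp_prop
            acc_window += 1
            if i >= burn_in:
                acc_post += 1
        if i >= burn_in:
            n_post += 1
        draws[i] = x
        if i < burn_in and (i + 1) % adapt_interval == 0:
            rate = acc_window / adapt_interval
            scale *= float(np.exp(rate - target_accept))
            acc_window = 0
            if i + 1 >= max(4 * adapt_interval, 400):
                window = draws[(i + 1) // 2:i + 1]
                emp = np.cov(window.T).reshape(p, p)
                moved = np.all(np.diag(emp) > 1e-12)
                if moved:
                    # shrink toward the diagonal: short windows overstate
                    # correlations and badly scale slow eigendirections
                    emp = 0.8 * emp + 0.2 * np.diag(np.diag(emp))
                    emp += 1e-10 * np.eye(p) * max(np.trace(emp) / p, 1.0)
                    try:
                        chol = np.linalg.cholesky(emp) * (2.38 / np.sqrt(p))
                        scale = 1.0
                    except np.linalg.LinAlgError:
                        pass
    acc_rate = acc_post / n_post if n_post else 0.0
    return draws, float(acc_rate)


def mh_sample(
    data: Dataset,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    *,
    init: CureModelParams | None = None,
    fixed_theta: float | None = None,
    likelihood_off: bool = False,
) -> list[PosteriorChain]:
    """Sample the posterior with ``config.n_chains`` independent chains.

    Chain ``c`` uses seed ``config.seed + c`` and a slightly jittered copy
    of the starting point, so runs are exactly reproducible given the
    seed. ``fixed_theta`` pins the frailty parameter (no-frailty reduced
    model); ``likelihood_off`` targets the prior alone (a sampler
    self-check).
    """
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    transform = ParamTransform.for_dataset(data, fixed_theta=fixed_theta)
    names = transform.names(data.incidence_names, data.latency_names)
    x0 = transform.pack(init if init is not None
                        else default_init(data, fixed_theta))
    target = _make_log_target(data, priors, transform,
                              likelihood_off=likelihood_off)
    if not np.isfinite(target(x0)):
        raise ValueError("posterior is not finite at the starting values")
    if config.proposal_sds is not None:
        base_sds = np.atleast_1d(np.asarray(config.proposal_sds, dtype=float))
    elif likelihood_off:
        # the target IS the prior: scale proposals to it directly
        base_sds = priors.sds(transform) * 2.4 / np.sqrt(transform.n_params)
    else:
        base_sds = np.full(transform.n_params, 0.1)
    if base_sds.size == 1:
        base_sds = np.full(transform.n_params, float(base_sds[0]))
    if base_sds.shape != (transform.n_params,):
        raise ValueError("proposal_sds has the wrong length")

    chains = []
    for c in range(config.n_chains):
        seed_c = int(config.seed) + c
        rng = np.random.default_rng(seed_c)
        start = x0 if c == 0 else x0 + 0.05 * rng.standard_normal(x0.size)
        if not np.isfinite(target(start)):
            start = x0
        draws, acc = random_walk_metropolis(
            target, start, base_sds.copy(), config.n_iter, rng,
            burn_in=config.burn_in, adapt_interval=config.adapt_interval,
            target_accept=config.target_accept,
        )
        chains.append(PosteriorChain(
            draws=draws, param_names=names, burn_in=config.burn_in,
            thin=config.thin, seed=seed_c, acceptance_rate=acc,
            log_scale_idx=transform.log_scale_idx,
        ))
    return chains


# ---------------------------------------------------------------------------
# Summaries and diagnostics
# ---------------------------------------------------------------------------


def _as_chain_list(chain_or_chains) -> list[PosteriorChain]:
    if isinstance(chain_or_chains, PosteriorChain):
        return [chain_or_chains]
    chains = list(chain_or_chains)
    if not chains:
        raise ValueError("no chains supplied")
    return chains


def posterior_summary(chain_or_chains, natural_scale: bool = True) -> PosteriorSummary:
    """Pooled posterior mean/SD and equal-tailed 95% percentile interval
    per parameter, after burn-in and thinning."""
    chains = _as_chain_list(chain_or_chains)
    names = chains[0].param_names
    pooled = np.vstack([
        (c.natural_draws() if natural_scale else c.kept) for c in chains
    ])
    if pooled.shape[0] < 100:
        raise ValueError(f"too few post-burn-in draws ({pooled.shape[0]}) for a "
                         "stable summary; need at least 100")
    mean = dict(zip(names, np.mean(pooled, axis=0)))
    sd = dict(zip(names, np.std(pooled, axis=0, ddof=1)))
    lo = np.percentile(pooled, 2.5, axis=0)
    hi = np.percentile(pooled, 97.5, axis=0)
    ci = {nm: (float(lo[k]), float(hi[k])) for k, nm in enumerate(names)}
    return PosteriorSummary(param_names=list(names), mean=mean, sd=sd, ci95=ci,
                            n_draws=pooled.shape[0])


def posterior_mean_params(chain_or_chains, transform: ParamTransform) -> CureModelParams:
    """Posterior mean taken on the sampling (unconstrained) scale, then
    back-transformed — the point estimate used for the DIC's plug-in
    deviance."""
    chains = _as_chain_list(chain_or_chains)
    pooled = np.vstack([c.kept for c in chains])
    return transform.unpack(pooled.mean(axis=0))


@dataclass
class DiagnosticsReport:
    acceptance_rates: list[float]
    rhat: dict[str, float]
    ess: dict[str, float]
    warnings: list[str]


def diagnostics(chain_or_chains, rhat_threshold: float = 1.05,
                ess_threshold: float = 100.0) -> DiagnosticsReport:
    """Convergence diagnostics: per-chain acceptance rate, (split-chain)
    potential-scale-reduction statistic and effective sample size via
    ``arviz``. Threshold violations produce warnings, never errors."""
    import arviz as az

    chains = _as_chain_list(chain_or_chains)
    names = chains[0].param_names
    kept = np.stack([c.kept for c in chains])  # (chain, draw, param)
    data = {nm: kept[:, :, k] for k, nm in enumerate(names)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat_ds = az.rhat(az.convert_to_dataset(data))
        ess_ds = az.ess(az.convert_to_dataset(data))
    rhat = {nm: float(rhat_ds[nm].values) for nm in names}
    ess = {nm: float(ess_ds[nm].values) for nm in names}

    notes = []
    for c in chains:
        if c.acceptance_rate == 0.0:
            notes.append(f"chain with seed {c.seed}: no proposals accepted")
        elif c.acceptance_rate < 0.05:
            notes.append(f"chain with seed {c.seed}: very low acceptance rate "
                         f"{c.acceptance_rate:.3f}")
    for nm in names:
        if np.isfinite(rhat[nm]) and rhat[nm] > rhat_threshold:
            notes.append(f"{nm}: potential scale reduction {rhat[nm]:.3f} > "
                         f"{rhat_threshold}")
        if ess[nm] < ess_threshold:
            notes.append(f"{nm}: effective sample size {ess[nm]:.0f} < "
                         f"{ess_threshold:.0f}")
    for msg in notes:
        warnings.warn(msg, stacklevel=2)
    return DiagnosticsReport(
        acceptance_rates=[c.acceptance_rate for c in chains],
        rhat=rhat, ess=ess, warnings=notes,
    )


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_chain(chain: PosteriorChain, path_prefix: str,
               priors: PriorSpec | None = None) -> None:
    """Persist draws as CSV (parameter-name header) plus a JSON sidecar of
    the metadata needed for exact re-summarisation."""
    pd.DataFrame(chain.draws, columns=chain.param_names).to_csv(
        f"{path_prefix}.csv", index=False)
    meta = {
        "burn_in": chain.burn_in,
        "thin": chain.thin,
        "seed": chain.seed,
        "acceptance_rate": chain.acceptance_rate,
        "log_scale_idx": list(chain.log_scale_idx),
        "param_names": list(chain.param_names),
        "priors": asdict(priors) if priors is not None else None,
    }
    with open(f"{path_prefix}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_chain(path_prefix: str) -> PosteriorChain:
    draws = pd.read_csv(f"{path_prefix}.csv")
    with open(f"{path_prefix}.meta.json") as fh:
        meta = json.load(fh)
    return PosteriorChain(
        draws=draws.to_numpy(dtype=float),
        param_names=meta["param_names"],
        burn_in=meta["burn_in"],
        thin=meta["thin"],
        seed=meta["seed"],
        acceptance_rate=meta["acceptance_rate"],
        log_scale_idx=meta["log_scale_idx"],
    )
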