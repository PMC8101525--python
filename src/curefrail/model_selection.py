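"""Deviance-based information criteria (DIC, EAIC, EBIC).

For a posterior chain, with deviance ``D = -2 log L``:

* ``dbar`` — posterior mean deviance,
* ``pd = dbar - D(posterior mean)`` — effective number of parameters
  (Spiegelhalter form; the posterior mean is taken on the unconstrained
  sampling scale and back-transformed),
* ``DIC = dbar + pd``,
* ``EAIC = dbar + 2 p``, ``EBIC = dbar + p log n``.

For a maximum-likelihood fit the same report is produced by a plug-in
convention: the deviance at the MLE plays the role of ``dbar`` and
``pd = 0``, so ``DIC = D(MLE)``, ``EAIC = D(MLE) + 2p`` and
``EBIC = D(MLE) + p log n``. The convention is recorded in the report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import CureModelParams, Dataset, ParamTransform, log_likelihood
from .bayes_fit import PosteriorChain, _as_chain_list, posterior_mean_params
from .classical_fit import MLEResult

__all__ = ["ICReport", "deviance", "information_criteria",
           "classical_information_criteria"]


@dataclass
class ICReport:
    dic: float
    eaic: float
    ebic: float
    dbar: float
    pd: float
    n_params: int
    n_obs: int
    convention: str = "posterior"

    def to_frame(self, label: str = "model") -> pd.DataFrame:
        return pd.DataFrame(
            {label: [self.dic, self.eaic, self.ebic]},
            index=["DIC", "EAIC", "EBIC"],
        )


def deviance(params: CureModelParams, data: Dataset) -> float:
    """``D(params) = -2 log L(params; data)``."""
    return -2.0 * log_likelihood(data, params)


def information_criteria(
    chain_or_chains,
    data: Dataset,
    *,
    fixed_theta: float | None = None,
    max_draws: int = 4000,
) -> ICReport:
    """DIC/EAIC/EBIC from a posterior chain (or list of chains).

    ``dbar`` averages the deviance over the post-burn-in, thinned draws
    (subsampled evenly to at most ``max_draws`` evaluations); the plug-in
    deviance uses the posterior mean on the sampling scale.
    """
    chains = _as_chain_list(chain_or_chains)
    pooled = np.vstack([c.kept for c in chains])
    if pooled.shape[0] < 100:
        raise ValueError(f"chain too short ({pooled.shape[0]} kept draws); "
                         "need at least 100 for stable criteria")
    transform = _transform_for_chain(chains[0], data, fixed_theta)
    if pooled.shape[0] > max_draws:
        idx = np.linspace(0, pooled.shape[0] - 1, max_draws).astype(int)
        pooled_eval = pooled[idx]
    else:
        pooled_eval = pooled
    devs = np.array([deviance(transform.unpack(v), data) for v in pooled_eval])
    dbar = float(np.mean(devs))
    d_at_mean = deviance(posterior_mean_params(chains, transform), data)
    p_d = dbar - d_at_mean
    p = transform.n_params
    n = data.n
    return ICReport(
        dic=dbar + p_d, eaic=dbar + 2.0 * p, ebic=dbar + p * np.log(n),
        dbar=dbar, pd=p_d, n_params=p, n_obs=n, convention="posterior",
    )


def classical_information_criteria(result: MLEResult, data: Dataset) -> ICReport:
    """Plug-in criteria for an ML fit: ``dbar := D(MLE)``, ``pd = 0``."""
    d_mle = -2.0 * result.loglik
    p = result.n_params
    n = data.n
    return ICReport(
        dic=d_mle, eaic=d_mle + 2.0 * p, ebic=d_mle + p * np.log(n),
        dbar=d_mle, pd=0.0, n_params=p, n_obs=n,
        convention="plug-in MLE (pd = 0)",
    )


def _transform_for_chain(chain: PosteriorChain, data: Dataset,
                         fixed_theta: float | None) -> ParamTransform:
    transform = ParamTransform.for_dataset(data, fixed_theta=fixed_theta)
    if transform.n_params != chain.draws.shape[1]:
        if fixed_theta is None and "theta" not in chain.param_names:
            raise ValueError("chain was sampled with theta fixed; pass "
                             "fixed_theta to information_criteria")
        raise ValueError("chain dimension does not match the dataset design")
    return transform
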