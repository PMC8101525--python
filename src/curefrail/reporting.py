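"""Cohort descriptives and fitted-model report tables.

Three table shapes are produced:

* a cohort characteristics table (counts and per-covariate cross-tabs by
  event status),
* a short-term (latency) parameter table with estimate / SD / 95%
  interval per inference method,
* a long-term (incidence) table of cure odds ratios and cure
  probabilities per covariate level.

Classical intervals are Wald intervals, transformed where needed (OR =
exp of the coefficient interval; cure probability via the logistic delta
method on the linear predictor). Bayesian intervals are equal-tailed
percentiles of the transformed posterior draws. The two constructions
are not interchangeable and each row records which was used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .model_core import Dataset
from .classical_fit import MLEResult
from .bayes_fit import PosteriorChain, _as_chain_list

__all__ = [
    "CohortSummary",
    "LongTermRow",
    "cohort_summary",
    "odds_ratio_summary",
    "cure_probability_summary",
    "short_term_table",
    "long_term_table",
]

_Z975 = 1.959963984540054


# ---------------------------------------------------------------------------
# Cohort descriptives
# ---------------------------------------------------------------------------


@dataclass
class CohortSummary:
    n_total: int
    n_events: int
    n_censored: int
    event_rate: float
    crosstabs: dict[str, pd.DataFrame]

    def to_frame(self) -> pd.DataFrame:
        rows = [("n_total", self.n_total), ("n_events", self.n_events),
                ("n_censored", self.n_censored), ("event_rate", self.event_rate),
                ("censored_rate", 1.0 - self.event_rate)]
        return pd.DataFrame(rows, columns=["statistic", "value"])


def cohort_summary(data: Dataset) -> CohortSummary:
    """Exact counts, event rate and per-covariate cross-tabs by status."""
    n = data.n
    n_events = data.n_events
    tabs = {}
    status = pd.Series(np.where(data.event == 1, "died", "censored"))
    for j, name in enumerate(data.covariate_names):
        col = pd.Series(data.covariates[:, j])
        tab = pd.crosstab(col, status)
        tab.index.name = name
        tabs[name] = tab
    return CohortSummary(
        n_total=n, n_events=n_events, n_censored=n - n_events,
        event_rate=n_events / n, crosstabs=tabs,
    )


# ---------------------------------------------------------------------------
# Long-term (incidence) summaries
# ---------------------------------------------------------------------------


@dataclass
class LongTermRow:
    variable: str
    level: str
    odds_ratio: float
    or_ci: tuple[float, float]
    survival_probability: float
    sp_ci: tuple[float, float]
    method: str


def _is_mle(fit) -> bool:
    return isinstance(fit, MLEResult)


def _incidence_names(fit) -> list[str]:
    names = (fit.param_names if _is_mle(fit)
             else _as_chain_list(fit)[0].param_names)
    return [nm for nm in names if nm.startswith("incidence:")]


def _resolve_incidence(fit, variable) -> str:
    inc = _incidence_names(fit)
    if isinstance(variable, (int, np.integer)):
        if not 0 <= variable < len(inc):
            raise KeyError(f"incidence covariate index {variable} out of range")
        return inc[int(variable)]
    for nm in inc:
        stripped = nm.removeprefix("incidence:")
        if variable in (nm, stripped, stripped.split(":")[0]):
            return nm
    raise KeyError(f"unknown incidence variable '{variable}' "
                   f"(available: {[s.removeprefix('incidence:') for s in inc]})")


def _coef_draws(fit, name: str) -> np.ndarray:
    chains = _as_chain_list(fit)
    k = chains[0].param_names.index(name)
    return np.concatenate([c.kept[:, k] for c in chains])


def odds_ratio_summary(fit, variable, direction: str = "level-vs-ref") -> LongTermRow:
    """Cure odds ratio for one incidence covariate.

    ``direction="ref-vs-level"`` reports the reciprocal (odds of cure for
    the reference level relative to the named level).
    """
    if direction not in ("level-vs-ref", "ref-vs-level"):
        raise ValueError(f"unknown direction '{direction}'")
    name = _resolve_incidence(fit, variable)
    stripped = name.removeprefix("incidence:")
    var, _, level = stripped.partition(":")
    level = level or "yes"

    if _is_mle(fit):
        coef = fit.estimate[name]
        lo_c, hi_c = fit.ci[name]
        if direction == "ref-vs-level":
            coef, lo_c, hi_c = -coef, -hi_c, -lo_c
        out = LongTermRow(var, level, float(np.exp(coef)),
                          (float(np.exp(lo_c)), float(np.exp(hi_c))),
                          np.nan, (np.nan, np.nan), method="wald")
    else:
        draws = _coef_draws(fit, name)
        if direction == "ref-vs-level":
            draws = -draws
        ors = np.exp(draws)
        out = LongTermRow(var, level, float(np.mean(ors)),
                          (float(np.percentile(ors, 2.5)),
                           float(np.percentile(ors, 97.5))),
                          np.nan, (np.nan, np.nan), method="posterior")
    return out


def cure_probability_summary(fit, covariate_profile):
    """Cure probability pi(x) at a covariate profile (incidence part),
    with a 95% interval.

    Classical: delta method on the linear predictor, interval transformed
    through the logistic link. Bayesian: percentiles of the transformed
    draws. Returns ``(estimate, (low, high))``.
    """
    x = np.atleast_1d(np.asarray(covariate_profile, dtype=float))
    if _is_mle(fit):
        inc = _incidence_names(fit)
        if x.size != len(inc):
            raise ValueError(f"profile has {x.size} entries; the incidence "
                             f"part has {len(inc)} covariates")
        names = fit.param_names
        idx = [names.index("intercept")] + [names.index(nm) for nm in inc]
        a = np.zeros(len(names))
        a[idx[0]] = 1.0
        for xi, k in zip(x, idx[1:]):
            a[k] = xi
        eta = float(a @ fit.vector)
        se_eta = float(np.sqrt(a @ fit.cov @ a))
        return (float(expit(eta)),
                (float(expit(eta - _Z975 * se_eta)),
                 float(expit(eta + _Z975 * se_eta))))
    chains = _as_chain_list(fit)
    names = chains[0].param_names
    inc = [nm for nm in names if nm.startswith("incidence:")]
    if x.size != len(inc):
        raise ValueError(f"profile has {x.size} entries; the incidence part "
                         f"has {len(inc)} covariates")
    pooled = np.vstack([c.kept for c in chains])
    eta = pooled[:, names.index("intercept")].copy()
    for xi, nm in zip(x, inc):
        eta += xi * pooled[:, names.index(nm)]
    pi = expit(eta)
    return (float(np.mean(pi)),
            (float(np.percentile(pi, 2.5)), float(np.percentile(pi, 97.5))))


def long_term_table(fit, data: Dataset) -> pd.DataFrame:
    """Cure odds ratio and cure probability per incidence covariate level
    (all other covariates at reference, i.e. 0)."""
    inc = _incidence_names(fit)
    rows = []
    for j, nm in enumerate(inc):
        stripped = nm.removeprefix("incidence:")
        var, _, level = stripped.partition(":")
        level = level or "yes"
        ref_level = data.reference_levels.get(var, "reference")
        row = odds_ratio_summary(fit, nm)
        profile = np.zeros(len(inc))
        profile[j] = 1.0
        sp, sp_ci = cure_probability_summary(fit, profile)
        sp0, sp0_ci = cure_probability_summary(fit, np.zeros(len(inc)))
        rows.append({"variable": var, "level": level,
                     "odds_ratio": row.odds_ratio,
                     "or_low": row.or_ci[0], "or_high": row.or_ci[1],
                     "cure_probability": sp,
                     "cp_low": sp_ci[0], "cp_high": sp_ci[1],
                     "method": row.method})
        rows.append({"variable": var, "level": ref_level,
                     "odds_ratio": 1.0, "or_low": np.nan, "or_high": np.nan,
                     "cure_probability": sp0,
                     "cp_low": sp0_ci[0], "cp_high": sp0_ci[1],
                     "method": row.method})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Short-term (latency) table
# ---------------------------------------------------------------------------


def _method_columns(fit, label: str) -> pd.DataFrame:
    if _is_mle(fit):
        names = fit.param_names
        est, sd = fit.estimate, fit.se
        ci = fit.ci
    else:
        from .bayes_fit import posterior_summary

        summ = posterior_summary(fit)
        names = summ.param_names
        est, sd, ci = summ.mean, summ.sd, summ.ci95
    keep = [nm for nm in names
            if nm in ("shape", "scale", "theta", "intercept")
            or nm.startswith("latency:")]
    return pd.DataFrame({
        f"{label}_mean": [est[nm] for nm in keep],
        f"{label}_sd": [sd[nm] for nm in keep],
        f"{label}_low": [ci[nm][0] for nm in keep],
        f"{label}_high": [ci[nm][1] for nm in keep],
    }, index=keep)


def short_term_table(classical: MLEResult | None = None,
                     bayesian=None,
                     reference_levels: dict[str, str] | None = None) -> pd.DataFrame:
    """Short-term parameter table: Weibull baseline, frailty, incidence
    intercept and latency coefficients, one column block per inference
    method. Reference covariate levels appear as rows of zeros."""
    if classical is None and bayesian is None:
        raise ValueError("at least one fitted model is required")
    blocks = []
    if classical is not None:
        blocks.append(_method_columns(classical, "classical"))
    if bayesian is not None:
        blocks.append(_method_columns(bayesian, "bayesian"))
    table = pd.concat(blocks, axis=1)
    table.index.name = "parameter"
    if reference_levels:
        zero = {c: (0.0 if c.endswith(("_mean", "_sd", "_low", "_high")) else np.nan)
                for c in table.columns}
        for var, ref in reference_levels.items():
            table.loc[f"latency:{var}:{ref} (reference)"] = zero
    return table


def round_for_display(table: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Rounded copy for human-readable output; machine-readable CSVs keep
    full precision."""
    return table.round(decimals)
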