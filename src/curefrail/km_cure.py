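"""Kaplan-Meier estimation and plateau-based cure-fraction diagnosis.

A nonzero plateau in the Kaplan-Meier curve — the survival estimate
levelling off above zero while censored follow-up continues beyond the
last event — is the standard visual evidence that the cohort contains
long-term survivors and that a cure model is appropriate. Here the
"plateau" is operationalised as the product-limit estimate at the last
event time, together with a check that enough censored observations lie
strictly beyond it (insufficient tail follow-up makes the plateau
uninterpretable).

Estimation is delegated to :class:`lifelines.KaplanMeierFitter`; ties of
events and censorings at the same time follow the usual convention of
events first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = ["KMCurve", "PlateauReport", "km_estimate", "plateau_cure_fraction"]


@dataclass
class KMCurve:
    """Product-limit survival estimate.

    ``times`` are the sorted distinct event times; ``survival`` the step
    function values S(t) at those times; ``at_risk`` and ``n_events`` the
    risk-set sizes and event counts entering each factor. The raw input
    times/events are retained for follow-up checks.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    input_times: np.ndarray
    input_events: np.ndarray

    def survival_at(self, t) -> np.ndarray:
        """Step-function value S(t) (right-continuous; 1 before the first
        event)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        padded = np.concatenate(([1.0], self.survival))
        out = padded[idx]
        return float(out) if np.ndim(t) == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times,
            "survival": self.survival,
            "at_risk": self.at_risk,
            "n_events": self.n_events,
        })

    def write_csv(self, path) -> None:
        """Two-column step-function export (time, survival), with the
        origin point included for plotting."""
        step = pd.DataFrame({
            "time": np.concatenate(([0.0], self.times)),
            "survival": np.concatenate(([1.0], self.survival)),
        })
        step.to_csv(path, index=False)


@dataclass
class PlateauReport:
    """Cure-fraction read-off from the KM tail."""

    cure_estimate: float
    last_event_time: float
    censored_beyond: int
    sufficient_followup: bool
    no_events: bool = False


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    Parameters are the follow-up times (months, >= 0) and 0/1 event
    indicators.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times < 0):
        raise ValueError("negative times")
    if not np.all(np.isin(events, (0, 1))):
        raise ValueError("event indicator must be 0/1")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    mask = table["observed"] > 0
    ev_times = table.index.to_numpy(dtype=float)[mask]
    surv = kmf.survival_function_at_times(ev_times).to_numpy(dtype=float)
    return KMCurve(
        times=ev_times,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=int)[mask],
        n_events=table["observed"].to_numpy(dtype=int)[mask],
        input_times=times.copy(),
        input_events=events.copy(),
    )


def plateau_cure_fraction(curve: KMCurve, min_tail_censored: int = 5) -> PlateauReport:
    """Estimate the cure fraction as the KM value at the last event time.

    ``sufficient_followup`` is True when at least ``min_tail_censored``
    censored observations lie strictly beyond the last event time — a
    pragmatic stand-in for the visual judgement that the curve has reached
    a stable plateau.
    """
    if curve.times.size == 0:
        warnings.warn("no events observed; cure fraction estimate defaults to 1",
                      stacklevel=2)
        tail = int(np.sum(curve.input_events == 0))
        return PlateauReport(
            cure_estimate=1.0,
            last_event_time=0.0,
            censored_beyond=tail,
            sufficient_followup=tail >= min_tail_censored,
            no_events=True,
        )
    t_last = float(curve.times[-1])
    beyond = (curve.input_times > t_last) & (curve.input_events == 0)
    n_beyond = int(np.sum(beyond))
    return PlateauReport(
        cure_estimate=float(curve.survival[-1]),
        last_event_time=t_last,
        censored_beyond=n_beyond,
        sufficient_followup=n_beyond >= min_tail_censored,
    )
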