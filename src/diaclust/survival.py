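"""One-vs-rest Cox models and DerSimonian-Laird random-effects pooling.

Within each cohort, each archetype is contrasted against the other four
with a Cox proportional-hazards model on a single binary covariate
(Efron tie handling, no further adjustment). The per-cohort log hazard
ratios are then pooled across cohorts with the DerSimonian-Laird
random-effects estimator:

    w_i    = 1 / se_i^2                  (fixed-effect weights)
    Q      = sum_i w_i (theta_i - theta_FE)^2
    tau^2  = max(0, (Q - (m - 1)) / (sum w_i - sum w_i^2 / sum w_i))
    w*_i   = 1 / (se_i^2 + tau^2)
    theta  = sum w*_i theta_i / sum w*_i,   SE = (sum w*_i)^(-1/2)

with a two-sided Wald confidence interval and p value on the log scale,
exponentiated for reporting. No Knapp-Hartung adjustment is applied by
default (plain DL Wald intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .data_model import ARCHETYPES
from .endpoint import EndpointResult

__all__ = [
    "HazardEstimate",
    "InestimableError",
    "MetaResult",
    "cox_one_vs_rest",
    "meta_random_effects",
    "survival_table",
]


class InestimableError(RuntimeError):
    """The requested contrast cannot be estimated (e.g. a group without events)."""


@dataclass(frozen=True)
class HazardEstimate:
    """One cohort's one-vs-rest log hazard ratio for one archetype."""

    cohort_id: str
    archetype: str
    theta: float       # log hazard ratio
    se: float
    n: int
    n_events: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")
        if self.n_events > self.n:
            raise ValueError("n_events cannot exceed n")

    @property
    def hr(self) -> float:
        return float(np.exp(self.theta))


@dataclass
class MetaResult:
    """Random-effects pooled summary for one archetype across cohorts."""

    archetype: str
    estimates: list[HazardEstimate] = field(repr=False, default_factory=list)
    q: float = float("nan")
    tau2: float = float("nan")
    theta: float = float("nan")
    se_theta: float = float("nan")
    hr: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p_value: float = float("nan")

    @property
    def n_cohorts(self) -> int:
        return len(self.estimates)


def _endpoint_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        frame = results[["subject_id", "time_days", "event"]].copy()
    else:
        frame = pd.DataFrame({
            "subject_id": [r.subject_id for r in results],
            "time_days": [r.time_days for r in results],
            "event": [r.event for r in results],
        })
    frame["subject_id"] = frame["subject_id"].astype(str)
    return frame


def cox_one_vs_rest(
    results: Sequence[EndpointResult] | pd.DataFrame,
    labels: Mapping[str, str],
    target: str,
    cohort_id: str = "",
) -> HazardEstimate:
    """Cox PH fit of one archetype against the remaining archetypes.

    ``labels`` maps subject_id to archetype; the model has a single binary
    covariate (subject in ``target`` vs not) and uses Efron's method for
    tied event times. Raises :class:`InestimableError` when either group has
    no events.
    """
    frame = _endpoint_frame(results)
    missing = [sid for sid in frame["subject_id"] if sid not in labels]
    if missing:
        raise KeyError(f"archetype label missing for subject(s): {missing[:5]}")
    frame["in_target"] = [
        1.0 if labels[sid] == target else 0.0 for sid in frame["subject_id"]]
    # zero-duration rows carry no partial-likelihood information; nudge to half a day
    frame["duration"] = frame["time_days"].clip(lower=0.5)

    events_target = int(frame.loc[frame.in_target == 1, "event"].sum())
    events_rest = int(frame.loc[frame.in_target == 0, "event"].sum())
    if events_target == 0 or events_rest == 0:
        raise InestimableError(
            f"{cohort_id or 'cohort'}/{target}: no events in "
            f"{'target' if events_target == 0 else 'reference'} group")

    cph = CoxPHFitter()
    cph.fit(frame[["duration", "event", "in_target"]],
            duration_col="duration", event_col="event")
    return HazardEstimate(
        cohort_id=cohort_id,
        archetype=target,
        theta=float(cph.params_["in_target"]),
        se=float(cph.standard_errors_["in_target"]),
        n=len(frame),
        n_events=events_target + events_rest,
    )


def meta_random_effects(
    estimates: Sequence[HazardEstimate],
    alpha: float = 0.05,
    allow_single: bool = False,
) -> MetaResult:
    """DerSimonian-Laird random-effects pooling of per-cohort estimates.

    With ``allow_single=True`` a single estimate passes through unchanged
    (tau^2 = 0, Q = 0); otherwise at least two estimates are required.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("no estimates to pool")
    if len(estimates) == 1 and not allow_single:
        raise ValueError("need >= 2 estimates (or allow_single=True)")
    archetypes = {e.archetype for e in estimates}
    if len(archetypes) > 1:
        raise ValueError(f"estimates mix archetypes {sorted(archetypes)}")

    theta = np.array([e.theta for e in estimates])
    se = np.array([e.se for e in estimates])
    w = 1.0 / se**2
    theta_fe = float((w * theta).sum() / w.sum())
    q = float((w * (theta - theta_fe) ** 2).sum())
    m = len(estimates)
    if m > 1:
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - (m - 1)) / denom)
    else:
        tau2 = 0.0
    w_star = 1.0 / (se**2 + tau2)
    pooled = float((w_star * theta).sum() / w_star.sum())
    se_pooled = float(w_star.sum() ** -0.5)
    z = stats.norm.ppf(1 - alpha / 2)
    p = float(2 * stats.norm.sf(abs(pooled / se_pooled)))
    return MetaResult(
        archetype=estimates[0].archetype,
        estimates=estimates,
        q=q,
        tau2=tau2,
        theta=pooled,
        se_theta=se_pooled,
        hr=float(np.exp(pooled)),
        ci_low=float(np.exp(pooled - z * se_pooled)),
        ci_high=float(np.exp(pooled + z * se_pooled)),
        p_value=p,
    )


def survival_table(estimates: Sequence[HazardEstimate],
                   min_cohorts: int = 2) -> pd.DataFrame:
    """Pooled HR (95% CI) and p per archetype, in reporting shape.

    Archetypes estimated in fewer than ``min_cohorts`` cohorts are marked
    inestimable (NaN row). Columns: archetype, hr, ci_low, ci_high, p,
    tau2, q, n_cohorts.
    """
    by_archetype: dict[str, list[HazardEstimate]] = {}
    for e in estimates:
        by_archetype.setdefault(e.archetype, []).append(e)

    rows = []
    for archetype in ARCHETYPES:
        ests = by_archetype.get(archetype, [])
        if len(ests) < min_cohorts:
            rows.append({"archetype": archetype, "hr": float("nan"),
                         "ci_low": float("nan"), "ci_high": float("nan"),
                         "p": float("nan"), "tau2": float("nan"),
                         "q": float("nan"), "n_cohorts": len(ests)})
            continue
        meta = meta_random_effects(ests)
        rows.append({"archetype": archetype, "hr": meta.hr,
                     "ci_low": meta.ci_low, "ci_high": meta.ci_high,
                     "p": meta.p_value, "tau2": meta.tau2, "q": meta.q,
                     "n_cohorts": meta.n_cohorts})
    return pd.DataFrame(rows)
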