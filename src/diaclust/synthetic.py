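"""Synthetic multi-cohort generator with known five-cluster structure.

Real diabetes-register data of this kind are held by cohort steering
committees and are not public, so every downstream stage (clustering,
archetype naming, cross-cohort validation, endpoint derivation, survival
meta-analysis) is exercised against simulated cohorts whose ground truth is
known.

Cross-sectional structure: a five-component mixture per sex on a transformed
scale (age linear and truncated to [35, 95]; BMI, HbA1c, C-peptide and HDL
log-normal, so all positive-scale variables are strictly positive). The
component profiles encode the five archetypes: SIDD (high HbA1c, younger),
SIRD (high C-peptide, older), MOD (high BMI, youngest), MD (no extreme
characteristics) and MDH (older, high HDL). Component weights default to
(0.15, 0.15, 0.20, 0.32, 0.18), inside the observed cohort ranges, and the
marginal medians approximate the published cohort tables (BMI ~30 kg/m^2,
HbA1c ~52-57 mmol/mol).

Longitudinal structure: annual visits with a per-cluster HbA1c setpoint and
drift, a deterministic oral-therapy escalation ladder driven by the HbA1c
path, and a stochastic insulin-initiation time from a proportional-hazards
model with per-cluster log hazards. Default log hazards are calibrated so
that the *one-vs-rest* hazard ratio of each cluster equals the published
progression contrasts (SIDD 3.40, SIRD 0.59, MOD 1.17, MD 0.81, MDH 0.44);
see :func:`calibrate_cluster_hazards`.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .data_model import ARCHETYPES, Cohort, SubjectRecord
from .endpoint import Hba1cMeasurement, LongitudinalRecord, PrescriptionInterval

__all__ = [
    "DEFAULT_ONE_VS_REST_HR",
    "FollowupConfig",
    "MixtureConfig",
    "TruthLabels",
    "calibrate_cluster_hazards",
    "default_mixture_config",
    "simulate_cross_section",
    "simulate_followup",
]

#: default per-cluster one-vs-rest hazard-ratio contrasts for progression to
#: insulin requirement (SIDD, SIRD, MOD, MD, MDH)
DEFAULT_ONE_VS_REST_HR = (3.40, 0.59, 1.17, 0.81, 0.44)

_SEXES = ("male", "female")

# archetype profiles on the natural scale (age yr, BMI kg/m^2, HbA1c
# mmol/mol, C-peptide nmol/l, HDL mmol/l)
_NATURAL_PROFILES = {
    "SIDD": (55.0, 28.0, 85.0, 0.75, 1.05),
    "SIRD": (66.0, 31.0, 50.0, 2.30, 1.00),
    "MOD": (50.0, 38.0, 52.0, 1.50, 1.00),
    "MD": (61.0, 29.0, 51.0, 1.05, 1.15),
    "MDH": (68.0, 27.5, 50.0, 0.95, 1.70),
}

# within-component standard deviations on the transformed scale
# (age in years; the rest on the log scale)
_TRANSFORMED_SD = np.array([5.0, 0.09, 0.09, 0.18, 0.08])

# small additive sex offsets on the transformed scale, emulating known sex
# differences in HDL / C-peptide / BMI
_SEX_OFFSETS = {
    "male": np.array([0.0, -0.010, 0.0, 0.03, -0.05]),
    "female": np.array([0.0, 0.015, 0.0, -0.04, 0.07]),
}

_AGE_BOUNDS = (35.0, 95.0)
_BASE_DIAGNOSIS_DATE = datetime.date(2006, 1, 1)

_ORAL_LADDER = ("metformin", "sulfonylurea", "dpp4_inhibitor")


def _transformed_mean(natural: tuple[float, ...]) -> np.ndarray:
    age, bmi, hba1c, cpep, hdl = natural
    return np.array([age, np.log(bmi), np.log(hba1c), np.log(cpep), np.log(hdl)])


@dataclass
class TruthLabels:
    """Ground-truth component index and archetype name per generated subject."""

    components: dict[str, int]
    archetypes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.archetypes:
            self.archetypes = {
                sid: ARCHETYPES[c] for sid, c in self.components.items()}

    def component_of(self, subject_id: str) -> int:
        return self.components[subject_id]

    def archetype_of(self, subject_id: str) -> str:
        return self.archetypes[subject_id]

    def __len__(self) -> int:
        return len(self.components)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": list(self.components),
            "component": [self.components[s] + 1 for s in self.components],
            "archetype": [self.archetypes[s] for s in self.components],
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TruthLabels":
        frame = pd.read_csv(path, dtype={"subject_id": str})
        return cls(
            components={r.subject_id: int(r.component) - 1 for r in frame.itertuples()},
            archetypes={r.subject_id: r.archetype for r in frame.itertuples()},
        )


@dataclass
class MixtureConfig:
    """Five-component, per-sex mixture on the transformed scale.

    ``means[sex]`` is a (5 components x 5 variables) matrix on the
    transformed scale and ``covariances[sex]`` a (5, 5, 5) stack of
    symmetric positive-definite matrices. ``separation`` scales each
    component mean's offset from the weighted mixture centre, so larger
    values give better-separated clusters without moving the overall centre.
    """

    n_subjects: int = 3000
    seed: int = 0
    weights: tuple[float, ...] = (0.15, 0.15, 0.20, 0.32, 0.18)
    separation: float = 1.0
    male_fraction: float = 0.58
    means: dict[str, np.ndarray] | None = None
    covariances: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be non-negative and sum to 1")
        if self.means is None:
            base = np.stack([_transformed_mean(_NATURAL_PROFILES[a]) for a in ARCHETYPES])
            self.means = {sex: base + _SEX_OFFSETS[sex] for sex in _SEXES}
        if self.covariances is None:
            cov = np.diag(_TRANSFORMED_SD ** 2)
            self.covariances = {sex: np.stack([cov] * len(ARCHETYPES)) for sex in _SEXES}
        for sex in _SEXES:
            for c, cov in enumerate(self.covariances[sex]):
                if not np.allclose(cov, cov.T):
                    raise ValueError(f"covariance for {sex}/component {c} not symmetric")
                try:
                    np.linalg.cholesky(cov)
                except np.linalg.LinAlgError as exc:
                    raise ValueError(
                        f"covariance for {sex}/component {c} not positive definite") from exc


def default_mixture_config(n_subjects: int = 3000, seed: int = 0,
                           **overrides) -> MixtureConfig:
    """The study-default mixture, optionally with field overrides."""
    return MixtureConfig(n_subjects=n_subjects, seed=seed, **overrides)


def calibrate_cluster_hazards(
    one_vs_rest_hr: tuple[float, ...] = DEFAULT_ONE_VS_REST_HR,
    weights: tuple[float, ...] = (0.15, 0.15, 0.20, 0.32, 0.18),
) -> np.ndarray:
    """Per-cluster log hazards whose one-vs-rest ratios match given targets.

    A one-vs-rest hazard ratio compares cluster ``c`` with the weighted
    average of the remaining clusters, so target ratios ``H_c`` translate to
    relative hazards ``x_c`` through ``x_c = H_c * sum_{j != c} w_j x_j /
    (1 - w_c)``. Up to scale the hazards have one degree of freedom fewer
    than the number of ratio equations, and published ratios need not be
    jointly consistent with any weight vector, so the system is solved in
    weighted least squares on the log scale: the most extreme contrast (the
    headline fast-progressing cluster) is matched to numerical precision
    and the small residual inconsistency is spread evenly over the other
    clusters, which preserves every ordering margin. Scale is fixed by
    ``sum_c w_c x_c = 1``; the result is deterministic.
    """
    h = np.asarray(one_vs_rest_hr, dtype=float)
    w = np.asarray(weights, dtype=float)
    if h.shape != w.shape:
        raise ValueError("one_vs_rest_hr and weights must have equal length")
    resid_weight = np.ones_like(h)
    resid_weight[int(np.argmax(np.abs(np.log(h))))] = 1e3  # pin the extreme contrast

    def residuals(u: np.ndarray) -> np.ndarray:
        x = np.exp(u)
        total = float(w @ x)
        rest = (total - w * x) / (1.0 - w)
        ratio_resid = resid_weight * (np.log(x) - np.log(rest) - np.log(h))
        return np.concatenate([ratio_resid, [total - 1.0]])

    sol = least_squares(residuals, x0=np.log(h), method="lm", xtol=1e-14, ftol=1e-14)
    beta = sol.x - np.log(w @ np.exp(sol.x))  # exact renormalisation
    return beta


@dataclass
class FollowupConfig:
    """Longitudinal follow-up generator settings.

    Per-cluster vectors are ordered (SIDD, SIRD, MOD, MD, MDH). The HbA1c
    path is ``setpoint + drift * years + noise`` (mmol/mol), reflecting
    treated glycaemia that deteriorates slowly; oral-therapy escalation is a
    deterministic state machine on that path (one extra class whenever a
    visit value exceeds ``escalation_threshold``, up to ``max_oral_classes``)
    so only insulin initiation is stochastic. ``cluster_log_hazards=None``
    uses :func:`calibrate_cluster_hazards` on ``one_vs_rest_hr``/``weights``.
    """

    visit_interval_days: int = 365
    max_followup_years: float = 10.0
    hba1c_setpoint: tuple[float, ...] = (51.0, 47.0, 49.0, 47.0, 44.0)
    hba1c_drift: tuple[float, ...] = (0.7, 0.45, 0.6, 0.4, 0.25)  # mmol/mol per year
    setpoint_sd: float = 4.0
    measurement_sd: float = 3.0
    escalation_threshold: float = 58.0
    max_oral_classes: int = 3
    baseline_hazard: float = 0.02  # insulin initiations per person-year
    one_vs_rest_hr: tuple[float, ...] = DEFAULT_ONE_VS_REST_HR
    weights: tuple[float, ...] = (0.15, 0.15, 0.20, 0.32, 0.18)
    cluster_log_hazards: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_followup_years <= 0:
            raise ValueError("max_followup_years must be positive")
        if self.baseline_hazard < 0:
            raise ValueError("baseline_hazard must be non-negative")

    def resolved_log_hazards(self) -> np.ndarray:
        if self.cluster_log_hazards is not None:
            return np.asarray(self.cluster_log_hazards, dtype=float)
        return calibrate_cluster_hazards(self.one_vs_rest_hr, self.weights)


def _sample_component(rng: np.random.Generator, mean: np.ndarray,
                      cov: np.ndarray, n: int) -> np.ndarray:
    """Draw n points, redrawing rows whose age falls outside [35, 95]."""
    chol = np.linalg.cholesky(cov)
    out = mean + rng.standard_normal((n, mean.size)) @ chol.T
    lo, hi = _AGE_BOUNDS
    for _ in range(100):
        bad = (out[:, 0] < lo) | (out[:, 0] > hi)
        if not bad.any():
            break
        out[bad] = mean + rng.standard_normal((int(bad.sum()), mean.size)) @ chol.T
    np.clip(out[:, 0], lo, hi, out=out[:, 0])
    return out


def simulate_cross_section(config: MixtureConfig, cohort_id: str,
                           ) -> tuple[Cohort, TruthLabels]:
    """Generate one cross-sectional cohort plus its ground-truth labels.

    Reproducible given ``config.seed``; all positive-scale variables are
    strictly positive by construction (log-scale sampling).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    weights = np.asarray(config.weights, dtype=float)
    components = rng.choice(len(ARCHETYPES), size=n, p=weights)
    male = rng.random(n) < config.male_fraction

    values = np.empty((n, 5))
    for sex, sex_mask in (("male", male), ("female", ~male)):
        means = config.means[sex]
        centre = weights @ means
        for c in range(len(ARCHETYPES)):
            mask = sex_mask & (components == c)
            if not mask.any():
                continue
            mean_eff = centre + config.separation * (means[c] - centre)
            values[mask] = _sample_component(
                rng, mean_eff, config.covariances[sex][c], int(mask.sum()))

    delay_days = rng.integers(14, 701, size=n)
    diag_offset = rng.integers(0, 3653, size=n)

    subjects: list[SubjectRecord] = []
    comp_map: dict[str, int] = {}
    for i in range(n):
        sid = f"{cohort_id}-{i:05d}"
        age_visit = float(values[i, 0])
        diagnosis = _BASE_DIAGNOSIS_DATE + datetime.timedelta(days=int(diag_offset[i]))
        first_visit = diagnosis + datetime.timedelta(days=int(delay_days[i]))
        subjects.append(SubjectRecord(
            subject_id=sid,
            cohort_id=cohort_id,
            sex="male" if male[i] else "female",
            age_at_diagnosis=max(35.0, age_visit - delay_days[i] / 365.25),
            age_at_first_visit=age_visit,
            bmi=float(np.exp(values[i, 1])),
            hba1c=float(np.exp(values[i, 2])),
            c_peptide=float(np.exp(values[i, 3])),
            hdl=float(np.exp(values[i, 4])),
            gad_positive=False,
            diagnosis_date=diagnosis,
            first_visit_date=first_visit,
        ))
        comp_map[sid] = int(components[i])
    return Cohort(cohort_id, subjects), TruthLabels(components=comp_map)


def _oral_prescriptions(subject_id: str, class_starts: Mapping[str, datetime.date],
                        censor: datetime.date) -> list[PrescriptionInterval]:
    """Yearly 300-day scripts per class (65-day refill gaps merge away)."""
    out = []
    for drug_class, start in class_starts.items():
        cursor = start
        while cursor <= censor:
            end = min(cursor + datetime.timedelta(days=300), censor)
            out.append(PrescriptionInterval(subject_id, drug_class, False, cursor, end))
            cursor = cursor + datetime.timedelta(days=365)
    return out


def simulate_followup(
    cohort: Cohort,
    labels: TruthLabels,
    config: FollowupConfig,
    return_truth: bool = False,
):
    """Simulate longitudinal records for every subject of a cohort.

    Returns a list of :class:`LongitudinalRecord`; with ``return_truth=True``
    additionally returns a dict mapping subject_id to the simulated insulin
    initiation date (None when no initiation occurred during follow-up).
    Reproducible given ``config.seed``.
    """
    missing = [s.subject_id for s in cohort if s.subject_id not in labels.components]
    if missing:
        raise KeyError(f"labels missing for subject(s): {', '.join(missing[:5])}")

    rng = np.random.default_rng(config.seed)
    beta = config.resolved_log_hazards()
    n = len(cohort)
    comp = np.array([labels.component_of(s.subject_id) for s in cohort])
    rates = config.baseline_hazard * np.exp(beta)[comp]
    with np.errstate(divide="ignore"):
        event_years = np.where(
            rates > 0, rng.exponential(1.0, size=n) / np.where(rates > 0, rates, 1.0),
            np.inf)
    setpoints = (np.asarray(config.hba1c_setpoint)[comp]
                 + rng.normal(0.0, config.setpoint_sd, size=n))
    drifts = np.asarray(config.hba1c_drift)[comp]

    followup_days = int(round(config.max_followup_years * 365.25))
    records: list[LongitudinalRecord] = []
    insulin_truth: dict[str, datetime.date | None] = {}

    for i, subj in enumerate(cohort):
        sid = subj.subject_id
        diagnosis = subj.diagnosis_date
        censor = diagnosis + datetime.timedelta(days=followup_days)

        # visit schedule and HbA1c path
        visit_dates = []
        d = subj.first_visit_date
        while d <= censor:
            visit_dates.append(d)
            d = d + datetime.timedelta(days=config.visit_interval_days)
        years = np.array([(v - subj.first_visit_date).days / 365.25 for v in visit_dates])
        noise = rng.normal(0.0, config.measurement_sd, size=len(visit_dates))
        hba1c_values = np.maximum(20.0, setpoints[i] + drifts[i] * years + noise)

        measurements = [
            Hba1cMeasurement(sid, v, float(x))
            for v, x in zip(visit_dates, hba1c_values)
        ]

        # deterministic oral escalation ladder driven by the HbA1c path
        class_starts: dict[str, datetime.date] = {}
        if visit_dates:
            class_starts[_ORAL_LADDER[0]] = visit_dates[0]
        for v, x in zip(visit_dates, hba1c_values):
            if (x > config.escalation_threshold
                    and len(class_starts) < min(config.max_oral_classes, len(_ORAL_LADDER))):
                class_starts[_ORAL_LADDER[len(class_starts)]] = v
        prescriptions = _oral_prescriptions(sid, class_starts, censor)

        # stochastic insulin initiation (proportional hazards on true cluster)
        event_days = event_years[i] * 365.25
        insulin_date = None
        if np.isfinite(event_days) and event_days <= followup_days:
            insulin_date = diagnosis + datetime.timedelta(days=int(round(event_days)))
            if insulin_date < censor:
                prescriptions.append(PrescriptionInterval(
                    sid, "insulin", True, insulin_date, censor))
            else:
                insulin_date = None
        insulin_truth[sid] = insulin_date

        records.append(LongitudinalRecord(
            subject_id=sid, time_zero=diagnosis, censor_date=censor,
            prescriptions=prescriptions, hba1c=measurements))

    if return_truth:
        return records, insulin_truth
    return records


def with_separation(config: MixtureConfig, separation: float) -> MixtureConfig:
    """Copy of a mixture config at a different separation level."""
    return replace(config, separation=separation)
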