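"""Archetype naming, cross-cohort assignment and agreement statistics.

The five-cluster solution is named by a sequential argmax over sex-averaged
z-centroids: the cluster with the highest HbA1c z-profile is SIDD (severe
insulin-deficient); among the rest, highest C-peptide is SIRD (severe
insulin-resistant); then highest BMI is MOD (mild obesity-related); then
highest HDL-cholesterol is MDH (mild with high HDL); the remaining cluster
is MD (mild). Cross-cohort stability is quantified by re-assigning one
cohort's subjects with another cohort's model (scaler + nearest centroid)
and comparing against the cohort's own clusters via a confusion matrix with
per-archetype sensitivity and specificity (exact Clopper-Pearson CIs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from statsmodels.stats.proportion import proportion_confint

from .clustering import ClusterModel
from .data_model import ARCHETYPES, CLUSTERING_VARIABLES, Cohort

__all__ = [
    "ArchetypeNaming",
    "ConfusionResult",
    "assign",
    "compare_to_external",
    "cross_validate",
    "name_archetypes",
]

# variable that defines each archetype, in naming priority order
_NAMING_SEQUENCE = (
    ("hba1c", "SIDD"),
    ("c_peptide", "SIRD"),
    ("bmi", "MOD"),
    ("hdl", "MDH"),
)


@dataclass
class ArchetypeNaming:
    """Cluster-index -> archetype map plus the z-profile evidence."""

    mapping: dict[int, str]
    evidence: np.ndarray          # (k, 5) sex-averaged z-centroids
    variables: tuple[str, ...] = CLUSTERING_VARIABLES


@dataclass
class ConfusionResult:
    """Matched confusion matrix with per-class sensitivity/specificity.

    Rows are reference labels, columns predicted labels after alignment;
    ``metrics`` carries one row per reference class with Clopper-Pearson 95%
    confidence bounds.
    """

    reference_labels: tuple[str, ...]
    predicted_labels: tuple[str, ...]
    matrix: np.ndarray
    metrics: pd.DataFrame
    n: int

    def __post_init__(self) -> None:
        if np.any(self.matrix < 0):
            raise ValueError("confusion counts must be non-negative")
        if int(self.matrix.sum()) != self.n:
            raise ValueError("confusion counts do not sum to n")

    def sensitivity(self, label: str) -> float:
        row = self.metrics.set_index("archetype")
        return float(row.loc[label, "sensitivity"])

    def specificity(self, label: str) -> float:
        row = self.metrics.set_index("archetype")
        return float(row.loc[label, "specificity"])

    def counts_frame(self) -> pd.DataFrame:
        rows = []
        for i, ref in enumerate(self.reference_labels):
            for j, pred in enumerate(self.predicted_labels):
                rows.append({"reference": ref, "predicted": pred,
                             "count": int(self.matrix[i, j])})
        return pd.DataFrame(rows)

    def to_json(self, path=None) -> str:
        payload = {
            "n": self.n,
            "reference_labels": list(self.reference_labels),
            "predicted_labels": list(self.predicted_labels),
            "matrix": self.matrix.astype(int).tolist(),
            "metrics": self.metrics.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def name_archetypes(model: ClusterModel, attach: bool = True) -> ArchetypeNaming:
    """Name the clusters of a five-cluster model by their z-profiles.

    Sequential argmax over the sex-averaged z-centroids (see module
    docstring); defined only for k = 5, where it is a bijection onto the
    five archetypes. The evidence matrix is retained for audit.
    """
    if model.k != len(ARCHETYPES):
        raise ValueError(f"archetype naming requires k=5, got k={model.k}")
    evidence = np.mean([model.centroids[sex] for sex in model.centroids], axis=0)
    var_index = {v: i for i, v in enumerate(CLUSTERING_VARIABLES)}

    mapping: dict[int, str] = {}
    remaining = set(range(model.k))
    for variable, archetype in _NAMING_SEQUENCE:
        column = evidence[:, var_index[variable]]
        candidates = sorted(remaining)
        best = candidates[int(np.argmax(column[candidates]))]
        mapping[best] = archetype
        remaining.discard(best)
    mapping[remaining.pop()] = "MD"

    naming = ArchetypeNaming(mapping=mapping, evidence=evidence)
    if attach:
        model.archetypes = dict(mapping)
    return naming


def assign(cohort: Cohort, model: ClusterModel) -> dict[str, int]:
    """Assign every complete-case subject to the nearest model centroid.

    Subjects are standardized with the *model's* per-sex scaler (the model
    is a self-contained classifier) and labelled by smallest squared
    Euclidean distance; exact ties go to the lowest cluster index.
    """
    labels: dict[str, int] = {}
    for subj in cohort:
        if not subj.has_complete_clustering_variables:
            raise ValueError(
                f"subject {subj.subject_id} has incomplete clustering variables")
        if subj.sex not in model.scalers:
            raise ValueError(
                f"model for cohort {model.cohort_id} has no scaler for sex "
                f"{subj.sex!r}")
        z = model.scalers[subj.sex].transform(np.array(subj.clustering_values()))
        d2 = ((model.centroids[subj.sex] - z) ** 2).sum(axis=1)
        labels[subj.subject_id] = int(np.argmin(d2))
    return labels


def _confusion_from_pairs(
    ref: Mapping[str, str], pred: Mapping[str, str],
    row_labels: tuple[str, ...], col_labels: tuple[str, ...],
    alpha: float = 0.05,
) -> ConfusionResult:
    subjects = list(ref)
    n = len(subjects)
    row_index = {lab: i for i, lab in enumerate(row_labels)}
    col_index = {lab: j for j, lab in enumerate(col_labels)}
    matrix = np.zeros((len(row_labels), len(col_labels)), dtype=int)
    for sid in subjects:
        matrix[row_index[ref[sid]], col_index[pred[sid]]] += 1

    rows = []
    for lab in row_labels:
        i = row_index[lab]
        tp = int(matrix[i, col_index[lab]]) if lab in col_index else 0
        fn = int(matrix[i].sum()) - tp
        fp = (int(matrix[:, col_index[lab]].sum()) - tp) if lab in col_index else 0
        tn = n - tp - fn - fp
        sens_n, spec_n = tp + fn, tn + fp
        sens = tp / sens_n if sens_n else float("nan")
        spec = tn / spec_n if spec_n else float("nan")
        s_lo, s_hi = (proportion_confint(tp, sens_n, alpha=alpha, method="beta")
                      if sens_n else (float("nan"), float("nan")))
        p_lo, p_hi = (proportion_confint(tn, spec_n, alpha=alpha, method="beta")
                      if spec_n else (float("nan"), float("nan")))
        rows.append({
            "archetype": lab,
            "sensitivity": sens, "sens_ci_low": float(s_lo), "sens_ci_high": float(s_hi),
            "specificity": spec, "spec_ci_low": float(p_lo), "spec_ci_high": float(p_hi),
            "n_reference": sens_n,
        })
    return ConfusionResult(
        reference_labels=row_labels, predicted_labels=col_labels,
        matrix=matrix, metrics=pd.DataFrame(rows), n=n)


def cross_validate(cohort_a: Cohort, model_a: ClusterModel,
                   model_b: ClusterModel) -> ConfusionResult:
    """Agreement between a cohort's own clusters and another model's.

    Reference labels come from assigning cohort A with its own model A,
    predictions from assigning the same subjects with model B; columns are
    aligned through the archetype names of the two models, which makes the
    result invariant to either model's internal cluster numbering. Both
    models must be named (see :func:`name_archetypes`).
    """
    if model_a.archetypes is None or model_b.archetypes is None:
        raise ValueError("both models must carry archetype names")
    if model_a.k != model_b.k:
        raise ValueError("models must share k")
    if model_a.variables != model_b.variables:
        raise ValueError("models must share variable order")
    ref_raw = assign(cohort_a, model_a)
    pred_raw = assign(cohort_a, model_b)
    ref = {sid: model_a.archetypes[c] for sid, c in ref_raw.items()}
    pred = {sid: model_b.archetypes[c] for sid, c in pred_raw.items()}
    return _confusion_from_pairs(ref, pred, ARCHETYPES, ARCHETYPES)


def compare_to_external(
    predicted: Mapping[str, str],
    external: Mapping[str, str],
    merge: set[str] | None = None,
) -> ConfusionResult:
    """Compare predicted archetypes against an external reference labelling.

    ``merge`` pools a set of predicted archetypes into one class before the
    confusion is computed (e.g. pooling the two mild clusters against a
    single external mild-age-related class). When the two label vocabularies
    differ, predicted classes are aligned to external classes by
    maximum-overlap matching; identical names are matched directly.
    """
    missing = sorted(set(external) ^ set(predicted))
    if missing:
        raise ValueError(f"label sets disagree on subject(s): {', '.join(missing[:10])}")

    if merge:
        merged_name = "+".join(a for a in ARCHETYPES if a in merge)
        if not merged_name:
            merged_name = "+".join(sorted(merge))
        predicted = {
            sid: merged_name if lab in merge else lab
            for sid, lab in predicted.items()
        }

    row_labels = tuple(dict.fromkeys(external.values()))
    col_labels = tuple(dict.fromkeys(predicted.values()))

    if set(row_labels) != set(col_labels):
        # overlap-maximising alignment: rename each matched predicted class
        # to the external class it best covers
        counts = np.zeros((len(row_labels), len(col_labels)))
        ri = {lab: i for i, lab in enumerate(row_labels)}
        ci = {lab: j for j, lab in enumerate(col_labels)}
        for sid, ext_lab in external.items():
            counts[ri[ext_lab], ci[predicted[sid]]] += 1
        size = max(len(row_labels), len(col_labels))
        padded = np.zeros((size, size))
        padded[:len(row_labels), :len(col_labels)] = counts
        rows, cols = linear_sum_assignment(-padded)
        rename = {}
        for r, c in zip(rows, cols):
            if r < len(row_labels) and c < len(col_labels) and padded[r, c] > 0:
                rename[col_labels[c]] = row_labels[r]
        predicted = {sid: rename.get(lab, lab) for sid, lab in predicted.items()}
        col_labels = tuple(dict.fromkeys(
            list(row_labels) + [l for l in predicted.values() if l not in row_labels]))

    else:
        col_labels = row_labels

    return _confusion_from_pairs(external, predicted, row_labels, col_labels)
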