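"""Classification-agreement statistics for pollen reading sessions.

Implements the evaluation summary of a two-expert, two-modality study:
per-evaluator and pooled accuracy, raw and row-normalised confusion
matrices, per-class F1 scores, and Cohen's κ for inter-observer and
inter-modality agreement,

    κ = (p_o − p_e) / (1 − p_e),

with p_o the observed agreement fraction and p_e the chance agreement
expected from the two raters' marginal label frequencies.  Percentages are
rounded half-up to one decimal and F1 to three decimals, matching how such
tables are conventionally printed; pooled statistics are always computed
from pooled counts, never by averaging already-rounded percentages
((97.9 + 93.8)/2 = 95.85, whereas the pooled 92/96 prints as 95.8).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, InvalidArgumentError

__all__ = [
    "POLLEN_CLASSES", "EvaluationRecord", "ConfusionMatrix", "AgreementResult",
    "accuracy_percent", "pooled_accuracy", "build_confusion", "per_class_f1",
    "cohen_kappa", "summarize_study", "records_to_dataframe",
    "records_from_dataframe",
]

#: The closed label set, in fixed display order.
POLLEN_CLASSES: tuple[str, ...] = (
    "timothy_grass", "common_ragweed", "silver_birch",
    "common_alder", "olive_tree", "hazel",
)


@dataclass(frozen=True)
class EvaluationRecord:
    """One reading: an evaluator assigns a species to one image."""

    image_id: str
    modality: str
    evaluator: str
    true_species: str
    assigned_species: str


@dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = assigned class."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def normalized(self) -> np.ndarray:
        """Row-stochastic matrix; empty rows become all zeros (with a warning)."""
        row_sums = self.counts.sum(axis=1, keepdims=True)
        empty = row_sums[:, 0] == 0
        if empty.any():
            warnings.warn("confusion matrix has empty true-class rows; "
                          "normalised rows set to zero", stacklevel=2)
        safe = np.where(row_sums == 0, 1, row_sums)
        out = self.counts / safe
        out[empty] = 0.0
        return out


@dataclass
class AgreementResult:
    """Cohen's κ with its observed/expected agreement components."""

    kappa: float
    observed_agreement: float
    expected_agreement: float
    n_pairs: int


def round_half_up(value, decimals: int) -> float:
    """Round half away from zero at the given number of decimals."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def _ratio_percent(numerator: int, denominator: int) -> float:
    """100·num/den rounded half-up to one decimal, exactly in Decimal."""
    val = Decimal(100 * numerator) / Decimal(denominator)
    return float(val.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def accuracy_percent(records: Sequence[EvaluationRecord]) -> float:
    """Percent of records whose assigned species equals the true species."""
    records = list(records)
    if not records:
        raise DegenerateInputError("accuracy of an empty record set is undefined")
    correct = sum(r.assigned_species == r.true_species for r in records)
    return _ratio_percent(correct, len(records))


def pooled_accuracy(record_sets: Iterable[Sequence[EvaluationRecord]]) -> float:
    """Accuracy over the union of several record sets, from pooled counts."""
    correct = total = 0
    for records in record_sets:
        for r in records:
            total += 1
            correct += r.assigned_species == r.true_species
    if total == 0:
        raise DegenerateInputError("pooled accuracy of empty record sets is undefined")
    return _ratio_percent(correct, total)


def build_confusion(records: Sequence[EvaluationRecord], normalise: bool = False,
                    classes: Sequence[str] = POLLEN_CLASSES):
    """Aggregate records into a confusion matrix (counts or row-stochastic)."""
    records = list(records)
    if not records:
        raise DegenerateInputError("cannot build a confusion matrix from no records")
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for r in records:
        try:
            counts[index[r.true_species], index[r.assigned_species]] += 1
        except KeyError as exc:
            raise InvalidArgumentError(f"unknown class label {exc.args[0]!r}") from exc
    cm = ConfusionMatrix(classes=classes, counts=counts)
    return cm.normalized() if normalise else cm


def per_class_f1(cm: ConfusionMatrix) -> dict[str, float]:
    """Per-class F1 = 2TP/(2TP+FP+FN), three decimals; empty classes → 0."""
    out: dict[str, float] = {}
    col_sums = cm.counts.sum(axis=0)
    row_sums = cm.counts.sum(axis=1)
    for i, cls in enumerate(cm.classes):
        tp = int(cm.counts[i, i])
        fp = int(col_sums[i] - tp)
        fn = int(row_sums[i] - tp)
        denom = 2 * tp + fp + fn
        if denom == 0:
            warnings.warn(f"class {cls!r} absent from records; F1 set to 0",
                          stacklevel=2)
            out[cls] = 0.0
        else:
            out[cls] = float((Decimal(2 * tp) / Decimal(denom))
                             .quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))
    return out


def cohen_kappa(assignments_a: Sequence[str],
                assignments_b: Sequence[str]) -> AgreementResult:
    """Chance-corrected agreement between two aligned label vectors.

    p_e is computed from the product of the raters' marginal label
    proportions.  When p_e = 1 (both raters constant), κ is 1 if the
    raters agree everywhere and undefined otherwise.
    """
    a = list(assignments_a)
    b = list(assignments_b)
    if len(a) != len(b):
        raise InvalidArgumentError("label vectors must have equal length")
    if not a:
        raise InvalidArgumentError("label vectors must be non-empty")
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    labels = sorted(set(a) | set(b))
    p_e = sum((a.count(c) / n) * (b.count(c) / n) for c in labels)
    if p_e >= 1.0:
        if p_o == 1.0:
            return AgreementResult(1.0, p_o, p_e, n)
        raise DegenerateInputError(
            "kappa undefined: expected agreement is 1 but observed is not")
    kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementResult(kappa, p_o, p_e, n)


def records_to_dataframe(records: Sequence[EvaluationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records],
                        columns=["image_id", "modality", "evaluator",
                                 "true_species", "assigned_species"])


def records_from_dataframe(df: pd.DataFrame) -> list[EvaluationRecord]:
    required = ["image_id", "modality", "evaluator", "true_species",
                "assigned_species"]
    for col in required:
        if col not in df.columns:
            raise InvalidArgumentError(f"records are missing column {col!r}")
    return [EvaluationRecord(str(r.image_id), str(r.modality), str(r.evaluator),
                             str(r.true_species), str(r.assigned_species))
            for r in df.itertuples(index=False)]


def _aligned_labels(df: pd.DataFrame, key_col: str, group_a, group_b,
                    value_col: str = "assigned_species"):
    """Align two raters'/modalities' labels on shared image ids."""
    a = df[df[key_col] == group_a].set_index("image_id")[value_col]
    b = df[df[key_col] == group_b].set_index("image_id")[value_col]
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise InvalidArgumentError(
            f"no shared image_ids between {group_a!r} and {group_b!r}")
    shared = sorted(shared)
    return list(a.loc[shared]), list(b.loc[shared])


def summarize_study(records: Sequence[EvaluationRecord]) -> pd.DataFrame:
    """Build the study summary table from raw records.

    Emits per-evaluator/per-modality accuracies, pooled accuracies, and —
    when exactly two evaluators are present — inter-observer κ per modality
    and overall, plus inter-modality κ per evaluator and pooled (each
    evaluator's first-modality labels paired with their own second-modality
    labels on matching images).  Accuracies are percentages (one decimal),
    κ values rounded half-up to two decimals.
    """
    records = list(records)
    if not records:
        raise DegenerateInputError("cannot summarise an empty record set")
    df = records_to_dataframe(records)
    modalities = list(dict.fromkeys(df.modality))
    evaluators = list(dict.fromkeys(df.evaluator))
    rows: list[dict] = []

    def rec_subset(**kv):
        m = np.ones(len(df), dtype=bool)
        for col, val in kv.items():
            m &= (df[col] == val).to_numpy()
        return [records[i] for i in np.flatnonzero(m)]

    for m in modalities:
        for e in evaluators:
            sub = rec_subset(modality=m, evaluator=e)
            if sub:
                rows.append({"metric": "accuracy_percent", "modality": m,
                             "evaluator": e, "value": accuracy_percent(sub)})
        rows.append({"metric": "accuracy_percent", "modality": m,
                     "evaluator": "pooled",
                     "value": accuracy_percent(rec_subset(modality=m))})
    for e in evaluators:
        rows.append({"metric": "accuracy_percent", "modality": "pooled",
                     "evaluator": e,
                     "value": accuracy_percent(rec_subset(evaluator=e))})
    rows.append({"metric": "accuracy_percent", "modality": "pooled",
                 "evaluator": "pooled", "value": accuracy_percent(records)})

    if len(evaluators) == 2:
        e1, e2 = evaluators
        pooled_a: list[str] = []
        pooled_b: list[str] = []
        for m in modalities:
            sub = df[df.modality == m]
            a, b = _aligned_labels(sub, "evaluator", e1, e2)
            pooled_a += a
            pooled_b += b
            rows.append({"metric": "kappa_inter_observer", "modality": m,
                         "evaluator": f"{e1}|{e2}",
                         "value": round_half_up(cohen_kappa(a, b).kappa, 2)})
        rows.append({"metric": "kappa_inter_observer", "modality": "pooled",
                     "evaluator": f"{e1}|{e2}",
                     "value": round_half_up(cohen_kappa(pooled_a, pooled_b).kappa, 2)})

    if len(modalities) == 2:
        m1, m2 = modalities
        pooled_a, pooled_b = [], []
        for e in evaluators:
            sub = df[df.evaluator == e]
            try:
                a, b = _aligned_labels(sub, "modality", m1, m2)
            except InvalidArgumentError:
                continue
            pooled_a += a
            pooled_b += b
            rows.append({"metric": "kappa_inter_modality",
                         "modality": f"{m1}|{m2}", "evaluator": e,
                         "value": round_half_up(cohen_kappa(a, b).kappa, 2)})
        if pooled_a:
            rows.append({"metric": "kappa_inter_modality",
                         "modality": f"{m1}|{m2}", "evaluator": "pooled",
                         "value": round_half_up(cohen_kappa(pooled_a, pooled_b).kappa, 2)})
    return pd.DataFrame(rows, columns=["metric", "modality", "evaluator", "value"])
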