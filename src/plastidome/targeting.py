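"""Consensus-workflow evaluation for chloroplast transit-peptide predictors.

A *workflow* is a k-of-n voting rule over a subset of binary predictors: a
protein is called plastid-targeted when at least ``m`` of the chosen
predictors agree.  All non-empty subsets and all thresholds are enumerated
(``n * 2**(n-1)`` workflows for ``n`` predictors) and ranked by Matthews
correlation coefficient against experimentally labelled proteins.

Statistics follow the study conventions for plastid-targeting benchmarks:

* ``sensitivity``  = tp / (tp + fn)
* ``specificity``  = tp / (tp + fp)  — *precision-style*: this field keeps
  the benchmark's naming, which differs from the conventional
  tn / (tn + fp); the conventional quantity is exposed separately as
  ``specificity_conventional`` to avoid silent confusion.
* ``mcc``          = (tp*tn - fp*fn) / sqrt((tp+fn)(tp+fp)(tn+fn)(tn+fp))
* ``accuracy``     = (tp + tn) / total

Zero-denominator cases return 0 (flagged ``degenerate``) so exhaustive
sweeps never abort on constant classifiers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "StatRecord",
    "WorkflowSpec",
    "classification_stats",
    "enumerate_workflows",
    "apply_workflow",
    "evaluate_workflows",
    "stratified_difference",
    "reconstruct_confusion",
    "ReconstructionResult",
    "round_half_up",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(
        cls,
        truth: Mapping[str, bool] | pd.Series,
        predicted: Mapping[str, bool] | pd.Series,
    ) -> "ConfusionMatrix":
        truth = pd.Series(truth, dtype=bool)
        predicted = pd.Series(predicted, dtype=bool).reindex(truth.index)
        if predicted.isna().any():
            missing = predicted.index[predicted.isna()][0]
            raise KeyError(f"no prediction for labelled protein {missing!r}")
        return cls(
            tp=int((truth & predicted).sum()),
            fp=int((~truth & predicted).sum()),
            tn=int((~truth & ~predicted).sum()),
            fn=int((truth & ~predicted).sum()),
        )


@dataclass(frozen=True)
class StatRecord:
    sensitivity: float
    specificity: float            # precision-style tp/(tp+fp)
    specificity_conventional: float
    mcc: float
    accuracy: float
    degenerate: bool = False


def classification_stats(cm: ConfusionMatrix) -> StatRecord:
    """Compute SE, SP (both conventions), MCC, and ACC for one matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    degenerate = False

    def _ratio(num: int, den: int) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    se = _ratio(tp, tp + fn)
    sp_paper = _ratio(tp, tp + fp)
    sp_conv = _ratio(tn, tn + fp)
    acc = (tp + tn) / cm.total
    marginals = (tp + fn, tp + fp, tn + fn, tn + fp)
    if 0 in marginals:
        degenerate = True
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(math.prod(float(m) for m in marginals))
    return StatRecord(se, sp_paper, sp_conv, mcc, acc, degenerate)


@dataclass(frozen=True)
class WorkflowSpec:
    """A k-of-n voting rule: predictor subset plus accept threshold."""

    predictors: tuple[str, ...]
    threshold: int

    def __post_init__(self) -> None:
        if not self.predictors:
            raise ValueError("workflow needs at least one predictor")
        object.__setattr__(self, "predictors", tuple(sorted(self.predictors)))
        if not (1 <= self.threshold <= len(self.predictors)):
            raise ValueError(
                f"threshold {self.threshold} out of 1..{len(self.predictors)}"
            )

    @property
    def label(self) -> str:
        return f"{self.threshold} of ({', '.join(self.predictors)})"


def enumerate_workflows(predictor_names: Sequence[str]) -> list[WorkflowSpec]:
    """All (non-empty subset, threshold) workflows, deterministically ordered.

    Ordering: subset size, then lexicographic subset, then threshold.  The
    count is ``n * 2**(n-1)``; five predictors give 80 workflows.
    """
    names = sorted(set(predictor_names))
    if not names:
        raise ValueError("need at least one predictor")
    if len(names) != len(predictor_names):
        raise ValueError("predictor names must be unique")
    specs: list[WorkflowSpec] = []
    for size in range(1, len(names) + 1):
        for subset in combinations(names, size):
            for m in range(1, size + 1):
                specs.append(WorkflowSpec(subset, m))
    return specs


def apply_workflow(spec: WorkflowSpec, calls: pd.DataFrame) -> pd.Series:
    """Binary call per protein: plastid iff >= m subset predictors agree."""
    missing = [p for p in spec.predictors if p not in calls.columns]
    if missing:
        raise KeyError(f"predictors missing from call table: {missing}")
    sub = calls[list(spec.predictors)]
    if sub.isna().any().any():
        raise ValueError("call table has missing cells for scored predictors")
    votes = sub.astype(bool).sum(axis=1)
    return (votes >= spec.threshold).rename(spec.label)


def _assign_ranks(group: pd.DataFrame) -> pd.Series:
    order = group.sort_values(
        by=["mcc", "accuracy", "sensitivity", "workflow"],
        ascending=[False, False, False, True],
        kind="mergesort",
    ).index
    return pd.Series(range(1, len(order) + 1), index=order)


def evaluate_workflows(
    calls: pd.DataFrame,
    labels: pd.Series | Mapping[str, bool],
    strata: Mapping[str, str] | pd.Series | None = None,
    predictors: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Evaluate every k-of-n workflow against experimental labels.

    Returns one row per (stratum, workflow) with the confusion matrix, all
    statistics, and an MCC rank (ties broken by accuracy, then sensitivity,
    then workflow label).  With no ``strata`` a single stratum ``all`` is
    used.  Strata with zero positives or negatives are flagged degenerate
    but still reported under the zero-marginal convention.
    """
    labels = pd.Series(labels, dtype=bool)
    missing = labels.index.difference(calls.index)
    if len(missing):
        raise KeyError(f"labelled proteins missing from call table: {list(missing)[:3]}")
    calls = calls.loc[labels.index]
    if strata is None:
        strata_series = pd.Series("all", index=labels.index)
    else:
        strata_series = pd.Series(strata).reindex(labels.index)
        if strata_series.isna().any():
            raise KeyError("every labelled protein needs a stratum")
    names = list(predictors) if predictors is not None else list(calls.columns)
    specs = enumerate_workflows(names)

    rows = []
    for stratum in sorted(strata_series.unique()):
        mask = strata_series == stratum
        truth = labels[mask]
        sub_calls = calls[mask]
        for spec in specs:
            predicted = apply_workflow(spec, sub_calls)
            cm = ConfusionMatrix.from_predictions(truth, predicted)
            st = classification_stats(cm)
            rows.append(
                {
                    "stratum": stratum,
                    "workflow": spec.label,
                    "predictors": ",".join(spec.predictors),
                    "threshold": spec.threshold,
                    "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
                    "sensitivity": st.sensitivity,
                    "specificity": st.specificity,
                    "specificity_conventional": st.specificity_conventional,
                    "mcc": st.mcc,
                    "accuracy": st.accuracy,
                    "degenerate": st.degenerate,
                }
            )
    table = pd.DataFrame(rows)
    ranks = pd.concat(
        [_assign_ranks(g) for _, g in table.groupby("stratum", sort=False)]
    )
    table["rank"] = ranks.astype(int)
    return table.sort_values(["stratum", "rank"]).reset_index(drop=True)


def stratified_difference(
    table: pd.DataFrame, stratum_a: str, stratum_b: str
) -> pd.DataFrame:
    """Per-workflow statistic differences between two strata (A minus B)."""
    stats = ["sensitivity", "specificity", "mcc", "accuracy"]
    a = table[table["stratum"] == stratum_a].set_index("workflow")[stats]
    b = table[table["stratum"] == stratum_b].set_index("workflow")[stats]
    diff = (a - b).dropna()
    diff.columns = [f"{c}_diff" for c in stats]
    return diff.reset_index()


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves away from zero going up."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ReconstructionResult:
    matrix: ConfusionMatrix
    clamped: bool
    #: MCC / ACC ranges obtained by perturbing tp by +-1 — published
    #: statistics are rounded, so single-count shifts gauge how fragile the
    #: recomputed cells are.
    mcc_range: tuple[float, float]
    acc_range: tuple[float, float]


def reconstruct_confusion(
    se: float, sp: float, n_pos: int, n_neg: int
) -> ReconstructionResult:
    """Infer a confusion matrix from published (rounded) SE and SP.

    ``sp`` is the precision-style specificity tp/(tp+fp).  Using half-up
    rounding: tp = round(SE * n_pos); predicted positives = round(tp / SP);
    fp, fn, tn follow by subtraction, clamped at zero with a flag.
    """
    if not (0 < se <= 1) or not (0 < sp <= 1):
        raise ValueError("SE and SP must be in (0, 1]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class sizes must be positive")

    def _build(tp: int) -> tuple[ConfusionMatrix, bool]:
        pred_pos = round_half_up(tp / sp)
        fp = pred_pos - tp
        fn = n_pos - tp
        tn = n_neg - fp
        clamped = min(fp, fn, tn) < 0
        return (
            ConfusionMatrix(tp=tp, fp=max(fp, 0), tn=max(tn, 0), fn=max(fn, 0)),
            clamped,
        )

    tp0 = round_half_up(se * n_pos)
    cm, clamped = _build(tp0)
    mccs, accs = [], []
    for tp in (tp0 - 1, tp0, tp0 + 1):
        if 0 <= tp <= n_pos:
            alt, _ = _build(tp)
            st = classification_stats(alt)
            mccs.append(st.mcc)
            accs.append(st.accuracy)
    return ReconstructionResult(
        matrix=cm,
        clamped=clamped,
        mcc_range=(min(mccs), max(mccs)),
        acc_range=(min(accs), max(accs)),
    )
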