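"""Held-out classifier metrics and hypergeometric gene-list enrichment.

Enrichment of a feature (e.g. membership in an independent validation gene
list) in an analyzed gene list, relative to a background universe, is

    enrichment = (b/n) / (B/N)

with N the background size, B the feature-positive genes in the background,
n the analyzed-list size and b the feature-positive genes in the list.  Its
significance is the exact upper-tail hypergeometric probability
P(X >= b) — over-representation only; depletion is not tested.

The enrichment-versus-threshold curve sweeps the classification threshold,
rebuilding the intersection catalogue at each point: it is the central
diagnostic for comparing a subsampled ensemble against single classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score

from synapred.ensemble import intersect_at_threshold
from synapred.training import SubsampleSplit, TrainedClassifier

__all__ = [
    "EnrichmentResult",
    "ClassifierMetrics",
    "EnrichmentCurve",
    "enrichment",
    "hypergeom_pvalue",
    "enrichment_test",
    "evaluate_classifier",
    "enrichment_curve",
]


def _check_counts(N: int, B: int, n: int, b: int) -> None:
    if N <= 0 or n <= 0 or B <= 0:
        raise ValueError("N, B and n must all be positive")
    if b < 0 or b > min(n, B) or n > N or B > N:
        raise ValueError(f"inconsistent counts N={N}, B={B}, n={n}, b={b}")


def enrichment(N: int, B: int, n: int, b: int) -> float:
    """(b/n) / (B/N): over-representation of the feature in the analyzed list."""
    _check_counts(N, B, n, b)
    return (b / n) / (B / N)


def hypergeom_pvalue(N: int, B: int, n: int, b: int) -> float:
    """Exact upper-tail P(X >= b), X ~ Hypergeometric(N, B, n)."""
    _check_counts(N, B, n, b)
    # sf(b - 1) = P(X > b - 1) = P(X >= b)
    return float(hypergeom.sf(b - 1, N, B, n))


@dataclass(frozen=True)
class EnrichmentResult:
    """One enrichment test: the four counts, the ratio and its p-value."""

    N: int
    B: int
    n: int
    b: int
    enrichment: float
    p_value: float


def enrichment_test(N: int, B: int, n: int, b: int) -> EnrichmentResult:
    return EnrichmentResult(
        N=N, B=B, n=n, b=b,
        enrichment=enrichment(N, B, n, b),
        p_value=hypergeom_pvalue(N, B, n, b),
    )


@dataclass(frozen=True)
class ClassifierMetrics:
    """Accuracy, F1 and AUROC of one classifier on its own held-out test set."""

    algorithm: str
    fold_index: int
    accuracy: float
    f1: float
    auroc: float


def evaluate_classifier(
    classifier: TrainedClassifier,
    split: SubsampleSplit,
    features: pd.DataFrame,
) -> ClassifierMetrics:
    """Metrics on the split's test fifth, which the classifier never saw.

    Accuracy and F1 call a gene positive at probability >= 0.5; AUROC uses
    the full probability ranking.  F1 targets the positive (synaptic) class.
    """
    test = split.test
    if not test.positives or not test.negatives:
        raise ValueError("test set must contain both classes (AUROC undefined otherwise)")
    ids = sorted(test.positives) + sorted(test.negatives)
    y_true = [1] * len(test.positives) + [0] * len(test.negatives)
    probs = classifier.predict_proba(features.loc[ids])
    y_pred = (probs.to_numpy() >= 0.5).astype(int)
    return ClassifierMetrics(
        algorithm=classifier.algorithm,
        fold_index=classifier.fold_index,
        accuracy=float(accuracy_score(y_true, y_pred)),
        f1=float(f1_score(y_true, y_pred, pos_label=1)),
        auroc=float(roc_auc_score(y_true, probs.to_numpy())),
    )


@dataclass
class EnrichmentCurve:
    """Enrichment of a validation gene set as the threshold increases.

    ``results[i]`` is None where the intersection catalogue at
    ``thresholds[i]`` is empty — the enrichment is undefined there, not zero.
    """

    grouping: str
    thresholds: tuple[float, ...]
    results: list[EnrichmentResult | None]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, r in zip(self.thresholds, self.results):
            if r is None:
                rows.append({"threshold": t, "n": 0, "b": 0, "B": pd.NA, "N": pd.NA,
                             "enrichment": float("nan"), "p_value": float("nan"),
                             "defined": False})
            else:
                rows.append({"threshold": t, "n": r.n, "b": r.b, "B": r.B, "N": r.N,
                             "enrichment": r.enrichment, "p_value": r.p_value,
                             "defined": True})
        return pd.DataFrame(rows)


def _select_columns(table: pd.DataFrame, grouping: str) -> list[str]:
    if grouping == "all":
        return list(table.columns)
    if grouping in table.columns:  # one single classifier
        return [grouping]
    per_alg = [c for c in table.columns if c.split("_")[0] == grouping]
    if per_alg:
        return per_alg
    raise ValueError(
        f"grouping {grouping!r} matches neither 'all', a column, nor an algorithm prefix"
    )


def enrichment_curve(
    table: pd.DataFrame,
    validation: Iterable[str],
    thresholds: Sequence[float],
    grouping: str = "all",
) -> EnrichmentCurve:
    """Sweep thresholds, intersecting the selected classifier columns at each.

    ``grouping`` selects which probability columns must simultaneously clear
    the threshold: ``"all"`` (the full ensemble), an algorithm name (that
    algorithm's folds only), or an exact column name (a single classifier).
    The background N is the whole probability table; B is the validation
    genes present in it.
    """
    thresholds = [float(t) for t in thresholds]
    if any(t2 <= t1 for t1, t2 in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    validation = set(validation)
    missing = validation - set(table.index)
    if missing:
        raise ValueError(
            f"{len(missing)} validation genes absent from the probability table"
        )
    cols = _select_columns(table, grouping)
    N = table.shape[0]
    B = len(validation)
    if B == 0:
        raise ValueError("validation set shares no genes with the table (B = 0)")

    sub = table[cols]
    results: list[EnrichmentResult | None] = []
    for t in thresholds:
        members = intersect_at_threshold(sub, t).members
        n = len(members)
        if n == 0:
            results.append(None)
            continue
        b = len(members & validation)
        results.append(enrichment_test(N, B, n, b))
    return EnrichmentCurve(grouping=grouping, thresholds=tuple(thresholds), results=results)
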