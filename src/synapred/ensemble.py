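"""Genome-wide prediction and intersection-at-threshold catalogue construction.

Each of the trained classifiers assigns every gene a probability of being
synaptic.  A catalogue at threshold t is the *intersection* of the
per-classifier above-threshold sets — a gene enters only if every classifier
simultaneously assigns it probability >= t — annotated with the unweighted
mean of its probabilities.  Labeled training genes are excluded from
prediction by default: catalogues are of putative, not already-known, genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable

import pandas as pd

from synapred.training import TrainedClassifier

__all__ = ["Catalogue", "predict_all", "intersect_at_threshold", "exclude_annotated"]


def predict_all(
    classifiers: list[TrainedClassifier],
    features: pd.DataFrame,
    exclude: Iterable[str] = (),
) -> pd.DataFrame:
    """Probability table: one column per classifier, one row per retained gene.

    ``exclude`` (typically the labeled training genes) are dropped from the
    rows.  Column names carry each classifier's (algorithm, fold) identity.
    """
    if not classifiers:
        raise ValueError("no classifiers given")
    keep = features.index.difference(pd.Index(list(exclude)), sort=False)
    sub = features.loc[keep]
    table = pd.concat([clf.predict_proba(sub) for clf in classifiers], axis=1)
    if table.columns.has_duplicates:
        raise ValueError("duplicate classifier identities in table columns")
    table.index.name = "gene_id"
    return table


@dataclass
class Catalogue:
    """Genes whose probability clears ``threshold`` under every classifier."""

    threshold: float
    mean_probability: pd.Series  # index: member gene IDs, descending probability
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def members(self) -> frozenset[str]:
        return frozenset(self.mean_probability.index)

    def __len__(self) -> int:
        return len(self.mean_probability)


def intersect_at_threshold(
    table: pd.DataFrame, threshold: float, strict: bool = False
) -> Catalogue:
    """Catalogue of genes above ``threshold`` in *all* classifier columns.

    Membership uses >= by default (``strict=True`` switches to >).  Members
    are annotated with the arithmetic mean of their per-classifier
    probabilities and sorted by descending mean, ties broken by gene ID.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    minima = table.min(axis=1)
    mask = minima > threshold if strict else minima >= threshold
    mean = table.loc[mask].mean(axis=1)
    mean = mean.sort_index().sort_values(ascending=False, kind="stable")
    mean.name = "mean_probability"
    return Catalogue(
        threshold=threshold,
        mean_probability=mean,
        provenance={"n_classifiers": table.shape[1], "strict": strict},
    )


def exclude_annotated(catalogue: Catalogue, annotated: Iterable[str]) -> Catalogue:
    """Remove already-annotated genes, leaving the putative novel members.

    Mirrors the final cataloguing step in which members carrying a relevant
    existing functional annotation are set aside so the published list
    contains only candidates whose function is still undocumented.
    """
    annotated = set(annotated)
    kept = catalogue.mean_probability[
        [g for g in catalogue.mean_probability.index if g not in annotated]
    ]
    prov = dict(catalogue.provenance)
    prov["n_excluded_annotated"] = len(catalogue) - len(kept)
    return Catalogue(threshold=catalogue.threshold, mean_probability=kept, provenance=prov)
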