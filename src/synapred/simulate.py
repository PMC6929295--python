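"""Synthetic developmental-transcriptome generator with planted gene classes.

Emulates the data regime the predictor was designed for: a gene x stage
matrix of non-negative, right-skewed (FPKM-like) expression values over 24
ordered developmental stages spanning embryo to adult.  Three gene classes
are planted with known ground truth:

* ``synaptic`` genes — elevated expected expression during two developmental
  "waves" (an embryonic and a pupal block), the temporal signature of massive
  synapse assembly.  All labeled positives and all hidden positives (stand-ins
  for independently discovered synaptic genes, withheld from training) follow
  this law.
* ``adult_only`` genes — exactly zero outside the adult stages; drawn from the
  labeled-negative pool.  These are the genes the preprocessing filter must
  remove.
* ``background`` genes — flat expected profile (includes the remaining,
  non-adult-only labeled negatives).

Baseline expression is log-normal: each gene draws a log-scale location once,
and stage values are drawn i.i.d. around it with a configurable dispersion.
The wave elevation is multiplicative and applied before noise, so it survives
per-gene max normalization as a profile-shape signal — which is exactly what
the downstream classifiers must detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SimulationConfig", "SyntheticDataset", "generate_dataset"]

#: default embryonic + pupal wave blocks within a 24-stage axis
DEFAULT_WAVE_STAGES: tuple[tuple[int, ...], tuple[int, ...]] = (
    (3, 4, 5, 6),
    (14, 15, 16, 17),
)
#: default trailing adult stages
DEFAULT_ADULT_STAGES: tuple[int, ...] = (20, 21, 22, 23)


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic developmental transcriptome.

    Defaults mirror the scale of the real study: ~5000 genes over 24 stages,
    92 labeled positive and 397 labeled negative training genes, and 79
    hidden positives playing the role of later-discovered synaptic genes.
    """

    n_genes: int = 5000
    n_stages: int = 24
    wave_stages: tuple[tuple[int, ...], tuple[int, ...]] = DEFAULT_WAVE_STAGES
    n_pos_labeled: int = 92
    n_neg_labeled: int = 397
    n_hidden_pos: int = 79
    frac_adult_only: float = 0.1
    adult_stage_indices: tuple[int, ...] = DEFAULT_ADULT_STAGES
    noise_dispersion: float = 0.5
    wave_fold: float = 4.0
    #: location/scale of the across-gene distribution of log baseline expression
    log_baseline_loc: float = 1.0
    log_baseline_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_stages <= 0:
            raise ConfigurationError("n_genes and n_stages must be positive")
        if self.n_pos_labeled < 0 or self.n_neg_labeled < 0 or self.n_hidden_pos < 0:
            raise ConfigurationError("class counts must be non-negative")
        if self.n_pos_labeled + self.n_neg_labeled + self.n_hidden_pos > self.n_genes:
            raise ConfigurationError(
                "n_pos_labeled + n_neg_labeled + n_hidden_pos exceeds n_genes"
            )
        if not 0.0 <= self.frac_adult_only < 1.0:
            raise ConfigurationError("frac_adult_only must lie in [0, 1)")
        if self.noise_dispersion <= 0:
            raise ConfigurationError("noise_dispersion must be positive")
        if self.wave_fold < 1.0:
            raise ConfigurationError("wave_fold must be >= 1")
        wave_all = [i for block in self.wave_stages for i in block]
        if len(self.wave_stages) != 2 or not all(self.wave_stages):
            raise ConfigurationError("wave_stages must be two non-empty index blocks")
        if len(set(wave_all)) != len(wave_all):
            raise ConfigurationError("wave_stages blocks must be disjoint")
        for idx in (*wave_all, *self.adult_stage_indices):
            if not 0 <= idx < self.n_stages:
                raise ConfigurationError(f"stage index {idx} out of range [0, {self.n_stages})")
        if not self.adult_stage_indices:
            raise ConfigurationError("adult_stage_indices must be non-empty")
        if set(wave_all) & set(self.adult_stage_indices):
            raise ConfigurationError("wave_stages and adult_stage_indices must be disjoint")

    @property
    def n_adult_only(self) -> int:
        """Number of adult-only genes, carved out of the labeled negatives."""
        return int(round(self.frac_adult_only * self.n_neg_labeled))

    @property
    def stage_labels(self) -> list[str]:
        return [f"stage_{i:02d}" for i in range(self.n_stages)]


@dataclass
class SyntheticDataset:
    """One generated transcriptome with its ground truth.

    ``matrix`` is a gene x stage DataFrame of non-negative expression values;
    ``positives``/``negatives`` are the labeled training IDs;
    ``hidden_positives`` follow the positive-class generative law but are
    withheld from training; ``truth`` tags every gene as ``synaptic``,
    ``adult_only`` or ``background``.
    """

    matrix: pd.DataFrame
    positives: frozenset[str]
    negatives: frozenset[str]
    hidden_positives: frozenset[str]
    truth: pd.Series
    config: SimulationConfig = field(repr=False)

    @property
    def adult_stage_indices(self) -> tuple[int, ...]:
        return tuple(self.config.adult_stage_indices)


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw one synthetic dataset; identical config reproduces it bit-for-bit.

    Gene-to-class assignment uses a seeded permutation, so labeled, hidden
    and background genes are interleaved in the matrix rather than blocked.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    gene_ids = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    order = rng.permutation(config.n_genes)
    n_pos, n_hid, n_neg = config.n_pos_labeled, config.n_hidden_pos, config.n_neg_labeled
    pos_idx = order[:n_pos]
    hid_idx = order[n_pos : n_pos + n_hid]
    neg_idx = order[n_pos + n_hid : n_pos + n_hid + n_neg]
    adult_only_idx = neg_idx[: config.n_adult_only]

    wave_mask = np.zeros(config.n_stages, dtype=bool)
    for block in config.wave_stages:
        wave_mask[list(block)] = True
    adult_mask = np.zeros(config.n_stages, dtype=bool)
    adult_mask[list(config.adult_stage_indices)] = True

    # log-normal baseline: one location per gene, i.i.d. stage noise around it
    loc = rng.normal(config.log_baseline_loc, config.log_baseline_scale, size=config.n_genes)
    log_mean = np.repeat(loc[:, None], config.n_stages, axis=1)

    synaptic_rows = np.concatenate([pos_idx, hid_idx])
    log_mean[np.ix_(synaptic_rows, np.flatnonzero(wave_mask))] += np.log(config.wave_fold)

    values = np.exp(log_mean + rng.normal(0.0, config.noise_dispersion, size=log_mean.shape))
    values[np.ix_(adult_only_idx, np.flatnonzero(~adult_mask))] = 0.0

    truth = pd.Series("background", index=gene_ids, name="truth", dtype=object)
    truth.iloc[synaptic_rows] = "synaptic"
    truth.iloc[adult_only_idx] = "adult_only"

    matrix = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                          columns=config.stage_labels)
    return SyntheticDataset(
        matrix=matrix,
        positives=frozenset(gene_ids[pos_idx]),
        negatives=frozenset(gene_ids[neg_idx]),
        hidden_positives=frozenset(gene_ids[hid_idx]),
        truth=truth,
        config=config,
    )
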