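"""Hybrid detection-conditional imputation with repeated stochastic cycles.

Missing cells are routed by how often the protein was detected within its
replicate group (condition):

* at most one detection in the group -> the protein is treated as below the
  detection limit there; its missing cells are drawn from a narrow Gaussian
  shifted left of the sample's observed intensity distribution
  (mean_s - mnar_shift * sd_s, width mnar_width * sd_s);
* two or more detections -> missing cells are drawn from the Normal
  maximum-likelihood fit to the observed values of that protein x condition
  block.

Both draws are stochastic, so repeating the completion (cycles) propagates
imputation uncertainty into downstream testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .core import IntensityMatrix

LABEL_OBSERVED = "observed"
LABEL_MNAR = "mnar_rule"
LABEL_MLE = "mle_rule"


@dataclass
class MissingnessLabels:
    """Per-cell routing: observed / mnar_rule / mle_rule."""

    labels: pd.DataFrame  # strings, same shape as the intensity matrix

    def count(self, label: str) -> int:
        return int((self.labels == label).to_numpy().sum())


@dataclass
class ColumnStats:
    """Per-sample mean and sd (n-1 denominator) over observed cells."""

    stats: pd.DataFrame  # index sample, columns ["mean", "sd", "n_observed"]

    def mean(self, sample: str) -> float:
        return float(self.stats.loc[sample, "mean"])

    def sd(self, sample: str) -> float:
        return float(self.stats.loc[sample, "sd"])


@dataclass
class ImputedCycle:
    """One stochastic completion of the matrix (no missing cells)."""

    cycle_index: int
    data: pd.DataFrame
    rng_key: str


def classify_missing(m: IntensityMatrix) -> MissingnessLabels:
    """Label each cell by the imputation rule that will fill it.

    For every protein x condition block: <= 1 detection routes the block's
    missing cells to the downshifted-Gaussian rule (mnar_rule); >= 2
    detections route them to the Normal-MLE rule (mle_rule).
    """
    for c in m.conditions:
        if len(m.condition_samples(c)) < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 replicates")
    values = m.data.to_numpy()
    labels = np.full(values.shape, LABEL_OBSERVED, dtype=object)
    missing = np.isnan(values)
    for cond in m.conditions:
        cols = [m.data.columns.get_loc(s) for s in m.condition_samples(cond)]
        block_missing = missing[:, cols]
        detections = (~block_missing).sum(axis=1)
        rule = np.where(detections <= 1, LABEL_MNAR, LABEL_MLE)
        block_labels = np.broadcast_to(rule[:, None], block_missing.shape).copy()
        block_labels[~block_missing] = LABEL_OBSERVED
        labels[:, cols] = block_labels
    return MissingnessLabels(
        labels=pd.DataFrame(labels, index=m.data.index, columns=m.data.columns)
    )


def column_stats(m: IntensityMatrix) -> ColumnStats:
    """Observed-data mean and sd per sample column (sd uses n-1)."""
    stats = []
    for s in m.data.columns:
        obs = m.data[s].dropna()
        if len(obs) < 2:
            raise ValueError(f"sample {s!r} has fewer than 2 observed values")
        stats.append((float(obs.mean()), float(obs.std(ddof=1)), len(obs)))
    return ColumnStats(
        stats=pd.DataFrame(stats, index=m.data.columns, columns=["mean", "sd", "n_observed"])
    )


def draw_mnar(
    mean_s: float,
    sd_s: float,
    config: AnalysisConfig,
    rng: np.random.Generator,
    size: Optional[int] = None,
) -> Union[float, np.ndarray]:
    """Draw from the left-shifted Gaussian for a below-detection cell.

    The distribution is Normal(mean_s - mnar_shift * sd_s,
    (mnar_width * sd_s)^2); with sd_s = 0 it degenerates to the point mass
    at mean_s.
    """
    if sd_s < 0:
        raise ValueError("sd must be >= 0")
    loc = mean_s - config.mnar_shift * sd_s
    scale = config.mnar_width * sd_s
    out = rng.normal(loc, scale, size=size)
    return float(out) if size is None else out


def mle_fit(values: Sequence[float]) -> Tuple[float, float]:
    """Normal maximum-likelihood fit: arithmetic mean, n-denominator sd."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("MLE fit needs >= 2 observed values")
    return float(arr.mean()), float(arr.std(ddof=0))


def draw_mle(
    values: Sequence[float],
    rng: np.random.Generator,
    size: Optional[int] = None,
) -> Union[float, np.ndarray]:
    """Draw from the Normal MLE fit to a block's observed values."""
    mu, sigma = mle_fit(values)
    out = rng.normal(mu, sigma, size=size)
    return float(out) if size is None else out


def _cell_moments(
    m: IntensityMatrix,
    labels: MissingnessLabels,
    stats: ColumnStats,
    config: AnalysisConfig,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell (mean, sd) of the imputation distribution at missing cells."""
    values = m.data.to_numpy()
    lab = labels.labels.to_numpy()
    cell_mean = np.zeros(values.shape)
    cell_sd = np.zeros(values.shape)

    col_mean = stats.stats["mean"].to_numpy()
    col_sd = stats.stats["sd"].to_numpy()
    mnar = lab == LABEL_MNAR
    mnar_mean = col_mean - config.mnar_shift * col_sd
    mnar_sd = config.mnar_width * col_sd
    cell_mean += mnar * mnar_mean[None, :]
    cell_sd += mnar * mnar_sd[None, :]

    mle = lab == LABEL_MLE
    if mle.any():
        for cond in m.conditions:
            cols = [m.data.columns.get_loc(s) for s in m.condition_samples(cond)]
            block = values[:, cols]
            present = ~np.isnan(block)
            cnt = np.maximum(present.sum(axis=1), 1)
            filled0 = np.where(present, block, 0.0)
            bmean = filled0.sum(axis=1) / cnt
            bsd = np.sqrt(
                (np.where(present, (block - bmean[:, None]) ** 2, 0.0)).sum(axis=1) / cnt
            )
            block_mle = mle[:, cols]
            for j, c in enumerate(cols):
                sel = block_mle[:, j]
                cell_mean[sel, c] = bmean[sel]
                cell_sd[sel, c] = bsd[sel]
    return cell_mean, cell_sd, np.isnan(values)


def run_cycles(
    m: IntensityMatrix,
    labels: MissingnessLabels,
    stats: ColumnStats,
    config: AnalysisConfig,
) -> List[ImputedCycle]:
    """Produce ``config.n_cycles`` stochastic completions of the matrix.

    Each cycle uses its own rng substream spawned deterministically from
    ``config.seed``; within a cycle every cell has a position-indexed draw,
    so results do not depend on traversal order. Observed cells are copied
    bit-exactly into every cycle.
    """
    cell_mean, cell_sd, missing = _cell_moments(m, labels, stats, config)
    values = m.data.to_numpy()
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_cycles)
    cycles: List[ImputedCycle] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        z = rng.standard_normal(values.shape)
        filled = np.where(missing, cell_mean + cell_sd * z, values)
        cycles.append(
            ImputedCycle(
                cycle_index=i,
                data=pd.DataFrame(filled, index=m.data.index, columns=m.data.columns),
                rng_key=f"seed={config.seed}/cycle={i}",
            )
        )
    return cycles
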