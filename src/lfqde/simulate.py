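"""Synthetic label-free quantification datasets with known ground truth.

Emulates a two-condition, few-replicate LFQ experiment: per-protein baseline
log2 intensities, a minority of truly differential proteins with balanced
up/down effects, Gaussian replicate noise, soft intensity-dependent
(left-censoring) missingness plus a completely-at-random component. Every
missing cell's mechanism is recorded so imputation and error rates can be
scored against the truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import IntensityMatrix

#: per-cell missingness mechanisms
MECH_NONE = "none"
MECH_CENSORED = "censored"
MECH_MCAR = "mcar"


@dataclass
class SimulationParams:
    """Generative settings for one synthetic dataset.

    Defaults are sized to a typical organoid LFQ study: two conditions with
    three replicates each, ~5,500 quantified proteins of which ~4% are truly
    differential, log2 intensities centred near 20 with 2.5 log2 units of
    between-protein spread, 0.3 log2 units of replicate noise, and soft
    left-censoring that removes mostly low-abundance cells.
    """

    n_proteins: int = 5500
    n_replicates: int = 3
    de_fraction: float = 0.04
    effect_size_mean: float = 2.0  # mean |delta|, log2 units
    effect_size_sd: float = 0.5
    baseline_mean: float = 20.0
    baseline_sd: float = 2.5
    replicate_sd: float = 0.3
    mnar_censor_midpoint: float = 16.0  # log2 intensity of 50% dropout
    mnar_censor_scale: float = 0.8
    mcar_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        if not 0 <= self.mcar_rate <= 1:
            raise ValueError("mcar_rate must be in [0, 1]")
        for name in ("effect_size_sd", "baseline_sd", "replicate_sd", "mnar_censor_scale"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated dataset.

    ``proteins`` has one row per protein (``is_de``, signed ``delta``,
    ``baseline``); ``mechanism`` mirrors the intensity matrix and names the
    cause of each missing cell; ``latent`` holds the pre-censoring values.
    """

    proteins: pd.DataFrame
    mechanism: pd.DataFrame
    latent: pd.DataFrame

    def __post_init__(self) -> None:
        if ((~self.proteins["is_de"]) & (self.proteins["delta"] != 0)).any():
            raise ValueError("delta must be 0 wherever is_de is false")


CONDITIONS = ("control", "treated")


def generate_dataset(params: SimulationParams) -> Tuple[IntensityMatrix, SyntheticTruth]:
    """Draw one reproducible dataset.

    Per protein g: baseline mu_g ~ Normal(baseline_mean, baseline_sd); the
    second condition's mean is mu_g + delta_g, with delta_g != 0 only for a
    de_fraction subset whose signs alternate (balanced up/down). Each cell is
    Normal(condition mean, replicate_sd), censored with probability
    logistic((midpoint - value)/scale), and independently lost completely at
    random at mcar_rate.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n, r = p.n_proteins, p.n_replicates

    n_de = int(round(p.de_fraction * n))
    if p.de_fraction > 0 and n_de < 1:
        warnings.warn("de_fraction * n_proteins < 1; generating zero DE proteins")
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    delta = np.zeros(n)
    if n_de:
        magnitudes = np.abs(rng.normal(p.effect_size_mean, p.effect_size_sd, n_de))
        signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
        delta[de_idx] = signs * magnitudes

    baseline = rng.normal(p.baseline_mean, p.baseline_sd, n)
    cond_means = np.stack([baseline, baseline + delta], axis=1)  # n x 2
    cell_means = np.repeat(cond_means, r, axis=1)  # n x 2r
    latent = rng.normal(cell_means, p.replicate_sd)

    p_censor = expit((p.mnar_censor_midpoint - latent) / p.mnar_censor_scale)
    censored = rng.random(latent.shape) < p_censor
    mcar = (rng.random(latent.shape) < p.mcar_rate) & ~censored

    values = latent.copy()
    values[censored | mcar] = np.nan
    mech = np.full(latent.shape, MECH_NONE, dtype=object)
    mech[censored] = MECH_CENSORED
    mech[mcar] = MECH_MCAR

    protein_ids = [f"P{i:05d}" for i in range(n)]
    sample_ids = [f"{c}_{j + 1}" for c in CONDITIONS for j in range(r)]
    design = {s: s.rsplit("_", 1)[0] for s in sample_ids}

    matrix = IntensityMatrix(
        data=pd.DataFrame(values, index=protein_ids, columns=sample_ids),
        design=design,
    )
    truth = SyntheticTruth(
        proteins=pd.DataFrame(
            {"is_de": delta != 0, "delta": delta, "baseline": baseline},
            index=protein_ids,
        ),
        mechanism=pd.DataFrame(mech, index=protein_ids, columns=sample_ids),
        latent=pd.DataFrame(latent, index=protein_ids, columns=sample_ids),
    )
    return matrix, truth


def truth_confusion(calls: pd.DataFrame, truth: SyntheticTruth) -> Dict[str, float]:
    """Score final significance calls against the simulated truth.

    ``calls`` is a DE table (indexed by protein) with a boolean
    ``significant`` column. Returns TP/FP/TN/FN counts plus the
    false-discovery proportion FP / max(1, FP + TP) and sensitivity
    TP / max(1, TP + FN).
    """
    if set(calls.index) != set(truth.proteins.index):
        raise ValueError("protein ids of calls and truth do not match")
    called = calls["significant"].reindex(truth.proteins.index).to_numpy(dtype=bool)
    is_de = truth.proteins["is_de"].to_numpy(dtype=bool)
    tp = int((called & is_de).sum())
    fp = int((called & ~is_de).sum())
    fn = int((~called & is_de).sum())
    tn = int((~called & ~is_de).sum())
    return {
        "TP": tp,
        "FP": fp,
        "TN": tn,
        "FN": fn,
        "FDP": fp / max(1, fp + tp),
        "sensitivity": tp / max(1, tp + fn),
    }


def write_truth(truth: SyntheticTruth, path) -> None:
    truth.proteins.to_csv(path, sep="\t", index_label="protein")
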