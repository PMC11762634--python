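"""Analysis configuration.

All numeric constants of the published workflow live here: the downshifted-
Gaussian imputation parameters (width 0.3, shift 2.5 column standard
deviations), the number of imputation cycles (20), the final significance
thresholds (|log2FC| >= 1 and adjusted p <= 0.05), the looser counting
thresholds used for descriptive bar charts (|log2FC| > 0.5, raw p < 0.05),
and the boxplot whisker multiplier (1.5 IQR).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import yaml

SIG_MODES = ("dual_threshold", "curve")


@dataclass
class AnalysisConfig:
    """Tunable parameters for the whole pipeline.

    Parameters
    ----------
    mnar_width:
        Width of the left-shifted Gaussian used for missing-not-at-random
        imputation, as a multiple of the per-sample standard deviation.
    mnar_shift:
        Downshift of that Gaussian's mean below the per-sample mean, in
        per-sample standard deviations.
    n_cycles:
        Number of stochastic imputation cycles.
    lfc_min:
        Minimum absolute log2 fold change for a final significance call.
    q_max:
        Maximum Benjamini-Hochberg adjusted p-value for a final call.
    count_lfc_cut, count_p_cut:
        Strict thresholds used by descriptive counting (``> count_lfc_cut``
        on |log2FC|, ``< count_p_cut`` on the raw p-value).
    whisker_mult:
        Boxplot whiskers extend to the furthest datum within this multiple
        of the IQR beyond the quartiles.
    sig_mode:
        ``dual_threshold`` (default) requires both cuts outright; ``curve``
        lets the effective adjusted-p threshold rise from 0 at
        ``|lfc| = lfc_min`` toward ``q_max`` asymptotically.
    curve_steepness:
        Rate parameter of the curve mode threshold (per log2 unit).
    contaminant_prefixes:
        Protein-id prefixes marking contaminant/decoy rows to drop.
    zero_as_missing:
        Treat raw zero intensities as not-quantified (missing) on read.
    seed:
        Root seed for every stochastic step.
    """

    mnar_width: float = 0.3
    mnar_shift: float = 2.5
    n_cycles: int = 20
    lfc_min: float = 1.0
    q_max: float = 0.05
    count_lfc_cut: float = 0.5
    count_p_cut: float = 0.05
    whisker_mult: float = 1.5
    sig_mode: str = "dual_threshold"
    curve_steepness: float = 1.0
    contaminant_prefixes: Sequence[str] = ("CON__", "REV__")
    zero_as_missing: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mnar_width", "mnar_shift", "whisker_mult", "curve_steepness"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("q_max", "count_p_cut"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.lfc_min < 0 or self.count_lfc_cut < 0:
            raise ValueError("fold-change cuts must be non-negative")
        if self.sig_mode not in SIG_MODES:
            raise ValueError(f"sig_mode must be one of {SIG_MODES}")
        self.contaminant_prefixes = tuple(self.contaminant_prefixes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contaminant_prefixes"] = list(self.contaminant_prefixes)
        return d

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kw) -> "AnalysisConfig":
        return dataclasses.replace(self, **kw)
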