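"""Plot-ready tables: volcano coordinates, boxplot statistics, qPCR folds."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig

logger = logging.getLogger(__name__)

_TINY = np.finfo(float).tiny


@dataclass
class BoxplotStats:
    """Five-number summary with IQR-rule whiskers and outliers.

    Quartiles use linear interpolation between order statistics; whiskers
    reach the furthest datum within ``whisker_mult`` IQRs of the box.
    """

    median: float
    q1: float
    q3: float
    iqr: float
    whisker_lo: float
    whisker_hi: float
    outliers: np.ndarray


def volcano_table(
    table: pd.DataFrame,
    config: AnalysisConfig,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Volcano coordinates (lfc, -log10 p) plus threshold-line metadata.

    Categories use the descriptive chart thresholds: ``up``/``down`` need
    |lfc| > count_lfc_cut and raw p < count_p_cut, everything else is ``ns``.
    Zero p-values are clamped to the smallest positive float.
    """
    p = table["p"].to_numpy(dtype=float)
    n_zero = int((p == 0).sum())
    if n_zero:
        logger.warning("clamping %d zero p-values for -log10", n_zero)
    p = np.maximum(p, _TINY)
    lfc = table["lfc"].to_numpy(dtype=float)
    up = (lfc > config.count_lfc_cut) & (p < config.count_p_cut)
    down = (lfc < -config.count_lfc_cut) & (p < config.count_p_cut)
    category = np.where(up, "up", np.where(down, "down", "ns"))
    out = pd.DataFrame(
        {"lfc": lfc, "neg_log10_p": -np.log10(p), "category": category},
        index=table.index,
    )
    meta = {
        "vline_lo": -config.count_lfc_cut,
        "vline_hi": config.count_lfc_cut,
        "hline": -math.log10(config.count_p_cut),
    }
    return out, meta


def boxplot_stats(values: Sequence[float], whisker_mult: float = 1.5) -> BoxplotStats:
    """Boxplot summary of one group of values."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("boxplot_stats needs at least one value")
    if np.isnan(arr).any():
        arr = arr[~np.isnan(arr)]
        if arr.size == 0:
            raise ValueError("boxplot_stats needs at least one non-missing value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo_fence = q1 - whisker_mult * iqr
    hi_fence = q3 + whisker_mult * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    # clamp to the box when no datum lies beyond a quartile, so
    # whisker_lo <= Q1 <= Q3 <= whisker_hi always holds
    whisker_lo = float(min(inside.min(), q1))
    whisker_hi = float(max(inside.max(), q3))
    outliers = np.sort(arr[(arr < whisker_lo) | (arr > whisker_hi)])
    return BoxplotStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        whisker_lo=whisker_lo,
        whisker_hi=whisker_hi,
        outliers=outliers,
    )


def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the ddCt method, 2^(-ddCt).

    dCt = Ct(target) - Ct(reference housekeeping gene) within each
    condition; ddCt = dCt(case) - dCt(control).
    """
    cts = (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)
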