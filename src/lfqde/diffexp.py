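"""Moderated t-testing, FDR adjustment, significance calls, cycle aggregation.

The per-protein variance is shrunk toward an empirical-Bayes prior estimated
across all proteins. Under the hierarchical model the sample variances s_g^2
are scaled-F distributed, s_g^2 ~ s0^2 F(d_g, d0); the prior (d0, s0^2) is
obtained by matching the mean and variance of log s_g^2 to the theoretical
digamma/trigamma moments. The moderated statistic

    t_g = (mean2 - mean1) / sqrt(s~_g^2 (1/n1 + 1/n2)),
    s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g)

is referred to a t distribution with d0 + d_g degrees of freedom (a Normal
when d0 is unbounded). p-values are corrected by the Benjamini-Hochberg
step-up, and per-cycle significance calls (|log2FC| and adjusted-p cuts) are
aggregated across imputation cycles by strict-majority vote.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Union

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .config import AnalysisConfig
from .core import IntensityMatrix

_TINY = np.finfo(float).tiny


@dataclass
class VariancePrior:
    """Empirical-Bayes prior: d0 degrees of freedom (may be inf), s0^2."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValueError("d0 must be > 0")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be > 0")


def trigamma_inverse(x: float, rtol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration on 1/y scale."""
    if x <= 0:
        raise ValueError("trigamma_inverse needs x > 0")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < rtol:
            break
    return float(y)


def fit_variance_prior(
    s2: Sequence[float],
    df: Union[float, Sequence[float]],
) -> VariancePrior:
    """Estimate (d0, s0^2) from per-protein sample variances.

    Moment matching on z = log s^2: with e = z - psi(d/2) + log(d/2),
    E[e] = log s0^2 - psi(d0/2) + log(d0/2) and
    Var[e] = psi'(d/2) + psi'(d0/2). If the empirical variance of e does not
    exceed psi'(d/2) there is no detectable between-protein spread and d0 is
    unbounded (s~^2 = s0^2 for every protein).
    """
    s2 = np.asarray(s2, dtype=float)
    d = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (d > 0)
    if not ok.any():
        raise ValueError("all sample variances are zero or invalid")
    if ok.sum() < 2:
        raise ValueError("need >= 2 proteins with positive variance")
    z = np.log(s2[ok])
    d = d[ok]
    e = z - special.digamma(d / 2) + np.log(d / 2)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    excess = evar - float(special.polygamma(1, d / 2).mean())
    if excess <= 0:
        # no detectable between-protein spread: on the d0 = inf boundary
        # E[s^2] = s0^2 exactly, so match the raw first moment (this also
        # returns the common value when every s^2 is identical)
        return VariancePrior(d0=math.inf, s0_sq=float(s2[ok].mean()))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_sq = math.exp(emean + special.digamma(d0 / 2) - math.log(d0 / 2))
    return VariancePrior(d0=d0, s0_sq=s0_sq)


def moderated_t(
    data: pd.DataFrame,
    design: Dict[str, str],
    prior: VariancePrior,
) -> pd.DataFrame:
    """Moderated two-sample t-test on a complete (imputed) matrix.

    Returns one row per protein: ``lfc`` (condition2 - condition1, condition
    order by first appearance in the design), pooled variance ``s2`` with
    ``df`` = n1 + n2 - 2, moderated variance ``s2_mod``, statistic ``t``,
    two-sided ``p`` and BH-adjusted ``q``.
    """
    if data.isna().to_numpy().any():
        raise ValueError("matrix must be complete (run imputation first)")
    conds: List[str] = []
    for s in design:
        if design[s] not in conds:
            conds.append(design[s])
    if len(conds) != 2:
        raise ValueError(f"exactly 2 conditions required, got {conds}")
    g1 = [s for s in data.columns if design[s] == conds[0]]
    g2 = [s for s in data.columns if design[s] == conds[1]]
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each condition needs >= 2 replicates")

    x1 = data[g1].to_numpy()
    x2 = data[g2].to_numpy()
    lfc = x2.mean(axis=1) - x1.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    d_g = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d_g

    if math.isinf(prior.d0):
        s2_mod = np.full_like(s2, prior.s0_sq)
        df_total = math.inf
    else:
        s2_mod = (prior.d0 * prior.s0_sq + d_g * s2) / (prior.d0 + d_g)
        df_total = prior.d0 + d_g

    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    if math.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df=df_total)
    p = np.clip(p, _TINY, 1.0)

    out = pd.DataFrame(
        {
            "lfc": lfc,
            "s2": s2,
            "df": float(d_g),
            "s2_mod": s2_mod,
            "t": t,
            "p": p,
        },
        index=data.index,
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sort ascending, take q_(i) = min_{j >= i} p_(j) * n / j, cap at 1 and
    restore the input order; tied p-values receive identical q.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def significance_call(
    lfc: Union[float, np.ndarray],
    q: Union[float, np.ndarray],
    config: AnalysisConfig,
) -> Union[bool, np.ndarray]:
    """Apply the combined fold-change / adjusted-p significance criterion.

    ``dual_threshold``: |lfc| >= lfc_min and q <= q_max. ``curve``: the
    effective adjusted-p threshold rises from 0 at |lfc| = lfc_min toward
    q_max asymptotically, q_thr = q_max * (1 - 2^(-k (|lfc| - lfc_min))).
    """
    lfc_arr = np.asarray(lfc, dtype=float)
    q_arr = np.asarray(q, dtype=float)
    a = np.abs(lfc_arr)
    if config.sig_mode == "dual_threshold":
        flag = (a >= config.lfc_min) & (q_arr <= config.q_max)
    else:
        q_thr = config.q_max * (1.0 - 2.0 ** (-config.curve_steepness * (a - config.lfc_min)))
        flag = (a > config.lfc_min) & (q_arr <= q_thr)
    if np.isscalar(lfc) and np.isscalar(q):
        return bool(flag)
    return flag


def aggregate_cycles(
    cycle_results: Sequence[pd.DataFrame],
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Combine per-cycle test results into the final DE table.

    Aggregated log2FC is the mean over cycles; p and q are per-cycle medians
    (diagnostics); ``n_cycles_significant`` counts per-cycle calls; the final
    flag requires significance in strictly more than half the cycles and the
    aggregated fold change itself passing the fold-change cut, so the
    reported lfc always supports the call. Direction follows the aggregated
    lfc sign.
    """
    if not cycle_results:
        raise ValueError("need >= 1 cycle result")
    index = cycle_results[0].index
    for r in cycle_results[1:]:
        if not index.equals(r.index):
            raise ValueError("cycle results have inconsistent protein sets")
    n_cycles = len(cycle_results)
    lfc = np.mean([r["lfc"].to_numpy() for r in cycle_results], axis=0)
    t = np.median([r["t"].to_numpy() for r in cycle_results], axis=0)
    p = np.median([r["p"].to_numpy() for r in cycle_results], axis=0)
    q = np.median([r["q"].to_numpy() for r in cycle_results], axis=0)
    per_cycle_calls = np.stack(
        [significance_call(r["lfc"].to_numpy(), r["q"].to_numpy(), config) for r in cycle_results]
    )
    n_sig = per_cycle_calls.sum(axis=0)

    a = np.abs(lfc)
    if config.sig_mode == "dual_threshold":
        lfc_ok = a >= config.lfc_min
    else:
        lfc_ok = a > config.lfc_min
    significant = (n_sig > n_cycles / 2.0) & lfc_ok

    direction = np.where(significant & (lfc > 0), "up", np.where(significant & (lfc < 0), "down", "ns"))
    return pd.DataFrame(
        {
            "lfc": lfc,
            "t": t,
            "p": p,
            "q": q,
            "n_cycles_significant": n_sig.astype(int),
            "significant": significant,
            "direction": direction,
        },
        index=index,
    )


def count_by_thresholds(table: pd.DataFrame, config: AnalysisConfig) -> Dict[str, int]:
    """Descriptive counts at the looser chart thresholds (strict inequalities).

    Uses the raw (unadjusted) p-value: down/up at |lfc| > count_lfc_cut,
    significant at p < count_p_cut, and their conjunctions.
    """
    if len(table) == 0:
        return {"down": 0, "up": 0, "significant": 0, "nonsignificant": 0,
                "down_sig": 0, "up_sig": 0}
    lfc = table["lfc"].to_numpy()
    p = table["p"].to_numpy()
    down = lfc < -config.count_lfc_cut
    up = lfc > config.count_lfc_cut
    sig = p < config.count_p_cut
    return {
        "down": int(down.sum()),
        "up": int(up.sum()),
        "significant": int(sig.sum()),
        "nonsignificant": int((~sig).sum()),
        "down_sig": int((down & sig).sum()),
        "up_sig": int((up & sig).sum()),
    }
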