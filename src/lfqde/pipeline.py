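"""End-to-end pipeline: filter -> classify -> impute cycles -> test -> aggregate."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional

import pandas as pd

from .config import AnalysisConfig
from .core import IntensityMatrix, filter_contaminants
from .diffexp import aggregate_cycles, fit_variance_prior, moderated_t
from .impute import ColumnStats, ImputedCycle, MissingnessLabels, classify_missing, column_stats, run_cycles

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything one run produces, for downstream summaries and audits."""

    matrix: IntensityMatrix  # after contaminant filtering
    labels: MissingnessLabels
    stats: ColumnStats
    cycles: List[ImputedCycle]
    cycle_results: List[pd.DataFrame]
    de_table: pd.DataFrame

    @property
    def mean_matrix(self) -> pd.DataFrame:
        """Across-cycle mean of the completed matrices (PCA/heatmap input)."""
        out = self.cycles[0].data.copy()
        for c in self.cycles[1:]:
            out += c.data
        return out / len(self.cycles)


def run_pipeline(m: IntensityMatrix, config: Optional[AnalysisConfig] = None) -> PipelineResult:
    """Run the differential-expression workflow on one intensity matrix.

    Contaminant rows are dropped, missing cells are routed by detection
    count, ``config.n_cycles`` stochastic completions are drawn, each is
    tested with the moderated t (prior refit per cycle) and BH-adjusted, and
    the per-cycle calls are aggregated by strict-majority vote.
    """
    config = config or AnalysisConfig()
    m = filter_contaminants(m, config)
    m.check_de_ready()
    conds = m.conditions
    logger.info("log2FC orientation: %s minus %s", conds[1], conds[0])
    labels = classify_missing(m)
    stats = column_stats(m)
    cycles = run_cycles(m, labels, stats, config)
    cycle_results = []
    for cyc in cycles:
        res = _test_one_cycle(cyc.data, m.design)
        cycle_results.append(res)
    de_table = aggregate_cycles(cycle_results, config)
    logger.info(
        "aggregation: mean lfc, median p/q, strict-majority vote over %d cycles",
        config.n_cycles,
    )
    return PipelineResult(
        matrix=m,
        labels=labels,
        stats=stats,
        cycles=cycles,
        cycle_results=cycle_results,
        de_table=de_table,
    )


def _test_one_cycle(data: pd.DataFrame, design) -> pd.DataFrame:
    # the prior is refit on this cycle's pooled variances
    conds: List[str] = []
    for s in design:
        if design[s] not in conds:
            conds.append(design[s])
    g1 = [s for s in data.columns if design[s] == conds[0]]
    g2 = [s for s in data.columns if design[s] == conds[1]]
    x1 = data[g1].to_numpy()
    x2 = data[g2].to_numpy()
    s2 = (
        (len(g1) - 1) * x1.var(axis=1, ddof=1) + (len(g2) - 1) * x2.var(axis=1, ddof=1)
    ) / (len(g1) + len(g2) - 2)
    prior = fit_variance_prior(s2, len(g1) + len(g2) - 2)
    return moderated_t(data, design, prior)
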