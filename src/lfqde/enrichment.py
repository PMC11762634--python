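"""Set over-representation and signed activation statistics.

Over-representation of a query (e.g. the significant proteins) in each named
set is scored by the one-sided hypergeometric tail — the Fisher exact test
for enrichment — with BH adjustment across sets. For sets carrying expected
regulation directions, a sign-agreement activation z-score
(n_agree - n_disagree) / sqrt(n_agree + n_disagree) summarizes whether the
observed up/down calls push the set's activity up (z > 0) or down (z < 0).
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GeneSetCollection
from .diffexp import bh_adjust

_TINY = np.finfo(float).tiny


def fisher_enrichment(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
    two_sided: bool = False,
) -> pd.DataFrame:
    """Per-set overlap significance against a background universe.

    Sets are intersected with the universe before testing. With overlap k,
    set size m, query size n and universe size N the one-sided p is the
    hypergeometric upper tail P(X >= k); ``two_sided`` switches to the
    two-sided Fisher exact test. Returns one row per set: k, m, n, N, p, q.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query)
    extra = query - universe
    if extra:
        raise ValueError(f"query ids outside the universe: {sorted(extra)[:5]}")
    N, n = len(universe), len(query)
    rows = []
    for name, (_, members) in sets.sets.items():
        mem = set(members) & universe
        m = len(mem)
        k = len(mem & query)
        if two_sided:
            table = [[k, m - k], [n - k, N - m - (n - k)]]
            p = float(sps.fisher_exact(table, alternative="two-sided")[1])
        else:
            p = float(sps.hypergeom.sf(k - 1, N, m, n))
        rows.append((name, k, m, n, N, min(max(p, _TINY), 1.0)))
    out = pd.DataFrame(rows, columns=["set", "k", "m", "n", "N", "p"]).set_index("set")
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


def activation_z(
    observed: Mapping[str, int],
    expected: Mapping[str, int],
) -> float:
    """Sign-agreement activation z-score for one regulon.

    ``observed`` maps member id -> observed regulation sign (+1 up, -1 down,
    0/absent unusable); ``expected`` maps member id -> the set's expected
    sign. z = (n_agree - n_disagree) / sqrt(n_agree + n_disagree); NaN when
    no member carries both signs.
    """
    agree = disagree = 0
    for member, exp_sign in expected.items():
        if exp_sign not in (1, -1):
            raise ValueError(f"expected sign for {member!r} must be +/-1")
        obs = observed.get(member, 0)
        if obs == 0:
            continue
        if obs == exp_sign:
            agree += 1
        else:
            disagree += 1
    total = agree + disagree
    if total == 0:
        return math.nan
    return (agree - disagree) / math.sqrt(total)


def activation_scores(
    de_table: pd.DataFrame,
    sets: GeneSetCollection,
) -> pd.Series:
    """Activation z per signed set, from a DE table's direction column."""
    if sets.directions is None:
        raise ValueError("collection carries no expected directions")
    observed = {
        pid: (1 if d == "up" else -1 if d == "down" else 0)
        for pid, d in de_table["direction"].items()
    }
    return pd.Series(
        {name: activation_z(observed, exp) for name, exp in sets.directions.items()},
        name="activation_z",
    )
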