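"""Core containers and text-format IO.

The central object is :class:`IntensityMatrix`: a proteins x samples table of
log2 intensities with explicit missing cells (NaN) plus a sample -> condition
design. Tables are plain TSV/CSV with a protein-id first column; the design is
a two-column file (sample, condition). Gene sets use the standard GMT layout.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .config import AnalysisConfig

logger = logging.getLogger(__name__)

#: strings read as missing cells on disk
NA_STRINGS = ("", "NA", "NaN", "nan", "na")


@dataclass
class IntensityMatrix:
    """Proteins x samples matrix of log2 intensities with a design.

    ``data`` holds one row per protein and one column per sample; missing
    cells are NaN. ``design`` maps every sample id to a condition label;
    condition order (hence log2FC orientation: second minus first) follows
    first appearance in the design.
    """

    data: pd.DataFrame
    design: Dict[str, str]
    is_log2: bool = True

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate protein id: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        missing_design = [s for s in self.data.columns if s not in self.design]
        if missing_design:
            raise ValueError(f"samples lack a condition assignment: {missing_design}")
        self.data = self.data.astype(float)

    @property
    def protein_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.columns)

    @property
    def conditions(self) -> List[str]:
        """Condition labels ordered by first appearance in the design."""
        seen: List[str] = []
        for s in self.design:
            c = self.design[s]
            if c not in seen:
                seen.append(c)
        return seen

    def condition_samples(self, condition: str) -> List[str]:
        return [s for s in self.data.columns if self.design[s] == condition]

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def check_de_ready(self) -> None:
        """DE requires exactly two conditions with >= 2 replicates each."""
        conds = self.conditions
        if len(conds) != 2:
            raise ValueError(f"differential expression needs exactly 2 conditions, got {conds}")
        for c in conds:
            if len(self.condition_samples(c)) < 2:
                raise ValueError(f"condition {c!r} has fewer than 2 replicates")


@dataclass
class GeneSetCollection:
    """Named member sets, optionally with expected regulation signs (+1/-1)."""

    sets: Dict[str, Tuple[str, Tuple[str, ...]]]
    directions: Optional[Dict[str, Dict[str, int]]] = None

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        if self.directions:
            for name, d in self.directions.items():
                bad = {v for v in d.values()} - {1, -1}
                if bad:
                    raise ValueError(f"set {name!r} has directions other than +/-1: {bad}")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> Tuple[str, ...]:
        return self.sets[name][1]


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_design(path) -> Dict[str, str]:
    """Read a two-column sample/condition table (optional header)."""
    df = pd.read_csv(path, sep=_sep_for(path), header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"design file needs two columns, got {df.shape[1]}")
    rows = df.iloc[:, :2].values.tolist()
    if rows and isinstance(rows[0][0], str) and rows[0][0].lower() in ("sample", "sample_id"):
        rows = rows[1:]
    design: Dict[str, str] = {}
    for sample, condition in rows:
        if sample in design:
            raise ValueError(f"duplicate sample in design: {sample!r}")
        design[sample] = condition
    return design


def write_design(design: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tcondition\n")
        for s, c in design.items():
            fh.write(f"{s}\t{c}\n")


def read_intensity_table(
    path,
    design: Union[Mapping[str, str], str, os.PathLike],
    config: Optional[AnalysisConfig] = None,
    is_log2: bool = True,
) -> IntensityMatrix:
    """Read a delimited proteins x samples intensity table.

    The first column holds protein ids, the header row sample ids. Empty
    cells and NA strings are missing; raw zeros become missing when
    ``config.zero_as_missing`` (default). When ``is_log2`` is false the
    positive raw intensities are log2-transformed on read.
    """
    config = config or AnalysisConfig()
    if not isinstance(design, Mapping):
        design = read_design(design)
    raw = pd.read_csv(
        path, sep=_sep_for(path), index_col=0, dtype=str,
        keep_default_na=False, na_values=list(NA_STRINGS),
    )
    for s in design:
        if s not in raw.columns:
            raise ValueError(f"design sample {s!r} not found in table header")
    raw = raw.loc[:, [c for c in raw.columns if c in design]]

    # cell-wise float() keeps parsing correctly rounded (bit-exact round trips)
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        values = np.empty(len(raw), dtype=float)
        for i, cell in enumerate(raw[col].to_numpy()):
            if not isinstance(cell, str):  # NA cell
                values[i] = np.nan
                continue
            try:
                values[i] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell at protein {raw.index[i]!r}, sample {col!r}: {cell!r}"
                ) from None
        numeric[col] = values

    if config.zero_as_missing:
        n_zero = int((numeric == 0).to_numpy().sum())
        if n_zero:
            logger.info("treating %d zero intensities as missing", n_zero)
            numeric = numeric.mask(numeric == 0)

    if not is_log2:
        neg = numeric < 0
        if neg.to_numpy().any():
            raise ValueError("negative raw intensities cannot be log2 transformed")
        numeric = np.log2(numeric)

    return IntensityMatrix(data=numeric, design=dict(design), is_log2=True)


def write_intensity_table(m: IntensityMatrix, path) -> None:
    """Write the matrix as TSV/CSV with NA for missing cells.

    Floats are written with 17 significant digits so a write/read cycle
    reproduces values bit-identically.
    """
    m.data.to_csv(
        path, sep=_sep_for(path), na_rep="NA", index_label="protein", float_format="%.17g"
    )


def filter_contaminants(m: IntensityMatrix, config: Optional[AnalysisConfig] = None) -> IntensityMatrix:
    """Drop rows whose protein id starts with a contaminant/decoy prefix."""
    config = config or AnalysisConfig()
    prefixes = tuple(config.contaminant_prefixes)
    if prefixes:
        keep = [not str(p).startswith(prefixes) for p in m.data.index]
    else:
        keep = [True] * len(m.data.index)
    removed = len(keep) - sum(keep)
    logger.info("filter_contaminants removed %d of %d rows", removed, len(keep))
    if sum(keep) == 0:
        logger.warning("all rows matched contaminant prefixes; matrix is empty")
    return IntensityMatrix(data=m.data.loc[keep], design=dict(m.design), is_log2=m.is_log2)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB member...

    Duplicate members within a set are dropped (first occurrence kept).
    """
    sets: Dict[str, Tuple[str, Tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
            name, description, *members = fields
            deduped = tuple(dict.fromkeys(m for m in members if m))
            sets[name] = (description, deduped)
    return GeneSetCollection(sets=sets)


def read_regulons(path) -> GeneSetCollection:
    """Read a signed set table: set TAB member TAB direction(+1/-1)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise ValueError("regulon file needs three columns: set, member, direction")
    sets: Dict[str, Tuple[str, Tuple[str, ...]]] = {}
    directions: Dict[str, Dict[str, int]] = {}
    for name, member, sign in df.iloc[:, :3].values:
        directions.setdefault(name, {})[member] = int(sign)
    for name, d in directions.items():
        sets[name] = ("", tuple(d))
    return GeneSetCollection(sets=sets, directions=directions)
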