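"""Consensus differentially-expressed gene sets across cell-line groups.

Each cell line contributes a differential-expression table (gene, log2
fold-change ATRA vs vehicle, FDR).  Per line, the significantly (FDR <
0.1) up- and down-regulated sets are extracted; a group's consensus sets
are the intersections of those per-line sets, and overlaps between groups
identify genes modulated in the same direction everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_FDR_MAX = 0.1

DE_COLUMNS = ["gene", "log2fc", "fdr"]


@dataclass
class ConsensusSets:
    group: str
    member_lines: list[str]
    common_up: set[str]
    common_down: set[str]

    def __post_init__(self) -> None:
        overlap = self.common_up & self.common_down
        if overlap:
            raise ValueError(f"genes in both consensus arms: {sorted(overlap)}")


def _validate_de(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DE table missing columns: {missing}")
    if table["gene"].duplicated().any():
        raise ValueError("duplicate genes within a DE table")
    fdr = table["fdr"].to_numpy(dtype=float)
    if np.any((fdr < 0) | (fdr > 1) | ~np.isfinite(fdr)):
        raise ValueError("fdr must lie in [0, 1]")
    if not np.all(np.isfinite(table["log2fc"].to_numpy(dtype=float))):
        raise ValueError("log2fc must be finite")
    return table


def significant_sets(table: pd.DataFrame, fdr_max: float = DEFAULT_FDR_MAX) -> tuple[set[str], set[str]]:
    """Split a DE table into (up, down) sets at strict ``fdr < fdr_max``.

    Rows with log2fc == 0 belong to neither set.
    """
    tab = _validate_de(table)
    sig = tab[tab["fdr"] < fdr_max]
    up = set(sig.loc[sig["log2fc"] > 0, "gene"])
    down = set(sig.loc[sig["log2fc"] < 0, "gene"])
    return up, down


def common_sets(
    tables: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
    fdr_max: float = DEFAULT_FDR_MAX,
    group: str = "group",
) -> ConsensusSets:
    """Intersect per-line significant sets into group consensus sets.

    A gene absent from any member table is treated as not significant in
    that line, so it cannot enter the consensus.  A gene up in one line
    and down in another is excluded from both arms by intersection.
    """
    if isinstance(tables, Mapping):
        items = list(tables.items())
    else:
        items = [(f"line_{i + 1}", t) for i, t in enumerate(tables)]
    if len(items) < 2:
        raise ValueError("need >=2 DE tables for a consensus")
    per_line = [significant_sets(t, fdr_max=fdr_max) for _, t in items]
    common_up = set.intersection(*(up for up, _ in per_line))
    common_down = set.intersection(*(down for _, down in per_line))
    return ConsensusSets(
        group=group,
        member_lines=[name for name, _ in items],
        common_up=common_up,
        common_down=common_down,
    )


def cross_group_overlap(a: ConsensusSets, b: ConsensusSets) -> tuple[set[str], set[str]]:
    """Genes shared by two groups' consensus sets, per direction."""
    return a.common_up & b.common_up, a.common_down & b.common_down
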