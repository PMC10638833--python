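"""Dose-response scoring: vehicle normalization, AUC and the ATRA-score.

The sensitivity of a cell line to all-trans retinoic acid (ATRA) is
summarised by the area under its vehicle-normalized growth curve,
integrated over log10(concentration).  Within a panel, AUCs are inverted
and min-max rescaled so the most inhibited line scores 1.00 and the least
inhibited 0.00; lines at or above a threshold (default 0.55) are called
"high" sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

GROWTH_COLUMNS = ["cell_line", "concentration_uM", "day", "replicate", "viability"]

DEFAULT_THRESHOLD = 0.55
DEFAULT_DAY = 6


@dataclass
class DoseResponseCurve:
    """A vehicle-normalized growth curve for one cell line at one day.

    ``log10_conc`` is strictly increasing; ``response`` is expressed as a
    percentage of the vehicle mean (vehicle itself is 100 by construction
    and excluded, since log10(0) is undefined).
    """

    cell_line: str
    day: int
    log10_conc: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        self.log10_conc = np.asarray(self.log10_conc, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.log10_conc.ndim != 1 or self.log10_conc.shape != self.response.shape:
            raise ValueError("log10_conc and response must be 1-D and equal length")
        if not np.all(np.isfinite(self.log10_conc)) or not np.all(np.isfinite(self.response)):
            raise ValueError(f"non-finite values in curve for {self.cell_line!r}")
        if np.any(np.diff(self.log10_conc) <= 0):
            raise ValueError(f"concentrations not strictly increasing for {self.cell_line!r}")


def _validate_growth(raw: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GROWTH_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"growth table missing columns: {missing}")
    tab = raw[GROWTH_COLUMNS].copy()
    if tab["viability"].isna().any() or not np.all(np.isfinite(tab["viability"])):
        raise ValueError("viability must be finite")
    if (tab["viability"] < 0).any():
        raise ValueError("viability must be >= 0")
    if (tab["concentration_uM"] < 0).any():
        raise ValueError("concentrations must be >= 0")
    return tab


def normalize_growth(raw: pd.DataFrame, day: int = DEFAULT_DAY) -> list[DoseResponseCurve]:
    """Normalize raw viability to the vehicle mean (taken as 100%).

    For each cell line at the requested day, replicates are averaged per
    concentration and expressed as ``100 * mean(conc) / mean(vehicle)``.
    Concentration 0 encodes vehicle.  Returns one curve per line, ordered
    by cell-line name and by concentration within a curve.
    """
    tab = _validate_growth(raw)
    tab = tab[tab["day"] == day]
    if tab.empty:
        raise ValueError(f"no measurements at day {day}")
    curves: list[DoseResponseCurve] = []
    for line, grp in tab.groupby("cell_line", sort=True):
        vehicle = grp.loc[grp["concentration_uM"] == 0, "viability"]
        if vehicle.empty:
            raise ValueError(f"no vehicle (concentration 0) records for line {line!r} at day {day}")
        v_mean = float(vehicle.mean())
        if v_mean == 0:
            raise ValueError(f"vehicle mean viability is 0 for line {line!r}")
        treated = grp[grp["concentration_uM"] > 0]
        means = treated.groupby("concentration_uM", sort=True)["viability"].mean()
        if len(means) < 2:
            raise ValueError(f"line {line!r} has fewer than 2 non-zero concentrations at day {day}")
        curves.append(
            DoseResponseCurve(
                cell_line=str(line),
                day=int(day),
                log10_conc=np.log10(means.index.to_numpy(dtype=float)),
                response=100.0 * means.to_numpy(dtype=float) / v_mean,
            )
        )
    return curves


def compute_auc(curve: DoseResponseCurve) -> float:
    """Trapezoidal area under the response curve over log10(concentration).

    Units are %·log10-µM.  Requires at least two points and a strictly
    increasing abscissa (both enforced by :class:`DoseResponseCurve`).
    """
    if len(curve.log10_conc) < 2:
        raise ValueError(f"need >=2 points to integrate curve for {curve.cell_line!r}")
    return float(np.trapezoid(curve.response, curve.log10_conc))


def compute_atra_scores(aucs: Mapping[str, float]) -> pd.DataFrame:
    """Inverted min-max rescaling of panel AUCs to ATRA-scores in [0, 1].

    ``score_i = (max(AUC) - AUC_i) / (max(AUC) - min(AUC))``: the line with
    the smallest AUC (strongest response) scores exactly 1.00, the largest
    exactly 0.00.  Degenerate panels (all AUCs identical) are rejected.
    """
    if len(aucs) < 2:
        raise ValueError("need AUCs from >=2 cell lines to rescale")
    lines = list(aucs)
    a = np.asarray([aucs[k] for k in lines], dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("AUCs must be finite")
    span = a.max() - a.min()
    if span == 0:
        raise ValueError("all AUCs identical: ATRA-score undefined for a degenerate panel")
    scores = (a.max() - a) / span
    return pd.DataFrame({"cell_line": lines, "auc": a, "atra_score": scores})


def classify_sensitivity(scores: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Append high/low sensitivity calls: ``high`` iff score >= threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    s = scores["atra_score"].to_numpy(dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("atra_score values must lie in [0, 1]")
    out = scores.copy()
    out["call"] = np.where(s >= threshold, "high", "low")
    return out


class AtraScorer(BaseEstimator):
    """Panel-level ATRA-score estimator over a long-format growth table.

    Parameters
    ----------
    day:
        Day of exposure used for scoring (day 6 is the reference basis;
        other days are accepted and flagged in :attr:`metadata_`).
    threshold:
        ATRA-score at or above which a line is called "high" sensitivity.

    Attributes
    ----------
    curves_ : list of DoseResponseCurve
    auc_ : dict mapping cell line to AUC (%·log10-µM)
    score_table_ : DataFrame with cell_line, auc, atra_score, call
    """

    def __init__(self, day: int = DEFAULT_DAY, threshold: float = DEFAULT_THRESHOLD):
        self.day = day
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None) -> "AtraScorer":
        """Compute curves, AUCs and rescaled scores from a growth table."""
        self.curves_ = normalize_growth(X, day=self.day)
        self.auc_ = {c.cell_line: compute_auc(c) for c in self.curves_}
        table = compute_atra_scores(self.auc_)
        self.score_table_ = classify_sensitivity(table, threshold=self.threshold)
        self.metadata_ = {
            "day": self.day,
            "threshold": self.threshold,
            "n_lines": len(self.curves_),
            "nonreference_day": self.day != DEFAULT_DAY,
        }
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Score a growth table; equivalent to ``fit(X).score_table_``."""
        return self.fit(X).score_table_
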