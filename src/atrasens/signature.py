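"""Derivation of the ATRA-sensitivity expression signature.

Basal (untreated) log2-CPM expression of each gene is correlated with the
panel's ATRA-scores (Spearman).  Genes passing the screen (p < 0.01 and
|rho| > 0.4 by default) form a candidate list split into a *direct* arm
(rho > 0: high basal expression goes with high sensitivity) and an
*inverse* arm (rho < 0).  The candidate list is then pruned by protein-
interaction connectivity: only genes with degree >= 2 within the subgraph
induced by the candidates are retained.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

DEFAULT_P_MAX = 0.01
DEFAULT_RHO_MIN = 0.4
DEFAULT_MIN_DEGREE = 2

_EXACT_N_MAX = 8  # exact permutation null enumerated up to this sample size


@dataclass
class SensitivitySignature:
    """A directional gene signature with per-gene screening statistics.

    ``direct`` and ``inverse`` are disjoint; ``stats`` holds one row per
    signature gene (gene, direction, rho, p, and -- after connectivity
    filtering -- degree).  ``meta`` records thresholds and stage counts.
    """

    direct: list[str]
    inverse: list[str]
    stats: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.direct) & set(self.inverse)
        if overlap:
            raise ValueError(f"genes in both arms: {sorted(overlap)}")

    @property
    def genes(self) -> list[str]:
        return list(self.direct) + list(self.inverse)


def _exact_spearman_pvalues(rank_x: np.ndarray, rank_y: np.ndarray) -> np.ndarray:
    """Two-sided permutation p-values for Spearman rho, exhaustively.

    ``rank_x`` is (n_genes, n) of per-gene expression ranks, ``rank_y`` the
    score ranks.  All n! permutations of the score ranks are enumerated
    (feasible for n <= 8); ties are handled because correlations are
    computed directly on the (possibly tied, averaged) rank vectors.
    """
    n = rank_y.size
    perms = np.array(list(itertools.permutations(rank_y)), dtype=float)  # (n!, n)
    pc = perms - perms.mean(axis=1, keepdims=True)
    pc_norm = np.linalg.norm(pc, axis=1)
    xc = rank_x - rank_x.mean(axis=1, keepdims=True)
    x_norm = np.linalg.norm(xc, axis=1)
    pvals = np.full(rank_x.shape[0], np.nan)
    ok = x_norm > 0
    if not np.any(ok):
        return pvals
    # null rho for every gene x permutation pair
    null = (xc[ok] @ pc.T) / (x_norm[ok, None] * pc_norm[None, :])
    yc = rank_y - rank_y.mean()
    obs = (xc[ok] @ yc) / (x_norm[ok] * np.linalg.norm(yc))
    pvals[ok] = np.mean(np.abs(null) >= np.abs(obs)[:, None] - 1e-12, axis=1)
    return pvals


def correlate_expression(expr: pd.DataFrame, scores: pd.Series | pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of each gene's basal expression with ATRA-scores.

    Parameters
    ----------
    expr:
        genes x samples log2-CPM matrix (unique row/column ids).
    scores:
        per-sample ATRA-scores; a Series indexed by sample, or a score
        table with ``cell_line`` and ``atra_score`` columns.

    Returns a DataFrame (gene, rho, p, n) over the samples shared between
    the two inputs.  Average ranks handle ties; p-values are two-sided,
    from exhaustive permutation for n <= 8 and the t-approximation above.
    Constant genes get NaN rho/p and are excluded downstream.
    """
    if isinstance(scores, pd.DataFrame):
        scores = scores.set_index("cell_line")["atra_score"]
    if expr.index.duplicated().any() or expr.columns.duplicated().any():
        raise ValueError("duplicate gene or sample identifiers in expression matrix")
    shared = [s for s in expr.columns if s in scores.index]
    n = len(shared)
    if n < 3:
        raise ValueError(f"need >=3 shared samples for correlation, found {n}")
    X = expr[shared].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("expression matrix contains non-finite values")
    y = scores.loc[shared].to_numpy(dtype=float)

    rank_x = stats.rankdata(X, axis=1)
    rank_y = stats.rankdata(y)
    xc = rank_x - rank_x.mean(axis=1, keepdims=True)
    yc = rank_y - rank_y.mean()
    x_norm = np.linalg.norm(xc, axis=1)
    y_norm = np.linalg.norm(yc)
    constant = x_norm == 0
    if y_norm == 0:
        raise ValueError("scores are constant across shared samples")
    rho = np.full(X.shape[0], np.nan)
    rho[~constant] = (xc[~constant] @ yc) / (x_norm[~constant] * y_norm)
    rho = np.clip(rho, -1.0, 1.0)

    if n <= _EXACT_N_MAX:
        p = _exact_spearman_pvalues(rank_x, rank_y)
    else:
        p = np.full(X.shape[0], np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        finite = ~constant
        p[finite] = 2.0 * stats.t.sf(np.abs(t[finite]), df=n - 2)
        p[finite & (np.abs(rho) >= 1.0)] = 0.0
        p = np.where(~constant, np.minimum(p, 1.0), np.nan)
    return pd.DataFrame({"gene": expr.index, "rho": rho, "p": p, "n": n})


def select_candidates(
    stats_table: pd.DataFrame,
    p_max: float = DEFAULT_P_MAX,
    rho_min: float = DEFAULT_RHO_MIN,
) -> SensitivitySignature:
    """Threshold the correlation screen: keep p < p_max and |rho| > rho_min.

    Direction is *direct* for rho > 0, *inverse* for rho < 0.  The rho
    cutoff is applied to |rho| so that inversely correlated genes are kept
    alongside directly correlated ones.
    """
    if stats_table.empty:
        raise ValueError("empty correlation table")
    usable = stats_table.dropna(subset=["rho", "p"])
    kept = usable[(usable["p"] < p_max) & (usable["rho"].abs() > rho_min)].copy()
    kept["direction"] = np.where(kept["rho"] > 0, "direct", "inverse")
    direct = kept.loc[kept["direction"] == "direct", "gene"].tolist()
    inverse = kept.loc[kept["direction"] == "inverse", "gene"].tolist()
    return SensitivitySignature(
        direct=direct,
        inverse=inverse,
        stats=kept[["gene", "direction", "rho", "p"]].reset_index(drop=True),
        meta={"p_max": p_max, "rho_min": rho_min, "n_candidates": len(kept)},
    )


def connectivity_filter(
    cands: SensitivitySignature,
    graph: nx.Graph,
    min_degree: int = DEFAULT_MIN_DEGREE,
) -> SensitivitySignature:
    """Prune candidates by degree within their induced interaction subgraph.

    A single pass: each candidate's degree is counted against the other
    candidates only (not the whole graph), and genes with degree below
    ``min_degree`` are dropped.  Candidates absent from the graph have
    degree 0 (a warning lists them).
    """
    if min_degree < 0:
        raise ValueError("min_degree must be >= 0")
    genes = cands.genes
    missing = [g for g in genes if g not in graph]
    if missing:
        warnings.warn(
            f"{len(missing)} candidate gene(s) absent from the interaction graph "
            f"(degree 0): {missing[:10]}{'...' if len(missing) > 10 else ''}",
            stacklevel=2,
        )
    sub = graph.subgraph([g for g in genes if g in graph])
    degree = {g: (sub.degree(g) if g in sub else 0) for g in genes}
    keep = {g for g in genes if degree[g] >= min_degree}
    stats_out = cands.stats[cands.stats["gene"].isin(keep)].copy()
    stats_out["degree"] = stats_out["gene"].map(degree)
    meta = dict(cands.meta)
    meta.update({"min_degree": min_degree, "n_connected": len(keep)})
    return SensitivitySignature(
        direct=[g for g in cands.direct if g in keep],
        inverse=[g for g in cands.inverse if g in keep],
        stats=stats_out.reset_index(drop=True),
        meta=meta,
    )


def derive_signature(
    expr: pd.DataFrame,
    scores: pd.Series | pd.DataFrame,
    graph: nx.Graph,
    p_max: float = DEFAULT_P_MAX,
    rho_min: float = DEFAULT_RHO_MIN,
    min_degree: int = DEFAULT_MIN_DEGREE,
) -> SensitivitySignature:
    """Full signature derivation: correlate, threshold, connectivity-prune.

    Deterministic given identical inputs.  Stage counts and thresholds are
    recorded in the result's ``meta``.
    """
    corr = correlate_expression(expr, scores)
    cands = select_candidates(corr, p_max=p_max, rho_min=rho_min)
    sig = connectivity_filter(cands, graph, min_degree=min_degree)
    sig.meta.update(
        {
            "n_genes_screened": len(corr),
            "n_constant": int(corr["rho"].isna().sum()),
            "n_samples": int(corr["n"].iloc[0]) if len(corr) else 0,
        }
    )
    return sig


class SensitivitySignatureScreen(BaseEstimator):
    """Estimator wrapper around the correlation + connectivity screen.

    Follows the scikit-learn convention: ``X`` is samples x genes and ``y``
    the per-sample ATRA-scores.  The interaction graph is a structural
    hyperparameter, like a precomputed connectivity matrix.

    Attributes
    ----------
    stats_ : DataFrame of per-gene rho/p over the screened genes
    signature_ : SensitivitySignature (direct + inverse arms)
    direct_, inverse_ : lists of retained gene ids
    """

    def __init__(
        self,
        graph: nx.Graph | None = None,
        p_max: float = DEFAULT_P_MAX,
        rho_min: float = DEFAULT_RHO_MIN,
        min_degree: int = DEFAULT_MIN_DEGREE,
    ):
        self.graph = graph
        self.p_max = p_max
        self.rho_min = rho_min
        self.min_degree = min_degree

    def fit(self, X: pd.DataFrame, y) -> "SensitivitySignatureScreen":
        if self.graph is None:
            raise ValueError("an interaction graph is required (graph=...)")
        expr = X.T  # genes x samples
        y = pd.Series(np.asarray(y, dtype=float), index=X.index)
        self.stats_ = correlate_expression(expr, y)
        self.signature_ = derive_signature(
            expr, y, self.graph, p_max=self.p_max, rho_min=self.rho_min, min_degree=self.min_degree
        )
        self.direct_ = list(self.signature_.direct)
        self.inverse_ = list(self.signature_.inverse)
        return self
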