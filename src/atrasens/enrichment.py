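"""Per-sample Similarity-scores from a directional signature (ssGSEA-style).

Each sample's genes are ranked by decreasing expression and a single-sample
enrichment score is computed for the direct and the inverse signature arm
as the summed difference between a rank-weighted in-set ECDF and the
uniform out-of-set ECDF (the Barbie-type running-sum statistic with
exponent alpha, default 0.25).  The Similarity-score is
``ES(direct) - ES(inverse)``; within a cohort it is min-max rescaled to a
predicted ATRA-score in [0, 1], and samples at or above the 0.55 threshold
are called "high" predicted sensitivity.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .dose_response import DEFAULT_THRESHOLD
from .signature import SensitivitySignature

DEFAULT_ALPHA = 0.25


def ssgsea_score(
    profile: pd.Series,
    gene_set: Iterable[str],
    alpha: float = DEFAULT_ALPHA,
    method: str = "ssgsea",
) -> float:
    """Single-sample enrichment score of ``gene_set`` in one expression profile.

    Genes are ordered by decreasing expression (ties keep average ranks and
    are broken deterministically by gene id).  Walking down that list, the
    in-set ECDF steps by ``rank^alpha`` (ascending average rank, so the
    top-expressed gene carries the largest weight), normalized so the set's
    weights sum to 1; the out-of-set ECDF steps uniformly by ``1/(N-m)``.

    ``method="ssgsea"`` returns the sum of (in-set ECDF - out-of-set ECDF)
    over all positions (the integral form); ``method="ks_max"`` returns the
    signed maximum-deviation (Kolmogorov-Smirnov-like) variant.
    """
    if method not in ("ssgsea", "ks_max"):
        raise ValueError(f"unknown method {method!r}")
    values = profile.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("expression profile contains non-finite values")
    genes = profile.index
    in_set = genes.isin(set(gene_set)).astype(bool)
    m = int(in_set.sum())
    n = len(genes)
    if m == 0:
        raise ValueError("gene set does not intersect the profile")
    if m == n:
        raise ValueError("gene set covers the whole profile; out-of-set ECDF undefined")

    ranks = stats.rankdata(values)  # ascending, average ties
    # decreasing expression; stable tie-break on gene id for determinism
    by_gene = np.argsort(np.asarray(genes, dtype=object), kind="stable")
    order = by_gene[np.argsort(-values[by_gene], kind="stable")]
    w = np.where(in_set[order], ranks[order] ** alpha, 0.0)
    w_total = w.sum()
    step_in = np.cumsum(w) / w_total
    step_out = np.cumsum(np.where(in_set[order], 0.0, 1.0)) / (n - m)
    diff = step_in - step_out
    if method == "ssgsea":
        return float(diff.sum())
    return float(diff[np.argmax(np.abs(diff))])


def similarity_scores(
    expr: pd.DataFrame,
    sig: SensitivitySignature,
    alpha: float = DEFAULT_ALPHA,
    method: str = "ssgsea",
) -> pd.DataFrame:
    """Per-sample ES(direct), ES(inverse) and their difference.

    ``expr`` is genes x samples.  An arm with no gene in the matrix
    contributes 0, but at least one arm must be represented.
    """
    direct = [g for g in sig.direct if g in expr.index]
    inverse = [g for g in sig.inverse if g in expr.index]
    if not direct and not inverse:
        raise ValueError("no signature gene present in the expression matrix")
    rows = []
    for sample in expr.columns:
        profile = expr[sample]
        es_d = ssgsea_score(profile, direct, alpha=alpha, method=method) if direct else 0.0
        es_i = ssgsea_score(profile, inverse, alpha=alpha, method=method) if inverse else 0.0
        rows.append((sample, es_d, es_i, es_d - es_i))
    return pd.DataFrame(rows, columns=["sample", "es_direct", "es_inverse", "similarity"])


def predict_atra_scores(
    similarity: pd.DataFrame | pd.Series,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Min-max rescale cohort Similarity-scores to predicted ATRA-scores.

    The rescaling mirrors the experimental score's construction: the
    highest-similarity sample maps to 1.00 and the lowest to 0.00.  Calls
    follow the same >= threshold rule as the experimental score.
    """
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if isinstance(similarity, pd.Series):
        table = pd.DataFrame({"sample": similarity.index, "similarity": similarity.to_numpy()})
    else:
        table = similarity.copy()
    sim = table["similarity"].to_numpy(dtype=float)
    if len(sim) < 2:
        raise ValueError("need >=2 samples to rescale similarity scores")
    span = sim.max() - sim.min()
    if span == 0:
        raise ValueError("all similarity values identical: predicted score undefined")
    table["predicted_score"] = (sim - sim.min()) / span
    table["call"] = np.where(table["predicted_score"] >= threshold, "high", "low")
    return table


class SimilarityScorePredictor(BaseEstimator):
    """Cohort-level predicted-ATRA-score estimator from a gene signature.

    ``X`` is samples x genes (scikit-learn orientation).  ``fit`` computes
    the cohort similarity range; ``predict_table`` returns the full
    enrichment table (es_direct, es_inverse, similarity, predicted_score,
    call); ``transform`` returns the predicted scores; ``predict`` the
    high/low calls.

    The min-max map is cohort-relative: predicted scores are comparable
    within the fitted cohort, not across cohorts.
    """

    def __init__(
        self,
        signature: SensitivitySignature | None = None,
        alpha: float = DEFAULT_ALPHA,
        threshold: float = DEFAULT_THRESHOLD,
        method: str = "ssgsea",
    ):
        self.signature = signature
        self.alpha = alpha
        self.threshold = threshold
        self.method = method

    def fit(self, X: pd.DataFrame, y=None) -> "SimilarityScorePredictor":
        if self.signature is None:
            raise ValueError("a SensitivitySignature is required (signature=...)")
        sim = similarity_scores(X.T, self.signature, alpha=self.alpha, method=self.method)
        table = predict_atra_scores(sim, threshold=self.threshold)
        self.table_ = table
        self.similarity_min_ = float(sim["similarity"].min())
        self.similarity_max_ = float(sim["similarity"].max())
        return self

    def predict_table(self, X: pd.DataFrame) -> pd.DataFrame:
        """Enrichment table for a new cohort using the fitted similarity range."""
        sim = similarity_scores(X.T, self.signature, alpha=self.alpha, method=self.method)
        span = self.similarity_max_ - self.similarity_min_
        sim["predicted_score"] = np.clip(
            (sim["similarity"] - self.similarity_min_) / span, 0.0, 1.0
        )
        sim["call"] = np.where(sim["predicted_score"] >= self.threshold, "high", "low")
        return sim

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        return self.predict_table(X)["predicted_score"].to_numpy()

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.predict_table(X)["call"].to_numpy()
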