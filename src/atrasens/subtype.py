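"""Nearest-template subtype classification (G-INT / G-DIFF) and clustering.

A subtype template assigns each template gene to one class.  Samples are
classified by restricting the expression matrix to template genes,
z-scoring each gene across the cohort, and assigning every sample to the
class whose +1/-1 centroid vector (+1 at the class's own genes, -1 at the
other template genes) lies at the smallest Euclidean distance.
Classification accuracy is estimated by repeated random-split
cross-validation with empirical training centroids; cohort structure can
also be inspected with Ward/Euclidean hierarchical clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from sklearn.base import BaseEstimator, ClassifierMixin

DEFAULT_N_PERM = 100
DEFAULT_SPLIT_FRACTION = 0.5
_MAX_SPLIT_RETRIES = 100


@dataclass
class SubtypeTemplate:
    """Mapping gene -> class label with at least two classes."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.entries.values())) < 2:
            raise ValueError("template must contain >=2 classes")

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.entries.values()))

    @property
    def genes(self) -> list[str]:
        return list(self.entries)


@dataclass
class CrossValidationResult:
    n_perm: int
    split_fraction: float
    accuracies: np.ndarray
    mean_accuracy: float = field(init=False)
    sd_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if len(self.accuracies) != self.n_perm:
            raise ValueError("one accuracy per permutation required")
        if np.any((self.accuracies < 0) | (self.accuracies > 1)):
            raise ValueError("accuracies must lie in [0, 1]")
        self.mean_accuracy = float(self.accuracies.mean())
        self.sd_accuracy = float(self.accuracies.std(ddof=1)) if self.n_perm > 1 else 0.0


def _standardized_template_matrix(
    expr: pd.DataFrame, template: SubtypeTemplate
) -> tuple[np.ndarray, list[str]]:
    """Restrict to usable template genes and z-score each across samples."""
    if expr.shape[1] < 2:
        raise ValueError("need >=2 samples for per-gene standardization")
    genes = [g for g in template.genes if g in expr.index]
    sub = expr.loc[genes].to_numpy(dtype=float)
    if np.any(~np.isfinite(sub)):
        raise ValueError("expression matrix contains non-finite values")
    sd = sub.std(axis=1, ddof=0)
    dropped = [g for g, s in zip(genes, sd) if s == 0]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance template gene(s): {dropped[:5]}",
                      stacklevel=3)
        keep = sd > 0
        genes = [g for g, k in zip(genes, keep) if k]
        sub, sd = sub[keep], sd[keep]
    if len(genes) < 2:
        raise ValueError("fewer than 2 usable template genes in the expression matrix")
    Z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    return Z, genes


def ntp_classify(expr: pd.DataFrame, template: SubtypeTemplate) -> pd.DataFrame:
    """Assign each sample (column of ``expr``) to the nearest class centroid.

    Returns a table with the assignment, one ``dist_<class>`` column per
    class, and the margin (second-best minus best distance).  Exact ties
    break to the alphabetically first class with a warning.
    """
    Z, genes = _standardized_template_matrix(expr, template)
    classes = template.classes
    centroids = np.array(
        [[1.0 if template.entries[g] == k else -1.0 for g in genes] for k in classes]
    )  # n_classes x n_genes
    # distances: samples x classes
    D = np.sqrt(((Z.T[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2))
    best = D.argmin(axis=1)
    sorted_d = np.sort(D, axis=1)
    margin = sorted_d[:, 1] - sorted_d[:, 0]
    ties = np.isclose(margin, 0.0)
    if ties.any():
        warnings.warn(
            f"{int(ties.sum())} sample(s) equidistant from two templates; "
            "tie broken to the first class label", stacklevel=2,
        )
    out = pd.DataFrame({"sample": expr.columns, "assigned": [classes[i] for i in best]})
    for j, k in enumerate(classes):
        out[f"dist_{k}"] = D[:, j]
    out["margin"] = margin
    return out


def ntp_cross_validate(
    expr: pd.DataFrame,
    template: SubtypeTemplate,
    labels: pd.Series | None = None,
    n_perm: int = DEFAULT_N_PERM,
    split_fraction: float = DEFAULT_SPLIT_FRACTION,
    seed: int | None = None,
) -> CrossValidationResult:
    """Random-split cross-validation of nearest-template classification.

    Reference labels default to the full-cohort template calls (the
    procedure is then optimistically biased under the null, since the
    reference labels are derived from the same data; supply external
    ``labels`` for an unbiased estimate).  Per permutation, samples are
    split into training and test sets; empirical class centroids are the
    means of the training samples' standardized profiles grouped by
    reference label, and accuracy is the fraction of test samples whose
    nearest empirical centroid agrees with their reference label.  Splits
    missing a class in either half are resampled (bounded retries).
    """
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must be in (0, 1)")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Z, genes = _standardized_template_matrix(expr, template)
    samples = list(expr.columns)
    if labels is None:
        ref = ntp_classify(expr, template).set_index("sample")["assigned"]
    else:
        ref = labels.reindex(samples)
        if ref.isna().any():
            raise ValueError("labels missing for some samples")
    y = ref.loc[samples].to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("reference labels contain a single class; nothing to cross-validate")
    n = len(samples)
    n_train = int(round(split_fraction * n))
    if n_train < len(classes) or n - n_train < len(classes):
        raise ValueError("cohort too small for the requested split")
    rng = np.random.default_rng(seed)
    accuracies = np.empty(n_perm)
    for b in range(n_perm):
        for _ in range(_MAX_SPLIT_RETRIES):
            perm = rng.permutation(n)
            train, test = perm[:n_train], perm[n_train:]
            if set(y[train]) == set(classes) and set(y[test]) == set(classes):
                break
        else:
            raise RuntimeError("could not draw a split containing every class")
        centroids = np.array([Z[:, train[y[train] == k]].mean(axis=1) for k in classes])
        D = np.sqrt(((Z[:, test].T[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2))
        pred = classes[D.argmin(axis=1)]
        accuracies[b] = float(np.mean(pred == y[test]))
    return CrossValidationResult(n_perm=n_perm, split_fraction=split_fraction,
                                 accuracies=accuracies)


def hclust_samples(expr: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Ward's minimum-variance agglomeration of samples on Euclidean distances.

    Returns the SciPy linkage matrix and the sample order matching its leaf
    indices.  Merge heights are non-decreasing by construction of Ward
    linkage.
    """
    if expr.shape[1] < 2:
        raise ValueError("need >=2 samples to cluster")
    X = expr.to_numpy(dtype=float).T  # samples x genes
    if np.any(~np.isfinite(X)):
        raise ValueError("expression matrix contains NaN or infinite values")
    return linkage(X, method="ward", metric="euclidean"), list(expr.columns)


class NearestTemplateClassifier(ClassifierMixin, BaseEstimator):
    """scikit-learn-style nearest-template subtype classifier.

    The template supplies the classes, so ``fit`` is unsupervised: it
    validates the template against the cohort and stores the full-cohort
    calls.  Classification is transductive (per-gene z-scores are computed
    across the cohort being classified), so ``predict`` re-standardizes
    within the given cohort.
    """

    def __init__(self, template: SubtypeTemplate | None = None):
        self.template = template

    def fit(self, X: pd.DataFrame, y=None) -> "NearestTemplateClassifier":
        if self.template is None:
            raise ValueError("a SubtypeTemplate is required (template=...)")
        self.classes_ = np.array(self.template.classes)
        self.calls_ = ntp_classify(X.T, self.template)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return ntp_classify(X.T, self.template)["assigned"].to_numpy()

    def cross_validate(self, X: pd.DataFrame, labels: pd.Series | None = None,
                       n_perm: int = DEFAULT_N_PERM,
                       split_fraction: float = DEFAULT_SPLIT_FRACTION,
                       seed: int | None = None) -> CrossValidationResult:
        return ntp_cross_validate(X.T, self.template, labels=labels, n_perm=n_perm,
                                  split_fraction=split_fraction, seed=seed)
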