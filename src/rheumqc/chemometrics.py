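"""Multivariate and correlation machinery for the quality-assessment pipeline.

Covers principal component analysis (PCA), orthogonal projections to latent
structures discriminant analysis (OPLS-DA) with cross-validated R²/Q², Ward
hierarchical clustering, two-group t tests, Spearman rank correlation and
the thresholded compound–DL correlation network.

OPLS-DA follows the standard two-block NIPALS scheme: after autoscaling,
variation in X orthogonal to the class variable y is removed component by
component, and a single predictive PLS component is fitted on the filtered
matrix.  R² is the in-fit fraction of class variance explained; Q² is
1 − PRESS/TSS under stratified k-fold cross-validation in which scaling and
filtering are re-estimated inside each training fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA as _SKPCA

__all__ = [
    "FeatureMatrix",
    "LatentModel",
    "CorrelationEdge",
    "pca",
    "oplsda",
    "ward_hclust",
    "ttest_two_group",
    "spearman_rho",
    "classify_rho",
    "correlation_network",
    "edges_to_frame",
]

# |rho| class bounds for the correlation network
RHO_WEAK = 0.30
RHO_MODERATE = 0.50
RHO_STRONG = 0.70


@dataclass(frozen=True)
class FeatureMatrix:
    """Samples × features data block with optional per-sample class labels."""

    sample_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray
    class_labels: tuple | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.values, dtype=float)
        if X.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError("values must be (n_samples, n_features)")
        if len(self.sample_ids) < 2:
            raise ValueError("need at least two samples")
        if np.any(~np.isfinite(X)):
            raise ValueError("values contain missing or non-finite entries")
        if self.class_labels is not None and len(self.class_labels) != len(self.sample_ids):
            raise ValueError("class_labels length must match sample_ids")
        object.__setattr__(self, "values", X)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, labels: Sequence | None = None) -> "FeatureMatrix":
        return cls(
            sample_ids=tuple(str(i) for i in df.index),
            feature_names=tuple(str(c) for c in df.columns),
            values=df.to_numpy(dtype=float),
            class_labels=tuple(labels) if labels is not None else None,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_names)
        )


@dataclass(frozen=True)
class LatentModel:
    """Scores/loadings of a latent-variable model plus fit statistics.

    For PCA, ``explained_variance`` holds per-component variances and R2/Q2
    are None.  For OPLS-DA, the first score/loading column is the predictive
    component and the rest are orthogonal components; R2 is the in-fit
    explained class variance and Q2 its cross-validated counterpart.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray | None = None
    R2: float | None = None
    Q2: float | None = None
    feature_names: tuple[str, ...] | None = None
    sample_ids: tuple[str, ...] | None = None
    kind: str = "pca"

    def __post_init__(self) -> None:
        if self.R2 is not None and self.Q2 is not None and self.Q2 > self.R2 + 1e-9:
            raise ValueError("Q2 cannot exceed R2 for the same model and data")


@dataclass(frozen=True)
class CorrelationEdge:
    """One compound ↔ DL-property Spearman correlation with its strength class."""

    compound: str
    dl_property: str
    rho: float
    strength: Literal["none", "weak", "moderate", "strong"]
    sign: Literal["positive", "negative"]

    @property
    def is_linear(self) -> bool:
        """True when |rho| exceeds the linear-relationship threshold (0.30)."""
        return self.strength != "none"


def _nonconstant(X: np.ndarray) -> np.ndarray:
    """Columns whose spread is meaningfully above floating-point noise."""
    sd = X.std(axis=0, ddof=1)
    return sd > 1e-12 * (np.abs(X).max(axis=0) + 1.0)


def _autoscale(X: np.ndarray, drop_constant: bool = False):
    """Mean-center and unit-variance scale; optionally drop constant features."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = _nonconstant(X)
    if not drop_constant and not keep.all():
        raise ValueError("constant feature encountered with scaling enabled")
    sd_safe = np.where(keep, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd_safe, keep


def pca(
    X: FeatureMatrix,
    center: bool = True,
    scale: bool = True,
    n_components: int | None = None,
) -> LatentModel:
    """Principal component analysis of a feature block.

    Constant features are dropped (with a warning) when scaling is requested,
    since unit-variance scaling is undefined for them.
    """
    values = X.values
    names = np.asarray(X.feature_names)
    if scale:
        keep = _nonconstant(values)
        if not keep.all():
            warnings.warn(
                f"dropping constant feature(s) before scaling: {list(names[~keep])}",
                stacklevel=2,
            )
            values = values[:, keep]
            names = names[keep]
        values = values / values.std(axis=0, ddof=1)
    if center:
        values = values - values.mean(axis=0)
    max_rank = min(values.shape[0] - 1, values.shape[1])
    k = max_rank if n_components is None else n_components
    if k > max_rank:
        raise ValueError(f"n_components={k} exceeds rank bound {max_rank}")
    model = _SKPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(values)
    return LatentModel(
        scores=scores,
        loadings=model.components_.T,
        explained_variance=model.explained_variance_,
        feature_names=tuple(names),
        sample_ids=X.sample_ids,
        kind="pca",
    )


def _encode_binary(labels: Sequence) -> np.ndarray:
    classes = sorted(set(labels), key=str)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    return np.where(np.asarray(labels) == classes[1], 1.0, -1.0)


def _opls_fit(Xc: np.ndarray, y: np.ndarray, n_orthogonal: int):
    """Core OPLS decomposition on centered/scaled X and centered y.

    Returns (W_orth, P_orth, w_pred, p_pred, coef) such that new data are
    deflated by the orthogonal loadings and projected on w_pred; coef maps
    filtered X to predicted y.
    """
    X = Xc.copy()
    W_o, P_o = [], []
    for _ in range(n_orthogonal):
        w = X.T @ y / (y @ y)
        w /= np.linalg.norm(w)
        t = X @ w
        p = X.T @ t / (t @ t)
        w_orth = p - (w @ p) * w
        norm = np.linalg.norm(w_orth)
        if norm < 1e-12:
            break  # no orthogonal variation left
        w_orth /= norm
        t_orth = X @ w_orth
        p_orth = X.T @ t_orth / (t_orth @ t_orth)
        X = X - np.outer(t_orth, p_orth)
        W_o.append(w_orth)
        P_o.append(p_orth)
    w = X.T @ y / (y @ y)
    w /= np.linalg.norm(w)
    t = X @ w
    p = X.T @ t / (t @ t)
    q = float(y @ t / (t @ t))
    return np.array(W_o), np.array(P_o), w, p, q


def _opls_filter(X: np.ndarray, W_o: np.ndarray, P_o: np.ndarray) -> np.ndarray:
    for w_orth, p_orth in zip(W_o, P_o):
        t_orth = X @ w_orth
        X = X - np.outer(t_orth, p_orth)
    return X


def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Deterministic stratified fold assignment (round-robin within class)."""
    fold = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def oplsda(
    X: FeatureMatrix,
    n_orthogonal: int = 1,
    cv_folds: int = 7,
    seed: int = 0,
) -> LatentModel:
    """OPLS-DA of a two-class feature block with cross-validated Q².

    The class variable is encoded ±1 and centered; X is autoscaled.  If the
    smaller class has fewer members than ``cv_folds`` the fold count is
    reduced (with a warning) so every fold sees both classes.
    """
    if X.class_labels is None:
        raise ValueError("oplsda requires class_labels on the feature matrix")
    y = _encode_binary(X.class_labels)
    if np.allclose(X.values.std(axis=0), 0):
        raise ValueError("feature matrix carries no variation")

    smallest = min(int((y == 1).sum()), int((y == -1).sum()))
    if smallest < cv_folds:
        warnings.warn(
            f"reducing cv_folds from {cv_folds} to {smallest} "
            "(smaller class has too few members)",
            stacklevel=2,
        )
        cv_folds = max(2, smallest)

    Xs, _, _, keep = _autoscale(X.values, drop_constant=True)
    Xs = Xs[:, keep]
    yc = y - y.mean()

    W_o, P_o, w, p, q = _opls_fit(Xs, yc, n_orthogonal)
    Xf = _opls_filter(Xs, W_o, P_o)
    t_pred = Xf @ w
    y_hat = q * t_pred
    tss = float(yc @ yc)
    r2 = 1.0 - float((yc - y_hat) @ (yc - y_hat)) / tss

    # cross-validated PRESS with in-fold preprocessing
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(y, cv_folds, rng)
    press = 0.0
    for k in range(cv_folds):
        test = fold == k
        train = ~test
        Xtr = X.values[train]
        mean = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0, ddof=1)
        ok = _nonconstant(Xtr)
        Xtr_s = (Xtr[:, ok] - mean[ok]) / sd[ok]
        Xte_s = (X.values[test][:, ok] - mean[ok]) / sd[ok]
        ytr = y[train]
        ytr_c = ytr - ytr.mean()
        Wo, Po, wk, pk, qk = _opls_fit(Xtr_s, ytr_c, n_orthogonal)
        Xte_f = _opls_filter(Xte_s, Wo, Po)
        y_pred = qk * (Xte_f @ wk) + ytr.mean()
        press += float(np.sum((y[test] - y_pred) ** 2))
    q2 = 1.0 - press / tss

    # orthogonal scores on the fitted model, for plotting
    scores = [t_pred]
    loadings = [p]
    Xtmp = Xs.copy()
    for w_orth, p_orth in zip(W_o, P_o):
        scores.append(Xtmp @ w_orth)
        loadings.append(p_orth)
        Xtmp = Xtmp - np.outer(Xtmp @ w_orth, p_orth)
    names = tuple(np.asarray(X.feature_names)[keep])
    return LatentModel(
        scores=np.column_stack(scores),
        loadings=np.column_stack(loadings),
        R2=r2,
        Q2=min(q2, r2),  # guard against CV noise nudging Q2 past R2
        feature_names=names,
        sample_ids=X.sample_ids,
        kind="oplsda",
    )


def ward_hclust(X: FeatureMatrix, k: int = 2):
    """Ward hierarchical clustering on Euclidean distances.

    Returns ``(labels, linkage_matrix)`` where labels are 1-based cluster
    indices from cutting the tree at ``k`` clusters and the linkage matrix
    follows the scipy convention (merge heights are the Ward-scaled
    Euclidean distances between merged clusters, non-decreasing).
    """
    if k > len(X.sample_ids):
        raise ValueError(f"k={k} exceeds the number of samples")
    Z = hierarchy.linkage(X.values, method="ward", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return labels, Z


def ttest_two_group(
    a: Sequence[float],
    b: Sequence[float],
    variant: Literal["student", "welch"] = "student",
) -> tuple[float, float, float]:
    """Two-sided unpaired t test; Student (pooled variance) by default.

    Returns (t, df, p).  Two identical constant groups give t=0, p=1; zero
    variance with different means drives p toward 0 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            df = a.size + b.size - 2 if variant == "student" else float(a.size + b.size - 2)
            return 0.0, float(df), 1.0
        warnings.warn("zero variance with different means; p -> 0", stacklevel=2)
        return math.inf if a.mean() > b.mean() else -math.inf, float(a.size + b.size - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mean ranks for ties); NaN if not computable."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def classify_rho(rho: float) -> tuple[str, str]:
    """(strength, sign) class of a Spearman coefficient.

    A linear relationship requires |rho| strictly above 0.30; 0.50 and 0.70
    bound the moderate and strong classes inclusively.
    """
    if math.isnan(rho):
        return "none", "positive"
    a = abs(rho)
    if a <= RHO_WEAK:
        strength = "none"
    elif a < RHO_MODERATE:
        strength = "weak"
    elif a < RHO_STRONG:
        strength = "moderate"
    else:
        strength = "strong"
    return strength, "negative" if rho < 0 else "positive"


def correlation_network(
    compounds: FeatureMatrix, dl: pd.DataFrame
) -> list[CorrelationEdge]:
    """Spearman correlation edges between every compound and DL property.

    ``dl`` is a per-sample table indexed by sample_id with columns
    I0/Tau/Beta/T.  All (compound, property) pairs are returned; edges with
    strength above "none" carry the "linear relationship" flag through
    :attr:`CorrelationEdge.is_linear`.
    """
    dl_ids = [str(i) for i in dl.index]
    missing = sorted(set(compounds.sample_ids) ^ set(dl_ids))
    if missing:
        raise ValueError(f"sample mismatch between tables: {missing}")
    dl = dl.loc[list(compounds.sample_ids)]
    edges = []
    for j, name in enumerate(compounds.feature_names):
        for prop in ("I0", "Tau", "Beta", "T"):
            rho = spearman_rho(compounds.values[:, j], dl[prop].to_numpy())
            strength, sign = classify_rho(rho)
            edges.append(
                CorrelationEdge(
                    compound=name, dl_property=prop, rho=rho, strength=strength, sign=sign
                )
            )
    return edges


def edges_to_frame(edges: Sequence[CorrelationEdge]) -> pd.DataFrame:
    """Edge list as a DataFrame (TSV-exportable for network tools)."""
    return pd.DataFrame(
        [
            {
                "compound": e.compound,
                "dl_property": e.dl_property,
                "rho": e.rho,
                "sign": e.sign,
                "strength": e.strength,
                "linear_relationship": e.is_linear,
            }
            for e in edges
        ]
    )
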