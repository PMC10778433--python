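"""Correlation, principal-component and cluster exploration of the samples.

PCA is performed on the correlation matrix (standardized variables): the
responses mix units (% DW, mg/kg, dimensionless color), so covariance PCA
would be dominated by the mg/kg minerals. Hierarchical clustering defaults
to Ward linkage on raw Euclidean distances, which reproduces the study's
printed sample partitions where any standard linkage does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster
from scipy.cluster.hierarchy import linkage as scipy_linkage

from .dataset import RESPONSES, StudyDataset

__all__ = ["CHEMICAL_VARS", "MINERAL_VARS", "BIOACTIVE_COLOR_VARS",
           "VARIABLE_SETS", "CorrelationResult", "correlation_matrix",
           "PCAResult", "pca", "variable_contributions",
           "ClusterResult", "hcluster"]

#: Proximate chemical-composition variables (Table 2 of the study design).
CHEMICAL_VARS = ("moisture", "sugars", "proteins", "cellulose", "carbs",
                 "fats", "ash")
#: Mineral variables (mg/kg).
MINERAL_VARS = ("K", "Mg", "Ca", "Fe", "Na")
#: Bioactivity assays plus CIELab color.
BIOACTIVE_COLOR_VARS = ("phenols", "dpph", "abts", "rp", "soa", "aia",
                        "ahga", "a", "b", "L")

VARIABLE_SETS = {
    "chemical": CHEMICAL_VARS,
    "minerals": MINERAL_VARS,
    "bioactives": BIOACTIVE_COLOR_VARS,
    "all": RESPONSES,
}


def _matrix(ds: StudyDataset | pd.DataFrame,
            variables=None) -> pd.DataFrame:
    df = ds.responses if isinstance(ds, StudyDataset) else ds
    if variables is not None:
        missing = [v for v in variables if v not in df.columns]
        if missing:
            raise KeyError(f"unknown variable(s) {missing}")
        df = df[list(variables)]
    const = [c for c in df.columns if df[c].nunique() == 1]
    if const:
        raise ValueError(f"constant variable(s) {const} cannot be analyzed")
    return df


@dataclass
class CorrelationResult:
    """Pairwise Pearson correlations with two-sided p-values."""

    r: pd.DataFrame
    p: pd.DataFrame

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.p <= alpha

    def to_csv(self, path) -> None:
        self.r.to_csv(path)


def correlation_matrix(ds: StudyDataset | pd.DataFrame,
                       variables=None) -> CorrelationResult:
    """Pearson correlation matrix over the samples.

    p-values come from the exact t-transform of r; no multiplicity
    correction is applied.
    """
    df = _matrix(ds, variables)
    n = len(df)
    if n < 3:
        raise ValueError("need at least 3 samples for correlations")
    X = df.to_numpy(float)
    R = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(R, 1.0)
    # two-sided p via the t distribution with n-2 df
    rr = np.clip(R, -0.9999999999, 0.9999999999)
    t = rr * np.sqrt((n - 2) / (1 - rr ** 2))
    P = 2 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(P, 0.0)
    cols = df.columns
    return CorrelationResult(pd.DataFrame(R, index=cols, columns=cols),
                             pd.DataFrame(P, index=cols, columns=cols))


@dataclass
class PCAResult:
    """Eigendecomposition of the correlation (or covariance) matrix."""

    eigenvalues: np.ndarray
    variance_fractions: np.ndarray        # percent, sums to 100
    scores: pd.DataFrame                  # samples x components
    loadings: pd.DataFrame                # variables x components
    eigenvectors: pd.DataFrame            # variables x components, unit norm

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def contributions(self, component: int) -> pd.Series:
        """Per-variable contribution (%) to one component (1-based).

        Squared unit-norm eigenvector entries; sums to 100 per component.
        """
        if not 1 <= component <= self.n_components:
            raise IndexError(f"component must be in 1..{self.n_components}")
        v = self.eigenvectors.iloc[:, component - 1]
        return 100.0 * v ** 2 / np.sum(v ** 2)


def pca(ds: StudyDataset | pd.DataFrame, variables=None,
        standardize: bool = True) -> PCAResult:
    """Principal components of the selected variables across samples.

    With ``standardize`` (default) the decomposition is of the correlation
    matrix. Components are oriented so that each one's largest-magnitude
    eigenvector entry is positive (a deterministic sign convention).
    """
    df = _matrix(ds, variables)
    if df.shape[1] < 2 or len(df) < 3:
        raise ValueError("need >= 2 variables and >= 3 samples")
    X = df.to_numpy(float)
    Xc = X - X.mean(axis=0)
    if standardize:
        Xc = Xc / X.std(axis=0, ddof=1)
    C = (Xc.T @ Xc) / (len(X) - 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for k in range(evecs.shape[1]):            # deterministic sign
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] *= -1
    comp = [f"PC{k+1}" for k in range(len(evals))]
    scores = Xc @ evecs
    loadings = evecs * np.sqrt(evals)
    index = (ds.responses.index if isinstance(ds, StudyDataset)
             else df.index)
    return PCAResult(
        eigenvalues=evals,
        variance_fractions=100.0 * evals / evals.sum(),
        scores=pd.DataFrame(scores, index=index, columns=comp),
        loadings=pd.DataFrame(loadings, index=df.columns, columns=comp),
        eigenvectors=pd.DataFrame(evecs, index=df.columns, columns=comp),
    )


def variable_contributions(result: PCAResult, component: int) -> pd.Series:
    """Alias for `PCAResult.contributions` (1-based component index)."""
    return result.contributions(component)


_LINKAGES = ("ward", "complete", "average", "single", "weighted")
_METRICS = ("euclidean", "cityblock", "chebyshev", "cosine", "correlation")


@dataclass
class ClusterResult:
    """Agglomerative merge tree over samples with flat-cut memberships."""

    merges: np.ndarray                     # scipy linkage matrix
    ids: np.ndarray                        # sample ids in leaf order

    def membership(self, k: int) -> pd.Series:
        """Cluster label (1..k) per sample id at a k-cluster cut."""
        labels = fcluster(self.merges, k, criterion="maxclust")
        return pd.Series(labels, index=self.ids, name="cluster")

    def groups(self, k: int) -> set[frozenset]:
        """The k clusters as frozensets of sample ids."""
        m = self.membership(k)
        return {frozenset(m.index[m == g]) for g in m.unique()}

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges,
                            columns=["left", "right", "height", "size"])


def hcluster(ds: StudyDataset | pd.DataFrame, variables=None,
             linkage: str = "ward", metric: str = "euclidean",
             standardize: bool = False) -> ClusterResult:
    """Hierarchical agglomerative clustering of samples.

    Defaults (Ward linkage, Euclidean metric, unstandardized variables)
    match the study's analysis; the printed linkage-distance magnitudes
    indicate distances on the raw measurement scales.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; one of {_LINKAGES}")
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; one of {_METRICS}")
    if linkage == "ward" and metric != "euclidean":
        raise ValueError("ward linkage requires the euclidean metric")
    df = _matrix(ds, variables)
    if len(df) < 2:
        raise ValueError("need at least 2 samples to cluster")
    X = df.to_numpy(float)
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    Z = scipy_linkage(X, method=linkage, metric=metric)
    ids = (ds.responses.index.to_numpy() if isinstance(ds, StudyDataset)
           else df.index.to_numpy())
    return ClusterResult(Z, ids)
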