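"""Principal component analysis of the stress-tolerance index matrix.

The seven indices span orders of magnitude (STI near 1 versus a
published-mode GMPI near 0.01), so the default is correlation-matrix
PCA: each index standardized, eigendecomposition of the explicit
correlation matrix so that the eigenvalues sum exactly to the number of
variables. Loadings are eigenvectors scaled by the square root of their
eigenvalue; the sign of each component is fixed so its largest-magnitude
loading is positive (biplot orientation is otherwise arbitrary). The
contribution of a variable to a component is its squared loading as a
percentage of the component's total squared loading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PcaResult", "pca_on_indices", "variable_contributions", "scree_data"]


@dataclass(frozen=True)
class PcaResult:
    scaling: str  # "correlation" | "covariance"
    eigenvalues: np.ndarray  # descending
    variance_pct: np.ndarray
    cumulative_pct: np.ndarray
    loadings: pd.DataFrame  # variables × components
    contributions_pct: pd.DataFrame  # variables × components

    @property
    def components(self) -> list[str]:
        return list(self.loadings.columns)


def pca_on_indices(matrix: pd.DataFrame, scaling: str = "correlation") -> PcaResult:
    """Eigendecomposition of the index matrix's correlation (default) or
    covariance matrix.

    Requires >= 3 rows and no missing cells; under correlation scaling a
    constant column has no defined standardization and is rejected by
    name.
    """
    if scaling not in ("correlation", "covariance"):
        raise ValueError("scaling must be 'correlation' or 'covariance'")
    X = matrix.astype(float)
    if len(X) < 3:
        raise ValueError("need at least 3 observations for PCA")
    if X.isna().any().any():
        raise ValueError("index matrix contains missing cells")

    if scaling == "correlation":
        constant = [c for c in X.columns if np.isclose(X[c].std(ddof=0), 0.0)]
        if constant:
            raise ValueError(f"constant column(s) under correlation scaling: {constant}")
        S = np.corrcoef(X.to_numpy(), rowvar=False)
    else:
        S = np.cov(X.to_numpy(), rowvar=False)

    w, V = np.linalg.eigh(S)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    V = V[:, order]

    # sign convention: largest-|loading| entry of each component positive
    for k in range(V.shape[1]):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]

    loadings = V * np.sqrt(w)[None, :]
    comp_names = [f"PC{i + 1}" for i in range(len(w))]
    loadings = pd.DataFrame(loadings, index=X.columns, columns=comp_names)

    sq = loadings**2
    denom = sq.sum(axis=0)
    contrib = pd.DataFrame(
        np.where(denom.to_numpy() > 0, 100.0 * sq / denom.replace(0, np.nan), np.nan),
        index=X.columns,
        columns=comp_names,
    )

    pct = 100.0 * w / w.sum()
    return PcaResult(
        scaling=scaling,
        eigenvalues=w,
        variance_pct=pct,
        cumulative_pct=np.cumsum(pct),
        loadings=loadings,
        contributions_pct=contrib,
    )


def variable_contributions(result: PcaResult, component: int) -> pd.Series:
    """Percent contribution of each variable to one component (1-based).

    Undefined (all-NaN) for a zero-eigenvalue component.
    """
    if not 1 <= component <= len(result.eigenvalues):
        raise IndexError(f"component {component} out of range")
    return result.contributions_pct[f"PC{component}"]


def scree_data(result: PcaResult) -> pd.DataFrame:
    """Scree table with the Kaiser retention flag (eigenvalue > 1)."""
    return pd.DataFrame(
        {
            "component": result.components,
            "eigenvalue": result.eigenvalues,
            "variance_pct": result.variance_pct,
            "cumulative_pct": result.cumulative_pct,
            "kaiser": result.eigenvalues > 1.0,
        }
    )
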