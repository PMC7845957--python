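"""Principal component analysis on the standardised feature matrix.

The covariance of standardised data equals its correlation matrix, so the
PCA here is the classical route: C = X^T X / (n-1), symmetric
eigendecomposition, eigenvalues in descending order, scores Y = X A.  For
n observations of centred data at most n-1 eigenvalues are non-zero; the
zero cutoff is ``RANK_TOL`` times the largest eigenvalue.

Eigenvector signs are fixed so each column's entry sum is non-negative
(ties broken by making the first non-zero entry positive); with features
aligned to a common rating this renders the first component's weights all
positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .features import FeatureDataset, StandardizationConstants

__all__ = ["RANK_TOL", "PCAModel", "covariance_matrix", "eigendecompose",
           "project", "variance_fractions", "fit_pca"]

#: eigenvalues below RANK_TOL * lambda_max count as zero
RANK_TOL = 1e-10

_SYM_TOL = 1e-8


def _as_matrix(X: FeatureDataset | np.ndarray) -> np.ndarray:
    if isinstance(X, FeatureDataset):
        return X.values
    return np.asarray(X, dtype=float)


def covariance_matrix(X: FeatureDataset | np.ndarray) -> np.ndarray:
    """Sample covariance C = X^T X / (n-1) of standardised data.

    Input must already be standardised (zero mean, unit sample variance per
    column); then C coincides with the pairwise correlation matrix.
    """
    values = _as_matrix(X)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need an n x p matrix with n >= 2")
    if np.abs(values.mean(axis=0)).max() > 1e-8:
        raise ValueError("input is not centred; standardise first")
    if np.abs(values.std(axis=0, ddof=1) - 1.0).max() > 1e-6:
        raise ValueError("input does not have unit sample variance")
    return values.T @ values / (values.shape[0] - 1)


def eigendecompose(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Real eigenpairs of a symmetric matrix, descending, sign-fixed.

    Returns (eigenvalues, eigenvectors) with unit-norm eigenvector columns.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("C must be square")
    if np.abs(C - C.T).max() > _SYM_TOL:
        raise ValueError("C is not symmetric")
    eigenvalues, eigenvectors = np.linalg.eigh((C + C.T) / 2.0)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    eigenvectors = eigenvectors[:, order]
    for j in range(eigenvectors.shape[1]):
        column = eigenvectors[:, j]
        total = column.sum()
        if abs(total) > 1e-12:
            sign = np.sign(total)
        else:
            nonzero = column[np.abs(column) > 1e-12]
            sign = np.sign(nonzero[0]) if nonzero.size else 1.0
        eigenvectors[:, j] = column * sign
    return eigenvalues, eigenvectors


def project(X: FeatureDataset | np.ndarray, A: np.ndarray) -> np.ndarray:
    """Scores Y = X A."""
    values = _as_matrix(X)
    A = np.asarray(A, dtype=float)
    if values.shape[1] != A.shape[0]:
        raise ValueError(
            f"shape mismatch: X has {values.shape[1]} columns, "
            f"A has {A.shape[0]} rows")
    return values @ A


def variance_fractions(eigenvalues: np.ndarray) -> np.ndarray:
    """Percentage of total variance per component (sums to 100)."""
    w = np.asarray(eigenvalues, dtype=float)
    if np.any(w < -1e-10):
        raise ValueError("eigenvalues must be non-negative (beyond round-off)")
    w = np.clip(w, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero spectrum")
    return 100.0 * w / total


@dataclass
class PCAModel:
    """Eigenstructure of a standardised feature dataset.

    Holds everything needed to project new observations: the eigenpairs,
    variance fractions, the column labels, and the standardisation
    constants of the training data.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    scores: np.ndarray
    fractions: np.ndarray
    columns: tuple[str, ...]
    constants: StandardizationConstants | None = None

    @property
    def n_components(self) -> int:
        """Number of eigenvalues above the rank tolerance."""
        if self.eigenvalues.size == 0:
            return 0
        cutoff = RANK_TOL * float(self.eigenvalues.max())
        return int(np.sum(self.eigenvalues > cutoff))

    def to_json(self, path, n_vectors: int = 3) -> None:
        payload = {
            "schema": "biospeckle-pca/1",
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_fractions_percent": self.fractions.tolist(),
            "columns": list(self.columns),
            "eigenvectors": self.eigenvectors[:, :n_vectors].T.tolist(),
            "standardization": None if self.constants is None else {
                "means": self.constants.means.tolist(),
                "stds": self.constants.stds.tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def fit_pca(X: FeatureDataset | np.ndarray,
            constants: StandardizationConstants | None = None,
            columns: tuple[str, ...] | None = None) -> PCAModel:
    """Full PCA of a standardised dataset: covariance, eigenpairs, scores."""
    values = _as_matrix(X)
    if columns is None:
        columns = tuple(X.columns) if isinstance(X, FeatureDataset) \
            else tuple(f"x{k}" for k in range(values.shape[1]))
    C = covariance_matrix(values)
    eigenvalues, eigenvectors = eigendecompose(C)
    scores = project(values, eigenvectors)
    fractions = variance_fractions(eigenvalues)
    return PCAModel(eigenvalues=eigenvalues, eigenvectors=eigenvectors,
                    scores=scores, fractions=fractions, columns=columns,
                    constants=constants)
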