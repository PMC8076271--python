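"""PCA on second-derivative spectra and cluster-separation scoring.

Principal component analysis of DII traces is the standard chemometric
view of a spectral panel: amyloid and non-amyloid spectra separate along
the leading components because the fibril band near 1630 cm^-1 dominates
the covariance.  Separation is quantified with the mean silhouette of the
class labels in score space, since visual cluster separation has no
printed coordinates to compare against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .spectra import DerivativeSpectrum

__all__ = ["PcaResult", "pca_on_dii", "separation_score"]


@dataclass(frozen=True)
class PcaResult:
    """Scores, loadings and explained variance of a spectral PCA."""

    scores: np.ndarray  # (n_spectra, n_components)
    explained_variance_fraction: np.ndarray  # (n_components,)
    loadings: np.ndarray  # (n_components, n_wavenumbers)
    wavenumbers: np.ndarray
    labels: tuple | None = None

    def __post_init__(self) -> None:
        evf = np.asarray(self.explained_variance_fraction, dtype=float)
        if np.any(evf < -1e-12) or np.any(evf > 1 + 1e-12) or evf.sum() > 1 + 1e-9:
            raise ValueError("explained variance fractions must lie in [0, 1] and sum <= 1")
        if np.any(np.diff(evf) > 1e-12):
            raise ValueError("explained variance fractions must be non-increasing")


def pca_on_dii(
    spectra: list[DerivativeSpectrum],
    n_components: int = 2,
    labels=None,
) -> PcaResult:
    """Mean-centered PCA over a panel of DII traces on a common grid.

    No unit-variance scaling is applied.  Each component is oriented so
    that its largest-magnitude loading is positive, which makes score
    plots reproducible (PCA is otherwise sign-ambiguous).

    Raises
    ------
    ValueError
        With fewer than 3 spectra, mismatched grids, ``n_components``
        exceeding the data rank, or a zero-variance panel.
    """
    if len(spectra) < 3:
        raise ValueError("need at least 3 spectra for PCA")
    grid = spectra[0].wavenumbers
    for s in spectra[1:]:
        if s.wavenumbers.shape != grid.shape or not np.allclose(s.wavenumbers, grid):
            raise ValueError("all spectra must share one wavenumber grid")
    X = np.vstack([s.dii for s in spectra])
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if not (1 <= n_components <= max_rank):
        raise ValueError(f"n_components must lie in [1, {max_rank}] for this panel")
    if np.allclose(X - X.mean(axis=0), 0):
        raise ValueError("zero-variance panel: all spectra identical")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    loadings = pca.components_.copy()
    for k in range(n_components):
        if loadings[k, np.argmax(np.abs(loadings[k]))] < 0:
            loadings[k] *= -1
            scores[:, k] *= -1
    return PcaResult(
        scores=scores,
        explained_variance_fraction=pca.explained_variance_ratio_,
        loadings=loadings,
        wavenumbers=grid,
        labels=tuple(labels) if labels is not None else None,
    )


def separation_score(result: PcaResult, k_components: int = 2) -> float:
    """Mean silhouette of the class labels in the first ``k`` score axes.

    Values near 1 indicate tight, well-separated class clusters; values
    near 0 indicate overlap; negative values indicate misassignment.

    Raises
    ------
    ValueError
        If the result carries no labels or only one class is present.
    """
    if result.labels is None:
        raise ValueError("PcaResult carries no labels")
    labels = np.asarray(result.labels)
    if np.unique(labels).size < 2:
        raise ValueError("separation score needs at least 2 classes")
    k = min(k_components, result.scores.shape[1])
    return float(silhouette_score(result.scores[:, :k], labels))
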