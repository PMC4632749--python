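"""PCA of log10-normalized metabolite profiles.

Covariance PCA: profiles are log10-transformed, column-mean-centered and
decomposed by eigendecomposition of the sample covariance matrix — no
unit-variance scaling by default, matching the classic metabolomics-viewer
convention (scaling is available via a flag). Signs are fixed
deterministically (the largest-magnitude loading of each component is made
positive) so outputs are stable across linear-algebra backends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AbundanceTable


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # metabolites x components
    explained_variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def log10_normalize(table: AbundanceTable) -> pd.DataFrame:
    """Elementwise log10 of the abundance matrix (positivity is an invariant)."""
    if (table.data <= 0).any().any():
        raise ValueError("abundances must be > 0 for log10 normalization")
    return np.log10(table.data)


def pca(table: AbundanceTable, k: int = 2, scale: bool = False) -> PCAResult:
    """Covariance PCA of the log10 profiles with k retained components."""
    X = log10_normalize(table).to_numpy(float)
    n, m = X.shape
    if not 1 <= k <= min(n - 1, m):
        raise ValueError(f"k={k} out of range for {n} samples x {m} metabolites")
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    cov = np.cov(X, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(eigvecs.shape[1]):
        pivot = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[pivot, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    total = float(eigvals.sum())
    frac = eigvals / total if total > 0 else np.zeros_like(eigvals)
    comps = [f"PC{i + 1}" for i in range(k)]
    loadings = pd.DataFrame(eigvecs[:, :k], index=table.metabolites, columns=comps)
    scores = pd.DataFrame(X @ eigvecs[:, :k], columns=comps)
    return PCAResult(scores, loadings, frac[:k])


def top_loadings(result: PCAResult, component: int, n: int | None = None) -> list[str]:
    """Metabolites ranked by |loading| on one component (1-based index).

    Ties are broken alphabetically; ``n`` beyond the panel returns the full
    ranking.
    """
    if not 1 <= component <= result.n_components:
        raise ValueError(f"component {component} not in 1..{result.n_components}")
    col = result.loadings[f"PC{component}"]
    ranked = sorted(col.index, key=lambda name: (-abs(col[name]), name))
    return ranked if n is None else ranked[:n]
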