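"""Cross-environment concordance of genotype GSL profiles via PCA.

Principal components are fitted on one reference environment's genotype
mean profiles (covariance PCA: centered, unscaled, since all structures
share pmol/mm^2 units).  Genotype means from other environments are then
projected onto the same loadings and the per-component scores correlated
against the reference scores: high correlations mean the genotypes keep
the same relative chemotypes across environments even if absolute levels
shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = ["PcaModel", "fit_pca", "project", "score_correlations"]


@dataclass
class PcaModel:
    center: np.ndarray
    loadings: np.ndarray  # (n_components, n_features), orthonormal rows
    variance_fractions: np.ndarray
    columns: tuple[str, ...]
    n_components: int
    scale: np.ndarray | None = None  # per-column divisor (scaled PCA only)

    def __post_init__(self) -> None:
        gram = self.loadings @ self.loadings.T
        if not np.allclose(gram, np.eye(len(gram)), atol=1e-8):
            raise ValueError("loadings must be orthonormal")
        vf = self.variance_fractions
        if (vf < -1e-12).any() or vf.sum() > 1 + 1e-9 or (np.diff(vf) > 1e-9).any():
            raise ValueError(
                "variance fractions must be non-increasing, in [0,1], sum <= 1"
            )


def _as_matrix(profiles: pd.DataFrame) -> tuple[np.ndarray, tuple[str, ...]]:
    if not isinstance(profiles, pd.DataFrame):
        raise TypeError("expected a genotype x structure DataFrame")
    return profiles.to_numpy(dtype=float), tuple(profiles.columns)


def fit_pca(
    reference_means: pd.DataFrame, n_components: int = 4, scale: bool = False
) -> PcaModel:
    """Fit centered (optionally scaled) PCA on genotype mean profiles.

    Rows are genotypes (>= 2), columns GSL structures (>= 2).  Component
    signs are fixed by making each loading's largest-magnitude element
    positive, so results are bit-stable across runs and orderings.
    """
    X, columns = _as_matrix(reference_means)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 genotypes and >= 2 structures")
    scale_vec = None
    if scale:
        scale_vec = X.std(axis=0, ddof=1)
        if (scale_vec == 0).any():
            raise ValueError("cannot scale constant structure columns")
        X = X / scale_vec
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    loadings = pca.components_.copy()
    for i, row in enumerate(loadings):
        if row[np.argmax(np.abs(row))] < 0:
            loadings[i] = -row
    return PcaModel(
        center=pca.mean_,
        loadings=loadings,
        variance_fractions=pca.explained_variance_ratio_.copy(),
        columns=columns,
        n_components=n_components,
        scale=scale_vec,
    )


def project(model: PcaModel, means: pd.DataFrame) -> pd.DataFrame:
    """Scores of genotype means on the model's components.

    Columns must match the structure set the model was fitted on.  Each
    projected dataset is centered by its OWN column means (scores are
    generated independently per environment, as when correlating profiles
    across environments), so environment-wide level shifts — a constant
    added to every profile — leave the scores unchanged.
    """
    X, columns = _as_matrix(means)
    if columns != model.columns:
        raise ValueError(
            "structure columns do not match the fitted model: "
            f"{columns} vs {model.columns}"
        )
    if model.scale is not None:
        X = X / model.scale
    scores = (X - X.mean(axis=0)) @ model.loadings.T
    return pd.DataFrame(
        scores,
        index=means.index,
        columns=[f"PC{i + 1}" for i in range(model.n_components)],
    )


def score_correlations(
    reference_scores: pd.DataFrame, env_scores: pd.DataFrame
) -> pd.DataFrame:
    """Per-component Pearson correlation of scores across environments."""
    if len(reference_scores) < 3:
        raise ValueError("need >= 3 genotypes")
    common = reference_scores.index.intersection(env_scores.index)
    if len(common) < 3:
        raise ValueError("need >= 3 shared genotypes")
    rows = []
    for comp in reference_scores.columns:
        x = reference_scores.loc[common, comp].to_numpy()
        y = env_scores.loc[common, comp].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"constant scores on {comp}")
        r, p = stats.pearsonr(x, y)
        rows.append({"component": comp, "R": r, "p": p, "n": len(common)})
    return pd.DataFrame(rows)
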