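"""Indirect gradient analysis: PCA of the species matrix with passive
environmental arrows.

The decomposition is a species-centred, non-standardised (covariance)
PCA of log(x+1)-transformed abundances — the common default for species
data.  Environmental variables never enter the decomposition; they are
projected afterwards as arrows of correlations with the sample scores,
which is what makes the analysis indirect.  Axis signs are fixed by
forcing the largest-magnitude species loading on each axis to be
positive, so results are reproducible bit for bit.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import SpecificationError

DEFAULT_TOP_SPECIES = 10


@dataclass
class OrdinationResult:
    """PCA output: eigenvalue fractions, scores, loadings and species fit."""

    eigenvalue_fractions: np.ndarray   # lambda_k / sum(lambda), retained axes
    sample_scores: pd.DataFrame        # samples x axes (U * S)
    species_scores: pd.DataFrame       # species x axes (V scaled by sqrt eigenvalue)
    species_fit: pd.Series             # fraction of each species' variance shown
    top_species: list                  # top-N species codes by fit
    env_correlations: Optional[pd.DataFrame] = None

    @property
    def n_axes(self) -> int:
        return self.eigenvalue_fractions.size


def pca_species(matrix: pd.DataFrame, n_axes: int = 2,
                top_species: int = DEFAULT_TOP_SPECIES) -> OrdinationResult:
    """Species-centred SVD of an (already log-transformed) species matrix.

    ``eigenvalue_fractions[k] = lambda_k / sum(lambda)``.  ``species_fit``
    is the fraction of each species' variance captured by the retained
    axes, used to limit the displayed species scores to the best-fitting
    ``top_species``.
    """
    if matrix.shape[0] < 3 or matrix.shape[1] < 2:
        raise SpecificationError(
            f"need >= 3 samples and >= 2 species, got {matrix.shape}")
    X = matrix.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise SpecificationError("species matrix is constant; no variance to ordinate")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| species positive on each axis
    for k in range(S.size):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    lam = S ** 2
    n_axes = min(n_axes, S.size)
    fractions = lam[:n_axes] / lam.sum()
    axes = [f"axis{k + 1}" for k in range(n_axes)]
    scores = pd.DataFrame(U[:, :n_axes] * S[:n_axes], index=matrix.index,
                          columns=axes)
    n = X.shape[0]
    loadings = pd.DataFrame(
        (Vt[:n_axes].T * (S[:n_axes] / np.sqrt(max(n - 1, 1)))),
        index=matrix.columns, columns=axes)
    per_axis = (Vt.T * S) ** 2                   # species x all axes variance
    total = per_axis.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fit = np.where(total > 0, per_axis[:, :n_axes].sum(axis=1) / total, 0.0)
    species_fit = pd.Series(fit, index=matrix.columns, name="fit")
    top = list(species_fit.sort_values(ascending=False).index[:top_species])
    return OrdinationResult(fractions, scores, loadings, species_fit, top)


def project_env(result: OrdinationResult, env: pd.DataFrame) -> pd.DataFrame:
    """Passive arrows: correlation of each standardised variable with the axes.

    ``env`` rows must align with the ordination's sample index (same
    dates, any order).  Constant variables get zero-length arrows.
    """
    scores = result.sample_scores
    missing = scores.index.difference(env.index)
    if len(missing):
        raise SpecificationError(
            f"env matrix misses {len(missing)} ordination dates "
            f"(first: {missing[0]})")
    env = env.loc[scores.index]
    arrows = {}
    for var in env.columns:
        x = env[var].to_numpy(dtype=float)
        sd = np.std(x)
        if not np.isfinite(sd) or sd == 0:
            arrows[var] = np.zeros(scores.shape[1])
            continue
        arrows[var] = np.array([
            _pearson(x, scores[ax].to_numpy()) for ax in scores.columns])
    out = pd.DataFrame(arrows, index=scores.columns).T
    result.env_correlations = out
    return out


def _pearson(x, y) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
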