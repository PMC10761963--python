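"""Two-dimensional PC embedding of the binary matrix and the linear
projection of trait-space velocities onto the leading components.

The loadings A2 are the first two eigenvectors of the sample covariance
of the (imputed) binary matrix D; sample scores are (D - mean) @ A2 and a
velocity field projects as V @ A2 (centering cancels in the difference,
so projecting the difference equals differencing the projections).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import TraitMatrix, ValidationError, VelocityField

_RANK_TOL = 1e-10


@dataclass
class PCEmbedding:
    """Principal-component embedding of the samples.

    ``loadings`` (p x d) has orthonormal columns with a deterministic sign
    convention: the largest-magnitude loading of each component is positive.
    """

    sample_ids: list[str]
    pc_values: np.ndarray  # n x d
    loadings: np.ndarray  # p x d
    explained_variance: np.ndarray  # d eigenvalues
    column_means: np.ndarray  # p


def fit_pca(tm: TraitMatrix, n_components: int = 2, scale: bool = False) -> PCEmbedding:
    """Eigendecomposition of the sample covariance of the binary matrix.

    Requires a fully observed (imputed) matrix.  Components are ordered by
    descending eigenvalue; ``scale=True`` divides each trait by its standard
    deviation first (off by default).
    """
    if tm.has_missing:
        raise ValidationError("PCA requires an imputed (fully observed) matrix")
    n, p = tm.values.shape
    if n < 3:
        raise ValidationError("need at least 3 samples for PCA")
    d = tm.values.astype(float)
    means = d.mean(axis=0)
    x = d - means
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    cov = (x.T @ x) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    informative = int((evals > _RANK_TOL * max(evals[0], 1.0)).sum())
    if informative < n_components:
        raise ValidationError(
            f"fewer than {n_components} informative components (rank {informative})"
        )
    a = evecs[:, :n_components]
    # deterministic sign: largest-|loading| entry of each component positive
    for c in range(n_components):
        pivot = np.argmax(np.abs(a[:, c]))
        if a[pivot, c] < 0:
            a[:, c] = -a[:, c]
    return PCEmbedding(
        list(tm.sample_ids), x @ a, a, evals[:n_components], means
    )


def project_velocity_pc(field: VelocityField, emb: PCEmbedding, m: float | None = None) -> VelocityField:
    """Project a trait-space velocity field onto the PC loadings: V_pc = V @ A2."""
    if field.frame != "trait":
        raise ValidationError("project_velocity_pc expects a trait-frame field")
    if field.vectors.shape[1] != emb.loadings.shape[0]:
        raise ValidationError(
            f"field dimension {field.vectors.shape[1]} does not match "
            f"loadings ({emb.loadings.shape[0]} traits)"
        )
    return VelocityField("pc", emb.pc_values[:, :2], field.vectors @ emb.loadings, ids=field.ids)
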