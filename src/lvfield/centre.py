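"""Dispersal-centre inference from the gridded velocity field.

Around a true dispersal centre the field should point radially outward, so
the *directions* of nearby grid vectors disperse over the circle.  Each
supported grid point g is scored by the radiativity

    sigma_g^2 = tr[ U^T (E_s - 11^T/s) U ] / (2 (s - 1)),

the mean of the two per-axis sample variances of the s unit-normalised
grid vectors nearest to g.  The supported grid point with maximal score is
the centre; its uncertainty comes from leave-one-sample-out jackknifing of
the whole pipeline.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial import cKDTree

from .containers import CentreEstimate, GeoGrid, ValidationError

logger = logging.getLogger(__name__)

FLAT_FIELD_SIGMA2 = 0.05


def radiativity_scores(grid: GeoGrid, s_grid: int | None = None) -> GeoGrid:
    """Fill ``grid.sigma2`` with the radiativity score of every supported point.

    For each supported grid point, the ``s_grid`` nearest supported grid
    points' vectors (zero vectors skipped) are normalised to unit length and
    their centered covariance trace over 2(s-1) is the score.  Points with
    fewer than 2 usable neighbours stay unscored (NaN).
    """
    sup_idx = np.flatnonzero(grid.supported)
    lengths = np.linalg.norm(grid.vectors[sup_idx], axis=1)
    usable = sup_idx[lengths > 0]
    if lengths.min(initial=np.inf) <= 0 and len(usable) < len(sup_idx):
        logger.warning(
            "%d supported grid points carry zero vectors; skipped in radiativity",
            len(sup_idx) - len(usable),
        )
    m_usable = len(usable)
    if m_usable < 2:
        raise ValidationError("fewer than 2 supported grid points with nonzero vectors")
    s = min(m_usable, 30) if s_grid is None else s_grid
    if not (2 <= s <= m_usable):
        raise ValidationError(
            f"s_grid={s} must be between 2 and the {m_usable} usable grid points"
        )
    units = grid.vectors[usable] / np.linalg.norm(grid.vectors[usable], axis=1)[:, None]
    tree = cKDTree(grid.grid_coords[usable])
    _, local = tree.query(grid.grid_coords[usable], k=s)
    if local.ndim == 1:
        local = local[:, None]
    nbr_units = units[local]  # m x s x 2
    centered = nbr_units - nbr_units.mean(axis=1, keepdims=True)
    sigma2 = (centered**2).sum(axis=(1, 2)) / (2.0 * (s - 1))
    out = np.full(grid.n_points, np.nan)
    out[usable] = sigma2
    grid.sigma2 = out
    return grid


def infer_centre(grid: GeoGrid) -> CentreEstimate:
    """Argmax of the radiativity score over supported grid points.

    Ties break to the lowest grid index.  A flat (translation-like) field
    with a weak maximum is flagged in the log rather than rejected.
    """
    scored = np.flatnonzero(np.isfinite(grid.sigma2))
    if scored.size == 0:
        raise ValidationError("no scored grid points; run radiativity_scores first")
    best_rel = int(np.argmax(grid.sigma2[scored]))  # first max -> lowest index
    best = int(scored[best_rel])
    smax = float(grid.sigma2[best])
    n_ties = int((grid.sigma2[scored] == smax).sum())
    if n_ties > 1:
        logger.warning("radiativity argmax tie among %d grid points; lowest index kept", n_ties)
    if smax < FLAT_FIELD_SIGMA2:
        logger.warning(
            "weak radiativity maximum (sigma2=%.4f < %.2f): field may lack a source",
            smax,
            FLAT_FIELD_SIGMA2,
        )
    lon, lat = grid.grid_coords[best]
    return CentreEstimate(lon=float(lon), lat=float(lat), sigma2_max=smax)


def jackknife_sd(replicates: np.ndarray) -> np.ndarray:
    """Jackknife SD per column:  sqrt((n-1)/n * sum((theta_i - mean)^2))."""
    reps = np.asarray(replicates, dtype=float)
    n = reps.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 jackknife replicates")
    dev = reps - reps.mean(axis=0)
    return np.sqrt((n - 1) / n * (dev**2).sum(axis=0))
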