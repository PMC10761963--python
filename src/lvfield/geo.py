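"""Kernel projection of PC-space velocities into geographic space, plus
spatial and grid smoothing.

The projection follows the transition-kernel idea used for RNA-velocity
embeddings: for each sample l, the alignment between its PC-velocity and
the displacement towards each of its s PC-nearest neighbours j is turned
into a softmax transition probability P_lj; the geographic vector is then
the P-weighted (minus the uniform baseline) sum of unit geographic
displacement vectors towards those neighbours:

    V_geo_l = sum_j (P_lj - 1/s) * (C_j - C_l) / ||C_j - C_l||.

Smoothing only ever touches vector *lengths* (directions are what centre
inference consumes): each geographic vector is rescaled to the length of
its PC counterpart, lengths are then locally averaged under a Gaussian
kernel, and finally the field is resampled onto a regular lon/lat grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .containers import (
    CoordinateTable,
    GeoGrid,
    ValidationError,
    VelocityField,
    _stable_knn,
)
from .pca import PCEmbedding

logger = logging.getLogger(__name__)


@dataclass
class TransitionKernel:
    """Row-stochastic transition probabilities over PC-nearest neighbours."""

    sample_ids: list[str]
    neighbour_index: np.ndarray  # n x s
    P: np.ndarray  # n x s, rows sum to 1
    tau: float


def gaussian_kernel(a: np.ndarray, b: np.ndarray, sigma: float) -> np.ndarray:
    """K_sigma(a, b) = exp(-||a - b||^2 / (2 sigma^2)), rowwise over b."""
    d2 = ((a[..., None, :] - b[None, ...]) ** 2).sum(axis=-1)
    return np.exp(-d2 / (2.0 * sigma**2))


def auto_sigma(coords: CoordinateTable) -> float:
    """Default bandwidth: 1/10 of the bounding-box diagonal."""
    span = coords.xy.max(axis=0) - coords.xy.min(axis=0)
    diag = float(np.hypot(*span))
    if diag == 0:
        raise ValidationError("all samples coincide; bandwidth undefined")
    return diag / 10.0


def transition_probabilities(
    field_pc: VelocityField,
    emb: PCEmbedding,
    s_proj: int,
    tau: float = 0.05,
) -> TransitionKernel:
    """Softmax-of-cosine transition kernel over PC-nearest neighbours.

    For each sample l and each of its ``s_proj`` nearest neighbours j in PC
    space (self excluded), a_lj is the cosine similarity between V_pc_l and
    PC_j - PC_l; P_lj = softmax(a_lj / tau).  A zero-velocity sample gets a
    uniform row; a coincident neighbour contributes a_lj = 0.
    """
    if field_pc.frame != "pc":
        raise ValidationError("expected a pc-frame field")
    pcs = emb.pc_values
    n = pcs.shape[0]
    if not (1 <= s_proj <= n - 1):
        raise ValidationError(f"s_proj={s_proj} must be in [1, n-1]")
    if tau <= 0:
        raise ValidationError("tau must be > 0")
    v = field_pc.vectors[:, : pcs.shape[1]]
    nbrs_with_self = _stable_knn(pcs, pcs, s_proj + 1)
    # drop self wherever it appears (coincident points may shuffle it)
    nbrs = np.empty((n, s_proj), dtype=int)
    for l in range(n):
        row = [j for j in nbrs_with_self[l] if j != l][:s_proj]
        if len(row) < s_proj:
            row += [j for j in range(n) if j != l and j not in row][: s_proj - len(row)]
        nbrs[l] = row
    disp = pcs[nbrs] - pcs[:, None, :]  # n x s x d
    disp_norm = np.linalg.norm(disp, axis=2)
    v_norm = np.linalg.norm(v, axis=1)
    if (disp_norm == 0).any():
        logger.warning(
            "%d coincident PC neighbour pairs; their alignment set to 0",
            int((disp_norm == 0).sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (disp * v[:, None, :]).sum(axis=2) / (disp_norm * v_norm[:, None])
    cos[~np.isfinite(cos)] = 0.0
    logits = cos / tau
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    p[v_norm == 0] = 1.0 / s_proj
    return TransitionKernel(list(field_pc.ids or map(str, range(n))), nbrs, p, tau)


def project_geo(kernel: TransitionKernel, coords: CoordinateTable) -> VelocityField:
    """Geographic velocity vectors from the transition kernel.

    Each vector is the sum over PC-neighbours of (P_lj - 1/s) times the unit
    geographic displacement towards that neighbour; geographically coincident
    neighbours contribute zero.
    """
    coords = coords.align_to(kernel.sample_ids)
    xy = coords.xy
    n, s = kernel.P.shape
    disp = xy[kernel.neighbour_index] - xy[:, None, :]  # n x s x 2
    norms = np.linalg.norm(disp, axis=2)
    coincident = norms == 0
    if coincident.any():
        logger.warning(
            "%d geographically coincident neighbour pairs contribute zero terms",
            int(coincident.sum()),
        )
    safe = np.where(coincident, 1.0, norms)
    unit = disp / safe[..., None]
    unit[coincident] = 0.0
    weights = kernel.P - 1.0 / s
    vectors = (weights[..., None] * unit).sum(axis=1)
    return VelocityField("geo", xy, vectors, ids=list(kernel.sample_ids))


def spatial_smooth(
    field_geo: VelocityField,
    field_pc: VelocityField,
    coords: CoordinateTable,
    sigma_geo: float | None = None,
) -> VelocityField:
    """Length-only smoothing of the geographic field.

    Step 1 rescales each geographic vector to the length of its PC
    counterpart; step 2 replaces each length by the Gaussian-kernel weighted
    mean (weights normalised to sum 1) of all samples' step-1 lengths.
    Directions never change; zero-length vectors stay zero and are excluded
    from the weighting.
    """
    if field_geo.frame != "geo" or field_pc.frame != "pc":
        raise ValidationError("expected geo- and pc-frame fields")
    if field_geo.n != field_pc.n:
        raise ValidationError("field sizes differ")
    coords = coords.align_to(field_geo.ids or list(map(str, range(field_geo.n))))
    sigma = auto_sigma(coords) if sigma_geo is None else float(sigma_geo)
    geo_len = field_geo.lengths()
    pc_len = field_pc.lengths()
    nonzero = geo_len > 0
    directions = np.zeros_like(field_geo.vectors)
    directions[nonzero] = field_geo.vectors[nonzero] / geo_len[nonzero, None]
    scaled_len = np.where(nonzero, pc_len, 0.0)

    w = gaussian_kernel(coords.xy, coords.xy, sigma)
    w[:, ~nonzero] = 0.0  # zero vectors carry no length information
    totals = w.sum(axis=1)
    smooth_len = np.zeros_like(scaled_len)
    ok = totals > 0
    smooth_len[ok] = (w[ok] @ scaled_len) / totals[ok]
    smooth_len[~nonzero] = 0.0
    return VelocityField(
        "geo", field_geo.anchors, directions * smooth_len[:, None], ids=field_geo.ids
    )


def make_grid(
    coords: CoordinateTable, nx: int = 50, ny: int = 50, pad: float = 0.05
) -> np.ndarray:
    """Row-major (ny x nx) lattice over the padded bounding box, as M x 2."""
    lo = coords.xy.min(axis=0)
    hi = coords.xy.max(axis=0)
    span = hi - lo
    if (span == 0).all():
        raise ValidationError("degenerate bounding box: all samples coincide")
    lo = lo - pad * span
    hi = hi + pad * span
    gx = np.linspace(lo[0], hi[0], nx)
    gy = np.linspace(lo[1], hi[1], ny)
    xx, yy = np.meshgrid(gx, gy)
    return np.column_stack([xx.ravel(), yy.ravel()])


def grid_smooth(
    field: VelocityField,
    coords: CoordinateTable,
    grid_coords: np.ndarray | None = None,
    s_grid: int | None = None,
    sigma_geo: float | None = None,
    support_radius: float | None = None,
    nx: int = 50,
    ny: int = 50,
) -> GeoGrid:
    """Resample the smoothed sample field onto a regular grid.

    Each grid vector is the Gaussian-kernel weighted mean (weights
    normalised to sum 1) of its ``s_grid`` geographically nearest samples'
    vectors.  Grid points farther than ``support_radius`` from every sample
    are marked unsupported and carry zero vectors.
    """
    if field.frame != "geo":
        raise ValidationError("grid_smooth expects a geo-frame field")
    coords = coords.align_to(field.ids or list(map(str, range(field.n))))
    n = coords.n_samples
    s = min(n, 30) if s_grid is None else s_grid
    if not (1 <= s <= n):
        raise ValidationError(f"s_grid={s} must be in [1, n]")
    sigma = auto_sigma(coords) if sigma_geo is None else float(sigma_geo)
    radius = 2.0 * sigma if support_radius is None else float(support_radius)
    if grid_coords is None:
        grid_coords = make_grid(coords, nx, ny)
    else:
        grid_coords = np.asarray(grid_coords, dtype=float)
        nx, ny = grid_coords.shape[0], 1  # caller-provided lattice: flat shape

    tree = cKDTree(coords.xy)
    dist, idx = tree.query(grid_coords, k=min(s, n))
    if idx.ndim == 1:
        dist, idx = dist[:, None], idx[:, None]
    w = np.exp(-(dist**2) / (2.0 * sigma**2))
    totals = w.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    w = w / totals
    vectors = np.einsum("ms,msd->md", w, field.vectors[idx])
    supported = dist[:, 0] <= radius
    vectors[~supported] = 0.0
    return GeoGrid(grid_coords, vectors, supported, nx=nx, ny=ny)
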