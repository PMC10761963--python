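"""Shared data containers for velocity-field estimation.

The pipeline moves a cohort of *n* language samples, each scored on *p*
binary traits and pinned to a (longitude, latitude) coordinate, through a
sequence of representations: the raw binary matrix, k-NN state frequencies,
velocity vectors in trait space, their PC-space projection, the geographic
projection, and finally a regular grid of smoothed vectors from which the
dispersal centre is read off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

MISSING_CODES = {"?", "-", ""}

Frame = Literal["trait", "pc", "geo", "grid"]


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass
class TraitMatrix:
    """Binary character matrix with an explicit missing mask.

    ``values`` is n x p with entries in {0, 1}; entries flagged in
    ``missing_mask`` are unspecified and must be ignored downstream.
    """

    sample_ids: list[str]
    trait_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.trait_ids) != p:
            raise ValidationError("id lists do not match matrix shape")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if len(set(self.trait_ids)) != p:
            raise ValidationError("duplicate trait ids")
        if self.missing_mask.shape != (n, p):
            raise ValidationError("missing_mask shape mismatch")
        observed = self.values[~self.missing_mask]
        if observed.size and not np.isin(observed, (0.0, 1.0)).all():
            raise ValidationError("non-binary value in observed cells")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())

    def observed(self) -> np.ma.MaskedArray:
        return np.ma.MaskedArray(self.values, mask=self.missing_mask)

    def subset_samples(self, keep: Sequence[int]) -> "TraitMatrix":
        keep = list(keep)
        return TraitMatrix(
            [self.sample_ids[i] for i in keep],
            list(self.trait_ids),
            self.values[keep],
            self.missing_mask[keep],
        )

    def subset_traits(self, keep: Sequence[int]) -> "TraitMatrix":
        keep = list(keep)
        return TraitMatrix(
            list(self.sample_ids),
            [self.trait_ids[i] for i in keep],
            self.values[:, keep],
            self.missing_mask[:, keep],
        )


@dataclass
class CoordinateTable:
    """Per-sample geographic coordinates in decimal degrees."""

    sample_ids: list[str]
    lon: np.ndarray
    lat: np.ndarray

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        n = len(self.sample_ids)
        if self.lon.shape != (n,) or self.lat.shape != (n,):
            raise ValidationError("coordinate arrays do not match sample ids")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids in coordinates")
        if np.any(np.abs(self.lon) > 180) or np.any(np.abs(self.lat) > 90):
            bad = [
                self.sample_ids[i]
                for i in range(n)
                if abs(self.lon[i]) > 180 or abs(self.lat[i]) > 90
            ]
            raise ValidationError(f"coordinates out of range for samples: {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def xy(self) -> np.ndarray:
        """n x 2 array of (lon, lat), the planar working representation."""
        return np.column_stack([self.lon, self.lat])

    def align_to(self, sample_ids: Sequence[str]) -> "CoordinateTable":
        """Reorder to match ``sample_ids``; missing ids are a hard error.

        Joining is by explicit id match, never by row order.
        """
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ValidationError(f"samples without coordinates: {missing}")
        order = [index[s] for s in sample_ids]
        return CoordinateTable(list(sample_ids), self.lon[order], self.lat[order])

    def subset_samples(self, keep: Sequence[int]) -> "CoordinateTable":
        keep = list(keep)
        return CoordinateTable(
            [self.sample_ids[i] for i in keep], self.lon[keep], self.lat[keep]
        )


@dataclass
class FrequencyMatrix:
    """Per-sample, per-trait state-1 frequencies at a given time.

    ``time_label`` is 0 for the present and ``-m`` for a reconstructed past.
    """

    sample_ids: list[str]
    trait_ids: list[str]
    freq: np.ndarray
    time_label: float = 0.0

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (len(self.sample_ids), len(self.trait_ids)):
            raise ValidationError("frequency matrix shape mismatch")
        if not np.isfinite(self.freq).all():
            raise ValidationError("non-finite frequency")
        if self.freq.min() < -1e-12 or self.freq.max() > 1 + 1e-12:
            raise ValidationError("frequencies outside [0, 1]")


@dataclass
class VelocityField:
    """A collection of per-sample (or per-grid) velocity vectors.

    ``frame`` identifies the space: high-dimensional trait space, the
    2-D PC plane, geographic lon/lat, or the regular geographic grid.
    ``anchors`` locate each vector's origin in that space (for the trait
    frame, anchors are the 2-D PC positions used for plotting).
    """

    frame: Frame
    anchors: np.ndarray
    vectors: np.ndarray
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.anchors = np.asarray(self.anchors, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.anchors.shape[0] != self.vectors.shape[0]:
            raise ValidationError("anchors and vectors row counts differ")
        if not np.isfinite(self.vectors).all():
            raise ValidationError("non-finite velocity vector")

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)


@dataclass
class ModelParams:
    """Tunable parameters of the velocity-field estimator.

    k : neighbours for the binary -> frequency conversion (includes self).
    lam : Poisson mutation rate lambda of the prestige estimator.
    m : reconstruction time, in units of expected mutations.
    s_proj : PC-space neighbours for the kernel projection.
    s_grid : neighbours for grid smoothing / radiativity (None = auto).
    tau : softmax temperature of the transition kernel.
    sigma_geo : Gaussian kernel bandwidth in degrees (None = auto,
        1/10 of the bounding-box diagonal).
    grid_nx, grid_ny : grid resolution.
    support_radius : max distance from a grid point to its nearest sample
        for the point to count as supported (None = auto, 2 * sigma_geo).
    max_missing : per-trait missing fraction above which the trait is dropped.
    impute_mode : 'mode_value' | 'frequency_value' | 'zero_value' | None
        fill rule for the complete matrix PCA and prestige need
        (None falls back to mode_value there).
    freq_use_imputed : if True, k-NN frequencies are computed from the
        imputed matrix; by default originally-missing cells are simply
        disregarded in the neighbourhood counts (exact treatment).
    seed : master seed for stochastic imputation and resampling.
    """

    k: int = 10
    lam: float = 1.0
    m: float = 1.0
    s_proj: int | None = None
    s_grid: int | None = None
    tau: float = 0.05
    sigma_geo: float | None = None
    grid_nx: int = 50
    grid_ny: int = 50
    support_radius: float | None = None
    max_missing: float = 0.75
    impute_mode: str | None = "mode_value"
    freq_use_imputed: bool = False
    n_components: int = 2
    scale_pca: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be a positive integer")
        if self.lam <= 0:
            raise ValidationError("lam must be > 0")
        if self.m <= 0:
            raise ValidationError("m must be > 0")
        if self.tau <= 0:
            raise ValidationError("tau must be > 0")
        if not (0 <= self.max_missing < 1):
            raise ValidationError("max_missing must be in [0, 1)")
        if self.impute_mode not in (None, "mode_value", "frequency_value", "zero_value"):
            raise ValidationError(f"unknown impute_mode {self.impute_mode!r}")

    def resolve_s_proj(self, n: int) -> int:
        s = self.s_proj if self.s_proj is not None else min(n - 1, 30)
        if not (1 <= s <= n - 1):
            raise ValidationError(f"s_proj={s} must satisfy 1 <= s_proj <= n-1={n - 1}")
        return s

    def resolve_s_grid_samples(self, n: int) -> int:
        s = self.s_grid if self.s_grid is not None else min(n, 30)
        if not (1 <= s <= n):
            raise ValidationError(f"s_grid={s} exceeds sample count {n}")
        return s

    def resolve_s_grid_points(self, m_supported: int) -> int:
        s = self.s_grid if self.s_grid is not None else min(m_supported, 30)
        if not (2 <= s <= m_supported):
            raise ValidationError(
                f"s_grid={s} must be between 2 and the {m_supported} supported grid points"
            )
        return s

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


@dataclass
class GeoGrid:
    """Regular lon/lat lattice carrying the grid-smoothed velocity field.

    ``sigma2`` holds the per-point radiativity score (NaN until scored);
    unsupported points (far from every sample) carry zero vectors and are
    excluded from centre inference.
    """

    grid_coords: np.ndarray  # M x 2, row-major over (ny, nx)
    vectors: np.ndarray  # M x 2
    supported: np.ndarray  # M bools
    nx: int
    ny: int
    sigma2: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        m = self.grid_coords.shape[0]
        if m != self.nx * self.ny:
            raise ValidationError("grid size mismatch")
        if self.sigma2 is None:
            self.sigma2 = np.full(m, np.nan)

    @property
    def n_points(self) -> int:
        return self.grid_coords.shape[0]

    def as_field(self) -> VelocityField:
        return VelocityField("grid", self.grid_coords, self.vectors)


@dataclass
class CentreEstimate:
    """Inferred dispersal centre: the supported grid point whose
    surrounding vectors are most radially outward."""

    lon: float
    lat: float
    sigma2_max: float
    jackknife_sd_lon: float | None = None
    jackknife_sd_lat: float | None = None
    n_jackknife: int | None = None

    def to_dict(self) -> dict:
        return {
            "lon": self.lon,
            "lat": self.lat,
            "sigma2_max": self.sigma2_max,
            "jackknife_sd_lon": self.jackknife_sd_lon,
            "jackknife_sd_lat": self.jackknife_sd_lat,
            "n_jackknife": self.n_jackknife,
        }


def _stable_knn(points: np.ndarray, query: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest ``points`` to each row of ``query``.

    Euclidean distance on the plane; ties broken by lowest index so the
    result is deterministic under coincident coordinates.
    """
    d = np.linalg.norm(query[:, None, :] - points[None, :, :], axis=2)
    # lexicographic (distance, index) order via stable mergesort
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k]
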