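"""Phylogeny-free homeland baselines: diversity, centroid, minimal distance.

These are the classical comparison methods: the diversity approach places
the homeland at the sample with the highest linguistic diversity (summed
binary entropy of its k-NN state frequencies); the centroid approach at
the area centroid of the convex hull of sample locations; the minimal
distance approach at the sample with the smallest mean distance to all
other samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPoint

from .containers import CoordinateTable, FrequencyMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class BaselineResult:
    method: str  # DIV | Centr | MD
    lon: float
    lat: float
    per_sample_score: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {"method": self.method, "lon": self.lon, "lat": self.lat}


def _binary_entropy(x: np.ndarray) -> np.ndarray:
    """Elementwise -x ln x - (1-x) ln(1-x) with the 0 ln 0 = 0 convention."""
    out = np.zeros_like(x, dtype=float)
    for val in (x, 1.0 - x):
        pos = val > 0
        out[pos] -= val[pos] * np.log(val[pos])
    return out


def diversity_centre(freq_now: FrequencyMatrix, coords: CoordinateTable) -> BaselineResult:
    """Homeland = location of the sample with maximal summed trait entropy."""
    coords = coords.align_to(freq_now.sample_ids)
    div = _binary_entropy(freq_now.freq).sum(axis=1)
    best = int(np.argmax(div))  # ties -> first sample in id order
    if (div == div[best]).sum() > 1:
        logger.warning("diversity argmax tie; first sample in id order kept")
    return BaselineResult("DIV", float(coords.lon[best]), float(coords.lat[best]), div)


def centroid_centre(coords: CoordinateTable) -> BaselineResult:
    """Homeland = planar area centroid of the convex hull of the samples.

    Collinear (zero-area) configurations fall back to the coordinate mean.
    """
    if coords.n_samples < 3:
        raise ValidationError("need at least 3 samples for the centroid approach")
    hull = MultiPoint([tuple(p) for p in coords.xy]).convex_hull
    if hull.geom_type != "Polygon":
        logger.warning("collinear samples: centroid falls back to coordinate mean")
        lon, lat = coords.xy.mean(axis=0)
    else:
        lon, lat = hull.centroid.x, hull.centroid.y
    return BaselineResult("Centr", float(lon), float(lat))


def minimal_distance_centre(coords: CoordinateTable) -> BaselineResult:
    """Homeland = the sample minimising mean planar distance to the others."""
    if coords.n_samples < 2:
        raise ValidationError("need at least 2 samples")
    xy = coords.xy
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=2)
    mean_d = d.sum(axis=1) / (coords.n_samples - 1)
    best = int(np.argmin(mean_d))  # ties -> first sample in id order
    return BaselineResult("MD", float(coords.lon[best]), float(coords.lat[best]), mean_d)
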