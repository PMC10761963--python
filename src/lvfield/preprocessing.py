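"""Missing-data filtering, imputation, and the binary -> frequency conversion.

The estimator needs traits valued in [0, 1].  Each binary trait is turned
into a *state frequency*: for sample l, the fraction of state-1 values of
that trait among the k geographically nearest samples (including l itself).
"""

from __future__ import annotations

import numpy as np

from .containers import (
    CoordinateTable,
    FrequencyMatrix,
    TraitMatrix,
    ValidationError,
    _stable_knn,
)


def filter_traits(tm: TraitMatrix, max_missing: float = 0.75) -> TraitMatrix:
    """Drop traits whose missing fraction exceeds ``max_missing``.

    The default keeps traits with at most 75% missing values.  Column
    order is preserved.
    """
    if not (0 <= max_missing < 1):
        raise ValidationError("max_missing must be in [0, 1)")
    frac = tm.missing_mask.mean(axis=0)
    keep = np.flatnonzero(frac <= max_missing)
    if keep.size == 0:
        raise ValidationError("no traits survive filtering")
    if keep.size == tm.n_traits:
        return tm
    return tm.subset_traits(keep)


def impute(
    tm: TraitMatrix,
    mode: str = "mode_value",
    seed: int | np.random.Generator = 0,
) -> TraitMatrix:
    """Fill missing cells; observed cells never change.

    mode_value : most frequent observed state of the trait (ties -> 1,
        matching the 0.5 rounding of a frequency estimate).
    frequency_value : Bernoulli draw with the trait's observed state-1
        frequency (seeded).
    zero_value : 0.
    """
    if not tm.has_missing:
        return tm
    values = tm.values.copy()
    mask = tm.missing_mask
    n_obs = (~mask).sum(axis=0)
    if (n_obs == 0).any():
        bad = [tm.trait_ids[j] for j in np.flatnonzero(n_obs == 0)]
        raise ValidationError(f"traits with no observed cells cannot be imputed: {bad}")
    with np.errstate(invalid="ignore"):
        freq1 = np.where(mask, 0.0, values).sum(axis=0) / n_obs
    if mode == "mode_value":
        fill = np.broadcast_to((freq1 >= 0.5).astype(float), values.shape)
    elif mode == "zero_value":
        fill = np.zeros_like(values)
    elif mode == "frequency_value":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        fill = (rng.random(values.shape) < freq1[None, :]).astype(float)
    else:
        raise ValidationError(f"unknown imputation mode {mode!r}")
    values[mask] = fill[mask]
    return TraitMatrix(
        list(tm.sample_ids), list(tm.trait_ids), values, np.zeros_like(mask)
    )


def geographic_neighbours(coords: CoordinateTable, k: int) -> np.ndarray:
    """n x k indices of each sample's k nearest samples (including itself).

    Planar Euclidean distance on (lon, lat); ties broken by sample order.
    """
    n = coords.n_samples
    if not (1 <= k <= n):
        raise ValidationError(f"k={k} must satisfy 1 <= k <= n={n}")
    return _stable_knn(coords.xy, coords.xy, k)


def to_frequency(
    tm: TraitMatrix,
    coords: CoordinateTable,
    k: int = 10,
    fallback: TraitMatrix | None = None,
) -> FrequencyMatrix:
    """k-NN state frequencies at the present (time 0).

    freq[l, i] is the fraction of state-1 among the non-missing trait-i
    values of the k samples nearest to l.  Missing values are disregarded;
    when every neighbour is missing for some (l, i), the neighbourhood
    frequency of a complete ``fallback`` matrix (imputed) is used if given,
    otherwise an error instructs the caller to impute first.
    """
    coords = coords.align_to(tm.sample_ids)
    nbrs = geographic_neighbours(coords, k)  # n x k
    vals = tm.values[nbrs]  # n x k x p
    obs = ~tm.missing_mask[nbrs]  # n x k x p
    n_obs = obs.sum(axis=1)  # n x p
    empty = n_obs == 0
    if empty.any() and fallback is None:
        l, i = np.argwhere(empty)[0]
        raise ValidationError(
            f"all {k} neighbours missing for sample {tm.sample_ids[l]!r}, "
            f"trait {tm.trait_ids[i]!r}; impute missing values first"
        )
    n_obs_safe = np.where(empty, 1, n_obs)
    freq = np.where(obs, vals, 0.0).sum(axis=1) / n_obs_safe
    if empty.any():
        if fallback.has_missing or fallback.sample_ids != tm.sample_ids:
            raise ValidationError("fallback must be a complete matrix of the same samples")
        freq[empty] = (fallback.values[nbrs].mean(axis=1))[empty]
    return FrequencyMatrix(list(tm.sample_ids), list(tm.trait_ids), freq, time_label=0.0)
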