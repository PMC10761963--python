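"""Trait-evolution dynamics: prestige estimation, past-state reconstruction,
and the high-dimensional velocity field.

Each binary trait i evolves by competition between its two states, in the
spirit of the Abrams–Strogatz language-competition model.  With x1 the
state-1 frequency and s1, s0 the per-state *prestige* (probability that a
state persists over one unit of time), the frequency obeys the logistic law

    dx1/dt = (s1 - s0) * x1 * (1 - x1),

whose backward-in-time solution is applied in closed form.  Prestige is
estimated from a Poisson mutation process with rate lambda:

    s_j = exp(-lam) + (1 - exp(-lam)) * pi_j,

where pi_j is the global frequency of state j for the trait across all
samples.  The velocity vector of sample l is the per-trait change per unit
time between the reconstructed past and the present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import (
    FrequencyMatrix,
    TraitMatrix,
    ValidationError,
    VelocityField,
)

_EPS = 1e-12


@dataclass
class PrestigeTable:
    """Per-trait prestige of the two states under a Poisson mutation clock."""

    trait_ids: list[str]
    s1: np.ndarray
    s0: np.ndarray
    pi1: np.ndarray
    lam: float

    @property
    def drift(self) -> np.ndarray:
        """s1 - s0 = (1 - e^-lam) * (2*pi1 - 1), the per-trait selection drift."""
        return self.s1 - self.s0


def estimate_prestige(tm: TraitMatrix, lam: float = 1.0) -> PrestigeTable:
    """Estimate per-trait state prestige from global state frequencies.

    pi1[i] is the fraction of state-1 among the non-missing entries of
    trait i over all samples; prestige interpolates between 1 (lam -> 0,
    nothing mutates) and pi itself (lam -> inf).
    """
    if lam <= 0:
        raise ValidationError("lam must be > 0")
    n_obs = (~tm.missing_mask).sum(axis=0)
    if (n_obs == 0).any():
        bad = [tm.trait_ids[j] for j in np.flatnonzero(n_obs == 0)]
        raise ValidationError(f"traits with no observed cells: {bad}")
    pi1 = np.where(tm.missing_mask, 0.0, tm.values).sum(axis=0) / n_obs
    decay = np.exp(-lam)
    s1 = decay + (1 - decay) * pi1
    s0 = decay + (1 - decay) * (1 - pi1)
    return PrestigeTable(list(tm.trait_ids), s1, s0, pi1, lam)


def reconstruct_past(
    freq_now: FrequencyMatrix, prestige: PrestigeTable, m: float = 1.0
) -> FrequencyMatrix:
    """State frequencies m time units before the present.

    Entrywise closed form of the logistic competition dynamics run
    backwards:  x(-m) = 1 / (1 + (1/x(0) - 1) * exp((s1 - s0) * m)).
    The fixed points 0 and 1 are preserved exactly (continuity limits).
    """
    if m <= 0:
        raise ValidationError("m must be > 0")
    if freq_now.trait_ids != prestige.trait_ids:
        raise ValidationError("trait ids of frequencies and prestige differ")
    x0 = freq_now.freq
    if not np.isfinite(x0).all():
        raise ValidationError("non-finite input frequency")
    at_zero = x0 <= 0.0
    at_one = x0 >= 1.0
    x = np.clip(x0, _EPS, 1 - _EPS)
    past = 1.0 / (1.0 + (1.0 / x - 1.0) * np.exp(prestige.drift[None, :] * m))
    past[at_zero] = 0.0
    past[at_one] = 1.0
    return FrequencyMatrix(
        list(freq_now.sample_ids), list(freq_now.trait_ids), past, time_label=-m
    )


def velocity_trait_space(
    freq_now: FrequencyMatrix,
    freq_past: FrequencyMatrix,
    m: float,
    anchors: np.ndarray | None = None,
) -> VelocityField:
    """Per-sample velocity vectors in trait space:  V_l = (X_l(0) - X_l(-m)) / m.

    ``anchors`` (n x 2, e.g. PC positions) locate the vectors for plotting;
    they default to zeros since the trait frame has no natural 2-D anchor.
    """
    if freq_now.freq.shape != freq_past.freq.shape:
        raise ValidationError("frequency matrices have different shapes")
    if freq_now.sample_ids != freq_past.sample_ids:
        raise ValidationError("sample ids differ between time points")
    if freq_now.time_label != 0.0 or freq_past.time_label != -m:
        raise ValidationError("expected time labels 0 and -m")
    vectors = (freq_now.freq - freq_past.freq) / m
    if anchors is None:
        anchors = np.zeros((vectors.shape[0], 2))
    return VelocityField("trait", anchors, vectors, ids=list(freq_now.sample_ids))
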