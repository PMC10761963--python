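"""Relatedness matrices and the comparison statistics of the validation
protocols: Mantel permutation test, quartet delta score, cosine field
similarity, Procrustes consistency, and small hypothesis-test helpers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.spatial import procrustes as _scipy_procrustes

from .containers import TraitMatrix, ValidationError, VelocityField
from .pca import PCEmbedding


@dataclass
class RelatednessMatrix:
    """Symmetric zero-diagonal pairwise distance matrix between samples.

    kind 'overall' = Manhattan distance on binary traits, 'pca' = Euclidean
    distance on the two leading PCs, 'tree' = cophenetic (patristic)
    distance on a phylogeny.
    """

    kind: str
    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("relatedness matrix must be square")
        if not np.allclose(m, m.T) or np.any(np.diag(m) != 0) or (m < 0).any():
            raise ValidationError("matrix must be symmetric, nonnegative, zero-diagonal")
        self.matrix = m


def overall_relatedness(tm: TraitMatrix) -> RelatednessMatrix:
    """Pairwise Manhattan distance on the binary traits.

    Missing values are excluded pairwise and the distance rescaled by
    p / (number of commonly observed traits), so sparsity does not shrink
    distances.
    """
    v = tm.values
    obs = (~tm.missing_mask).astype(float)
    n, p = v.shape
    diff = np.abs(v[:, None, :] - v[None, :, :])
    both = obs[:, None, :] * obs[None, :, :]
    counts = both.sum(axis=2)
    if (counts == 0).any():
        raise ValidationError("sample pairs with no commonly observed traits")
    d = (diff * both).sum(axis=2) * (p / counts)
    np.fill_diagonal(d, 0.0)
    return RelatednessMatrix("overall", list(tm.sample_ids), d)


def pca_relatedness(emb: PCEmbedding) -> RelatednessMatrix:
    """Pairwise Euclidean distance between the two leading PC scores."""
    pcs = emb.pc_values[:, :2]
    d = np.linalg.norm(pcs[:, None, :] - pcs[None, :, :], axis=2)
    return RelatednessMatrix("pca", list(emb.sample_ids), d)


def tree_relatedness(tree, sample_ids: list[str]) -> RelatednessMatrix:
    """Cophenetic (patristic) distances on a dendropy tree."""
    from .io import cophenetic_distances

    return RelatednessMatrix("tree", list(sample_ids), cophenetic_distances(tree, sample_ids))


def _upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def mantel(
    m1: RelatednessMatrix,
    m2: RelatednessMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Mantel test of matrix correlation.

    Returns (r, r^2, p) where r is the Pearson correlation of the strict
    upper triangles and p the one-tailed (greater) permutation p-value,
    (#{r_perm >= r_obs} + 1) / (n_perm + 1), permuting rows/columns of m2
    jointly.
    """
    if m1.sample_ids != m2.sample_ids:
        raise ValidationError("sample ids differ between matrices")
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    a, b = m1.matrix, m2.matrix
    x = _upper(a)
    if x.std() == 0 or _upper(b).std() == 0:
        raise ValidationError("constant distance matrix: correlation undefined")
    n = a.shape[0]
    xc = x - x.mean()
    xs = np.sqrt((xc**2).sum())

    def corr_with(bperm: np.ndarray) -> float:
        y = _upper(bperm)
        yc = y - y.mean()
        return float((xc * yc).sum() / (xs * np.sqrt((yc**2).sum())))

    r_obs = corr_with(b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr_with(b[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return r_obs, r_obs**2, p


@dataclass
class DeltaScoreResult:
    """Mean quartet delta: 0 for additive (tree-like) distances, larger
    under reticulation/contact."""

    mean_delta: float
    per_quartet_count: int
    mode: str  # exact | sampled
    seed: int | None = None


def _quartet_deltas(d: np.ndarray, quartets: np.ndarray) -> np.ndarray:
    i, j, k, l = quartets.T
    sums = np.stack(
        [d[i, j] + d[k, l], d[i, k] + d[j, l], d[i, l] + d[j, k]], axis=1
    )
    sums.sort(axis=1)  # s3 <= s2 <= s1
    s3, s2, s1 = sums[:, 0], sums[:, 1], sums[:, 2]
    span = s1 - s3
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = (s1 - s2) / span
    delta[span == 0] = 0.0  # equidistant quartet carries no signal
    return delta


def delta_score(
    dist: RelatednessMatrix,
    mode: str = "auto",
    max_quartets: int = 100_000,
    seed: int = 0,
) -> DeltaScoreResult:
    """Mean quartet delta score of a distance matrix.

    For each sample quartet the three pairwise-sum quantities are ordered
    s1 >= s2 >= s3 and the quartet scores (s1 - s2)/(s1 - s3) (0 when all
    equal).  All C(n,4) quartets are enumerated when feasible, otherwise a
    seeded uniform sample of ``max_quartets`` quartets is used.
    """
    d = dist.matrix
    n = d.shape[0]
    if n < 4:
        raise ValidationError("delta score needs at least 4 samples")
    n_total = n * (n - 1) * (n - 2) * (n - 3) // 24
    if mode == "auto":
        mode = "exact" if n_total <= max_quartets else "sampled"
    if mode == "exact":
        quartets = np.array(list(itertools.combinations(range(n), 4)))
        used_seed = None
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        # uniform 4-subsets: first 4 positions of a random permutation per row
        quartets = rng.random((max_quartets, n)).argsort(axis=1)[:, :4]
        used_seed = seed
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    deltas = _quartet_deltas(d, quartets)
    return DeltaScoreResult(float(deltas.mean()), len(quartets), mode, used_seed)


def cosine_field_similarity(f1: VelocityField, f2: VelocityField) -> tuple[float, int]:
    """Mean per-sample cosine similarity between two fields of one frame.

    Pairs where either vector is zero are skipped; the count of compared
    pairs is returned alongside the mean.
    """
    if f1.frame != f2.frame:
        raise ValidationError(f"frame mismatch: {f1.frame} vs {f2.frame}")
    if f1.vectors.shape != f2.vectors.shape:
        raise ValidationError("field shapes differ")
    n1 = np.linalg.norm(f1.vectors, axis=1)
    n2 = np.linalg.norm(f2.vectors, axis=1)
    ok = (n1 > 0) & (n2 > 0)
    if not ok.any():
        raise ValidationError("no nonzero vector pairs to compare")
    cos = (f1.vectors[ok] * f2.vectors[ok]).sum(axis=1) / (n1[ok] * n2[ok])
    return float(cos.mean()), int(ok.sum())


def procrustes_consistency(emb1: PCEmbedding, emb2: PCEmbedding) -> tuple[float, float]:
    """Procrustes agreement between two PC embeddings of the same samples.

    Returns (scaled RMSD, Procrustes correlation).  Both configurations are
    translated, scaled to unit total variance and optimally rotated; the
    residual sum of squares D gives RMSD = sqrt(D / n) and correlation
    sqrt(1 - D).
    """
    if emb1.sample_ids != emb2.sample_ids:
        raise ValidationError("sample ids differ between embeddings")
    a, b = emb1.pc_values[:, :2], emb2.pc_values[:, :2]
    if np.allclose(a.std(axis=0), 0) or np.allclose(b.std(axis=0), 0):
        raise ValidationError("degenerate (zero-variance) embedding")
    _, _, disparity = _scipy_procrustes(a, b)
    disparity = min(max(disparity, 0.0), 1.0)
    rmsd = float(np.sqrt(disparity / a.shape[0]))
    return rmsd, float(np.sqrt(1.0 - disparity))


# --- hypothesis-test helpers -------------------------------------------------


def wilcoxon_rank_sum(a, b, alternative: str = "two-sided") -> float:
    """Rank-sum (Mann-Whitney) p-value."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("empty input to rank-sum test")
    return float(sps.mannwhitneyu(a, b, alternative=alternative).pvalue)


def bootstrap_ci(
    samples, n_boot: int = 200, level: float = 0.95, side: str = "two-sided", seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap interval for the mean (seeded)."""
    x = np.asarray(samples, float)
    if x.size == 0:
        raise ValidationError("empty input to bootstrap")
    rng = np.random.default_rng(seed)
    means = rng.choice(x, size=(n_boot, x.size), replace=True).mean(axis=1)
    alpha = 1 - level
    if side == "two-sided":
        lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    elif side == "greater":
        lo, hi = np.quantile(means, alpha), np.inf
    elif side == "less":
        lo, hi = -np.inf, np.quantile(means, 1 - alpha)
    else:
        raise ValidationError(f"unknown side {side!r}")
    return float(lo), float(hi)


def monte_carlo_p(observed: float, null_samples, side: str = "greater") -> float:
    """Monte-Carlo p-value:  (#{null beyond observed} + 1) / (N + 1)."""
    null = np.asarray(null_samples, float)
    if null.size == 0:
        raise ValidationError("empty null sample")
    if side == "greater":
        count = int((null >= observed).sum())
    elif side == "less":
        count = int((null <= observed).sum())
    else:
        raise ValidationError(f"unknown side {side!r}")
    return (count + 1) / (null.size + 1)
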