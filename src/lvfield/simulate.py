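"""Synthetic validation data with a known dispersal centre, and the
effectiveness / robustness protocols run against it.

Each dataset emulates the validation design: a random bifurcating (Yule)
tree scaled to height 1 carrying 20 samples; 306 binary traits, each
evolving as an independent symmetric 2-state Markov chain with a
Gamma-distributed per-trait rate; and geographic coordinates produced by a
Brownian random walk along the tree starting from the planted centre, with
per-axis step SD geo_step_sd * sqrt(branch length).

An optional horizontal-borrowing switch copies contiguous trait blocks
between non-sister tips, injecting the contact signal that breaks
tree-likeness; an optional missing_rate masks cells at random.  Both are
off by default: the baseline design is purely vertical and fully observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .containers import CoordinateTable, TraitMatrix, ValidationError

BLOCK_SIZE = 10  # traits copied per borrowing event
BORROW_COVERAGE = 0.55  # expected fraction of a recipient's traits borrowed


@dataclass
class SimParams:
    birth_rate: float = 1.0
    trait_rate_mean: float = 1.0
    trait_rate_shape: float = 1.0
    geo_step_sd: float = 5.0  # degrees per unit sqrt(branch length)
    borrowing_rate: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.birth_rate <= 0 or self.trait_rate_mean < 0 or self.trait_rate_shape <= 0:
            raise ValidationError("rates must be positive (trait_rate_mean >= 0)")
        if self.geo_step_sd < 0:
            raise ValidationError("geo_step_sd must be >= 0")
        if not (0 <= self.borrowing_rate <= 1) or not (0 <= self.missing_rate < 1):
            raise ValidationError("borrowing_rate/missing_rate out of range")


@dataclass
class SimulatedDataset:
    tree: dendropy.Tree
    traits: TraitMatrix
    coords: CoordinateTable
    true_centre: tuple[float, float]
    sim_params: SimParams = field(default_factory=SimParams)
    seed: int = 0


def _yule_tree(n_tips: int, birth_rate: float, rng: np.random.Generator) -> dendropy.Tree:
    """Pure-birth tree with ``n_tips`` leaves, rescaled to height 1."""
    taxa = dendropy.TaxonNamespace([f"s{i}" for i in range(n_tips)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tips = [tree.seed_node]
    heights = {tree.seed_node: 0.0}
    t = 0.0
    while len(tips) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(tips)))
        parent = tips.pop(rng.integers(len(tips)))
        parent.edge.length = t - heights[parent]
        for _ in range(2):
            child = parent.new_child()
            heights[child] = t
            tips.append(child)
    t_end = t + rng.exponential(1.0 / (birth_rate * len(tips)))
    order = 0
    for node in tree.leaf_node_iter():
        node.edge.length = t_end - heights[node]
        node.taxon = taxa[order]
        order += 1
    tree.seed_node.edge.length = None
    # crown height = time from the first split to the present
    crown = t_end - min(heights[c] for c in tree.seed_node.child_nodes())
    if crown > 0:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length /= crown
    return tree


def _evolve_traits(
    tree: dendropy.Tree, n_traits: int, params: SimParams, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Symmetric 2-state Markov chain per trait along the tree.

    Over a branch of length t at rate r, the state flips with probability
    (1 - exp(-r t)) / 2; rates are Gamma(shape, mean) per trait and the
    root state is Bernoulli(0.5).
    """
    rates = (
        np.zeros(n_traits)
        if params.trait_rate_mean == 0
        else rng.gamma(
            params.trait_rate_shape, params.trait_rate_mean / params.trait_rate_shape, n_traits
        )
    )
    states = {tree.seed_node: (rng.random(n_traits) < 0.5).astype(float)}
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            pass
        else:
            p_flip = 0.5 * (1.0 - np.exp(-rates * node.edge.length))
            flips = rng.random(n_traits) < p_flip
            states[node] = np.where(flips, 1.0 - states[node.parent_node], states[node.parent_node])
        if node.is_leaf():
            out[node.taxon.label] = states[node]
    return out


def _walk_coordinates(
    tree: dendropy.Tree,
    centre: tuple[float, float],
    step_sd: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Brownian walk along the tree from the root placed at the centre."""
    pos = {tree.seed_node: np.asarray(centre, dtype=float)}
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            step = rng.normal(0.0, step_sd * np.sqrt(node.edge.length), size=2)
            pos[node] = pos[node.parent_node] + step
        if node.is_leaf():
            out[node.taxon.label] = pos[node]
    return out


def _non_sister_pairs(tree: dendropy.Tree) -> list[tuple[str, str]]:
    leaves = list(tree.leaf_node_iter())
    pairs = []
    for a in leaves:
        for b in leaves:
            if a is b:
                continue
            if a.parent_node is b.parent_node:
                continue
            pairs.append((a.taxon.label, b.taxon.label))
    return pairs


def simulate_dataset(
    n_samples: int = 20,
    n_traits: int = 306,
    true_centre: tuple[float, float] = (0.0, 0.0),
    sim_params: SimParams | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """One validation dataset: tree, binary traits, coordinates, truth."""
    if n_samples < 4:
        raise ValidationError("need at least 4 samples")
    params = sim_params or SimParams()
    rng = np.random.default_rng(seed)
    tree = _yule_tree(n_samples, params.birth_rate, rng)
    trait_states = _evolve_traits(tree, n_traits, params, rng)
    positions = _walk_coordinates(tree, true_centre, params.geo_step_sd, rng)

    sample_ids = sorted(trait_states)
    values = np.stack([trait_states[s] for s in sample_ids])

    if params.borrowing_rate > 0:
        # persistent contact dyads: a few fixed non-sister pairs repeatedly
        # exchange trait blocks, so phylogenetically distant samples converge
        # -- the reticulation signal a tree cannot explain but the observed
        # data (and its PC embedding) carry coherently
        idx = {s: i for i, s in enumerate(sample_ids)}
        pairs = _non_sister_pairs(tree)
        # borrowing_rate scales the fraction of samples engaged in a contact
        # dyad; each recipient borrows ~BORROW_COVERAGE of its inventory from
        # its partner -- deep enough to contradict vertical descent, partial
        # enough that the conflicting signals raise the quartet delta
        n_dyads = max(1, int(round(params.borrowing_rate * n_samples)))
        n_dyads = min(n_dyads, len(pairs))
        dyads = [pairs[int(j)] for j in rng.choice(len(pairs), n_dyads, replace=False)]
        frac = BLOCK_SIZE / n_traits
        per_dyad = max(1, int(np.ceil(np.log1p(-BORROW_COVERAGE) / np.log1p(-frac))))
        for donor, recipient in dyads:
            for _ in range(per_dyad):
                start = int(rng.integers(max(n_traits - BLOCK_SIZE, 0) + 1))
                block = slice(start, start + BLOCK_SIZE)
                values[idx[recipient], block] = values[idx[donor], block]

    mask = np.zeros_like(values, dtype=bool)
    if params.missing_rate > 0:
        mask = rng.random(values.shape) < params.missing_rate

    traits = TraitMatrix(sample_ids, [f"t{j}" for j in range(n_traits)], values, mask)
    xy = np.stack([positions[s] for s in sample_ids])
    lon = np.clip(xy[:, 0], -180, 180)
    lat = np.clip(xy[:, 1], -90, 90)
    coords = CoordinateTable(sample_ids, lon, lat)
    return SimulatedDataset(tree, traits, coords, tuple(true_centre), params, seed)


def replicate_datasets(
    n_datasets: int,
    seed: int = 0,
    n_samples: int = 20,
    n_traits: int = 306,
    true_centre: tuple[float, float] | None = None,
    sim_params: SimParams | None = None,
    centre_box: tuple[float, float] = (60.0, 40.0),
) -> list[SimulatedDataset]:
    """Independent replicates with per-replicate seeds derived from ``seed``.

    Each replicate gets its own planted dispersal centre, drawn uniformly
    from +-``centre_box`` degrees (lon, lat) around the origin, emulating a
    collection of expansions with distinct homelands; pass ``true_centre``
    to pin every replicate to one location instead.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_datasets)]
    rng = np.random.default_rng(np.random.SeedSequence(seed).generate_state(2)[1])
    out = []
    for s in child_seeds:
        if true_centre is None:
            centre = (
                float(rng.uniform(-centre_box[0], centre_box[0])),
                float(rng.uniform(-centre_box[1], centre_box[1])),
            )
        else:
            centre = true_centre
        out.append(simulate_dataset(n_samples, n_traits, centre, sim_params, seed=s))
    return out


def effectiveness_protocol(
    datasets: list[SimulatedDataset],
    params_grid: list[dict] | None = None,
    alpha: float = 0.05,
) -> dict:
    """Centre-recovery check across simulated replicates.

    For each parameter setting, the centre is inferred on every dataset and
    the inferred longitudes/latitudes are compared with the planted truth by
    a two-sided rank-sum test per axis; a setting passes when both p-values
    exceed ``alpha`` (no significant displacement).
    """
    from .model import DispersalModel
    from .stats import wilcoxon_rank_sum

    if len(datasets) < 30:
        raise ValidationError("effectiveness protocol needs >= 30 datasets")
    grid = params_grid or [{}]
    true_lon = np.array([ds.true_centre[0] for ds in datasets])
    true_lat = np.array([ds.true_centre[1] for ds in datasets])
    results = []
    for setting in grid:
        lons, lats = [], []
        for ds in datasets:
            res = DispersalModel.from_simulated(ds, **setting).fit()
            lons.append(res.centre.lon)
            lats.append(res.centre.lat)
        p_lon = wilcoxon_rank_sum(lons, true_lon)
        p_lat = wilcoxon_rank_sum(lats, true_lat)
        results.append(
            {
                "params": setting,
                "p_lon": p_lon,
                "p_lat": p_lat,
                "mean_abs_err_lon": float(np.mean(np.abs(np.array(lons) - true_lon))),
                "mean_abs_err_lat": float(np.mean(np.abs(np.array(lats) - true_lat))),
                "pass": bool(p_lon > alpha and p_lat > alpha),
            }
        )
    return {"n_datasets": len(datasets), "alpha": alpha, "settings": results}


def robustness_protocol(
    dataset: SimulatedDataset,
    params_grid: list[dict],
    frame: str = "pc",
) -> dict:
    """Pairwise mean cosine similarity of velocity fields across settings."""
    from .model import DispersalModel
    from .stats import cosine_field_similarity

    if len(params_grid) < 2:
        raise ValidationError("robustness protocol needs >= 2 settings")
    fields = []
    for setting in params_grid:
        res = DispersalModel.from_simulated(dataset, **setting).fit(infer_centre=False)
        fields.append(res.field_pc if frame == "pc" else res.field_trait)
    n = len(fields)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            value, _ = cosine_field_similarity(fields[i], fields[j])
            sim[i, j] = sim[j, i] = value
    off = sim[np.triu_indices(n, k=1)]
    return {
        "matrix": sim,
        "min": float(off.min()),
        "median": float(np.median(off)),
    }
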