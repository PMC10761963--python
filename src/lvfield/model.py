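"""Model/Results interface tying the pipeline together.

``DispersalModel`` holds a trait matrix, sample coordinates and the
estimator parameters; ``fit()`` runs filtering -> imputation -> k-NN
frequency conversion -> prestige estimation -> past-state reconstruction
-> velocity field -> PC projection -> kernel geographic projection ->
smoothing -> gridding -> centre inference, and returns a
``DispersalResults`` carrying every intermediate representation, the
centre estimate and a ``summary()`` table.  ``jackknife()`` reruns the
whole pipeline leaving one sample out at a time to attach standard
deviations to the centre coordinates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import baselines as _baselines
from .centre import infer_centre as _infer_centre
from .centre import jackknife_sd, radiativity_scores
from .containers import (
    CentreEstimate,
    CoordinateTable,
    GeoGrid,
    ModelParams,
    TraitMatrix,
    ValidationError,
    VelocityField,
)
from .dynamics import (
    PrestigeTable,
    estimate_prestige,
    reconstruct_past,
    velocity_trait_space,
)
from .geo import (
    TransitionKernel,
    auto_sigma,
    grid_smooth,
    project_geo,
    spatial_smooth,
    transition_probabilities,
)
from .pca import PCEmbedding, fit_pca, project_velocity_pc
from .preprocessing import filter_traits, impute, to_frequency

logger = logging.getLogger(__name__)


class DispersalModel:
    """Velocity-field dispersal model for one cohort of samples.

    Parameters
    ----------
    traits : TraitMatrix
        Binary character matrix (missing values allowed).
    coords : CoordinateTable
        Longitude/latitude per sample; joined to ``traits`` by id.
    params : ModelParams, optional
        Estimator settings; defaults are k=10, lam=1, m=1.
    """

    def __init__(
        self,
        traits: TraitMatrix,
        coords: CoordinateTable,
        params: ModelParams | None = None,
    ) -> None:
        self.params = params or ModelParams()
        if traits.n_samples < 3:
            raise ValidationError("need at least 3 samples")
        if self.params.k > traits.n_samples:
            raise ValidationError(
                f"k={self.params.k} exceeds the {traits.n_samples} samples"
            )
        self.traits = traits
        self.coords = coords.align_to(traits.sample_ids)

    # -- constructors --------------------------------------------------

    @classmethod
    def from_files(
        cls,
        traits_path: str | Path,
        coords_path: str | Path,
        params: ModelParams | None = None,
        trait_format: str | None = None,
    ) -> "DispersalModel":
        from .io import read_coordinates, read_trait_matrix

        return cls(
            read_trait_matrix(traits_path, trait_format),
            read_coordinates(coords_path),
            params,
        )

    @classmethod
    def from_simulated(cls, dataset, **param_overrides) -> "DispersalModel":
        """Build from a ``SimulatedDataset``; kwargs override ModelParams."""
        params = ModelParams(**param_overrides) if param_overrides else ModelParams()
        return cls(dataset.traits, dataset.coords, params)

    @classmethod
    def from_dataframe(cls, traits_df, coords_df, params: ModelParams | None = None):
        """Build from pandas frames: traits indexed by sample id, coords with
        columns id/lon/lat."""
        tm = TraitMatrix(
            [str(s) for s in traits_df.index],
            [str(t) for t in traits_df.columns],
            np.nan_to_num(traits_df.to_numpy(float)),
            np.isnan(traits_df.to_numpy(float)),
        )
        ct = CoordinateTable(
            [str(s) for s in coords_df["id"]],
            coords_df["lon"].to_numpy(float),
            coords_df["lat"].to_numpy(float),
        )
        return cls(tm, ct, params)

    # -- fitting -------------------------------------------------------

    def fit(self, infer_centre: bool = True) -> "DispersalResults":
        p = self.params
        tm = filter_traits(self.traits, p.max_missing)
        if tm.has_missing:
            mode = p.impute_mode or "mode_value"
            tm_complete = impute(tm, mode, seed=p.seed)
        else:
            tm_complete = tm
        # the k-NN frequency estimator handles missing cells exactly (they
        # are disregarded within the neighbourhood), so imputed values feed
        # only the steps that need a complete matrix (PCA, prestige) unless
        # explicitly requested
        tm_freq = tm_complete if p.freq_use_imputed else tm

        freq_now = to_frequency(tm_freq, self.coords, p.k, fallback=tm_complete)
        prestige = estimate_prestige(tm_complete, p.lam)
        freq_past = reconstruct_past(freq_now, prestige, p.m)

        emb = fit_pca(tm_complete, n_components=p.n_components, scale=p.scale_pca)
        field_trait = velocity_trait_space(freq_now, freq_past, p.m, anchors=emb.pc_values[:, :2])
        field_pc = project_velocity_pc(field_trait, emb)

        n = tm.n_samples
        kernel = transition_probabilities(field_pc, emb, p.resolve_s_proj(n), p.tau)
        field_geo_raw = project_geo(kernel, self.coords)
        sigma = auto_sigma(self.coords) if p.sigma_geo is None else p.sigma_geo
        field_geo = spatial_smooth(field_geo_raw, field_pc, self.coords, sigma)
        grid = grid_smooth(
            field_geo,
            self.coords,
            s_grid=p.resolve_s_grid_samples(n),
            sigma_geo=sigma,
            support_radius=p.support_radius,
            nx=p.grid_nx,
            ny=p.grid_ny,
        )
        centre = None
        if infer_centre:
            grid = radiativity_scores(grid, p.s_grid)
            centre = _infer_centre(grid)
        return DispersalResults(
            model=self,
            traits_filtered=tm,
            traits_complete=tm_complete,
            freq_now=freq_now,
            freq_past=freq_past,
            prestige=prestige,
            embedding=emb,
            field_trait=field_trait,
            field_pc=field_pc,
            field_geo_raw=field_geo_raw,
            field_geo=field_geo,
            grid=grid,
            centre=centre,
            sigma_geo=sigma,
        )


@dataclass
class DispersalResults:
    """Fitted velocity fields, the inferred centre, and diagnostics."""

    model: DispersalModel
    traits_filtered: TraitMatrix
    traits_complete: TraitMatrix
    freq_now: object
    freq_past: object
    prestige: PrestigeTable
    embedding: PCEmbedding
    field_trait: VelocityField
    field_pc: VelocityField
    field_geo_raw: VelocityField
    field_geo: VelocityField
    grid: GeoGrid
    centre: CentreEstimate | None
    sigma_geo: float

    @property
    def params(self) -> ModelParams:
        return self.model.params

    # -- uncertainty ---------------------------------------------------

    def jackknife(self) -> CentreEstimate:
        """Leave-one-out jackknife SD of the centre coordinates.

        The entire pipeline is rerun on each n-1 subset; failed replicates
        are dropped with a warning and ``n_jackknife`` reports successes.
        """
        if self.centre is None:
            raise ValidationError("fit with infer_centre=True before jackknifing")
        model = self.model
        n = model.traits.n_samples
        if n < 4:
            raise ValidationError("jackknife needs at least 4 samples")
        centres = []
        for i in range(n):
            keep = [j for j in range(n) if j != i]
            sub_params = replace(model.params, seed=model.params.seed + i + 1)
            if sub_params.k > n - 1:
                sub_params = replace(sub_params, k=n - 1)
            try:
                res = DispersalModel(
                    model.traits.subset_samples(keep),
                    model.coords.subset_samples(keep),
                    sub_params,
                ).fit()
                centres.append((res.centre.lon, res.centre.lat))
            except ValidationError as exc:
                logger.warning("jackknife replicate %d failed: %s", i, exc)
        if len(centres) < 2:
            raise ValidationError("too few successful jackknife replicates")
        sds = jackknife_sd(np.asarray(centres))
        self.centre = replace(
            self.centre,
            jackknife_sd_lon=float(sds[0]),
            jackknife_sd_lat=float(sds[1]),
            n_jackknife=len(centres),
        )
        return self.centre

    # -- comparisons ---------------------------------------------------

    def baselines(self) -> dict[str, _baselines.BaselineResult]:
        """Diversity, centroid and minimal-distance homeland estimates."""
        return {
            "DIV": _baselines.diversity_centre(self.freq_now, self.model.coords),
            "Centr": _baselines.centroid_centre(self.model.coords),
            "MD": _baselines.minimal_distance_centre(self.model.coords),
        }

    # -- reporting -----------------------------------------------------

    def summary(self) -> str:
        p = self.params
        n, ptr = self.traits_filtered.values.shape
        lines = [
            "Language velocity field estimation",
            "==================================",
            f"samples: {n}    traits: {ptr} (of {self.model.traits.n_traits} before filtering)",
            f"params: k={p.k} lam={p.lam} m={p.m} tau={p.tau} "
            f"grid={p.grid_nx}x{p.grid_ny} sigma_geo={self.sigma_geo:.4g}",
            f"PC1/PC2 explained variance: "
            f"{self.embedding.explained_variance[0]:.4g}, "
            f"{self.embedding.explained_variance[1]:.4g}",
            f"supported grid points: {int(self.grid.supported.sum())} / {self.grid.n_points}",
        ]
        if self.centre is not None:
            c = self.centre
            lines.append(
                f"dispersal centre: lon={c.lon:.4f} lat={c.lat:.4f} "
                f"(max radiativity sigma2={c.sigma2_max:.4f})"
            )
            if c.n_jackknife:
                lines.append(
                    f"jackknife SD: lon={c.jackknife_sd_lon:.4f} "
                    f"lat={c.jackknife_sd_lat:.4f} (n={c.n_jackknife})"
                )
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        """Write field CSVs and the centre JSON into ``out_dir``."""
        from .io import write_field

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_field(self.field_pc, out / "field_pc.csv")
        write_field(self.field_geo, out / "field_geo.csv")
        write_field(self.grid.as_field(), out / "field_grid.csv")
        payload = {"params": self.params.to_dict()}
        if self.centre is not None:
            payload.update(self.centre.to_dict())
        (out / "centre.json").write_text(json.dumps(payload, indent=2, sort_keys=True))

    def plot_quiver(self, ax=None, frame: str = "grid"):
        """Quiver plot of the geographic or grid field (sanity-check aid)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fld = self.grid.as_field() if frame == "grid" else self.field_geo
        keep = fld.lengths() > 0
        ax.quiver(
            fld.anchors[keep, 0],
            fld.anchors[keep, 1],
            fld.vectors[keep, 0],
            fld.vectors[keep, 1],
            angles="xy",
        )
        if self.centre is not None:
            ax.plot(self.centre.lon, self.centre.lat, "r*", markersize=12)
        ax.set_xlabel("longitude")
        ax.set_ylabel("latitude")
        return ax
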