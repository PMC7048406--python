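"""End-to-end pipeline: simulate -> NDVI -> fit -> cross-calibrate -> invert
-> extract -> validate, with a manifest for reproducibility.

Each stage is also usable on its own through the library (or the CLI); the
pipeline wires them together, writes every intermediate artifact into the
run directory and records SHA-256 hashes, the configuration and the seed in
``manifest.json``. A rerun with the same configuration and seed reproduces
every numeric output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from .crosscal import CompositeModel, CrossCalibration, compose, fit_cross_calibration
from .errors import PipelineStageError
from .invert import DEFAULT_SATURATION_THRESHOLD, apply_model, extract_at_points
from .raster import BiomassRaster, write_geotiff
from .regress import FAMILIES, FamilyComparison, compare_families, split_data
from .spectra import ndvi_table
from .synth import CampaignConfig, SyntheticCampaign, simulate_campaign, write_campaign
from .validate import ValidationReport, scatter_plot, validate

_CSV_FLOAT_FORMAT = "%.12g"


def default_split(n_quadrats: int) -> Tuple[int, int, int]:
    """Scale the canonical 153/20/115 split of a 173-quadrat campaign to n."""
    if n_quadrats == 173:
        return (153, 20, 115)
    holdout = max(2, round(n_quadrats * 20 / 173))
    model = n_quadrats - holdout
    train = max(3, round(model * 115 / 153))
    return (model, holdout, train)


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration of a full run."""

    campaign: CampaignConfig = field(default_factory=CampaignConfig)
    #: (model_n, holdout_n, train_n); None derives it from the quadrat count.
    split: Optional[Tuple[int, int, int]] = None
    families: Tuple[str, ...] = FAMILIES
    saturation_threshold: float = DEFAULT_SATURATION_THRESHOLD
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown families: {sorted(unknown)}")
        if self.saturation_threshold <= 0:
            raise ValueError("saturation_threshold must be > 0")

    def resolved_split(self) -> Tuple[int, int, int]:
        return self.split if self.split is not None else default_split(self.campaign.n_quadrats)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(payload)
        if isinstance(kwargs.get("campaign"), dict):
            cfields = {f.name for f in dataclasses.fields(CampaignConfig)}
            cunknown = set(kwargs["campaign"]) - cfields
            if cunknown:
                raise ValueError(f"unknown campaign keys: {sorted(cunknown)}")
            camp = dict(kwargs["campaign"])
            for key in ("cover_range", "raster_shape", "origin"):
                if key in camp:
                    camp[key] = tuple(camp[key])
            kwargs["campaign"] = CampaignConfig(**camp)
        if kwargs.get("split") is not None:
            kwargs["split"] = tuple(kwargs["split"])
        if "families" in kwargs:
            kwargs["families"] = tuple(kwargs["families"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "campaign": self.campaign.to_dict(),
            "split": list(self.split) if self.split else None,
            "families": list(self.families),
            "saturation_threshold": self.saturation_threshold,
            "seed": self.seed,
        }


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    config: PipelineConfig
    campaign: SyntheticCampaign
    quadrats: pd.DataFrame
    plots: pd.DataFrame
    comparison: FamilyComparison
    cross: CrossCalibration
    composite: CompositeModel
    biomass: BiomassRaster
    predictions: pd.DataFrame
    report: ValidationReport
    outdir: Optional[Path]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir=None, make_plots: bool = True) -> PipelineResult:
    """Execute the full chain; write artifacts when ``outdir`` is given.

    A failing stage raises :class:`PipelineStageError` naming the stage;
    artifacts of completed stages are left in place.
    """
    out = Path(outdir) if outdir is not None else None
    written = []

    def _save_csv(df: pd.DataFrame, name: str):
        if out is not None:
            path = out / name
            path.parent.mkdir(parents=True, exist_ok=True)
            df.to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)
            written.append(path)

    def _save_json(payload: dict, name: str):
        if out is not None:
            path = out / name
            path.parent.mkdir(parents=True, exist_ok=True)
            path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
            written.append(path)

    stage = "simulate"
    try:
        campaign = simulate_campaign(
            dataclasses.replace(config.campaign, seed=config.campaign.seed or config.seed)
        )
        if out is not None:
            write_campaign(campaign, out / "campaign")
            written += sorted((out / "campaign").iterdir())

        stage = "ndvi"
        # Recompute quadrat NDVI from the spectra table (the generator's own
        # column is not reused downstream) and plot means from quadrat NDVIs.
        qndvi = ndvi_table(campaign.spectra)
        quadrats = qndvi.merge(
            campaign.quadrats[["quadrat_id", "plot_id", "agb_g_m2"]], on="quadrat_id"
        )
        plot_means = (
            quadrats.groupby("plot_id", sort=True)["soc_ndvi"].mean().rename("soc_ndvi_mean")
        )
        plots = campaign.plots.drop(columns=["soc_ndvi_mean"]).merge(
            plot_means.reset_index(), on="plot_id"
        )
        _save_csv(quadrats, "ndvi_quadrats.csv")
        _save_csv(plots, "ndvi_plots.csv")

        stage = "fit"
        split = split_data(quadrats["quadrat_id"], config.resolved_split(), seed=config.seed)
        by_id = quadrats.set_index("quadrat_id")
        train = by_id.loc[list(split.train_ids)].reset_index()
        test = by_id.loc[list(split.test_ids)].reset_index()
        comparison = compare_families(train, test, families=config.families)
        _save_csv(comparison.table().reset_index(names="statistic"), "comparison_table.csv")
        _save_json(
            {
                "selected": comparison.selected,
                "fits": {f: dataclasses.asdict(fit) for f, fit in comparison.fits.items()},
                "metrics": {f: dataclasses.asdict(m) for f, m in comparison.metrics.items()},
                "failures": comparison.failures,
                "split_seed": config.seed,
                "split_sizes": list(config.resolved_split()),
            },
            "fits.json",
        )

        stage = "crosscal"
        cross = fit_cross_calibration(plots)
        if "exponential" not in comparison.fits:
            raise PipelineStageError(stage, "exponential ground fit unavailable for composition")
        composite = compose(comparison.fits["exponential"], cross)
        _save_json(dataclasses.asdict(cross), "crosscal.json")
        _save_json(composite.to_dict(), "composite_model.json")

        stage = "invert"
        biomass = apply_model(campaign.raster, composite, config.saturation_threshold)
        if out is not None:
            write_geotiff(out / "agb.tif", biomass)
            written.append(out / "agb.tif")

        stage = "extract"
        holdout = by_id.loc[list(split.holdout_ids)].reset_index()
        coords = holdout.merge(campaign.plots[["plot_id", "x", "y"]], on="plot_id")
        points = coords.rename(columns={"quadrat_id": "point_id"})[["point_id", "x", "y"]]
        predictions = extract_at_points(biomass, points)
        _save_csv(points, "points.csv")
        _save_csv(predictions, "pred.csv")

        stage = "validate"
        merged = coords.merge(
            predictions, left_on="quadrat_id", right_on="point_id", how="left"
        )
        report = validate(merged["agb_g_m2"], merged["predicted_agb_g_m2"])
        if out is not None:
            report.to_json(out / "validation_report.json")
            written.append(out / "validation_report.json")
            if make_plots:
                scatter_plot(report, out / "validation_scatter.png")
                written.append(out / "validation_scatter.png")
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    if out is not None:
        manifest = {
            "package": "grassinvert",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "outputs": {
                str(p.relative_to(out)): _sha256(p) for p in sorted(set(written)) if p.is_file()
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        config=config,
        campaign=campaign,
        quadrats=quadrats,
        plots=plots,
        comparison=comparison,
        cross=cross,
        composite=composite,
        biomass=biomass,
        predictions=predictions,
        report=report,
        outdir=out,
    )
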