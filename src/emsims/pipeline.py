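"""End-to-end orchestration: fixture generation, registration,
quantification, morphometry and statistics from one configuration.

A run is reproducible from its manifest: one global seed is split into
named substreams per stage and per field, and identical configuration +
seed produce identical result tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._rng import substream
from . import __version__
from .cohort import (
    compare_morphology,
    compare_to_whole,
    extreme_subsets,
    nascent_fraction_contrast,
    normalize_and_contrast_ages,
    paired_regression,
)
from .geometry import polygon_mask
from .isotope_ratio import DisplayConfig, display_image, ratio_map, roi_ratio, save_display, whole_area_ratio
from .morphometry import measure
from .registration import apply_affine, fit_affine
from .simdata import (
    AcquisitionParams,
    Fixture,
    SceneSpec,
    build_scene,
    export_fixture,
    import_fixture,
    simulate_acquisition,
)

__all__ = ["RunConfig", "PipelineError", "run", "make_fixture", "analyze_fixtures"]

log = logging.getLogger("emsims")

#: morphometry parameters compared between extreme-turnover subsets
EXTREME_PARAMETERS = {
    "presynapse": ("area_um2", "vesicle_count"),
    "postsynapse": ("area_um2",),
    "PSD": ("area_um2", "length_um"),
    "mitochondrion": ("area_um2",),
    "neurite": ("area_um2",),
    "axon": ("area_um2",),
    "myelin": ("thickness_nm",),
}

PAIRINGS = (
    ("presynapse", "active_zone"),
    ("postsynapse", "PSD"),
    ("presynapse", "postsynapse"),
)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class RunConfig:
    """Configuration of a run (see the CLI's ``--config`` YAML file).

    ``scene`` and ``acquisition`` hold keyword overrides for
    :class:`~emsims.simdata.SceneSpec` and
    :class:`~emsims.simdata.AcquisitionParams`. In the default simulated
    cohort the aged enrichments are the young ones scaled by
    ``aged_ratio_scale`` (global slowdown) with an extra presynaptic factor
    ``aged_presynapse_extra`` as a planted, recoverable age effect.
    """

    mode: str = "full"
    seed: int = 0
    out_dir: str = "results"
    regions: tuple[str, ...] = ("CA1", "cortex", "DG")
    ages: tuple[str, ...] = ("young", "aged")
    images_per_stratum: int = 1
    scene: dict = field(default_factory=dict)
    acquisition: dict = field(default_factory=dict)
    aged_ratio_scale: float = 0.81
    aged_presynapse_extra: float = 0.95
    k_extremes: int = 18
    display: dict = field(default_factory=dict)
    fixtures: list = field(default_factory=list)  # analyze-mode inputs

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.regions = tuple(cfg.regions)
        cfg.ages = tuple(cfg.ages)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["regions"] = list(self.regions)
        d["ages"] = list(self.ages)
        return d


def _stage(name: str):
    """Decorator surfacing stage failures with the stage name."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(f"stage {name!r} failed: {err}") from err

        return inner

    return wrap


def _scene_spec(config: RunConfig, region: str, age: str, index: int) -> SceneSpec:
    overrides = dict(config.scene)
    enrich = dict(overrides.pop("class_enrichment", {}) or {})
    base = SceneSpec(**overrides).class_enrichment | enrich
    if age == "aged":
        base = {c: r * config.aged_ratio_scale for c, r in base.items()}
        base["presynapse"] *= config.aged_presynapse_extra
    seed = int(
        substream(config.seed, f"scene/{region}/{age}/{index}").integers(2**31)
    )
    return SceneSpec(**overrides, class_enrichment=base, seed=seed)


@_stage("simulate")
def make_fixture(config: RunConfig, out_dir) -> list[dict]:
    """Generate the simulated cohort fixture set; returns its inventory."""
    out = Path(out_dir)
    inventory = []
    for region in config.regions:
        for age in config.ages:
            for i in range(config.images_per_stratum):
                spec = _scene_spec(config, region, age, i)
                acq_seed = int(
                    substream(config.seed, f"acq/{region}/{age}/{i}").integers(2**31)
                )
                acq = AcquisitionParams(**{"seed": acq_seed, **config.acquisition})
                truth = build_scene(spec)
                pair = simulate_acquisition(truth, acq)
                name = f"{region}_{age}_{i}"
                export_fixture(truth, pair, out / "fixtures" / name)
                inventory.append(
                    {
                        "path": str(out / "fixtures" / name),
                        "region": region,
                        "age_group": age,
                        "image_id": name,
                    }
                )
                log.info("simulated fixture %s (%d objects)", name, len(truth.objects))
    (out / "fixtures" / "inventory.json").write_text(json.dumps(inventory, indent=1))
    return inventory


@_stage("quantify")
def _quantify_fixture(entry: dict, display_cfg: DisplayConfig, out: Path) -> pd.DataFrame:
    """Register, quantify and measure one fixture; returns table rows."""
    fx: Fixture = import_fixture(entry["path"])
    affine = fit_affine(fx.landmarks_em, fx.landmarks_sims)
    shape = fx.pair.shape
    whole = whole_area_ratio(fx.pair)

    disp_dir = out / "display"
    disp_dir.mkdir(parents=True, exist_ok=True)
    disp = display_image(ratio_map(fx.pair), display_cfg)
    save_display(
        disp,
        png_path=disp_dir / f"{entry['image_id']}.png",
        tiff_path=disp_dir / f"{entry['image_id']}.tif",
    )

    presynapses = [a for a in fx.annotations if a.structure == "presynapse"]
    rows = []
    for ann in fx.annotations:
        sims_poly = apply_affine(affine, ann.polygon)
        mask = polygon_mask(sims_poly, shape)
        if ann.inner_contour is not None:
            mask &= ~polygon_mask(apply_affine(affine, ann.inner_contour), shape)
        try:
            rr = roi_ratio(fx.pair, mask, roi_name=f"{entry['image_id']}:{ann.object_id}")
        except ValueError as err:
            raise PipelineError(
                f"stage 'quantify' failed for object {ann.object_id} "
                f"in {entry['image_id']}: {err}"
            ) from err
        rec = measure(ann, fx.pair.pixel_size_nm, presynapses=presynapses)
        rows.append(
            {
                "object_id": f"{entry['image_id']}:{ann.object_id}",
                "structure": ann.structure,
                "region": entry["region"],
                "age_group": entry["age_group"],
                "image_id": entry["image_id"],
                "ratio": rr.ratio,
                "sum15": rr.sum15,
                "sum14": rr.sum14,
                "n_pixels": rr.n_pixels,
                "whole_area_ratio": whole.ratio,
                "image_sum15": whole.sum15,
                "image_sum14": whole.sum14,
                "area_um2": rec.area_um2,
                "length_um": rec.length_um,
                "vesicle_count": rec.vesicle_count,
                "thickness_nm": rec.thickness_nm,
                "nascent_zone": rec.nascent_zone,
                "in_presynapse": rec.in_presynapse,
                "pair_id": (
                    None if ann.pair_id is None else f"{entry['image_id']}:{ann.pair_id}"
                ),
                "registration_rms_px": affine.rms_residual,
            }
        )
    return pd.DataFrame(rows)


@_stage("statistics")
def _run_statistics(table: pd.DataFrame, config: RunConfig, out: Path) -> None:
    # structure vs whole-area contrasts, per stratum
    contrast_rows = []
    strata = table[["region", "age_group"]].drop_duplicates().to_numpy()
    for region, age in strata:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for res in compare_to_whole(table, region, age):
                contrast_rows.append(
                    {
                        "region": region,
                        "age_group": age,
                        "structure": res.structure,
                        "raw_p": res.raw_p,
                        "corrected_p": res.corrected_p,
                        "n_objects": res.n_objects,
                        "n_whole": res.n_whole,
                        "effect_direction": res.effect_direction,
                        "correction_m": res.correction_m,
                    }
                )
    pd.DataFrame(contrast_rows).to_csv(out / "contrasts_whole.csv", index=False)

    # aged vs young, whole-organ normalized
    ages = set(table["age_group"])
    if {"young", "aged"} <= ages:
        young = table[table["age_group"] == "young"]
        aged = table[table["age_group"] == "aged"]
        rows = []
        for res in normalize_and_contrast_ages(young, aged):
            row = {
                "structure": res.structure,
                "mean_over_regions": res.mean_over_regions,
                "raw_p": res.raw_p,
                "corrected_p": res.corrected_p,
                "correction_m": res.correction_m,
            }
            row.update(
                {f"norm_{r}": v for r, v in res.normalized_by_region.items()}
            )
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "age_contrasts.csv", index=False)

    # extreme-subset morphology, per stratum and class
    extreme_rows = []
    psd_high, psd_low = [], []
    for region, age in strata:
        for cls, parameters in EXTREME_PARAMETERS.items():
            sub = table[
                (table["region"] == region)
                & (table["age_group"] == age)
                & (table["structure"] == cls)
            ]
            k = min(config.k_extremes, len(sub) // 2)
            if k < 2:
                log.info("skipping extremes for %s in %s/%s (n=%d)", cls, region, age, len(sub))
                continue
            high, low = extreme_subsets(table, cls, region, age, k=k)
            if cls == "PSD":
                psd_high.append(high)
                psd_low.append(low)
            for parameter in parameters:
                if high[parameter].isna().any() or low[parameter].isna().any():
                    continue
                cmp = compare_morphology(high, low, parameter)
                extreme_rows.append(
                    {
                        "region": region,
                        "age_group": age,
                        "structure": cls,
                        "parameter": parameter,
                        "k": k,
                        "p_value": cmp.p_value,
                        "median_high": cmp.median_high,
                        "median_low": cmp.median_low,
                    }
                )
    pd.DataFrame(extreme_rows).to_csv(out / "extreme_morphology.csv", index=False)

    # nascent-zone percentages across strata
    if psd_high and len(psd_high) >= 2:
        high_all = pd.concat(psd_high)
        low_all = pd.concat(psd_low)
        if high_all["nascent_zone"].notna().all() and low_all["nascent_zone"].notna().all():
            res = nascent_fraction_contrast(high_all, low_all)
            pd.DataFrame(
                {
                    "region": [s[0] for s in res.strata],
                    "age_group": [s[1] for s in res.strata],
                    "high_pct": res.high_pct,
                    "low_pct": res.low_pct,
                    "p_value": res.p_value,
                }
            ).to_csv(out / "nascent_contrast.csv", index=False)

    # paired pre/post regressions, per stratum
    reg_rows = []
    for region, age in strata:
        sub = table[(table["region"] == region) & (table["age_group"] == age)]
        for x_cls, y_cls in PAIRINGS:
            try:
                res = paired_regression(sub, x_cls, y_cls)
            except ValueError:
                continue
            reg_rows.append(
                {
                    "region": region,
                    "age_group": age,
                    "x": x_cls,
                    "y": y_cls,
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "r_squared": res.r_squared,
                    "p_value": res.p_value,
                    "n_pairs": res.n_pairs,
                }
            )
    pd.DataFrame(reg_rows).to_csv(out / "paired_regressions.csv", index=False)


def analyze_fixtures(config: RunConfig, inventory: list[dict], out_dir) -> pd.DataFrame:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    display_cfg = DisplayConfig(**config.display)
    tables = [_quantify_fixture(e, display_cfg, out) for e in inventory]
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(out / "turnover_table.csv", index=False)
    morpho_cols = [
        "object_id",
        "structure",
        "region",
        "age_group",
        "area_um2",
        "length_um",
        "vesicle_count",
        "thickness_nm",
        "nascent_zone",
        "in_presynapse",
    ]
    table[morpho_cols].to_csv(out / "morphometry.csv", index=False)
    _run_statistics(table, config, out)
    return table


def _write_manifest(config: RunConfig, out: Path) -> None:
    cfg = config.to_dict()
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode("utf8")
    ).hexdigest()
    import scipy
    import shapely

    manifest = {
        "config": cfg,
        "config_sha256": digest,
        "seed": config.seed,
        "versions": {
            "emsims": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "shapely": shapely.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def run(config: RunConfig, out_dir=None) -> Path:
    """Execute a run; returns the results directory.

    Modes: ``simulate`` writes the fixture set only; ``analyze`` consumes
    the fixtures listed in the config; ``full`` simulates then analyzes.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    try:
        _write_manifest(config, out)
        if config.mode not in ("simulate", "analyze", "full"):
            raise PipelineError(f"unknown mode {config.mode!r}")
        if config.mode in ("simulate", "full"):
            inventory = make_fixture(config, out)
        else:
            inventory = config.fixtures
            if not inventory:
                raise PipelineError("analyze mode requires a fixtures list")
        if config.mode in ("analyze", "full"):
            analyze_fixtures(config, inventory, out)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
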