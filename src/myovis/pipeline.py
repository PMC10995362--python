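"""End-to-end orchestration: simulate -> cones -> choroid -> csf -> stats.

Each stage reads/writes plain CSV/JSON/TIFF under an output directory and a
single JSON manifest records the seed, the config hash, and the package
version, so a run can be replayed exactly.  Reruns with the same config and
seed produce byte-identical CSV/JSON payloads (no timestamps are written).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .choroid import (
    BinarizationParams,
    INNER_SUBFIELD,
    OUTER_SUBFIELD,
    choroid_mask_from_boundaries,
    choroid_metrics,
    linearize,
    niblack_binarize,
    read_boundaries,
    sublayer_thickness,
    write_boundaries,
)
from .cone_mosaic import AOImage, DetectionParams, ROISpec, detect_cones, mosaic_metrics
from .csf import PsiGridConfig, run_session
from .stats import group_table, regression_screen, sex_distribution_test
from .synthetic import (
    ChoroidPhantomSpec,
    CohortSpec,
    MosaicSpec,
    ObserverSpec,
    SimulatedObserver,
    gen_choroid_phantom,
    gen_cohort,
    gen_mosaic,
)

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "STAGES"]

log = logging.getLogger("myovis.pipeline")

STAGES = ("simulate", "cones", "choroid", "csf", "stats")

_SPEC_CLASSES = {
    "mosaic": MosaicSpec,
    "phantom": ChoroidPhantomSpec,
    "observer": ObserverSpec,
}

_DEFAULT_STATS_OUTCOMES = [
    "aulcsf",
    "cutoff_sf",
    "cone_density_inner",
    "cone_density_outer",
    "cone_spacing_inner",
    "cone_spacing_outer",
    "cone_regularity",
    "ct_um",
    "cvi",
    "tca_mm2",
]

_DEFAULT_STATS_PREDICTORS = [
    "al_mm",
    "cone_density_outer",
    "ct_um",
    "cvi",
    "is_um",
    "os_um",
    "izrpe_um",
]


class ConfigError(ValueError):
    """Configuration failed validation; the message names the offending field."""


def _build_spec(cls, block: dict, field_path: str, seed: int):
    valid = {f.name for f in dc_fields(cls)}
    for key in block:
        if key not in valid:
            raise ConfigError(f"unknown field {field_path}.{key}")
    kwargs = dict(block)
    kwargs.setdefault("seed", seed)
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid value in {field_path}: {e}") from e


class RunConfig:
    """Validated pipeline configuration.

    Top-level keys: ``stages`` (list or "all"), ``out_dir``, ``seed``, and
    one optional parameter block per stage (``simulate``, ``cones``,
    ``choroid``, ``csf``, ``stats``).  Unknown or invalid fields raise
    :class:`ConfigError` naming the field.
    """

    _TOP_KEYS = {"stages", "out_dir", "seed", *STAGES}

    def __init__(self, raw: dict):
        for key in raw:
            if key not in self._TOP_KEYS:
                raise ConfigError(f"unknown field {key}")
        self.raw = raw
        stages = raw.get("stages", "all")
        if stages == "all":
            stages = list(STAGES)
        if not isinstance(stages, list) or any(s not in STAGES for s in stages):
            raise ConfigError(f"stages must be 'all' or a subset of {STAGES}")
        self.stages = stages
        self.out_dir = Path(raw.get("out_dir", "myovis_run"))
        self.seed = int(raw.get("seed", 0))
        if self.seed < 0:
            raise ConfigError("seed must be non-negative")
        csf_block = raw.get("csf", {})
        n_trials = csf_block.get("n_trials_per_freq", 45)
        if not isinstance(n_trials, int) or n_trials < 0:
            raise ConfigError("csf.n_trials_per_freq must be a non-negative integer")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as f:
            raw = yaml.safe_load(f)
        return cls(raw or {})

    def config_hash(self) -> str:
        # hash the scientific parameters only, not the output location
        canon = json.dumps(
            {k: v for k, v in self.raw.items() if k != "out_dir"},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as f:
        json.dump(obj, f, sort_keys=True, indent=1)


def _stage_simulate(cfg: RunConfig, out: Path) -> None:
    block = cfg.raw.get("simulate", {})
    import tifffile

    mosaic_spec = _build_spec(MosaicSpec, block.get("mosaic", {}), "simulate.mosaic", cfg.seed)
    image, truth = gen_mosaic(mosaic_spec)
    tifffile.imwrite(out / "mosaic.tif", image.pixels.astype(np.float32))
    pd.DataFrame(truth, columns=["x_um", "y_um"]).to_csv(
        out / "mosaic_truth.csv", index=False, float_format="%.4f"
    )
    _write_json(
        {"pixel_scale": mosaic_spec.pixel_scale, "side_um": mosaic_spec.side_um},
        out / "mosaic_meta.json",
    )

    phantom_spec = _build_spec(
        ChoroidPhantomSpec, block.get("phantom", {}), "simulate.phantom", cfg.seed
    )
    scan, boundaries, labels = gen_choroid_phantom(phantom_spec)
    tifffile.imwrite(out / "phantom.tif", scan.pixels.astype(np.float32))
    tifffile.imwrite(out / "phantom_labels.tif", labels.astype(np.uint8))
    write_boundaries(boundaries, out / "phantom_boundaries.json")
    _write_json(
        {
            "lateral_scale": phantom_spec.lateral_scale,
            "axial_scale": phantom_spec.axial_scale,
            "fovea_column": scan.fovea_column,
            "lumen_fraction": phantom_spec.lumen_fraction,
        },
        out / "phantom_meta.json",
    )

    cohort_spec = CohortSpec(seed=cfg.seed)
    cohort_block = block.get("cohort", {})
    for key in cohort_block:
        if key != "seed":
            raise ConfigError(f"unknown field simulate.cohort.{key}")
    gen_cohort(cohort_spec, seed=cohort_block.get("seed", cfg.seed)).to_csv(
        out / "cohort.csv", index=False, float_format="%.6g"
    )
    log.info("simulate: wrote mosaic, phantom, cohort to %s", out)


def _stage_cones(cfg: RunConfig, out: Path) -> None:
    import tifffile

    img_path = out / "mosaic.tif"
    if not img_path.exists():
        raise FileNotFoundError("cones stage requires simulate output (mosaic.tif)")
    with open(out / "mosaic_meta.json") as f:
        meta = json.load(f)
    px = tifffile.imread(img_path).astype(float)
    image = AOImage(
        pixels=px, pixel_scale=meta["pixel_scale"], fovea_xy=(px.shape[1] / 2, px.shape[0] / 2)
    )
    block = cfg.raw.get("cones", {})
    valid = {f.name for f in dc_fields(DetectionParams)}
    for key in block:
        if key not in valid:
            raise ConfigError(f"unknown field cones.{key}")
    params = DetectionParams(**block)
    roi = ROISpec(center_eccentricity=0.0, meridian="temporal", region_label="inner")
    mosaic = detect_cones(image, roi, params)
    metrics = mosaic_metrics(mosaic)
    pd.DataFrame(mosaic.positions, columns=["x_um", "y_um"]).to_csv(
        out / "cone_positions.csv", index=False, float_format="%.4f"
    )
    pd.DataFrame(
        [
            {
                "density": metrics.density,
                "spacing": metrics.spacing,
                "regularity": metrics.regularity,
                "n_cones": metrics.n_cones,
            }
        ]
    ).to_csv(out / "cone_metrics.csv", index=False, float_format="%.6g")
    log.info("cones: %d cones, density %.0f/mm^2", metrics.n_cones, metrics.density)


def _stage_choroid(cfg: RunConfig, out: Path) -> None:
    import tifffile

    scan_path = out / "phantom.tif"
    if not scan_path.exists():
        raise FileNotFoundError("choroid stage requires simulate output (phantom.tif)")
    with open(out / "phantom_meta.json") as f:
        meta = json.load(f)
    from .choroid import BScan

    scan = BScan(
        pixels=tifffile.imread(scan_path).astype(float),
        lateral_scale=meta["lateral_scale"],
        axial_scale=meta["axial_scale"],
        fovea_column=meta["fovea_column"],
    )
    boundaries = read_boundaries(out / "phantom_boundaries.json")
    block = cfg.raw.get("choroid", {})
    valid = {f.name for f in dc_fields(BinarizationParams)}
    for key in block:
        if key not in valid:
            raise ConfigError(f"unknown field choroid.{key}")
    params = BinarizationParams(**block)
    flat, fb, _ = linearize(scan, boundaries)
    choroid = choroid_mask_from_boundaries(flat, fb)
    lumen = niblack_binarize(flat, choroid, params)
    rows = []
    for sub in (INNER_SUBFIELD, OUTER_SUBFIELD):
        q = choroid_metrics(flat, fb, lumen, sub)
        layer_um = sublayer_thickness(
            fb, sub, scan.axial_scale, scan.fovea_column, scan.lateral_scale
        )
        rows.append(
            {
                "subfield": sub.label,
                "CT_um": q.CT,
                "LA_mm2": q.LA,
                "SA_mm2": q.SA,
                "TCA_mm2": q.TCA,
                "CVI": q.CVI,
                **{f"{k}_um": v for k, v in layer_um.items()},
            }
        )
    pd.DataFrame(rows).to_csv(out / "choroid_metrics.csv", index=False, float_format="%.6g")
    log.info("choroid: CVI inner %.3f", rows[0]["CVI"])


def _stage_csf(cfg: RunConfig, out: Path) -> None:
    block = dict(cfg.raw.get("csf", {}))
    n_trials = block.pop("n_trials_per_freq", 45)
    obs_spec = _build_spec(ObserverSpec, block.pop("observer", {}), "csf.observer", cfg.seed)
    for key in block:
        raise ConfigError(f"unknown field csf.{key}")
    observer = SimulatedObserver(obs_spec)
    result = run_session(
        observer,
        n_trials_per_freq=n_trials,
        rng=np.random.default_rng(cfg.seed),
        config=PsiGridConfig(),
    )
    result.trial_log.to_csv(out / "csf_trials.csv", index=False, float_format="%.6g")
    _write_json(
        {
            "frequencies_cpd": list(result.spatial_frequencies),
            "thresholds": [round(t, 8) for t in result.thresholds],
            "log_sensitivities": [round(s, 8) for s in result.log_sensitivities],
            "aulcsf": round(result.aulcsf, 8),
            "cutoff_sf_log10cpd": round(result.cutoff_sf, 8),
            "metadata": result.metadata,
        },
        out / "csf_result.json",
    )
    log.info("csf: AULCSF %.3f, cutoff %.3f log10 cpd", result.aulcsf, result.cutoff_sf)


def _stage_stats(cfg: RunConfig, out: Path) -> None:
    cohort_path = out / "cohort.csv"
    if not cohort_path.exists():
        raise FileNotFoundError("stats stage requires a cohort table (cohort.csv)")
    df = pd.read_csv(cohort_path)
    block = cfg.raw.get("stats", {})
    for key in block:
        if key not in {"outcomes", "regression_outcome", "predictors"}:
            raise ConfigError(f"unknown field stats.{key}")
    outcomes = block.get("outcomes", _DEFAULT_STATS_OUTCOMES)
    gt = group_table(df, outcomes)
    gt.to_csv(out / "group_comparisons.csv", index=False, float_format="%.6g")
    chi2, p = sex_distribution_test(df)
    screen = regression_screen(
        df,
        block.get("regression_outcome", "aulcsf"),
        block.get("predictors", _DEFAULT_STATS_PREDICTORS),
    )
    uni_rows = [
        {
            "predictor": p_,
            "beta": r.beta[p_],
            "beta_std": r.beta_standardized[p_],
            "p": r.p_values[p_],
        }
        for p_, r in screen.univariate.items()
    ]
    pd.DataFrame(uni_rows).to_csv(
        out / "regression_univariate.csv", index=False, float_format="%.6g"
    )
    if screen.final is not None:
        multi_rows = [
            {
                "predictor": p_,
                "beta": screen.final.beta[p_],
                "beta_std": screen.final.beta_standardized[p_],
                "p": screen.final.p_values[p_],
            }
            for p_ in screen.final.predictors
        ]
    else:
        multi_rows = []
    pd.DataFrame(multi_rows, columns=["predictor", "beta", "beta_std", "p"]).to_csv(
        out / "regression_multivariate.csv", index=False, float_format="%.6g"
    )
    _write_json({"sex_chi2": round(chi2, 8), "sex_p": round(p, 8)}, out / "sex_test.json")
    log.info("stats: %d outcomes compared; sex chi2 p=%.3f", len(outcomes), p)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "cones": _stage_cones,
    "choroid": _stage_choroid,
    "csf": _stage_csf,
    "stats": _stage_stats,
}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the selected stages in dependency order; returns the out dir."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        if stage in config.stages:
            log.info("running stage %s", stage)
            _STAGE_FUNCS[stage](config, out)
    _write_json(
        {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stages": list(config.stages),
            "version": __version__,
        },
        out / "manifest.json",
    )
    return out
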