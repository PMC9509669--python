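"""End-to-end orchestration: occurrences → niche dynamics → SDM → range shifts.

A run compares a "native" (progenitor-like) and an "introduced"
(crop-like) entity on one landscape: records are cleaned and spatially
rarefied, derived climate layers (growing degree days, aridity) are added,
the COUE niche partition is computed in the PCA environment space, climate
means and ranges are compared statistically, an ensemble SDM produces a
binary potential range per entity, and the two ranges are compared by
Mapcurves GOF, range ratio and percent increase.

Inputs come either from a :class:`~nichedyn.synthetic_data.SyntheticScenario`
(generated at run time) or from occurrence CSVs plus an ESRI ASCII raster
directory. All randomness derives from the config seed, so a run is
deterministic end to end.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate_stats, niche_dynamics, range_comparison, sdm_ensemble
from .occurrence_prep import OccurrenceSet, clean_records, rarefy, read_occurrences
from .predictors import (
    SampleMatrix,
    TMEAN_NAMES,
    add_derived_layers,
    extract_at_points,
    min_max_scale,
    pooled_reference,
)
from .raster import PredictorStack, read_stack
from .synthetic_data import SyntheticScenario, gen_env_rasters, gen_occurrences

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1"


@dataclass
class PipelineConfig:
    """Parameters of one two-entity comparison run."""

    scenario: SyntheticScenario | None = None
    native_csv: str | None = None
    intro_csv: str | None = None
    raster_dir: str | None = None
    native_taxon: str = "progenitor"
    intro_taxon: str = "crop"
    max_uncertainty_km: float = 10.0
    rarefy_radius_km: float = 10.0
    resolution: int = 100
    bandwidth: str | float = "silverman"
    threshold_quantile: float = 0.0
    threshold_mode: str = "value"
    algorithms: list[str] = field(default_factory=lambda: list(sdm_ensemble.DEFAULT_ALGORITHMS))
    test_size: float = 0.3
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        if self.scenario is None:
            missing = [
                n for n, v in [
                    ("native_csv", self.native_csv),
                    ("intro_csv", self.intro_csv),
                    ("raster_dir", self.raster_dir),
                ] if v is None
            ]
            if missing:
                raise ValueError(
                    f"config must provide a scenario or input paths; missing {missing}"
                )
            for p in (self.native_csv, self.intro_csv, self.raster_dir):
                if not Path(p).exists():
                    raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "scenario" in raw and raw["scenario"] is not None:
            from .synthetic_data import GaussianNiche

            sc = dict(raw["scenario"])
            for key in ("native_niche", "intro_niche"):
                if key in sc and isinstance(sc[key], dict):
                    sc[key] = GaussianNiche(
                        tuple(sc[key]["mean"]),
                        tuple(tuple(r) for r in sc[key]["cov"]),
                    )
            if "grid_shape" in sc:
                sc["grid_shape"] = tuple(sc["grid_shape"])
            raw["scenario"] = SyntheticScenario(**sc)
        return cls(**raw)


@dataclass
class RunReport:
    """Machine-readable results of one pipeline run."""

    counts: dict
    niche: dict
    stats: dict
    sdm: dict
    range_shift: dict
    config: dict
    schema_version: str = REPORT_SCHEMA_VERSION

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_fingerprint(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.scenario is not None:
        d["scenario"] = dataclasses.asdict(config.scenario)
    return d


def _load_inputs(config: PipelineConfig) -> tuple[PredictorStack, OccurrenceSet, OccurrenceSet]:
    if config.scenario is not None:
        sc = config.scenario
        stack = gen_env_rasters(sc)
        native = gen_occurrences(
            stack, sc.native_niche, sc.n_native, seed=sc.seed * 1000 + 1,
            taxon=config.native_taxon,
        )
        intro = gen_occurrences(
            stack, sc.intro_niche, sc.n_intro, seed=sc.seed * 1000 + 2,
            taxon=config.intro_taxon,
        )
        return stack, native, intro
    stack = read_stack(config.raster_dir)
    native = read_occurrences(config.native_csv, taxon=config.native_taxon)
    intro = read_occurrences(config.intro_csv, taxon=config.intro_taxon)
    return stack, native, intro


def analysis_predictor_names(stack: PredictorStack) -> list[str]:
    """Predictors entering the ordination/SDM: everything except the raw
    monthly temperatures and PET (which only feed the derived layers)."""
    drop = set(TMEAN_NAMES) | {"pet"}
    return [n for n in stack.names if n not in drop]


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages for one two-entity comparison. Deterministic per seed."""
    config.validate()
    stack, native_raw, intro_raw = _load_inputs(config)

    # --- occurrence preparation -------------------------------------------
    native_clean = clean_records(native_raw, config.max_uncertainty_km)
    intro_clean = clean_records(intro_raw, config.max_uncertainty_km)
    native = rarefy(native_clean, config.rarefy_radius_km, seed=config.seed * 100 + 11)
    intro = rarefy(intro_clean, config.rarefy_radius_km, seed=config.seed * 100 + 12)
    counts = {
        "native_raw": len(native_raw), "native_clean": len(native_clean),
        "native_rarefied": len(native),
        "intro_raw": len(intro_raw), "intro_clean": len(intro_clean),
        "intro_rarefied": len(intro),
    }

    # --- predictors --------------------------------------------------------
    if set(TMEAN_NAMES) <= set(stack.names) and "pet" in stack.names:
        stack = add_derived_layers(stack)
    pred_names = analysis_predictor_names(stack)
    pred_stack = stack.subset(pred_names)
    native_x = extract_at_points(pred_stack, native)
    intro_x = extract_at_points(pred_stack, intro)
    background = SampleMatrix(
        pd.DataFrame(pred_stack.to_matrix(), columns=pred_names), group="background"
    )

    # --- niche dynamics ----------------------------------------------------
    space = niche_dynamics.fit_env_pca(background, resolution=config.resolution)
    bg_scores = space.project(background)
    native_grid = niche_dynamics.density_grid(
        space.project(native_x), bg_scores, space,
        bandwidth=config.bandwidth,
        threshold_quantile=config.threshold_quantile,
        threshold_mode=config.threshold_mode,
    )
    intro_grid = niche_dynamics.density_grid(
        space.project(intro_x), bg_scores, space,
        bandwidth=config.bandwidth,
        threshold_quantile=config.threshold_quantile,
        threshold_mode=config.threshold_mode,
    )
    idx = niche_dynamics.niche_indices(native_grid, intro_grid)
    verdict = niche_dynamics.conservatism_verdict(idx)
    niche_report = {
        **idx.as_dict(),
        "verdict": verdict,
        "explained": [float(v) for v in space.explained],
        "top_pc1": niche_dynamics.top_loadings(space, 1, 3),
        "top_pc2": niche_dynamics.top_loadings(space, 2, 3),
    }

    # --- climatic comparisons ---------------------------------------------
    ref = pooled_reference(native_x, intro_x)
    native_s = min_max_scale(native_x, ref)
    intro_s = min_max_scale(intro_x, ref)
    stats_report: dict = {}
    for axis in (1, 2):
        top = niche_dynamics.top_loadings(space, axis, 1)[0]
        tt = climate_stats.independent_t(
            intro_x.values[top].to_numpy(), native_x.values[top].to_numpy()
        )
        stats_report[f"pc{axis}_top_predictor"] = top
        stats_report[f"pc{axis}_mean_test"] = dataclasses.asdict(tt)
    pt = climate_stats.paired_t(
        climate_stats.column_ranges(intro_s), climate_stats.column_ranges(native_s)
    )
    stats_report["paired_range_test"] = dataclasses.asdict(pt)
    stats_report["times_wider"] = climate_stats.range_breadth_ratio(intro_s, native_s)

    # --- ensemble SDMs -----------------------------------------------------
    sdm_report: dict = {}
    predictions = {}
    for label, occ, x, pa_seed in (
        ("native", native, native_x, config.seed * 100 + 21),
        ("intro", intro, intro_x, config.seed * 100 + 22),
    ):
        pa_sets = sdm_ensemble.sample_pseudo_absences(
            len(occ), pred_stack, seed=pa_seed, presence=occ
        )
        pa_x = [
            SampleMatrix(_extract_pa(pred_stack, pa.points, pred_names), group=f"pa{pa.set_id}")
            for pa in pa_sets
        ]
        fits = sdm_ensemble.fit_and_predict(
            x, pa_x, pred_stack, algorithms=config.algorithms,
            test_size=config.test_size, seed=config.seed * 100 + 31,
        )
        eval_x = pd.concat([x.values] + [m.values for m in pa_x], ignore_index=True)
        eval_y = np.concatenate(
            [np.ones(len(x), dtype=int)] + [np.zeros(len(m), dtype=int) for m in pa_x]
        )
        ens = sdm_ensemble.ensemble_predict(fits, eval_x, eval_y)
        predictions[label] = ens
        sdm_report[label] = {
            "area_km2": ens.area_km2,
            "mss_threshold": ens.mss_threshold,
            "mean_tss": ens.mean_tss,
            "mean_auc": ens.mean_auc,
            "n_retained": len(ens.weights),
            "n_fitted": len(fits),
            "evaluations": [dataclasses.asdict(f.evaluation) for f in fits],
        }

    # --- range comparison --------------------------------------------------
    gof = range_comparison.mapcurves_gof(
        predictions["intro"].binary_range, predictions["native"].binary_range
    )
    ratio = range_comparison.range_ratio(
        predictions["intro"].area_km2, predictions["native"].area_km2
    )
    range_report = {
        "gof": gof.gof,
        "ABC": gof.per_category[0],
        "range_ratio": ratio,
        "range_percent_increase": range_comparison.percent_increase(ratio),
        "breadth_percent_increase": range_comparison.percent_increase(idx.BR),
    }

    report = RunReport(
        counts=counts,
        niche=niche_report,
        stats=stats_report,
        sdm=sdm_report,
        range_shift=range_report,
        config=_config_fingerprint(config),
    )
    if config.outdir:
        write_report(report, config.outdir, formats=("json", "csv", "markdown"))
    return report


def _extract_pa(stack: PredictorStack, df: pd.DataFrame, names: list[str]) -> pd.DataFrame:
    rows = []
    valid = stack.combined_valid()
    for lon, lat in df[["lon", "lat"]].to_numpy(dtype=float):
        idx = stack.transform.index_of(lon, lat, stack.shape)
        if idx is None or not valid[idx]:
            continue
        rows.append([stack[n].values[idx] for n in names])
    return pd.DataFrame(rows, columns=names)


def _flatten(d: dict, prefix: str = "") -> list[tuple[str, object]]:
    out = []
    for k, v in d.items():
        key = f"{prefix}.{k}" if prefix else str(k)
        if isinstance(v, dict):
            out.extend(_flatten(v, key))
        elif isinstance(v, (list, tuple)) and not all(
            isinstance(x, (int, float, str)) for x in v
        ):
            continue
        else:
            out.append((key, v))
    return out


def write_report(
    report: RunReport,
    outdir: str | Path,
    formats: tuple[str, ...] = ("json",),
    stem: str = "report",
) -> list[Path]:
    """Write the run report as json, csv and/or markdown files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    d = report.to_dict()
    for fmt in formats:
        if fmt == "json":
            p = outdir / f"{stem}.json"
            with p.open("w") as fh:
                json.dump(d, fh, indent=2, default=_json_default)
        elif fmt == "csv":
            p = outdir / f"{stem}.csv"
            rows = _flatten({k: v for k, v in d.items() if k != "config"})
            pd.DataFrame(rows, columns=["metric", "value"]).to_csv(p, index=False)
        elif fmt == "markdown":
            p = outdir / f"{stem}.md"
            with p.open("w") as fh:
                fh.write("# Niche and range dynamics report\n\n")
                for section in ("counts", "niche", "stats", "sdm", "range_shift"):
                    fh.write(f"## {section}\n\n| metric | value |\n|---|---|\n")
                    for k, v in _flatten(d[section]):
                        fh.write(f"| {k} | {v} |\n")
                    fh.write("\n")
        else:
            raise ValueError(f"unknown report format {fmt!r}")
        paths.append(p)
    return paths


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
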