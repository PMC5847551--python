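"""End-to-end orchestration: from a config (file paths or a synthetic bundle
spec) to the full result set — calibration model, per-species exposure,
trends, evenness, richness correlations and the use comparison."""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import StablePixelOptions, calibrate_stack
from .errors import InputError, ParameterError
from .exposure import (
    DEFAULT_THRESHOLD,
    evenness_table,
    exposure_table,
    period_mean,
)
from .grids import CompositeGrid, RangeMask, SpeciesRange, load_ranges, read_stack, rasterize_all
from .groups import compare_use
from .richness import build_richness, richness_brightness_correlation, richness_levels
from .synthetic import (
    DatasetBundle,
    DistortionSpec,
    NightscapeParams,
    RangeParams,
    make_dataset,
)
from .trends import classify_trends, mann_kendall, mean_lit_series, trend_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    outdir: str = "nightrange_out"
    seed: int = 0
    threshold: float = DEFAULT_THRESHOLD
    alpha: float = 0.05
    reference_year: int | None = None
    period_first: list[int] | None = None  # default: first five years of stack
    period_last: list[int] | None = None  # default: last five years
    # either synthetic generation ...
    synthetic: dict | None = None
    # ... or real inputs
    stack_paths: list[str] | None = None
    stack_years: list[int] | None = None
    ranges_path: str | None = None
    calibration: dict = field(default_factory=dict)  # StablePixelOptions overrides

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 63:
            raise ParameterError("threshold must be in (0, 63)")
        if self.synthetic is None and not self.stack_paths:
            self.synthetic = {}

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        doc = yaml.safe_load(text)
        return cls(**doc)


def default_synthetic_config(seed: int = 0) -> dict:
    """The default bundle: growing light placed away from the richness
    gradient, 1,435 species over 21 years, mild per-year distortions."""
    return {
        "nightscape": {
            "grid_rows": 200,
            "grid_cols": 400,
            "n_years": 21,
            "n_urban_seeds": 100,
            "growth_rate": 0.06,
            "base_brightness_decay": 8.0,
            "noise_sd": 0.3,
            "seed": seed,
            "start_year": 1992,
            "seed_col_frac": (0.0, 0.4),
        },
        "distortion": {"random": True, "noise_sd": 0.5, "seed": seed + 1},
        "ranges": {
            "n_species": 1435,
            "range_size_min": 1,
            "range_size_max": 10_000,
            "seed": seed + 2,
            "col_weight_power": 2.0,
        },
    }


def build_bundle(synthetic_cfg: dict, seed: int, threshold: float) -> DatasetBundle:
    cfg = default_synthetic_config(seed)
    for key in ("nightscape", "distortion", "ranges"):
        cfg[key].update(synthetic_cfg.get(key, {}))
    ns = dict(cfg["nightscape"])
    ns["seed_col_frac"] = tuple(ns["seed_col_frac"])
    np_params = NightscapeParams(**ns)
    dcfg = cfg["distortion"]
    if dcfg.get("random", True):
        dist = DistortionSpec.random(
            np_params.years, seed=dcfg.get("seed", seed + 1), noise_sd=dcfg.get("noise_sd", 0.5)
        )
    else:
        dist = DistortionSpec(
            coeffs={int(y): tuple(c) for y, c in dcfg["coeffs"].items()},
            noise_sd=dcfg.get("noise_sd", 0.0),
        )
    rp = RangeParams(**cfg["ranges"])
    return make_dataset(np_params, dist, rp, threshold=threshold)


def table1_analog(
    grids: dict[str, CompositeGrid],
    masks: Sequence[RangeMask],
    threshold: float,
) -> pd.DataFrame:
    """Species counts (and range-size spans) with lit / no lit / only lit
    pixels in their range, per labelled image."""
    rows = []
    for label, grid in grids.items():
        sizes = {"with_lit": [], "no_lit": [], "only_lit": []}
        for m in masks:
            vals = m.values(grid)
            n_lit = int((vals >= threshold).sum())
            if n_lit == 0:
                sizes["no_lit"].append(m.n_pixels)
            else:
                sizes["with_lit"].append(m.n_pixels)
                if n_lit == m.n_pixels:
                    sizes["only_lit"].append(m.n_pixels)
        for group, sz in sizes.items():
            rows.append(
                {
                    "scope": label,
                    "group": group,
                    "n_species": len(sz),
                    "range_size_min": int(min(sz)) if sz else None,
                    "range_size_max": int(max(sz)) if sz else None,
                }
            )
    return pd.DataFrame(
        rows, columns=["scope", "group", "n_species", "range_size_min", "range_size_max"]
    )


def summarize_percentages(table1: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Per scope: percentage of species with some, only, and no lit pixels."""
    out: dict[str, dict[str, float]] = {}
    for label, sub in table1.groupby("scope"):
        counts = dict(zip(sub["group"], sub["n_species"]))
        total = counts.get("with_lit", 0) + counts.get("no_lit", 0)
        if total == 0:
            raise InputError(f"no species in scope {label!r}")
        out[str(label)] = {
            "n_species": total,
            "pct_with_lit": 100.0 * counts.get("with_lit", 0) / total,
            "pct_all_lit": 100.0 * counts.get("only_lit", 0) / total,
            "pct_dark": 100.0 * counts.get("no_lit", 0) / total,
        }
    return out


@dataclass
class RunResult:
    outdir: Path
    table1: pd.DataFrame
    percentages: dict
    exposure: pd.DataFrame
    evenness: pd.DataFrame
    trends: pd.DataFrame
    trend_counts: dict
    global_trend: dict
    correlations: pd.DataFrame
    use_comparison: dict
    calibration_model: Any
    manifest: dict


def run(config: RunConfig) -> RunResult:
    """Execute the full analysis and write all outputs under config.outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    if config.synthetic is not None:
        logger.info("stage: synthetic bundle")
        bundle = build_bundle(config.synthetic, config.seed, config.threshold)
        stack = bundle.observed_stack
        masks = bundle.masks
        ranges = bundle.ranges
        grid_spec = bundle.grid
    else:
        logger.info("stage: reading inputs")
        stack = read_stack(config.stack_paths, config.stack_years)
        ranges = load_ranges(config.ranges_path)
        grid_spec = stack[0].grid
        masks = rasterize_all(ranges, grid_spec, skip_empty=True)
        bundle = None
    years = [g.year for g in stack]
    by_id = {r.species_id: r for r in ranges}

    plen = max(1, min(5, len(years) // 2))
    period_first = config.period_first or years[:plen]
    period_last = config.period_last or years[-plen:]
    if set(period_first) & set(period_last):
        raise ParameterError("periods must not overlap")
    periods = {
        f"{period_first[0]}-{period_first[-1]}": period_first,
        f"{period_last[0]}-{period_last[-1]}": period_last,
    }
    label_first, label_last = list(periods)

    # --- calibration ------------------------------------------------------
    logger.info("stage: intercalibration")
    opts = StablePixelOptions(**{"fallback_identity": True, **config.calibration})
    calibrated, model = calibrate_stack(stack, config.reference_year, opts)

    # --- exposure ---------------------------------------------------------
    logger.info("stage: exposure")
    expo = exposure_table(calibrated, masks, config.threshold, periods)
    even = evenness_table(calibrated, masks, periods)
    n_undefined = int((~even["defined"]).sum())
    if n_undefined:
        logger.info("evenness undefined (fully dark range-period) for %d rows", n_undefined)

    # --- trends -----------------------------------------------------------
    logger.info("stage: trends")
    per_species = {}
    for m in masks:
        sub = expo[(expo.species_id == m.species_id) & expo.scope.isin(map(str, years))]
        per_species[m.species_id] = (
            sub.sort_values("scope", key=lambda s: s.astype(int))["n_lit"].to_numpy()
        )
    results = [mann_kendall(v, series_id=k) for k, v in per_species.items()]
    tdf = trend_table(results)
    counts = classify_trends(results, alpha=config.alpha)
    gres = mann_kendall(mean_lit_series(per_species), series_id="mean-all-species")
    global_trend = {
        "tau": gres.tau,
        "S": gres.S,
        "p_two_sided": gres.p_two_sided,
        "n_years": gres.n,
    }

    # --- richness ---------------------------------------------------------
    logger.info("stage: richness")
    grid_last = period_mean(calibrated, period_last)
    grid_first = period_mean(calibrated, period_first)
    threatened_ids = {r.species_id for r in ranges if r.threatened}
    rich_all = build_richness(masks, grid_spec, subset="all")
    rich_thr = build_richness(
        masks, grid_spec, subset="threatened", predicate=lambda m: m.species_id in threatened_ids
    )
    from .richness import CorrelationResult

    corr_rows = []
    for subset, rg in (("all", rich_all), ("threatened", rich_thr)):
        for plabel, pgrid in ((label_first, grid_first), (label_last, grid_last)):
            try:
                c = richness_brightness_correlation(rg, pgrid)
            except InputError as exc:  # too few richness levels to correlate
                logger.warning("correlation %s/%s undefined: %s", subset, plabel, exc)
                c = CorrelationResult(
                    float("nan"), 0, float("nan"), float("nan"), float("nan"), False
                )
            corr_rows.append(
                {
                    "subset": subset,
                    "period": plabel,
                    "r": c.r,
                    "n": c.n,
                    "ci_low": c.ci_low,
                    "ci_high": c.ci_high,
                    "p_two_sided": c.p_two_sided,
                    "defined": c.defined,
                }
            )
    corr_df = pd.DataFrame(corr_rows)
    levels_all = richness_levels(rich_all, grid_last)
    levels_thr = richness_levels(rich_thr, grid_last)

    # --- use comparison ---------------------------------------------------
    logger.info("stage: use comparison")
    pf = expo[expo.scope == label_first].set_index("species_id")
    pl = expo[expo.scope == label_last].set_index("species_id")
    # lit counts averaged over both periods, divided by range size
    avg_prop = (pf["n_lit"] + pl["n_lit"]) / 2.0 / pf["n_pixels"]
    used_ids = [sid for sid in avg_prop.index if by_id[sid].used]
    not_used_ids = [sid for sid in avg_prop.index if not by_id[sid].used]
    use_cmp: dict[str, Any] = {}
    for label, series in (
        ("both-periods", avg_prop),
        (label_first, pf["prop_lit"]),
        (label_last, pl["prop_lit"]),
    ):
        res = compare_use(series.loc[used_ids], series.loc[not_used_ids])
        use_cmp[label] = {
            "F": res.F,
            "df_between": res.df_between,
            "df_within": res.df_within,
            "p_two_sided": res.p_two_sided,
            "mean_diff_transformed": res.mean_diff,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "n_used": res.n1,
            "n_not_used": res.n2,
            "mean_used_raw": res.mean1_raw,
            "mean_not_used_raw": res.mean2_raw,
        }

    # --- table 1 analog ---------------------------------------------------
    first_year_grid = calibrated[0]
    last_year_grid = calibrated[-1]
    t1 = table1_analog(
        {
            str(years[0]): first_year_grid,
            str(years[-1]): last_year_grid,
            label_first: grid_first,
            label_last: grid_last,
        },
        masks,
        config.threshold,
    )
    percentages = summarize_percentages(t1)

    # --- outputs ----------------------------------------------------------
    logger.info("stage: writing outputs")
    expo.to_csv(outdir / "exposure.csv", index=False)
    even.to_csv(outdir / "evenness.csv", index=False)
    tdf.to_csv(outdir / "trends.csv", index=False)
    corr_df.to_csv(outdir / "richness_correlations.csv", index=False)
    levels_all.to_csv(outdir / "richness_levels_all.csv", index=False)
    levels_thr.to_csv(outdir / "richness_levels_threatened.csv", index=False)
    t1.to_csv(outdir / "table1_analog.csv", index=False)
    model.to_json(outdir / "calibration_model.json")
    (outdir / "use_comparison.json").write_text(json.dumps(use_cmp, indent=2))
    (outdir / "trend_summary.json").write_text(
        json.dumps({"global": global_trend, "per_species_counts": counts}, indent=2)
    )
    manifest = {
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": config.seed,
        "threshold": config.threshold,
        "alpha": config.alpha,
        "reference_year": model.reference_year,
        "periods": {k: list(v) for k, v in periods.items()},
        "years": years,
        "n_species": len(masks),
        "synthetic": config.synthetic,
        "percentages": percentages,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return RunResult(
        outdir=outdir,
        table1=t1,
        percentages=percentages,
        exposure=expo,
        evenness=even,
        trends=tdf,
        trend_counts=counts,
        global_trend=global_trend,
        correlations=corr_df,
        use_comparison=use_cmp,
        calibration_model=model,
        manifest=manifest,
    )
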