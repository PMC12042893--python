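"""End-to-end pipeline: simulate -> classify -> coexpose -> metrics ->
trend -> disparity.

Every stage reads its inputs from, and writes its artifacts to, a run
directory, so each is runnable standalone on the previous stage's
on-disk outputs.  A run manifest records the configuration, its hash
and per-artifact row counts; outputs carry no timestamps, so a fixed
seed reproduces a byte-identical run directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexposure as cx
from . import disparity as dp
from . import geo_io as gio
from . import hazards as hz
from . import metrics as mx
from . import trends as tr
from .containers import TractDayMatrix, ValidationError
from .synthetic import SimConfig, simulate_bundle

log = logging.getLogger("cohaz")

HAZARDS = ["eh", "wfbz", "wfs"]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    CLI flags override values loaded from a YAML config file.
    """

    outdir: str = "cohaz_run"
    seed: int = 0
    simulate: dict = field(default_factory=dict)   # SimConfig overrides
    wfs_threshold: float = 0.0
    window: str = "same_day"                       # same_day | two_day
    credit: str = "both"                           # two-day credit rule
    percentile: float = 95.0
    baseline_years: list[int] | None = None
    warm_season: tuple[int, int] = (5, 9)
    manual_edges: tuple[float, ...] = dp.DEFAULT_MANUAL_EDGES
    svi_cut: float = 0.9
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.window not in ("same_day", "two_day"):
            raise ValidationError(f"window must be same_day|two_day, "
                                  f"got {self.window!r}")
        if self.credit not in ("both", "later"):
            raise ValidationError(f"credit must be both|later, got {self.credit!r}")
        if self.wfs_threshold < 0:
            raise ValidationError("wfs_threshold must be >= 0")
        # building the SimConfig validates the simulation block
        self.sim_config()

    def sim_config(self) -> SimConfig:
        sim = dict(self.simulate)
        sim.setdefault("seed", self.seed)
        if "years" in sim:
            sim["years"] = tuple(sim["years"])
        return SimConfig(**sim)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["warm_season"] = list(self.warm_season)
        d["manual_edges"] = list(self.manual_edges)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _outdir(config: RunConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


# ---------------------------------------------------------------------------
# stages

def stage_simulate(config: RunConfig) -> dict:
    out = _outdir(config)
    bundle = simulate_bundle(config.sim_config())
    gio.write_tracts(bundle.tracts, out / "tracts.geojson")
    gio.write_field(bundle.temperature, out / "temperature.nc")
    gio.write_field(bundle.smoke, out / "smoke.nc")
    gio.write_fire_points(bundle.fire_points, out / "fire_points.csv")
    truth = bundle.truth.copy()
    truth["date"] = truth["date"].dt.strftime("%Y-%m-%d")
    gio.write_table(truth, out / "truth.csv")
    log.info("simulate: %d tracts, %d days, %d fire points, %d truth rows",
             len(bundle.tracts), len(bundle.temperature.dates),
             len(bundle.fire_points), len(truth))
    return {"n_tracts": len(bundle.tracts),
            "n_days": len(bundle.temperature.dates),
            "n_fire_points": len(bundle.fire_points),
            "n_truth_rows": len(truth)}


def stage_classify(config: RunConfig) -> dict:
    out = _outdir(config)
    for name in ("tracts.geojson", "temperature.nc", "smoke.nc",
                 "fire_points.csv"):
        if not (out / name).exists():
            raise FileNotFoundError(f"classify: missing input {out / name}")
    tracts = gio.read_tracts(out / "tracts.geojson")
    tmax_field = gio.read_field(out / "temperature.nc")
    smoke_field = gio.read_field(out / "smoke.nc")
    points = gio.read_fire_points(out / "fire_points.csv")

    tmax = gio.zonal_mean(tmax_field, tracts)
    smoke = gio.zonal_mean(smoke_field, tracts)
    counts, unassigned = gio.points_to_counts(points, tracts, tmax.dates)
    n_unassigned = int(unassigned.sum())
    if n_unassigned:
        log.warning("classify: %d fire points outside all tracts", n_unassigned)

    flags, thresholds = hz.classify_all(
        tmax, counts, smoke,
        baseline_years=config.baseline_years,
        warm_season=tuple(config.warm_season),
        percentile=config.percentile,
        wfs_threshold_ugm3=config.wfs_threshold,
    )
    gio.write_matrix(tmax, out / "tmax_tract.csv")
    gio.write_matrix(smoke, out / "smoke_tract.csv")
    gio.write_matrix(counts, out / "fire_counts.csv")
    thr = thresholds.relative_c.reset_index()
    thr.columns = ["tract_id", "relative_c"]
    thr["absolute_c"] = thresholds.absolute_c
    gio.write_table(thr, out / "thresholds.csv")
    for name, m in flags.as_dict().items():
        gio.write_matrix(m, out / f"flags_{name}.csv")
    log.info("classify: EH %d, WFBZ %d, WFS %d flagged tract-days; "
             "%.1f%% of tracts below the absolute threshold",
             flags.eh.values.sum(), flags.wfbz.values.sum(),
             flags.wfs.values.sum(), 100 * thresholds.share_below_absolute)
    return {"n_unassigned_fire_points": n_unassigned,
            "share_relative_below_absolute": thresholds.share_below_absolute,
            "tract_days": {n: int(m.values.sum())
                           for n, m in flags.as_dict().items()}}


def _read_flags(out: Path) -> hz.HazardFlags:
    mats = {}
    for name in HAZARDS:
        path = out / f"flags_{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing flag matrix {path}")
        mats[name] = gio.read_matrix(path, boolean=True, name=name)
    return hz.HazardFlags(eh=mats["eh"], wfbz=mats["wfbz"], wfs=mats["wfs"])


def stage_coexpose(config: RunConfig) -> dict:
    out = _outdir(config)
    flags = _read_flags(out)
    coex = cx.coexpose(flags, window=config.window, credit=config.credit)
    for name, m in coex.as_dict().items():
        gio.write_matrix(m, out / f"coex_{name}.csv")
    log.info("coexpose (%s): %s", config.window,
             {n: int(m.values.sum()) for n, m in coex.as_dict().items()})
    return {"window": config.window,
            "tract_days": {n: int(m.values.sum())
                           for n, m in coex.as_dict().items()}}


def _all_matrices(out: Path) -> dict[str, TractDayMatrix]:
    flags = _read_flags(out)
    mats = dict(flags.as_dict())
    any_flag = flags.eh.values | flags.wfbz.values | flags.wfs.values
    mats["any"] = TractDayMatrix(any_flag, flags.eh.tract_ids,
                                 flags.eh.dates, name="any")
    for name in cx.COMBINATIONS:
        path = out / f"coex_{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing coexposure matrix {path}")
        mats[name] = gio.read_matrix(path, boolean=True, name=name)
    return mats


def stage_metrics(config: RunConfig) -> dict:
    out = _outdir(config)
    tracts = gio.read_tracts(out / "tracts.geojson")
    mats = _all_matrices(out)
    n_years = len(set(mats["eh"].dates.year))
    pops = tracts.population
    states = tracts.attribute("state")

    summary = mx.summarize_combinations(mats, pops, states, n_years)
    gio.write_table(summary, out / "metrics.csv")

    monthly = pd.DataFrame({
        name: mx.monthly_distribution(m) for name, m in mats.items()
    })
    monthly.insert(0, "month", range(1, 13))
    gio.write_table(monthly, out / "monthly.csv")

    rows = []
    for name, m in mats.items():
        region = mx.annual_series(m)
        person = mx.annual_person_series(m, pops)
        for year in region.index:
            rows.append(("all", name, "tract_days", int(year), region[year]))
            rows.append(("all", name, "person_days", int(year), person[year]))
        for state in states.unique():
            sub = TractDayMatrix(
                m.values[(states == state).to_numpy()],
                m.tract_ids[(states == state).to_numpy()],
                m.dates, name=m.name,
            )
            s_region = mx.annual_series(sub)
            s_person = mx.annual_person_series(sub, pops)
            for year in s_region.index:
                rows.append((state, name, "tract_days", int(year),
                             s_region[year]))
                rows.append((state, name, "person_days", int(year),
                             s_person[year]))
    annual = pd.DataFrame(
        rows, columns=["scope", "combination", "unit", "year", "value"]
    )
    gio.write_table(annual, out / "annual_series.csv")
    log.info("metrics: %d summary rows, %d annual rows", len(summary), len(annual))
    return {"n_metric_rows": len(summary), "n_annual_rows": len(annual)}


def stage_trend(config: RunConfig) -> dict:
    out = _outdir(config)
    path = out / "annual_series.csv"
    if not path.exists():
        raise FileNotFoundError(f"trend: missing input {path}")
    annual = pd.read_csv(path)
    annual = annual[annual["unit"] == "tract_days"]
    table = tr.trend_table(annual, skip_short=True)
    gio.write_table(table, out / "trends.csv")
    log.info("trend: %d series tested", len(table))
    return {"n_trend_rows": len(table)}


def stage_disparity(config: RunConfig) -> dict:
    out = _outdir(config)
    tracts = gio.read_tracts(out / "tracts.geojson")
    mats = _all_matrices(out)
    e: dict[str, pd.Series] = {
        name: mx.exposure_days_per_tract(m)[0] for name, m in mats.items()
    }

    comp_parts = []
    for name in ("eh", "wfs", "eh_wfs"):
        try:
            c = dp.quintile_composition(e[name], tracts)
        except dp.DegenerateBinsError:
            c = dp.manual_category_composition(
                e[name], tracts, edges=tuple(config.manual_edges))
        c.insert(0, "combination", name)
        comp_parts.append(c)
    for name in ("wfbz", "eh_wfbz", "wfbz_wfs", "eh_wfbz_wfs"):
        c = dp.manual_category_composition(
            e[name], tracts, edges=tuple(config.manual_edges))
        c.insert(0, "combination", name)
        comp_parts.append(c)
    gio.write_table(pd.concat(comp_parts, ignore_index=True),
                    out / "composition.csv")

    overlay_parts, missing_svi = [], 0
    for name, ei in e.items():
        flag, by_state, n_miss = dp.svi_overlay(ei, tracts, config.svi_cut)
        missing_svi = max(missing_svi, n_miss)
        by_state.insert(0, "combination", name)
        overlay_parts.append(by_state)
    gio.write_table(pd.concat(overlay_parts, ignore_index=True),
                    out / "svi_overlay.csv")

    restrict = e["wfbz"] >= 1
    comp_rows = []
    for name in cx.COMBINATIONS:
        try:
            c = dp.compare_groups(e[name], tracts, "tribal_overlap",
                                  restrict=restrict)
        except ValidationError as exc:
            log.warning("disparity: tribal comparison skipped for %s (%s)",
                        name, exc)
            continue
        c.insert(0, "combination", name)
        comp_rows.append(c)
    if comp_rows:
        gio.write_table(pd.concat(comp_rows, ignore_index=True),
                        out / "tribal_comparison.csv")

    top_parts = []
    for name in cx.COMBINATIONS:
        t = dp.top_tracts(e[name], tracts, n=10)
        t.insert(0, "combination", name)
        top_parts.append(t)
    gio.write_table(pd.concat(top_parts, ignore_index=True),
                    out / "top_tracts.csv")
    log.info("disparity: composition/overlay/comparison/top tables written")
    return {"n_missing_svi": missing_svi}


STAGES = [
    ("simulate", stage_simulate),
    ("classify", stage_classify),
    ("coexpose", stage_coexpose),
    ("metrics", stage_metrics),
    ("trend", stage_trend),
    ("disparity", stage_disparity),
]


def run_all(config: RunConfig) -> Path:
    """Run every stage in order; write the run manifest; return outdir."""
    out = _outdir(config)
    (out / "config.json").write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True)
    )
    manifest: dict = {"config_hash": config.config_hash(), "stages": {}}
    for name, fn in STAGES:
        try:
            manifest["stages"][name] = fn(config)
        except Exception as exc:
            manifest["stages"][name] = {"error": str(exc)}
            (out / "manifest.json").write_text(
                json.dumps(manifest, indent=2, sort_keys=True))
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return out
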