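"""End-to-end pipeline: simulate -> fit -> topography -> between-map stats.

Everything is deterministic given the config and its seeds; each stage
writes a TSV the next stage can re-load, plus a structured JSON log of
versions, seeds and parameters.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .fitting import TimingPRF, cross_validate
from .forward import HRFParams
from .map_stats import anova_measures, summarize_maps
from .models import ModelSpec
from .stimuli import make_run, write_events_tsv
from .synthetic import calibrate_noise_sd, simulate_map, simulate_sites, timecourse_matrix
from .topography import bin_and_fit, distance_along_map, progression_correlations


@dataclass
class PipelineConfig:
    """Settings for one demo-scale pipeline run."""

    seed: int = 0
    tr: float = 2.1
    n_maps: int = 2
    n_sites_per_map: int = 50
    n_runs: int = 4
    target_ve: float = 0.3
    jitter_sd: float = 0.05
    progression: str = "log"
    extent_rule: str = "linear"
    fit_family: str = "tuned_2d_anisotropic"
    refine: bool = True
    n_boot: int = 1000
    map_labels: tuple[str, ...] = ("TLO", "TPO")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        d = io.read_json(path)
        d.pop("version", None)
        if "map_labels" in d:
            d["map_labels"] = tuple(d["map_labels"])
        return cls(**d)


def run_pipeline(config: PipelineConfig, outdir) -> dict[str, Path]:
    """Run the full pipeline into ``outdir``; returns paths of artifacts."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    schedule = make_run(tr=config.tr)
    paths["events"] = out / "events.tsv"
    write_events_tsv(schedule, paths["events"])

    noise_sd = calibrate_noise_sd(config.target_ve, config.n_runs)
    spec = ModelSpec(config.fit_family)
    est = TimingPRF(spec=spec, schedule=schedule, refine=config.refine)
    cv_pair = tuple(
        TimingPRF(spec=spec, schedule=schedule, refine=False) for _ in range(2)
    )
    for e in cv_pair:
        e._design_cache = est._design()

    site_tables, geom_tables, fit_tables = [], [], []
    for i in range(config.n_maps):
        label = config.map_labels[i % len(config.map_labels)]
        smap = simulate_map(
            n_sites=config.n_sites_per_map,
            seed=config.seed + i,
            jitter_sd=config.jitter_sd,
            progression=config.progression,
            extent_rule=config.extent_rule,
            noise_sd=noise_sd,
            n_runs=config.n_runs,
            map_label=label,
        )
        data = simulate_sites(smap.truth, schedule, design=est._design())
        for split, tab in data.items():
            t = tab.copy()
            t.insert(1, "map", label)
            t.insert(1, "split", split)
            site_tables.append(t)
        geom_tables.append(smap.geometry)

        est.fit(timecourse_matrix(data["full"]))
        fits = est.results_table(site_ids=smap.geometry["site_id"])
        fits.insert(1, "map", label)
        cv_pair[0]._grid_cache = est._grid_cache
        cv = cross_validate(
            spec,
            timecourse_matrix(data["odd"]),
            timecourse_matrix(data["even"]),
            schedule,
            _estimators=cv_pair,
        )
        fit_tables.append(pd.concat([fits, cv], axis=1))

    paths["data"] = out / "sites.tsv"
    io.write_tsv(pd.concat(site_tables, ignore_index=True), paths["data"])
    geometry = pd.concat(geom_tables, ignore_index=True)
    paths["geometry"] = out / "geometry.tsv"
    io.write_tsv(geometry, paths["geometry"])
    fits_all = pd.concat(fit_tables, ignore_index=True)
    paths["fits"] = out / "fits.tsv"
    io.write_tsv(fits_all, paths["fits"])

    # topography: coordinates, binned progressions, correlations
    sites = fits_all.merge(geometry, on=["site_id", "map"])
    sites["coordinate_mm"] = distance_along_map(
        sites["d_low_mm"], sites["d_high_mm"], sites["d_low_mm"].max()
    )
    topo_rows = []
    for label, g in sites.groupby("map"):
        g = g.loc[~g["excluded"].astype(bool)]
        _, fits_prog = bin_and_fit(
            g, n_boot=config.n_boot, seed=config.seed, upsampling=float(g["upsampling"].iloc[0])
        )
        for col, pf in fits_prog.items():
            topo_rows.append(
                {
                    "map": label,
                    "value": col,
                    "slope": pf.slope,
                    "intercept": pf.intercept,
                    "slope_ci_low": pf.slope_ci[0],
                    "slope_ci_high": pf.slope_ci[1],
                }
            )
    corr = progression_correlations(sites.loc[~sites["excluded"].astype(bool)])
    paths["topography"] = out / "topography.tsv"
    io.write_tsv(pd.DataFrame(topo_rows), paths["topography"])
    paths["correlations"] = out / "correlations.tsv"
    io.write_tsv(corr, paths["correlations"])

    summaries = summarize_maps(sites)
    paths["summaries"] = out / "map_summaries.tsv"
    io.write_tsv(summaries, paths["summaries"])
    stats_rows = []
    if summaries["map"].nunique() >= 2 and summaries["subject"].nunique() >= 2:
        for measure in ("mean_exp_freq", "mean_pref_duration"):
            res = anova_measures(summaries, measure)
            if not res.degenerate:
                tab = res.anova_table.reset_index(names="term")
                tab.insert(0, "measure", measure)
                stats_rows.append(tab)
    if stats_rows:
        paths["stats"] = out / "stats.tsv"
        io.write_tsv(pd.concat(stats_rows, ignore_index=True), paths["stats"])

    log = {
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "noise_sd": noise_sd,
        "artifacts": {k: str(v) for k, v in paths.items()},
    }
    paths["log"] = out / "pipeline_log.json"
    with open(paths["log"], "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return paths
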