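"""End-to-end orchestration from a single configuration.

:func:`run_pipeline` executes ingest → sector matrix → sector chronologies
and statistics → ring-width standardization → monthly/seasonal/spatial
climate correlations → optimal-season table → changepoint test, writing
tidy CSV artifacts plus a JSON run manifest (config echo, seed, per-stage
row counts). All outputs are deterministic for a fixed config and seed; the
manifest carries no timestamps so re-runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .chronology import (
    chronology_frame,
    chronology_stats,
    detrend_ringwidths,
    rw_chronology,
    sector_chronology,
    split_group_test,
)
from .climate import (
    SeasonWindow,
    best_season,
    monthly_correlations,
    seasonal_scan,
    spatial_correlation,
)
from .io_formats import (
    ValidationError,
    read_cell_table,
    read_grid_table,
    read_monthly_climate,
    read_rwl,
    write_chronology,
)
from .tracheidogram import build_sector_matrix

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and context."""


@dataclass
class PipelineConfig:
    """Everything a full analysis run needs, with study defaults."""

    cells: str | None = None
    rwl: str | None = None
    climate: dict[str, str] = field(default_factory=dict)  # variable -> path
    grid: str | None = None
    grid_variable: str | None = None
    out_dir: str = "qwa_out"
    period: tuple[int, int] = (1963, 2019)
    n_sectors: int = 10
    min_files: int = 10
    mad_k: float = 3.0
    chron_method: str = "arithmetic"
    rw_method: str = "biweight"
    filter: str = "none"  # "none" | "first_diff"
    alpha: float = 0.05
    season_lengths: tuple[int, int] = (1, 19)
    spatial_window: tuple[int, int] = (22, 4)  # (end slot, length): Jul–Oct
    split_year: int = 1992
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("period", "season_lengths", "spatial_window"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["period"] = list(self.period)
        d["season_lengths"] = list(self.season_lengths)
        d["spatial_window"] = list(self.spatial_window)
        return d


def _header(config: PipelineConfig) -> str:
    return (
        f"# period={config.period[0]}:{config.period[1]} "
        f"filter={config.filter} alpha={config.alpha}\n"
    )


def _write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, index=index, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.echo(),
        "qwa_version": __version__,
        "stages": {},
        "artifacts": {},
    }

    def _stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return deco

    # ---- ingest -----------------------------------------------------------
    @_stage("ingest")
    def ingested():
        for label, path in [("cells", config.cells), ("rwl", config.rwl)] + [
            (f"climate:{v}", p) for v, p in config.climate.items()
        ]:
            if path is not None and not Path(path).exists():
                raise ValidationError(f"input file for {label} not found: {path}")
        cells = read_cell_table(config.cells) if config.cells else None
        rws = read_rwl(config.rwl) if config.rwl else None
        climates = {
            var: read_monthly_climate(path, var)
            for var, path in config.climate.items()
        }
        grid = (
            read_grid_table(config.grid, variable=config.grid_variable)
            if config.grid
            else None
        )
        return cells, rws, climates, grid

    cells, rws, climates, grid = ingested
    manifest["stages"]["ingest"] = {
        "n_cells": 0 if cells is None else int(len(cells)),
        "n_cores": 0 if rws is None else len(rws.series),
        "climate_variables": sorted(climates),
        "grid": bool(grid),
    }

    chron_tables = {}

    # ---- anatomy ----------------------------------------------------------
    if cells is not None:
        @_stage("sector_matrix")
        def matrix():
            return build_sector_matrix(
                cells, n_sectors=config.n_sectors,
                min_files=config.min_files, mad_k=config.mad_k,
            )

        report = matrix.attrs["outlier_report"]
        _write_csv(report, out / "outlier_report.csv", config)
        manifest["stages"]["sector_matrix"] = {
            "n_rings": int((matrix["depth"].values > 0).sum()),
            "n_outliers_removed": int(len(report)),
        }

        for param in ("ld", "cwt"):
            @_stage(f"chronology_{param}")
            def chron_stage(param=param):
                chrons = sector_chronology(
                    matrix, param=param, method=config.chron_method,
                    period=config.period,
                )
                stats = chronology_stats(matrix, param=param, period=config.period)
                return chrons, stats

            chrons, stats_tbl = chron_stage
            write_chronology(chrons, out / f"chron_{param}.csv")
            _write_csv(stats_tbl, out / f"stats_{param}.csv", config, index=True)
            chron_tables[param] = chronology_frame(chrons)
            manifest["stages"][f"chronology_{param}"] = {
                "n_sectors": len(chrons),
                "years": [int(chron_tables[param].index.min()),
                          int(chron_tables[param].index.max())],
            }

        # changepoint test on every LD sector chronology
        @_stage("split_group_test")
        def split_rows():
            rows = []
            for lab in chron_tables["ld"].columns:
                res = split_group_test(chron_tables["ld"][lab], config.split_year)
                rows.append(
                    {
                        "sector": lab,
                        "F": res.f_stat,
                        "p": res.p_value,
                        "mean_before": res.mean_before,
                        "mean_after": res.mean_after,
                        "n_before": res.n_before,
                        "n_after": res.n_after,
                    }
                )
            return pd.DataFrame(rows)

        _write_csv(split_rows, out / "split_test_ld.csv", config)
        manifest["stages"]["split_group_test"] = {"n_sectors": int(len(split_rows))}

    # ---- ring widths ------------------------------------------------------
    if rws is not None:
        @_stage("rw_standardization")
        def rw_chron():
            indices = detrend_ringwidths(rws)
            return rw_chronology(indices, method=config.rw_method)

        write_chronology(rw_chron, out / "chron_rw.csv")
        chron_tables["rw"] = pd.DataFrame({"RW": rw_chron.as_series()})
        manifest["stages"]["rw_standardization"] = {
            "n_years": int(len(rw_chron.years))
        }

    # ---- climate correlations --------------------------------------------
    if climates and chron_tables:
        prefixes = {"ld": "LD_", "cwt": "CWT_", "rw": ""}
        targets = pd.concat(
            [chron_tables[k].add_prefix(prefixes[k]) for k in chron_tables], axis=1
        )
        targets = targets.loc[
            (targets.index >= config.period[0]) & (targets.index <= config.period[1])
        ]

        @_stage("monthly_correlations")
        def monthly():
            return monthly_correlations(
                targets, climates, alpha=config.alpha, filter=config.filter
            )

        _write_csv(monthly, out / "monthly_correlations.csv", config)
        manifest["stages"]["monthly_correlations"] = {"n_cells": int(len(monthly))}

        @_stage("seasonal_scan")
        def seasonal():
            lengths = range(config.season_lengths[0], config.season_lengths[1] + 1)
            frames = []
            best_rows = []
            for var, ct in climates.items():
                for cname in targets.columns:
                    scan = seasonal_scan(
                        targets[cname], ct, lengths=lengths,
                        alpha=config.alpha, filter=config.filter,
                    )
                    scan.insert(0, "chronology", cname)
                    frames.append(scan)
                    usable = scan.dropna(subset=["r"])
                    if not usable.empty:
                        b = best_season(scan)
                        best_rows.append(
                            {
                                "chronology": cname,
                                "variable": var,
                                "season": b["label"],
                                "length": int(b["length"]),
                                "r": b["r"],
                                "p": b["p"],
                                "n": int(b["n"]),
                            }
                        )
            return pd.concat(frames, ignore_index=True), pd.DataFrame(best_rows)

        scan_df, best_df = seasonal
        _write_csv(scan_df, out / "seasonal_scan.csv", config)
        _write_csv(best_df, out / "best_seasons.csv", config)
        manifest["stages"]["seasonal_scan"] = {
            "n_windows": int(len(scan_df)),
            "n_best": int(len(best_df)),
        }

    # ---- spatial ----------------------------------------------------------
    if grid is not None and "ld" in chron_tables:
        @_stage("spatial_correlation")
        def spatial():
            lab = chron_tables["ld"].columns[-1]  # last sector (ring end)
            window = SeasonWindow(
                end_slot=config.spatial_window[0],
                length=config.spatial_window[1],
                aggregate="sum" if "prec" in (grid.variable or "") else "mean",
            )
            ds = spatial_correlation(
                chron_tables["ld"][lab].dropna(), grid, window, alpha=config.alpha
            )
            df = ds.to_dataframe().reset_index()
            df.insert(0, "chronology", lab)
            return df

        _write_csv(spatial, out / "spatial_correlation.csv", config)
        manifest["stages"]["spatial_correlation"] = {"n_cells": int(len(spatial))}

    manifest["artifacts"] = sorted(p.name for p in out.iterdir() if p.is_file())
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
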