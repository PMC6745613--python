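"""Run configuration, validation, logging and the pipeline entry point.

A run is described by a flat JSON config (or equivalent CLI flags; flags
override config keys).  ``run(config)`` dispatches to one of the pipelines —
simulate, fit, predict, study, postprocess — and writes a manifest next to
the outputs recording the full config echo, the seed, package versions and
wall time, so every artifact is reconstructible from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("gridvax")

__all__ = ["RunConfig", "run", "load_config", "setup_logging"]

COMMANDS = ("simulate", "fit", "predict", "study", "postprocess")


def setup_logging(level=logging.INFO):
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)


@dataclass
class RunConfig:
    """Declarative description of one pipeline run.

    Prior-related keys mirror :class:`gridvax.model.PriorSpec`; mesh keys
    mirror the inference controls.  Unknown keys are rejected at load time
    with every offending key listed at once.
    """

    command: str = "study"
    seed: int = 0
    engine: str = "laplace"
    out: str = "gridvax_out"
    # simulation / study
    r: float = 0.5
    n_side: int = 5
    grid_n: int = 60
    replicates: int = 25
    ranges: list = None  # study design override, e.g. [0.3, 0.7]
    sides: list = None  # e.g. [3, 10]
    # file inputs (fit / predict / postprocess)
    sim_dir: str = None  # directory written by `simulate`
    areal: str = None  # CSV area_id,Y,N
    boundaries: str = None  # GeoJSON FeatureCollection
    covariates: list = None  # ASCII-grid or delimited-matrix paths
    log_covariates: bool = False
    population: str = None  # ASCII-grid aligned to the prediction grid
    predictions: str = None  # predictions CSV (postprocess input)
    threshold: float = 0.80
    # prior overrides
    beta_var: float = 1e5
    car_prec_shape: float = 1.0
    car_prec_rate: float = 0.01
    rho_logit_mean: float = 0.0
    rho_logit_var: float = 0.45
    # mesh / optimizer controls
    max_edge: float = None
    offset: float = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        errors = [f"unknown config key: {k!r}" for k in d if k not in known]
        cfg = cls(**{k: v for k, v in d.items() if k in known})
        if cfg.command not in COMMANDS:
            errors.append(f"unknown command: {cfg.command!r} (choose from {COMMANDS})")
        if cfg.engine not in ("laplace", "mcmc"):
            errors.append(f"unknown engine: {cfg.engine!r}")
        if cfg.replicates < 1:
            errors.append("replicates must be >= 1")
        if errors:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
        return cfg

    def priors(self, m: float):
        from .model import PriorSpec

        return PriorSpec(
            beta_var=self.beta_var,
            car_prec_gamma=(self.car_prec_shape, self.car_prec_rate),
            rho_logit_normal=(self.rho_logit_mean, self.rho_logit_var),
        ).with_median_distance(m)

    def controls(self) -> dict:
        ctl = {}
        if self.max_edge is not None:
            ctl["max_edge"] = self.max_edge
        if self.offset is not None:
            ctl["offset"] = self.offset
        return ctl or None


def load_config(path=None, overrides: dict = None) -> RunConfig:
    """Load a JSON config file and apply CLI overrides (flags win)."""
    d = {}
    if path is not None:
        with open(path) as fh:
            d = json.load(fh)
    if overrides:
        d.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig.from_dict(d)


def _write_manifest(outdir: Path, cfg: RunConfig, t0: float, artifacts: list):
    import scipy

    from . import __version__

    manifest = {
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "versions": {
            "gridvax": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "python": sys.version.split()[0],
        },
        "wall_time_s": round(time.time() - t0, 3),
        "artifacts": artifacts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run(cfg: RunConfig) -> int:
    """Execute the configured pipeline; returns a shell exit status."""
    setup_logging()
    t0 = time.time()
    outdir = Path(cfg.out)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("command=%s seed=%d engine=%s out=%s", cfg.command, cfg.seed, cfg.engine, cfg.out)
    artifacts = getattr(_PIPELINES[cfg.command], "__call__")(cfg, outdir)
    _write_manifest(outdir, cfg, t0, artifacts)
    logger.info("done in %.1fs", time.time() - t0)
    return 0


# ---------------------------------------------------------------------------
# Pipelines
# ---------------------------------------------------------------------------


def _pipeline_simulate(cfg: RunConfig, outdir: Path) -> list:
    from .simulation import SimSetting, simulate_dataset

    setting = SimSetting(r=cfg.r, n_side=cfg.n_side, grid_n=cfg.grid_n, seed=cfg.seed)
    counts, cov, p_grid, p_area = simulate_dataset(setting, 0)
    pd.DataFrame(
        {"area_id": range(len(counts.Y)), "Y": counts.Y.astype(int), "N": counts.N.astype(int)}
    ).to_csv(outdir / "areal.csv", index=False)
    np.savetxt(outdir / "covariates_grid.txt", cov.X_grid, fmt="%.10g")
    np.savetxt(outdir / "covariates_area.txt", cov.X_area, fmt="%.10g")
    np.savetxt(outdir / "p_true_grid.txt", p_grid, fmt="%.10g")
    np.savetxt(outdir / "p_true_area.txt", p_area, fmt="%.10g")
    return [
        "areal.csv",
        "covariates_grid.txt",
        "covariates_area.txt",
        "p_true_grid.txt",
        "p_true_area.txt",
    ]


def _load_problem(cfg: RunConfig):
    """Assemble (counts, cov, partition, grid) from files or a sim directory."""
    from .geometry import (
        CovariateStack,
        assign_membership,
        block_average,
        build_grid,
        build_unit_square_partition,
        raster_to_grid,
        read_areal_csv,
        read_ascii_grid,
        read_boundaries_geojson,
        read_delimited_matrix,
    )

    if cfg.sim_dir is not None:
        simdir = Path(cfg.sim_dir)
        partition = build_unit_square_partition(cfg.n_side)
        grid = build_grid(cfg.grid_n, cfg.grid_n, (0, 0, 1, 1))
        member = assign_membership(grid, partition)
        counts = read_areal_csv(simdir / "areal.csv")
        X_grid = read_delimited_matrix(simdir / "covariates_grid.txt")
        area_file = simdir / "covariates_area.txt"
        if area_file.exists():
            X_area = read_delimited_matrix(area_file)
        else:
            X_area = block_average(X_grid, member, partition.n_areas)
        cov = CovariateStack(X_grid, X_area, [f"x{j}" for j in range(X_grid.shape[1])])
        return counts, cov, partition, grid
    if cfg.areal is None or cfg.boundaries is None:
        raise ValueError("fit/predict need either sim_dir or areal + boundaries inputs")
    partition = read_boundaries_geojson(cfg.boundaries)
    xs = np.concatenate([np.asarray(p.exterior.coords)[:, 0] for p in partition.polygons])
    ys = np.concatenate([np.asarray(p.exterior.coords)[:, 1] for p in partition.polygons])
    grid = build_grid(cfg.grid_n, cfg.grid_n, (xs.min(), ys.min(), xs.max(), ys.max()))
    member = assign_membership(grid, partition)
    counts = read_areal_csv(cfg.areal, order=partition.area_ids)
    layers = [np.ones(grid.n_points)]
    names = ["intercept"]
    for path in cfg.covariates or []:
        path = Path(path)
        if path.suffix == ".asc":
            arr, header = read_ascii_grid(path)
            vals = raster_to_grid(arr, header, grid)
        else:
            vals = read_delimited_matrix(path).ravel()
        if cfg.log_covariates:
            vals = np.log(np.clip(vals, 1e-6, None))
        layers.append(vals)
        names.append(path.stem)
    X_grid = np.column_stack(layers)
    valid = np.all(np.isfinite(X_grid), axis=1) & (member >= 0)
    X_area = block_average(
        np.where(valid[:, None], X_grid, 0.0),
        np.where(valid, member, -1),
        partition.n_areas,
    )
    cov = CovariateStack(X_grid, X_area, names, [cfg.log_covariates] * len(names))
    return counts, cov, partition, grid


def _fit_once(cfg: RunConfig):
    from .geometry import median_pairwise_distance
    from .inference import fit as fit_model

    counts, cov, partition, grid = _load_problem(cfg)
    m = median_pairwise_distance(grid, seed=cfg.seed)
    fitres = fit_model(
        counts, cov, partition, grid,
        priors=cfg.priors(m), engine=cfg.engine, seed=cfg.seed, controls=cfg.controls(),
    )
    return fitres, counts, cov, partition, grid


def _pipeline_fit(cfg: RunConfig, outdir: Path) -> list:
    fitres, *_ = _fit_once(cfg)
    fitres.summary_csv(outdir / "summary.csv")
    with open(outdir / "diagnostics.json", "w") as fh:
        json.dump(fitres.diagnostics, fh, indent=2, default=str)
    return ["summary.csv", "diagnostics.json"]


def _pipeline_predict(cfg: RunConfig, outdir: Path) -> list:
    from .geometry import write_ascii_grid
    from .inference import predict

    fitres, counts, cov, partition, grid = _fit_once(cfg)
    pred = predict(fitres, cov, grid, grid.membership)
    fitres.summary_csv(outdir / "summary.csv")
    pred.to_frame(grid.points).to_csv(outdir / "predictions.csv", index=False)
    artifacts = ["summary.csv", "predictions.csv"]
    n = int(round(np.sqrt(grid.n_points)))
    if n * n == grid.n_points:  # square grids also export raster bands
        for band in ("mean", "sd", "lower95", "upper95"):
            arr = getattr(pred, band).reshape(n, n)[::-1]  # north row first
            write_ascii_grid(
                outdir / f"{band}.asc", arr,
                xllcorner=grid.points[:, 0].min() - grid.resolution / 2,
                yllcorner=grid.points[:, 1].min() - grid.resolution / 2,
                cellsize=grid.resolution,
            )
            artifacts.append(f"{band}.asc")
    pd.DataFrame(
        {
            "area_id": partition.area_ids,
            "estimate": pred.area_estimates,
            "lower95": pred.area_lower95,
            "upper95": pred.area_upper95,
            "observed": counts.observed,
        }
    ).to_csv(outdir / "area_estimates.csv", index=False)
    artifacts.append("area_estimates.csv")
    return artifacts


def _pipeline_study(cfg: RunConfig, outdir: Path) -> list:
    from .simulation import DEFAULT_RANGES, DEFAULT_SIDES, SimSetting, run_study

    ranges = cfg.ranges or list(DEFAULT_RANGES)
    sides = cfg.sides or list(DEFAULT_SIDES)
    settings = [
        SimSetting(r=r, n_side=ns, grid_n=cfg.grid_n, replicates=cfg.replicates, seed=cfg.seed)
        for r in ranges
        for ns in sides
    ]
    table = run_study(settings, engine=cfg.engine, seed=cfg.seed, controls=cfg.controls())
    table.to_csv(outdir / "study_metrics.csv")
    return ["study_metrics.csv"]


def _pipeline_postprocess(cfg: RunConfig, outdir: Path) -> list:
    from .geometry import read_ascii_grid
    from .postprocess import coldspot_classes, threshold_attainment, unvaccinated_counts

    if cfg.predictions is None:
        raise ValueError("postprocess needs a predictions CSV (key 'predictions')")
    df = pd.read_csv(cfg.predictions)
    mean = df["mean"].to_numpy()
    cold = coldspot_classes(mean)
    cold.to_frame().to_csv(outdir / "coldspots.csv", index=False)
    flags, pct = threshold_attainment(mean[np.isfinite(mean)], threshold=cfg.threshold)
    summary = {
        "coldspot_cutpoints": list(cold.cutpoints),
        "attainment_threshold": cfg.threshold,
        "percent_cells_attaining": pct,
        "proxy_note": "coverage in 12-23-month-olds used as a proxy for under-5 coverage",
    }
    artifacts = ["coldspots.csv", "postprocess_summary.json"]
    if cfg.population is not None:
        arr, _ = read_ascii_grid(cfg.population)
        pop = arr[::-1].ravel()  # back to south-row-first cell order
        summary["national_unvaccinated"] = unvaccinated_counts(mean, pop, level="national")
    with open(outdir / "postprocess_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return artifacts


_PIPELINES = {
    "simulate": _pipeline_simulate,
    "fit": _pipeline_fit,
    "predict": _pipeline_predict,
    "study": _pipeline_study,
    "postprocess": _pipeline_postprocess,
}
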