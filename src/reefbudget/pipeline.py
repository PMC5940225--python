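"""Pipeline orchestration: simulate -> budget -> summarize -> krige ->
threshold, with habitat summary tables (the per-habitat mean/CI surface)
and a deterministic artifact directory per run.

The habitat summary reports, per island x habitat stratum, the mean gross
calcification, total erosion and net production over sites (or transects),
with 95% confidence half-widths from the t distribution; pooled outer
strata, pooled across-island habitat rows, and the all-habitat grand mean
are appended.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import budget as bdg
from . import gamm, kriging, synth
from .constants import DEFAULT_CONSTANTS, BudgetConstants
from .survey import SurveyDataset, TraitTable

__all__ = [
    "budget_table", "summarize_by_habitat", "run_pipeline",
    "PipelineStageError", "load_config",
]

log = logging.getLogger("reefbudget")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def budget_table(ds: SurveyDataset, traits: TraitTable,
                 constants: BudgetConstants = DEFAULT_CONSTANTS,
                 per_transect: bool = False) -> pd.DataFrame:
    """Budgets joined to site metadata, one row per site (or transect)."""
    rows = []
    for site in ds.sites:
        budgets = (bdg.transect_budgets(site, traits, constants)
                   if per_transect else [bdg.net_production(site, traits, constants)])
        for b in budgets:
            rows.append({
                "site_id": site.site_id,
                "transect_id": b.transect_id,
                "island": site.island,
                "habitat": site.habitat,
                "habitat_label": site.habitat_label,
                "lat": site.lat,
                "lon": site.lon,
                "lcc": b.live_coral_cover,
                "gross": b.gross_calcification,
                "cca": b.cca_component,
                "parrotfish": b.parrotfish_erosion,
                "urchin": b.urchin_erosion,
                "macroboring": b.macroboring_erosion,
                "erosion": b.total_erosion,
                "sediment": b.sediment,
                "net": b.net_production,
            })
    return pd.DataFrame(rows)


def _ci_halfwidth(x: np.ndarray) -> float:
    """95% half-width, mean +/- t(0.975, n-1) * se; 0 for a single value."""
    n = len(x)
    if n < 2:
        return 0.0
    se = np.std(x, ddof=1) / np.sqrt(n)
    return float(stats.t.ppf(0.975, n - 1) * se)


def summarize_by_habitat(budgets: pd.DataFrame,
                         weighting: str = "site") -> pd.DataFrame:
    """Habitat summary of a budget table.

    ``budgets`` must carry one row per site for ``weighting='site'`` or one
    row per transect for ``weighting='transect'`` (the output of
    :func:`budget_table` with the matching ``per_transect`` flag); rows are
    averaged as given, so the weighting choice is the table's granularity.

    Strata reported per island: the four base habitats, a pooled ``outer``
    row, then pooled across-island habitat rows (island = 'All') and the
    all-habitat grand mean (habitat = 'all').  Empty strata are omitted.
    """
    if weighting not in ("site", "transect"):
        raise ValueError("weighting must be 'site' or 'transect'")
    need = {"island", "habitat", "gross", "erosion", "net"}
    if not need <= set(budgets.columns):
        raise ValueError(f"budget table missing columns {need - set(budgets.columns)}")

    def _row(island, habitat, sub):
        return {
            "island": island, "habitat": habitat, "n": len(sub),
            "mean_gross": sub["gross"].mean(),
            "ci_gross": _ci_halfwidth(sub["gross"].to_numpy()),
            "mean_erosion": sub["erosion"].mean(),
            "ci_erosion": _ci_halfwidth(sub["erosion"].to_numpy()),
            "mean_net": sub["net"].mean(),
            "ci_net": _ci_halfwidth(sub["net"].to_numpy()),
        }

    rows = []
    pooled_hab = budgets["habitat"].str.replace(r"^outer_.*", "outer", regex=True)
    for island in sorted(budgets["island"].unique()):
        isl = budgets[budgets["island"] == island]
        for hab in ("outer", "outer_west", "outer_east", "patch", "inner"):
            if hab == "outer":
                sub = isl[isl["habitat"].str.startswith("outer")]
            else:
                sub = isl[isl["habitat"] == hab]
            if len(sub):
                rows.append(_row(island, hab, sub))
    for hab in ("outer", "patch", "inner"):
        sub = budgets[pooled_hab == hab]
        if len(sub):
            rows.append(_row("All", hab, sub))
    rows.append(_row("All", "all", budgets))
    return pd.DataFrame(rows)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _write(df: pd.DataFrame, path: Path) -> None:
    """Write via a .partial file so an aborted stage leaves no truncated
    final artifact, only a clearly-suffixed partial one."""
    tmp = path.with_suffix(path.suffix + ".partial")
    df.to_csv(tmp, index=False)
    tmp.rename(path)


def run_pipeline(config: dict | str | Path, outdir=None) -> Path:
    """Run the full chain on a synthetic scenario and write the artifacts.

    ``config`` is a dict (or YAML path) with optional keys: ``seed`` (int,
    default 0), ``constants`` (overrides for :class:`BudgetConstants`),
    ``kriging`` (``family``, ``n_lags``, ``nx``, ``ny``), ``threshold``
    (``chains``, ``draws``, ``warmup``) and ``outdir``.  Outputs:
    ``budgets.csv``, ``habitat_summary.csv``, ``kriged_surface.csv``,
    ``thresholds.csv`` and ``run.log``.  Deterministic given the seed.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(config.get("seed", 0))
    outdir = Path(outdir or config.get("outdir", "reefbudget_run"))
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        constants = DEFAULT_CONSTANTS.replace(**config.get("constants", {}))
        log.info("config: %s", config)
        log.info("constants: %s", asdict(constants))

        stage = "simulate"
        try:
            scenario = synth.palau_yap_scenario(seed)
            ds, truth = synth.generate_survey_dataset(scenario)
            traits = synth.default_trait_table()
            log.info("simulate: %d sites, seed %d", len(ds.sites), seed)
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc

        stage = "budget"
        try:
            site_df = budget_table(ds, traits, constants)
            transect_df = budget_table(ds, traits, constants, per_transect=True)
            _write(site_df, outdir / "budgets.csv")
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc

        stage = "summarize"
        try:
            summary = summarize_by_habitat(site_df, weighting="site")
            _write(summary, outdir / "habitat_summary.csv")
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc

        stage = "krige"
        try:
            kcfg = config.get("kriging", {})
            surfaces = []
            for island in sorted(site_df["island"].unique()):
                isl = site_df[site_df["island"] == island]
                sample = kriging.SpatialSample.from_lonlat(
                    isl["lon"], isl["lat"], isl["net"])
                emp = kriging.empirical_semivariogram(
                    sample, n_lags=int(kcfg.get("n_lags", 10)))
                model = kriging.fit_variogram(emp, kcfg.get("family", "exponential"))
                log.info("krige %s: %s nugget=%.3g psill=%.3g range=%.3g",
                         island, model.family, model.nugget,
                         model.partial_sill, model.range_m)
                grid = kriging.make_grid(sample, nx=int(kcfg.get("nx", 100)),
                                         ny=int(kcfg.get("ny", 100)))
                pred, var = kriging.ordinary_krige(sample, model, grid)
                surfaces.append(pd.DataFrame({
                    "island": island, "x": grid[:, 0], "y": grid[:, 1],
                    "prediction": pred, "variance": var}))
            _write(pd.concat(surfaces, ignore_index=True),
                   outdir / "kriged_surface.csv")
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc

        stage = "threshold"
        try:
            tcfg = config.get("threshold", {})
            table = transect_df.drop(columns=["habitat"]).rename(
                columns={"habitat_label": "habitat"})
            table = table.assign(country=table["island"])[
                ["lcc", "net", "habitat", "country"]]
            design = gamm.GammDesign.from_table(table)
            post = gamm.fit_production_gamm(
                design,
                chains=int(tcfg.get("chains", 4)),
                draws=int(tcfg.get("draws", 2000)),
                warmup=int(tcfg.get("warmup", 1000)),
                seed=seed,
            )
            log.info("threshold: max R-hat %.4f, min ESS %.0f",
                     post.rhat_max, post.ess_min)
            _write(gamm.estimate_all_thresholds(post), outdir / "thresholds.csv")
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc

        log.info("run complete: %s", outdir)
        return outdir
    finally:
        log.removeHandler(handler)
        handler.close()
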