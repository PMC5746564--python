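"""End-to-end orchestration: simulate → fit → map → standardize → compare.

A single master seed fans out deterministically (via numpy SeedSequence
spawn keys) to the landscape generator, each per-iteration forest fit
and each permutation pass, so a full run is bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synth
from .grids import (read_ascii_grid, read_census_csv, write_ascii_grid,
                    write_census_csv, CovariateStack, ZoneMap)
from .model import (ForestParams, build_feature_table, dasymetric_redistribute,
                    iterative_covariate_selection, predict_weight_grid)
from .standardize import (load_default_class_map, compute_wir,
                          assemble_study_table, read_importance_csv,
                          wir_from_importances)
from .stats import run_all_designs, run_design, reports_to_frames

__all__ = [
    "RunConfig",
    "demo_study_spec",
    "fit_map_country",
    "country_importance",
    "analyze_study",
    "reanalyze",
    "save_country_bundle",
    "load_country_bundle",
]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Run settings: seeds, significance level, RF parameters, paths."""

    seed: int = 0
    alpha: float = 0.05
    n_trees: int = 250
    min_samples_leaf: int = 5
    max_features: int | None = None
    outdir: str = "."
    landscape: dict = field(default_factory=dict)
    study: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw[k] for k in
                 ("seed", "alpha", "n_trees", "min_samples_leaf",
                  "max_features", "outdir", "landscape", "study")
                 if k in raw}
        return cls(**known)

    def forest_params(self, seed: int | None = None) -> ForestParams:
        return ForestParams(n_trees=self.n_trees,
                            max_features=self.max_features,
                            min_samples_leaf=self.min_samples_leaf,
                            seed=self.seed if seed is None else seed)

    def landscape_spec(self) -> synth.LandscapeSpec:
        raw = dict(self.landscape) if self.landscape else {}
        covs = [synth.CovariateSpec(**c) for c in raw.pop("covariates", [])]
        if not covs:
            return demo_study_spec(seed=self.seed)
        raw.setdefault("seed", self.seed)
        return synth.LandscapeSpec(covariates=covs, **raw)


def demo_study_spec(n_zones: int = 150, grid: int = 60,
                    seed: int = 0) -> synth.LandscapeSpec:
    """The packaged demo country: 8 covariates spanning several variable
    classes, with planted effects a spatial demographer would recognise
    (population concentrates in and around built-up areas, avoids steep
    high terrain, tracks roads)."""
    covs = [
        synth.CovariateSpec("urban_extent", "binary-extent"),
        synth.CovariateSpec("lights_at_night", "smooth-field"),
        synth.CovariateSpec("dist_roads", "distance-to-feature"),
        synth.CovariateSpec("dist_river", "distance-to-feature"),
        synth.CovariateSpec("elevation", "smooth-field"),
        synth.CovariateSpec("slope", "derived-gradient", source="elevation"),
        synth.CovariateSpec("temperature", "smooth-field"),
        synth.CovariateSpec("cropland", "binary-extent"),
    ]
    betas = {"urban_extent": 1.2, "lights_at_night": 0.9,
             "dist_roads": -0.7, "dist_river": -0.2, "elevation": -0.8,
             "slope": -0.5, "temperature": 0.3, "cropland": 0.4}
    return synth.LandscapeSpec(grid_rows=grid, grid_cols=grid,
                               n_zones=n_zones, covariates=covs,
                               effect_weights=betas, intercept=6.0,
                               noise_sd=0.3, seed=seed)


def recovery_study_spec(seed: int = 0) -> synth.LandscapeSpec:
    """Structure-recovery conditions: 300 admin units, 3 planted smooth
    fields (log-density effects 1.0, −0.8, 0.6 s.d.) among 7 pure-noise
    fields, pixel noise s.d. 0.25."""
    covs = [synth.CovariateSpec(f"signal_{i}", "smooth-field")
            for i in range(3)]
    covs += [synth.CovariateSpec(f"noise_{i}", "smooth-field")
             for i in range(7)]
    betas = {"signal_0": 1.0, "signal_1": -0.8, "signal_2": 0.6}
    return synth.LandscapeSpec(grid_rows=80, grid_cols=80, n_zones=300,
                               covariates=covs, effect_weights=betas,
                               noise_sd=0.25, seed=seed)


def planted_recovery_rate(n_seeds: int = 50, n_trees: int = 500,
                          seed: int = 0) -> dict:
    """Fraction of seeds in which all planted covariates survive the
    elimination loop and occupy the top importance ranks.

    Each seed generates a fresh country from :func:`recovery_study_spec`
    and runs the full iterative selection at ``n_trees`` trees.
    """
    hits = 0
    planted = {"signal_0", "signal_1", "signal_2"}
    for i in range(n_seeds):
        rep_seed = int(np.random.default_rng(np.random.SeedSequence(
            entropy=seed, spawn_key=(300, i))).integers(2 ** 31))
        country = synth.generate_country(recovery_study_spec(rep_seed))
        X, y = build_feature_table(country.stack, country.zones,
                                   country.census)
        trace = iterative_covariate_selection(
            X, y, ForestParams(n_trees=n_trees), seed=rep_seed)
        imp = trace.final_importance
        survived = planted <= set(trace.final_covariates)
        top = set(imp["covariate"].head(len(planted)))
        hits += int(survived and top == planted)
    return {"rate": hits / n_seeds, "n_seeds": n_seeds, "hits": hits}


def calibration_study_template() -> tuple[synth.LandscapeSpec,
                                          dict[str, int]]:
    """Null-calibration conditions: 4 regions × 5 countries sharing one
    set of generating coefficients (the exchangeable null), on small
    30×30 landscapes with 36 admin units and 6 covariates spanning six
    variable classes."""
    covs = [synth.CovariateSpec("urban_extent", "binary-extent"),
            synth.CovariateSpec("lights_at_night", "smooth-field"),
            synth.CovariateSpec("dist_roads", "distance-to-feature"),
            synth.CovariateSpec("elevation", "smooth-field"),
            synth.CovariateSpec("cropland", "binary-extent"),
            synth.CovariateSpec("dist_river", "distance-to-feature")]
    betas = {"urban_extent": 1.0, "lights_at_night": 0.8,
             "dist_roads": -0.6, "elevation": -0.5, "cropland": 0.3,
             "dist_river": -0.2}
    template = synth.LandscapeSpec(grid_rows=30, grid_cols=30, n_zones=36,
                                   covariates=covs, effect_weights=betas,
                                   noise_sd=0.3, seed=0)
    return template, {f"region-{i + 1}": 5 for i in range(4)}


def interregional_null_rejection_rate(n_replicates: int = 500,
                                      alpha: float = 0.05,
                                      n_trees: int = 50,
                                      seed: int = 0) -> dict:
    """Type-I error of the inter-regional Kruskal–Wallis test under the
    exchangeable null.

    Every replicate generates a fresh study from
    :func:`calibration_study_template` (identical coefficients in every
    region), runs the fit+importance stage per country (a single forest;
    the elimination loop is skipped — it does not alter exchangeability
    across regions and one fit keeps 500 replicates tractable), pools
    WIRs and runs the inter-regional design for every class.  Returns
    the rejection fraction over all (replicate, class) tests.
    """
    template, n_per_region = calibration_study_template()
    cmap = load_default_class_map()
    rejections = 0
    n_tests = 0
    for rep in range(n_replicates):
        rep_seed = int(np.random.default_rng(np.random.SeedSequence(
            entropy=seed, spawn_key=(400, rep))).integers(2 ** 31))
        study = synth.generate_study(n_per_region, template, seed=rep_seed)
        parts = []
        for i, country in enumerate(study):
            c_seed = int(np.random.default_rng(np.random.SeedSequence(
                entropy=rep_seed, spawn_key=(401, i))).integers(2 ** 31))
            imp = country_importance(country,
                                     ForestParams(n_trees=n_trees),
                                     seed=c_seed, select=False)
            parts.append(compute_wir(imp, country=country.country_label,
                                     region=country.region_label,
                                     cmap=cmap))
        table = assemble_study_table(parts)
        for cls_ in sorted(table.loc[table["testable"], "class"].unique()):
            rep_result = run_design(table, "inter-regional-by-region",
                                    scope=cls_, alpha=alpha)
            if rep_result.untestable:
                continue
            n_tests += 1
            rejections += int(rep_result.kw.pvalue <= alpha)
    return {"rate": rejections / n_tests if n_tests else float("nan"),
            "n_tests": n_tests, "n_replicates": n_replicates,
            "rejections": rejections}


def fit_map_country(country: synth.SyntheticCountry,
                    params: ForestParams | None = None,
                    seed: int = 0, select: bool = True) -> dict:
    """Run the three-step chain on one country bundle.

    Returns a dict with the selection trace, final importance table,
    weighting layer, population grid and a JSON-able model summary.
    """
    params = params or ForestParams()
    X, y = build_feature_table(country.stack, country.zones, country.census)
    if select:
        trace = iterative_covariate_selection(X, y, params, seed=seed)
    else:
        from .model import fit_forest, oob_permutation_importance, \
            SelectionTrace
        model = fit_forest(X, y, ForestParams(
            n_trees=params.n_trees, max_features=params.max_features,
            min_samples_leaf=params.min_samples_leaf, seed=seed))
        imp = oob_permutation_importance(model, X, y, seed=seed)
        trace = SelectionTrace()
        trace.append(0, list(X.columns), imp, model)
    model = trace.final_model
    final_stack = country.stack.subset(trace.final_covariates)
    weights = predict_weight_grid(model, final_stack)
    pop = dasymetric_redistribute(weights, country.zones, country.census)
    summary = {
        "country": country.country_label,
        "region": country.region_label,
        "n_units": int(len(y)),
        "n_trees": params.n_trees,
        "asr_km": country.asr_km,
        "oob_mse": model.oob_mse,
        "variance_explained": model.variance_explained,
        "final_covariates": trace.final_covariates,
        "n_iterations": len(trace.iterations),
    }
    return {"trace": trace, "importance": trace.final_importance,
            "model": model, "weights": weights, "population": pop,
            "summary": summary, "X": X, "y": y}


def country_importance(country: synth.SyntheticCountry,
                       params: ForestParams | None = None,
                       seed: int = 0, select: bool = True) -> pd.DataFrame:
    """Final-model importance table only (no mapping) — the cheap path
    for large replicate studies."""
    params = params or ForestParams()
    X, y = build_feature_table(country.stack, country.zones, country.census)
    if select:
        trace = iterative_covariate_selection(X, y, params, seed=seed)
        return trace.final_importance
    from .model import fit_forest, oob_permutation_importance
    model = fit_forest(X, y, ForestParams(
        n_trees=params.n_trees, max_features=params.max_features,
        min_samples_leaf=params.min_samples_leaf, seed=seed))
    return oob_permutation_importance(model, X, y, seed=seed)


def analyze_study(countries: list[synth.SyntheticCountry],
                  params: ForestParams | None = None, seed: int = 0,
                  alpha: float = 0.05, select: bool = True) -> dict:
    """Fit every country, build the pooled WIR table and run all
    comparison designs."""
    cmap = load_default_class_map()
    wir_parts = []
    summaries = []
    for i, country in enumerate(countries):
        c_seed = int(np.random.default_rng(np.random.SeedSequence(
            entropy=seed, spawn_key=(200, i))).integers(2 ** 31))
        imp = country_importance(country, params, seed=c_seed, select=select)
        wir_parts.append(compute_wir(imp, country=country.country_label,
                                     region=country.region_label, cmap=cmap))
        summaries.append({"country": country.country_label,
                          "region": country.region_label,
                          "n_final_covariates": len(imp)})
    table = assemble_study_table(wir_parts)
    reports = run_all_designs(table, alpha=alpha)
    return {"wir_table": table, "reports": reports, "summaries": summaries}


def reanalyze(importance_csv, alpha: float = 0.05,
              per_country_median: bool = False) -> dict:
    """Re-run the comparison stage from an external importance table.

    The input CSV (``country,region,covariate,per_inc_mse``) mirrors the
    per-model summary exports of a population-mapping run; covariates
    are classified, WIRs computed per country and all four designs run.
    """
    df = read_importance_csv(importance_csv)
    table = wir_from_importances(df)
    reports = run_all_designs(table, alpha=alpha,
                              per_country_median=per_country_median)
    return {"wir_table": table, "reports": reports}


def save_country_bundle(outdir, country: synth.SyntheticCountry) -> None:
    """Write a country bundle as ASCII grids + census CSV + metadata."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name in country.stack.names:
        write_ascii_grid(out / f"cov_{name}.asc", country.stack.grid(name),
                         mask=country.stack.mask)
    write_ascii_grid(out / "zones.asc", country.zones.labels,
                     nodata=0)
    write_census_csv(out / "census.csv", country.census)
    meta = {
        "covariates": country.stack.names,
        "kinds": country.stack.kinds,
        "pixel_area": country.zones.pixel_area,
        "asr_km": country.asr_km,
        "region": country.region_label,
        "country": country.country_label,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))


def load_country_bundle(indir) -> synth.SyntheticCountry:
    """Read back a bundle written by :func:`save_country_bundle`."""
    ind = Path(indir)
    meta = json.loads((ind / "meta.json").read_text())
    grids, mask = [], None
    for name in meta["covariates"]:
        g, m = read_ascii_grid(ind / f"cov_{name}.asc")
        g = np.nan_to_num(g)
        grids.append(g)
        mask = m if mask is None else (mask & m)
    stack = CovariateStack(names=meta["covariates"],
                           data=np.stack(grids), mask=mask,
                           kinds=meta.get("kinds", {}))
    zgrid, _ = read_ascii_grid(ind / "zones.asc")
    zones = ZoneMap(labels=np.nan_to_num(zgrid).astype(np.int64),
                    pixel_area=meta["pixel_area"])
    census = read_census_csv(ind / "census.csv")
    return synth.SyntheticCountry(
        stack=stack, zones=zones, census=census,
        true_log_density=np.zeros(stack.shape),
        asr_km=meta.get("asr_km", float("nan")),
        region_label=meta.get("region", ""),
        country_label=meta.get("country", ""))


def write_reports(outdir, reports, prefix: str = "compare") -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    kw_frame, pair_frame = reports_to_frames(reports)
    kw_frame.to_csv(out / f"{prefix}_kw.csv", index=False)
    pair_frame.to_csv(out / f"{prefix}_dunn.csv", index=False)
    summary = kw_frame.to_dict(orient="records")
    (out / f"{prefix}_summary.json").write_text(
        json.dumps(summary, indent=2, default=float))
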