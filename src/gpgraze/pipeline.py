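"""End-to-end orchestration: simulate -> QC -> metrics -> cohort -> models
-> association statistics, with a manifest for deterministic replay.

Every stage is file-based when an output directory is given (fix table,
daily metrics, cow profiles, rosters, selection traces, confusion matrices,
model JSON, association tables, manifest), so any stage can be re-run in
isolation; in-memory callers get everything back in a
:class:`PipelineResult`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, cohort, metrics, qc
from .discriminant import GenotypeDiscriminant
from .presets import preset_variable_sets
from .simulate import (
    SimulationConfig,
    default_profiles,
    identical_profiles,
    simulate_herd,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "build_association_table"]


@dataclass
class PipelineConfig:
    """Single-document run configuration (YAML/JSON friendly).

    The named constants of the study design are surfaced here with their
    conventional defaults: the 75% fix-rate rule, the 8-degree hill
    threshold, the 7-day deployment minimum, the 3500 m and 350 m
    herd-relative anchors (fixed in :mod:`gpgraze.metrics`), the VIF < 10
    screen, the 5% genotype floor and 4 cows per genotype x farm cell.
    """

    seed: int = 0
    scenario: str = "separated"          # separated | identical
    n_farms: int = 4
    days: int = 15
    cows_per_genotype_per_farm: int = 7
    fix_interval_s: int = 300
    gps_noise_sd: float = 5.0
    dropout_probability: float = 0.10
    paddock_area_ha: float = 34.5
    relief_amplitude: float = 300.0
    min_fix_fraction: float = 0.75
    hill_threshold_deg: float = 8.0
    min_valid_days: int = 7
    per_cell: int = 4
    genotype_floor: float = 0.05
    outlier_alpha: float = 0.01
    outlier_components: int = 5
    vif_max: float = 10.0
    transform_policy: str = "skip"       # on_invalid policy for transforms

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            n_farms=self.n_farms,
            paddock_area_ha=self.paddock_area_ha,
            fix_interval_s=self.fix_interval_s,
            days=self.days,
            cows_per_genotype_per_farm=self.cows_per_genotype_per_farm,
            gps_noise_sd=self.gps_noise_sd,
            dropout_probability=self.dropout_probability,
            relief_amplitude=self.relief_amplitude,
            seed=self.seed,
        )


@dataclass
class PipelineResult:
    config: PipelineConfig
    fixes: pd.DataFrame = None
    truth: pd.DataFrame = None
    daily: pd.DataFrame = None
    profiles_raw: pd.DataFrame = None
    profiles: pd.DataFrame = None        # transformed, imputed, analysis cohort
    transform_log: list = field(default_factory=list)
    design: cohort.CohortDesign = None
    results: dict = field(default_factory=dict)      # model name -> DiscriminantResults
    accuracies: dict = field(default_factory=dict)   # model name -> (train, test)
    association_table: pd.DataFrame = None
    manova: "association.ManovaMap" = None
    hill_days: pd.DataFrame = None
    qc_report: dict = None
    manifest: dict = None


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def run_pipeline(
    config: PipelineConfig | dict | None = None,
    outdir: str | Path | None = None,
    exclusion_calendar: pd.DataFrame | None = None,
    fixes: pd.DataFrame | None = None,
    terrains=None,
) -> PipelineResult:
    """Run the full analysis.

    Without ``fixes``, a synthetic herd is simulated under the config's
    scenario.  Raises a "no eligible cows" error when every deployment
    fails the minimum-valid-days filter (for instance a deployment shorter
    than seven days).
    """
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    res = PipelineResult(config=config)

    # ------------------------------------------------------------- simulate
    if fixes is None:
        profiles_gen = (
            identical_profiles() if config.scenario == "identical" else default_profiles()
        )
        fixes, truth, terrains = simulate_herd(profiles_gen, config.simulation_config())
        res.truth = truth
    if terrains is None:
        raise ValueError("terrains must be provided with user-supplied fixes")
    res.fixes = fixes

    # ------------------------------------------------------------------- qc
    clean, day_table, hills, report = qc.qc_herd(
        fixes, terrains, exclusion_calendar, fix_interval_s=config.fix_interval_s
    )
    res.hill_days = hills
    res.qc_report = report.as_dict()
    if not len(clean):
        raise RuntimeError(
            "no eligible cows: every deployment failed the "
            f"{config.min_valid_days}-valid-day minimum"
        )

    # -------------------------------------------------------------- metrics
    daily = metrics.compute_daily_metrics(clean)
    daily = metrics.adjusted_and_relative_metrics(daily)
    res.daily = daily

    # ---------------------------------------------------- provisional profiles
    prof0 = metrics.compute_cow_profiles(daily, min_days=config.min_valid_days)
    if not len(prof0):
        raise RuntimeError(
            "no eligible cows: every deployment failed the "
            f"{config.min_valid_days}-valid-day minimum"
        )
    res.profiles_raw = prof0
    t0, _ = metrics.apply_transforms(prof0, on_invalid=config.transform_policy)

    # ------------------------------------------------------ cohort building
    outliers = cohort.screen_outliers_within_genotype(
        t0,
        metrics.PROFILE_VARIABLES,
        alpha=config.outlier_alpha,
        n_components=config.outlier_components,
        seed=config.seed,
    )
    design = cohort.build_training_set(
        prof0,
        per_cell=config.per_cell,
        genotype_floor=config.genotype_floor,
        seed=config.seed,
        outliers=outliers,
    )
    design = cohort.build_testing_set(prof0, design)
    res.design = design

    # farm centring recomputed over the final analysis cohort
    cohort_ids = list(design.training["cow_id"]) + list(design.testing["cow_id"])
    prof = metrics.compute_cow_profiles(
        daily, cohort_cow_ids=cohort_ids, min_days=config.min_valid_days
    )
    prof, tlog = metrics.apply_transforms(prof, on_invalid=config.transform_policy)
    res.transform_log = tlog
    prof, imput_log = cohort.impute_missing(
        prof, metrics.PROFILE_VARIABLES, seed=config.seed
    )
    design.imputation_log = imput_log
    res.profiles = prof

    train = prof.loc[prof["cow_id"].isin(set(design.training["cow_id"]))].reset_index(drop=True)
    test = prof.loc[prof["cow_id"].isin(set(design.testing["cow_id"]))].reset_index(drop=True)

    # ---------------------------------------------------------------- models
    model_specs = {
        name: {"variables": vars_, "select": False}
        for name, vars_ in preset_variable_sets().items()
    }
    model_specs["denovo"] = {"variables": metrics.PROFILE_VARIABLES, "select": True}
    for name, spec in model_specs.items():
        model = GenotypeDiscriminant(train, variables=spec["variables"])
        fitres = model.fit(select=spec["select"], vif_max=config.vif_max)
        conf_test = fitres.evaluate(test) if len(test) else None
        res.results[name] = fitres
        res.accuracies[name] = (
            fitres.confusion_train.accuracy,
            conf_test.accuracy if conf_test is not None else float("nan"),
        )

    # ------------------------------------------------------------ statistics
    res.association_table = build_association_table(
        res.results["denovo"], train, daily, config
    )
    denovo = res.results["denovo"]
    res.manova = association.manova_map(
        denovo._scaled_train, train["genotype"].to_numpy(), denovo.selected_variables
    )

    # -------------------------------------------------------------- manifest
    res.manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "digests": {
            "cow_profiles": _digest(prof),
            "roster": _digest(design.roster()),
            "daily_metrics": _digest(
                daily.drop(columns=["date"]).assign(date=daily["date"].astype(str))
            ),
        },
        "accuracies": {
            k: {"train": a, "test": b} for k, (a, b) in res.accuracies.items()
        },
        "n_outliers": len(design.outliers),
        "transform_log": res.transform_log,
    }

    if outdir is not None:
        _write_outputs(Path(outdir), res)
    return res


def build_association_table(
    fitres, train: pd.DataFrame, daily: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    """Per-variable association summary for the selected variables.

    Columns mirror the conventional report: VIF, pooled LDA score, ICC2
    (daily behaviours; CV variables show the across-cow mean CV instead),
    a univariate MANOVA-framework p, the two-way genotype ANOVA p, and the
    variant presence/absence p per variant.
    """
    selected = fitres.selected_variables
    scaled = fitres._scaled_train
    labels = train["genotype"].to_numpy()
    manova = association.manova_map(scaled, labels, selected)
    train_daily = daily.loc[daily["cow_id"].isin(set(train["cow_id"]))]
    rows = []
    for v in selected:
        base = v[:-3] if v.endswith("_cv") else v
        if v.endswith("_cv"):
            icc_val = np.nan
            mean_cv = float(train[v].mean())
        else:
            mean_cv = np.nan
            try:
                icc_val = association.icc2(train_daily, base).icc2
            except (ValueError, KeyError):
                icc_val = np.nan
        try:
            geno = two_way_p(train, v, "genotype")
        except ValueError:
            geno = np.nan
        var_p = {}
        try:
            vp = association.variant_presence_anova(
                train[v], train["genotype"], train["farm_id"]
            )
            for variant in ("A", "B", "C"):
                sel = vp.loc[(vp["variant"] == variant) & (vp["term"] == "presence"), "p"]
                var_p[variant] = float(sel.iloc[0]) if len(sel) else np.nan
        except ValueError:
            var_p = {"A": np.nan, "B": np.nan, "C": np.nan}
        rows.append(
            {
                "variable": v,
                "vif": float(fitres.vif[v]),
                "pooled_score": float(fitres.lda.pooled_scores[v]),
                "icc2": icc_val,
                "mean_cv": mean_cv,
                "manova_p": float(manova.per_variable_p[v]),
                "anova_genotype_p": geno,
                "anova_variant_A_p": var_p.get("A", np.nan),
                "anova_variant_B_p": var_p.get("B", np.nan),
                "anova_variant_C_p": var_p.get("C", np.nan),
            }
        )
    out = pd.DataFrame(rows)
    for col in ["manova_p", "anova_genotype_p"]:
        out[f"{col}_lt_0.05"] = out[col] < 0.05
        out[f"{col}_lt_0.1"] = out[col] < 0.1
    return out


def two_way_p(train: pd.DataFrame, variable: str, term: str) -> float:
    table = association.two_way_anova(
        train[variable], train["genotype"], train["farm_id"]
    )
    sel = table.loc[table["term"] == term, "p"]
    return float(sel.iloc[0]) if len(sel) else float("nan")


def _write_outputs(outdir: Path, res: PipelineResult) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    res.daily.to_csv(outdir / "daily_metrics.csv", index=False)
    res.profiles.to_csv(outdir / "cow_profiles.csv", index=False)
    res.design.roster().to_csv(outdir / "roster.csv", index=False)
    if res.design.imputation_log is not None:
        res.design.imputation_log.to_csv(outdir / "imputation_log.csv", index=False)
    res.hill_days.to_csv(outdir / "hill_days.csv", index=False)
    res.association_table.to_csv(outdir / "association_table.csv", index=False)
    if res.manova is not None:
        coords = pd.concat(
            [
                res.manova.centroids.assign(kind="centroid"),
                res.manova.loadings.assign(kind="loading"),
            ]
        )
        coords.index.name = "name"
        coords.to_csv(outdir / "manova_map_coordinates.csv")
    for name, fitres in res.results.items():
        if fitres.selection_trace is not None:
            fitres.selection_trace.to_csv(outdir / f"selection_trace_{name}.csv", index=False)
        fitres.confusion_train.table.to_csv(outdir / f"confusion_train_{name}.csv")
        (outdir / f"model_{name}.json").write_text(fitres.to_json())
        fitres.class_score_table().to_csv(outdir / f"class_scores_{name}.csv")
    inventory = sorted(
        {p.name for p in outdir.iterdir() if p.is_file()} | {"manifest.json"}
    )
    res.manifest["outputs"] = inventory
    (outdir / "manifest.json").write_text(json.dumps(res.manifest, indent=2, default=str))
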