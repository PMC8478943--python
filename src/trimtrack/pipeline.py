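"""End-to-end orchestration: simulate/ingest -> preprocess -> impute ->
growth + path + prediction -> pooled report.

A single master seed deterministically derives every stage seed through
``numpy.random.SeedSequence(master_seed).spawn(...)`` in a fixed order
(simulation, imputation, path, prediction), so two runs with the same
configuration produce byte-identical report tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .growth import compare_models, fit_growth_model, variance_components
from .impute import MAX_MISSING_RATE, impute_chained, pool_estimates
from .path import PathModelSpec, fit_path_model
from .predict import SamplerSettings, run_prediction_experiment
from .preprocess import (aggregate_trimesters, build_wide_matrix,
                         filter_complete_three_trimester, outcome_analysis_set)
from .simulate import (MEASURES, SimulationConfig, ValidationError,
                       read_cohort_csv, simulate_cohort, write_cohort_csv)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Exactly one of ``input_path`` / ``simulation`` provides the cohort.
    Defaults follow the analysis protocol: 3 imputed sets, 3 chains with
    1000 burn-in of 2500 iterations, a 200-woman holdout with 25 events,
    10 prediction replicates, and a 0.001 significance level for the
    slope-variation test.
    """

    input_path: str | None = None
    simulation: SimulationConfig | None = None
    measures: tuple[str, ...] = MEASURES
    covariates: tuple[str, ...] = ("age", "origin")
    m_imputations: int = 3
    imputation_iter: int = 10
    chains: int = 3
    burnin: int = 1000
    total_iter: int = 2500
    n_hold: int = 200
    n_hold_events: int = 25
    prediction_replicates: int = 10
    alpha: float = 0.001
    run_prediction: bool = True
    run_path: bool = True
    master_seed: int = 0
    output_dir: str = "trimtrack_output"

    def validate(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValidationError(
                "provide exactly one of input_path or simulation config")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        d["measures"] = list(self.measures)
        d["covariates"] = list(self.covariates)
        return d

    @classmethod
    def from_dict(cls, d) -> "RunConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        for k in ("measures", "covariates"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def validate_input(table: pd.DataFrame,
                   measures: Sequence[str] = MEASURES) -> list[dict]:
    """Report-only validation of a long-format cohort table.

    Returns a list of issues, each with keys ``severity`` (warning or
    blocking), ``check`` and ``detail``; an empty list means a clean table.
    """
    issues: list[dict] = []

    def add(severity, check, detail):
        issues.append({"severity": severity, "check": check, "detail": detail})

    required = ["woman_id", "gestational_week", "age", "origin",
                "delivery_mode", "blood_loss_ml"]
    for c in required + list(measures):
        if c not in table.columns:
            add("blocking", "missing_column", f"column {c!r} absent")
    if issues:
        return issues

    weeks = table["gestational_week"].to_numpy()
    bad = np.flatnonzero((weeks < 0) | (weeks > 42))
    for i in bad[:20]:
        add("blocking", "week_range",
            f"gestational_week {weeks[i]} outside [0, 42] at row {int(i)}")
    loss = table["blood_loss_ml"].to_numpy(float)
    if np.nanmin(loss) < 0 if len(loss) else False:
        add("blocking", "blood_loss", "negative blood_loss_ml present")
    ages = table["age"].to_numpy(float)
    out_age = int(np.sum((ages < 18) | (ages > 48)))
    if out_age:
        add("warning", "age_range", f"{out_age} rows with age outside [18, 48]")
    for m in measures:
        frac = float(table[m].isna().mean())
        if frac > MAX_MISSING_RATE:
            add("blocking", "missingness",
                f"column {m!r} has {frac:.1%} missing, above the 15% limit")
    dup = table.duplicated(subset=["woman_id", "gestational_week"]).sum()
    if dup:
        add("warning", "duplicates",
            f"{int(dup)} duplicate woman/week rows (same-day draws are averaged)")
    return issues


def _stage_seed(child: np.random.SeedSequence) -> int:
    return int(child.generate_state(1)[0] % (2**31 - 1))


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write the pooled report bundle.

    Writes under ``config.output_dir``: ``growth_components.csv`` (per-measure
    variance shares and the slope-variation test), ``associations.csv``
    (per-measure, per-trimester ORs with credible intervals),
    ``prediction_auc.csv`` (per-model mean/SE AUC), the simulated cohort (if
    simulated), and ``manifest.json``.  Returns the bundle as a dict of
    DataFrames plus the manifest.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger("trimtrack").addHandler(log_handler)
    try:
        return _run_all_inner(config, outdir)
    finally:
        logging.getLogger("trimtrack").removeHandler(log_handler)
        log_handler.close()


def _run_all_inner(config: RunConfig, outdir: Path) -> dict:
    ss = np.random.SeedSequence(config.master_seed)
    seed_sim, seed_imp, seed_path, seed_pred = ss.spawn(4)

    if config.simulation is not None:
        sim_cfg = dataclasses.replace(config.simulation, seed=_stage_seed(seed_sim))
        table = simulate_cohort(sim_cfg)
        write_cohort_csv(table, outdir / "cohort.csv")
    else:
        table = read_cohort_csv(config.input_path)

    issues = validate_input(table, config.measures)
    blocking = [i for i in issues if i["severity"] == "blocking"]
    if blocking:
        raise ValidationError(f"input validation failed: {blocking}")
    for i in issues:
        logger.warning("validate_input: %s", i)

    wide = build_wide_matrix(table, config.measures)
    growth_base = filter_complete_three_trimester_wide(wide, config.measures)
    n_missing_covar = int(growth_base["origin"].isna().sum()
                          + growth_base["age"].isna().sum())
    if n_missing_covar:
        logger.warning("dropping %d women missing covariates", n_missing_covar)
        growth_base = growth_base.dropna(subset=["age", "origin"]).reset_index(drop=True)

    value_cols = [f"{m}_t{j}" for m in config.measures for j in (1, 2, 3)]
    numeric = growth_base[["age"] + value_cols]
    any_missing = bool(numeric.isna().any().any())
    if any_missing:
        imp = impute_chained(numeric, m=config.m_imputations,
                             n_iter=config.imputation_iter,
                             seed=_stage_seed(seed_imp))
        completed = []
        for filled in imp.completed:
            c = growth_base.copy()
            c[numeric.columns] = filled
            completed.append(c)
        m_eff = imp.m
    else:
        completed = [growth_base]
        m_eff = 1

    # --- growth + path per measure, pooled over imputed sets -----------
    growth_rows, assoc_frames, exclusions = [], [], []
    path_spec = PathModelSpec(chains=config.chains, burnin=config.burnin,
                              total_iter=config.total_iter,
                              seed=_stage_seed(seed_path))
    for mi, m in enumerate(config.measures):
        try:
            comp_sets, lrt_sets, assoc_sets = [], [], []
            for k, data in enumerate(completed):
                tm = data[["woman_id", f"{m}_t1", f"{m}_t2", f"{m}_t3",
                           "age", "origin", "pph"]].rename(
                    columns={f"{m}_t{j}": f"value_t{j}" for j in (1, 2, 3)})
                fit1 = fit_growth_model(tm, config.covariates, "intercept_slope")
                fit0 = fit_growth_model(tm, config.covariates, "intercept_only")
                cmp_ = compare_models(fit0, fit1, alpha=config.alpha)
                vc = variance_components(fit1)
                comp_sets.append(pd.Series({
                    "repeatability": vc.repeatability, "change": vc.change,
                    "cov": vc.cov, "residual": vc.residual,
                    "phenotypic_variance": vc.phenotypic_variance,
                }))
                lrt_sets.append(pd.Series({
                    "lrt": cmp_.lrt, "p_naive": cmp_.p_naive,
                    "p_boundary": cmp_.p_boundary,
                }))
                if config.run_path:
                    spec_k = dataclasses.replace(
                        path_spec, seed=(path_spec.seed + 1000 * mi + k) % (2**31 - 1))
                    pfit = fit_path_model(tm, config.covariates, spec_k)
                    assoc_sets.append(pfit.or_summaries[["or", "lower", "upper"]])
            pooled_comp = pool_estimates(comp_sets)
            pooled_lrt = pool_estimates(lrt_sets)
            row = {"measure": m, **pooled_comp.to_dict(), **pooled_lrt.to_dict()}
            row["slope_variation_significant"] = bool(row["p_naive"] < config.alpha)
            growth_rows.append(row)
            if config.run_path and assoc_sets:
                pooled_or = pool_estimates(assoc_sets, log_scale=True)
                pooled_or.insert(0, "measure", m)
                pooled_or["associated"] = (pooled_or["lower"] > 1.0) | (pooled_or["upper"] < 1.0)
                assoc_frames.append(pooled_or.reset_index())
        except (ValidationError, RuntimeError) as exc:
            logger.error("measure %s excluded: %s", m, exc)
            exclusions.append({"measure": m, "reason": str(exc)})

    growth_table = pd.DataFrame(growth_rows)
    assoc_table = (pd.concat(assoc_frames, ignore_index=True)
                   if assoc_frames else pd.DataFrame())

    # --- prediction experiment, pooled over imputed sets ----------------
    pred_summary = pd.DataFrame()
    if config.run_prediction:
        outcome_sets = [d.dropna(subset=["pph"]).reset_index(drop=True)
                        for d in completed]
        summaries = []
        pseed = _stage_seed(seed_pred)
        for k, d in enumerate(outcome_sets):
            _, summ = run_prediction_experiment(
                d, replicates=config.prediction_replicates,
                n_hold=config.n_hold, n_events=config.n_hold_events,
                seed=(pseed + k) % (2**31 - 1), measures=config.measures,
                settings=SamplerSettings(chains=config.chains,
                                         burnin=config.burnin,
                                         total_iter=config.total_iter))
            summaries.append(summ.set_index("model_id"))
        pred_summary = pool_estimates(summaries).reset_index()

    fmt = lambda df: df.to_csv(index=False, float_format="%.10g")
    (outdir / "growth_components.csv").write_text(fmt(growth_table))
    (outdir / "associations.csv").write_text(fmt(assoc_table))
    (outdir / "prediction_auc.csv").write_text(fmt(pred_summary))

    cfg_dict = config.to_dict()
    cfg_dict.pop("output_dir", None)  # hash the analysis, not its destination
    manifest = {
        "trimtrack_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "master_seed": config.master_seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "n_women_input": int(table["woman_id"].nunique()),
        "n_growth_set": int(len(growth_base)),
        "n_outcome_set": int(growth_base["pph"].notna().sum()),
        "n_events": int(growth_base["pph"].sum()),
        "m_imputations_effective": m_eff,
        "measures": list(config.measures),
        "exclusions": exclusions,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"growth": growth_table, "associations": assoc_table,
            "prediction": pred_summary, "manifest": manifest}


def filter_complete_three_trimester_wide(wide: pd.DataFrame,
                                         measures: Sequence[str]) -> pd.DataFrame:
    """Women with at least one draw in every trimester bin (any measure
    observed in the bin counts as coverage of that bin)."""
    keep = np.ones(len(wide), dtype=bool)
    for j in (1, 2, 3):
        cols = [f"{m}_t{j}" for m in measures]
        keep &= wide[cols].notna().any(axis=1)
    return wide.loc[keep].reset_index(drop=True)
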