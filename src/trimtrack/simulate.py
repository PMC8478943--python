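"""Synthetic pregnancy blood-count cohort generator.

Emulates a prospective maternity cohort in which each woman contributes
complete-blood-count (CBC) draws across the three trimesters of pregnancy.
Per woman and per measure the trajectory follows a random-coefficient
(latent growth) model: a latent intercept/slope pair drawn from a bivariate
normal, a linear trend over trimester time ``t = 0, 1, 2``, and independent
occasion-specific Gaussian measurement noise.  A binary postpartum
hemorrhage (PPH) outcome is generated from a Bernoulli logit whose linear
predictor combines the (optionally standardized) trimester means of every
measure, and the recorded blood loss in ml is drawn consistently with that
outcome so the downstream 500 ml threshold recovers it exactly.

The generator exists so that every downstream analysis stage — trimester
aggregation, chained-equation imputation, growth modelling, Bayesian path
analysis and held-out prediction — can be exercised on data whose true
parameters are known.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

#: The 14 CBC measures carried through every analysis stage.
MEASURES: tuple[str, ...] = (
    "ERY", "HT", "MCH", "MCHC", "MCV", "HB", "RDW",
    "PLATE", "MPV", "LEUC", "EOSI", "LYMPH", "MONO", "NEUT",
)

#: Gestational-week bins defining trimesters 1-3 (inclusive integer bounds).
TRIMESTER_BINS: tuple[tuple[int, int], ...] = ((0, 13), (14, 27), (28, 42))

# Stylized population trajectories (intercept at trimester 1, change per
# trimester) in conventional laboratory units.  These are generator defaults,
# not reference ranges.
DEFAULT_LATENT_MEAN_INTERCEPT: dict[str, float] = {
    "ERY": 4.10, "HT": 36.0, "MCH": 29.5, "MCHC": 33.5, "MCV": 88.0,
    "HB": 12.4, "RDW": 13.3, "PLATE": 245.0, "MPV": 10.2, "LEUC": 9.0,
    "EOSI": 0.12, "LYMPH": 1.9, "MONO": 0.50, "NEUT": 6.3,
}
DEFAULT_LATENT_MEAN_SLOPE: dict[str, float] = {
    "ERY": -0.15, "HT": -1.2, "MCH": 0.30, "MCHC": -0.40, "MCV": 1.2,
    "HB": -0.50, "RDW": 0.50, "PLATE": -15.0, "MPV": 0.25, "LEUC": 1.0,
    "EOSI": -0.01, "LYMPH": -0.10, "MONO": 0.05, "NEUT": 0.90,
}
#: Among-women intercept variance psi00 per measure (units squared).
DEFAULT_PSI00: dict[str, float] = {
    "ERY": 0.10, "HT": 4.0, "MCH": 2.9, "MCHC": 0.80, "MCV": 16.0,
    "HB": 0.80, "RDW": 1.0, "PLATE": 2500.0, "MPV": 0.80, "LEUC": 3.2,
    "EOSI": 0.008, "LYMPH": 0.25, "MONO": 0.016, "NEUT": 2.6,
}
#: Among-women slope variance psi11: non-zero only for the measures whose
#: trajectories are allowed to differ between women in the default scenario
#: (the red-cell index / platelet group), zero elsewhere.
DEFAULT_PSI11: dict[str, float] = {
    "ERY": 0.0, "HT": 0.0, "MCH": 0.08, "MCHC": 0.05, "MCV": 0.90,
    "HB": 0.0, "RDW": 0.09, "PLATE": 300.0, "MPV": 0.09, "LEUC": 0.0,
    "EOSI": 0.0, "LYMPH": 0.0, "MONO": 0.0, "NEUT": 0.0,
}
#: Occasion residual variance theta (same at each of the 3 occasions).
DEFAULT_THETA: dict[str, float] = {
    "ERY": 0.13, "HT": 5.0, "MCH": 0.90, "MCHC": 0.50, "MCV": 4.0,
    "HB": 1.0, "RDW": 0.35, "PLATE": 900.0, "MPV": 0.25, "LEUC": 4.0,
    "EOSI": 0.003, "LYMPH": 0.30, "MONO": 0.020, "NEUT": 3.2,
}

#: Default trimester-specific log-odds coefficients of standardized trimester
#: means on PPH.  Non-zero defaults mirror the sign pattern reported for
#: erythrocytes, platelet count and mean platelet volume (risk-increasing in
#: trimester 1, protective in trimester 3); all other measures are null.
DEFAULT_GAMMA_PATH: dict[str, tuple[float, float, float]] = {
    **{m: (0.0, 0.0, 0.0) for m in MEASURES},
    "ERY": (float(np.log(1.36)), 0.0, float(np.log(0.67))),
    "PLATE": (float(np.log(1.20)), 0.0, float(np.log(0.85))),
    "MPV": (float(np.log(1.58)), 0.0, float(np.log(0.79))),
}

#: Baseline log-odds of PPH: prevalence 119/1012 when all path effects are 0.
DEFAULT_OUTCOME_INTERCEPT: float = float(logit(119.0 / 1012.0))

DEFAULT_ORIGIN_PROBS: dict[str, float] = {
    "EUR": 0.68, "AFR": 0.12, "ASI": 0.10, "OTH": 0.10,
}
#: Origin effects on the latent intercept, in units of the within-measure
#: intercept SD (sqrt(psi00)); reference category EUR.
DEFAULT_ORIGIN_EFFECTS: dict[str, float] = {
    "EUR": 0.0, "AFR": 0.20, "ASI": -0.10, "OTH": 0.10,
}


class ValidationError(ValueError):
    """Raised when a configuration or input table violates its invariants."""


def _per_measure(value, measures: Sequence[str], name: str) -> dict[str, float]:
    """Broadcast a scalar to all measures, or validate a per-measure mapping."""
    if isinstance(value, Mapping):
        missing = [m for m in measures if m not in value]
        if missing:
            raise ValidationError(f"{name} missing entries for measures {missing}")
        return {m: value[m] for m in measures}
    return {m: float(value) for m in measures}


def _theta_per_measure(value, measures, name) -> dict[str, tuple[float, float, float]]:
    def as3(v):
        if np.isscalar(v):
            return (float(v),) * 3
        v = tuple(float(x) for x in v)
        if len(v) != 3:
            raise ValidationError(f"{name} must give 3 occasion variances, got {v}")
        return v
    if isinstance(value, Mapping):
        missing = [m for m in measures if m not in value]
        if missing:
            raise ValidationError(f"{name} missing entries for measures {missing}")
        return {m: as3(value[m]) for m in measures}
    return {m: as3(value) for m in measures}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Per-measure fields accept a scalar (broadcast to all measures) or a
    mapping ``{measure: value}``; after construction they are always stored
    as fully-expanded mappings.
    """

    n_women: int = 1457
    measures: tuple[str, ...] = MEASURES
    latent_mean_intercept: Mapping[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_LATENT_MEAN_INTERCEPT))
    latent_mean_slope: Mapping[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_LATENT_MEAN_SLOPE))
    psi00: Mapping[str, float] | float = field(default_factory=lambda: dict(DEFAULT_PSI00))
    psi11: Mapping[str, float] | float = field(default_factory=lambda: dict(DEFAULT_PSI11))
    psi01: Mapping[str, float] | float = 0.0
    theta: Mapping[str, tuple] | float | tuple = field(default_factory=lambda: dict(DEFAULT_THETA))
    # age effect on the latent intercept, in intercept-SD units per year of
    # (centered) maternal age; origin effects likewise in intercept-SD units.
    age_effect: float = 0.02
    origin_effects: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ORIGIN_EFFECTS))
    origin_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ORIGIN_PROBS))
    gamma_path: Mapping[str, tuple] = field(default_factory=lambda: dict(DEFAULT_GAMMA_PATH))
    outcome_intercept: float = DEFAULT_OUTCOME_INTERCEPT
    standardize_outcome_predictors: bool = True
    missing_rate: float = 0.0
    draws_per_trimester: int = 2
    cesarean_fraction: float = 0.0
    age_mean: float = 30.65
    age_sd: float = 5.0
    age_range: tuple[float, float] = (18.0, 48.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.measures = tuple(self.measures)
        ms = self.measures
        self.latent_mean_intercept = _per_measure(self.latent_mean_intercept, ms, "latent_mean_intercept")
        self.latent_mean_slope = _per_measure(self.latent_mean_slope, ms, "latent_mean_slope")
        self.psi00 = _per_measure(self.psi00, ms, "psi00")
        self.psi11 = _per_measure(self.psi11, ms, "psi11")
        self.psi01 = _per_measure(self.psi01, ms, "psi01")
        self.theta = _theta_per_measure(self.theta, ms, "theta")
        gp = self.gamma_path
        if not isinstance(gp, Mapping):
            raise ValidationError("gamma_path must map measure -> (g_t1, g_t2, g_t3)")
        self.gamma_path = {
            m: tuple(float(g) for g in gp.get(m, (0.0, 0.0, 0.0))) for m in ms
        }
        for m, g in self.gamma_path.items():
            if len(g) != 3:
                raise ValidationError(f"gamma_path[{m}] must have 3 entries")
        self.validate()

    def validate(self) -> None:
        if self.n_women < 1:
            raise ValidationError("n_women must be >= 1")
        if not 0.0 <= self.missing_rate <= 0.15:
            raise ValidationError(
                f"missing_rate must lie in [0, 0.15], got {self.missing_rate}")
        if self.draws_per_trimester < 1:
            raise ValidationError("draws_per_trimester must be >= 1")
        if not 0.0 <= self.cesarean_fraction < 1.0:
            raise ValidationError("cesarean_fraction must lie in [0, 1)")
        for m in self.measures:
            psi = self.psi_matrix(m)
            eig = np.linalg.eigvalsh(psi)
            if eig.min() < -1e-10 * max(1.0, eig.max()):
                raise ValidationError(
                    f"latent covariance for {m} is not positive semi-definite: {psi.tolist()}")
            if any(t < 0 for t in self.theta[m]):
                raise ValidationError(f"theta entries for {m} must be >= 0")
        if abs(sum(self.origin_probs.values()) - 1.0) > 1e-8:
            raise ValidationError("origin_probs must sum to 1")

    def psi_matrix(self, measure: str) -> np.ndarray:
        return np.array([
            [self.psi00[measure], self.psi01[measure]],
            [self.psi01[measure], self.psi11[measure]],
        ])

    # --- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["measures"] = list(self.measures)
        d["theta"] = {m: list(v) for m, v in self.theta.items()}
        d["gamma_path"] = {m: list(v) for m, v in self.gamma_path.items()}
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sample_psd(rng: np.random.Generator, mean: np.ndarray, cov: np.ndarray,
                n: int) -> np.ndarray:
    """Draw from a possibly-singular bivariate normal via eigendecomposition."""
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    z = rng.standard_normal((n, cov.shape[0]))
    return mean + (z * np.sqrt(w)) @ v.T


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, n) -> np.ndarray:
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a long-format cohort table, one row per blood draw.

    Columns: ``woman_id``, ``gestational_week``, the 14 CBC measures,
    ``age``, ``origin``, ``delivery_mode``, ``blood_loss_ml``.  Identical
    config (including seed) yields a bit-identical table.
    """
    config.validate()
    n = config.n_women
    d = config.draws_per_trimester
    ss = np.random.SeedSequence(config.seed)
    rng_cov, rng_week, rng_lat, rng_noise, rng_out, rng_loss, rng_miss = (
        np.random.default_rng(s) for s in ss.spawn(7))

    ages = _truncated_normal(rng_cov, config.age_mean, config.age_sd,
                             *config.age_range, n)
    origin_names = list(config.origin_probs)
    origins = rng_cov.choice(origin_names, size=n, p=[config.origin_probs[o] for o in origin_names])
    modes = np.where(rng_cov.random(n) < config.cesarean_fraction, "cesarean", "vaginal")

    # integer gestational weeks, uniform within each trimester bin
    weeks = np.empty((n, 3, d), dtype=int)
    for j, (lo, hi) in enumerate(TRIMESTER_BINS):
        weeks[:, j, :] = rng_week.integers(lo, hi + 1, size=(n, d))

    t = np.array([0.0, 1.0, 2.0])
    origin_shift_unit = np.array([config.origin_effects.get(o, 0.0) for o in origins])
    age_c = ages - config.age_mean

    values: dict[str, np.ndarray] = {}
    tri_means = np.empty((n, 3, len(config.measures)))
    for k, m in enumerate(config.measures):
        psi = config.psi_matrix(m)
        mean = np.array([config.latent_mean_intercept[m], config.latent_mean_slope[m]])
        lat = _sample_psd(rng_lat, mean, psi, n)
        sd0 = np.sqrt(config.psi00[m]) if config.psi00[m] > 0 else 1.0
        lat[:, 0] += sd0 * (config.age_effect * age_c + origin_shift_unit)
        # (n, 3, d): linear trend in trimester time plus occasion noise
        line = lat[:, [0]] + lat[:, [1]] * t[None, :]
        theta = np.asarray(config.theta[m])
        eps = rng_noise.standard_normal((n, 3, d)) * np.sqrt(theta)[None, :, None]
        y = line[:, :, None] + eps
        values[m] = y
        tri_means[:, :, k] = y.mean(axis=2)

    # Bernoulli-logit outcome from (optionally standardized) trimester means
    eta = np.full(n, config.outcome_intercept)
    for k, m in enumerate(config.measures):
        g = np.asarray(config.gamma_path[m])
        if not g.any():
            continue
        tm = tri_means[:, :, k]
        if config.standardize_outcome_predictors:
            tm = (tm - tm.mean(axis=0)) / tm.std(axis=0)
        eta += tm @ g
    pph = (rng_out.random(n) < expit(eta)).astype(int)

    # blood loss consistent with the 500 ml threshold that defines PPH
    loss = np.where(
        pph == 1,
        500.0 + rng_loss.gamma(shape=1.5, scale=200.0, size=n),
        500.0 * rng_loss.beta(2.0, 3.0, size=n),
    )

    width = max(4, len(str(n)))
    ids = np.array([f"W{i + 1:0{width}d}" for i in range(n)])
    rows = n * 3 * d
    table = pd.DataFrame({
        "woman_id": np.repeat(ids, 3 * d),
        "gestational_week": weeks.reshape(rows),
    })
    for m in config.measures:
        table[m] = values[m].reshape(rows)
    table["age"] = np.repeat(np.round(ages, 2), 3 * d)
    table["origin"] = np.repeat(origins, 3 * d)
    table["delivery_mode"] = np.repeat(modes, 3 * d)
    table["blood_loss_ml"] = np.repeat(np.round(loss, 1), 3 * d)
    table = table.sort_values(["woman_id", "gestational_week"],
                              kind="stable").reset_index(drop=True)

    if config.missing_rate > 0:
        miss_seed = int(rng_miss.integers(0, 2**31 - 1))
        table = inject_missingness(table, config.missing_rate, miss_seed,
                                   measures=config.measures)
    return table


def inject_missingness(table: pd.DataFrame, rate: float, seed: int,
                       measures: Sequence[str] = MEASURES) -> pd.DataFrame:
    """Blank measure cells missing-at-random, never exceeding 15% per column.

    The per-cell blanking probability depends on the woman's (observed) age —
    a missing-at-random mechanism — with marginal expectation ``rate``.  Any
    column whose realised missing fraction would exceed 15% has randomly
    chosen cells restored, so the cap holds by construction.
    """
    if not 0.0 <= rate <= 0.15:
        raise ValidationError(f"missingness rate must lie in [0, 0.15], got {rate}")
    out = table.copy()
    if rate == 0.0 or len(out) == 0:
        return out
    rng = np.random.default_rng(seed)
    age = out["age"].to_numpy(float)
    # MAR weight: older mothers slightly more likely to have gaps; mean ~= rate
    w = 1.0 + 0.5 * np.tanh((age - np.mean(age)) / 10.0)
    p = np.clip(rate * w / np.mean(w), 0.0, 0.15)
    cap = int(np.floor(0.15 * len(out)))
    for m in measures:
        if m not in out.columns:
            continue
        mask = rng.random(len(out)) < p
        extra = int(mask.sum()) - cap
        if extra > 0:
            idx = np.flatnonzero(mask)
            restore = rng.choice(idx, size=extra, replace=False)
            mask[restore] = False
        col = out[m].to_numpy(float).copy()
        col[mask] = np.nan
        out[m] = col
    return out


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    """Write a cohort table as UTF-8 CSV; missing cells become empty strings."""
    table.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort table written by :func:`write_cohort_csv`."""
    table = pd.read_csv(path, dtype={"woman_id": str})
    return table
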