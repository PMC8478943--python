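"""Held-out prediction of PPH from trimester CBC features.

The experiment mirrors a repeated stratified-holdout design: 200 women (25
with PPH, 175 without) are removed from the outcome-eligible cohort, five
Bayesian logistic models are fit on the remainder — a baseline with age and
origin only, one model per trimester adding that trimester's 14 CBC
averages, and a "tracking" model adding all 42 — and each model's AUC is
computed on the same held-out women.  The whole cycle repeats across
replicates; the mean and standard error of the AUC across replicates are
reported per model.

Coefficient priors are normal with mean 0 and variance 2, and features are
standardized with training-set statistics only (no information from the
held-out women touches the fit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._mcmc import LogisticPosterior, sample_mwg
from .simulate import MEASURES, ValidationError

logger = logging.getLogger(__name__)

MODEL_IDS = ("baseline", "tri1", "tri2", "tri3", "tracking")


@dataclass
class SamplerSettings:
    """MCMC settings for the prediction models (3 chains, 1000 of 2500
    iterations discarded as burn-in)."""

    chains: int = 3
    burnin: int = 1000
    total_iter: int = 2500


def auc(scores, labels) -> float:
    """Probability that a random event outranks a random non-event.

    Rank-sum (Mann-Whitney) formulation with average ranks, so ties
    contribute one half.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if set(np.unique(labels)) - {0, 1}:
        raise ValidationError("labels must be 0/1")
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUC requires both classes present")
    ranks = rankdata(scores, method="average")
    r1 = float(np.sum(ranks[labels == 1]))
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def holdout_split(matrix: pd.DataFrame, n_hold: int = 200, n_events: int = 25,
                  seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified test split with exactly ``n_events`` events and
    ``n_hold - n_events`` non-events, sampled without replacement."""
    y = matrix["pph"].to_numpy(float)
    if np.isnan(y).any():
        raise ValidationError("holdout_split requires a complete pph column")
    ev = np.flatnonzero(y == 1)
    nev = np.flatnonzero(y == 0)
    n_non = n_hold - n_events
    if len(ev) < n_events or len(nev) < n_non:
        raise ValidationError(
            f"insufficient women for a {n_events}/{n_non} split: "
            f"{len(ev)} events, {len(nev)} non-events available")
    rng = np.random.default_rng(seed)
    test_idx = np.concatenate([
        rng.choice(ev, size=n_events, replace=False),
        rng.choice(nev, size=n_non, replace=False),
    ])
    mask = np.zeros(len(matrix), dtype=bool)
    mask[test_idx] = True
    return (matrix.loc[~mask].reset_index(drop=True),
            matrix.loc[mask].reset_index(drop=True))


@dataclass
class BayesLogisticFit:
    """Posterior of a logistic model plus the train-set standardization."""

    draws: np.ndarray                  # (chains, kept, p) coefficient draws
    feature_names: list[str]
    center: np.ndarray
    scale: np.ndarray
    dropped: list[str] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        Z = (X[self.feature_names].to_numpy(float) - self.center) / self.scale
        return np.column_stack([np.ones(len(Z)), Z])

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Posterior-mean event probability for new rows (full posterior
        average of the logistic link, not a plug-in at the mean)."""
        D = self._design(X)
        flat = self.draws.reshape(-1, self.draws.shape[-1])
        eta = D @ flat.T
        return np.mean(1.0 / (1.0 + np.exp(-eta)), axis=1)


def fit_bayes_logistic(X: pd.DataFrame, y, prior_mean: float = 0.0,
                       prior_var: float = 2.0,
                       settings: SamplerSettings | None = None,
                       seed: int = 0) -> BayesLogisticFit:
    """Bayesian logistic regression with Normal(0, 2) coefficient priors.

    Features are standardized using the statistics of ``X`` (the training
    rows); constant features are dropped with a warning.  The prior
    regularizes, so complete separation still yields a proper posterior.
    """
    settings = settings or SamplerSettings()
    y = np.asarray(y, float)
    if np.isnan(X.to_numpy(float)).any():
        raise ValidationError("features must be complete for fitting")
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome must contain both classes")
    vals = X.to_numpy(float)
    sds = vals.std(axis=0)
    keep = sds > 0
    dropped = [c for c, k in zip(X.columns, keep) if not k]
    if dropped:
        logger.warning("dropping constant features: %s", dropped)
    names = [c for c, k in zip(X.columns, keep) if k]
    center = vals[:, keep].mean(axis=0)
    scale = sds[keep]
    Z = (vals[:, keep] - center) / scale
    D = np.column_stack([np.ones(len(Z)), Z])
    post = LogisticPosterior(D, y, prior_mean=prior_mean, prior_var=prior_var)
    res = sample_mwg(post, settings.total_iter, settings.burnin,
                     settings.chains, seed,
                     param_names=["intercept"] + names)
    return BayesLogisticFit(draws=res.draws, feature_names=names,
                            center=center, scale=scale, dropped=dropped)


def model_features(model_id: str,
                   measures: Sequence[str] = MEASURES) -> list[str]:
    """Feature column names for one of the five prediction models."""
    base = ["age"]
    if model_id == "baseline":
        return base
    if model_id in ("tri1", "tri2", "tri3"):
        j = model_id[-1]
        return base + [f"{m}_t{j}" for m in measures]
    if model_id == "tracking":
        return base + [f"{m}_t{j}" for m in measures for j in (1, 2, 3)]
    raise ValidationError(f"unknown model_id {model_id!r}")


def _with_origin_dummies(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    if "origin" not in matrix.columns:
        return matrix, []
    dummies = pd.get_dummies(matrix["origin"], prefix="origin",
                             drop_first=True).astype(float)
    return pd.concat([matrix, dummies], axis=1), list(dummies.columns)


def run_prediction_experiment(matrix: pd.DataFrame, replicates: int = 10,
                              n_hold: int = 200, n_events: int = 25,
                              seed: int = 0,
                              measures: Sequence[str] = MEASURES,
                              settings: SamplerSettings | None = None,
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired stratified-holdout AUC comparison of the five models.

    ``matrix`` is a wide per-woman table (columns ``{measure}_t{1,2,3}``,
    ``age``, ``origin``, ``pph``) restricted to the outcome-eligible cohort.
    Returns ``(per_replicate, summary)`` where ``summary`` holds each model's
    mean AUC and its standard error (sample SD across replicates / sqrt(R)).
    Within a replicate the same split serves all five models.
    """
    settings = settings or SamplerSettings()
    work = matrix.dropna(subset=["pph"]).reset_index(drop=True)
    work, origin_cols = _with_origin_dummies(work)
    ss = np.random.SeedSequence(seed)
    rows = []
    for r, child in enumerate(ss.spawn(replicates), start=1):
        split_seed, *fit_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                                  for s in child.spawn(1 + len(MODEL_IDS))]
        train, test = holdout_split(work, n_hold=n_hold, n_events=n_events,
                                    seed=split_seed)
        for model_id, fseed in zip(MODEL_IDS, fit_seeds):
            feats = model_features(model_id, measures) + origin_cols
            fit = fit_bayes_logistic(train[feats], train["pph"],
                                     settings=settings, seed=fseed)
            scores = fit.predict_proba(test[feats])
            rows.append({"model_id": model_id, "replicate": r,
                         "auc": auc(scores, test["pph"].to_numpy(int))})
    per_rep = pd.DataFrame(rows)
    summary = (per_rep.groupby("model_id", sort=False)["auc"]
               .agg(mean_auc="mean",
                    se_auc=lambda a: a.std(ddof=1) / np.sqrt(len(a)))
               .reset_index())
    return per_rep, summary
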