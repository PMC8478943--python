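"""Multiple imputation by chained equations with Bayesian linear draws.

Each incomplete numeric variable is regressed on all other numeric variables;
regression parameters are drawn from their approximate posterior (normal for
the coefficients around the least-squares fit, scaled inverse chi-square for
the residual variance) before predicting, and Gaussian residual noise is
added to every imputed value.  The cycle over variables is repeated for a
fixed number of iterations and the whole procedure is run independently m
times, yielding m completed datasets whose observed cells are bit-identical
to the input.

Downstream results computed on each completed set are combined by simple
averaging (point estimates on their natural scale, odds ratios on the log
scale); Rubin's-rules variance pooling is available as a non-default option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import ValidationError

#: Maximum tolerated per-variable missing fraction.
MAX_MISSING_RATE = 0.15


@dataclass
class ImputationSet:
    """m completed copies of one input table plus a convergence trace."""

    completed: list[pd.DataFrame]
    m: int
    trace: pd.DataFrame  # columns: dataset, iteration, variable, imputed_mean
    columns_imputed: list[str] = field(default_factory=list)


def _check_missingness(data: pd.DataFrame, numeric_cols: list[str]) -> None:
    n = len(data)
    for c in numeric_cols:
        frac = data[c].isna().mean()
        if frac >= 1.0:
            raise ValidationError(f"column {c!r} is entirely missing")
        if frac > MAX_MISSING_RATE:
            raise ValidationError(
                f"column {c!r} has {frac:.1%} missing, above the 15% limit")
    if n and data[numeric_cols].isna().all(axis=1).any():
        raise ValidationError("some rows are missing every numeric variable")


def _bayes_linear_draw(X: np.ndarray, y: np.ndarray, Xmis: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Predict missing targets from a Bayesian draw of a linear regression."""
    n, p = X.shape
    XtX = X.T @ X
    # ridge jitter keeps the draw defined under collinearity
    XtX_reg = XtX + 1e-8 * np.eye(p) * max(1.0, np.trace(XtX) / p)
    beta_hat = np.linalg.solve(XtX_reg, X.T @ y)
    resid = y - X @ beta_hat
    dof = max(n - p, 1)
    sigma2_hat = float(resid @ resid) / dof
    sigma2 = sigma2_hat * dof / rng.chisquare(dof)
    cov = sigma2 * np.linalg.inv(XtX_reg)
    beta = rng.multivariate_normal(beta_hat, cov, method="cholesky")
    return Xmis @ beta + rng.normal(0.0, np.sqrt(sigma2), size=len(Xmis))


def impute_chained(data: pd.DataFrame, m: int = 3, n_iter: int = 10,
                   seed: int = 0) -> ImputationSet:
    """Chained-equation imputation producing ``m`` completed datasets.

    Only numeric columns participate; non-numeric columns must be complete
    (categorical covariates are never imputed — rows missing them should be
    dropped beforehand).  Deterministic under a fixed seed.
    """
    if m < 1:
        raise ValidationError("m must be >= 1")
    numeric_cols = [c for c in data.columns
                    if pd.api.types.is_numeric_dtype(data[c])]
    if len(numeric_cols) < 2:
        raise ValidationError("need at least 2 numeric columns for chained equations")
    non_numeric = [c for c in data.columns if c not in numeric_cols]
    for c in non_numeric:
        if data[c].isna().any():
            raise ValidationError(
                f"non-numeric column {c!r} has missing values; drop or encode it first")
    _check_missingness(data, numeric_cols)

    incomplete = [c for c in numeric_cols if data[c].isna().any()]
    masks = {c: data[c].isna().to_numpy() for c in incomplete}
    ss = np.random.SeedSequence(seed)
    completed: list[pd.DataFrame] = []
    trace_rows = []
    for k, child in enumerate(ss.spawn(m)):
        rng = np.random.default_rng(child)
        filled = data.copy()
        # initial fill: observed-column means
        for c in incomplete:
            filled.loc[masks[c], c] = data[c].mean()
        if incomplete:
            for it in range(n_iter):
                for c in incomplete:
                    others = [o for o in numeric_cols if o != c]
                    X = np.column_stack([np.ones(len(filled)),
                                         filled[others].to_numpy(float)])
                    y = filled[c].to_numpy(float)
                    obs = ~masks[c]
                    draws = _bayes_linear_draw(X[obs], y[obs], X[masks[c]], rng)
                    filled.loc[masks[c], c] = draws
                    trace_rows.append((k, it, c, float(np.mean(draws))))
        completed.append(filled)
    trace = pd.DataFrame(trace_rows,
                         columns=["dataset", "iteration", "variable", "imputed_mean"])
    return ImputationSet(completed=completed, m=m, trace=trace,
                         columns_imputed=incomplete)


def pool_estimates(per_dataset_estimates, log_scale: bool = False):
    """Average congruent numeric summaries across the m completed datasets.

    Scalars, arrays, Series and DataFrames are supported; shapes (and, for
    pandas objects, indexes) must agree.  With ``log_scale=True`` the mean is
    taken on the log scale and exponentiated — the convention for pooling
    odds ratios.
    """
    ests = list(per_dataset_estimates)
    if not ests:
        raise ValidationError("no estimates to pool")
    first = ests[0]
    if isinstance(first, (pd.Series, pd.DataFrame)):
        for e in ests[1:]:
            if not first.index.equals(e.index) or (
                    isinstance(first, pd.DataFrame)
                    and not first.columns.equals(e.columns)):
                raise ValidationError("mismatched shapes in pooled estimates")
        stack = [np.log(e.astype(float)) if log_scale else e.astype(float)
                 for e in ests]
        pooled = sum(stack) / len(stack)
        return np.exp(pooled) if log_scale else pooled
    arrs = [np.asarray(e, dtype=float) for e in ests]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValidationError("mismatched shapes in pooled estimates")
    if log_scale:
        out = np.exp(np.mean(np.log(arrs), axis=0))
    else:
        out = np.mean(arrs, axis=0)
    return float(out) if out.shape == () else out


def pool_rubin(point_estimates, variances):
    """Rubin's rules: pooled point estimate and total variance.

    Non-default alternative to simple averaging; the total variance adds the
    between-imputation spread inflated by (1 + 1/m).
    """
    q = np.asarray(point_estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape:
        raise ValidationError("point estimates and variances must align")
    m = q.shape[0]
    qbar = q.mean(axis=0)
    ubar = u.mean(axis=0)
    b = q.var(axis=0, ddof=1) if m > 1 else np.zeros_like(qbar)
    total = ubar + (1.0 + 1.0 / m) * b
    return qbar, total
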