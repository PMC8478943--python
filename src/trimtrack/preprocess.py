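"""Trimester aggregation, outcome derivation and eligibility filters.

Long-format blood-draw records are reduced to one row per woman with the
within-trimester average of each CBC measure (trimester bins 0-13, 14-27 and
28-42 completed gestational weeks, inclusive at both ends).  The postpartum
hemorrhage indicator is a pure threshold — blood loss of 500 ml or more after
a vaginal birth — and cesarean deliveries are excluded from the outcome
analysis set while remaining eligible for growth modelling.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import MEASURES, TRIMESTER_BINS, ValidationError

logger = logging.getLogger(__name__)

#: Threshold (ml) at or above which blood loss after vaginal birth is PPH.
PPH_THRESHOLD_ML = 500.0

#: White-cell subtypes that may arrive as percentages of the leucocyte count.
WBC_SUBTYPES = ("EOSI", "LYMPH", "MONO", "NEUT")


def assign_trimester(weeks) -> np.ndarray:
    """Map gestational weeks to trimester indices 1, 2, 3.

    Raises a :class:`ValidationError` naming the offending rows for weeks
    outside [0, 42].
    """
    weeks = np.asarray(weeks)
    bad = np.flatnonzero((weeks < 0) | (weeks > 42))
    if bad.size:
        raise ValidationError(
            f"gestational_week outside [0, 42] at rows {bad[:10].tolist()}"
            f"{'...' if bad.size > 10 else ''}")
    tri = np.full(weeks.shape, 3, dtype=int)
    tri[weeks <= TRIMESTER_BINS[1][1]] = 2
    tri[weeks <= TRIMESTER_BINS[0][1]] = 1
    return tri


def derive_outcome(table: pd.DataFrame) -> pd.Series:
    """Per-woman PPH indicator: 1 if blood loss >= 500 ml after vaginal birth.

    Returns a float series indexed by ``woman_id``: 1.0 / 0.0 for vaginal
    deliveries, NaN for cesarean deliveries (excluded from the outcome
    analysis set) and for women lacking a blood-loss record.
    """
    per_woman = table.groupby("woman_id", sort=True).agg(
        blood_loss_ml=("blood_loss_ml", "first"),
        delivery_mode=("delivery_mode", "first"),
    )
    loss = per_woman["blood_loss_ml"]
    if (loss.dropna() < 0).any():
        bad = per_woman.index[loss < 0].tolist()
        raise ValidationError(f"negative blood_loss_ml for women {bad[:5]}")
    pph = (loss >= PPH_THRESHOLD_ML).astype(float)
    pph[loss.isna()] = np.nan
    pph[per_woman["delivery_mode"] != "vaginal"] = np.nan
    pph.name = "pph"
    return pph


def aggregate_trimesters(table: pd.DataFrame, measure: str) -> pd.DataFrame:
    """One CBC measure's per-woman trimester averages, wide layout.

    Returns a frame with columns ``woman_id``, ``value_t1``, ``value_t2``,
    ``value_t3``, ``age``, ``origin``, ``delivery_mode`` and ``pph``.  A
    trimester cell is missing iff the woman had no non-missing draw of the
    measure in that bin; multiple draws (including same-day draws) are
    averaged arithmetically.
    """
    if measure not in table.columns or measure in (
            "woman_id", "gestational_week", "age", "origin",
            "delivery_mode", "blood_loss_ml"):
        raise ValidationError(f"unknown CBC measure {measure!r}")
    work = table[["woman_id", "gestational_week", measure]].copy()
    work["trimester"] = assign_trimester(work["gestational_week"].to_numpy())
    wide = (work.pivot_table(index="woman_id", columns="trimester",
                             values=measure, aggfunc="mean")
            .reindex(columns=[1, 2, 3]))
    wide.columns = [f"value_t{j}" for j in (1, 2, 3)]
    covars = table.groupby("woman_id", sort=True).agg(
        age=("age", "first"),
        origin=("origin", "first"),
        delivery_mode=("delivery_mode", "first"),
    )
    out = wide.join(covars, how="outer")
    if "blood_loss_ml" in table.columns:
        out = out.join(derive_outcome(table))
    else:
        out["pph"] = np.nan
    return out.reset_index()


def filter_complete_three_trimester(matrix: pd.DataFrame) -> pd.DataFrame:
    """Retain women with at least one draw in every trimester bin."""
    cols = [f"value_t{j}" for j in (1, 2, 3)]
    keep = matrix[cols].notna().all(axis=1)
    return matrix.loc[keep].reset_index(drop=True)


def outcome_analysis_set(matrix: pd.DataFrame) -> pd.DataFrame:
    """Women eligible for outcome analyses: complete trimesters, vaginal
    delivery, and a recorded PPH indicator."""
    complete = filter_complete_three_trimester(matrix)
    keep = complete["pph"].notna()
    return complete.loc[keep].reset_index(drop=True)


def derive_absolute_counts(table: pd.DataFrame,
                           percent_subtypes: bool = False,
                           subtypes: Sequence[str] = WBC_SUBTYPES) -> pd.DataFrame:
    """Convert white-cell subtype percentages to absolute counts.

    When ``percent_subtypes`` is true, each subtype column is interpreted as a
    percentage of the leucocyte count and replaced by
    ``(percentage / 100) * LEUC``; otherwise the table passes through
    unchanged.  Percentages outside [0, 100] are an error; subtype sums
    slightly above 100 (machine rounding) only log a warning.
    """
    if not percent_subtypes:
        return table.copy()
    out = table.copy()
    if "LEUC" not in out.columns:
        raise ValidationError("LEUC column required to derive absolute counts")
    pct = out[list(subtypes)].to_numpy(float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(pct) < 0 or np.nanmax(pct) > 100:
            raise ValidationError("subtype percentages must lie in [0, 100]")
        sums = np.nansum(pct, axis=1)
    n_over = int((sums > 100.0).sum())
    if n_over:
        logger.warning(
            "subtype percentages exceed 100%% in %d rows (max %.3f); proceeding",
            n_over, float(np.max(sums)))
    leuc = out["LEUC"].to_numpy(float)
    for i, s in enumerate(subtypes):
        out[s] = pct[:, i] / 100.0 * leuc
    return out


def build_wide_matrix(table: pd.DataFrame,
                      measures: Sequence[str] = MEASURES) -> pd.DataFrame:
    """Per-woman wide matrix with every measure's three trimester averages.

    Columns ``{measure}_t{1,2,3}`` for each measure, plus ``age``, ``origin``,
    ``delivery_mode`` and ``pph``.  Used by the path-model and prediction
    stages, which need all measures simultaneously.
    """
    base = None
    for m in measures:
        tm = aggregate_trimesters(table, m)
        renamed = tm.rename(columns={f"value_t{j}": f"{m}_t{j}" for j in (1, 2, 3)})
        if base is None:
            base = renamed
        else:
            base = base.merge(
                renamed[["woman_id"] + [f"{m}_t{j}" for j in (1, 2, 3)]],
                on="woman_id", how="outer")
    # keep covariates last for readability
    covar_cols = ["age", "origin", "delivery_mode", "pph"]
    value_cols = [c for c in base.columns if c not in covar_cols and c != "woman_id"]
    return base[["woman_id"] + value_cols + covar_cols]
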