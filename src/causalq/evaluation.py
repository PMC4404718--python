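"""Scoring model predictions against rating data.

Model fit is measured by the mean squared error (MSE) between each variant's
per-condition prediction (on [0, 1]) and each subject's rating (divided by
100), grouped by question format. Because MSE decomposes into squared bias
plus rating variance around the group mean, question formats that produce
more heterogeneous ratings are fit worse by *every* deterministic model —
the mechanism this module is built to expose.

Uncertainty comes from a subject-level bootstrap (resampling subjects with
replacement preserves the repeated-measures structure); differences in MSE
across question formats are tested with the Friedman rank test on
per-subject mean squared errors, which yields a chi-square statistic without
normality assumptions. A Kruskal-Wallis alternative is available for
comparisons across independent groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MseComparison",
    "prediction_mse",
    "bootstrap_mse",
    "per_subject_squared_errors",
    "mse_difference_test",
    "pearson_r",
]


@dataclass(frozen=True)
class MseComparison:
    """Result of a rank test on MSEs across groups."""

    statistic: float
    df: int
    p_value: float
    grouping: str
    method: str = "friedman"


_MERGE_KEYS = ["condition", "valence"]


def _merged_errors(predictions: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    """Inner-join predictions to ratings and attach squared errors.

    Ratings are rescaled by /100. Rows for (family, valence) pairs a model
    does not cover are absent from the prediction table and therefore drop
    out of the join; the count of such exclusions is attached as
    ``frame.attrs["n_excluded"]``.
    """
    recs = records.copy()
    recs["condition"] = recs["covariance"]
    recs["rating"] = recs["best"] / 100.0
    merged = recs.merge(predictions, on=_MERGE_KEYS, how="inner")
    n_full = len(recs) * predictions["variant"].nunique()
    merged["sq_error"] = (merged["prediction"] - merged["rating"]) ** 2
    merged.attrs["n_excluded"] = n_full - len(merged)
    return merged


def prediction_mse(
    predictions: pd.DataFrame,
    records: pd.DataFrame,
    grouping: tuple[str, ...] = ("variant", "question", "valence"),
) -> pd.DataFrame:
    """MSE of each model variant against individual ratings, by group.

    Parameters
    ----------
    predictions
        Output of :func:`causalq.causal_models.enumerate_variants`.
    records
        Rating records with columns covariance, valence, question, best.
    grouping
        Columns defining the MSE cells.

    Returns
    -------
    DataFrame with the grouping columns plus ``mse`` and ``n``.
    """
    merged = _merged_errors(predictions, records)
    if merged.empty:
        raise ValueError("no overlapping records between predictions and ratings")
    out = (
        merged.groupby(list(grouping), observed=True)["sq_error"]
        .agg(mse="mean", n="size")
        .reset_index()
    )
    out.attrs["n_excluded"] = merged.attrs["n_excluded"]
    return out


def bootstrap_mse(
    predictions: pd.DataFrame,
    records: pd.DataFrame,
    grouping: tuple[str, ...] = ("variant", "question", "valence"),
    B: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Point MSEs with percentile bootstrap CIs from subject resampling.

    Subjects (not records) are resampled with replacement ``B`` times; the
    CI bounds are the percentile interval of the resampled group MSEs.
    """
    if B < 100:
        raise ValueError("B must be at least 100 for percentile intervals")
    rng = np.random.default_rng(seed)
    merged = _merged_errors(predictions, records)
    point = prediction_mse(predictions, records, grouping)

    subjects = merged["subject"].unique()
    by_subject = {s: g for s, g in merged.groupby("subject", observed=True)}
    boots: dict[tuple, list[float]] = {}
    glist = list(grouping)
    for _ in range(B):
        sample = rng.choice(subjects, size=len(subjects), replace=True)
        frame = pd.concat([by_subject[s] for s in sample], ignore_index=True)
        g = frame.groupby(glist, observed=True)["sq_error"].mean()
        for key, val in g.items():
            key = key if isinstance(key, tuple) else (key,)
            boots.setdefault(key, []).append(val)
    a = (1.0 - ci_level) / 2.0
    lo = {k: float(np.quantile(v, a)) for k, v in boots.items()}
    hi = {k: float(np.quantile(v, 1.0 - a)) for k, v in boots.items()}
    keys = [tuple(row) for row in point[glist].itertuples(index=False)]
    point["ci_lower"] = [lo.get(k, np.nan) for k in keys]
    point["ci_upper"] = [hi.get(k, np.nan) for k in keys]
    return point


def per_subject_squared_errors(
    predictions: pd.DataFrame,
    records: pd.DataFrame,
    format_col: str = "question",
) -> pd.DataFrame:
    """Per-subject mean squared error in each question format (wide).

    Rows are subjects, columns the question formats, averaged over variants
    and conditions; subjects missing any format are dropped.
    """
    merged = _merged_errors(predictions, records)
    wide = merged.pivot_table(index="subject", columns=format_col,
                              values="sq_error", aggfunc="mean", observed=True)
    return wide.dropna()


def mse_difference_test(
    per_subject: pd.DataFrame, method: str = "friedman"
) -> MseComparison:
    """Test whether MSEs differ across question formats.

    ``per_subject`` is the wide frame from
    :func:`per_subject_squared_errors` (one mean squared error per subject
    per format). The Friedman rank test treats subjects as blocks and yields
    a chi-square statistic with k-1 degrees of freedom; ``method="kruskal"``
    instead compares the columns as independent samples.
    """
    cols = [per_subject[c].to_numpy() for c in per_subject.columns]
    if len(cols) < 2:
        raise ValueError("need at least two question formats to compare")
    if per_subject.isna().any().any():
        raise ValueError("subjects missing a format; drop or impute first")
    if np.allclose(np.ptp(np.column_stack(cols), axis=1), 0.0):
        # every subject ties across all formats: no evidence of a difference
        return MseComparison(0.0, len(cols) - 1, 1.0, "question", method)
    if method == "friedman":
        if len(cols) == 2:
            # Friedman with k=2 degenerates; scipy requires k >= 3
            raise ValueError("friedman needs >= 3 formats; use method='kruskal'")
        res = stats.friedmanchisquare(*cols)
    elif method == "kruskal":
        res = stats.kruskal(*cols)
    else:
        raise ValueError(f"unknown method {method!r}")
    return MseComparison(float(res.statistic), len(cols) - 1, float(res.pvalue),
                         "question", method)


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length sequences of at least 3 values")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
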