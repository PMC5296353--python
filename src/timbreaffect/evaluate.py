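"""Rating aggregation, reliability, model metrics and comparison tables.

Covers the evaluation arithmetic around the two models: per-stimulus mean
ratings on the raw 1-9 and normalised [0, 1] scales, Cronbach's alpha per
rating scale (participants as items over the stimulus observations),
pairwise Pearson correlations among scale means, R-squared / RMSE, the
percent-improvement comparison of the network over the regression, and
rank tables of the top-|loading| / top-|contribution| descriptors.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .descriptors import CANONICAL_DESCRIPTORS


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Ratings
# ---------------------------------------------------------------------------


def aggregate_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-stimulus mean rating per scale, with normalised companions.

    Input is the long table (participant_id, stimulus_id, scale, rating);
    output has one row per stimulus, columns ``<scale>`` (raw 1-9 mean) and
    ``<scale>_norm`` (``(raw - 1) / 8``).  Missing cells are an error.
    """
    pivot = ratings.pivot_table(index="stimulus_id", columns="scale",
                                values="rating", aggfunc="mean")
    counts = ratings.pivot_table(index="stimulus_id", columns="scale",
                                 values="rating", aggfunc="count")
    if (pivot.isna().any().any() or counts.isna().any().any()
            or counts.to_numpy().min() != counts.to_numpy().max()):
        raise EvaluationError("rating table has missing participant x stimulus cells")
    out = pivot.copy()
    for scale in pivot.columns:
        out[f"{scale}_norm"] = (pivot[scale] - 1.0) / 8.0
    out.columns.name = None
    return out


def rating_matrix(ratings: pd.DataFrame, scale: str) -> pd.DataFrame:
    """Participants x stimuli matrix of raw ratings for one scale."""
    sub = ratings[ratings["scale"] == scale]
    if sub.empty:
        raise EvaluationError(f"no ratings for scale {scale!r}")
    return sub.pivot_table(index="participant_id", columns="stimulus_id",
                           values="rating")


def cronbach_alpha(matrix: pd.DataFrame) -> float:
    """Internal consistency of a participants x stimuli rating matrix.

    ``alpha = k / (k - 1) * (1 - sum(per-participant variance) /
    var(participant sums))`` with k participants as the "items" and the
    stimuli as observations.  1 when all participants agree exactly on a
    non-constant profile.
    """
    M = np.asarray(matrix, dtype=float)
    k, n = M.shape
    if k < 2 or n < 2:
        raise EvaluationError("need at least 2 participants and 2 stimuli")
    item_vars = M.var(axis=1, ddof=1)
    total_var = M.sum(axis=0).var(ddof=1)
    if total_var == 0:
        raise EvaluationError("zero variance of the summed ratings")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def reliability_report(ratings: pd.DataFrame) -> dict:
    """Cronbach's alpha per scale plus the scale-mean correlation matrix."""
    alphas = {scale: cronbach_alpha(rating_matrix(ratings, scale))
              for scale in sorted(ratings["scale"].unique())}
    means = aggregate_ratings(ratings)
    raw_cols = [c for c in means.columns if not c.endswith("_norm")]
    r, p = pearson_matrix(means[raw_cols])
    return {"alpha": alphas, "pearson_r": r, "pearson_p": p,
            "n": int(means.shape[0])}


def pearson_matrix(means: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All pairwise Pearson r with two-sided p-values (df = n - 2)."""
    if len(means) < 3:
        raise EvaluationError("need at least 3 stimuli")
    const = means.columns[means.std(ddof=0) == 0]
    if len(const):
        raise EvaluationError(f"constant scale(s): {', '.join(const)}")
    cols = list(means.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            res = stats.pearsonr(means[a], means[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p


# ---------------------------------------------------------------------------
# Model metrics and comparison
# ---------------------------------------------------------------------------


def metrics(y_true, y_pred) -> tuple[float, float]:
    """(R-squared, RMSE).  R2 = 1 - SSE/TSS about the sample mean; RMSE is
    the root of the population mean squared error."""
    yt = np.asarray(y_true, dtype=float).ravel()
    yp = np.asarray(y_pred, dtype=float).ravel()
    if yt.size != yp.size or yt.size < 2:
        raise EvaluationError("need equal-length arrays of at least 2 values")
    tss = float(np.sum((yt - yt.mean()) ** 2))
    if tss == 0:
        raise EvaluationError("zero total variance in y_true")
    sse = float(np.sum((yt - yp) ** 2))
    return 1.0 - sse / tss, float(np.sqrt(np.mean((yt - yp) ** 2)))


def percent_improvement(plsr_value: float, nn_value: float) -> int:
    """Signed integer percent change of the network value over the
    regression baseline, rounded half away from zero; positive means the
    network value is higher."""
    if plsr_value == 0:
        raise EvaluationError("zero baseline value")
    x = 100.0 * (nn_value - plsr_value) / plsr_value
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def comparison_table(plsr_metrics: pd.DataFrame, nn_metrics: pd.DataFrame
                     ) -> pd.DataFrame:
    """Model-comparison table: metric x dimension values for both models
    plus the integer percent improvement of the network.

    Both inputs are metric-rows x dimension-columns frames (rows like
    ``r2``/``q2``/``rmse``).
    """
    rows = []
    for metric in plsr_metrics.index:
        for dim in plsr_metrics.columns:
            pv = float(plsr_metrics.loc[metric, dim])
            nv = float(nn_metrics.loc[metric, dim])
            rows.append({"metric": metric, "dimension": dim, "plsr": pv,
                         "nn": nv, "improvement_pct": percent_improvement(pv, nv)})
    return pd.DataFrame(rows)


def top_k_table(values: pd.Series, k: int = 6) -> pd.Series:
    """Ranks 1..k of the k largest |values|; others NaN.

    Ties are broken by canonical descriptor order (then name), so rank
    tables are deterministic and stable under positive rescaling.
    """
    if len(values) < k:
        raise EvaluationError(f"need at least {k} entries")

    def order_key(name):
        try:
            return (CANONICAL_DESCRIPTORS.index(name), str(name))
        except ValueError:
            return (len(CANONICAL_DESCRIPTORS), str(name))

    nonzero = [n for n in values.index if values[n] != 0]
    ranked = sorted(nonzero, key=lambda n: (-abs(values[n]), order_key(n)))[:k]
    out = pd.Series(np.nan, index=values.index, name="rank")
    for pos, name in enumerate(ranked, start=1):
        out[name] = pos
    return out


def rank_table(plsr_loadings: dict[str, pd.DataFrame],
               nn_contributions: dict[str, pd.Series], k: int = 6) -> pd.DataFrame:
    """Descriptor x (dimension, method) rank table.

    PLSR descriptors are ranked by their maximum absolute loading across
    the selected components; network descriptors by absolute averaged
    contribution.
    """
    cols = {}
    for dim, table in plsr_loadings.items():
        cols[(dim, "plsr")] = top_k_table(table.abs().max(axis=1), k)
    for dim, contrib in nn_contributions.items():
        cols[(dim, "nn")] = top_k_table(contrib, k)
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["dimension", "method"])
    return out


def render_table(df: pd.DataFrame, title: str = "") -> str:
    """Aligned plain-text rendering for CLI reports."""
    body = df.to_string(float_format=lambda v: f"{v:.4f}")
    return f"{title}\n{body}" if title else body
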