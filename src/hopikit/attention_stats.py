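"""Aggregation and inferential statistics for AOI fixation metrics.

Fixation records are one row per respondent x object (AOI) with time to
first fixation (TTFF, missing when the object was never fixated), total
fixation duration, and number of fixations; average fixation time is the
derived ratio duration/count.  Aggregation means these metrics per object
across respondents and per macro-category across objects.

The inferential layer wraps the study's comparisons: an omnibus test across
macro-categories (one-way ANOVA or Kruskal-Wallis) with Bonferroni-adjusted
pairwise post-hocs (Dunn's rank test for the Kruskal path, Welch t for the
ANOVA path), OLS regression of object salience on the eye-tracking metrics
and object size, a Spearman correlation between salience and identification
scores, and the paired/unpaired t-test contrasting general- versus
specific-plant salience.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from hopikit.lexicon import Lexicon

logger = logging.getLogger(__name__)

FIXATION_METRICS = ("ttff_s", "tfd_s", "n_fix", "avg_fix_s")


@dataclass
class StatResult:
    """Carrier for one statistical test."""

    test: str
    statistic: float
    df: object | None
    pvalue: float
    pairwise: pd.DataFrame | None = None
    direction: str | None = None
    extra: dict = field(default_factory=dict)

    def __repr__(self) -> str:  # compact, report-friendly
        s = f"{self.test}: stat={self.statistic:.4g}, p={self.pvalue:.4g}"
        if self.df is not None:
            s += f", df={self.df}"
        if self.direction:
            s += f" [{self.direction}]"
        return s


# ---------------------------------------------------------------------------
# aggregation


def validate_fixation_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check schema and ranges; add the derived average fixation time.

    Required columns: ``respondent``, ``object``, ``ttff_s``, ``tfd_s``,
    ``n_fix``.  TTFF may be NaN (never fixated); durations must be
    non-negative; ``avg_fix_s`` is duration/count, NaN when count is 0.
    """
    required = {"respondent", "object", "ttff_s", "tfd_s", "n_fix"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"fixation table missing columns: {sorted(missing)}")
    if (records["tfd_s"] < 0).any() or (records["ttff_s"].dropna() < 0).any():
        raise ValueError("negative durations in fixation table")
    if (records["n_fix"] < 0).any():
        raise ValueError("negative fixation counts")
    out = records.copy()
    out["avg_fix_s"] = np.where(out["n_fix"] > 0, out["tfd_s"] / out["n_fix"].replace(0, np.nan), np.nan)
    return out


def aggregate_fixations(
    records: pd.DataFrame, lexicon: Lexicon
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean fixation metrics per object and per macro-category.

    Missing TTFF values (never fixated) are excluded pairwise from the TTFF
    mean but the row still contributes its fixation count (0) to the count
    mean.  Per-category means average over that category's *objects*, not
    over raw rows, so large categories are not dominated by their most
    numerous objects.  Objects absent from the lexicon fall into the
    ``unknown`` category with a warning.
    """
    rec = validate_fixation_records(records)
    per_object = rec.groupby("object")[list(FIXATION_METRICS)].mean()
    cats = []
    for obj in per_object.index:
        macro = lexicon.macro_of(obj)
        if lexicon.canonical_of(obj) is None:
            logger.warning("object %r not in lexicon; grouped under 'unknown'", obj)
        cats.append(macro)
    per_object = per_object.assign(macro_category=cats)
    per_category = per_object.groupby("macro_category")[list(FIXATION_METRICS)].mean()
    return per_object, per_category


# ---------------------------------------------------------------------------
# omnibus + post-hoc


def _dunn_pairwise(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-sum pairwise z tests with tie correction.

    Pools all observations, ranks them (mid-ranks for ties), and compares
    mean ranks of each pair with the large-sample normal approximation.
    Raw two-sided p-values; adjustment is applied by the caller.
    """
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n_total - 1))
    mean_ranks: dict[str, float] = {}
    sizes: dict[str, int] = {}
    offset = 0
    for g in names:
        n_g = len(groups[g])
        mean_ranks[g] = ranks[offset : offset + n_g].mean()
        sizes[g] = n_g
        offset += n_g
    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt((n_total * (n_total + 1) / 12 - tie_term) * (1 / sizes[a] + 1 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        rows.append({"group_a": a, "group_b": b, "statistic": z, "p_raw": 2 * stats.norm.sf(abs(z))})
    return pd.DataFrame(rows)


def _welch_pairwise(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for a, b in itertools.combinations(list(groups), 2):
        t, p = stats.ttest_ind(groups[a], groups[b], equal_var=False)
        rows.append({"group_a": a, "group_b": b, "statistic": float(t), "p_raw": float(p)})
    return pd.DataFrame(rows)


def compare_categories(
    groups: Mapping[str, Sequence[float]],
    method: Literal["anova", "kruskal"] = "anova",
    posthoc: Literal["dunn", "welch", "none"] | None = None,
) -> StatResult:
    """Omnibus comparison of a metric across >= 2 groups with
    Bonferroni-adjusted pairwise post-hocs.

    ``method='anova'`` runs one-way ANOVA (default post-hoc: Welch pairwise
    t); ``'kruskal'`` runs Kruskal-Wallis (default post-hoc: Dunn's rank
    test).  Adjusted p-values are ``min(1, m * p_raw)`` for m pairs.
    """
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for g, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    if posthoc is None:
        posthoc = "dunn" if method == "kruskal" else "welch"
    k = len(arrays)
    n_total = sum(len(v) for v in arrays.values())
    if method == "anova":
        stat, p = stats.f_oneway(*arrays.values())
        df = (k - 1, n_total - k)
        name = "one-way ANOVA"
    elif method == "kruskal":
        stat, p = stats.kruskal(*arrays.values())
        df = k - 1
        name = "Kruskal-Wallis"
    else:
        raise ValueError(f"unknown method {method!r}")
    pairwise = None
    if posthoc != "none":
        pairwise = _dunn_pairwise(arrays) if posthoc == "dunn" else _welch_pairwise(arrays)
        m = len(pairwise)
        pairwise["p_adjusted"] = np.minimum(1.0, pairwise["p_raw"] * m)
    means = {g: float(v.mean()) for g, v in arrays.items()}
    direction = " > ".join(sorted(means, key=means.get, reverse=True))
    return StatResult(
        test=f"{name} + {posthoc} post-hoc (Bonferroni)" if posthoc != "none" else name,
        statistic=float(stat),
        df=df,
        pvalue=float(p),
        pairwise=pairwise,
        direction=direction,
        extra={"group_means": means},
    )


# ---------------------------------------------------------------------------
# regression and correlation


def regress_salience(
    data: pd.DataFrame,
    response: str = "salience",
    predictors: Sequence[str] = ("ttff_s", "tfd_s", "avg_fix_s", "n_fix", "percent_of_image"),
) -> StatResult:
    """OLS regression of per-object salience on eye-tracking metrics and
    object size.

    Rows with any missing predictor are dropped listwise (with a warning);
    constant predictors are dropped (with a warning) since they are
    collinear with the intercept.  Requires >= 7 complete objects.
    """
    cols = [response, *predictors]
    complete = data[cols].dropna()
    n_dropped = len(data) - len(complete)
    if n_dropped:
        warnings.warn(f"listwise deletion removed {n_dropped} objects", stacklevel=2)
    if len(complete) < 7:
        raise ValueError(f"only {len(complete)} complete objects; need >= 7")
    used = []
    for p in predictors:
        if complete[p].nunique() <= 1:
            warnings.warn(f"predictor {p!r} is constant; dropped", stacklevel=2)
        else:
            used.append(p)
    X = sm.add_constant(complete[used])
    model = sm.OLS(complete[response], X).fit()
    coef = pd.DataFrame(
        {"coef": model.params, "se": model.bse, "t": model.tvalues, "p": model.pvalues}
    )
    return StatResult(
        test="OLS regression",
        statistic=float(model.fvalue),
        df=(int(model.df_model), int(model.df_resid)),
        pvalue=float(model.f_pvalue),
        pairwise=coef,
        extra={"r_squared": float(model.rsquared), "n": int(model.nobs), "predictors": used},
    )


def correlate_salience_identification(
    salience: Sequence[float], identification: Sequence[float]
) -> StatResult:
    """Spearman rank correlation between per-taxon salience and mean
    identification score (ties mid-ranked)."""
    x = np.asarray(salience, dtype=float)
    y = np.asarray(identification, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired taxa of equal length")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rho undefined: constant vector")
    rho, p = stats.spearmanr(x, y)
    return StatResult(test="Spearman correlation", statistic=float(rho), df=len(x) - 2, pvalue=float(p))


def compare_general_specific(
    general: Sequence[float],
    specific: Sequence[float],
    paired: bool = True,
) -> StatResult:
    """t-test contrasting general- versus specific-plant salience.

    Paired by default: the same respondents contribute both a general and
    a specific value.  Direction reports which class has the larger mean.
    """
    g = np.asarray(general, dtype=float)
    s = np.asarray(specific, dtype=float)
    if paired:
        if len(g) != len(s):
            raise ValueError("paired test requires equal-length vectors")
        if len(g) < 2:
            raise ValueError("need >= 2 respondents")
        if np.allclose(g, s):
            t, p = 0.0, 1.0  # zero difference everywhere; scipy yields nan here
        else:
            t, p = stats.ttest_rel(g, s)
        df = len(g) - 1
    else:
        if min(len(g), len(s)) < 2:
            raise ValueError("need >= 2 respondents per class")
        t, p = stats.ttest_ind(g, s, equal_var=False)
        df = None
    direction = "general > specific" if g.mean() > s.mean() else "specific > general"
    if np.isclose(g.mean(), s.mean()):
        direction = "no difference"
    return StatResult(
        test="paired t-test" if paired else "Welch t-test",
        statistic=float(t),
        df=df,
        pvalue=float(p),
        direction=direction,
        extra={"mean_general": float(g.mean()), "mean_specific": float(s.mean())},
    )
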