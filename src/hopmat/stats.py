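"""Cohort statistics: physiological range, timepoint tests, score agreement.

The physiological (reference) range of a symmetry ratio is the central 95%
of all pooled preoperative single-run values, i.e. the interval from the
2.5th to the 97.5th percentile (linear interpolation between order
statistics).  No range is defined for per-day mean values: a handful of
animal means would make the interval arbitrarily strict.  A postoperative
value outside the range indicates lameness.

Timepoint comparisons use the Wilcoxon signed-rank test on paired
per-animal session means — the cohort is small, so the exact null
distribution is computed by enumerating sign assignments (as a convolution
over signed ranks) rather than by a large-sample approximation.
Agreement between the instrument and the visual lameness score is
summarised two ways, Spearman's rank correlation and the coefficient of
determination of a linear fit, so both a monotone and a linear reading are
covered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PhysiologicalRange",
    "StatResult",
    "UndefinedStatisticError",
    "quantile",
    "physiological_range",
    "classify_in_range",
    "wilcoxon_signed_rank",
    "spearman_rho",
    "r_squared",
    "session_summaries",
    "cohort_table",
    "compare_timepoints",
    "score_agreement",
]

RATIO_METRICS = ("ratio_pressure", "ratio_force")


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


@dataclass(frozen=True)
class PhysiologicalRange:
    """Quantile interval of pooled preoperative single-run ratios."""

    metric: str
    lower: float
    upper: float
    q_low: float = 2.5
    q_high: float = 97.5
    n_values: int = 0

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("range lower bound exceeds upper bound")


@dataclass(frozen=True)
class StatResult:
    """Outcome of one hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    n: int
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def quantile(values, q: float) -> float:
    """Order-statistic quantile with linear interpolation.

    The q-th percentile sits at position (n - 1) * q / 100 on the sorted
    sample, interpolating linearly between neighbours; q = 0 and q = 100
    give the minimum and maximum.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("quantile of an empty sample is undefined")
    if not 0 <= q <= 100:
        raise ValueError("q must be in [0, 100]")
    return float(np.percentile(values, q, method="linear"))


def physiological_range(
    preop_values, metric: str, q_low: float = 2.5, q_high: float = 97.5
) -> PhysiologicalRange:
    """Build the reference interval from pooled preoperative single values.

    Values from all animals and all preoperative days are pooled; with
    fewer than 40 values the tail quantiles are unstable, which is warned
    about but still computed.
    """
    values = np.asarray(preop_values, dtype=float)
    if values.size == 0:
        raise ValueError("physiological range needs at least one value")
    if values.size < 40:
        warnings.warn(
            f"physiological range from only {values.size} values is unstable",
            stacklevel=2,
        )
    return PhysiologicalRange(
        metric=metric,
        lower=quantile(values, q_low),
        upper=quantile(values, q_high),
        q_low=q_low,
        q_high=q_high,
        n_values=int(values.size),
    )


def classify_in_range(values, prange: PhysiologicalRange) -> tuple[np.ndarray, float]:
    """Flag which values fall inside the closed reference interval.

    Returns (boolean flags, fraction inside).  The interval is closed:
    a value exactly on a bound counts as physiological.
    """
    values = np.asarray(values, dtype=float)
    flags = (values >= prange.lower) & (values <= prange.upper)
    fraction = float(flags.mean()) if values.size else float("nan")
    return flags, fraction


def _exact_signed_rank_pvalue(doubled_ranks: np.ndarray, w2_obs: int) -> float:
    """Two-sided exact p-value by convolving the signed-rank distribution.

    Ranks are doubled so that midranks from ties become integers; the
    distribution of the doubled positive-rank sum over all 2^m equally
    likely sign assignments is built by polynomial convolution.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    denom = counts.sum()  # == 2 ** m, exact in float64 for m <= 25
    p_le = counts[: w2_obs + 1].sum() / denom
    p_ge = counts[w2_obs:].sum() / denom
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(x, y, mode: str = "auto") -> StatResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped before ranking and tied absolute
    differences receive their average rank.  ``mode`` selects the null
    distribution: ``exact`` enumerates all 2^m sign assignments of the m
    nonzero differences (via convolution, feasible through m = 25),
    ``normal_approximation`` uses the tie-corrected large-sample normal
    with a continuity correction, and ``auto`` picks exact for m <= 25.  The statistic reported is W+,
    the sum of ranks of the positive differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("x and y must be equal-length non-empty 1-D sequences")
    if mode not in ("exact", "normal_approximation", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    d = x - y
    d = d[d != 0.0]
    m = d.size
    if m == 0:
        warnings.warn("all paired differences are zero; test is degenerate", stacklevel=2)
        return StatResult("wilcoxon_signed_rank", 0.0, 1.0, 0, "degenerate")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if mode == "auto":
        mode = "exact" if m <= 25 else "normal_approximation"
    if mode == "exact":
        doubled = np.rint(2 * ranks).astype(np.int64)
        p = _exact_signed_rank_pvalue(doubled, int(round(2 * w_plus)))
        return StatResult("wilcoxon_signed_rank", w_plus, p, m, "exact")
    mu = m * (m + 1) / 4.0
    var = m * (m + 1) * (2 * m + 1) / 24.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return StatResult("wilcoxon_signed_rank", w_plus, 1.0, m, "degenerate")
    dev = w_plus - mu
    dev = np.sign(dev) * max(0.0, abs(dev) - 0.5)  # continuity correction
    z = dev / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return StatResult("wilcoxon_signed_rank", w_plus, p, m, "normal_approximation")


def spearman_rho(x, y) -> float:
    """Tie-corrected Spearman rank correlation.

    Pearson correlation of the average ranks; undefined (raises) when the
    ranks of either input have zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman_rho needs two equal-length sequences, n >= 3")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedStatisticError("rank correlation undefined for constant input")
    return float(sps.pearsonr(rx, ry).statistic)


def r_squared(x, y) -> float:
    """Coefficient of determination of the least-squares line of y on x.

    Equals the squared Pearson correlation; raises when either input is
    constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("r_squared needs two equal-length sequences, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("R^2 undefined for constant input")
    return float(sps.pearsonr(x, y).statistic ** 2)


def session_summaries(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-animal, per-session mean and SD of each symmetry ratio.

    ``metrics`` is the per-run table; if it carries a ``qc_accepted``
    column only accepted runs enter the summary.  SD is NaN (undefined)
    for single-run sessions, flagged via ``n_runs``.
    """
    df = metrics
    if "qc_accepted" in df.columns:
        df = df[df["qc_accepted"].astype(bool)]
    if df.empty:
        raise ValueError("no accepted runs to summarise")
    grouped = df.groupby(["animal_id", "session_id"], sort=True)
    out = grouped.agg(
        n_runs=("run_id", "size"),
        mean_ratio_pressure=("ratio_pressure", "mean"),
        sd_ratio_pressure=("ratio_pressure", lambda v: v.std(ddof=1)),
        mean_ratio_force=("ratio_force", "mean"),
        sd_ratio_force=("ratio_force", lambda v: v.std(ddof=1)),
    ).reset_index()
    return out


def cohort_table(
    summaries: pd.DataFrame,
    metrics: pd.DataFrame,
    sessions: list[str],
    metric: str,
    preop_sessions: list[str] | None = None,
) -> pd.DataFrame:
    """Per-day cohort summary of one ratio, single values and animal means.

    One row per session with range / mean / SD of the single-run values and
    of the per-animal session means, plus — when ``preop_sessions`` is
    given — a pooled preoperative row whose mean-value columns are computed
    from each animal's across-day mean (which is why the pooled mean-value
    range is narrower than any single day's).
    """
    if metric not in RATIO_METRICS:
        raise ValueError(f"metric must be one of {RATIO_METRICS}")
    df = metrics
    if "qc_accepted" in df.columns:
        df = df[df["qc_accepted"].astype(bool)]
    mean_col = f"mean_{metric}"

    def _row(label: str, singles: np.ndarray, means: np.ndarray) -> dict:
        return {
            "session": label,
            "n_single": singles.size,
            "single_min": singles.min(),
            "single_max": singles.max(),
            "single_mean": singles.mean(),
            "single_sd": singles.std(ddof=1) if singles.size > 1 else np.nan,
            "mean_min": means.min(),
            "mean_max": means.max(),
            "mean_mean": means.mean(),
            "mean_sd": means.std(ddof=1) if means.size > 1 else np.nan,
        }

    rows = []
    for sid in sessions:
        singles = df.loc[df["session_id"] == sid, metric].to_numpy()
        means = summaries.loc[summaries["session_id"] == sid, mean_col].to_numpy()
        if singles.size == 0 or means.size == 0:
            raise ValueError(f"session {sid!r} has no accepted runs")
        rows.append(_row(sid, singles, means))
    if preop_sessions:
        singles = df.loc[df["session_id"].isin(preop_sessions), metric].to_numpy()
        per_animal = (
            summaries[summaries["session_id"].isin(preop_sessions)]
            .groupby("animal_id")[mean_col]
            .mean()
            .to_numpy()
        )
        rows.append(_row("preoperative_pooled", singles, per_animal))
    return pd.DataFrame(rows)


def compare_timepoints(
    summaries: pd.DataFrame,
    session_pairs: list[tuple[str, str]],
    metrics: tuple[str, ...] = RATIO_METRICS,
    mode: str = "auto",
) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank tests between sessions, per metric.

    Pairs the per-animal session means; animals missing one of the two
    sessions are dropped with a warning.  Significance is flagged at both
    0.05 and 0.01.
    """
    records = []
    for sid_a, sid_b in session_pairs:
        a = summaries[summaries["session_id"] == sid_a].set_index("animal_id")
        b = summaries[summaries["session_id"] == sid_b].set_index("animal_id")
        shared = a.index.intersection(b.index)
        dropped = set(a.index.symmetric_difference(b.index))
        if dropped:
            warnings.warn(
                f"unpaired animals dropped for {sid_a} vs {sid_b}: {sorted(dropped)}",
                stacklevel=2,
            )
        if len(shared) == 0:
            raise ValueError(f"no paired animals between {sid_a!r} and {sid_b!r}")
        for metric in metrics:
            col = f"mean_{metric}"
            res = wilcoxon_signed_rank(
                a.loc[shared, col].to_numpy(), b.loc[shared, col].to_numpy(), mode=mode
            )
            records.append(
                {
                    "session_a": sid_a,
                    "session_b": sid_b,
                    "metric": metric,
                    "n_pairs": len(shared),
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "method": res.method,
                    "significant_0.05": res.p_value < 0.05,
                    "significant_0.01": res.p_value < 0.01,
                }
            )
    return pd.DataFrame(records)


def score_agreement(
    scores: pd.DataFrame,
    summaries: pd.DataFrame,
    metrics: tuple[str, ...] = RATIO_METRICS,
) -> dict[str, dict]:
    """Agreement between visual lameness scores and instrument ratios.

    Matches scores and session summaries on (animal_id, session_id), pools
    the matched points, and reports per metric: Spearman's rho, the R^2 of
    a linear fit, and the min/max band of mean ratios observed at each
    score value.  Raises if there is no overlap, and surfaces the
    undefined-correlation case (all scores equal) instead of returning 0.
    """
    merged = scores.merge(summaries, on=["animal_id", "session_id"], how="inner")
    if merged.empty:
        raise ValueError("no (animal, session) overlap between scores and summaries")
    out: dict[str, dict] = {}
    for metric in metrics:
        col = f"mean_{metric}"
        x = merged["score"].to_numpy(dtype=float)
        y = merged[col].to_numpy(dtype=float)
        bands = (
            merged.groupby("score")[col]
            .agg(n="size", ratio_min="min", ratio_max="max")
            .reset_index()
        )
        out[metric] = {
            "rho": spearman_rho(x, y),
            "r_squared": r_squared(x, y),
            "n": int(merged.shape[0]),
            "per_score": bands,
        }
    return out
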