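"""Candidate cis-RE calling from depletion trajectories.

For every tile the screen yields replicate percentage measurements in two
conditions (NE, buffer) at each sequenced round.  The calling statistic:

1. average the replicate percentages per condition and round;
2. form the per-round depletion ratio  mean_NE / mean_buffer;
3. fit an ordinary least-squares slope of ratio against round number
   (default rounds 1, 4, 7, 10);
4. at every sequenced round, compare the NE and buffer replicate
   percentages with a two-sided two-sample Student's t-test (pooled
   variance by default; Welch available);
5. call a tile a candidate iff the slope is negative AND every per-round
   p-value is below alpha (default 0.05).  No multiplicity adjustment
   gates the call — the screen deliberately keeps every possible positive
   and defers specificity to downstream validation — though a BH-FDR
   column is reported for reference.

Only the slope's sign enters the call, so using round numbers versus round
indices as the regression abscissa cannot change any call (the map between
the two is affine increasing); round numbers are the default.  Ratios are
fit on the natural scale; a log-ratio mode is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import PercentageMatrix

__all__ = [
    "CallingConfig",
    "condition_means",
    "ratio_trajectory",
    "fit_slope",
    "per_round_test",
    "call_candidates",
    "run_depletion_calling",
    "validation_false_positive_rate",
]

_TINY_P = 5e-324  # degenerate zero-variance, unequal-means convention


@dataclass(frozen=True)
class CallingConfig:
    alpha: float = 0.05
    rounds: tuple[int, ...] = (1, 4, 7, 10)
    slope_x: str = "round_number"  # or "round_index"
    test: str = "student_pooled"  # or "welch"
    test_scope: str = "per_round"  # or "all_rounds": one test pooling every round
    log_ratio: bool = False
    adjust: str = "none"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.slope_x not in ("round_number", "round_index"):
            raise ValueError(f"unknown slope_x {self.slope_x!r}")
        if self.test not in ("student_pooled", "welch"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.test_scope not in ("per_round", "all_rounds"):
            raise ValueError(f"unknown test_scope {self.test_scope!r}")


def condition_means(pct: PercentageMatrix) -> pd.DataFrame:
    """Arithmetic mean of replicate fractions per (condition, round).

    Returns a DataFrame indexed by tile_id with (condition, round)
    MultiIndex columns.  Every (condition, round, replicate) cell must be
    present and finite.
    """
    frac = pct.fractions
    if frac.isna().any().any():
        bad = frac.isna().stack([0, 1, 2], future_stack=True)
        cell = bad[bad].index[0]
        raise ValueError(f"missing replicate cell {cell}")
    n_reps = frac.columns.to_frame(index=False).groupby(["condition", "round"]).size()
    if (n_reps < 2).any():
        raise ValueError("need >= 2 replicates per (condition, round)")
    return frac.T.groupby(level=["condition", "round"]).mean().T


def ratio_trajectory(means: pd.DataFrame) -> pd.DataFrame:
    """Per-round NE/buffer mean-percentage ratio, one column per round."""
    ne = means["NE"]
    buf = means["buffer"]
    if (buf.to_numpy() <= 0).any():
        raise ValueError("zero buffer mean percentage; use a pseudocount upstream")
    return ne / buf


def fit_slope(ratios, rounds=(1, 4, 7, 10)) -> float:
    """OLS slope of the depletion ratio against round number.

    Closed form: sum((x - x̄)(y - ȳ)) / sum((x - x̄)²).
    """
    y = np.asarray(ratios, dtype=float)
    x = np.asarray(rounds, dtype=float)
    if y.shape != x.shape:
        raise ValueError("ratios and rounds must have equal length")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite ratio")
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


def _fit_slopes(ratio_df: pd.DataFrame, x: np.ndarray) -> pd.Series:
    y = ratio_df.to_numpy(dtype=float)
    xc = x - x.mean()
    slopes = (y - y.mean(axis=1, keepdims=True)) @ xc / (xc @ xc)
    return pd.Series(slopes, index=ratio_df.index, name="slope")


def per_round_test(ne_pcts, buffer_pcts, config: CallingConfig | None = None) -> float:
    """Two-sided two-sample t p-value for one tile at one round.

    Pooled-variance Student's t by default.  Degenerate zero-variance
    inputs: equal means → p = 1; unequal means → p → 0 (smallest positive
    float, so the value still sorts and thresholds sanely).
    """
    config = config or CallingConfig()
    a = np.asarray(ne_pcts, dtype=float)
    b = np.asarray(buffer_pcts, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite percentage")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else _TINY_P
    with warnings.catch_warnings():
        # near-identical replicates trip scipy's precision warning; the
        # fully degenerate case is handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=(config.test == "student_pooled"))
    return float(res.pvalue)


def _per_round_pvalues(
    pct: PercentageMatrix, rounds: tuple[int, ...], config: CallingConfig
) -> pd.DataFrame:
    """Vectorized per-round t-tests over all tiles; columns = rounds."""
    frac = pct.fractions
    out = {}
    for r in rounds:
        a = frac["NE"][r].to_numpy(dtype=float)  # tiles x replicates
        b = frac["buffer"][r].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(
                a, b, axis=1, equal_var=(config.test == "student_pooled")
            )
        p = np.asarray(res.pvalue, dtype=float)
        degenerate = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
        if degenerate.any():
            eq = np.isclose(a.mean(axis=1), b.mean(axis=1))
            p = np.where(degenerate & eq, 1.0, p)
            p = np.where(degenerate & ~eq, _TINY_P, p)
        out[r] = p
    return pd.DataFrame(out, index=frac.index)


def _all_rounds_pvalue(
    pct: PercentageMatrix, rounds: tuple[int, ...], config: CallingConfig
) -> pd.Series:
    """Alternative single-test mode: one t-test pooling all rounds' replicates."""
    frac = pct.fractions
    a = np.concatenate([frac["NE"][r].to_numpy(dtype=float) for r in rounds], axis=1)
    b = np.concatenate([frac["buffer"][r].to_numpy(dtype=float) for r in rounds], axis=1)
    res = stats.ttest_ind(a, b, axis=1, equal_var=(config.test == "student_pooled"))
    return pd.Series(np.asarray(res.pvalue, dtype=float), index=frac.index)


def call_candidates(
    records: pd.DataFrame, config: CallingConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Apply the conjunctive filter to a record table with a ``slope``
    column and per-round ``pvalue_<r>`` columns.

    Sets ``is_candidate = (slope < 0) AND (every pvalue < alpha)`` and
    returns ``(records, summary)`` where summary counts tiles tested,
    slope-negative tiles, and candidates.
    """
    config = config or CallingConfig()
    records = records.copy()
    pcols = [c for c in records.columns if str(c).startswith("pvalue_")]
    if not pcols:
        raise ValueError("records lack pvalue_<round> columns")
    sig = (records[pcols] < config.alpha).all(axis=1)
    records["is_candidate"] = (records["slope"] < 0) & sig
    summary = {
        "n_tested": int(len(records)),
        "n_slope_negative": int((records["slope"] < 0).sum()),
        "n_candidates": int(records["is_candidate"].sum()),
    }
    return records, summary


def run_depletion_calling(
    pct: PercentageMatrix, config: CallingConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Full calling pipeline: percentages → per-tile record table + summary.

    The table is indexed by tile_id with columns ``mean_NE_<r>``,
    ``mean_buffer_<r>``, ``ratio_<r>``, ``slope``, ``pvalue_<r>``,
    ``q_value`` (BH over each tile's worst per-round p-value; reference
    only, never gates the call) and ``is_candidate``.
    """
    config = config or CallingConfig()
    rounds = tuple(config.rounds)
    means = condition_means(pct)
    present = set(means["NE"].columns)
    missing = [r for r in rounds if r not in present]
    if missing:
        raise ValueError(f"rounds {missing} not present in the percentage matrix")

    ratios = ratio_trajectory(means)[list(rounds)]
    y = np.log(ratios) if config.log_ratio else ratios
    if config.slope_x == "round_number":
        x = np.asarray(rounds, dtype=float)
    else:
        x = np.arange(len(rounds), dtype=float)
    slopes = _fit_slopes(y, x)

    records = pd.DataFrame(index=means.index)
    for r in rounds:
        records[f"mean_NE_{r}"] = means[("NE", r)]
        records[f"mean_buffer_{r}"] = means[("buffer", r)]
        records[f"ratio_{r}"] = ratios[r]
    records["slope"] = slopes

    if config.test_scope == "all_rounds":
        p = _all_rounds_pvalue(pct, rounds, config)
        for r in rounds:
            records[f"pvalue_{r}"] = p  # single test replicated across columns
    else:
        pvals = _per_round_pvalues(pct, rounds, config)
        for r in rounds:
            records[f"pvalue_{r}"] = pvals[r]

    worst = records[[f"pvalue_{r}" for r in rounds]].max(axis=1)
    records["q_value"] = _benjamini_hochberg(worst.to_numpy())
    return call_candidates(records, config)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def validation_false_positive_rate(n_validated: int, n_tested: int) -> float:
    """Empirical false-positive rate of a validation experiment: the
    fraction of tested candidates that failed orthogonal validation
    (e.g. 8 of 10 candidates confirmed by EMSA → 0.2)."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    if not 0 <= n_validated <= n_tested:
        raise ValueError("n_validated must lie in [0, n_tested]")
    return (n_tested - n_validated) / n_tested
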