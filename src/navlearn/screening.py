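"""Behavioural and metric screening.

Two screens precede the brain-behaviour correlations:

* a per-participant permutation test of learning-curve fit quality — the
  trial order is shuffled many times, the fit statistic (R^2) is recomputed
  for each shuffle, and participants whose true R^2 does not exceed the
  upper edge of the central 68% of their own null distribution (the 84th
  percentile, i.e. "1 SD" in the normal reading) are flagged as showing no
  behavioural evidence of learning;
* a univariate median-absolute-deviation (MAD) outlier filter applied to
  each tract metric separately, removing values beyond 2.5 scaled MADs from
  the median.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .learning import LatencySeries, _loglog_batch, _quadratic_batch

__all__ = [
    "PermutationNullResult",
    "OutlierMask",
    "permutation_learning_null",
    "flag_nonlearners",
    "mad_outlier_filter",
]

#: Normal-consistency constant: scaled MAD estimates the SD for Gaussian data.
MAD_CONSISTENCY = 1.4826


@dataclass(frozen=True)
class PermutationNullResult:
    participant_id: str
    true_r_squared: float
    null_r_squared: np.ndarray
    threshold: float
    excluded: bool
    n_perm: int
    pipeline_mode: str
    threshold_rule: str


@dataclass(frozen=True)
class OutlierMask:
    values: np.ndarray
    median: float
    mad_scaled: float
    lower: float
    upper: float
    keep: np.ndarray


def _r_squared_batch(Y: np.ndarray, pipeline_mode: str) -> np.ndarray:
    """Fit statistic per row of Y under the requested pipeline mode.

    "full" re-derives the quadratic cut-off for each (shuffled) series and
    fits the power model up to it — the same statistic as computed on the
    observed ordering.  "all_trials" fits the power model to every trial.
    """
    Y = np.atleast_2d(Y)
    if pipeline_mode == "full":
        _, _, cutoffs = _quadratic_batch(Y)
    elif pipeline_mode == "all_trials":
        cutoffs = np.full(Y.shape[0], Y.shape[1], dtype=int)
    else:
        raise ValueError(f"unknown pipeline_mode {pipeline_mode!r}")
    _, _, r2 = _loglog_batch(Y, cutoffs)
    return r2


def permutation_learning_null(
    series: LatencySeries,
    n_perm: int = 500,
    pipeline_mode: str = "full",
    rng: np.random.Generator | None = None,
    threshold_rule: str = "percentile",
    ci_level: float = 0.68,
) -> PermutationNullResult:
    """Permutation null for one participant's learning-curve fit.

    Each permutation uniformly reorders the trial latencies and recomputes
    the fit R^2.  The exclusion threshold is, by default, the empirical
    ``50 + 100*ci_level/2`` percentile of the null (the upper edge of its
    central 68% interval); the ``"mean_plus_sd"`` variant uses the null mean
    plus one null SD.  A participant is excluded when the true R^2 does not
    exceed the threshold.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    if not 0 < ci_level < 1:
        raise ValueError(f"ci_level must lie in (0, 1), got {ci_level}")
    if rng is None:
        rng = np.random.default_rng()
    y = series.latencies
    true_r2 = float(_r_squared_batch(y[None, :], pipeline_mode)[0])
    perms = np.array([rng.permutation(series.n_trials) for _ in range(n_perm)])
    null = _r_squared_batch(y[perms], pipeline_mode)
    if threshold_rule == "percentile":
        threshold = float(np.percentile(null, 50.0 + 100.0 * ci_level / 2.0))
    elif threshold_rule == "mean_plus_sd":
        threshold = float(null.mean() + null.std(ddof=1))
    else:
        raise ValueError(f"unknown threshold_rule {threshold_rule!r}")
    return PermutationNullResult(
        participant_id=series.participant_id,
        true_r_squared=true_r2,
        null_r_squared=null,
        threshold=threshold,
        excluded=bool(true_r2 <= threshold),
        n_perm=int(n_perm),
        pipeline_mode=pipeline_mode,
        threshold_rule=threshold_rule,
    )


def flag_nonlearners(
    cohort: Iterable[LatencySeries],
    n_perm: int = 500,
    seed: "int | np.random.SeedSequence | None" = None,
    pipeline_mode: str = "full",
    threshold_rule: str = "percentile",
    ci_level: float = 0.68,
) -> tuple[pd.DataFrame, list[PermutationNullResult]]:
    """Apply the permutation screen to every participant in a cohort.

    Each participant gets an independent RNG substream spawned from the
    master seed (SeedSequence spawning by participant position, so adding
    participants at the end never perturbs earlier streams).  Returns the
    exclusion table (participant_id, true_r2, threshold, excluded) and the
    per-participant null results.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("cohort must contain at least one participant")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(len(cohort))
    results = [
        permutation_learning_null(
            s,
            n_perm=n_perm,
            pipeline_mode=pipeline_mode,
            rng=np.random.default_rng(stream),
            threshold_rule=threshold_rule,
            ci_level=ci_level,
        )
        for s, stream in zip(cohort, streams)
    ]
    table = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in results],
            "true_r2": [r.true_r_squared for r in results],
            "threshold": [r.threshold for r in results],
            "excluded": [r.excluded for r in results],
        }
    )
    return table, results


def mad_outlier_filter(
    values: Sequence[float],
    threshold: float = 2.5,
    consistency_constant: float = MAD_CONSISTENCY,
) -> OutlierMask:
    """Two-sided MAD outlier screen.

    A value is kept when ``|x - median| <= threshold * mad_scaled`` with
    ``mad_scaled = consistency_constant * median(|x - median|)``.  When the
    MAD is zero (over half the values identical) only values equal to the
    median are kept.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError(f"need at least 3 values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    med = float(np.median(x))
    mad_scaled = float(consistency_constant * np.median(np.abs(x - med)))
    lower = med - threshold * mad_scaled
    upper = med + threshold * mad_scaled
    keep = (x >= lower) & (x <= upper)
    return OutlierMask(
        values=x,
        median=med,
        mad_scaled=mad_scaled,
        lower=lower,
        upper=upper,
        keep=keep,
    )
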