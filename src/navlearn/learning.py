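"""Per-participant learning-curve estimation.

A participant's navigational learning across trials is summarised by the
power model ``time = a * x**b`` fitted to the trial latencies, where the
exponent ``b`` (more negative = faster learning) is the learning-rate index.
Because many participants learn quickly, plateau, and then behave
erratically, the power model is fitted only up to a data-driven cut-off
trial: the trough (vertex) of a second-order polynomial fitted to all
trials.  An alternative non-slope measure, the mean latency up to the
cut-off, is derived alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "LatencySeries",
    "QuadraticFit",
    "PowerFit",
    "LearningRateResult",
    "fit_quadratic_cutoff",
    "fit_power_model",
    "mean_latency_to_cutoff",
    "derive_learning_rate",
    "LearningCurveModel",
]

#: Lower clamp for the cut-off trial: a two-parameter fit needs at least four
#: points to retain residual degrees of freedom.
MIN_CUTOFF = 4


@dataclass(frozen=True)
class LatencySeries:
    """One participant's per-trial times to reach the hidden sensor.

    Parameters
    ----------
    participant_id : str
        Identifier carried through every downstream table.
    latencies : ndarray
        Seconds per trial, trial index x = 1..n.  All values must lie in
        (0, t_max]; timed-out trials enter at ``t_max`` (the sensor is
        revealed at the timeout, so the recorded latency is the ceiling).
    t_max : float
        Trial timeout in seconds.
    """

    participant_id: str
    latencies: np.ndarray
    t_max: float = 60.0

    def __post_init__(self) -> None:
        lat = np.asarray(self.latencies, dtype=float)
        object.__setattr__(self, "latencies", lat)
        if lat.ndim != 1 or lat.size < MIN_CUTOFF:
            raise ValueError(
                f"latency series {self.participant_id!r} needs >= {MIN_CUTOFF} "
                f"trials, got shape {lat.shape}"
            )
        if not np.all(np.isfinite(lat)):
            raise ValueError(f"non-finite latency in series {self.participant_id!r}")
        if np.any(lat <= 0) or np.any(lat > self.t_max):
            raise ValueError(
                f"latencies of {self.participant_id!r} must lie in (0, {self.t_max}]"
            )

    @property
    def n_trials(self) -> int:
        return int(self.latencies.size)


@dataclass(frozen=True)
class QuadraticFit:
    """OLS fit of latency on (1, x, x^2) and the derived cut-off trial."""

    c0: float
    c1: float
    c2: float
    vertex: float
    cutoff_trial: int
    used_all_trials: bool


@dataclass(frozen=True)
class PowerFit:
    """Fitted power model ``time = a * x**b`` on trials 1..n_used.

    ``r_squared`` is the coefficient of determination on the scale the fit
    was performed: the log-log scale for ``loglog_ols`` (a linear fit to the
    log-transformed data), the raw scale for ``nonlinear_ls``.
    """

    a: float
    b: float
    r_squared: float
    n_used: int
    method: str = "loglog_ols"


@dataclass(frozen=True)
class LearningRateResult:
    participant_id: str
    power: PowerFit
    quadratic: QuadraticFit
    mean_latency_to_cutoff: float


# ---------------------------------------------------------------------------
# Batch internals.  The permutation screen refits thousands of shuffled
# series, so the quadratic cut-off and the log-log power fit are implemented
# as closed-form array operations over a (m, T) matrix of series.
# ---------------------------------------------------------------------------


def _quad_design_pinv(n_trials: int) -> np.ndarray:
    x = np.arange(1, n_trials + 1, dtype=float)
    return np.linalg.pinv(np.column_stack([np.ones(n_trials), x, x * x]))


def _quadratic_batch(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coefficients, vertices and cut-off trials for each row of ``Y``.

    Returns (coeffs (m,3), vertex (m,), cutoff (m,) int).  Rows without an
    interior trough (c2 <= 0 or vertex outside [MIN_CUTOFF, T]) get
    cutoff = T.  The vertex is rounded half-up to the nearest trial.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    m, T = Y.shape
    coeffs = Y @ _quad_design_pinv(T).T
    c1, c2 = coeffs[:, 1], coeffs[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        vertex = np.where(c2 != 0, -c1 / (2 * c2), np.nan)
    has_trough = (c2 > 0) & (vertex >= MIN_CUTOFF) & (vertex <= T)
    cutoff = np.full(m, T, dtype=int)
    cutoff[has_trough] = np.floor(vertex[has_trough] + 0.5).astype(int)
    np.clip(cutoff, MIN_CUTOFF, T, out=cutoff)
    return coeffs, vertex, cutoff


def _loglog_batch(
    Y: np.ndarray, cutoffs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form log-log OLS power fits per row, each up to its cut-off.

    Returns (a, b, r_squared) arrays.  Rows are grouped by cut-off so each
    group is one vectorised computation with a shared log-trial design.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    m, T = Y.shape
    cutoffs = np.asarray(cutoffs, dtype=int)
    logY = np.log(Y)
    lx_full = np.log(np.arange(1, T + 1, dtype=float))
    a = np.empty(m)
    b = np.empty(m)
    r2 = np.empty(m)
    for c in np.unique(cutoffs):
        rows = np.flatnonzero(cutoffs == c)
        lx = lx_full[:c]
        lxc = lx - lx.mean()
        sxx = lxc @ lxc
        ly = logY[rows, :c]
        lyc = ly - ly.mean(axis=1, keepdims=True)
        sxy = lyc @ lxc
        syy = np.einsum("ij,ij->i", lyc, lyc)
        slope = sxy / sxx
        a[rows] = np.exp(ly.mean(axis=1) - slope * lx.mean())
        b[rows] = slope
        with np.errstate(divide="ignore", invalid="ignore"):
            rr = np.where(syy > 0, slope * slope * sxx / syy, 0.0)
        r2[rows] = np.clip(rr, 0.0, 1.0)
    return a, b, r2


# ---------------------------------------------------------------------------
# Public per-series operations
# ---------------------------------------------------------------------------


def fit_quadratic_cutoff(series: LatencySeries) -> QuadraticFit:
    """Locate the cut-off trial as the trough of a quadratic fit.

    A second-order polynomial is fitted by OLS to the latencies over all
    trials.  When the parabola opens upward (c2 > 0) and its vertex
    -c1/(2 c2) lies within [4, n_trials], the cut-off is the vertex rounded
    half-up to the nearest trial; otherwise there is no interior trough to
    trim at, and all trials are used.
    """
    coeffs, vertex, cutoff = _quadratic_batch(series.latencies[None, :])
    c0, c1, c2 = (float(v) for v in coeffs[0])
    T = series.n_trials
    used_all = int(cutoff[0]) == T and not (
        c2 > 0 and MIN_CUTOFF <= vertex[0] <= T and np.floor(vertex[0] + 0.5) == T
    )
    return QuadraticFit(
        c0=c0,
        c1=c1,
        c2=c2,
        vertex=float(vertex[0]) if np.isfinite(vertex[0]) else float("nan"),
        cutoff_trial=int(cutoff[0]),
        used_all_trials=bool(used_all),
    )


def fit_power_model(
    series: LatencySeries, cutoff: int, method: str = "loglog_ols"
) -> PowerFit:
    """Fit ``time = a * x**b`` to trials 1..cutoff.

    ``loglog_ols`` (default) regresses ln(latency) on ln(x); b is the slope,
    a = exp(intercept) and r_squared is the OLS R^2 on the log-log scale
    (this is the linear fit to the log-transformed data).  ``nonlinear_ls``
    refines (a, b) by least squares on the raw scale, initialised from the
    log-log solution, with R^2 on the raw scale.
    """
    cutoff = int(cutoff)
    if not MIN_CUTOFF <= cutoff <= series.n_trials:
        raise ValueError(
            f"cutoff must lie in [{MIN_CUTOFF}, {series.n_trials}], got {cutoff}"
        )
    if method not in ("loglog_ols", "nonlinear_ls"):
        raise ValueError(f"unknown power-fit method {method!r}")
    a, b, r2 = (
        float(v[0])
        for v in _loglog_batch(series.latencies[None, :], np.array([cutoff]))
    )
    if method == "nonlinear_ls":
        x = np.arange(1, cutoff + 1, dtype=float)
        y = series.latencies[:cutoff]
        try:
            (a, b), _ = curve_fit(
                lambda x, a, b: a * x**b, x, y, p0=[a, b], maxfev=10_000
            )
        except RuntimeError:
            pass  # fall back to the log-log solution
        resid = y - a * x**b
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
        r2 = float(np.clip(r2, 0.0, 1.0))
        a, b = float(a), float(b)
    return PowerFit(a=a, b=b, r_squared=r2, n_used=cutoff, method=method)


def mean_latency_to_cutoff(series: LatencySeries, cutoff: int) -> float:
    """Arithmetic mean of the latencies over trials 1..cutoff (seconds)."""
    cutoff = int(cutoff)
    if not 1 <= cutoff <= series.n_trials:
        raise ValueError(f"cutoff must lie in [1, {series.n_trials}], got {cutoff}")
    return float(series.latencies[:cutoff].mean())


def derive_learning_rate(
    series: LatencySeries, method: str = "loglog_ols"
) -> LearningRateResult:
    """Cut-off, power fit and mean latency for one participant.

    Deterministic composition: quadratic-trough cut-off, then the power fit
    on trials up to the cut-off, then the mean latency over the same trials.
    """
    quad = fit_quadratic_cutoff(series)
    power = fit_power_model(series, quad.cutoff_trial, method=method)
    return LearningRateResult(
        participant_id=series.participant_id,
        power=power,
        quadratic=quad,
        mean_latency_to_cutoff=mean_latency_to_cutoff(series, quad.cutoff_trial),
    )


class LearningCurveModel:
    """Power learning-curve model for a single participant's latencies.

    Thin model/results wrapper over :func:`derive_learning_rate`::

        res = LearningCurveModel(series).fit()
        print(res.summary())
    """

    def __init__(self, series: LatencySeries):
        self.series = series

    @classmethod
    def from_latencies(
        cls, latencies, participant_id: str = "p", t_max: float = 60.0
    ) -> "LearningCurveModel":
        return cls(LatencySeries(participant_id, np.asarray(latencies, float), t_max))

    def fit(self, method: str = "loglog_ols") -> "LearningCurveResults":
        return LearningCurveResults(self, derive_learning_rate(self.series, method))


@dataclass(frozen=True)
class LearningCurveResults:
    model: LearningCurveModel
    result: LearningRateResult

    @property
    def b(self) -> float:
        return self.result.power.b

    @property
    def a(self) -> float:
        return self.result.power.a

    @property
    def r_squared(self) -> float:
        return self.result.power.r_squared

    @property
    def cutoff_trial(self) -> int:
        return self.result.quadratic.cutoff_trial

    def predict(self, trials=None) -> np.ndarray:
        """Model latencies a * x**b at the given (1-based) trial indices."""
        if trials is None:
            trials = np.arange(1, self.model.series.n_trials + 1)
        return self.a * np.asarray(trials, float) ** self.b

    def summary(self) -> str:
        r = self.result
        lines = [
            f"Learning curve fit: participant {r.participant_id}",
            f"  method            {r.power.method}",
            f"  cutoff trial      {r.quadratic.cutoff_trial}"
            + ("  (no interior trough; all trials)" if r.quadratic.used_all_trials else ""),
            f"  a (initial s)     {r.power.a:10.4f}",
            f"  b (learning rate) {r.power.b:10.4f}",
            f"  R^2               {r.power.r_squared:10.4f}",
            f"  mean latency to cutoff {r.mean_latency_to_cutoff:8.3f} s",
        ]
        return "\n".join(lines)
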