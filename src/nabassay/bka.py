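"""Bacterial-killing assay (BKA) scoring from OD600 growth curves.

A plasma sample's bactericidal capacity is summarised by how long the
bacteria it was incubated with take to reach OD600 = 0.3: the "time to
threshold". Growth curves show a lag, a roughly linear rise, and usually a
plateau; the linear rise is isolated, fitted by ordinary least squares, and
the fitted line inverted at the threshold. Samples whose bacteria never
grow within the 14 h incubation are right-censored at 15 h. Killing is
classified relative to plasma-free controls: crossing no later than the
control mean is "no killing", a delayed crossing is "intermediate killing",
and no growth at all is "absolute killing".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _sps

from .config import AssayConfig

logger = logging.getLogger(__name__)

#: r-squared differences below this are treated as ties in window selection.
_R2_TIE_TOL = 1e-9


class KillingClass(str, Enum):
    NO_KILLING = "no_killing"
    INTERMEDIATE_KILLING = "intermediate_killing"
    ABSOLUTE_KILLING = "absolute_killing"


class CurveRole(str, Enum):
    PLASMA = "plasma"
    CONTROL = "control"
    HEAT_INACTIVATED = "heat_inactivated"


@dataclass(frozen=True)
class GrowthCurve:
    """One sample's OD600 time series over the incubation.

    ``times`` (hours) must be strictly increasing and ``od`` non-negative,
    with at least three observations.
    """

    sample_id: str
    role: CurveRole
    times: tuple[float, ...]
    od: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.od, dtype=float)
        if t.size != y.size or t.size < 3:
            raise ValueError(
                f"curve {self.sample_id!r}: need >=3 matched (time, od) points"
            )
        if not np.all(np.diff(t) > 0):
            raise ValueError(f"curve {self.sample_id!r}: times must be strictly increasing")
        if np.any(y < 0):
            raise ValueError(f"curve {self.sample_id!r}: negative OD600 reading")

    @property
    def times_arr(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @property
    def od_arr(self) -> np.ndarray:
        return np.asarray(self.od, dtype=float)


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of OD on time over a contiguous window of the curve."""

    intercept: float
    slope: float
    r2: float
    window: tuple[int, int]  # [start, stop) indices into the curve

    def __post_init__(self) -> None:
        if self.window[1] - self.window[0] < 3:
            raise ValueError("linear-fit window must span at least 3 points")


@dataclass(frozen=True)
class BkaResult:
    """Per-sample killing score.

    ``t_threshold`` is the crossing time of the OD threshold in hours (the
    censor value for no-growth samples), ``ln_t`` its natural log, and
    ``killing_class`` the control-relative class — ``None`` until a control
    baseline has been applied, except for censored samples which are
    absolute killers regardless of baseline.
    """

    sample_id: str
    grew: bool
    t_threshold: float
    censored: bool
    ln_t: float
    killing_class: KillingClass | None = None
    fit: LinearFit | None = None

    def __post_init__(self) -> None:
        if self.t_threshold <= 0:
            raise ValueError("t_threshold must be positive")
        if not math.isclose(self.ln_t, math.log(self.t_threshold), abs_tol=1e-9):
            raise ValueError("ln_t must equal ln(t_threshold)")
        if self.censored and self.killing_class is not KillingClass.ABSOLUTE_KILLING:
            raise ValueError("censored results are absolute killing by definition")


class CurveUnusableError(ValueError):
    """The curve grows but no linear window supports threshold inversion."""


def detect_growth(curve: GrowthCurve, config: AssayConfig = AssayConfig()) -> bool:
    """Decide whether bacterial growth was detected on this curve.

    Growth requires both a rise of at least ``growth_min_rise`` above the
    first read and an approach of the OD threshold (maximum OD within
    ``growth_min_rise`` of it). Flat curves and curves that drift upward
    without ever nearing the threshold count as no growth.
    """
    y = curve.od_arr
    rise = float(np.max(y) - y[0])
    approaches = float(np.max(y)) >= config.od_threshold - config.growth_min_rise
    return rise >= config.growth_min_rise and approaches


def _ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and r² of OLS y ~ t (closed form)."""
    res = _sps.linregress(t, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def select_linear_range(
    curve: GrowthCurve, config: AssayConfig = AssayConfig()
) -> tuple[int, int]:
    """Pick the contiguous window of points representing linear growth.

    Enumerates every contiguous window of at least ``min_window`` points,
    keeps those whose OLS slope is positive and whose OD span covers the
    crossing: either the window brackets the threshold (a point at or
    below it and one at or above it) or it contains the first
    above-threshold read — the latter matters when growth jumps the
    threshold inside the unobserved 0-5 h gap, where strict bracketing
    would drag the flat lag read into the fit. Curves that never reach
    the threshold only need to approach it within ``growth_min_rise``.
    The window maximising r² wins; ties go to the longer window, then the
    earlier start.

    Raises :class:`CurveUnusableError` when no window qualifies.
    """
    t, y = curve.times_arr, curve.od_arr
    n = t.size
    thr = config.od_threshold
    has_above = bool(np.any(y >= thr))
    first_above = int(np.argmax(y >= thr)) if has_above else -1

    best: tuple[float, int, int] | None = None  # (r2, length, -start)
    best_window: tuple[int, int] | None = None
    for start in range(0, n - config.min_window + 1):
        for stop in range(start + config.min_window, n + 1):
            tw, yw = t[start:stop], y[start:stop]
            slope, _, r2 = _ols(tw, yw)
            if not slope > 0:
                continue
            if has_above:
                brackets = bool(np.any(yw <= thr) and np.any(yw >= thr))
                if not brackets and not start <= first_above < stop:
                    continue
            else:
                if float(np.max(yw)) < thr - config.growth_min_rise:
                    continue
            key = (r2, stop - start, -start)
            if best is None or _window_key_better(key, best):
                best, best_window = key, (start, stop)
    if best_window is None:
        raise CurveUnusableError(
            f"curve {curve.sample_id!r}: no usable linear window near threshold"
        )
    return best_window


def _window_key_better(key: tuple[float, int, int], best: tuple[float, int, int]) -> bool:
    if key[0] > best[0] + _R2_TIE_TOL:
        return True
    if key[0] < best[0] - _R2_TIE_TOL:
        return False
    return key[1:] > best[1:]


def fit_linear_phase(curve: GrowthCurve, window: tuple[int, int]) -> LinearFit:
    """OLS regression of OD on time over ``window`` (indices [start, stop))."""
    start, stop = window
    if stop - start < 3:
        raise ValueError("window must contain at least 3 points")
    t = curve.times_arr[start:stop]
    y = curve.od_arr[start:stop]
    if np.ptp(t) == 0:
        raise ValueError("zero time-variance in window")
    slope, intercept, r2 = _ols(t, y)
    return LinearFit(intercept=intercept, slope=slope, r2=r2, window=(start, stop))


def time_to_threshold(fit: LinearFit, config: AssayConfig = AssayConfig()) -> float:
    """Invert the fitted line at the OD threshold.

    Returns ``(od_threshold - intercept) / slope`` in hours. Crossing times
    past the incubation horizon are kept as extrapolated values; only
    samples that never grew receive the censor value, elsewhere.
    """
    if fit.slope <= 0:
        raise ValueError(f"cannot invert non-positive slope {fit.slope}")
    t = (config.od_threshold - fit.intercept) / fit.slope
    if not math.isfinite(t) or t <= 0:
        raise ValueError(
            f"non-positive crossing time {t:.3g} h — linear window mis-selected"
        )
    return float(t)


def _censored_result(sample_id: str, config: AssayConfig) -> BkaResult:
    return BkaResult(
        sample_id=sample_id,
        grew=False,
        t_threshold=config.censor_time_h,
        censored=True,
        ln_t=math.log(config.censor_time_h),
        killing_class=KillingClass.ABSOLUTE_KILLING,
    )


def score_bka(curve: GrowthCurve, config: AssayConfig = AssayConfig()) -> BkaResult:
    """Score one growth curve: censoring, linear fit, threshold inversion.

    No-growth curves are censored at ``censor_time_h``. Growing curves go
    through window selection, OLS and inversion; if the curve never comes
    near the threshold but a stage fails, the failure downgrades to a
    censored result with a warning, since such a curve is operationally a
    no-growth curve.
    """
    if not detect_growth(curve, config):
        return _censored_result(curve.sample_id, config)
    try:
        window = select_linear_range(curve, config)
        fit = fit_linear_phase(curve, window)
        t = time_to_threshold(fit, config)
    except (CurveUnusableError, ValueError):
        if float(np.max(curve.od_arr)) < config.od_threshold:
            logger.warning(
                "curve %s grows but never approaches OD %.2f; censoring",
                curve.sample_id,
                config.od_threshold,
            )
            return _censored_result(curve.sample_id, config)
        raise
    return BkaResult(
        sample_id=curve.sample_id,
        grew=True,
        t_threshold=t,
        censored=False,
        ln_t=math.log(t),
        fit=fit,
    )


def average_replicates(results: Sequence[BkaResult], config: AssayConfig = AssayConfig()) -> BkaResult:
    """Average technical replicates of one sample on the hours scale.

    Replicates are combined as the arithmetic mean of ``t_threshold``
    before the log transform. The merged result is censored only when all
    replicates are.
    """
    if not results:
        raise ValueError("no replicates to average")
    ids = {r.sample_id for r in results}
    if len(ids) != 1:
        raise ValueError(f"replicates span multiple samples: {sorted(ids)}")
    t = float(np.mean([r.t_threshold for r in results]))
    censored = all(r.censored for r in results)
    if censored:
        return _censored_result(results[0].sample_id, config)
    return BkaResult(
        sample_id=results[0].sample_id,
        grew=any(r.grew for r in results),
        t_threshold=t,
        censored=False,
        ln_t=math.log(t),
    )


def control_baseline(
    controls: Iterable[GrowthCurve], config: AssayConfig = AssayConfig()
) -> float:
    """Mean time-to-threshold of the plasma-free control curves.

    All controls must grow (a censored control indicates a failed run).
    A count different from ``n_controls_expected`` is accepted with a
    warning — the expected count reflects the plate design, not a
    mathematical requirement.
    """
    results = [score_bka(c, config) for c in controls]
    if not results:
        raise ValueError("at least one control curve is required")
    if len(results) != config.n_controls_expected:
        logger.warning(
            "expected %d control curves, got %d", config.n_controls_expected, len(results)
        )
    censored = [r.sample_id for r in results if r.censored]
    if censored:
        raise ValueError(f"control curves failed to grow: {censored}")
    return float(np.mean([r.t_threshold for r in results]))


def classify_killing(result: BkaResult, baseline: float) -> KillingClass:
    """Assign the control-relative killing class.

    Censored (never grew) → absolute killing; crossing at or before the
    control baseline → no killing; a delayed crossing → intermediate
    killing. The three classes partition any cohort.
    """
    if baseline <= 0:
        raise ValueError("control baseline must be positive")
    if result.censored:
        return KillingClass.ABSOLUTE_KILLING
    if result.t_threshold <= baseline:
        return KillingClass.NO_KILLING
    return KillingClass.INTERMEDIATE_KILLING


def with_class(result: BkaResult, baseline: float) -> BkaResult:
    """Return a copy of ``result`` with its killing class filled in."""
    return BkaResult(
        sample_id=result.sample_id,
        grew=result.grew,
        t_threshold=result.t_threshold,
        censored=result.censored,
        ln_t=result.ln_t,
        killing_class=classify_killing(result, baseline),
        fit=result.fit,
    )
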