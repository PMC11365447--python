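"""Dithionite fluorescence-trace analysis and lectin-capture summaries.

A dithionite scramblase assay records NBD fluorescence before and after
adding the membrane-impermeant reductant at t = 0.  The trace is normalized
to the mean pre-addition fluorescence (F_max) and the post-addition decay is
fit with a single exponential to a plateau,

    F/F_max(t) = p + (1 - p) * exp(-k t),

whose asymptote ``p`` is the protected (inner-leaflet plus unscrambled)
fraction; the bleached fraction is ``1 - p``.  The plateau, not the rate, is
the quantity of interest downstream: the real decay can be multiphasic
(fast outer-leaflet bleach plus slower scrambling-limited bleaching), so
``rate_k`` is descriptive only.  If the least-squares fit fails, the mean of
the final 10% of samples is used as the plateau (``method="tail_mean"``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .errors import InputError

MIN_PRE_SAMPLES = 5
MIN_POST_SAMPLES = 20

#: Tolerated upward drift of the tail relative to the early post-addition
#: signal before the trace is declared non-monotone and fit is skipped.
RISING_TAIL_TOLERANCE = 0.05


@dataclass
class FluorescenceTrace:
    """Time-stamped fluorescence record for one dithionite assay.

    The addition event defines t = 0: pre-addition samples have t < 0.
    ``f_max`` is populated once the trace has been normalized.
    """

    time_s: np.ndarray
    fluorescence: np.ndarray
    label: str = ""
    f_max: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.fluorescence.shape:
            raise InputError("time and fluorescence must be 1-D arrays of equal length")
        if self.time_s.size and not np.all(np.diff(self.time_s) > 0):
            raise InputError("time must be strictly increasing")
        if not np.all(np.isfinite(self.fluorescence)):
            raise InputError("fluorescence contains non-finite values")

    @property
    def pre(self) -> np.ndarray:
        return self.fluorescence[self.time_s < 0]

    @property
    def post_time(self) -> np.ndarray:
        return self.time_s[self.time_s >= 0]

    @property
    def post(self) -> np.ndarray:
        return self.fluorescence[self.time_s >= 0]


@dataclass(frozen=True)
class DithioniteFit:
    """Fitted decay parameters for one trace.

    ``plateau`` is the asymptote as a fraction of ``f_max`` (clamped to
    [0, 1]); ``delta_f = 1 - plateau`` is the bleached fraction and
    ``protected = plateau`` the protected fraction.  ``rate_k`` is None when
    the tail-mean fallback was used.  ``flagged`` marks fits whose residual
    sum of squares exceeded the caller's threshold.
    """

    label: str
    f_max: float
    plateau: float
    rate_k: float | None
    delta_f: float
    protected: float
    rss: float
    method: str
    flagged: bool = False


@dataclass(frozen=True)
class CaptureAssayData:
    """One replicate of a lectin (Con A) capture assay, in counts (cpm)."""

    captured_signal: float
    total_signal: float
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.total_signal <= 0:
            raise InputError("total_signal must be > 0")
        if not 0 <= self.captured_signal <= self.total_signal:
            raise InputError("captured_signal must lie in [0, total_signal]")

    @property
    def fraction(self) -> float:
        return self.captured_signal / self.total_signal


@dataclass(frozen=True)
class CaptureSummary:
    """Mean +/- sample SD of per-replicate capture fractions."""

    mean: float
    sd: float | None
    n: int
    fractions: tuple[float, ...] = field(default_factory=tuple)


def normalize_trace(trace: FluorescenceTrace) -> FluorescenceTrace:
    """Normalize a trace to its mean pre-addition fluorescence (F_max).

    The returned trace has a pre-addition mean of 1 (up to noise) and
    records the normalization constant in ``f_max``.  Normalizing an
    already-normalized trace is a no-op up to floating point.
    """
    pre = trace.pre
    if pre.size < 1:
        raise InputError("trace has no pre-addition (t < 0) samples")
    f_max = float(pre.mean())
    if f_max <= 0:
        raise InputError("pre-addition mean fluorescence must be > 0")
    return replace(
        trace,
        fluorescence=trace.fluorescence / f_max,
        f_max=f_max if trace.f_max is None else trace.f_max * f_max,
    )


def _decay(t: np.ndarray, p: float, k: float) -> np.ndarray:
    return p + (1.0 - p) * np.exp(-k * t)


def fit_dithionite_trace(
    trace: FluorescenceTrace, rss_threshold: float | None = None
) -> DithioniteFit:
    """Fit the post-addition decay of a (raw or normalized) trace.

    Requires at least 5 pre-addition and 20 post-addition samples.  The
    trace is normalized internally, so raw and pre-normalized traces give
    the same result.  A rising tail (beyond :data:`RISING_TAIL_TOLERANCE`)
    or a non-convergent fit falls back to the mean of the final 10% of
    samples, reported with ``method="tail_mean"``.
    """
    if trace.pre.size < MIN_PRE_SAMPLES:
        raise InputError(
            f"need >= {MIN_PRE_SAMPLES} pre-addition samples, got {trace.pre.size}"
        )
    if trace.post.size < MIN_POST_SAMPLES:
        raise InputError(
            f"need >= {MIN_POST_SAMPLES} post-addition samples, got {trace.post.size}"
        )
    norm = normalize_trace(trace)
    f_max = float(norm.f_max)  # type: ignore[arg-type]
    t = norm.post_time
    y = norm.post

    n_tail = max(2, y.size // 10)
    tail_mean = float(y[-n_tail:].mean())
    head_mean = float(y[:n_tail].mean())

    plateau: float
    rate_k: float | None
    if tail_mean > head_mean + RISING_TAIL_TOLERANCE:
        warnings.warn(
            f"trace {trace.label!r}: tail rises above early post-addition signal; "
            "using tail mean instead of exponential fit",
            stacklevel=2,
        )
        plateau, rate_k, method = tail_mean, None, "tail_mean"
        resid = y - plateau
    else:
        p0 = min(max(tail_mean, 0.0), 1.0)
        # crude half-life guess from the first crossing of the midpoint
        half = (y[0] + p0) / 2.0
        below = np.nonzero(y < half)[0]
        if below.size and t[below[0]] > 0:
            k0 = math.log(2.0) / t[below[0]]
        else:
            k0 = 10.0 / max(t[-1], 1e-9)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(
                    _decay,
                    t,
                    y,
                    p0=(p0, k0),
                    bounds=([0.0, 1e-12], [1.0, np.inf]),
                    maxfev=10_000,
                )
            plateau, rate_k = float(popt[0]), float(popt[1])
            method = "fit"
            resid = y - _decay(t, plateau, rate_k)
        except (RuntimeError, ValueError):
            warnings.warn(
                f"trace {trace.label!r}: exponential fit failed to converge; "
                "using tail mean",
                stacklevel=2,
            )
            plateau, rate_k, method = tail_mean, None, "tail_mean"
            resid = y - plateau

    plateau = min(max(plateau, 0.0), 1.0)
    rss = float(np.sum(resid**2))
    flagged = rss_threshold is not None and rss > rss_threshold
    delta_f = 1.0 - plateau
    return DithioniteFit(
        label=trace.label,
        f_max=f_max,
        plateau=plateau,
        rate_k=rate_k,
        delta_f=delta_f,
        protected=plateau,
        rss=rss,
        method=method,
        flagged=flagged,
    )


def capture_fraction(data: Sequence[CaptureAssayData]) -> CaptureSummary:
    """Per-replicate captured/total fractions with mean and sample SD.

    SD uses the n-1 denominator and is None for a single replicate.
    """
    if len(data) < 1:
        raise InputError("at least one capture replicate is required")
    fractions = tuple(rep.fraction for rep in data)
    mean = float(np.mean(fractions))
    sd = float(np.std(fractions, ddof=1)) if len(fractions) > 1 else None
    return CaptureSummary(mean=mean, sd=sd, n=len(fractions), fractions=fractions)
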