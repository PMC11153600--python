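"""Base-level (photoactivation-independent signal) estimation and correction.

Autofluorescence and other activation-independent sources produce
localizations that would inflate the molecule count.  Their rate is estimated
from the pre-activation video: the per-frame localization count inside the
segmented area is fitted with a decaying exponential ``N(f) = A exp(-b f)``
(optionally plus a constant floor), the fitted curve is integrated over the
activation-video frame window, and the predicted spurious count is subtracted
from the merged molecule count of the activation video.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .io import LocalizationTable


def counts_per_frame(
    table: LocalizationTable, frame_range: tuple[int, int]
) -> np.ndarray:
    """Number of localizations in each frame of ``frame_range`` (inclusive).

    The result has one entry per frame; entries sum to the number of
    localizations of the table that fall inside the range.
    """
    first, last = int(frame_range[0]), int(frame_range[1])
    if last < first:
        raise ValueError("frame_range must be increasing")
    frames = table.frame
    sel = (frames >= first) & (frames <= last)
    return np.bincount(frames[sel] - first, minlength=last - first + 1).astype(float)


@dataclass
class BaseLevelFit:
    """Fitted spurious-rate model and its integral over the prediction window.

    ``predicted_spurious`` is the expected number of photoactivation-
    independent localizations in the activation video, computed analytically
    as ``(A/b) (exp(-b f1) - exp(-b f2)) + c (f2 - f1)`` for the continuous
    integral over ``prediction_window = (f1, f2)`` (or as the discrete frame
    sum when requested).
    """

    amplitude: float
    decay: float
    floor: float = 0.0
    fit_window: tuple[int, int] = (1, 1000)
    prediction_window: tuple[int, int] = (1001, 2000)
    predicted_spurious: float = 0.0
    residual_norm: float = float("nan")
    method: str = "curve_fit"
    integral_mode: str = "continuous"
    flags: list[str] = field(default_factory=list)

    def rate(self, f) -> np.ndarray:
        return self.amplitude * np.exp(-self.decay * np.asarray(f, float)) + self.floor


def exponential_integral(
    amplitude: float,
    decay: float,
    floor: float,
    window: tuple[float, float],
    mode: str = "continuous",
) -> float:
    """Integral of ``A exp(-b f) + c`` over ``window``.

    ``mode="continuous"`` integrates between the two frame numbers;
    ``mode="discrete"`` sums the model over the integer frames of the
    (inclusive) window.
    """
    f1, f2 = float(window[0]), float(window[1])
    if mode == "continuous":
        if decay == 0.0:
            core = amplitude * (f2 - f1)
        else:
            core = (amplitude / decay) * (np.exp(-decay * f1) - np.exp(-decay * f2))
        return float(core + floor * (f2 - f1))
    if mode == "discrete":
        f = np.arange(int(f1), int(f2) + 1)
        return float(np.sum(amplitude * np.exp(-decay * f) + floor))
    raise ValueError(f"unknown integral mode {mode!r}")


def _loglinear_estimate(
    frames: np.ndarray, counts: np.ndarray, bin_size: int = 10
) -> tuple[float, float] | None:
    """Initial (A, b) from a log-linear regression on binned positive means."""
    n_bins = max(1, frames.size // bin_size)
    edges = np.array_split(np.arange(frames.size), n_bins)
    fm = np.array([frames[idx].mean() for idx in edges if idx.size])
    cm = np.array([counts[idx].mean() for idx in edges if idx.size])
    pos = cm > 0
    if pos.sum() < 2:
        return None
    res = stats.linregress(fm[pos], np.log(cm[pos]))
    b0 = max(-res.slope, 1e-9)
    a0 = float(np.exp(res.intercept))
    return a0, b0


def fit_base_level(
    counts: np.ndarray,
    fit_window: tuple[int, int] = (1, 1000),
    prediction_window: tuple[int, int] = (1001, 2000),
    with_floor: bool = False,
    bin_size: int = 1,
    integral_mode: str = "continuous",
) -> BaseLevelFit:
    """Least-squares exponential fit of per-frame spurious counts.

    ``counts[k]`` is the count in frame ``fit_window[0] + k``.  Counts may be
    binned (``bin_size > 1``) before fitting for sparse data; the fit is then
    performed on bin means against bin-center frames.  Initialization comes
    from a log-linear regression on binned positive counts.  If the
    non-linear fit fails or returns a non-positive decay, the log-linear
    estimate is used and flagged; an all-zero series short-circuits to a
    prediction of zero.
    """
    counts = np.asarray(counts, dtype=float)
    first, last = int(fit_window[0]), int(fit_window[1])
    if counts.size != last - first + 1:
        raise ValueError("counts length must match fit_window")
    frames = np.arange(first, last + 1, dtype=float)
    flags: list[str] = []

    if not np.any(counts > 0):
        return BaseLevelFit(
            amplitude=0.0,
            decay=0.0,
            fit_window=(first, last),
            prediction_window=tuple(prediction_window),
            predicted_spurious=0.0,
            method="skipped",
            integral_mode=integral_mode,
            flags=["all_zero"],
        )

    if bin_size > 1:
        n_bins = counts.size // bin_size
        use = n_bins * bin_size
        fit_f = frames[:use].reshape(n_bins, bin_size).mean(axis=1)
        fit_c = counts[:use].reshape(n_bins, bin_size).mean(axis=1)
    else:
        fit_f, fit_c = frames, counts

    init = _loglinear_estimate(frames, counts)
    if init is None:
        a0, b0 = float(fit_c.mean()), 1e-3
        flags.append("weak_initialization")
    else:
        a0, b0 = init

    if with_floor:
        model = lambda f, a, b, c: a * np.exp(-b * f) + c
        p0 = (a0, b0, 0.0)
        lower_b = (0.0, 1e-12, 0.0)
        upper_b = (np.inf, np.inf, np.inf)
    else:
        model = lambda f, a, b: a * np.exp(-b * f)
        p0 = (a0, b0)
        lower_b = (0.0, 1e-12)
        upper_b = (np.inf, np.inf)

    method = "curve_fit"
    try:
        popt, _ = optimize.curve_fit(
            model, fit_f, fit_c, p0=p0, bounds=(lower_b, upper_b), maxfev=20000
        )
        a, b = float(popt[0]), float(popt[1])
        c = float(popt[2]) if with_floor else 0.0
    except (RuntimeError, ValueError):
        a, b, c = a0, b0, 0.0
        method = "loglinear"
        flags.append("loglinear_fallback")

    if b <= 0:
        b = max(b0, 1e-9)
        a = a0
        method = "loglinear"
        flags.append("loglinear_fallback")

    if with_floor and (a < 1e-6 * max(fit_c.max(), 1.0) or b * (last - first) < 1e-3):
        flags.append("degenerate_decay")

    resid = model(fit_f, *popt) - fit_c if method == "curve_fit" else (
        a * np.exp(-b * fit_f) + c - fit_c
    )
    predicted = exponential_integral(a, b, c, prediction_window, integral_mode)
    return BaseLevelFit(
        amplitude=a,
        decay=b,
        floor=c,
        fit_window=(first, last),
        prediction_window=tuple(prediction_window),
        predicted_spurious=max(0.0, float(predicted)),
        residual_norm=float(np.sqrt(np.mean(resid**2))),
        method=method,
        integral_mode=integral_mode,
        flags=flags,
    )


@dataclass
class CorrectedCount:
    """Merged molecule count after subtracting the predicted spurious count."""

    value: float
    raw_count: float
    predicted_spurious: float
    clamped: bool = False


def correct_count(merged_count: float, fit: BaseLevelFit) -> CorrectedCount:
    """Subtract the predicted spurious localizations; clamp at zero.

    A density cannot be negative, so a prediction exceeding the measured
    count floors the corrected value at 0 and records the clamp.
    """
    if merged_count < 0:
        raise ValueError("merged_count must be >= 0")
    value = merged_count - fit.predicted_spurious
    clamped = value < 0
    return CorrectedCount(
        value=max(0.0, float(value)),
        raw_count=float(merged_count),
        predicted_spurious=float(fit.predicted_spurious),
        clamped=clamped,
    )
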