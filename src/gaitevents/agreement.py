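"""Agreement statistics: non-parametric Bland–Altman, RMSE, correlations.

Detection errors (predicted minus force-derived ground truth, in ms) are
summarised per event type with a non-parametric Bland–Altman analysis — the
median as bias and the 2.5th/97.5th percentiles as 95% limits of agreement —
because step-event error distributions are heavily discretised at the frame
level and far from normal. Normality is nevertheless tested and reported
(Kolmogorov–Smirnov against a normal with estimated moments, a Lilliefors-style
usage whose p-values are anti-conservative; the non-parametric estimates are
what the report carries regardless). Associations between errors and study
conditions (speed, foot-strike angle, incline) use Pearson's r with the
conventional magnitude bands: trivial (r < 0.1), small (0.1 <= r < 0.3),
moderate (0.3 <= r < 0.5) and large (r >= 0.5); ordinary least squares
coefficients are attached for non-trivial correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .events import EventErrors
from .model import PredictedContact

__all__ = [
    "BlandAltman",
    "CorrelationResult",
    "AgreementReport",
    "bland_altman",
    "rmse",
    "correlate_and_classify",
    "frame_accuracy",
    "build_report",
]

ALPHA = 0.05


@dataclass(frozen=True)
class BlandAltman:
    """Non-parametric Bland–Altman summary of one error distribution."""

    bias: float  # median error
    la_lower: float  # 2.5th percentile
    la_upper: float  # 97.5th percentile
    normality_p: float  # KS test with estimated mean/SD
    n: int

    def __post_init__(self) -> None:
        if not self.la_lower <= self.bias <= self.la_upper:
            raise ValueError("limits of agreement must bracket the bias")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with magnitude band and optional OLS fit."""

    r: float
    p: float
    magnitude: str
    slope: float | None = None
    intercept: float | None = None
    r_squared: float | None = None


def bland_altman(errors: np.ndarray) -> BlandAltman:
    """Median bias and percentile 95% limits of agreement.

    Percentiles use linear interpolation between order statistics; with other
    conventions the limits can shift by up to one sample spacing, so the
    choice is fixed here.
    """
    e = np.asarray(errors, dtype=float)
    if e.size < 3:
        raise ValueError(f"need >= 3 errors for Bland-Altman, got {e.size}")
    bias = float(np.median(e))
    lo, hi = np.percentile(e, [2.5, 97.5], method="linear")
    sd = e.std(ddof=1)
    if sd == 0:
        p = 0.0  # a point mass is maximally non-normal
    else:
        p = float(stats.kstest(e, "norm", args=(e.mean(), sd)).pvalue)
    return BlandAltman(bias=bias, la_lower=float(lo), la_upper=float(hi), normality_p=p, n=e.size)


def rmse(errors: np.ndarray) -> float:
    """Root mean squared error."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("empty error sequence")
    return float(np.sqrt(np.mean(e**2)))


def classify_r(r: float) -> str:
    """Magnitude band for a Pearson coefficient (boundaries inclusive on the left)."""
    a = abs(r)
    if a < 0.1:
        return "trivial"
    if a < 0.3:
        return "small"
    if a < 0.5:
        return "moderate"
    return "large"


def correlate_and_classify(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson r with magnitude classification and OLS fit for non-trivial r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if x.size < 3:
        raise ValueError("need >= 3 points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    magnitude = classify_r(r)
    if magnitude == "trivial":
        return CorrelationResult(r=float(r), p=float(p), magnitude=magnitude)
    fit = stats.linregress(x, y)
    return CorrelationResult(
        r=float(r),
        p=float(p),
        magnitude=magnitude,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(r) ** 2,
    )


def frame_accuracy(
    predictions: list[PredictedContact], truths: list[np.ndarray], threshold: float = 0.5
) -> float:
    """Fraction of unmasked frames classified correctly across a collection.

    ``truths`` holds full-length (padded) binary label vectors aligned with
    each prediction's mask; padded frames never count.
    """
    if len(predictions) != len(truths):
        raise ValueError(f"{len(predictions)} predictions vs {len(truths)} label sequences")
    correct = 0
    total = 0
    for pred, y in zip(predictions, truths):
        y = np.asarray(y)
        if y.shape != pred.probabilities.shape:
            raise ValueError("prediction and label lengths differ")
        m = pred.mask.astype(bool)
        binarised = pred.probabilities[m] >= threshold
        correct += int((binarised == y[m].astype(bool)).sum())
        total += int(m.sum())
    if total == 0:
        raise ValueError("no unmasked frames")
    return correct / total


@dataclass
class AgreementReport:
    """Full assessment: per-event Bland–Altman + RMSE, plus frame accuracy."""

    foot_strike: BlandAltman
    toe_off: BlandAltman
    contact_time: BlandAltman
    rmse_ms: dict[str, float]
    frame_accuracy: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, ba in (
            ("foot_strike", self.foot_strike),
            ("toe_off", self.toe_off),
            ("contact_time", self.contact_time),
        ):
            rows.append(
                {
                    "event": name,
                    "bias_ms": ba.bias,
                    "la_lower_ms": ba.la_lower,
                    "la_upper_ms": ba.la_upper,
                    "rmse_ms": self.rmse_ms[name],
                    "normality_p": ba.normality_p,
                    "normal_at_0.05": ba.normality_p >= ALPHA,
                    "n": ba.n,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = []
        if self.frame_accuracy is not None:
            lines.append(
                f"Frame classification accuracy (unmasked frames): "
                f"{100 * self.frame_accuracy:.2f}%"
            )
        for name, ba in (
            ("foot-strike", self.foot_strike),
            ("toe-off", self.toe_off),
            ("contact time", self.contact_time),
        ):
            key = name.replace("-", "_").replace(" ", "_")
            lines.append(
                f"{name}: bias {ba.bias:.1f} ms "
                f"[95% LA {ba.la_lower:.1f}, {ba.la_upper:.1f}] ms, "
                f"RMSE {self.rmse_ms[key]:.1f} ms, n={ba.n} "
                f"(KS normality p={ba.normality_p:.3g})"
            )
        return "\n".join(lines)


def build_report(
    errors: list[EventErrors], frame_acc: float | None = None
) -> AgreementReport:
    """Aggregate per-cycle event errors into the standard agreement report."""
    if not errors:
        raise ValueError("no event errors supplied")
    fs = np.array([e.foot_strike_ms for e in errors])
    to = np.array([e.toe_off_ms for e in errors])
    ct = np.array([e.contact_time_ms for e in errors])
    return AgreementReport(
        foot_strike=bland_altman(fs),
        toe_off=bland_altman(to),
        contact_time=bland_altman(ct),
        rmse_ms={"foot_strike": rmse(fs), "toe_off": rmse(to), "contact_time": rmse(ct)},
        frame_accuracy=frame_acc,
    )
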