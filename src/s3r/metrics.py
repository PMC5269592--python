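"""Error and variance statistics for landmark estimation.

Per-landmark error is the Euclidean distance between an estimate and its
ground truth; ME averages it over the 21 landmarks.  For repeated
estimation, Error is the distance from the mean estimated position to the
truth and Variance is the pooled three-coordinate sum of squared deviations
about the mean, divided by n - 1 (mm^2).  Power-law fits of mean error
against sample size are done by least squares in log-log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .virtual_1020 import LANDMARK_NAMES, LandmarkSet

__all__ = [
    "ErrorReport",
    "RepeatStats",
    "PowerFit",
    "landmark_errors",
    "repeat_stats",
    "pooled_variance",
    "operator_variances",
    "fit_power_law",
    "pearson_correlation",
]


@dataclass
class ErrorReport:
    errors: dict[str, float]   # per-landmark Error_i (mm)
    me: float                  # mean error over landmarks (mm)


@dataclass
class RepeatStats:
    mean_position: np.ndarray  # (x̄, ȳ, z̄)
    error: float               # ||truth - mean position|| (mm)
    variance: float            # pooled 3-coordinate variance (mm^2)
    n: int


@dataclass
class PowerFit:
    a: float
    b: float
    r_squared: float

    def predict(self, x):
        return self.a * np.asarray(x, dtype=float) ** self.b


def landmark_errors(est: LandmarkSet, truth: LandmarkSet) -> ErrorReport:
    """Per-landmark Euclidean errors and their mean (ME)."""
    if set(est) != set(truth):
        raise ValueError(
            f"landmark name mismatch: {sorted(set(est) ^ set(truth))}"
        )
    errors = {
        name: float(np.linalg.norm(np.asarray(est[name]) - np.asarray(truth[name])))
        for name in est
    }
    return ErrorReport(errors=errors, me=float(np.mean(list(errors.values()))))


def pooled_variance(points: np.ndarray) -> float:
    """Sum over x, y, z of squared deviations about the mean, over n - 1."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(points)
    if n < 2:
        raise ValueError("variance needs at least 2 repeats")
    dev = points - points.mean(axis=0)
    return float((dev**2).sum() / (n - 1))


def repeat_stats(repeats: list[LandmarkSet], truth: LandmarkSet) -> dict[str, RepeatStats]:
    """Error and Variance per landmark over repeated estimates."""
    if len(repeats) < 2:
        raise ValueError("need at least 2 repeats")
    out = {}
    for name in truth:
        pts = np.array([r[name] for r in repeats], dtype=float)
        mean = pts.mean(axis=0)
        out[name] = RepeatStats(
            mean_position=mean,
            error=float(np.linalg.norm(np.asarray(truth[name]) - mean)),
            variance=pooled_variance(pts),
            n=len(repeats),
        )
    return out


def operator_variances(data: np.ndarray) -> tuple[float, float, float]:
    """(total, inter, intra) variance of one landmark measured by several
    operators with several repeats each.

    ``data`` has shape (n_operators, n_repeats, 3).  Total pools all
    operator x repeat points; inter is the variance of the per-operator
    centres of gravity; intra is the mean within-operator variance.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:  # 1-D positions allowed for hand examples
        data = np.stack([data, np.zeros_like(data), np.zeros_like(data)], axis=-1)
    if data.ndim != 3 or data.shape[-1] != 3:
        raise ValueError("expected (n_operators, n_repeats, 3) array")
    if not np.all(np.isfinite(data)):
        raise ValueError("missing cells in operator grid")
    n_ops, n_rep, _ = data.shape
    total = pooled_variance(data.reshape(-1, 3))
    centres = data.mean(axis=1)
    inter = pooled_variance(centres) if n_ops >= 2 else 0.0
    intra = float(np.mean([pooled_variance(data[i]) for i in range(n_ops)])) if n_rep >= 2 else 0.0
    return total, inter, intra


def fit_power_law(sizes, mean_errors) -> PowerFit:
    """Fit y = a * x^b by least squares on log y vs log x; R^2 on log scale."""
    x = np.asarray(sizes, dtype=float)
    y = np.asarray(mean_errors, dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires positive sizes and errors")
    lx, ly = np.log(x), np.log(y)
    if np.ptp(lx) == 0 or np.ptp(ly) == 0:
        warnings.warn("degenerate power-law fit (constant data)", stacklevel=2)
        a = float(np.exp(ly.mean()))
        return PowerFit(a=a, b=0.0, r_squared=0.0)
    res = stats.linregress(lx, ly)
    return PowerFit(a=float(np.exp(res.intercept)), b=float(res.slope),
                    r_squared=float(res.rvalue**2))


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation and its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length sequences of at least 3 values")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
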