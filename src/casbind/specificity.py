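"""CRISPR specificity scoring: partition-function score, sliding-aware
extension, least-squares parameter fitting and tertile binning.

The base score is -log10 of the Boltzmann-weighted share of binding that
goes to off-targets:

    score = -log10( sum_i e^(-off_i/rt) / (sum_i e^(-off_i/rt) + e^(-on/rt)) )

computed in log space.  The extension adds fitted linear contributions from
the absolute deviation of each sliding-PAM dG_B from its training median.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .sliding import SlidingAnnotation

__all__ = [
    "FitError",
    "SpecificityModel",
    "crisprspec",
    "fit_ext_parameters",
    "crisprspec_ext",
    "tertile_bins",
    "apply_bins",
]

_LN10 = math.log(10.0)


class FitError(ValueError):
    pass


def crisprspec(on_dg_b: float, off_dg_bs: Sequence[float], rt: float) -> float:
    """Partition-function specificity score; +inf when there are no off-targets."""
    if rt <= 0:
        raise ValueError(f"rt must be > 0, got {rt}")
    offs = np.asarray(off_dg_bs, dtype=float)
    if offs.size == 0:
        return math.inf
    log_num = logsumexp(-offs / rt)
    # score = log10(1 + e^(-on/rt)/num); the log1p form keeps tiny scores
    # strictly positive instead of rounding the ratio to 1
    t = -on_dg_b / rt - log_num
    if t > 700.0:
        return (t + math.log1p(math.exp(-t))) / _LN10
    return math.log1p(math.exp(t)) / _LN10


def _ols_line(x: np.ndarray, y: np.ndarray, label: str) -> tuple[float, float]:
    """Least-squares intercept and slope of y on x.

    A constant response gives slope 0 exactly; a constant regressor with a
    varying response is singular and raises.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0:
        raise FitError(f"no observations to fit {label}")
    if np.ptp(y) == 0.0:
        return float(y[0]), 0.0
    if np.ptp(x) == 0.0:
        raise FitError(f"singular fit for {label}: regressor is constant")
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(slope)


@dataclass
class SpecificityModel:
    """Fitted coefficients and training medians for the extended score."""

    alpha0: float
    alpha1: float
    beta0: float = 0.0
    beta1: float = 0.0
    gamma0: float = 0.0
    gamma1: float = 0.0
    m_up: float = math.nan
    m_down: float = math.nan
    tertile_lo: float = math.nan
    tertile_hi: float = math.nan
    rt: float = math.nan
    parameter_version: str = "unversioned"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SpecificityModel":
        return cls(**json.loads(Path(path).read_text()))


def fit_ext_parameters(
    training: Sequence[tuple[float, float, Optional[float], Optional[float]]],
    *,
    rt: float = math.nan,
    parameter_version: str = "unversioned",
) -> SpecificityModel:
    """Fit the extension coefficients on (efficiency, score, dG_B_up?, dG_B_down?).

    The global line is fit on all rows; the sliding lines on the subsets that
    carry the respective sliding energy, against the absolute deviation from
    that subset's median.  Rows with infinite score must be excluded upstream.
    """
    if not training:
        raise FitError("empty training set")
    y = np.array([t[0] for t in training], float)
    spec = np.array([t[1] for t in training], float)
    if not np.all(np.isfinite(spec)):
        raise FitError("training rows with non-finite score must be excluded by the caller")
    alpha0, alpha1 = _ols_line(spec, y, "global score line (alpha)")

    ups = [(t[0], t[2]) for t in training if t[2] is not None]
    downs = [(t[0], t[3]) for t in training if t[3] is not None]
    beta0 = beta1 = gamma0 = gamma1 = 0.0
    m_up = m_down = math.nan
    if ups:
        y_up = np.array([u[0] for u in ups])
        e_up = np.array([u[1] for u in ups], float)
        m_up = float(np.median(e_up))
        beta0, beta1 = _ols_line(np.abs(e_up - m_up), y_up, "upstream sliding line (beta)")
    if downs:
        y_dn = np.array([d[0] for d in downs])
        e_dn = np.array([d[1] for d in downs], float)
        m_down = float(np.median(e_dn))
        gamma0, gamma1 = _ols_line(np.abs(e_dn - m_down), y_dn, "downstream sliding line (gamma)")

    lo, hi = tertile_bins([float(s) for s in spec])
    return SpecificityModel(
        alpha0=alpha0, alpha1=alpha1,
        beta0=beta0, beta1=beta1,
        gamma0=gamma0, gamma1=gamma1,
        m_up=m_up, m_down=m_down,
        tertile_lo=lo, tertile_hi=hi,
        rt=rt, parameter_version=parameter_version,
    )


def crisprspec_ext(
    spec: float, sliding: SlidingAnnotation, model: SpecificityModel
) -> float:
    """Sliding-aware rescaled score for one guide."""
    if not math.isfinite(spec):
        raise ValueError("spec must be finite; guides without off-targets are flagged upstream")
    value = model.alpha0 + model.alpha1 * spec
    if sliding.upstream:
        if sliding.dg_b_up is None:
            raise ValueError("upstream sliding flagged but dg_b_up is missing")
        value += model.beta0 + model.beta1 * abs(sliding.dg_b_up - model.m_up)
    if sliding.downstream:
        if sliding.dg_b_down is None:
            raise ValueError("downstream sliding flagged but dg_b_down is missing")
        value += model.gamma0 + model.gamma1 * abs(sliding.dg_b_down - model.m_down)
    return value


def tertile_bins(training_scores: Sequence[float]) -> tuple[float, float]:
    """33.33/66.67 percentile cut points (linear interpolation)."""
    scores = np.asarray(training_scores, float)
    if scores.size < 3:
        raise FitError("need >= 3 training scores for tertile binning")
    lo, hi = np.percentile(scores, [100 / 3.0, 200 / 3.0])
    return float(lo), float(hi)


def apply_bins(score: float, cuts: tuple[float, float]) -> str:
    """Classify a score against stored cut points; degenerate cuts map to medium."""
    lo, hi = cuts
    if lo == hi:
        return "medium"
    if score < lo:
        return "low"
    if score > hi:
        return "high"
    return "medium"
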