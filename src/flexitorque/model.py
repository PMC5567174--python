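"""Torque-per-strain factor: computation, log-linear fitting and prediction.

The combined factor eta = T/s absorbs the torque-angle and torque-velocity
effects.  Because its velocity dependence is experimentally negligible, a
per-subject averaged curve eta_bar(theta) trained from isokinetic flexions
predicts torque in any kinetic flexion as T = s * eta_bar(theta).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    OutOfRangeError,
    ParameterError,
    TrainingError,
)
from .preprocess import StrainSeries

logger = logging.getLogger(__name__)

DEFAULT_FIT_RANGE = (50.0, 100.0)
DEFAULT_MIN_STRAIN = 0.005


@dataclass
class EtaCurve:
    """Torque per unit strain (N*m) versus angle for one flexion."""

    angle: np.ndarray
    eta: np.ndarray
    valid: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.angle = np.asarray(self.angle, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.angle.size == self.eta.size == self.valid.size):
            raise ParameterError("eta curve arrays must share one length")


@dataclass(frozen=True)
class LogLinearFit:
    """Least-squares fit of log(eta) = a1*theta + a2 over a fit range."""

    a1: float                 # per degree
    a2: float                 # intercept in the chosen log base
    fit_range: tuple
    rms: float                # residual RMS in log units
    n: int
    base: str = "e"           # "e" or "10"


def compute_eta(strain: StrainSeries, torque=None,
                min_strain: float = DEFAULT_MIN_STRAIN) -> EtaCurve:
    """eta = torque / strain where strain is at least ``min_strain``.

    Samples below the strain threshold are masked: near the ROM limits the
    strain vanishes and the ratio blows up.  Non-positive or non-finite
    ratios are masked as well so that log analysis is always defined on the
    valid set.
    """
    if torque is None:
        torque = strain.torque
    if torque is None:
        raise ParameterError("no torque series supplied or attached to strain")
    torque = np.asarray(torque, dtype=float)
    if torque.size != strain.angle.size:
        raise ParameterError("torque series must align with the strain series")
    valid = strain.valid & np.isfinite(torque) & (strain.strain >= min_strain)
    eta = np.full(torque.size, np.nan)
    np.divide(torque, strain.strain, out=eta, where=valid)
    valid = valid & np.isfinite(eta) & (eta > 0)
    eta[~valid] = np.nan
    if not valid.any():
        raise DegenerateDataError(
            "no valid samples left after strain thresholding")
    masked_frac = 1.0 - valid.mean()
    if masked_frac > 0.5:
        logger.warning("eta curve %s: %.0f%% of samples masked",
                       strain.meta, 100 * masked_frac)
    return EtaCurve(strain.angle, eta, valid, dict(strain.meta))


def fit_log_eta(curve: EtaCurve, fit_range=DEFAULT_FIT_RANGE,
                base: str = "e") -> LogLinearFit:
    """Ordinary least squares of log(eta) on angle, restricted to the range.

    The natural log is the default; fitting in base 10 rescales both
    parameters by 1/ln(10) and changes no downstream conclusion.
    """
    lo, hi = fit_range
    sel = curve.valid & (curve.angle >= lo) & (curve.angle <= hi)
    n = int(sel.sum())
    if n < 2:
        raise InsufficientDataError(
            f"only {n} valid samples in fit range [{lo}, {hi}]")
    eta = curve.eta[sel]
    if np.any(eta <= 0):
        raise DegenerateDataError("non-positive eta inside the fit range")
    if base == "e":
        y = np.log(eta)
    elif base == "10":
        y = np.log10(eta)
    else:
        raise ParameterError(f"log base must be 'e' or '10', got {base!r}")
    a1, a2 = np.polyfit(curve.angle[sel], y, 1)
    resid = y - (a1 * curve.angle[sel] + a2)
    return LogLinearFit(float(a1), float(a2), (float(lo), float(hi)),
                        float(np.sqrt(np.mean(resid ** 2))), n, base)


@dataclass
class TorqueModel:
    """Averaged torque-per-strain curve eta_bar on a common angle grid."""

    angle: np.ndarray
    eta_bar: np.ndarray
    valid: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def valid_range(self) -> tuple:
        va = self.angle[self.valid]
        return float(va[0]), float(va[-1])

    def __call__(self, theta):
        lo, hi = self.valid_range
        th = np.asarray(theta, dtype=float)
        if np.any(th < lo - 1e-9) or np.any(th > hi + 1e-9):
            raise OutOfRangeError(
                f"angle outside model valid range [{lo:.2f}, {hi:.2f}]")
        return np.interp(th, self.angle[self.valid], self.eta_bar[self.valid])


def _curve_nodes(curve: EtaCurve):
    a = curve.angle[curve.valid]
    e = curve.eta[curve.valid]
    order = np.argsort(a, kind="stable")
    a, e = a[order], e[order]
    # collapse duplicate angles (e.g. samples at a clipped ROM limit)
    ua, inverse = np.unique(a, return_inverse=True)
    if ua.size != a.size:
        sums = np.bincount(inverse, weights=e)
        counts = np.bincount(inverse)
        e = sums / counts
        a = ua
    return a, e


def train_torque_model(curves, grid=None) -> TorqueModel:
    """Pointwise arithmetic mean of eta curves resampled onto a common grid.

    The model is valid on the intersection of the input curves' valid angle
    ranges; each curve is linearly interpolated onto the grid there.
    """
    curves = list(curves)
    if not curves:
        raise ParameterError("at least one eta curve is required")
    if grid is None:
        grid = np.arange(30.0, 121.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ParameterError("grid must be strictly increasing with >= 2 nodes")
    nodes = [_curve_nodes(c) for c in curves]
    lo = max(a[0] for a, _ in nodes)
    hi = min(a[-1] for a, _ in nodes)
    gsel = (grid >= lo) & (grid <= hi)
    if not gsel.any():
        raise TrainingError(
            "input curves have no common valid angle range on the grid")
    eta_bar = np.full(grid.size, np.nan)
    eta_bar[gsel] = np.mean(
        [np.interp(grid[gsel], a, e) for a, e in nodes], axis=0)
    meta = {
        "n_curves": len(curves),
        "sources": [c.meta for c in curves],
        "valid_range": (float(grid[gsel][0]), float(grid[gsel][-1])),
    }
    return TorqueModel(grid, eta_bar, gsel, meta)


def predict_torque(strain: StrainSeries, model: TorqueModel,
                   outside: str = "raise") -> np.ndarray:
    """Predicted torque T = s(theta) * eta_bar(theta) along a strain series.

    Samples where the strain is masked come out NaN.  Valid samples falling
    outside the model's valid angle range raise :class:`OutOfRangeError` by
    default (``outside="raise"``) or are masked with ``outside="mask"``; the
    curve endpoints are noise-dominated, so no extrapolation is offered.
    """
    if outside not in ("raise", "mask"):
        raise ParameterError("outside must be 'raise' or 'mask'")
    lo, hi = model.valid_range
    inside = (strain.angle >= lo) & (strain.angle <= hi)
    if outside == "raise" and np.any(strain.valid & ~inside):
        raise OutOfRangeError(
            f"strain series extends outside model valid range [{lo:.2f}, {hi:.2f}]")
    sel = strain.valid & inside
    out = np.full(strain.angle.size, np.nan)
    if sel.any():
        out[sel] = strain.strain[sel] * model(strain.angle[sel])
    return out
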