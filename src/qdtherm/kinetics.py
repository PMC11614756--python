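"""Initial-rate estimation from quantum-dot fluorescence kinetics.

A well's raw fluorescence trace is normalised to its starting value, a
polynomial is fitted by ordinary least squares over the regression window,
and the initial decay rate is taken as minus the linear coefficient, i.e.
the magnitude of the t = 0 slope of the fitted curve.  Fluorescence falls
as the microenvironment warms during ATP hydrolysis, so a larger initial
decay rate means more heat released per unit myosin — a *lower*
mechanochemical efficiency.  The pipeline reports the index with this sign
convention and never relabels it numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial

from .config import RunConfig

__all__ = [
    "FluorescenceTrace",
    "RelativeTrace",
    "RateEstimate",
    "TraceError",
    "normalize_trace",
    "fit_polynomial",
    "initial_rate_of",
]


class TraceError(ValueError):
    """Raised when a trace violates the assay's structural assumptions."""


@dataclass(frozen=True)
class FluorescenceTrace:
    """One well's raw kinetic read-out.

    ``times`` are seconds from the first reading (re-based so
    ``times[0] == 0``); ``intensities`` are raw fluorescence counts, all
    positive.  ``condition`` is ``"ATP"`` for the real reaction or
    ``"BLANK"`` for the 0 mM ATP drift control.
    """

    well_id: str
    times: np.ndarray
    intensities: np.ndarray
    condition: str
    preparation_id: str

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        intensities = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intensities)
        if times.ndim != 1 or intensities.ndim != 1:
            raise TraceError(f"well {self.well_id}: times/intensities must be 1-D")
        if len(times) != len(intensities):
            raise TraceError(f"well {self.well_id}: length mismatch")
        if len(times) < 4:
            raise TraceError(f"well {self.well_id}: need >= 4 readings")
        if times[0] != 0:
            raise TraceError(f"well {self.well_id}: times must be re-based to 0")
        if not np.all(np.diff(times) > 0):
            raise TraceError(f"well {self.well_id}: times not strictly increasing")
        if not np.all(np.isfinite(intensities)) or np.any(intensities <= 0):
            raise TraceError(f"well {self.well_id}: intensities must be finite and > 0")
        if self.condition not in ("ATP", "BLANK"):
            raise TraceError(f"well {self.well_id}: bad condition {self.condition!r}")


@dataclass(frozen=True)
class RelativeTrace:
    """A trace normalised to its starting fluorescence (first value 1)."""

    times: np.ndarray
    relative_intensity: np.ndarray

    def __post_init__(self) -> None:
        if self.relative_intensity[0] != 1.0:
            raise TraceError("relative trace must start at exactly 1")
        if np.any(self.relative_intensity <= 0):
            raise TraceError("relative intensities must stay positive")


@dataclass(frozen=True)
class RateEstimate:
    """Polynomial fit of a relative trace and its extracted initial rate.

    ``coefficients`` are in the power basis, intercept first, over time in
    seconds.  ``initial_decay_rate`` is ``-coefficients[1]`` (per second):
    positive for a decaying trace.
    """

    coefficients: np.ndarray
    initial_decay_rate: float
    r_squared: float
    degree: int
    window: tuple[float, float]
    well_id: str = ""
    condition: str = ""
    preparation_id: str = ""

    def __post_init__(self) -> None:
        if len(self.coefficients) != self.degree + 1:
            raise TraceError("coefficient count must equal degree + 1")
        if not np.isfinite(self.initial_decay_rate):
            raise TraceError("initial decay rate must be finite")


def normalize_trace(trace: FluorescenceTrace) -> RelativeTrace:
    """Divide a raw trace by its starting fluorescence.

    The result is scale invariant: multiplying every raw intensity by any
    positive constant leaves it unchanged (up to one floating division).
    """
    f0 = trace.intensities[0]
    if f0 <= 0:
        raise TraceError(f"well {trace.well_id}: first intensity must be > 0")
    rel = trace.intensities / f0
    rel[0] = 1.0  # exact by definition
    return RelativeTrace(times=trace.times, relative_intensity=rel)


def fit_polynomial(
    rel: RelativeTrace,
    degree: int,
    weights: np.ndarray | None = None,
) -> RateEstimate:
    """Ordinary (optionally weighted) least-squares polynomial fit.

    Uses a scaled-domain basis internally for conditioning and converts
    back to power-basis coefficients over seconds.  ``r_squared`` is the
    usual 1 - SSres/SStot, defined as 0 for a zero-variance trace.
    """
    t = np.asarray(rel.times, dtype=float)
    y = np.asarray(rel.relative_intensity, dtype=float)
    n = len(t)
    if degree >= n:
        raise TraceError(f"degree {degree} needs more than {n} points")
    if len(np.unique(t)) != n:
        raise TraceError("duplicated time points make the design rank-deficient")

    w = None if weights is None else np.asarray(weights, dtype=float)
    poly = Polynomial.fit(t, y, deg=degree, w=w)
    coeffs = poly.convert().coef
    if len(coeffs) < degree + 1:  # numpy trims exact trailing zeros
        coeffs = np.pad(coeffs, (0, degree + 1 - len(coeffs)))

    fitted = poly(t)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - fitted) ** 2))
    r2 = 0.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)

    return RateEstimate(
        coefficients=coeffs,
        initial_decay_rate=float(-coeffs[1]),
        r_squared=r2,
        degree=degree,
        window=(float(t[0]), float(t[-1])),
    )


def initial_rate_of(trace: FluorescenceTrace, config: RunConfig) -> RateEstimate:
    """Normalise a raw trace and fit it, returning the initial decay rate.

    Points beyond ``config.window_end_s`` are dropped before the fit.
    With ``config.weighted_fit`` the noisy tail is down-weighted in
    proportion to its assumed noise SD; the default is plain OLS over the
    full window.
    """
    rel = normalize_trace(trace)
    mask = rel.times <= config.window_end_s
    t = rel.times[mask]
    y = rel.relative_intensity[mask]
    if len(t) <= config.poly_degree:
        raise TraceError(
            f"well {trace.well_id}: window [0, {config.window_end_s}] leaves "
            f"{len(t)} points for a degree-{config.poly_degree} fit")
    weights = None
    if config.weighted_fit:
        weights = np.where(t <= config.noise_boundary_s,
                           1.0, 1.0 / config.weight_late_relative_sd)
    windowed = RelativeTrace(times=t, relative_intensity=y)
    est = fit_polynomial(windowed, config.poly_degree, weights=weights)
    return RateEstimate(
        coefficients=est.coefficients,
        initial_decay_rate=est.initial_decay_rate,
        r_squared=est.r_squared,
        degree=est.degree,
        window=est.window,
        well_id=trace.well_id,
        condition=trace.condition,
        preparation_id=trace.preparation_id,
    )
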