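"""Electrogram feature extraction: extrema, peak-to-peak, W90 width, RMSE.

Traces may be non-uniformly sampled; all integrals are trapezoidal.  The
signal width W90 is the interval between the 5% and 95% quantiles of the
cumulative absolute-signal mass

    S(t) = int_{t0}^{t} |Phi| dt' / int_{t0}^{t1} |Phi| dt',

inverted by linear interpolation, which is exact for piecewise-linear |Phi|.
No pre-filtering is applied by default — a caller-supplied filter hook can
be passed where appropriate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid

from .exceptions import (
    DegenerateSignalError,
    InvalidParameterError,
    InvalidWindowError,
)

__all__ = [
    "SignalTrace",
    "FeatureSet",
    "completion_fraction",
    "width_W90",
    "rmse",
    "split_qrs_t",
    "extract_features",
    "RMSE_WINDOWS",
]

#: Named RMSE comparison windows (ms) commonly used for slab electrograms.
RMSE_WINDOWS = {"qrs_250": (0.0, 250.0), "bip_150": (0.0, 150.0), "uni_300": (0.0, 300.0)}


@dataclass(frozen=True)
class SignalTrace:
    """A sampled potential trace: strictly increasing times (ms), mV values."""

    t: np.ndarray
    phi: np.ndarray
    label: str = ""
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        phi = np.asarray(self.phi, dtype=float)
        if t.ndim != 1 or t.shape != phi.shape or t.size < 2:
            raise InvalidParameterError("t and phi must be equal-length 1D, size >= 2")
        if not np.all(np.diff(t) > 0):
            raise InvalidParameterError("sample times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(phi))):
            raise InvalidParameterError("trace contains non-finite values")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "phi", phi)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class FeatureSet:
    """Scalar electrogram characteristics."""

    phi_min: float
    phi_max: float
    phi_pp: float
    t5: float
    t95: float
    W90: float


def completion_fraction(trace: SignalTrace) -> Callable:
    """Fraction-of-completion S(t) of the absolute-signal integral.

    Returns a callable mapping times (within the trace support) to [0, 1];
    non-decreasing, S(t_first) = 0, S(t_last) = 1.
    """
    mass = cumulative_trapezoid(np.abs(trace.phi), trace.t, initial=0.0)
    total = mass[-1]
    if total <= 0.0:
        raise DegenerateSignalError("trace has zero absolute integral")
    s = mass / total

    def S(t):
        return np.interp(np.asarray(t, dtype=float), trace.t, s)

    S.knots_t = trace.t
    S.knots_s = s
    return S


def _quantile_time(knots_t: np.ndarray, knots_s: np.ndarray, q: float) -> float:
    """First time at which the non-decreasing S reaches level q (linear interp)."""
    idx = int(np.searchsorted(knots_s, q, side="left"))
    if idx == 0:
        return float(knots_t[0])
    s0, s1 = knots_s[idx - 1], knots_s[idx]
    if s1 == s0:
        return float(knots_t[idx])
    w = (q - s0) / (s1 - s0)
    return float(knots_t[idx - 1] + w * (knots_t[idx] - knots_t[idx - 1]))


def width_W90(trace: SignalTrace) -> dict[str, float]:
    """W90 signal width: t95 - t5 with S(t5) = 0.05, S(t95) = 0.95 (ms)."""
    S = completion_fraction(trace)
    t5 = _quantile_time(S.knots_t, S.knots_s, 0.05)
    t95 = _quantile_time(S.knots_t, S.knots_s, 0.95)
    return {"t5": t5, "t95": t95, "W90": t95 - t5}


def rmse(
    trace1: SignalTrace,
    trace2: SignalTrace,
    t0: float,
    t1: float,
    n_resample: int = 2001,
) -> float:
    """Root-mean-squared difference between two traces over [t0, t1] (mV).

    Both traces are linearly resampled to a common uniform grid; the window
    must lie within the overlap of their supports.
    """
    if not t1 > t0:
        raise InvalidWindowError("window must satisfy t1 > t0")
    lo = max(trace1.t[0], trace2.t[0])
    hi = min(trace1.t[-1], trace2.t[-1])
    if t0 < lo or t1 > hi:
        raise InvalidWindowError(
            f"window [{t0}, {t1}] outside trace overlap [{lo}, {hi}]"
        )
    grid = np.linspace(t0, t1, n_resample)
    d = np.interp(grid, trace1.t, trace1.phi) - np.interp(grid, trace2.t, trace2.phi)
    return float(np.sqrt(trapezoid(d * d, grid) / (t1 - t0)))


def split_qrs_t(trace: SignalTrace) -> tuple[SignalTrace, SignalTrace]:
    """Split a trace at its midpoint into (depolarization, repolarization) halves.

    For simulated electrograms the first half holds the QRS complex and the
    second the T-wave; the analytic model produces no repolarization, so its
    second half is essentially flat.
    """
    mid = trace.t[0] + 0.5 * trace.duration
    first = trace.t < mid
    # keep every sample: first half strictly before the midpoint, rest after
    a = SignalTrace(trace.t[first], trace.phi[first], label=trace.label + "/qrs")
    b = SignalTrace(trace.t[~first], trace.phi[~first], label=trace.label + "/t")
    return a, b


def extract_features(trace: SignalTrace) -> FeatureSet:
    """All scalar features of a trace (extrema, peak-to-peak, W90)."""
    w = width_W90(trace)
    phi_min = float(np.min(trace.phi))
    phi_max = float(np.max(trace.phi))
    return FeatureSet(
        phi_min=phi_min,
        phi_max=phi_max,
        phi_pp=phi_max - phi_min,
        t5=w["t5"],
        t95=w["t95"],
        W90=w["W90"],
    )
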