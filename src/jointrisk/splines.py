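"""Natural (restricted) cubic spline basis on log time.

The baseline cumulative hazard of the flexible parametric survival model is
represented as a linear combination of ``1``, ``log t`` and the restricted
cubic basis functions evaluated here. Each basis function is

    nu_j(y) = (y - k_j)_+^3 - lam_j (y - k_min)_+^3 - (1 - lam_j) (y - k_max)_+^3

with ``lam_j = (k_max - k_j) / (k_max - k_min)`` and ``(.)_+`` the positive
part. This construction is a cubic between adjacent knots, has a continuous
second derivative everywhere, and is exactly linear outside the boundary
knots (identically zero below ``k_min``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateKnotsError, ValidationError

__all__ = ["KnotSet", "make_knots", "basis_value", "basis_derivative"]


@dataclass(frozen=True)
class KnotSet:
    """Boundary and internal knot locations on the log-time axis.

    ``internal`` may be empty (``m = 0``), in which case the spline part of
    the baseline vanishes and the model is linear in log time (Weibull-type).
    """

    boundary_low: float
    boundary_high: float
    internal: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "internal", tuple(float(v) for v in self.internal))
        object.__setattr__(self, "boundary_low", float(self.boundary_low))
        object.__setattr__(self, "boundary_high", float(self.boundary_high))
        knots = self.all_knots
        if not np.all(np.isfinite(knots)):
            raise ValidationError("knots must be finite")
        if np.any(np.diff(knots) <= 0):
            raise ValidationError(
                f"knots must be strictly increasing, got {list(knots)}"
            )

    @property
    def m(self) -> int:
        """Number of internal knots."""
        return len(self.internal)

    @property
    def all_knots(self) -> np.ndarray:
        return np.array(
            [self.boundary_low, *self.internal, self.boundary_high], dtype=float
        )

    def to_dict(self) -> dict:
        return {
            "boundary_low": self.boundary_low,
            "boundary_high": self.boundary_high,
            "internal": list(self.internal),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KnotSet":
        return cls(d["boundary_low"], d["boundary_high"], tuple(d["internal"]))


def make_knots(log_times, m: int) -> KnotSet:
    """Place knots from observed log event times.

    Boundary knots sit at the minimum and maximum of ``log_times``; the ``m``
    internal knots at the equally spaced quantiles strictly between them
    (e.g. ``m = 1`` -> median, ``m = 3`` -> quartiles). This is the standard
    data-driven placement for this model family and is reproducible from the
    data alone.
    """
    y = np.asarray(log_times, dtype=float)
    if y.size == 0:
        raise ValidationError("log_times must be non-empty")
    if not np.all(np.isfinite(y)):
        raise ValidationError("log_times must be finite")
    if m < 0:
        raise ValidationError(f"m must be >= 0, got {m}")
    distinct = np.unique(y)
    if distinct.size < m + 2:
        raise DegenerateKnotsError(
            f"need at least {m + 2} distinct log times for m={m} internal knots, "
            f"got {distinct.size}"
        )
    lo, hi = float(y.min()), float(y.max())
    if m == 0:
        return KnotSet(lo, hi, ())
    probs = np.arange(1, m + 1) / (m + 1)
    internal = np.quantile(y, probs)
    if np.any(internal <= lo) or np.any(internal >= hi) or np.any(np.diff(internal) <= 0):
        raise DegenerateKnotsError(
            f"quantile knots degenerate for m={m}: {internal.tolist()}"
        )
    return KnotSet(lo, hi, tuple(internal))


def _pos3(u: np.ndarray) -> np.ndarray:
    return np.where(u > 0, u, 0.0) ** 3


def basis_value(knots: KnotSet, y) -> np.ndarray:
    """Evaluate the m restricted-cubic basis functions at log time(s) ``y``.

    Returns shape ``(m,)`` for scalar ``y`` and ``(n, m)`` for array ``y``.
    ``m = 0`` yields an empty trailing axis.
    """
    y_arr = np.asarray(y, dtype=float)
    scalar = y_arr.ndim == 0
    y_arr = np.atleast_1d(y_arr)
    kmin, kmax = knots.boundary_low, knots.boundary_high
    out = np.empty((y_arr.size, knots.m))
    span = kmax - kmin
    for j, kj in enumerate(knots.internal):
        lam = (kmax - kj) / span
        out[:, j] = (
            _pos3(y_arr - kj)
            - lam * _pos3(y_arr - kmin)
            - (1.0 - lam) * _pos3(y_arr - kmax)
        )
    return out[0] if scalar else out


def _pos2(u: np.ndarray) -> np.ndarray:
    return np.where(u > 0, u, 0.0) ** 2


def basis_derivative(knots: KnotSet, y) -> np.ndarray:
    """Exact first derivative of :func:`basis_value` with respect to ``y``."""
    y_arr = np.asarray(y, dtype=float)
    scalar = y_arr.ndim == 0
    y_arr = np.atleast_1d(y_arr)
    kmin, kmax = knots.boundary_low, knots.boundary_high
    out = np.empty((y_arr.size, knots.m))
    span = kmax - kmin
    for j, kj in enumerate(knots.internal):
        lam = (kmax - kj) / span
        out[:, j] = 3.0 * (
            _pos2(y_arr - kj)
            - lam * _pos2(y_arr - kmin)
            - (1.0 - lam) * _pos2(y_arr - kmax)
        )
    return out[0] if scalar else out
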