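"""Four-parameter logistic dose-response fitting and EC50/EC90 derivation.

The model is the "variable slope" logistic in log10 concentration,

    y(c) = bottom + (top - bottom) / (1 + 10^(hill * (logEC50 - log10 c))),

fitted by bounded least squares with a multi-start grid over logEC50.
ECf — the concentration attaining an *absolute* response of f percent —
follows in closed form; when the fitted plateau never reaches f within the
tested range, the result is the typed :data:`NOT_REACHED`, never a number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import least_squares

from .events import ValidationError

__all__ = ["NOT_REACHED", "NotReached", "DoseResponseFit", "fit_4pl", "ec_fraction"]


class NotReached:
    """Singleton marker: the requested effect level is not attained."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NOT_REACHED"

    def __bool__(self) -> bool:
        return False


NOT_REACHED = NotReached()

#: soft parameter bounds: responses are percentages, hill slopes physical
BOUNDS_LO = np.array([-10.0, 10.0, -np.inf, 0.1])   # bottom, top, logEC50, hill
BOUNDS_HI = np.array([50.0, 110.0, np.inf, 10.0])


@dataclass
class DoseResponseFit:
    """Fitted 4PL parameters with derived effect concentrations."""

    bottom: float
    top: float
    log_ec50: float
    hill: float
    rss: float
    converged: bool
    n_points: int
    tested_range: Tuple[float, float]     # (min, max) concentration in uM
    degenerate: bool = False

    @property
    def ec50(self) -> Union[float, NotReached]:
        if not self.converged:
            return NOT_REACHED
        return 10.0 ** self.log_ec50

    @property
    def ec90(self) -> Union[float, NotReached]:
        return ec_fraction(self, 90.0)

    def predict(self, conc_uM):
        c = np.asarray(conc_uM, dtype=float)
        return _model(np.array([self.bottom, self.top, self.log_ec50, self.hill]),
                      np.log10(c))


def _model(theta: np.ndarray, log_c: np.ndarray) -> np.ndarray:
    bottom, top, log_ec50, hill = theta
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ec50 - log_c)))


def fit_4pl(
    concs_uM: Sequence[float],
    responses: Sequence[float],
    bounds: Optional[Tuple[Sequence[float], Sequence[float]]] = None,
    baseline_anchor: Optional[float] = None,
    anchor_weight: float = 2.0,
) -> DoseResponseFit:
    """Least-squares 4PL fit of % loss against concentration.

    Parameters
    ----------
    concs_uM
        Positive concentrations; at least four distinct values.  Zero-dose
        (vehicle) points are not log-transformable — pass their mean
        response as ``baseline_anchor`` instead.
    responses
        Observed % cyt c loss, same length.
    bounds
        Optional (lo, hi) 4-vectors overriding the default soft bounds.
    baseline_anchor
        Optional vehicle response anchoring the bottom plateau through a
        weighted pseudo-residual rather than a log-dose design point.
    anchor_weight
        Relative weight of the anchor pseudo-residual.

    The ``converged`` flag is honest: False when the optimizer fails or a
    parameter lands on a bound.  An all-equal response vector yields a
    degenerate, non-converged fit rather than fabricated parameters.
    """
    c = np.asarray(concs_uM, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.shape != y.shape:
        raise ValidationError("concs and responses must have equal length")
    if np.any(c <= 0):
        raise ValidationError(
            "concentrations must be > 0; pass zero-dose points as baseline_anchor"
        )
    distinct = np.unique(c)
    if distinct.size < 4:
        raise ValidationError(
            f"need >= 4 distinct concentrations, got {distinct.size}"
        )
    tested = (float(distinct.min()), float(distinct.max()))

    if np.ptp(y) == 0.0:
        return DoseResponseFit(
            bottom=float(y[0]), top=float(y[0]), log_ec50=np.nan, hill=np.nan,
            rss=0.0, converged=False, n_points=len(y), tested_range=tested,
            degenerate=True,
        )

    lo = np.array(bounds[0], dtype=float) if bounds else BOUNDS_LO.copy()
    hi = np.array(bounds[1], dtype=float) if bounds else BOUNDS_HI.copy()
    # keep logEC50 finite for the optimizer: one decade beyond the tested range
    log_lo, log_hi = np.log10(tested[0]) - 1.0, np.log10(tested[1]) + 1.0
    lo[2] = max(lo[2], log_lo) if np.isfinite(lo[2]) else log_lo
    hi[2] = min(hi[2], log_hi) if np.isfinite(hi[2]) else log_hi

    log_c = np.log10(c)

    def residuals(theta):
        res = _model(theta, log_c) - y
        if baseline_anchor is not None:
            res = np.append(res, anchor_weight * (theta[0] - baseline_anchor))
        return res

    y_lo, y_hi = float(y.min()), float(y.max())
    best = None
    for start_log_ec50 in np.linspace(log_lo + 0.5, log_hi - 0.5, 7):
        theta0 = np.array([
            np.clip(y_lo, lo[0], hi[0]),
            np.clip(y_hi, lo[1], hi[1]),
            start_log_ec50,
            1.0,
        ])
        try:
            sol = least_squares(residuals, theta0, bounds=(lo, hi), method="trf",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol

    if best is None:
        return DoseResponseFit(
            bottom=np.nan, top=np.nan, log_ec50=np.nan, hill=np.nan,
            rss=np.nan, converged=False, n_points=len(y), tested_range=tested,
        )

    theta = best.x
    at_bound = bool(np.any(np.isclose(theta, lo, atol=1e-9))
                    or np.any(np.isclose(theta, hi, atol=1e-9)))
    rss = float(np.sum((_model(theta, log_c) - y) ** 2))
    return DoseResponseFit(
        bottom=float(theta[0]), top=float(theta[1]),
        log_ec50=float(theta[2]), hill=float(theta[3]),
        rss=rss, converged=not at_bound, n_points=len(y), tested_range=tested,
    )


def ec_fraction(fit: DoseResponseFit, f: float) -> Union[float, NotReached]:
    """Concentration at which the fitted curve attains ``f`` percent response.

    ``f`` is on the absolute % loss scale.  Closed form:

        ECf = EC50 * (f_rel / (100 - f_rel))^(1/hill),
        f_rel = 100 * (f - bottom) / (top - bottom).

    Returns :data:`NOT_REACHED` when the plateau never attains ``f``
    (``f >= top``) or when the required concentration exceeds the tested
    range.  A non-converged fit is an error.
    """
    if not fit.converged:
        raise ValidationError("cannot derive an effect concentration from a non-converged fit")
    if not (0.0 < f < 100.0):
        raise ValidationError("f must lie strictly between 0 and 100 percent")
    if f >= fit.top:
        return NOT_REACHED
    f_rel = 100.0 * (f - fit.bottom) / (fit.top - fit.bottom)
    if f_rel <= 0.0:
        # f at or below the bottom plateau: attained at arbitrarily low dose
        return float(fit.tested_range[0])
    ec50 = 10.0 ** fit.log_ec50
    ecf = ec50 * (f_rel / (100.0 - f_rel)) ** (1.0 / fit.hill)
    if ecf > fit.tested_range[1]:
        return NOT_REACHED
    return float(ecf)
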