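"""IC50 determination from (concentration, % inhibition) points.

Two routes are provided, since published "graphical analysis" can mean
either:

* ``hill_fit`` — least-squares fit of the Hill inhibition curve
  ``y = top / (1 + (ic50 / c)^h)`` with the top fixed at 100% inhibition
  (free on request), by a deterministic log-grid search followed by local
  refinement.  No randomness is involved, so results are bit-stable.
* ``log_interpolation`` — linear interpolation of the 50% crossing on a
  log-concentration axis between the bracketing pair of points.

When the data never reach 50% inhibition (the half-maximal concentration is
beyond the tested range) both methods refuse with :class:`NoCrossingError`
rather than extrapolate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "InhibitionPoint",
    "Ic50Fit",
    "NoCrossingError",
    "fit_ic50",
    "MYRICETIN_POINTS",
    "FOA_POINTS",
]


class NoCrossingError(ValueError):
    """The inhibition data never bracket the 50% level."""


@dataclass(frozen=True)
class InhibitionPoint:
    concentration: float  # uM, > 0
    inhibition_pct: float  # [0, 100]

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be strictly positive")
        if not (0.0 <= self.inhibition_pct <= 100.0):
            raise ValueError("inhibition must be within [0, 100] percent")


#: Published inhibition of S. cerevisiae DHOase by myricetin.
MYRICETIN_POINTS = tuple(
    InhibitionPoint(c, y) for c, y in ((2.5, 22.0), (5.0, 35.0), (10.0, 43.0), (20.0, 71.0))
)

#: Published inhibition by 5-fluoroorotate; never reaches 50%.
FOA_POINTS = tuple(
    InhibitionPoint(c, y) for c, y in ((100.0, 5.0), (200.0, 10.0), (400.0, 23.0), (600.0, 33.0))
)


@dataclass
class Ic50Fit:
    ic50: float  # uM
    hill: float  # unitless slope (1.0 for log_interpolation)
    top: float  # % maximal inhibition assumed/fitted
    residual: float  # sum of squared % errors
    method: str

    def __post_init__(self) -> None:
        if self.ic50 <= 0 or self.hill <= 0:
            raise ValueError("ic50 and hill slope must be positive")


def _hill(c: np.ndarray, ic50: float, hill: float, top: float) -> np.ndarray:
    return top / (1.0 + (ic50 / c) ** hill)


def _sse(params: Sequence[float], logc: np.ndarray, y: np.ndarray, top: float | None) -> float:
    log_ic50, log_hill = params[0], params[1]
    t = params[2] if top is None else top
    pred = t / (1.0 + np.exp(-math.exp(log_hill) * (logc - log_ic50)))
    return float(np.sum((pred - y) ** 2))


def _require_crossing(points: Sequence[InhibitionPoint]) -> None:
    ys = [p.inhibition_pct for p in points]
    if max(ys) < 50.0 or min(ys) > 50.0:
        raise NoCrossingError(
            "inhibition never crosses 50% within the tested concentrations; "
            "IC50 exceeds the highest concentration tested"
        )


def fit_ic50(
    points: Iterable[InhibitionPoint],
    method: str = "hill_fit",
    free_top: bool = False,
) -> Ic50Fit:
    """Fit the IC50 from dose-response points.

    ``hill_fit`` needs at least 3 points spanning the 50% level;
    ``log_interpolation`` needs a bracketing pair.  Both are deterministic.
    """
    pts = sorted(points, key=lambda p: p.concentration)
    if method == "hill_fit":
        if len(pts) < 3:
            raise ValueError("hill_fit needs at least 3 points")
        _require_crossing(pts)
        return _fit_hill(pts, free_top=free_top)
    if method == "log_interpolation":
        if len(pts) < 2:
            raise ValueError("log_interpolation needs at least 2 points")
        _require_crossing(pts)
        return _interpolate(pts)
    raise ValueError(f"unknown method {method!r}")


def _fit_hill(pts: Sequence[InhibitionPoint], free_top: bool) -> Ic50Fit:
    logc = np.log(np.array([p.concentration for p in pts]))
    y = np.array([p.inhibition_pct for p in pts])
    top = None if free_top else 100.0
    # Coarse deterministic grid anchored to the data's own concentration range,
    # so rescaling every concentration by k shifts the optimum by exactly log k.
    ic50_grid = np.linspace(logc.min() - math.log(10.0), logc.max() + math.log(10.0), 241)
    hill_grid = np.log(np.linspace(0.3, 4.0, 75))
    best = None
    for li in ic50_grid:
        for lh in hill_grid:
            params = [li, lh] if top is not None else [li, lh, 100.0]
            sse = _sse(params, logc, y, top)
            if best is None or sse < best[0]:
                best = (sse, params)
    assert best is not None
    res = minimize(
        _sse,
        x0=np.array(best[1]),
        args=(logc, y, top),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
    )
    params = res.x
    fitted_top = 100.0 if top is not None else float(params[2])
    return Ic50Fit(
        ic50=float(math.exp(params[0])),
        hill=float(math.exp(params[1])),
        top=fitted_top,
        residual=float(res.fun),
        method="hill_fit",
    )


def _interpolate(pts: Sequence[InhibitionPoint]) -> Ic50Fit:
    for lo, hi in zip(pts, pts[1:]):
        if lo.inhibition_pct <= 50.0 <= hi.inhibition_pct:
            frac = (50.0 - lo.inhibition_pct) / (hi.inhibition_pct - lo.inhibition_pct)
            log_ic50 = math.log(lo.concentration) + frac * (
                math.log(hi.concentration) - math.log(lo.concentration)
            )
            ic50 = math.exp(log_ic50)
            resid = sum(
                (
                    _hill(np.array([p.concentration]), ic50, 1.0, 100.0)[0]
                    - p.inhibition_pct
                )
                ** 2
                for p in pts
            )
            return Ic50Fit(
                ic50=ic50, hill=1.0, top=100.0, residual=float(resid), method="log_interpolation"
            )
    raise NoCrossingError("no adjacent pair of points brackets 50% inhibition")
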