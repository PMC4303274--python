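"""Hill-plane analysis of saturation curves.

The Hill coefficient is the slope of ``log(Y/(1-Y))`` against the log
of ligand concentration.  For a two-identical-site MWC lobe it traces a
symmetric bell on the log axis, peaking at half-saturation; the value
there is the cooperativity index usually quoted alongside fits of the
phenomenological Hill equation ``Y = x^n / (K^n + x^n)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .allosteric import LobeParams, TargetSpec, _effective_L

__all__ = [
    "HillSummary",
    "hill_coefficient",
    "hill_coefficient_mwc",
    "half_saturation",
    "hill_summary",
    "fit_hill",
    "HillFit",
]


@dataclass(frozen=True)
class HillSummary:
    """Hill-plane summary of one saturation curve."""

    nH_at_half: float
    ca_half: float
    nH_max: float
    ca_grid: np.ndarray
    nH_profile: np.ndarray


def hill_coefficient(
    saturation_fn: Callable[[float], float],
    ca_free: float,
    rel_step: float = 1e-3,
    tol: float = 1e-6,
    max_refine: int = 12,
) -> float:
    """Hill-plane slope d log(Y/(1-Y)) / d log(ca) at one point.

    Central differences on the log-concentration axis, Richardson
    refined (successive halvings combined at fourth order) until two
    estimates agree to ``tol``.  Requires 0 < Y < 1 at the point.
    """
    Y0 = saturation_fn(ca_free)
    if not 0.0 < Y0 < 1.0:
        raise ValueError(f"Hill slope undefined at Y={Y0}")

    def logit_at(h: float) -> tuple[float, float]:
        Yp = saturation_fn(ca_free * math.exp(h))
        Ym = saturation_fn(ca_free * math.exp(-h))
        return Yp, Ym

    def slope(h: float) -> float:
        Yp, Ym = logit_at(h)
        if not (0.0 < Yp < 1.0 and 0.0 < Ym < 1.0):
            raise ValueError("saturation left (0,1) inside the difference stencil")
        return (math.log(Yp / (1.0 - Yp)) - math.log(Ym / (1.0 - Ym))) / (2.0 * h)

    h = rel_step
    prev = slope(h)
    for _ in range(max_refine):
        h /= 2.0
        cur = slope(h)
        richardson = (4.0 * cur - prev) / 3.0
        if abs(richardson - cur) < tol:
            return richardson
        prev = cur
    return richardson


def hill_coefficient_mwc(
    params: LobeParams,
    ca_free: float,
    targets: Sequence[tuple[TargetSpec, float]] = (),
) -> float:
    """Exact Hill slope of the two-site MWC lobe at fixed free target.

    With A = (1+a) + L'c(1+ca) and B = (1+a) + L'(1+ca) the Hill-plane
    ratio is Y/(1-Y) = a A / B, so
    ``nH = 1 + a A'/A - a B'/B`` with A' = 1 + L'c^2, B' = 1 + L'c.
    """
    Lp = _effective_L(params, targets)
    c = params.c
    a = ca_free / params.K_R
    if a <= 0:
        raise ValueError("Hill slope undefined at zero calcium")
    A = (1.0 + a) + Lp * c * (1.0 + c * a)
    B = (1.0 + a) + Lp * (1.0 + c * a)
    return 1.0 + a * (1.0 + Lp * c * c) / A - a * (1.0 + Lp * c) / B


def half_saturation(
    saturation_fn: Callable[[float], float],
    bracket: tuple[float, float] = (1e-12, 1.0),
    rtol: float = 1e-10,
) -> float:
    """Free calcium at Y = 0.5, by bracketing bisection (brentq).

    The curve must cross 0.5 inside ``bracket`` (molar); monotone
    curves give a unique root.
    """
    lo, hi = bracket
    f = lambda ca: saturation_fn(ca) - 0.5
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"half-saturation not bracketed on [{lo:g}, {hi:g}] M "
            f"(Y spans [{flo + 0.5:.4f}, {fhi + 0.5:.4f}])"
        )
    return float(optimize.brentq(f, lo, hi, rtol=rtol))


def hill_summary(
    saturation_fn: Callable[[float], float],
    bracket: tuple[float, float] = (1e-12, 1.0),
    n_grid: int = 201,
) -> HillSummary:
    """Hill profile over a log grid plus the slope at half-saturation."""
    ca_half = half_saturation(saturation_fn, bracket=bracket)
    # two decades either side of the midpoint covers the bell
    grid = np.geomspace(ca_half * 1e-2, ca_half * 1e2, n_grid)
    prof = np.array([hill_coefficient(saturation_fn, ca) for ca in grid])
    return HillSummary(
        nH_at_half=hill_coefficient(saturation_fn, ca_half),
        ca_half=ca_half,
        nH_max=float(prof.max()),
        ca_grid=grid,
        nH_profile=prof,
    )


@dataclass(frozen=True)
class HillFit:
    K_half: float
    nH: float
    residual_ss: float


def fit_hill(ca: np.ndarray, Y: np.ndarray) -> HillFit:
    """Least-squares fit of the Hill equation Y = x^n / (K^n + x^n).

    Points are weighted equally; the search runs in (log K, n).  The
    data must span both sides of half-saturation with at least 4 points.
    """
    ca = np.asarray(ca, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if ca.size < 4:
        raise ValueError("need at least 4 points for a Hill fit")
    if np.ptp(Y) == 0:
        raise ValueError("degenerate data: all saturations equal")
    if not (Y.min() < 0.5 < Y.max()):
        raise ValueError("data must span both sides of half-saturation")

    def model(logK_n: np.ndarray) -> np.ndarray:
        logK, n = logK_n
        z = n * (np.log(ca) - logK)
        return 1.0 / (1.0 + np.exp(-z))

    # midpoint of the data as the starting K
    k0 = float(np.interp(0.5, Y, ca)) if np.all(np.diff(Y) >= 0) else float(np.median(ca))
    res = optimize.least_squares(
        lambda p: model(p) - Y,
        x0=[math.log(k0), 1.5],
        bounds=([math.log(ca.min()) - 10, 0.05], [math.log(ca.max()) + 10, 8.0]),
    )
    K = math.exp(res.x[0])
    return HillFit(K_half=K, nH=float(res.x[1]), residual_ss=float(2 * res.cost))
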