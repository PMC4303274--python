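"""Two-state MWC mathematics for a single calmodulin lobe.

A lobe (two EF-hands, two identical calcium sites) is modelled as a
concerted two-state unit: a low-affinity T conformation (calcium
dissociation constant ``K_T``) and a high-affinity R conformation
(``K_R``), in equilibrium with allosteric constant ``L = [T0]/[R0]``.
Target peptides bind both conformations with different affinities and
therefore act purely through an effective allosteric constant ``L'``:
a target with ``e = K_Rt/K_Tt < 1`` stabilises R and left-shifts the
calcium saturation curve, ``e > 1`` stabilises T and right-shifts it.

All concentrations are molar.  Target concentrations entering these
functions are *free* concentrations; conversion from totals is the job
of :mod:`hemicam.equilibrium`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LobeParams",
    "TargetSpec",
    "EvaluationPoint",
    "effective_allosteric_constant",
    "lobe_saturation",
    "pure_state_curves",
    "state_fraction_R",
    "half_saturation_ca",
    "lobe_partition_weights",
]


@dataclass(frozen=True)
class LobeParams:
    """Allosteric state of one lobe.

    Parameters
    ----------
    L :
        Allosteric constant, ratio of unliganded T to R concentrations.
        ``L = 0`` is accepted as the pure-R limit.
    K_R, K_T :
        Calcium dissociation constants (molar) of the R and T states.
        R is the high-affinity state, so ``K_R <= K_T``.
    """

    L: float
    K_R: float
    K_T: float

    def __post_init__(self) -> None:
        if self.L < 0:
            raise ValueError(f"allosteric constant L must be >= 0, got {self.L}")
        if self.K_R <= 0 or self.K_T <= 0:
            raise ValueError("dissociation constants must be positive")
        if self.K_R > self.K_T:
            raise ValueError(
                f"K_R ({self.K_R}) must not exceed K_T ({self.K_T}): "
                "R is the high-affinity state"
            )

    @property
    def c(self) -> float:
        """Affinity ratio ``K_R / K_T`` (0 < c <= 1)."""
        return self.K_R / self.K_T


@dataclass(frozen=True)
class TargetSpec:
    """A target peptide's dissociation constants for the two lobe states.

    ``stoichiometry`` selects how many target molecules one lobe binds:
    ``"per_subunit"`` (one per calcium site, the Rubin–Changeux
    convention giving the squared effective-L factor) or
    ``"per_molecule"`` (a single whole-lobe site).
    """

    name: str
    K_Rt: float
    K_Tt: float
    stoichiometry: str = "per_subunit"

    def __post_init__(self) -> None:
        if self.K_Rt <= 0 or self.K_Tt <= 0:
            raise ValueError("target dissociation constants must be positive")
        if self.stoichiometry not in ("per_subunit", "per_molecule"):
            raise ValueError(f"unknown stoichiometry {self.stoichiometry!r}")

    @property
    def e(self) -> float:
        """Conformational preference ``K_Rt / K_Tt``; e<1 stabilises R."""
        return self.K_Rt / self.K_Tt

    @property
    def exponent(self) -> int:
        return 2 if self.stoichiometry == "per_subunit" else 1


@dataclass(frozen=True)
class EvaluationPoint:
    """One evaluated point of the saturation surface (diagnostic record)."""

    ca_free: float
    alpha: float
    gammas: tuple[float, ...]
    effective_L: float
    Y: float


def _check_gamma_e(gamma: float, e: float) -> None:
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    if e <= 0:
        raise ValueError(f"e must be > 0, got {e}")


def effective_allosteric_constant(
    L: float,
    targets: Iterable[tuple[float, float]] = (),
    exponent: int = 2,
) -> float:
    """Effective allosteric constant L' under free-target modulation.

    ``L' = L * prod_t ((1 + gamma_t * e_t) / (1 + gamma_t)) ** exponent``
    with ``gamma_t = [A_t]_free / K_Rt``.  The empty product returns L
    unchanged.  ``exponent=2`` is the per-subunit convention for a
    two-site lobe; ``exponent=1`` the per-molecule one.
    """
    if L < 0:
        raise ValueError(f"L must be >= 0, got {L}")
    if exponent not in (1, 2):
        raise ValueError(f"exponent must be 1 or 2, got {exponent}")
    factor = 1.0
    for gamma, e in targets:
        _check_gamma_e(gamma, e)
        if math.isinf(gamma):
            factor *= e**exponent
        else:
            factor *= ((1.0 + gamma * e) / (1.0 + gamma)) ** exponent
    return L * factor


def _gammas(targets: Sequence[tuple[TargetSpec, float]]) -> list[tuple[float, float, int]]:
    out = []
    for spec, conc in targets:
        if conc < 0:
            raise ValueError(f"free target concentration must be >= 0, got {conc}")
        out.append((conc / spec.K_Rt, spec.e, spec.exponent))
    return out


def _effective_L(params: LobeParams, targets: Sequence[tuple[TargetSpec, float]]) -> float:
    Lp = params.L
    for gamma, e, n in _gammas(targets):
        Lp = effective_allosteric_constant(Lp, [(gamma, e)], exponent=n)
    return Lp


def lobe_saturation(
    params: LobeParams,
    ca_free: float | np.ndarray,
    targets: Sequence[tuple[TargetSpec, float]] = (),
) -> float | np.ndarray:
    """Fractional calcium saturation of a two-site lobe.

    ``Y = [alpha(1+alpha) + L' alpha c (1 + alpha c)] /
    [(1+alpha)^2 + L'(1+alpha c)^2]`` with ``alpha = [Ca]_free / K_R``.
    Monotone increasing in calcium, Y(0)=0, Y(inf)=1.  ``ca_free`` may
    be a scalar (possibly ``inf``) or an array.
    """
    Lp = _effective_L(params, targets)
    c = params.c

    def _scalar(ca: float) -> float:
        if ca < 0:
            raise ValueError(f"ca_free must be >= 0, got {ca}")
        if math.isinf(ca):
            return 1.0
        a = ca / params.K_R
        num = a * (1.0 + a) + Lp * a * c * (1.0 + a * c)
        den = (1.0 + a) ** 2 + Lp * (1.0 + a * c) ** 2
        return num / den

    if np.ndim(ca_free) == 0:
        return _scalar(float(ca_free))
    return np.array([_scalar(float(x)) for x in np.asarray(ca_free, dtype=float)])


def pure_state_curves(
    params: LobeParams, ca_free: float | np.ndarray
) -> tuple[float | np.ndarray, float | np.ndarray]:
    """Saturation of the pure T and pure R populations (non-cooperative).

    Every mixture curve, with or without targets, lies between these two
    bounding hyperbolas; they anchor the fitting constraints on K_R, K_T.
    """
    ca = np.asarray(ca_free, dtype=float)
    if np.any(ca < 0):
        raise ValueError("ca_free must be >= 0")
    with np.errstate(invalid="ignore"):
        xT = ca / params.K_T
        xR = ca / params.K_R
        Y_T = np.where(np.isinf(ca), 1.0, xT / (1.0 + xT))
        Y_R = np.where(np.isinf(ca), 1.0, xR / (1.0 + xR))
    if np.ndim(ca_free) == 0:
        return float(Y_T), float(Y_R)
    return Y_T, Y_R


def state_fraction_R(
    params: LobeParams,
    ca_free: float,
    targets: Sequence[tuple[TargetSpec, float]] = (),
) -> float:
    """Population fraction of lobes in the R conformation.

    ``(1+alpha)^2 / ((1+alpha)^2 + L'(1+alpha c)^2)``; the population
    shift underlying cooperativity.  Rises from ``1/(1+L')`` at zero
    calcium to ``1/(1+L'c^2)`` at saturation (for c < 1).
    """
    Lp = _effective_L(params, targets)
    c = params.c
    if ca_free < 0:
        raise ValueError(f"ca_free must be >= 0, got {ca_free}")
    if math.isinf(ca_free):
        return 1.0 / (1.0 + Lp * c * c)
    a = ca_free / params.K_R
    wR = (1.0 + a) ** 2
    return wR / (wR + Lp * (1.0 + a * c) ** 2)


def half_saturation_ca(
    params: LobeParams, targets: Sequence[tuple[TargetSpec, float]] = ()
) -> float:
    """Closed-form free calcium at half saturation.

    Setting Y = 1/2 in the two-site saturation function gives
    ``alpha_half = sqrt((1 + L') / (1 + L' c^2))``, hence
    ``ca_half = alpha_half * K_R``.
    """
    Lp = _effective_L(params, targets)
    c = params.c
    return params.K_R * math.sqrt((1.0 + Lp) / (1.0 + Lp * c * c))


def lobe_partition_weights(
    params: LobeParams,
    ca_free: float,
    targets: Sequence[tuple[TargetSpec, float]] = (),
) -> tuple[float, float]:
    """Statistical weights (w_R, w_T) of the R and T conformer ensembles.

    ``w_R = (1+alpha)^2 * prod(1+gamma)^n`` and
    ``w_T = L (1+alpha c)^2 * prod(1+gamma e)^n``, relative to the
    unliganded R conformer.  Exposed for partition-function cross-checks.
    """
    a = ca_free / params.K_R
    wR = (1.0 + a) ** 2
    wT = params.L * (1.0 + a * params.c) ** 2
    for gamma, e, n in _gammas(targets):
        wR *= (1.0 + gamma) ** n
        wT *= (1.0 + gamma * e) ** n
    return wR, wT
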