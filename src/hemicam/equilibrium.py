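"""Equilibrium solving with total reagent concentrations.

Titration experiments fix *total* protein and peptide, while the MWC
closed forms consume *free* concentrations.  This module closes the gap:
given totals and a clamped free-calcium concentration (the buffered
titration setting) it solves the target mass-balance equations

    total_t = free_t + bound_t(free)

on the model's binding polynomial, which is monotone in each free
concentration, so the root is unique and bracketed in [0, total_t].
A conserved-total-calcium mode is provided for unbuffered scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .allosteric import LobeParams, TargetSpec
from .intact import CONFORMATIONS, IntactParams, IntactTargetSpec, intact_conformer_weight

__all__ = [
    "LobeSystem",
    "IntactSystem",
    "Mixture",
    "EquilibriumSolution",
    "SaturationCurve",
    "SolverError",
    "solve_free_concentrations",
    "titration_curve",
    "competing_targets_curve",
    "default_ca_grid",
]


class SolverError(RuntimeError):
    """Raised when a mass-balance solve fails to converge."""


def default_ca_grid(n: int = 60, lo: float = 1e-8, hi: float = 1e-3) -> np.ndarray:
    """Log-spaced free-calcium grid, 10 nM to 1 mM by default."""
    return np.geomspace(lo, hi, n)


class LobeSystem:
    """An isolated lobe (TR1C/TR2C) with zero or more targets.

    ``binding`` selects the multi-target convention:

    - ``"independent"``: each target binds its own sites, effective L
      is the product of per-target factors with the target's
      stoichiometry exponent (the analytic default);
    - ``"exclusive"``: at most one target molecule per lobe, all targets
      competing for the same surface (requires per_molecule targets).
    """

    n_sites = 2

    def __init__(
        self,
        params: LobeParams,
        targets: Sequence[TargetSpec] = (),
        binding: str = "independent",
    ):
        if binding not in ("independent", "exclusive"):
            raise ValueError(f"unknown binding mode {binding!r}")
        if binding == "exclusive" and any(t.stoichiometry != "per_molecule" for t in targets):
            raise ValueError("exclusive binding requires per_molecule targets")
        names = [t.name for t in targets]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate target names: {names}")
        self.params = params
        self.targets = tuple(targets)
        self.binding = binding

    @property
    def target_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.targets)

    def _weights(self, ca: float, free: Mapping[str, float]) -> tuple[float, float]:
        p = self.params
        a = ca / p.K_R
        wR = (1.0 + a) ** 2
        wT = p.L * (1.0 + a * p.c) ** 2
        if self.binding == "independent":
            for t in self.targets:
                g = free[t.name] / t.K_Rt
                wR *= (1.0 + g) ** t.exponent
                wT *= (1.0 + g * t.e) ** t.exponent
        else:
            sR = sum(free[t.name] / t.K_Rt for t in self.targets)
            sT = sum(free[t.name] / t.K_Tt for t in self.targets)
            wR *= 1.0 + sR
            wT *= 1.0 + sT
        return wR, wT

    def saturation(self, ca: float, free: Mapping[str, float]) -> float:
        p = self.params
        a = ca / p.K_R
        wR, wT = self._weights(ca, free)
        # occupied-site share of each conformer ensemble
        yR = a / (1.0 + a)
        yT = a * p.c / (1.0 + a * p.c)
        return (wR * yR + wT * yT) / (wR + wT)

    def bound_targets(self, ca: float, free: Mapping[str, float]) -> dict[str, float]:
        """Target molecules bound per protein molecule, for each target."""
        wR, wT = self._weights(ca, free)
        Z = wR + wT
        out: dict[str, float] = {}
        for t in self.targets:
            g = free[t.name] / t.K_Rt
            if self.binding == "independent":
                nu = (
                    wR * t.exponent * g / (1.0 + g)
                    + wT * t.exponent * g * t.e / (1.0 + g * t.e)
                )
            else:
                sR = sum(free[u.name] / u.K_Rt for u in self.targets)
                sT = sum(free[u.name] / u.K_Tt for u in self.targets)
                nu = (wR / (1.0 + sR)) * g + (wT / (1.0 + sT)) * g * t.e
            out[t.name] = nu / Z
        return out


class IntactSystem:
    """Intact calmodulin: four conformations, one exclusive target site."""

    n_sites = 4

    def __init__(self, params: IntactParams, targets: Sequence[IntactTargetSpec] = ()):
        names = [t.name for t in targets]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate target names: {names}")
        self.params = params
        self.targets = tuple(targets)

    @property
    def target_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.targets)

    def _conformer_terms(self, ca: float, free: Mapping[str, float]):
        for conf in CONFORMATIONS:
            w = intact_conformer_weight(self.params, conf, ca)
            tfac = 1.0 + sum(free[t.name] / t.K(conf) for t in self.targets)
            yield conf, w, tfac

    def saturation(self, ca: float, free: Mapping[str, float]) -> float:
        num = 0.0
        Z = 0.0
        for conf, w, tfac in self._conformer_terms(ca, free):
            occ = 0.0
            for lobe_label, state in zip("NC", conf):
                lp = self.params.lobe(lobe_label)
                x = ca / (lp.K_R if state == "R" else lp.K_T)
                occ += 2.0 * x / (1.0 + x)
            num += w * tfac * occ
            Z += w * tfac
        return num / (4.0 * Z)

    def bound_targets(self, ca: float, free: Mapping[str, float]) -> dict[str, float]:
        Z = sum(w * tfac for _, w, tfac in self._conformer_terms(ca, free))
        out: dict[str, float] = {}
        for t in self.targets:
            nu = sum(
                intact_conformer_weight(self.params, conf, ca) * free[t.name] / t.K(conf)
                for conf in CONFORMATIONS
            )
            out[t.name] = nu / Z
        return out


@dataclass(frozen=True)
class Mixture:
    """A reaction chamber: one protein model plus target totals (molar)."""

    system: LobeSystem | IntactSystem
    protein_total: float
    target_totals: Mapping[str, float] = field(default_factory=dict)
    calcium_mode: str = "clamped_free"

    def __post_init__(self) -> None:
        if self.protein_total < 0:
            raise ValueError("protein_total must be >= 0")
        if self.calcium_mode not in ("clamped_free", "conserved_total"):
            raise ValueError(f"unknown calcium_mode {self.calcium_mode!r}")
        extra = set(self.target_totals) - set(self.system.target_names)
        if extra:
            raise ValueError(f"totals given for unknown targets: {sorted(extra)}")
        if any(v < 0 for v in self.target_totals.values()):
            raise ValueError("target totals must be >= 0")


@dataclass(frozen=True)
class EquilibriumSolution:
    ca_free: float
    free_targets: dict[str, float]
    bound_targets: dict[str, float]  # molar, per target
    Y: float
    bound_ca: float  # molar


def _solve_targets(
    system, ca: float, totals: Mapping[str, float], p_tot: float, tol: float = 1e-10
) -> dict[str, float]:
    names = [n for n in system.target_names if totals.get(n, 0.0) > 0]
    free = {n: totals.get(n, 0.0) for n in system.target_names}
    if not names or p_tot == 0.0:
        return free
    for _ in range(200):
        worst = 0.0
        for n in names:
            tot = totals[n]

            def resid(f: float) -> float:
                trial = dict(free, **{n: f})
                return tot - f - p_tot * system.bound_targets(ca, trial)[n]

            # bound_t grows with free_t, so the residual decreases and the
            # root is unique in (0, tot]; bisect on log(free) so the root
            # is located with relative precision even when nearly depleted
            lo_u, hi_u = math.log(tot) - 80.0, math.log(tot)
            if resid(math.exp(lo_u)) <= 0.0:
                free[n] = math.exp(lo_u)  # effectively fully depleted
            elif resid(tot) >= 0.0:
                free[n] = tot  # effectively no binding
            else:
                u = optimize.brentq(
                    lambda v: resid(math.exp(v)), lo_u, hi_u, xtol=1e-13, rtol=1e-15
                )
                free[n] = math.exp(u)
            worst = max(worst, abs(resid(free[n])) / max(tot, p_tot))
        if worst < tol:
            return free
    raise SolverError(
        f"target mass balance did not converge at ca={ca:g} M "
        f"(relative residual {worst:g})"
    )


def solve_free_concentrations(mixture: Mixture, ca: float) -> EquilibriumSolution:
    """Equilibrium at one calcium point.

    In ``clamped_free`` mode ``ca`` is the buffered free calcium; in
    ``conserved_total`` mode it is the total calcium and the free value
    is solved from calcium conservation as well.
    """
    if ca < 0:
        raise ValueError("calcium concentration must be >= 0")
    sys_ = mixture.system
    if mixture.calcium_mode == "clamped_free":
        ca_free = ca
    else:
        def ca_resid(caf: float) -> float:
            fr = _solve_targets(sys_, caf, mixture.target_totals, mixture.protein_total)
            return ca - caf - sys_.n_sites * mixture.protein_total * sys_.saturation(caf, fr)

        ca_free = float(optimize.brentq(ca_resid, 0.0, ca, rtol=1e-14)) if ca > 0 else 0.0
    free = _solve_targets(sys_, ca_free, mixture.target_totals, mixture.protein_total)
    per_protein = sys_.bound_targets(ca_free, free)
    Y = sys_.saturation(ca_free, free)
    return EquilibriumSolution(
        ca_free=ca_free,
        free_targets=free,
        bound_targets={n: v * mixture.protein_total for n, v in per_protein.items()},
        Y=Y,
        bound_ca=Y * sys_.n_sites * mixture.protein_total,
    )


@dataclass(frozen=True)
class SaturationCurve:
    """A solved titration: Y and free-target concentrations on a grid."""

    ca_free: np.ndarray
    Y: np.ndarray
    free_targets: dict[str, np.ndarray]

    def to_dataframe(self):
        import pandas as pd

        data = {"ca_free_molar": self.ca_free, "saturation": self.Y}
        for name, arr in self.free_targets.items():
            data[f"free_{name}_molar"] = arr
        return pd.DataFrame(data)

    def to_csv(self, path, metadata: Mapping[str, object] | None = None) -> None:
        from .io import write_curve_csv

        write_curve_csv(self, path, metadata=metadata)


def titration_curve(mixture: Mixture, ca_grid: np.ndarray | None = None) -> SaturationCurve:
    """Saturation curve over a free-calcium grid (clamped-free mode)."""
    grid = default_ca_grid() if ca_grid is None else np.asarray(ca_grid, dtype=float)
    Ys = np.empty_like(grid)
    frees = {n: np.empty_like(grid) for n in mixture.system.target_names}
    for i, ca in enumerate(grid):
        sol = solve_free_concentrations(mixture, float(ca))
        Ys[i] = sol.Y
        for n in frees:
            frees[n][i] = sol.free_targets[n]
    return SaturationCurve(ca_free=grid, Y=Ys, free_targets=frees)


def competing_targets_curve(
    mixture: Mixture, ca_grid: np.ndarray | None = None
) -> SaturationCurve:
    """Titration with two or more mutually exclusive targets.

    Requires an exclusive-binding system; removing all but one target
    reduces this exactly to :func:`titration_curve`.
    """
    sys_ = mixture.system
    if isinstance(sys_, LobeSystem) and sys_.binding != "exclusive":
        raise ValueError("competing targets require an exclusive-binding LobeSystem")
    active = [n for n in sys_.target_names if mixture.target_totals.get(n, 0.0) > 0]
    if len(active) < 2:
        raise ValueError("competing-targets scenario needs at least two targets present")
    return titration_curve(mixture, ca_grid)
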