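"""Synthetic calcium-titration data with literature-like scatter.

Published calmodulin titrations are plots of fractional saturation
against buffered free calcium; across laboratories the half-saturation
point scatters by roughly a factor of two while the free-calcium axis
itself is known precisely.  The generator emulates that structure:
exact two-state MWC curves (with or without target peptides at fixed
total concentrations) plus additive Gaussian noise on saturation and,
optionally, Gaussian jitter on log10 calcium.

``fixtures`` holds the model parameter bundles used throughout: fitted
lobe parameters, peptide affinities for lobe and intact-calmodulin
states, and the competing-target scenario composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .allosteric import LobeParams, TargetSpec
from .equilibrium import IntactSystem, LobeSystem, Mixture, titration_curve
from .intact import IntactParams, IntactTargetSpec

__all__ = [
    "TitrationDataset",
    "NoiseModel",
    "fixtures",
    "generate_titration",
    "make_benchmark_suite",
    "FIXTURE_NAMES",
]


@dataclass(frozen=True)
class NoiseModel:
    """Additive saturation noise and log-calcium jitter.

    Defaults: sigma_Y = 0.03, no x-jitter — free calcium in buffered
    titrations is known to high precision, so noise acts on saturation.
    """

    sigma_Y: float = 0.03
    sigma_logCa: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_Y < 0 or self.sigma_logCa < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class TitrationDataset:
    """Points of (free calcium, saturation) plus composition metadata."""

    ca_free: np.ndarray
    Y: np.ndarray
    weight: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ca = np.asarray(self.ca_free, dtype=float)
        if np.any(np.diff(ca) <= 0):
            raise ValueError("ca_free must be strictly increasing")
        Y = np.asarray(self.Y, dtype=float)
        if np.any((Y < -0.1) | (Y > 1.1)):
            raise ValueError("saturation outside the reporting range [-0.1, 1.1]")

    @property
    def n(self) -> int:
        return len(self.ca_free)

    @property
    def targets(self) -> list[tuple[str, float]]:
        return [tuple(t) for t in self.metadata.get("targets", [])]

    @property
    def protein_total(self) -> float:
        return float(self.metadata.get("protein_total", 0.0))


# --- parameter fixtures ------------------------------------------------

def _tr2c() -> LobeParams:
    return LobeParams(L=8.616e3, K_R=1.979e-8, K_T=6.241e-5)


def _nlobe() -> LobeParams:
    return LobeParams(L=3.226e5, K_R=1.979e-8, K_T=9.192e-5)


_FIXTURES = {
    # fitted C-lobe (TR2C) parameters; K_T_NaV is the co-fitted T-state
    # affinity of the NaV1.2IQp peptide
    "tr2c": lambda: {"params": _tr2c(), "K_T_NaV": 6.095e-10},
    "nlobe": lambda: {"params": _nlobe()},
    "intact": lambda: {"params": IntactParams(N=_nlobe(), C=_tr2c())},
    # peptide affinities for the isolated-lobe states (dissociation constants)
    # lobe-target specs bind one peptide per molecule (whole-molecule
    # binding; the per-subunit squared convention is the analytic default
    # of effective_allosteric_constant only)
    "wff_lobe": lambda: TargetSpec(
        "WFF", K_Rt=76e-9, K_Tt=1.6e-6, stoichiometry="per_molecule"
    ),
    "wf10_lobe": lambda: TargetSpec(
        "WF10", K_Rt=712e-9, K_Tt=1.1e-6, stoichiometry="per_molecule"
    ),
    # NaV1.2IQp: only upper limits are published; the bound values are
    # used as the dissociation constants (flagged), K_Rt pinned at its
    # 75 nM limit in all fitting
    "nav": lambda: TargetSpec(
        "NaV1.2IQp", K_Rt=75e-9, K_Tt=25e-9, stoichiometry="per_molecule"
    ),
    # NaV1.2IQp with the fitted T-state affinity
    "nav_fitted": lambda: TargetSpec(
        "NaV1.2IQp", K_Rt=75e-9, K_Tt=6.095e-10, stoichiometry="per_molecule"
    ),
    # whole-molecule affinities for the four intact conformations
    "wff_intact": lambda: IntactTargetSpec(
        "WFF", K_RR=0.1e-9, K_RT=600e-6, K_TR=735e-9, K_TT=600e-6
    ),
    "wf10_intact": lambda: IntactTargetSpec(
        "WF10", K_RR=735e-9, K_RT=200e-6, K_TR=735e-9, K_TT=200e-6
    ),
    # competing-target scenario: 40 uM TR2C with neurogranin (T-preferring,
    # 43 nM T / 1.05 uM R) and a CaMKII peptide (R-preferring, 88 uM T /
    # 0.95 uM R) at a 1:1:2.5 molar ratio
    "ng": lambda: TargetSpec("Ng", K_Rt=1.05e-6, K_Tt=43e-9, stoichiometry="per_molecule"),
    "camkii": lambda: TargetSpec(
        "CaMKII", K_Rt=0.95e-6, K_Tt=88e-6, stoichiometry="per_molecule"
    ),
    "fig_competition": lambda: {
        "protein_total": 40e-6,
        "targets": [(_FIXTURES["ng"](), 40e-6), (_FIXTURES["camkii"](), 100e-6)],
    },
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def fixtures(name: str):
    """Look up a transcribed parameter bundle by name."""
    try:
        factory = _FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}") from None
    return factory()


# --- generation --------------------------------------------------------

def _build_mixture(
    model: LobeParams | IntactParams,
    protein_total: float,
    targets: Sequence[tuple[TargetSpec | IntactTargetSpec, float]],
    binding: str = "independent",
) -> Mixture:
    specs = [t for t, _ in targets]
    totals = {t.name: tot for t, tot in targets}
    if isinstance(model, IntactParams):
        system = IntactSystem(model, specs)
    else:
        system = LobeSystem(model, specs, binding=binding)
    return Mixture(system=system, protein_total=protein_total, target_totals=totals)


def generate_titration(
    model: LobeParams | IntactParams,
    protein_total: float = 5e-6,
    targets: Sequence[tuple[TargetSpec | IntactTargetSpec, float]] = (),
    n_points: int = 25,
    ca_range: tuple[float, float] = (1e-8, 1e-3),
    noise: NoiseModel = NoiseModel(),
    seed: int | None = None,
    label: str = "",
) -> TitrationDataset:
    """One synthetic titration dataset, deterministic given ``seed``.

    The exact model curve is computed with full mass balance at the
    given totals, then noise is applied: log-normal jitter on the
    calcium axis (if configured) and additive Gaussian noise on
    saturation, clipped to the reporting range [-0.1, 1.1].
    """
    if n_points < 4:
        raise ValueError("a titration needs at least 4 points")
    rng = np.random.default_rng(seed)
    ca = np.geomspace(*ca_range, n_points)
    if noise.sigma_logCa > 0:
        ca = ca * 10.0 ** rng.normal(0.0, noise.sigma_logCa, size=n_points)
        ca = np.sort(ca)
    mixture = _build_mixture(model, protein_total, targets)
    curve = titration_curve(mixture, ca)
    Y = curve.Y.copy()
    if noise.sigma_Y > 0:
        Y = np.clip(Y + rng.normal(0.0, noise.sigma_Y, size=n_points), -0.1, 1.1)
    meta = {
        "label": label,
        "protein_total": protein_total,
        "targets": [[t.name, tot] for t, tot in targets],
        "provenance": {
            "seed": seed,
            "noise": {"sigma_Y": noise.sigma_Y, "sigma_logCa": noise.sigma_logCa},
            "model": _model_provenance(model),
            "target_specs": [_target_provenance(t) for t, _ in targets],
        },
    }
    return TitrationDataset(ca_free=ca, Y=Y, weight=np.ones(n_points), metadata=meta)


def _model_provenance(model) -> dict:
    if isinstance(model, IntactParams):
        return {"kind": "intact", "N": _model_provenance(model.N), "C": _model_provenance(model.C)}
    return {"kind": "lobe", "L": model.L, "K_R": model.K_R, "K_T": model.K_T}


def _target_provenance(t) -> dict:
    if isinstance(t, IntactTargetSpec):
        return {
            "name": t.name, "K_RR": t.K_RR, "K_RT": t.K_RT,
            "K_TR": t.K_TR, "K_TT": t.K_TT,
        }
    return {
        "name": t.name, "K_Rt": t.K_Rt, "K_Tt": t.K_Tt,
        "stoichiometry": t.stoichiometry,
    }


def make_benchmark_suite(
    seed: int,
    protein_total: float = 5e-6,
    n_points: int = 25,
    sigma_Y: float = 0.02,
) -> dict[str, dict[str, TitrationDataset]]:
    """The fit/validation dataset split used to benchmark the protocol.

    Three fitting datasets — TR2C alone, TR2C + WFF at a 1:1.4 molar
    ratio, TR2C + NaV1.2IQp at 1:1.4 — and two validation datasets —
    TR2C + WF10 at 1:1.4 and TR2C + NaV1.2IQp at 1:2.8 — all generated
    from the fitted C-lobe parameters.  Validation datasets are never
    used for fitting.
    """
    truth = fixtures("tr2c")["params"]
    wff = fixtures("wff_lobe")
    wf10 = fixtures("wf10_lobe")
    nav = fixtures("nav_fitted")
    noise = NoiseModel(sigma_Y=sigma_Y)
    seeds = np.random.SeedSequence(seed).generate_state(5)

    def gen(label, targets, s):
        return generate_titration(
            truth, protein_total=protein_total, targets=targets,
            n_points=n_points, noise=noise, seed=int(s), label=label,
        )

    r = 1.4 * protein_total
    return {
        "fit": {
            "alone": gen("tr2c_alone", [], seeds[0]),
            "wff": gen("tr2c_wff_1to1.4", [(wff, r)], seeds[1]),
            "nav": gen("tr2c_nav_1to1.4", [(nav, r)], seeds[2]),
        },
        "validation": {
            "wf10": gen("tr2c_wf10_1to1.4", [(wf10, r)], seeds[3]),
            "nav_2x": gen("tr2c_nav_1to2.8", [(nav, 2 * r)], seeds[4]),
        },
    }
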