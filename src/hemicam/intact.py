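"""Intact calmodulin: two independent lobes, four conformations.

Conformational transitions are concerted within a lobe but independent
between lobes (hemiconcerted), so the whole molecule samples four
conformations RR, RT, TR, TT.  By convention the first letter is the
N lobe, the second the C lobe ("RT" = N lobe open, C lobe closed).
A target binds the whole molecule (one per calmodulin) with a separate
dissociation constant for each of the four conformations.
"""

from __future__ import annotations

from dataclasses import dataclass

from .allosteric import LobeParams

__all__ = ["IntactParams", "IntactTargetSpec", "CONFORMATIONS", "intact_conformer_weight"]

CONFORMATIONS = ("RR", "RT", "TR", "TT")


@dataclass(frozen=True)
class IntactParams:
    """Lobe parameters of intact calmodulin (N = low-affinity lobe)."""

    N: LobeParams
    C: LobeParams

    def lobe(self, which: str) -> LobeParams:
        return self.N if which == "N" else self.C


@dataclass(frozen=True)
class IntactTargetSpec:
    """Whole-molecule target dissociation constants per conformation."""

    name: str
    K_RR: float
    K_RT: float
    K_TR: float
    K_TT: float

    def __post_init__(self) -> None:
        for label in CONFORMATIONS:
            if self.K(label) <= 0:
                raise ValueError(f"K_{label} must be positive")

    def K(self, conformation: str) -> float:
        return {
            "RR": self.K_RR,
            "RT": self.K_RT,
            "TR": self.K_TR,
            "TT": self.K_TT,
        }[conformation]


def intact_conformer_weight(params: IntactParams, conformation: str, ca_free: float) -> float:
    """Statistical weight of one conformation's calcium ensemble.

    Relative to the unliganded RR conformer: each lobe in state S
    contributes ``(1 + ca/K_S)^2`` for its two sites, and a lobe in the
    T state an extra factor ``L`` of that lobe (``L = [T0]/[R0]``).
    """
    w = 1.0
    for lobe_label, state in zip("NC", conformation):
        lp = params.lobe(lobe_label)
        K = lp.K_R if state == "R" else lp.K_T
        w *= (1.0 + ca_free / K) ** 2
        if state == "T":
            w *= lp.L
    return w
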