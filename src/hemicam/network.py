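"""Combinatorial generation of the hemiconcerted calmodulin network.

Intact calmodulin has four calcium sites (A, B on the N lobe; C, D on
the C lobe) and two conformations per lobe, concerted within a lobe but
independent between lobes.  Enumerating 2 x 2 conformations and 2^4
site occupancies yields 64 calmodulin species; each mutually exclusive
whole-molecule target doubles-by-addition that count (64 bound copies).

Reactions are generated from three rules and are thermodynamically
consistent by construction (all equilibrium constants derive from one
free-energy assignment, so every cycle satisfies the Wegscheider
condition):

1. calcium binds an empty site with the microscopic ``K_R`` or ``K_T``
   of that site's lobe in the species' current conformation;
2. a lobe flips T->R with equilibrium constant ``1/(L c^k)`` where k is
   the calcium count on that lobe — each bound calcium scales the
   allosteric constant by ``c`` — times the ratio of target affinities
   when a target is bound;
3. a target binds the whole molecule with the conformation's
   dissociation constant.

The same rules applied to a single lobe give the 8-species, 12-reaction
isolated-lobe (TR1C/TR2C) network.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .allosteric import LobeParams, TargetSpec
from .intact import IntactParams, IntactTargetSpec

__all__ = [
    "SpeciesState",
    "Reaction",
    "ReactionNetwork",
    "enumerate_species",
    "build_network",
    "network_equilibrium",
    "assign_intact_target_affinities",
    "wegscheider_residuals",
    "stoichiometry_matrix",
]

CA_ID = "Ca"
_NOMINAL_KF = 1.0e6  # uniform nominal association rate; only ratios matter


@dataclass(frozen=True, order=True)
class SpeciesState:
    """One enumerated protein species.

    ``conformations`` holds the per-lobe state ("T"/"R"), one entry per
    lobe (N first for intact calmodulin); ``occupancy`` one 0/1 entry
    per site, lobe i owning sites 2i and 2i+1; ``bound_target`` at most
    one target name (whole-molecule exclusive binding).
    """

    conformations: tuple[str, ...]
    occupancy: tuple[int, ...]
    bound_target: str | None = None

    @property
    def conf_label(self) -> str:
        return "".join(self.conformations)

    @property
    def conf_N(self) -> str:
        return self.conformations[0]

    @property
    def conf_C(self) -> str:
        return self.conformations[-1]

    def ca_on_lobe(self, lobe_index: int) -> int:
        return sum(self.occupancy[2 * lobe_index : 2 * lobe_index + 2])

    @property
    def n_ca(self) -> int:
        return sum(self.occupancy)

    def species_id(self, prefix: str = "CaM") -> str:
        sites = "".join(
            f"{label}{occ}" for label, occ in zip("ABCD", self.occupancy)
        )
        tid = f"_t{self.bound_target}" if self.bound_target else ""
        return f"{prefix}_{self.conf_label}_{sites}{tid}"


@dataclass(frozen=True)
class Reaction:
    """One reversible reaction with its association equilibrium constant.

    ``Keq = kf / kr`` refers to the forward direction as written
    (binding: association constant 1/Kd; flip: T->R).
    """

    rid: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    Keq: float
    kind: str  # "ca_binding" | "flip" | "target_binding"
    kf: float = _NOMINAL_KF

    @property
    def kr(self) -> float:
        return self.kf / self.Keq


def _target_K(spec: TargetSpec | IntactTargetSpec, conf_label: str) -> float:
    if isinstance(spec, IntactTargetSpec):
        return spec.K(conf_label)
    return spec.K_Rt if conf_label == "R" else spec.K_Tt


@dataclass
class ReactionNetwork:
    """Enumerated species plus rule-generated reversible reactions."""

    lobes: tuple[LobeParams, ...]
    species: list[SpeciesState]
    reactions: list[Reaction]
    targets: dict[str, TargetSpec | IntactTargetSpec]
    prefix: str = "CaM"

    @property
    def species_ids(self) -> list[str]:
        return [s.species_id(self.prefix) for s in self.species]

    @property
    def ligand_ids(self) -> list[str]:
        return [CA_ID, *self.targets]

    @property
    def reference_species(self) -> SpeciesState:
        """The apo all-T species every other species is reachable from."""
        return SpeciesState(("T",) * len(self.lobes), (0,) * (2 * len(self.lobes)))

    def log_weight(self, s: SpeciesState, ca_free: float, free_targets: Mapping[str, float]) -> float:
        """log statistical weight (relative concentration over apo all-T).

        Derived purely from the reaction equilibrium constants along a
        canonical path: bind calcium in the T conformation, then flip
        lobes, then bind the target.
        """
        w = 0.0
        for i, lobe in enumerate(self.lobes):
            k = s.ca_on_lobe(i)
            if k:
                if ca_free == 0.0:
                    return -math.inf
                w += k * math.log(ca_free / lobe.K_T)
            if s.conformations[i] == "R":
                # flip after binding k calcium: Keq = 1/(L c^k)
                w -= math.log(lobe.L) + k * math.log(lobe.c)
        if s.bound_target is not None:
            conc = free_targets.get(s.bound_target, 0.0)
            if conc == 0.0:
                return -math.inf
            w += math.log(conc / _target_K(self.targets[s.bound_target], s.conf_label))
        return w


def enumerate_species(
    params: IntactParams | LobeParams,
    targets: Sequence[IntactTargetSpec | TargetSpec] = (),
) -> list[SpeciesState]:
    """Enumerate every protein species of the combinatorial model.

    Intact calmodulin with no targets gives exactly
    2 (N conformation) x 2 (C conformation) x 2^4 (site occupancy) = 64
    species; each exclusive target adds a bound copy of all of them.
    """
    names = [t.name for t in targets]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate target names: {names}")
    n_lobes = 2 if isinstance(params, IntactParams) else 1
    out = []
    for confs in itertools.product("RT", repeat=n_lobes):
        for occ in itertools.product((0, 1), repeat=2 * n_lobes):
            for tname in (None, *names):
                out.append(SpeciesState(tuple(confs), tuple(occ), tname))
    return sorted(out, key=lambda s: (s.bound_target or "", s.conf_label, s.occupancy))


def build_network(
    params: IntactParams | LobeParams,
    targets: Sequence[IntactTargetSpec | TargetSpec] = (),
) -> ReactionNetwork:
    """Generate the full reaction network from the three binding rules."""
    intact = isinstance(params, IntactParams)
    lobes = (params.N, params.C) if intact else (params,)
    if not intact:
        for t in targets:
            if not isinstance(t, TargetSpec):
                raise ValueError("single-lobe networks take TargetSpec targets")
    else:
        for t in targets:
            if not isinstance(t, IntactTargetSpec):
                raise ValueError("intact networks take IntactTargetSpec targets")
    species = enumerate_species(params, targets)
    tmap = {t.name: t for t in targets}
    prefix = "CaM" if intact else "Lobe"
    index = {s: s.species_id(prefix) for s in species}
    reactions: list[Reaction] = []

    for s in species:
        sid = index[s]
        # rule 1: calcium binding at each empty site
        for site, occ in enumerate(s.occupancy):
            if occ:
                continue
            lobe_i = site // 2
            conf = s.conformations[lobe_i]
            Kd = lobes[lobe_i].K_R if conf == "R" else lobes[lobe_i].K_T
            new_occ = list(s.occupancy)
            new_occ[site] = 1
            prod = SpeciesState(s.conformations, tuple(new_occ), s.bound_target)
            reactions.append(
                Reaction(
                    rid=f"bind_{'ABCD'[site]}__{sid}",
                    reactants=(sid, CA_ID),
                    products=(index[prod],),
                    Keq=1.0 / Kd,
                    kind="ca_binding",
                )
            )
        # rule 2: concerted T->R flip of each lobe
        for lobe_i, conf in enumerate(s.conformations):
            if conf != "T":
                continue
            new_confs = list(s.conformations)
            new_confs[lobe_i] = "R"
            prod = SpeciesState(tuple(new_confs), s.occupancy, s.bound_target)
            lobe = lobes[lobe_i]
            k = s.ca_on_lobe(lobe_i)
            Keq = 1.0 / (lobe.L * lobe.c**k)
            if s.bound_target is not None:
                spec = tmap[s.bound_target]
                Keq *= _target_K(spec, s.conf_label) / _target_K(spec, prod.conf_label)
            reactions.append(
                Reaction(
                    rid=f"flip_{'NC'[lobe_i] if intact else 'L'}__{sid}",
                    reactants=(sid,),
                    products=(index[prod],),
                    Keq=Keq,
                    kind="flip",
                )
            )
        # rule 3: whole-molecule target binding
        if s.bound_target is None:
            for t in targets:
                prod = SpeciesState(s.conformations, s.occupancy, t.name)
                reactions.append(
                    Reaction(
                        rid=f"bindt_{t.name}__{sid}",
                        reactants=(sid, t.name),
                        products=(index[prod],),
                        Keq=1.0 / _target_K(t, s.conf_label),
                        kind="target_binding",
                    )
                )
    return ReactionNetwork(
        lobes=lobes, species=species, reactions=reactions, targets=tmap, prefix=prefix
    )


def wegscheider_residuals(network: ReactionNetwork) -> dict[str, float]:
    """Detailed-balance residual of every reaction against a potential.

    A free-energy potential phi is assigned to each species by walking a
    spanning tree of the reaction graph (ligand reference potentials set
    to zero).  Thermodynamic consistency requires every reaction to
    satisfy ``phi(products) - phi(reactants) = log Keq``; the residual of
    the off-tree reactions equals the log cycle product of the
    corresponding independent cycle, which must vanish.
    """
    import networkx as nx

    g = nx.Graph()
    details = {}
    for r in network.reactions:
        # protein species are the first reactant and the only product
        a = r.reactants[0]
        b = r.products[0]
        g.add_edge(a, b, logK=math.log(r.Keq), src=a, rid=r.rid)
        details[r.rid] = (a, b, math.log(r.Keq))
    root = network.reference_species.species_id(network.prefix)
    phi = {root: 0.0}
    tree = nx.bfs_tree(g, root)
    for u, v in nx.bfs_edges(g, root):
        d = g[u][v]
        delta = d["logK"] if d["src"] == u else -d["logK"]
        phi[v] = phi[u] + delta
    return {
        rid: (phi[b] - phi[a]) - logK for rid, (a, b, logK) in details.items()
    }


def network_equilibrium(
    network: ReactionNetwork,
    protein_total: float,
    target_totals: Mapping[str, float] | None = None,
    ca_free: float = 0.0,
) -> dict[str, float]:
    """Equilibrium species concentrations at clamped free calcium.

    Statistical weights relative to the apo all-T species are taken
    from the reaction equilibrium constants; protein and target totals
    are then imposed by mass balance (free-target roots are unique
    because bound target is monotone in free target).  Returns a dict
    of concentrations for every species plus ``free_<target>`` entries.
    """
    target_totals = dict(target_totals or {})
    unknown = set(target_totals) - set(network.targets)
    if unknown:
        raise ValueError(f"totals for unknown targets: {sorted(unknown)}")

    def concentrations(free_t: Mapping[str, float]) -> dict[str, float]:
        logw = np.array(
            [network.log_weight(s, ca_free, free_t) for s in network.species]
        )
        m = logw.max()
        w = np.exp(logw - m)
        scale = protein_total / w.sum()
        return dict(zip(network.species_ids, w * scale))

    def bound_of(conc: Mapping[str, float], tname: str) -> float:
        return sum(
            conc[s.species_id(network.prefix)]
            for s in network.species
            if s.bound_target == tname
        )

    free = {n: target_totals.get(n, 0.0) for n in network.targets}
    active = [n for n, tot in target_totals.items() if tot > 0]
    if active and protein_total > 0:
        for _ in range(200):
            worst = 0.0
            for n in active:
                tot = target_totals[n]

                def resid(f: float) -> float:
                    c = concentrations(dict(free, **{n: f}))
                    return tot - f - bound_of(c, n)

                # log-space bisection locates nearly-depleted roots precisely
                lo_u, hi_u = math.log(tot) - 80.0, math.log(tot)
                if resid(math.exp(lo_u)) <= 0.0:
                    free[n] = math.exp(lo_u)
                elif resid(tot) >= 0.0:
                    free[n] = tot
                else:
                    u = optimize.brentq(
                        lambda v: resid(math.exp(v)), lo_u, hi_u, xtol=1e-13, rtol=1e-15
                    )
                    free[n] = math.exp(u)
                worst = max(worst, abs(resid(free[n])) / max(tot, protein_total))
            if worst < 1e-10:
                break
        else:
            raise RuntimeError(
                f"network equilibrium did not converge (relative residual {worst:g})"
            )
    conc = concentrations(free)
    for n, f in free.items():
        conc[f"free_{n}"] = f
    return conc


def network_saturation(network: ReactionNetwork, conc: Mapping[str, float]) -> float:
    """Fractional calcium saturation from solved species concentrations."""
    n_sites = 2 * len(network.lobes)
    tot = sum(conc[s.species_id(network.prefix)] for s in network.species)
    bound = sum(
        s.n_ca * conc[s.species_id(network.prefix)] for s in network.species
    )
    return bound / (n_sites * tot)


def assign_intact_target_affinities(
    name: str,
    K_apo: float,
    K_ca_saturated: float,
    K_TR2C_Rstate: float,
) -> IntactTargetSpec:
    """Map the three measurable affinities onto the four conformations.

    Measured target affinities exist for calcium-free calmodulin
    (TT-dominant), calcium-saturated calmodulin (RR-dominant) and the
    calcium-saturated C-lobe fragment.  The assignment: RR gets the
    saturated-CaM value, TT the apo value, TR (C lobe open) the R-state
    TR2C value, and RT — where only the weakly interacting N lobe is
    open — is taken roughly equal to the TT/apo value.
    """
    return IntactTargetSpec(
        name=name,
        K_RR=K_ca_saturated,
        K_RT=K_apo,
        K_TR=K_TR2C_Rstate,
        K_TT=K_apo,
    )


def stoichiometry_matrix(network: ReactionNetwork) -> tuple[list[str], list[str], np.ndarray]:
    """(row ids, reaction ids, matrix) with net stoichiometry entries."""
    rows = network.species_ids + network.ligand_ids
    idx = {r: i for i, r in enumerate(rows)}
    mat = np.zeros((len(rows), len(network.reactions)))
    for j, r in enumerate(network.reactions):
        for sp in r.reactants:
            mat[idx[sp], j] -= 1
        for sp in r.products:
            mat[idx[sp], j] += 1
    return rows, [r.rid for r in network.reactions], mat
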