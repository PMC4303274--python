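# Methods

## Model

Each calmodulin lobe is a two-state, two-identical-site MWC unit. The
statistical weights relative to the unliganded R conformer are
`(1+α)²` for the R ensemble and `L(1+αc)²` for the T ensemble, with
`α = [Ca²⁺]_free/K_R` and `c = K_R/K_T ≤ 1`. Fractional saturation,
the R-population fraction and the half-saturation point
`α½ = sqrt((1+L′)/(1+L′c²))` all follow in closed form. A target
peptide with dissociation constants `K_Rt`, `K_Tt` for the two states
multiplies the conformer weights by `(1+γ)ⁿ` and `(1+γe)ⁿ`
(`γ = [A]_free/K_Rt`, `e = K_Rt/K_Tt`), which is algebraically a
rescaling of the allosteric constant, `L′ = L((1+γe)/(1+γ))ⁿ`.

Two stoichiometry conventions are supported and must not be mixed up:

* `per_subunit` (n = 2) — one effector per calcium site, the classical
  squared form. This is the default of the bare analytic function
  `effective_allosteric_constant`.
* `per_molecule` (n = 1) — one peptide per lobe. All peptide fixtures,
  the equilibrium scenarios and the fitting protocol use this
  convention: target peptides occupy the hydrophobic groove of a whole
  lobe, and one molecule cannot carry two. The convention is observable:
  with per-subunit binding a 5 µM lobe solution can absorb 10 µM of
  peptide, so doubling the NaV1.2IQp dose from 1:1.4 to 1:2.8 moves the
  half-saturation by ~0.37 decades; with per-molecule binding the
  binding capacity is 5 µM, the modulation is already saturated at
  1:1.4, and the measured additional shift is 0.005 decades — matching
  the experimental observation that the second dose produces no further
  shift.

Intact calmodulin is the product of two independent lobe partition
functions (lobe coupling is omitted; truncated-fragment and intact-lobe
titrations superpose within the scatter of the data, so any coupling is
below the noise level). Whole-molecule targets bind each of the four
conformations RR, RT, TR, TT with its own dissociation constant; at
most one target per molecule, competition is mutually exclusive.

## Parameter fixtures (molar units)

| fixture | values |
|---|---|
| `tr2c` (C-lobe) | L = 8.616·10³, K_R = 1.979·10⁻⁸, K_T = 6.241·10⁻⁵, K_T_NaV = 6.095·10⁻¹⁰ |
| `nlobe` | L_N = 3.226·10⁵, K_R = 1.979·10⁻⁸, K_T = 9.192·10⁻⁵ |
| `wff_lobe` | K_Rt = 76 nM, K_Tt = 1.6 µM (e ≈ 0.0475, R-preferring) |
| `wf10_lobe` | K_Rt = 712 nM, K_Tt = 1.1 µM |
| `nav` | K_Rt = 75 nM, K_Tt = 25 nM — published upper limits used as values |
| `wff_intact` | K_RR = 0.1 nM, K_RT = 600 µM, K_TR = 735 nM, K_TT = 600 µM |
| `wf10_intact` | K_RR = 735 nM, K_RT = 200 µM, K_TR = 735 nM, K_TT = 200 µM |
| `ng` / `camkii` | 43 nM / 1.05 µM and 88 µM / 0.95 µM (T / R) |

Affinities published only as inequalities (`<0.1 nM`, `>600 µM`,
`≤75 nM`, `≤25 nM`) are encoded at their bound values; they are
configurable wherever they enter. The intact-CaM assignment rule maps
the three measurable affinities onto four conformations: RR ← saturated
CaM, TT ← apo CaM, TR ← R-state C-lobe fragment, RT ≈ apo (the open
N lobe interacts only weakly with targets). The WFF/WF10 TR value of
735 nM is kept as printed for the intact molecule even though the
lobe-level WF10 R-state value is 712 nM; the two transcriptions are
deliberately not reconciled.

## Equilibrium solving

Titrations clamp free calcium (buffered experiments) and conserve
protein and target totals. Free-target concentrations solve
`total = free + bound(free)` on the binding polynomial; `bound` is
monotone in `free`, so each root is unique and bracketed in
`(0, total]`. Roots are found by Brent bisection on log-free
concentration (relative precision even when the target is >99.99%
depleted), sweeping coordinate-wise for multiple targets until every
conservation residual is below 10⁻¹⁰ relative to the larger of the
target and protein totals. A conserved-total-calcium mode wraps the
same solve in an outer calcium-conservation bracket. The default grid
is 60 log-spaced points from 10 nM to 1 mM.

Multi-target conventions: independent binding multiplies per-target
factors (the product generalisation of the effective-L formula);
mutually exclusive competition (used for the neurogranin/CaMKII
scenario: 40 µM lobe, 40 µM Ng, 100 µM CaMKII, a 1:1:2.5 ratio) sums
γ terms inside one binding site. The two coincide for a single target.

## Reaction-network generation

Species are enumerated combinatorially (conformation per lobe ×
occupancy of sites A, B, C, D × bound target; 64 calmodulin species
with no targets, 64 more per exclusive target). Three rules generate
reactions: per-site calcium binding with the microscopic `K_R`/`K_T` of
the site's lobe in the current conformation; concerted per-lobe flips
with R→T constant `L·c^k` after k calcium bind that lobe, times the
ratio of target affinities when a target is bound; and whole-molecule
target binding with the conformation's constant. All equilibrium
constants derive from one free-energy assignment, so every reaction
cycle satisfies detailed balance by construction; `wegscheider_residuals`
verifies this independently by assigning a potential over a spanning
tree and checking every off-tree reaction (residuals ~10⁻¹⁵, asserted
< 10⁻⁹). Kinetic rates are not modelled: forward rates are a uniform
nominal value and backward rates follow from the equilibrium constants,
so only equilibria are meaningful.

`network_equilibrium` computes species concentrations from statistical
weights accumulated along the rule set (log-space for overflow safety)
plus protein/target mass balance — an independent route that must and
does agree with the closed forms to better than 10⁻⁸ in saturation.

SBML Level 3 Version 1 documents are written and re-read directly as
XML (lxml): one compartment, boundary-condition calcium, reversible
mass-action kinetic laws `kf·reactants − kr·products` with
`kf/kr = K_eq`. Species identifiers encode the enumeration
(`CaM_RT_A1B0C1D0_tWFF`), and a re-imported document reproduces the
stoichiometry matrix exactly.

## Synthetic titrations

The generator emulates the statistical structure of published
calcium titrations: exact model curves at total compositions, additive
Gaussian saturation noise (default σ_Y = 0.03; the x axis is exact by
default because buffered free calcium is known precisely), optional
log₁₀-calcium jitter for robustness studies, 25 log-spaced points over
10 nM–1 mM, and full provenance (seed, noise, generating parameters) in
the metadata, which round-trips through the CSV header. With
σ_Y = 0.05 and 0.1-decade x-jitter, replicate half-saturation estimates
stay inside the factor-two band that separates published curves of the
same fragment — the scatter the noise defaults were chosen to emulate.

The benchmark suite generates the protocol's fit/validation split from
the fitted C-lobe parameters at 5 µM protein: three fitting datasets
(lobe alone, +WFF 1:1.4, +NaV1.2IQp 1:1.4) and two validation datasets
(+WF10 1:1.4, +NaV1.2IQp 1:2.8) at σ_Y = 0.02. The 5 µM protein total
is a design choice: the source experiments do not state absolute
concentrations, only molar ratios. What passing recovery tests on these
data do *not* show: robustness to the systematic inter-laboratory
offsets, baseline/normalisation distortions and x-axis calibration
errors of real digitised curves, none of which the noise model
represents.

## Fitting protocol

The C-lobe fit searches (log₁₀ L, log₁₀ K_R, log₁₀ K_T, log₁₀ K_T_NaV)
with bounds L ∈ [1, 10⁸], K_R ∈ [0.1, 20] nM, K_T ∈ [10 µM, 1 mM],
K_T_NaV ∈ [0.01, 25] nM and the linear log-space constraint
c = K_R/K_T ≤ 0.002; WFF affinities are fixed at their measured values
and the NaV R-state affinity at its 75 nM upper limit. The optimiser is
seeded differential evolution with a total population of 20 and a
generation budget of 1000 (convergence tolerance usually stops it far
earlier), followed by a local polish; constraint handling is
feasibility-first. The score is `S = Σ_k (1/n_k) Σ_i (Y_model − Y_obs)²`
— the 1/n_k weight makes datasets with different point counts
contribute comparably; no other weighting scheme is implied by the
data. Residual-bootstrap standard deviations (200 resamples, seeded,
local re-polish) are available for both protocols but are not part of
the default fit.

The N-lobe is parameterised in two steps: K_T from a non-cooperative
two-identical-site fit `Y = x/(K_T + x)` to a disulfide-locked closed
mutant (a Hill fit with n > 1.2 raises a cooperativity warning flag),
then L from the wild-type lobe curve with K_R shared with the C-lobe —
both lobes are assumed to have the same open-state calcium affinity.

## Numerical choices

* Hill slopes: exact rational-derivative formula
  `n_H = 1 + αA′/A − αB′/B` for analytic MWC curves; Richardson-refined
  central differences on the log axis (relative step 10⁻³, refined
  until successive estimates agree to 10⁻⁶) for black-box curves.
* Half-saturation: Brent bisection to 10⁻¹⁰ relative, with a
  non-bracketing diagnostic.
* Infinite calcium is handled as an analytic limit, never as a float.
* Landscape sublevel widths measure decades of L in
  `{S ≤ (1+margin)·S_min}` on the evaluation grid.
* Tie-breaking among equal-score feasible points prefers the lowest L
  (deterministic reporting; in practice the polish step settles ties).

## Identifiability and known limitations

The target-free titration alone cannot identify (L, c): the score
surface has a flat diagonal valley along which `L·c²` is approximately
constant, exactly as the (L, c) exploration reproduces. The target
datasets and the pure-state bounds exclude the low-L/high-c branch —
the fitted K_R sits essentially on its 20 nM bound — but a *high-L*
residual degeneracy remains: a saturated target multiplies `L·c²` by
the constant `eⁿ`, so target-induced shifts are themselves nearly
invariant along the valley. Consequences worth knowing:

* Replicate noisy fits usually recover log₁₀ L within ±0.3, but
  occasional runs wander up the valley (with K_R falling as 1/√L); L
  should be read with a generous uncertainty, consistent with the
  factor-two insensitivity of the half-saturation point to L
  (doubling or halving L moves the midpoint by ≤ log₁₀2 ≈ 0.30, and in
  practice ≈ 0.15, decades).
* The 5%-of-minimum sublevel set of the (L, c) landscape is not a
  robust valley statistic at realistic noise: with noisy data the
  minimum sits at the noise floor and the band's extent is dominated by
  noise, while with noiseless data the fixed-K_T slice has a sharp
  tangency minimum. The robust statements — a broad near-optimal
  region on the target-free surface and a much harsher relative penalty
  at low L once target data are added — are what the tests assert.
* Fitted standard deviations are bootstrap estimates over residuals;
  no claim is made that they reproduce any particular published
  uncertainty column.
* Kinetics (rate constants, time courses), magnesium/buffer effects,
  and simultaneous multi-target binding to one molecule are out of
  scope; the network's rate constants are placeholders consistent with
  the equilibria.
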