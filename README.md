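# hemicam

Hemiconcerted Monod–Wyman–Changeux (MWC) allosteric modelling of
calmodulin: closed-form saturation theory for the isolated lobes,
combinatorial generation of the 64-species intact-calmodulin reaction
network with SBML export, equilibrium solving at total reagent
concentrations, Hill-plane analysis, and a constrained fitting protocol
with a synthetic titration-data generator.

## The scientific problem

Calmodulin transduces intracellular calcium signals by binding Ca²⁺ at
four EF-hand sites organised in two globular lobes (N and C). Each lobe
behaves as one cooperative unit: its two sites flip together between a
closed, low-affinity **T** conformation and an open, high-affinity **R**
conformation. The two lobes switch independently, so the intact molecule
samples four conformations (RR, RT, TR, TT) — *hemiconcerted*
transitions. Target peptides (kinase domains, IQ motifs, neurogranin…)
bind the conformations with different affinities and thereby shift the
calcium saturation curve without touching the calcium sites: a target
that prefers R left-shifts the curve, one that prefers T right-shifts
it. This package implements that model for quantitative work: simulating
titrations, analysing cooperativity, and reverse-engineering the
intrinsic state affinities from published-style saturation curves.

## The model

For one lobe with two identical sites, fractional saturation at free
calcium concentration giving α = [Ca²⁺]/K_R is

    Y = [α(1+α) + L′αc(1+αc)] / [(1+α)² + L′(1+αc)²]

with allosteric constant L = [T₀]/[R₀], affinity ratio c = K_R/K_T, and
an effective allosteric constant under target modulation

    L′ = L · ((1+γe)/(1+γ))ⁿ,   γ = [A]free/K_Rt,   e = K_Rt/K_Tt,

(n = 2 for per-subunit binding, n = 1 for one target per molecule).
Cooperativity is summarised by the Hill coefficient
n_H = d log(Y/(1−Y))/d log α. The intact molecule is the product of two
independent lobe partition functions with whole-molecule target binding
per conformation; enumerating 2×2 conformations × 2⁴ occupancies gives
64 species, generated together with all binding and flip reactions under
exact detailed balance (Wegscheider cycle condition) and exported as
SBML Level 3.

Fitting follows a constrained protocol: (L, K_R, K_T, and the T-state
affinity of the NaV1.2 IQ peptide) are fitted simultaneously to three
titrations (lobe alone, + skMLCK peptide WFF, + NaV1.2IQp) by seeded
differential evolution in log space under the pure-state bounds
K_R ≤ 20 nM, K_T ≥ 10 µM, c ≤ 0.002, because the target-free curve alone
leaves (L, c) degenerate along a flat score valley.

## Worked example

```python
from hemicam import (fixtures, half_saturation_ca, hill_coefficient_mwc,
                     LobeSystem, Mixture, solve_free_concentrations)
from hemicam.hill import half_saturation

tr2c = fixtures("tr2c")["params"]          # fitted C-lobe parameters
print(f"c = K_R/K_T           = {tr2c.c:.3e}")
print(f"half-saturation       = {half_saturation_ca(tr2c):.3e} M")
print(f"Hill coefficient n_H  = {hill_coefficient_mwc(tr2c, half_saturation_ca(tr2c)):.3f}")

wff = fixtures("wff_lobe")                 # skMLCK peptide, prefers R
mix = Mixture(system=LobeSystem(tr2c, [wff]), protein_total=5e-6,
              target_totals={"WFF": 7e-6})
shifted = half_saturation(lambda ca: solve_free_concentrations(mix, ca).Y)
print(f"half-saturation + WFF = {shifted:.3e} M")
```

prints

```
c = K_R/K_T           = 3.171e-04
half-saturation       = 1.836e-06 M
Hill coefficient n_H  = 1.923
half-saturation + WFF = 4.921e-07 M
```

The C-lobe half-saturates at 1.84 µM free calcium with a Hill
coefficient just below the two-site ceiling of 2; adding the
R-preferring WFF peptide at a 1:1.4 molar ratio pulls the midpoint to
0.49 µM — a 3.7-fold affinity gain produced purely by conformational
stabilisation.

The same pipeline is scriptable from the shell:

```
hemicam simulate --fixture tr2c --out curve.csv
hemicam sbml --fixture intact --target wff_intact --out cam_wff.xml
hemicam synth --seed 1 --out-dir data/
hemicam fit --alone data/fit_alone.csv --wff data/fit_wff.csv \
            --nav data/fit_nav.csv --seed 1 --out fit.json
hemicam hill --fixture tr2c
```

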