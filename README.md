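# protonfes

Free-energy machinery for proton-transfer tautomerization, at desk scale.

Rare enol tautomers of guanine and thymine turn a wobble G·T mispair (wGT)
into Watson–Crick-like mispairs (GT\*, G\*T) that can slip past replication
proofreading.  Studying that chemistry computationally takes a specific
toolchain: umbrella sampling over distance-difference reaction coordinates
ξ = R(donor,H) − R(acceptor,H), finite-temperature string optimization of
the minimum free energy path (MFEP), MBAR estimation of multidimensional
free-energy surfaces A(ξ), ring-polymer path-integral MD (PIMD) for
nuclear quantum effects, Δ-machine-learning corrections that upgrade a
cheap potential to reference accuracy, and transition-state-theory rates
k ∝ exp(−ΔA‡/kBT).

`protonfes` implements that entire toolchain against analytic model
systems — a planar eight-particle cluster with two transferable protons
emulating the wGT/GT\*/G\*T triad, plus harmonic, quartic double-well and
Müller-Brown benchmarks — so every estimator can be validated against
closed forms and independent oracles.  It is aimed at method developers
and students of free-energy simulation who need a transparent, fully
checkable reference implementation.

Core quantities, in the field's standard notation:

* umbrella bias `U = Σᵢ kᵢ (ξᵢ − ξ⁰ᵢ)²` (Amber-style, no ½; default
  k = 200 kcal mol⁻¹ Å⁻²);
* MBAR per-window free energies `f_k` solving
  `f_k = −ln Σₙ exp(−u_kn)/Σₗ Nₗ exp(f_l − u_ln)`;
* profiles `A(s) = −kBT ln ρ̂(ξ(s))` along the string's progress variable
  `s ∈ [0,1]`, with σ_err the SEM over independent trials;
* ring polymer `U_P = Σₙ ½ m ω_sp²|rₙ−rₙ₊₁|² + (1/P)Σₙ V(rₙ)`,
  ω_sp = √P/(βħ), with centroid restraints and the proton "degree of
  expansion" Δ|r_H| = (1/P)Σₙ |r_{H,n} − u_{H,c}|;
* TST factors `exp(ΔΔA‡/kBT)` and populations `exp(−ΔA/kBT)`.

See `docs/methods.md` for models, conventions and limitations.

## Worked example

The bundled reference table (`protonfes.refdata`) holds published
free-energy values for the three tautomerization steps of a G·T mispair in
B-DNA at 298 K.  The kinetics module turns the classical vs PIMD barriers
of the enol interconversion GT\* → G\*T into quantum rate-enhancement
factors:

```python
from protonfes.kinetics import tst_ratio, population_ratio
print(round(tst_ratio(7.06, 4.21, 298.0), 1))   # forward barriers, kcal/mol
print(round(tst_ratio(7.49, 3.95, 298.0), 1))   # reverse barriers
print(round(population_ratio(-0.43, 298.0), 2)) # K for dA = -0.43 kcal/mol
```

prints

```
123.1
394.6
2.07
```

— nuclear quantum effects speed the forward transfer ~123× and the reverse
~395×, while the GT\*:G\*T population ratio stays ~2:1.  The comparison
table for the same step (Δ columns vs the experimental estimate):

```
reaction   method         dA(err)             D  dAf(err)            D  dAr(err)            D
GT*->G*T   experiment     -0.62                  9.21                   9.83
GT*->G*T   PBE0/6-31G*    -0.91 (0.03)    -0.29  6.72 (0.05)     -2.49  7.63 (0.05)     -2.20
GT*->G*T   AM1/d          -1.36 (0.03)    -0.74  10.26 (0.03)    +1.05  11.62 (0.04)    +1.79
GT*->G*T   QM/MM-dMLP     -0.43 (0.07)    +0.19  7.06 (0.07)     -2.15  7.49 (0.07)     -2.34
GT*->G*T   PIMD           0.26 (0.03)     +0.88  4.21 (0.03)     -5.00  3.95 (0.04)     -5.88
```

An end-to-end simulation of the same physics on the toy cluster (string
optimization, then classical and P = 16 PIMD umbrella production, MBAR
profiles, barrier extraction):

```python
from protonfes.benchmarks import gt_nqe_comparison
r = gt_nqe_comparison(seed=1)
print(round(r["classical_barrier"], 2), round(r["pimd_barrier"], 2))
```

prints `7.65 5.16`: the concerted double-proton transfer loses ≈ 2.5
kcal/mol of barrier when the protons are quantized, and each proton's
ring-polymer expansion Δ|r_H| peaks at the crossing of its donor–H and
acceptor–H distance curves.

## Command line

```sh
protonfes all --system double_well_1d --outdir run1 --seed 7
protonfes build-system --system gt_toy --outdir gt
protonfes run-pimd --system gt_toy --beads 16 --outdir gt_pimd --seed 1
protonfes report run1
```

Each run directory carries a config copy, plain-text window/path/profile
tables with unit headers, and a SHA-256 manifest; the same config and seed
reproduce identical files.

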