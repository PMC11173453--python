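# Methods

`protonfes` re-creates, at desk scale, the free-energy machinery used to
study proton-transfer tautomerization in nucleobase mispairs: umbrella
sampling over distance-difference reaction coordinates, finite-temperature
string optimization of minimum free energy paths (MFEPs), MBAR estimation
of multidimensional free-energy surfaces, classical versus ring-polymer
path-integral dynamics, Δ-learning corrections from a cheap to a reference
potential, and transition-state-theory (TST) rate and population analysis.
This note records the models, conventions, parameter choices and known
limitations.

## Units and constants

Energies kcal/mol, lengths Å, time fs, mass amu, temperature K.  kB and ħ
are derived from SI values at import (`constants.py`): kB =
1.9872043e-3 kcal/mol/K, ħ = 15.17873 kcal·fs/mol.  A force of
1 kcal/mol/Å accelerates 1 amu by 4.184e-4 Å/fs² (thermochemical calorie).

## The toy G–T cluster

The model system is a planar eight-particle cluster carrying the
hydrogen-bonding atom labels of a wobble G–T pair (N3, H3, O6, O4, N1, H1,
N2, O2).  Two protons are transferable: H3 between N3 and O6, H1 between
N1 and O4.  The two reaction coordinates are the distance differences
ξ1 = R(N3,H3) − R(O6,H3) and ξ2 = R(N1,H1) − R(O4,H1), the standard
proton-transfer coordinates (negative: bound to donor; positive:
transferred).

The reference potential is built entirely from interparticle distances
(hence exactly invariant under rigid motions) as a sum of

* a reaction-coordinate potential on (ξ1, ξ2): a confining quartic bowl,
  three Gaussian wells (depths 13.0, 10.5, 11.0 kcal/mol, width 0.38 Å) at
  the wGT (−0.8, −0.8), GT* (+0.8, −0.8) and G*T (−0.8, +0.8) analog
  states, two positive Gaussian ridges (6.0 kcal/mol, width 0.35 Å) at the
  single-transfer saddles, and a bilinear shear coupling 0.5·ξ1·ξ2;
* stiff harmonic scaffold bonds (300 kcal/mol/Å²) between all heavy-atom
  pairs at their reference geometry;
* a collinearity term 100·(R(d,H) + R(a,H) − R(d,a)) per proton that
  confines it near its donor–acceptor axis.

The ridges enforce the experimentally observed ordering of the real
system: high barriers for the wobble→enol steps (the toy gives ≈ 12
kcal/mol for wGT→GT*) and a much lower barrier for the concerted
double-proton interconversion GT*→G*T (≈ 7.7 kcal/mol classical), so the
enol–enol step proceeds through the concerted channel near (0, 0) rather
than back through the wobble state.  Named states are polished to true
minima (max |∇V| < 1e-6 kcal/mol/Å, L-BFGS plus a Levenberg–Marquardt
stationarity polish) at build time; parameter sets that fail to produce
three distinct basins are rejected.

The proton wells are deliberately stiff: the position-space curvature at a
well bottom corresponds to an O–H/N–H-stretch-like frequency of roughly
2000 cm⁻¹, so that nuclear quantum effects on the transfer barrier are
physically sized (βħω ≈ 10 at 298 K).

The *base* surface (the stand-in for a fast semiempirical model) is the
reference minus a smooth truth correction: three Gaussians of amplitude
−2.5 kcal/mol (width 0.45 Å) in ξ-space centered at the saddle regions, so
the base model overestimates every barrier by ≈ 2.5–3.3 kcal/mol.  This
gives the Δ-learning problem a known, smooth ground truth.

## Umbrella sampling

The bias is U = Σᵢ kᵢ (ξᵢ − ξ⁰ᵢ)² — the force constant multiplies the
squared deviation directly with **no factor ½** (the convention of
Amber-style restraint definitions, under which the standard choice k = 200
kcal/mol/Å² produces window widths σ = √(kBT/2k) ≈ 0.04 Å at 298 K).  The
MBAR module consumes the identical convention.

Dynamics is BAOAB Langevin (velocity Verlet at γ = 0); defaults dt =
0.5 fs for classical toy runs, collision frequency γ = 5 ps⁻¹, T = 298 K,
coordinates recorded every 10 fs.  One RNG stream per (window, trial) is
derived from a SeedSequence keyed on (base seed, window id, trial id), so
trials are decorrelated the way independently seeded thermostats are, and
every run is bit-reproducible from (config, seed).  Window ladders
propagate as one batched state (leading axis = window) without changing
the per-window stream semantics.

Initial window configurations minimize surface+bias, windows prepared in
sequence along the ladder; production runs reuse the string's final
configurations.

## Finite-temperature string method

A string is M images in ξ-space with equal-arc-length parametrization
(progress s ∈ [0,1]).  Per iteration: umbrella windows at the images are
sampled briefly; each interior image moves a fraction η (default 0.3)
toward its window's sample mean; a three-point smoothing with weight κ
(default 0.1) suppresses sawtooth noise; the string is reparametrized by
piecewise-linear resampling to equal arc length (new images lie exactly on
the old polyline; chord length is preserved to O(h²)).  Endpoints are
minimized in coordinate space at setup and held fixed, which keeps the
named states well defined; convergence is reported as the RMS image
displacement per iteration (threshold 0.01 Å, iterations capped at the
scheduled count).

Two practical lessons are encoded in the Müller-Brown benchmark defaults
(32 images, string phase at kBT ≈ 1 with k = 800, η = 0.5): restrained
clouds must stay *harmonic* (steep anharmonic landscapes leak probability
over ridges and bias the sample mean, stalling the string on a
corner-cutting channel), and the per-iteration image motion is limited by
η|F|/2k, so overly stiff windows converge slowly.  Production for the
profile then runs warmer (kBT ≈ 2) so adjacent windows overlap for MBAR.

## MBAR and profiles

Reduced bias energies u_kn = β Σᵢ kᵢ (ξ_ni − ξ⁰_ki)² feed the standard
self-consistent MBAR equations, solved in log space: a sequential
exponential-averaging warm start, a short damped self-consistent phase,
then Newton iterations on the convex (UWHAM) objective to residual 1e-10.
Window overlap is diagnosed with the MBAR overlap matrix; a smallest
adjacent overlap below 0.01 emits a warning naming the weakly connected
groups.

Profiles along a path are kernel density estimates of the
MBAR-reweighted unbiased density: A(s) = −kBT ln Σₙ wₙ K_h(ξₙ − path(s))
with a product Gaussian kernel (default bandwidth 0.05 Å per coordinate,
recorded in the profile metadata), anchored so the reactant-side basin
minimum is zero.  A path point with no samples within three bandwidths is
a coverage gap and raises rather than extrapolates.  The headline profile
pools all trials into one MBAR solve; σ_err per point is the SEM over the
per-trial profiles (≥ 2 trials).  Block re-analysis divides each window's
pooled production series into non-overlapping time blocks, solves each
block independently, and reports the spread (max − min) of the
rate-controlling barrier.

Kernel smoothing biases barriers by ≈ ½V″h², which at the default
bandwidths is below 0.1 kcal/mol on the toy surfaces and ≈ 1–2 units on
the much stiffer Müller-Brown benchmark; the benchmark's tolerance
includes this plus an O(kBT) transverse-entropy allowance.

## Path-integral MD

A particle becomes a P-bead ring polymer sampling

U_P = Σₙ ½ m ω_sp² |rₙ − rₙ₊₁|² + (1/P) Σₙ V(rₙ),  ω_sp = √P/(βħ),

thermostatted at the physical temperature T.  This is the convention in
which the classical Boltzmann distribution of the ring reproduces the
discretized quantum position statistics at finite P (it is algebraically
equivalent to the often-quoted spring frequency P/(βħ) with full V per
bead sampled at P·T).  Integration is BAOAB-type with the free ring
polymer propagated *exactly* in normal-mode coordinates (orthonormal real
DFT transform; dynamic mode frequencies (2√P/βħ)·sin(kπ/P)), so the stiff
springs impose no step-size limit; the default dt = 0.25 fs is set by the
physical forces.  The thermostat is PILE: per-normal-mode white-noise
Ornstein–Uhlenbeck with friction 2ω_k on internal modes and a configurable
centroid friction (default 5 ps⁻¹).  P = 1 reduces bit-compatibly to the
classical BAOAB integrator.

A colored-noise (GLE) thermostat is deliberately not implemented; its
contract — correct quantum statistics at small P — is met instead by
raising the bead count.  The toy NQE comparison uses P = 16, which at the
toy's ≈ 2000 cm⁻¹ proton stiffness recovers the large majority of the
quantum effect (βħω ≈ 10); the harmonic validation suite checks P ∈
{1, 6, 32} against *exact* finite-P closed forms obtained independently by
Gaussian linear algebra on the ring precision matrix.

Umbrella restraints act on centroid coordinates, each bead receiving 1/P
of the centroid bias force; reaction coordinates are evaluated at the
centroid.  Estimators: the centroid-virial total energy, and the "degree
of expansion" of a tagged proton — the mean bead–centroid distance, a
direct measure of the thermal wave-packet delocalization, recorded
per sample during PIMD umbrella runs.

## Δ-learning

The correction model predicts E_ref − E_base from a rotation/translation
invariant descriptor (inverse distances of the donor–H, acceptor–H and
donor–acceptor pairs of each proton, plus the reaction coordinates) with
ridge regression over Gaussian radial basis features (centers: seeded
random subset of training descriptors, default 250; length scale: median
pairwise center distance).  Energies and forces enter one joint linear
least-squares system (weights 1.0 and 0.1), so the fit is closed-form and
deterministic, and the predicted force is the exact analytic gradient of
the predicted energy.  A held-out split (20%) reports validation RMSEs; an
extrapolation guard warns when the descriptor leaves the training bounding
box (inflated 5%).  Training data come from umbrella sampling on the base
surface along the reaction path — the ensemble the corrected surface will
revisit.

## Kinetics

Stationary points of a profile come from topographic-prominence peak
finding (default threshold 0.25 kcal/mol; suppressed sub-prominence
extrema are retained in the report).  Reactant/product free energies are
basin minima before the first/after the last transition state; the
rate-controlling transition state is the global interior maximum (ties
toward smaller s), and ΔAf‡ − ΔAr‡ = ΔA holds identically per profile.
Barriers are read from grid maxima without spline refinement.  TST rate
factors use exp(ΔΔA‡/kBT) with unit transmission coefficient at T = 298 K;
populations use exp(−ΔA/kBT).  The comparison-table generator emits CSV
and a fixed-width text layout with Δ columns against a designated
reference method, plus max-|Δ| summaries.

A small table of published free-energy values for the real B-DNA G–T
system (experimental estimates and several levels of theory, 298 K) is
bundled in `refdata.py`; it is input for worked examples — the 123×/395×
quantum rate-enhancement factors, population ratios, and Δ-column
bookkeeping — not something the package recomputes.

## Problem sizes

The validation experiments are sized for minutes on one desktop core, as
the package's own choice of scale: harmonic PIMD checks use 64 replicas ×
6 ps at P ∈ {1, 6, 32}; the Müller-Brown benchmark 32 images × 40 string
iterations + 4 × 0.8 ps production; the Δ-recovery experiment 16 windows ×
(string + 2 × 6 ps production) on three surfaces with 2400 training
frames; the NQE comparison 16 windows × 4 × 10 ps classical and 2 × 2.5 ps
PIMD at P = 16; block analysis re-uses the 40 ps of pooled classical
production in 16 blocks of 2.5 ps.  The full-scale protocol constants
(32 windows, k = 200 kcal/mol/Å², 298 K, 10 fs stride, 0.25 fs PIMD step,
50 string iterations) remain the package defaults.

## What the toy does and does not show

The analytic cluster reproduces the *structure* of the real problem — a
triple-well tautomer network in distance-difference coordinates, stiff
proton wells, a cheap/reference surface pair with a smooth learnable
residual, concerted double transfer with quantum barrier reduction — but
none of its chemistry: no electronic structure, no solvent or DNA
environment, no long-range electrostatics, and two-dimensional reaction
coordinate space instead of five.  Passing tests therefore demonstrate the
correctness of the estimators, integrators and optimizers (against closed
forms and independent oracles), and qualitative fidelity of the workflow,
not quantitative agreement with the condensed-phase system.  Known further
limitations: PILE at P = 16 slightly underconverges the proton quantum
statistics relative to a GLE-accelerated thermostat; kernel smoothing
biases barriers at sharp maxima; the extrapolation guard is a bounding
box, not an uncertainty model.
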