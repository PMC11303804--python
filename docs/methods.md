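# Methods

## The model

`euclidff` implements an equivariant transformer force field in which each
atom i carries two representations: an invariant feature vector f_i ∈ R^F and
a spherical tensor x_i (the *Euclidean variables*, EV) holding one block per
degree l ∈ {l_min, …, l_max}, packed degree-major with orders m = −l…l.  The
total energy is a sum of per-atom energies, E = Σ_i E_i(f_i^[T]), and forces
are the exact negative gradient of E with respect to the positions.

The EV are initialized from the local geometry,

    x_ilm = (1/⟨N⟩) Σ_{j∈N(i)} φ(r_ij) Y_lm(r̂_ij),

with a cosine cutoff φ(r) = ½(cos(πr/r_cut)+1) for r ≤ r_cut and the
training-set-wide mean neighbor count ⟨N⟩ (all-zero initialization is also
supported; the first attention update then populates the EV).  T transformer
blocks follow, each consisting of:

* **Euclidean self-attention.**  Interatomic messages use signed
  dot-product attention coefficients (no softmax) built from invariants
  only: the radial basis g_k(r_ij) = exp(−γ(exp(−r_ij)−μ_k)²) and the
  per-degree invariant contraction u_ij of the EV difference x_j − x_i.
  A filter w_ij = MLP_[F/4,F](u_ij) + MLP_[F,F](g_ij) (silu hidden layer,
  linear output) gates feature-space queries and keys,
  α = d^(−1/2) qᵢᵀ(w_ij ⊙ k_j), computed on h feature heads for the
  invariant branch and on one slice of width F/|degrees| per degree for the
  equivariant branch.  Updates keep skip connections:
  f_i ← f_i + Σ_j φ α_ij V f_j and x_ilm ← x_ilm + Σ_j φ α_ijl Y_lm(r̂_ij).
  A value matrix V is active by default; setting V = I recovers the plain
  aggregation of bare neighbor features.
* **Interaction block.**  A single silu layer of width F+|degrees| maps
  concat(f_i, u(x_i)) to a feature refinement a and per-degree gains b_l;
  the updates f_i ← f_i + a and x_ilm ← x_ilm + b_l x_ilm exchange
  information between the two representations at zero cost in equivariance
  (all inputs to the layer are invariants).

The per-degree contraction is the projection of x ⊗ x onto total degree
L = 0.  Because the Clebsch-Gordan L=0 block is diagonal in the real basis,
it reduces to Σ_m x_lm² (we fix the free constant to 1/√(2l+1)); the full CG
machinery exists in the package only as a brute-force oracle against which
the contraction and all equivariance properties are tested.  The readout is
a two-layer MLP (widths F → F/2 → 1, silu) followed by a per-element scale
and shift initialized from training-set statistics.

Degrees up to l = 3 are supported; the real spherical harmonics of the
network path are hardcoded Cartesian polynomials (matched component-by-
component against the general scipy-based implementation in the math layer).

### Symmetries

The energy is invariant under rotations, translations, permutations and
point inversion by construction: geometry enters only through distances and
products of even numbers of spherical harmonics of edge directions inside
invariant contractions.  The test suite asserts invariance/equivariance both
blockwise and end-to-end at double precision (1e-8 relative or better), and
compares analytic forces against central finite differences.

### Differentiation

Forces and training gradients come from a small reverse-mode autodiff
engine written for this package (`engine.py`).  Its backward rules are
themselves expressed in traced operations, so the force-matching loss —
which contains the forces, i.e. a gradient — can be differentiated again
with respect to the parameters (double backprop).  All arrays are float64.

## Training

The loss per structure is

    L = (1−β)(E−Ẽ)² + (β/3n) Σ_k Σ_{x,y,z} (F_k − F̃_k)²,

with β = 0.99 by default.  Optimization uses ADAM with initial learning
rate 10⁻³ decayed by 0.7 at a fixed step interval (default 100k steps; the
desk-scale experiments shorten the interval so the same exponential
schedule completes within their much smaller step budgets).  Batch size is
1 for ≤ 1000 training structures and 10 beyond.  Validation is split off
before training with the run seed; the best-validation parameters (checked
every `eval_interval` steps, including step 0) are returned.  Runs are
bit-for-bit reproducible given (seed, single thread, double precision).

## Molecular dynamics

Units: Å, fs, eV, amu; k_B = 8.617333262×10⁻⁵ eV/K; the acceleration
conversion 1 eV/(Å·amu) = 9.648533212×10⁻³ Å/fs² is stated to 10
significant digits in `data.py`.  Integrators: velocity Verlet (one force
call per step), Langevin via the BAOAB splitting (friction γ in fs⁻¹; γ=0
reduces exactly to Verlet), and a single (non-chained) Nosé–Hoover
thermostat with coupling time τ (default 100·dt) whose extended-system
invariant is tracked.  Instantaneous temperature uses N_dof = 3N−3 for
isolated systems (COM momentum removed at initialization and conserved)
and 3N for periodic ones.  Maxwell–Boltzmann initialization supports the
double-temperature convention for NVE starts (equipartition halves the
temperature once potential energy picks up its share) and exact rescaling
to a target temperature; for NVE runs started exactly at a minimum the
rigid-rotation component can additionally be projected out, so that the
whole kinetic energy budget lives in vibrations and the time-mean
temperature is T₀/2 exactly rather than biased upward by free rotation.

Energy conservation of the network potential is asserted on a 10-atom
argon cluster relaxed on the model's own (random-weight) surface, with the
per-element energy scale set to a few meV per atom so the random landscape
has the curvature of the argon-like systems the toy datasets emulate
(harmonic analysis of the relaxed fixture shows modes below ~170 cm⁻¹,
i.e. dt = 0.5 fs resolves every period by a factor ≳ 400).  Over 10⁴ NVE
steps the largest total-energy excursion stays well below 10⁻³ of the
kinetic-energy fluctuations; an unscaled random network is one to two
orders of magnitude stiffer than any physical argon surface and shows the
correspondingly larger — still bounded, symplectic — O((ωdt)²) energy
oscillation rather than secular drift.

## Stability diagnostics

A run fails mode A (non-physical dissociation) at the first frame whose
instantaneous temperature exceeds spike_factor × T_target (default 100) or
whose state is non-finite, and mode B at the first frame where any bond
deviates by more than 50% from its reference length.  Bonds are detected as
pairs closer than 1.25 × the sum of covalent radii (Cordero table) in the
starting geometry, with the initial distance as reference.  The stability
coefficient c_s = n_s/n_tot is the completed fraction of the run (1 when no
instability is found).  The spike factor and bond factor are configurable
pins; the 50% criterion is fixed.

## Observables

* RDF: shell-normalized pair histogram (minimum image, ideal-gas
  normalization at the system density) for periodic systems; normalized
  pair-distance density for isolated molecules.
* Power spectrum: FFT of the velocity autocorrelation averaged over atoms,
  components and time origins; Hann window, zero-padding to the next power
  of two, wavenumber axis in cm⁻¹.  Mass weighting is off by default.
* Radius of gyration, end-to-end distance, signed torsions (IUPAC
  convention, range (−180°, 180°]).
* Normal modes: central finite differences of analytic forces (step 10⁻³ Å)
  give the Hessian; after mass weighting, rigid translations and rotations
  are projected out; ZPE = ½ħΣω.  Eigenvalues below tolerance are reported
  as imaginary frequencies.  The ZPE-equivalent temperature uses the 3N−6
  vibrational-mode convention of a nonlinear molecule,
  T = E_ZPE/((3N−6)k_B).

## Minima hopping

Escape runs are NVE trajectories (default 1 ps at dt = 0.5 fs) started with
Maxwell–Boltzmann velocities rescaled exactly to the current temperature;
relaxation uses L-BFGS to max per-atom |F| < 10⁻⁴ eV/Å.  Minima are
identified by the RMSD minimized over proper rotations (Kabsch with the
det = +1 constraint) after COM removal, threshold 0.1 Å; atom order is
fixed, so permutation-equivalent copies of symmetric clusters count as
distinct entries (a documented limitation — recall against enumeration
oracles is therefore measured on distinct energy levels).  Defaults
T₀ = 1000 K and E_diff = 2 eV adapt by the factor 1.05: temperature rises
on revisits and falls on new minima; E_diff shrinks on accepted moves and
grows on rejections.  The transition-state estimate between two minima is
the maximum potential energy observed along the connecting escape path (an
upper bound); the disconnectivity graph merges minima below ascending
energy levels by union-find on these estimates.

## Synthetic data

Toy potentials stand in for quantum-chemistry labels: Lennard-Jones
clusters with argon parameters (ε = 0.0103 eV, σ = 3.4 Å, atomic number 18,
mass 39.948 amu), harmonic spring "molecules" with closed-form normal
modes, and a diatomic quartic double well with exact minima and barrier.
Every evaluator's forces are validated against finite differences.  Cluster
datasets are sampled by Langevin dynamics (default 25 K for LJ₇ — cold
enough that the cluster stays solid-like around one basin, warm enough for
meaningful force variance), labeled analytically and decorrelated by
sub-sampling; generation is deterministic per seed.  What these datasets do
not emulate: electronic effects, chemical diversity, label noise, and the
conformational richness of real molecules — passing the desk-scale learning
test demonstrates that the architecture, gradients and training loop are
correct and that the model can fit a smooth physical PES, not that it
reaches quantum-chemistry accuracy on real systems.

## Problem sizes used in the automated experiments

Desk-scale stand-ins for the full-scale protocols: the learning experiment
trains F = 32, T = 2, degrees {1,2}, K = 64 on 1000 LJ₇ frames (900/100
train/validation) for 6000 ADAM steps with the decay interval shortened to
1500 steps, and evaluates on 200 further frames from the same
distribution; the held-out force MAE lands well below 5% of the label
standard deviation.  Energy conservation runs 10⁴ NVE steps on a 10-atom
cluster; equipartition uses a harmonic triatomic over ≥ 100 vibrational
periods and 3 seeds; minima hopping explores LJ₇ against a 10⁴-restart
relaxation oracle.  The K = 64 radial resolution matters at argon bond
lengths because the Gaussian basis lives on exp(−r), which compresses
distances beyond a few Å; fewer basis functions visibly limit the
attainable force error.

## Known limitations

* Degrees above l = 3 are not implemented in the network path.
* No long-range electrostatics or dispersion beyond the cutoff; no Ewald.
* Minimum-image periodic boundaries only (cutoff ≤ half cell height).
* No permutation-invariant minimum identity; symmetric-cluster histories
  over-count (energy-level grouping recovers the physical count).
* Single-thermostat Nosé–Hoover (no chains), no barostat, no constraints.
* CPU-only, float64, small systems: the package optimizes for correctness
  and testability, not throughput.
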