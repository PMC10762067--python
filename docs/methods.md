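# Methods

## The model

The package simulates a coarse-grained bacterial chromosome — a closed
(ring) bead-spring polymer of `N` monomers of diameter `σ` — in a cubic
periodic box together with two other components:

* **H-NS dimers**, each a *triplex*: a core sphere of diameter `σ` with two
  small "sticky patch" spheres (diameter `0.178 σ`) embedded near its north
  and south poles, their centers `0.4 σ` from the core center.  Only the
  patches attract the polymer, so a dimer can bind one site (*dangling*) or
  bridge two sites (*cross-linking*).  Burying the patches in the core
  prevents one patch from touching several monomers at once and suppresses
  U-shaped (cis) dimer configurations.
* **Crowders**, inert spheres of diameter `σ_c` (default `2 σ`), which act
  on everything only through excluded volume.  Their entropy produces
  depletion attractions between the larger objects they surround.

One monomer coarse-grains ≈ 7.35 bp of B-DNA, giving the physical mapping
`σ = 2.5 nm`; energies are in `ε = k_BT` and times in `τ = σ√(m/ε)`.

### Interactions

All nonbonded pairs use a truncated-shifted Lennard-Jones potential
`U(r) = U_LJ(r) − U_LJ(r_c)` for `r < r_c`, zero beyond.  Pair parameters
(ε_ij, σ_ij, r_ij^c) live in a symmetric 4×4 `InteractionTable` over the
species {1: monomer, 2: patch, 3: core, 4: crowder}.  All pairs are purely
repulsive (WCA, `r_c = 2^{1/6} σ_ij`) except:

* **patch–monomer (1–2)**: ε₁₂ = 29 ε, σ₁₂ = 0.535 σ, r_c = 0.685 σ.  The
  cutoff is pushed `0.085 σ` past the WCA point, leaving an attractive well
  of depth **−8.65 k_BT** at `r ≈ 0.6 σ` — the model's encoding of the
  H-NS–DNA binding free energy (≈ −21 kJ/mol).  With this depth roughly a
  third of the dimers are bound at 25.5 µM and no crowding.
* **patch–core (2–3) and patch–crowder (2–4)**: no interaction.  These are
  represented explicitly as `active=False` entries so the table is an
  auditable, bit-faithful copy of its published form.

The table stores the published 3-decimal values (σ₁₂ = 0.535, σ₂₂ = 0.178)
rather than the exact identities 0.6/2^{1/6} and 0.2/2^{1/6}; the well
depth −8.65 reproduces only with the printed σ₁₂.  A side effect is that
"purely repulsive" pairs built from rounded σ retain a ≤ 3·10⁻⁵ ε residual
well at their cutoff, which is physically irrelevant but acknowledged by
the test tolerances.

Bonded terms: ring neighbors are joined by FENE springs
(`k₀ = 30 ε/σ²`, `r₀ = 1.5 σ`) on top of their WCA repulsion
(Kremer–Grest convention, equilibrium bond ≈ 0.97 σ, chain crossing
forbidden).  Each H-NS triplex is held by one radial spring
`K (r − r₀)²` per patch (`K = 120 ε/σ²`, `r₀ = 0.4 σ`) plus a single
harmonic angle `k_b (θ − π)²` (`k_b = 50 ε`) on the patch–core–patch
angle, keeping the patches antipodal.

### Dynamics

Langevin dynamics at `T = 1 ε/k_B`: velocity-Verlet with `dt = 0.005 τ`
plus an impulse-style Langevin thermostat — friction `−m v / τ_damp`
(damping time `τ_damp = τ`, applied to every particle) and Gaussian noise
of per-component variance `2 m k_BT/(τ_damp · dt)` entering the force
term.  With the thermostat off the integrator is plain symplectic NVE
velocity-Verlet, which the energy-conservation tests exercise.  All masses
are 1 (patches share the core's mass); masses do not affect equilibrium
observables.

Neighbor search: a Verlet list (skin 0.4 σ) built from a cell grid and
rebuilt when any particle has moved half a skin; the grid resolution is
capped at ~8 cells per particle so sparse systems do not pay for empty
cells.  The thermostat noise comes from a xoshiro256+ generator feeding a
128-layer ziggurat Gaussian sampler inside the jitted kernel (validated
against scipy's normal distribution by moment and KS tests); every run is
bit-reproducible given its seed.

### System assembly

The ring starts as a planar circle (exact chord length 0.97 σ) whenever
its diameter fits the box.  Rings longer than that — including the
flagship N=200 ring in the 50 σ box — are laid on a (1, q) winding of a
torus: once around a main circle while winding q times around the tube.
This curve is closed, non-self-intersecting and unknotted for any q, and
q is chosen as the smallest winding whose resampled beads keep all
non-consecutive pairs ≥ 0.9 σ apart.  Equilibration erases the memory of
either start (the N=200 Rouse time is ≈ 1.3·10³ τ; see below).

H-NS triplexes are inserted at random positions/orientations with
rejection; crowders by random sequential insertion on a cell grid.  After
assembly no active pair is closer than 0.9 σ_ij (the invariant demands
0.85); the integrator then runs a 2 000-step warmup with per-step
displacements capped at 0.05 σ to relax the residual soft overlaps.
Velocities are Maxwell–Boltzmann at T = 1 with zero net momentum.
Everything is deterministic given the spec seed.

The anchored control tethers one patch of each chosen dimer to a distinct,
uniformly chosen monomer by a stiff harmonic bond (k = 120 ε/σ², rest
length 0.6 σ — the binding distance) rather than freezing coordinates, so
anchored dimers still rotate and can bridge with the free patch.  The
crowder-permeable control zeroes only the core–crowder (3–4) pair.

## Observables

* **Rg/Rg0** — the ring is unwrapped by walking its bonds with
  minimum-image steps (error if a bond exceeds box/4 after imaging or the
  walk does not close, i.e. the ring wound around the torus); Rg is the
  usual root-mean-square distance from the centroid.  Rg0 is *measured*,
  from a matched crowder-free, H-NS-free run — never assumed.
* **Binding probability θ** — a patch is in contact with a monomer iff
  their minimum-image distance is < 0.685 σ (the outer edge of the
  attractive well; the model's natural "bound" criterion, exposed as a
  parameter).  A dimer with one contacting patch is *dangling*, with both
  *bridging*; θ = (dangling + bridging)/n_HNS, so
  θ = frac_dangling + frac_bridging holds exactly as count arithmetic.
  Bridged sites more than 2 monomers apart along the ring are labelled
  *trans* (threshold exposed as a parameter).
* **Clusters** — connected components of H-NS cores with edges at
  center-to-center distance ≤ 3 σ (minimum image), shape-agnostic;
  singletons count as size-1 clusters, and all dimers participate whether
  bound or not.  The pooled mean cluster size is the number-average over
  all clusters in all frames (the mass-weighted average is easily derived
  from the pooled histogram if wanted).
* Trajectory summaries carry block-bootstrap standard errors (10 blocks,
  200 resamples) to respect the serial correlation of the series.

## Schedules and problem sizes

The published production schedule (10⁸ equilibration + 10⁹ production
steps, sampled every 5·10³ steps = 25 τ) is available as the `paper-N200`
/ `paper-N2000` presets.  The package's own experiments run at desk scale,
sized from measured relaxation times on the N=200 system: the chain's
Rouse estimate is τ_R ≈ N²⟨b²⟩/(3π²D) ≈ 1.3·10³ τ, but the *binding*
degree of freedom is the slowest mode — in 4.8·10⁴ τ traces θ reaches its
plateau only after ≈ 4–8·10³ τ and then fluctuates with a correlation
time of a few 10³ τ:

* reference point (N=200, 30 H-NS, φ_c = 0): three replicas of 8·10³ τ
  equilibration + 1.2·10⁴ τ production, plus two binder-free baseline
  replicas of 4·10³ τ + 1.6·10⁴ τ (the baseline relaxes within a few
  Rouse times, so its budget goes into sampling Rg0), all sampled every
  25 τ (`scripts/acceptance.py`);
* qualitative crowding sweep (N=50, 8 H-NS, φ_c ∈ {0, 0.1, 0.2} in a
  20 σ box): 1.5·10³ τ + 5·10³ τ per condition;
* ideal-chain check (all nonbonded terms off): N ∈ {50, 100, 200},
  1.5·10³ τ + 4·10³ τ.

These lengths give ~10–25 effectively independent Rg samples per replica
(Rg autocorrelation ~ τ_R), i.e. ~2% standard errors on the compaction
ratio.  Under-equilibrating the binding biases the compaction ratio
upward (the chain is still shrinking while θ climbs), which is why the
H-NS runs get the long equilibration.

## What the desk-scale runs do and do not show

The crowder-free reference point is a faithful, if shorter, version of
the published experiment and reproduces its numbers (Rg/Rg0 ≈ 0.87,
θ ≈ 0.33).  The deep-crowding regime (φ_c = 0.32, ~9 549 crowders, where
Rg/Rg0 ≈ 0.54 for N=200 and the cluster-size distribution develops a
second peak near 24) needs the full 5·10⁶ τ schedule on ~10⁴ particles —
cluster-scale work.  The package retains those settings as presets, and
covers the *direction* of the effect at desk scale: on the small system,
compaction deepens and bridging and mean cluster size grow monotonically
with φ_c.  The small system cannot show the large-cluster second peak
(only 8 dimers) and its quantitative compaction differs from N=200; only
the trend transfers.

## Numerical choices and edge cases

* Harmonic-angle forces at θ = π use the analytic limit of
  (θ − π)/sin θ → −1 (the common singularity of angle potentials at
  180°), switched at sin θ < 10⁻⁸.
* FENE overstretch (r ≥ r₀) raises immediately, naming the bond — it is
  the canonical symptom of integrator instability.
* Positions are integrated unwrapped; minimum-imaging with `round(d/L)`
  is exact at any excursion.  Emitted frames store wrapped coordinates
  plus integer image counters, so files round-trip exactly.
* Cell-list forces are required (and tested) to match an all-pairs
  reference evaluation to 10⁻¹⁰, i.e. up to floating-point associativity.
* Crowder counts round half-up: `round(φ_c L³ / ((π/6) σ_c³))`, keeping
  the realized volume fraction within half a particle volume.
* Random-insertion packing fails explicitly (naming the achieved φ_c)
  after bounded retries; at the φ_c ≤ 0.4 range used here the insertion
  acceptance stays far from the RSA jamming limit.

## Known limitations

* No electrostatics, no chain stiffness, no hydrodynamics, no Mg²⁺
  dependence: effects beyond excluded volume + patch attraction enter only
  through the effective pair parameters.
* Cis (U-shaped) dimer binding is geometrically suppressed by
  construction, as in the parent model.
* Binding/unbinding kinetics are not analysed (equilibrium observables
  only); the Langevin friction sets no physical time scale mapping.
* The integrator's configurational sampling bias is O(γ dt) with
  γ dt = 0.005; equilibrium observables at this dt are
  discretization-insensitive at the reported precision.
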