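# nucleohns

Coarse-grained Langevin simulations of bacterial chromosome compaction by
biomolecular crowding and the DNA-bridging protein H-NS.

## The problem

Bacterial chromosomes are compacted by (at least) two very different
physical mechanisms: *depletion forces* from the crowded cytoplasm, and
*bridging* by nucleoid-associated proteins such as H-NS, a dimer that can
cross-link two DNA sites.  The two mechanisms reinforce each other:
crowders push chain segments together, which makes bridging easier; bound
dimers thicken the chain locally, which makes depletion stronger.  This
package implements a minimal particle-based model that makes that two-way
synergy measurable, for anyone who wants to simulate ring polymers with
mobile two-site binders in a crowded periodic box and analyse the
standard observables.

## The model

A ring of `N` beads (diameter `σ = 2.5 nm`, one bead ≈ 7.35 bp) is joined
by FENE springs (`k₀ = 30 ε/σ²`, `r₀ = 1.5 σ`) with WCA repulsion between
all beads.  H-NS is a triplex: a core sphere (diameter `σ`) carrying two
small patches (`0.178 σ`) embedded `0.4 σ` from its center on opposite
poles, held by stiff radial springs (`K = 120 ε/σ²`) and a harmonic angle
`k_b (θ − π)²` (`k_b = 50 ε`).  Crowders are inert WCA spheres (`σ_c = 2 σ`).
Every nonbonded pair interacts through a truncated-shifted Lennard-Jones
potential; the only attraction is patch–monomer, with
`ε₁₂ = 29 ε`, `σ₁₂ = 0.535 σ` and cutoff `0.685 σ`, giving a binding well
of depth ≈ `−8.65 k_BT` at `r ≈ 0.6 σ` — the model's encoding of the
H-NS–DNA binding free energy.  Dynamics are velocity-Verlet Langevin at
`T = 1 ε/k_B`, `dt = 0.005 τ`, in a periodic cube (side `50 σ = 125 nm`
for `N = 200`, so 200 monomers ≈ 170 µM and 30 dimers ≈ 25.5 µM).

Observables: the compaction ratio `Rg/Rg0` (baseline measured from a
matched crowder-free, binder-free run), the binding probability `θ` with
its dangling/bridging decomposition (patch–monomer contact when closer
than `0.685 σ`), and H-NS cluster statistics (connected components of
cores within `3 σ`).

## Worked example

```python
from nucleohns import SystemSpec, RunSchedule, run
from nucleohns.analysis import aggregate

spec = SystemSpec(n_monomers=50, box_side=20.0, phi_c=0.2, n_hns=8, seed=7)
traj, log = run(spec, schedule=RunSchedule(200_000, 800_000, 2_000))
df, summary = aggregate(traj)
print(summary["rg_mean"], summary["theta_mean"], summary["mean_cluster_size"])
```

The numbered drivers under `analysis/` run the package's experiments and
write tables under `results/`:

```text
$ python analysis/01_potential_calibration.py
patch-monomer well: minimum U = -8.6469 k_BT at r = 0.6005 sigma
attractive range: 0.6 < r < 0.685 sigma
monomers_200_in_125nm_box_uM: 170.04
hns_grid_uM: {0: 0.0, 4: 3.4, 8: 6.8, 12: 10.2, 16: 13.6, 20: 17.0, 30: 25.51}
```

— the patch–monomer well depth matches the H-NS–DNA binding free energy
the parameters were chosen to encode, and the copy-number grid maps to
the micromolar concentrations quoted for the 125 nm box.

```text
$ python analysis/02_reference_binding.py
Rg = 7.70 sigma, Rg0 = 8.67 sigma -> Rg/Rg0 = 0.887 +- 0.024
theta = 0.310 +- 0.025 (dangling 0.110, bridging 0.200)
```

— with 30 dimers (25.5 µM) and no crowders the ring shrinks by roughly a
tenth and about a third of the dimers are bound, most of them bridging.
`analysis/03_crowding_synergy.py` and `analysis/04_cluster_statistics.py`
then sweep the crowder volume fraction on a small system (N=50, 8
dimers): compaction deepens with `φ_c` (compaction ratio 0.90 → 0.82
from `φ_c = 0` to `0.2`) and the cluster-size distribution shifts weight
from singletons toward larger clusters.

A thin CLI mirrors the library (`nucleohns table|build|simulate|analyze|
sweep|report|fixtures`); `nucleohns table` prints the effective pair
table for audit, and `nucleohns simulate --preset paper-N200` runs the
full published schedule if you have the patience.

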