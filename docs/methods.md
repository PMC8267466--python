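# Methods

## Model overview

`sheetmem` studies a single rigid MoS₂ nanosheet interacting with a lipid
bilayer in a slab geometry (periodic in x,y; open z). The package works
throughout in nm, ps, kJ/mol, K and elementary charges, with
k_B = 0.0083144621 kJ·mol⁻¹·K⁻¹ and the Coulomb prefactor
f = 138.935458 kJ·mol⁻¹·nm·e⁻².

### Nanosheet

A 2H-MoS₂ monolayer is a three-plane S–Mo–S sandwich. Mo sites sit on a
triangular lattice (in-plane constant a = 0.316 nm by default, a standard
crystallographic value; overridable), sulfur columns on the displaced
honeycomb sublattice at ±0.156 nm vertical offset. The builder cuts an
equilateral triangle (reference side 2.89 nm) with one vertex toward +y:
Mo sites are kept if they lie inside the triangle (boundary inclusive),
and every sulfur column that coordinates a kept Mo is included. This
S-rich edge termination is deliberate: the subsequent neutralisation step
trims excess atoms of the over-represented species — farthest from the
centroid first, ties broken lexicographically — until Mo:S = 1:2, and
trimming sulfur preserves the Mo corners, so the cut's in-plane extent
stays within half a lattice constant of the nominal side length. Charges
(Mo +0.76 e, S −0.38 e) then sum to zero exactly.

Surface aging is represented solely by the sulfur LJ well depth:
ε_S = 1.6744 kJ/mol (fresh, WCA ≈ 69°) vs 1.0450 kJ/mol (aged,
WCA ≈ 90°), all other parameters identical. `eps_from_wca` interpolates
linearly through those two anchors and extrapolates with a warning
outside them. Edge sulfur atoms keep the uniform table charge; no edge
correction is applied.

### Implicit membrane

The sheet's centre of mass moves in a smooth slab potential

U(z, θ) = U_t·g(Δ) + U_h·(b(Δ) − b(0)·g(Δ)) + κ·cos²θ·g(Δ),  Δ = z − z₀,

with g(Δ) = exp(−Δ⁴/2h⁴) (flat-bottomed tail well, half-thickness
h = 2 nm) and b(Δ) = exp(−½[(Δ² − h²)/2hw]²) (interface bumps of height
≈ U_h at |Δ| = h, width w = 0.3 nm). The b(0)-correction makes
U(z₀, θ=π/2) = U_t exact. θ is the angle between sheet normal and
membrane normal; the κ = 10 kJ/mol term penalises face-on poses inside
the slab only, reproducing edge-on insertion. The tail well scales
linearly with the aging state, U_t = −c·ε_S with c = 10 (dimensionless):
fresh −16.7 kJ/mol (≈ 6.7 k_BT), aged −10.5 kJ/mol (≈ 4.2 k_BT). c was
chosen once so that the aged well is shallow enough for occasional
thermally activated escape within a desk-scale run while the fresh well
is clearly binding — that separation is what the fresh-vs-aged ordering
tests measure. The head barrier default U_h = 5 kJ/mol keeps insertion
two-stage without making it rare.

### Bead bilayer

For analyses that need explicit particles, `build_coarse_membrane` lays
two leaflets of grid lipids (head bead at midplane ± 2 nm, a
3-bead chain descending toward the midplane, 0.8 nm spacing; the
reference composition is 316 lipids per leaflet, dynamic runs default to
a 36-lipid patch). Chains start perfectly aligned (S_chain = 1). Beads
are harmonically tethered to their build positions (heads
100 kJ·mol⁻¹·nm⁻², chains 100 kJ·mol⁻¹·nm⁻²) and feel the sheet through
Lorentz–Berthelot-combined LJ forces plus truncated Coulomb (head beads
carry alternating ±0.2 e partials; tails are neutral). The tail-bead
ε = 12 kJ/mol is a coarse pseudo-parameter set once so that sheet-induced
chain deflections are resolvable above tether thermal noise; through the
geometric-mean combining rule the attraction scales as √ε_S, so the
fresh sheet binds tails harder than the aged one by construction.
Bead–sheet distances are clamped at 0.8σ (soft core) so transient
overlaps during insertion cannot produce divergent forces. There are no
bead–bead or intra-lipid forces; tethers carry the membrane's elasticity.

### Dynamics

All motion is overdamped (Brownian) Euler–Maruyama:
x ← x + dt·F/γ + N(0, 2k_BT·dt/γ), T = 300 K. A velocity-Verlet
thermostatted integrator would add parameters without changing the
equilibrium statistics the analyses consume. γ absorbs the mass
(sheet 50, beads 20 kJ·mol⁻¹·ps·nm⁻²); dt = 0.02 ps for bead systems.
For 1-D reaction-coordinate sampling the step is tied to the stiffest
restoring force, dt = s·γ/k_eff with s = 0.02, which bounds the
discretisation bias on sampled variances at about s/2 (≈ 1%). Identical
seeds give bit-identical trajectories; the z walls reflect far from the
membrane. The simulator drives beads with sheet forces but not the
reverse (the sheet follows the implicit potential); this one-way coupling
keeps the free-energy machinery independent of the bead fixtures and is
a deliberate coarse-model simplification.

### Scripted scenarios

`scripted_scenario` generates kinematic trajectories (approach,
preorganize-insert, direct-insert, no-insert) over a static bead
membrane, with ~85 surface waters riding rigidly on the sheet until they
detach monotonically as insertion deepens. The generator computes its
own per-frame contact and bound-water counts by direct vectorised
distance loops — an oracle deliberately independent of the analysis
module's KD-tree path — and records the true insertion frame.

## Umbrella sampling and WHAM

The reaction coordinate d is the signed sheet–membrane CoM separation
along the normal (positive on the bulk side; membrane reference is the
midplane CoM). The restraint follows the force convention
F = k·(d − d₀); the bias energy used everywhere is ½k(d − d₀)², the
harmonic form consistent with that force. Defaults: k = 2000
kJ·mol⁻¹·nm⁻², 0.1 nm spacing; the packaged ladder 0 → 4.9 nm gives 50
windows (the ladder is evaluated in exact rational arithmetic, so window
positions are exact decimals). Window production samples are thinned to
near-independence (thin = 60 steps at s = 0.02, lag-1 ρ ≈ 0.3); each
window's equilibration segment is discarded and a diverging window is
returned flagged, never silently dropped.

WHAM iterates the standard self-consistent equations in linear space
with precomputed bias Boltzmann factors (distant bins underflow
harmlessly), to tol 1e-7 on the window shifts fᵢ, max 10⁵ iterations,
default 200 bins over the sampled range. The PMF is shifted so the bins
in the outermost 10% of the sampled range (large-d side) average zero —
the bulk reference. Adjacent windows sharing no occupied bins raise an
error naming the gap; < 10 shared samples warns. Uncertainties come from
a moving-block bootstrap (default 50 resamples): block lengths are set
per window from the lag-1 autocorrelation, because naive resampling of
correlated samples underestimates the per-bin error by the square root
of the correlation factor.

`pmf_minimum` ignores bins with fewer than 5 samples (shot-noise spikes
at the sampled-range edges), refines the raw minimum with a
least-squares parabola over ±3 bins (more noise-tolerant than a
three-point fit), breaks ties toward smaller d, and flags a profile
degenerate when no bin deviates from the mean by more than 3 of its own
bootstrap errors. `pmf_difference` propagates the two minima's bootstrap
errors in quadrature.

During umbrella runs over the implicit membrane the tilt is held at its
in-membrane optimum (π/2), so the 1-D PMF equals the potential profile
and recovery of a known well depth is well posed; freeing the tilt would
fold an orientational-entropy contribution into the profile.

## Analysis definitions

- Contacts: group-b atoms with ≥ 1 group-a atom strictly within 0.5 nm,
  centre-to-centre, minimum image in x,y. "Heavy atoms" means
  non-hydrogen; the coarse model has no hydrogens, so the flag only
  matters for imported atomistic structures.
- Bound waters: oxygen within (inclusive) 0.35 nm of the nearest sheet
  atom centre — the simplest reading of distance to the "surface".
- Head/tail split partitions contacts by bead region label and sums to
  the total by construction.
- Energy decomposition uses the simulator's own truncation scheme
  (cut-and-shifted LJ, truncated Coulomb, 1.2 nm) rather than
  lattice-sum electrostatics — a deliberate divergence from atomistic
  practice, so trajectory energies match the dynamics that produced them.
- Membrane thickness: mean z of upper-leaflet head beads minus lower —
  the head-plane separation, since no other definition is canonical;
  both global and local (lipids with any atom within 1.0 nm of the
  sheet, whole lipids only) variants are provided.
- Insertion time: first frame at which the sheet CoM drops below the
  proximal head plane and stays below for a sustain window (default 5%
  of the trajectory) — a deterministic estimator of an otherwise
  eyeballed quantity.
- Neighbour searches use a KD-tree over the 3×3 in-plane periodic
  images; the test-suite oracles are plain python double loops.

## Problem sizes and test design

Simulation sizes were chosen so the full suite runs in minutes on one
CPU: dynamic bead runs use a 36-lipid-per-leaflet patch, a 1.6 nm sheet
and 8000 steps (160 ps) with the final 40% as the analysis window —
long enough for insertion and tail-window equilibration at these
friction coefficients; umbrella validation uses 1200–5000 samples per
window. Fresh-vs-aged comparisons are seed-paired (≥ 5 pairs) sign
tests on orderings only: the reference study's atomistic magnitudes
(hundreds of contacts, ~10³ kJ/mol energies, tens-of-ns insertion
times) are not reproduced at this scale and are not asserted.

The synthetic generator emulates the statistical structure the analyses
assume — approach/preorganisation/insertion staging, monotone
dehydration, ε_S-scaled binding — not the chemistry of real bilayers: no
solvent, no lipid conformational entropy, no electrostatic screening, no
ions (a bead-model salt concentration would be arbitrary). Passing tests
therefore demonstrate that the estimators and their orderings are
correct on data with known ground truth, not that the coarse model is
quantitatively predictive for POPE/POPC membranes.

## Numerical choices and limitations

- Euler–Maruyama bias is controlled, not eliminated: variances are
  inflated by ≈ s/2 (1%) at the default stability factor.
- WHAM well-depth recovery is accurate to a few percent at default
  budgets; residual error is window-stitching noise, which scales as
  1/√(samples per window) and accumulates diffusively along the ladder.
- The bead membrane's contact counts are O(1) per frame (a few beads of
  a small patch), so contact orderings are reported as tail-window
  means over seed pairs rather than per-frame values.
- Binary trajectory streams store float32; round-trips are exact at that
  precision. GRO/PDB/XYZ I/O goes through MDAnalysis with nm↔Å
  conversion at the boundary.
- The config system fills omissions with the reference protocol values
  (k = 2000, spacing 0.1 nm, T = 300 K, cutoffs 1.2/0.5/0.35/1.0 nm,
  side 2.89 nm) and rejects unknown keys; the pipeline writes a manifest
  with named seed streams and SHA-256 hashes of every artifact, and
  identical config+seed reruns are hash-identical.
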