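# Methods

## The model

Capsid proteins are hard spheres of radius `R = 1 nm` decorated with
spherical reaction patches of radius `r = 0.4 nm` whose centres sit on the
sphere surface.  The patch layout encodes the target geometry: two
*intra-capsomer* patches per monomer bind neighbours within a pentamer or
hexamer ring, and one or two *inter-capsomer* patches bind across rings.
Binding is a two-step encounter process: when two complementary, active,
unbound patches overlap diffusively (patch-centre distance below `2r`),
the encounter converts to a bond within a timestep `dt` with probability
`p_bind = k_a dt`; on acceptance the partners snap instantaneously into
the bond's ideal relative pose, with the repositioning split between the
two clusters in proportion to their translational diffusivities.  If the
snapped configuration would overlap any two hard spheres, the whole
attempt is rejected and all poses restored exactly.  Bonds break with
`p_break = k_d dt`; a break that disconnects a cluster's bond graph
splits it in two at unchanged poses, so freed patches remain in encounter
range and often rebind (this deliberate choice inflates effective
association constants relative to experiments — see Limitations).

Clusters are rigid bodies.  On every change of membership the 6×6
diffusion matrix is recomputed (see below) and drives correlated
translational + rotational Brownian steps drawn from `N(0, 2 D dt)` in
the body frame.

*Direct* assembly keeps every patch active throughout.  *Hierarchical*
assembly starts with only the two intra-capsomer patches active; the
moment a ring of 5 (pentamer) or 6 (hexamer) intra bonds closes, the
ring's intra patches and bonds lock permanently and the members'
inter-capsomer patches switch on.  A T1 capsid (60 monomers) is 12
pentamers; a T3 capsid (180 monomers) is 12 pentamers of one protein
type plus 20 hexamers alternating two types, so three types in total.

## Geometry construction

Exact patch angles are not tabulated anywhere; instead the ideal capsid
is the single source of geometric truth, built on the truncated
icosahedron:

* **T1** — one monomer per polyhedron vertex, scaled so the (uniform)
  edge length is `2R`.  Pentagonal faces are the pentamer rings (60
  intra bonds), edges between two hexagonal faces are the inter contacts
  (30 bonds); every monomer has exactly 2 intra + 1 inter patches and
  the complete shell carries 90 bonds.
* **T3** — one monomer per (face, vertex) incidence, pulled from the
  corner towards the face centre by a shrink factor `s`.  Face rings
  give 12 pentamers and 20 hexamers; at each of the 60 vertices the
  three incident faces (one pentagon, two hexagons) contribute a
  monomer each, forming the inter-capsomer triangle.  `s` is chosen so
  the closest inter contact rests at exactly `2R` while intra contacts
  are `2R` by scaling; the remaining inter contact kind rests slightly
  above `2R` (2.196 nm), which the snap-to-transform bond model allows.
  Hexamer rings are 2-coloured A/B by walking each face with the
  globally consistent outward orientation; this makes every vertex
  triangle contain exactly one P, one A and one B monomer, so six bond
  rules define the whole shell.

Per particle type, a reference slot defines body-frame patch directions;
every other slot's orientation is the unique rotation (Kabsch) mapping
the reference patch set onto its own bond directions, exact to ~1e-14 by
icosahedral symmetry.  Bond rules store the relative rigid transform of
each bonded pair, are checked for consistency across all instances
(tolerance 1e-6), and must compose to the identity around every ring.
`validate_blueprint` re-derives all of these invariants, and rebuilding
the shell slot-by-slot from any seed reproduces the ideal coordinates.

## Diffusion model

Cluster diffusion uses a rigid bead model: translational bead-bead
coupling by the Rotne–Prager–Yamakawa tensor, plus each bead's own
rotational Stokes friction `8 pi eta R^3` (pair rotational and
translation–rotation bead couplings neglected).  The bead mobility is
contracted onto rigid-body motion, inverted to a 6×6 resistance, and
reported about the centre of diffusion — the point where the coupling
block of `D = k_B T Xi^-1` is symmetric, found in closed form from the
centroid tensor.  A single bead reduces exactly to Stokes–Einstein
(`D_t = k_B T / 6 pi eta R = 0.1073 nm^2/ns`, `D_r = k_B T / 8 pi eta
R^3 = 0.0805 rad^2/ns` at 293 K and 2e-3 Pa s).  Absolute multi-bead
values depend on this model choice; tests therefore assert limits
(single sphere), symmetry/positive-definiteness, agreement with an
independently coded bead-model oracle, and monotone slow-down with
cluster growth, not absolute tensor entries.  Dimer tensors are obtained
from a cached canonical axis-aligned dimer rotated into place (bitwise
equivalent to the direct computation; dimers dominate the bind/unbind
churn).

Translation–rotation coupling is retained: steps use the Cholesky factor
of the full `2 D dt`.  Hydrodynamic interactions *between* clusters are
not modelled.

## Engine details

Timestep `dt = 0.1 ns`, temperature 293 K, viscosity 2e-3 Pa s.  T1 runs
use 60 monomers in a 28 nm periodic box (4.5 mM); T3 uses 180 monomers
in 55 nm (1.7 mM).  Each step: (1) propagate all clusters — a Brownian
move that would drive any member sphere into overlap with a monomer of
another cluster is rejected and the old pose kept for that step, so the
hard-sphere constraint holds at all times, not only at binding; clusters
are updated sequentially, each seeing earlier movers at their new
positions; (2) detect
encounters (Verlet candidate list on monomer centres, skin 1.2 nm,
rebuilt when any monomer moves half a skin; patch distances by minimum
image) and attempt associations in uniformly random order, skipping
events invalidated by earlier acceptances and re-checking separations at
current poses; (3) attempt dissociation for every unlocked bond in
random order.  Configuration validation rejects `k dt > 1`.

Two patches within one rigid cluster that sit exactly in their bound
geometry (ring closures and shell in-fill contacts, which the exact bond
transforms guarantee) convert at the same `p_bind` per step without any
repositioning; without this channel neither rings nor complete shells
could ever close.  The alignment tolerance is 1e-3 nm — true closures
land at ~1e-12 nm.

A trajectory is *successful* when a cluster holds `n_f` members *and*
the full bond complement of the blueprint (size alone cannot distinguish
a ring-deficient aggregate).  First-passage times record the first time
the maximum cluster size reached `n`, which makes the FPT map monotone
in `n` even when merges skip sizes or splits shrink clusters.  The
census records `nu_n(t)` at fixed intervals; occupancies use `p(n) =
nu_n n / N` so they normalise for any monomer surplus (for `N = n_f`
this is the conventional `nu_n n / n_f`).  Censored FPTs carry the
horizon value plus a flag; medians treat censored values as +infinity
and are themselves flagged when more than half the replicates are
censored; assembly speeds `v = 1/FPT(n_f)` average over completed
trajectories only.

Seeds: each trajectory consumes one integer seed driving two
deterministic streams (a NumPy generator for initial conditions and
reaction decisions, the kernel RNG for Brownian displacements); sweep
cells derive independent seeds from `(seed_base, grid indices,
replicate)` via `SeedSequence`.  Identical seeds give identical
trajectories.

## Ring master equation

For capsomer formation, mean-field populations `nu_n(t)` (`n <= n_f`)
evolve under size-independent pairwise coagulation at rate `a`,
fragmentation of open chains at rate `b` per bond with daughter
multiplicity `d_nk = 2` (`k < n`) and total decay `-(n-1) b`, and
irreversible ring closure at `n = n_f`.  Like-size association channels
carry the symmetrised factor 1/2, under which total monomer mass is
conserved identically.  Integration uses stiff-capable LSODA at relative
tolerance 1e-8 (populations clipped at zero; hard failure below -1e-10).
An exact Gillespie simulation of the same network serves as the
stochastic oracle; its ensemble mean agrees with the mean field up to
the O(1/N) moment-closure error (checked at 3 SE plus a declared
0.12-cluster allowance at N = 60).

The joint fit (`RingAssemblyME.fit`) estimates one association rate per
dataset and a shared `b` by trust-region least squares over
log-parameters (positivity by construction), equally weighted residuals
over all `n` and `t`, multistart from five log-spaced `b` initialisations
and a moment-based `a` guess.  Noise-free self-generated tables are
recovered to machine precision; recovery from 500-run Gillespie means is
tested at `N = 240`, where sampling noise rather than the ~10 % closure
bias of `N = 60` limits accuracy.  The molar association constant
follows from `a = k_a c / N` with the per-species concentration.

## Down-scaled hexamer experiment

Ten hexamers assemble from 60 monomers — either one self-complementary
type ("identical") or two alternating types ("T3-like") — alongside 30
pentamer-forming monomers, in a box of half the T3 volume (L = 43.66 nm,
preserving concentration), at `k_a = 9 ns^-1`, `k_d = 1.5e-3 ns^-1`.
Monomers carry intra patches only, so completed rings lock and become
inert, matching the master equation's absorbing ring state.  Fitting
(a_id, a_T3, shared b) to the ensemble-mean population tables yields
a_id / a_T3 ≈ 1.8–2: the two-type hexamer pays close to the factor-2
association penalty expected from halving the density of compatible
binding partners.

## Problem sizes in the test suite

The qualitative assembly phenomenology is verified on scaled-down study
designs chosen for a single CPU: T1 ensembles at the study concentration
with 8 replicates over 2e4 ns for the equal-horizon cluster-growth and
first-passage contrasts, 6 replicates over 4e4 ns for the strong-bond
near-completion yield contrast (hierarchical assembly needs ~3e4 ns to
pass three quarters of the shell at those rates), and hexamer ensembles
of 4 replicates over 1.5e4 ns.  Transport statistics use 1e4
independent spheres (1000 steps at `dt = 0.1 ns` for the MSD; 100 steps
at `dt = 0.02 ns` for orientational decay, where the finite-step
discretisation error of the autocorrelation is far below sampling
error).  Replicate counts are far below the reference ensembles (40–45),
so only ordinal claims (faster/slower, higher/lower yield) are asserted,
never figure-level numbers.

## What the generator does and does not emulate

Synthetic worlds start from uniformly random, non-overlapping monomer
positions and orientations at millimolar concentrations — the standard
simulation idealisation.  Real assembly environments differ: micromolar
concentrations, crowding, long-range interactions, continuous monomer
production, and capsid structural flexibility are all absent.  Exact
bond transforms preclude structural polymorphism and misassembly by
construction, so passing tests say nothing about malformed-capsid
pathways; conclusions are about the kinetic competition between
reorganisation (bond reversibility) and hierarchical patch switching
within this idealised geometry.

## Known limitations

* Post-dissociation partners stay in encounter range, inflating
  effective association constants by design; fitted `a` values are
  therefore interpreted through ratios, not absolute magnitudes.
* The bead-model diffusion tensor neglects bead-level rotational pair
  coupling; absolute rotational diffusivities of large clusters carry
  model error at the few-percent level.
* One association attempt per encounter pair per step; `p_bind` up to
  0.9 is used as a bare probability, as in the underlying scheme.
* Mean-field master-equation fits to small-N stochastic data inherit an
  O(1/N) closure bias.
* T numbers above 3, conformational switching of individual subunits,
  and open systems (monomer injection / capsid removal) are out of
  scope.
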