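# Methods

## The method in brief

`grestlite` implements solute tempering with a selected-surface-charged-
residue solute (gREST_SSCR) at desk scale.  In solute tempering, a chosen
subset of atoms and energy-term classes — the *solute region* (u) — is
simulated at an elevated effective temperature Tm while the rest of the
system (v) and the thermostat stay at the bath temperature T0.  Replica m
propagates under the modified potential

    E_m = (βm/β0)·E_uu + Σ_i (βm/β0)^{k_i/l_i}·E_uv,i + E_vv ,

where βm = 1/kB·Tm, β0 = 1/kB·T0, E_uu / E_uv,i / E_vv collect the
interactions internal to, bridging, and external to the solute, and k_i/l_i
is the per-class exponent (1/2 for pairwise Coulomb and Lennard-Jones terms:
l = 2 atoms form the term, k = 1 of them is solute).  Neighboring replicas
exchange configurations by a Metropolis test on

    Δ = β0·[E_m(X_b) + E_n(X_a) − E_m(X_a) − E_n(X_b)] ,

valid because all replicas share one bath temperature.  The SSCR idea is to
make the solute the surface charged residues near the interface of two
protein domains (plus charged hinge residues, completed to net neutrality):
raising their effective temperature weakens inter-domain salt bridges and
so enhances hinge-bending/twisting domain motions while leaving each
domain's internal interactions — and hence its fold — intact.

Two independent implementation routes of E_m are provided and
cross-checked: *term scaling* (decompose the energy by solute membership,
multiply the component sums) and *parameter scaling* (multiply solute
charges by √(βm/β0) and solute LJ ε by βm/β0 under geometric ε-mixing, then
evaluate the ordinary potential).  Their agreement to 1e-8 relative over
random configurations and rung temperatures is the central correctness test
of the Hamiltonian.

## The coarse-grained two-domain model

The atomistic machinery of a production simulation (explicit water, Ewald
electrostatics, constraint algorithms) is out of scope; all sampling claims
are demonstrated on a purpose-built bead-per-residue model that preserves
the features the method actually exercises:

* **Architecture.**  Two globular domains (beads on spherical shells,
  placed on a Fibonacci lattice) joined by a short hinge strand, with an
  inter-domain cleft — the topology of a periplasmic binding protein.  The
  NTD-plus-hinge and the CTD form two internally rigid units: every
  intra-unit distance is restrained by a harmonic elastic network, and the
  chain carries harmonic bonds and angles.
* **The hinge degree of freedom.**  The last two hinge beads sit exactly on
  the rotation axis through the pivot bead.  Elastic "ligaments" from these
  on-axis anchors to the nearest CTD beads have reference distances that
  are *exactly* invariant under rotation about that axis, so the bend is
  the single soft inter-domain degree of freedom — the analog of a real
  two-to-three-strand hinge.  Open and closed references are rigid
  rotations (default 45°) of one geometry, so every bonded reference value
  is satisfied exactly in both states and the hinge angle differs by
  ≥ 20° (≈ 27–36° in practice).
* **Nonbonded terms.**  Lennard-Jones (ε 0.2 kcal/mol, σ 5.5 Å, geometric
  ε-mixing, arithmetic σ), unscreened Coulomb with uniform dielectric 10,
  and double-basin Gaussian contact wells, all acting only *between* the
  two rigid units (intra-unit geometry is already fixed by the network, so
  intra-unit nonbonded terms would only fight the elastic reference).
* **The double basin.**  Three planted inter-domain charge pairs (opposite
  formal charges, the analog of inter-domain salt bridges) carry Gaussian
  wells (width 1.2 Å) at both their closed and their open pair distance.
  At build time the two well depths are solved (Brent's method on the
  rigid-rotation energy profile) so that (a) the closed and open basins are
  iso-energetic and (b) the barrier between them equals a target, default
  8 kBT at 300 K — high enough that an unbiased 300 K trajectory of 10⁵
  steps stays trapped, low enough that the top of a 300–550 K solute ladder
  crosses it.  The cleft is kept as tight as sterics allow so the LJ wall
  blocks over-closing, and the build verifies that the profile rises beyond
  both references; geometries that cannot be calibrated (e.g. the
  electrostatic loss alone exceeding the barrier target) are retried with a
  wider cleft or contact band and otherwise rejected.
* **Why tempering works here.**  All barrier-forming terms (charge-pair
  Coulomb and their contact wells) are solute–solute terms of the charged
  beads, so scaling by βm/β0 lowers the barrier to ≈ 4.4 kBT at the 550 K
  rung while leaving the basins balanced at every rung.  The contact wells
  are treated as a third nonbonded term class ("contact") and scaled
  alongside Coulomb and LJ; for an atomistic system the scaled classes
  would be Coulomb and LJ only, and the API takes the class list as an
  argument.
* **Charges.**  Interface pairs (6 beads), one ± pair on the hinge strand,
  and optionally a few "distant" charges placed as adjacent ± dipoles on
  the far side of a domain (so they add no electrostatic bias along the
  bend).  Distant charges are verified at build time to lie > 6.5 Å from
  every interface residue, i.e. strictly outside the 6 Å selection cutoff.
  The system is always net neutral.
* **Units and constants.**  kcal/mol, Å, K, amu, fs;
  kB = 0.0019872041 kcal mol⁻¹ K⁻¹; Coulomb constant 332.0637
  kcal Å mol⁻¹ e⁻²; masses 110 amu per bead.

What the toy does *not* emulate: explicit solvent and its dielectric
response (the uniform dielectric stands in), side-chain packing and
hydrogen-bond directionality, rugged intra-domain landscapes, and the
system-size scaling of exchange acceptance (with ~24 beads the solute
energy fluctuations are small, so neighbor acceptance on an 8-rung ladder
is ~90–99%, far above the 15–46% typical of solvated proteins; the
acceptance statistics pipeline is identical either way).  Passing tests
therefore validate the algorithmic machinery — Hamiltonian, exchanges,
selection logic, analysis — not any atomistic energetics.

## Solute selection (SSCR)

Given one or more conformations (closed first, by convention) and a domain
definition, the three criteria are:

1. surface charged residues whose Cα lies strictly within 6 Å of the Cα of
   the nearest interface residue;
2. every charged residue in the hinge ranges;
3. if the net formal charge is nonzero, further surface charged residues of
   the needed sign, added in order of increasing Cα distance from the
   interface centroid until the region is neutral (a deterministic
   completion rule; failure to neutralize is an error, not a warning).

"Interface residues" are residues of one domain with any heavy atom within
5 Å of the other domain (evaluated on the closed conformation);
"surface" means mean Shrake–Rupley SASA over the supplied conformations
≥ 50 Å² (probe 1.4 Å, 960 deterministic Fibonacci points per atom).  These
atomistic defaults are configurable; a built toy system carries its own
radius-scaled preset (contact cutoff = the construction band, surface
threshold 20 Å², since a fully exposed 2.75 Å bead has ~218 Å²).  SASA is
an own Shrake–Rupley implementation validated against the single-sphere
closed form and a dense Monte Carlo surface-integration oracle.

The published 22-residue ribose-binding-protein solute region ships as a
preset with per-residue provenance; converting it to an atom count with
CHARMM36m mid-chain residue sizes (ARG 24, LYS 22, ASP 12, GLU 15 atoms)
reproduces the printed 393-atom total.

## Propagator and replica exchange

* BAOAB-discretized Langevin dynamics, thermostatted at T0 = 300 K for
  every rung; defaults dt = 15 fs, friction 0.002 fs⁻¹ (CG beads tolerate
  long steps; the stiffest default force constant, 10 kcal mol⁻¹ Å⁻²,
  gives a ~720 fs period).  The harmonic-well variance and a double-well
  KS test validate the sampled distribution.
* Exchanges every 500 steps with deterministic even/odd neighbor-pair
  alternation; velocities are resampled from the bath Maxwell–Boltzmann
  distribution after an accepted swap (all rungs share T0, so rescaling
  would be a no-op).  One RNG stream per replica (following the replica
  through swaps) plus one for the exchange coin, spawned from the run
  seed: identical seeds give bitwise-identical logs.
* Exchange energies are assembled from one energy decomposition per
  configuration (E_m of any rung is a scalar combination of the same
  parts), so an attempt costs two decompositions regardless of ladder
  size.
* The inner force kernel is numba-compiled with a pure-numpy reference
  implementation kept as the fallback and cross-checked in the tests.
* Ladders: geometric Tᵢ = T_min·(T_max/T_min)^{i/(n−1)}, or explicit lists;
  the published 12-rung 300.00–550.00 K ladder ships verbatim as a preset
  (its spacing follows no closed-form rule).  Diagnostics: per-pair
  acceptance (undefined pairs reported as such, never as 0), replica
  rung-series, bottom→top→bottom round trips, and per-rung scaled-energy
  histograms with neighbor overlap coefficients.

## Analysis

* Hinge angle θ: bending angle at the hinge-region COM between the NTD and
  CTD COMs.  Twist angle φ: dihedral of (NTD-base COM, NTD COM, CTD COM,
  CTD-base COM), signed, IUPAC convention — the point order makes the
  NTD–CTD axis the dihedral axis; thresholds from the literature (φ < 58°,
  θ > 146°) are applied to the signed value as printed, with strict
  inequalities.
* RMSD by Kabsch superposition (SVD with reflection guard), tested against
  the quaternion (Kearsley) method; Rg mass-weighted.
* Contact maps are time-averaged residue–residue minimum side-chain
  distances; salt-bridge candidates are oppositely charged pairs with mean
  charged-group distance ≤ 10 Å.
* Hydrogen-bond/salt-bridge occupancy per state: percentage of that
  state's frames satisfying the criteria — charged-group heavy-atom
  distance ≤ 3.5 Å plus a donor–H–acceptor angle ≥ 120° when hydrogens
  exist; distance-only (≤ 4 Å around bead contact distances) for the
  hydrogen-free toy.  Errors are standard errors over 5 contiguous blocks
  of the state's frames; zero-frame states yield flagged NaN entries.
* k-means state clustering (k-means++ / Lloyd via scikit-learn, fixed
  seed) on frames superposed to the first frame over all Cα (= all beads).
* Free-energy surfaces F(θ, φ) = −kB·T·ln P on a 2° grid, shifted so the
  populated minimum is 0; empty bins masked, never imputed.
* Basin transitions are counted with hysteresis (closed-angle + 10° /
  open-angle − 10° thresholds) so thermal noise between the basins is not
  miscounted.

## Problem sizes and numerical choices

The shipped demonstrations use a 24-bead system (10 beads per domain,
4 hinge), an 8-rung geometric 300–550 K ladder, 10⁵ steps per rung with
exchanges every 500 steps, and a 1-D double-well comparison of 1.5×10⁵
replica-exchange steps against a 6×10⁵-step brute-force reference — sizes
chosen so each end-to-end check completes in tens of seconds while the
single-temperature control provably stays trapped.  Tie-breaks and edge
cases: altloc records resolve to highest occupancy; insertion codes are
rejected; histidine is neutral unless explicitly flagged; degenerate
angles/dihedrals raise instead of returning NaN; the exchange exponent is
clamped at e⁻⁷⁰⁰ to avoid overflow, which cannot affect any realizable
acceptance.

## Known limitations

* The toy's barrier calibration is exact along the rigid rotation path;
  thermal fluctuations move the true free-energy barrier slightly (local
  minimization from the references relaxes by < 1 kcal/mol on the default
  build, bounded in the tests).
* Exchange acceptances on the toy are far higher than for solvated
  proteins (see above); round-trip counts are correspondingly optimistic.
* No reweighting across rungs (WHAM/MBAR): analysis uses the bottom rung
  directly, mirroring how such simulations are usually analyzed at the
  bath temperature.
* The PDB reader handles single chains of standard residues; mmCIF,
  multi-model NMR ensembles and ligand topology perception are out of
  scope.
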