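# Methods

## What the package computes

`ionsite` analyses labeled point-set trajectories — frames of ion and
protein-atom coordinates — around a protein metal-binding region, with the
ZIP8 zinc transporter's binuclear center as the packaged default. The
analysis has four stages, run in a fixed order by the pipeline:

1. **Protein stability (RMSD).** Every frame's protein atoms are superposed
   onto a reference frame by the least-squares rigid fit (Kabsch problem,
   solved by SVD via `scipy`'s `Rotation.align_vectors`; reflections are
   rejected, so the rotation is always proper). RMSD is unweighted over the
   selected atoms. The per-frame transforms are cached and reused by the
   later stages, so ion distances are measured in the protein frame rather
   than the laboratory frame — without this, slow rigid drift of a membrane
   protein would masquerade as ion escape.

2. **Zone-state classification.** Each tracked ion is classified per frame
   by its distance *d* to a reference point (its own position in the
   reference frame by default, or a named site center):
   *d* ≤ 5 Å → BOUND; 5 < *d* ≤ 15 Å → EXCURSED (out of the binding site but
   still inside the protein); *d* > 15 Å → FREE. Both radii and the
   inclusivity convention ("exceeding" a threshold means strictly greater)
   are configurable and recorded in every report. There is no hysteresis in
   the rule itself; flicker suppression lives entirely in the transition
   detector.

3. **Site assignment and transitions.** An ion is assigned to the nearest
   site whose center lies within that site's capture radius (default 5 Å);
   ties break by distance, then by site order. A change of assignment
   becomes a transition event only if the new label persists for at least
   `min_dwell` frames (default 5 frames = 0.5 ns at 10 frames/ns); shorter
   runs are absorbed into the surrounding assignment, and unassigned runs of
   at least `min_dwell` frames produce events to/from "none". Events are
   stamped at the first frame of the accepted run.

4. **Ion/charge census.** Non-protein particles inside a sphere (default
   radius 10 Å, inclusive boundary) around the region center — the midpoint
   of the M1 and M2 centers by default — are counted per species, and the
   net formal charge is accumulated exactly in integer arithmetic. Means and
   standard deviations are taken over frames, optionally after dropping
   initial equilibration frames (`skip_frames`, default 0).

Site definitions come either from explicit coordinates or from a structure:
a site center is the unweighted centroid of the side-chain heavy atoms of
its coordinating residues (ZIP8 defaults: M1 = H314, E343, H347, D410;
M2 = N315, E344, D318; M4 = D311, E348, D351). Backbone atoms are excluded
because the coordinating chemistry is side-chain mediated (imidazole,
carboxylate, amide); glycine/alanine selectors fall back to CB, then CA, so
charge-removal mutants still define a geometric site. The anion positions
BCT1/BCT2 have no residue definition and enter as explicit coordinates
(e.g. docking poses). Residue-centroid centers are this package's
operationalization of "site position" and are flagged as such in report
provenance.

Degenerate inputs: superposition requires ≥ 3 non-collinear points and
reports collinear sets as errors; a one-frame trajectory yields a single
census frame, zero transitions and RMSD [0]; empty label sequences yield an
empty event list. If an orthorhombic box is declared on a trajectory,
distances use the minimum-image convention; otherwise raw Euclidean
distances are used.

## The synthetic trajectory generator

No reference trajectories are available at desk scale, so validation rests
on a generator that produces labeled data with the statistical structure the
analysis assumes. It is an overdamped Langevin process integrated with the
Euler–Maruyama scheme,

    x ← x − (D/kT) ∇U Δt + √(2 D Δt) ξ,    ξ ~ N(0, I₃),

and is deliberately *not* a molecular-dynamics engine: no force field, no
water, no membrane, no inertia. It is the simplest process that exhibits
binding, escape, site-to-site relocation, electrolyte screening and
counter-ion attraction, and it runs a 20 ns trajectory in about a second.

The potential U is a sum of three terms:

- **Site wells.** Negative Gaussians, depth·exp(−r²/2w²), at the five site
  centers. A particle of charge q feels an effective depth
  depth · max(0, −q·bias)/2, where the well's charge bias mimics the net
  coordinating-residue charge: metal wells (bias −1) attract Zn²⁺ at full
  depth and Na⁺ at half depth; anion wells (bias +2) attract HCO₃⁻. The
  anion wells are additionally restricted to the BCT species: bicarbonate
  recognition at those positions is specific hydrogen-bonding chemistry, not
  bulk electrostatics, and without the restriction background Cl⁻ (same
  charge) would occupy the anion sites in no-bicarbonate scenarios and erase
  exactly the contrast the generator exists to produce.
- **Screened Coulomb pairs.** U_ij = q_i q_j · A · exp(−s/λ)/s on the
  soft-core distance s = √(r² + a²), with prefactor A = 16 kT·Å, screening
  length λ = 8 Å (the Debye length of ~150 mM electrolyte) and soft core
  a = 2 Å (prevents the singular force of point charges at contact). This
  term carries the physics behind the headline effects: a bound anion
  deepens the metal ion's effective trap, and anionic site content draws
  Na⁺ into the census region.
- **Reflective walls** of a 40 Å orthorhombic box. Walls rather than
  periodic images keep "free" unambiguous for ground-truth labeling; the
  analysis layer still supports periodic boxes for external trajectories.

Default parameters, with units and why:

| parameter | default | rationale |
| --- | --- | --- |
| box | 40 Å cube | holds the site cluster plus bulk-like solvent shell |
| metal well depth | 18 kT | Kramers time ≈ prefactor·e^(0.87·depth) with these widths/diffusivities ⇒ hundreds of ns: wild-type ions stay bound over a run |
| anion well depth | 16 kT | tens of ns: mostly stable, occasional departure |
| well width w | 1.5 Å | coordination-shell scale; all site separations ≥ 4w |
| charge bias | −1 (metal), +2 (anion) | sign selects which charges a site attracts; magnitude sets Na⁺'s secondary attraction |
| coupling A | 16 kT·Å | gives a 3–4 kT anion–metal pair interaction at contact, strong enough that census and residence effects rise above counting noise at 150 mM |
| screening λ | 8 Å | Debye length at ~150 mM |
| soft core a | 2 Å | ionic contact distance; bounds forces |
| D (Å²/ns) | ZN 70, NA 133, CL 203, BCT 118 | free-solution diffusion coefficients |
| Δt | 10⁻³ ns | max drift+noise step ≲ 0.5 Å ≪ w; a step larger than the box diagonal aborts with a step-size diagnostic |
| output rate | 10 frames/ns | matches the trajectory resolution the analysis defaults assume |
| NaCl | 6 Na⁺ + 6 Cl⁻ | ≈150 mM in the 40 Å box |

The site layout is a package constant scaled from the described topology
(M1–M2 separation 6 Å; M4 6 Å below M2 toward the cytoplasmic side, so that
the M2 and M4 capture spheres overlap and a departing ion is handed over
rather than lost to an unassigned gap; BCT1/BCT2 adjacent to M1/M2). The
coordinates are not measured geometry.

**Scenario presets** mirror the study's simulation matrix: `full_occupancy`
(2 Zn²⁺ at M1/M2 + 2 HCO₃⁻ at BCT1/BCT2), `electroneutral_M1` /
`electroneutral_M2` (1 Zn²⁺ + 2 HCO₃⁻), `no_bicarbonate`, and the
charge-removal mutants `mutant_D318A` / `mutant_E343A` / `mutant_D410A`.
Mutants are modelled as (depth, bias) reduction factor pairs on the
binuclear wells — the directly mutated well is reduced hardest, and the
partner well is also weakened because the bridging electrostatics are shared
(D318A: both wells ×0.7 depth, ×0.9 bias; E343A: M1 ×0.55/0.9, M2 ×0.7/0.9;
D410A: M1 ×0.65/0.9, M2 ×0.85/0.95). The factors are package defaults
chosen by Kramers-time reasoning so the destabilized well empties on a
10–30 ns scale; they are not fitted to any measurement. Scenario runs
default to 2000 frames (200 ns); the test suite and the acceptance script
use 100–200-frame (10–20 ns) runs, which already contain hundreds of
independent well-relaxation times, so every code path is exercised at a
fraction of the cost.

**Ground truth** is produced by the generator itself, never by the analysis
layer: an ion truly occupies a well when it is within 2× the well width of
the center (ties broken by lowest well energy), and true transitions are
extracted from that membership by an independent run-length filter. Because
the membership sphere (3 Å) is tighter than the analysis capture radius
(5 Å), an ion displaced ~1 Å by strong pair coupling can read as "escaped"
in the truth labels while physically still bound; residence-versus-coupling
measurements therefore use the analysis layer's 5 Å bound zone.

## What passing tests do and do not show

The generator emulates: harmonic-like fluctuation in wells, stochastic
escape and relocation (including the M2→M4 pathway under a destabilized
M2), bulk electrolyte at 150 mM, anion-coupled lengthening of metal
residence, and Na⁺ penetration that grows as the region's net charge drops.
It does **not** emulate water structure, specific coordination geometry,
protonation states, conformational gating, or force-field energetics.
Passing tests therefore demonstrate that the *analysis layer* is correct
(exact agreement with brute-force geometry oracles) and that it *recovers
known truth* from data with the assumed statistical structure — they say
nothing about force-field accuracy on real trajectories.

## Numerical choices

- Zone thresholds are inclusive on the bound and excursed side (≤ 5 BOUND,
  ≤ 15 EXCURSED, > 15 FREE): "exceeding" a boundary is strict.
- Site-assignment ties: smallest distance, then SiteSet order (stable,
  documented, exercised by tests).
- The superposition rejects reflections (determinant +1 enforced) and
  raises on rank-deficient (collinear) point sets rather than returning an
  arbitrary rotation.
- Census charge is integer arithmetic; the identity net = Σ count×charge
  holds exactly per frame.
- Residence times are raw dwell-run lengths divided by the frame rate
  (1-frame quantization); the first exit time is the first FREE frame over
  the frame rate.
- Scenario comparison uses a block bootstrap over frames (default 1000
  resamples, block = 10 frames) because per-frame censuses are strongly
  autocorrelated; the resampling seed is recorded in the output.
- Free-particle diffusion is verified against MSD = 6Dτ using the time- and
  ensemble-averaged MSD at short lags, where origin averaging gives the
  most independent samples.
- All identical-seed runs are bit-identical: the only randomness source is
  one `numpy` generator per simulation, seeded from the config.

## Known limitations

- The two-zone rule references the ion's initial position by default (site
  centers are an option); if the first frame is itself atypical the bound
  fraction is biased — the reference frame index is configurable.
- Particles have no excluded volume beyond soft-core Coulomb repulsion;
  double occupancy of a well is possible in principle.
- The mutant presets encode the *direction* of charge-removal effects, not
  their magnitude; nothing in the generator is calibrated to measured
  kinetics, which the source data do not provide.
- Equilibration handling is left to the user (`skip_frames`, default 0),
  and the choice is recorded in report provenance.
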