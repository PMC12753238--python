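# ionsite

Ion-binding-site occupancy, transition and charge-census analysis for
MD-style trajectories — with a Langevin synthetic-trajectory generator for
end-to-end validation.

## The problem

Transition-metal transporters of the ZIP (SLC39) family move Zn²⁺, Mn²⁺,
Fe²⁺ and Cd²⁺ across membranes through a binuclear metal center: two
adjacent coordination sites, M1 (H314, E343, H347, D410 in human ZIP8) and
M2 (N315, E344, bridged by D318), with an additional cytoplasmic-side site
M4 (D311, E348, D351) and two bicarbonate positions BCT1/BCT2 nearby. A
standard way to interrogate such a center *in silico* is to simulate the
protein with ions placed at the sites and then ask, frame by frame: did each
ion stay bound, drift out of its site, or leave the protein? Which site is
it in? How many electrolyte ions penetrate the binding region, and what net
charge do they carry? Is the protein fold itself stable?

`ionsite` packages that analysis layer for anyone who has (or generates)
such trajectories: per-frame zone-state classification, site assignment
with dwell-filtered transition events, a spherical ion/charge census, and
superposed-RMSD monitoring, plus a fast stochastic generator that produces
ground-truth-labeled trajectories with the same statistical structure so
every stage can be verified without a cluster.

## The model

**Zone rule.** For each tracked ion with distance *d*(t) to its reference
point (its initial position, or a site center), measured after superposing
the protein onto a reference frame:

    d ≤ r_b          →  BOUND        (r_b = 5 Å)
    r_b < d ≤ r_f    →  EXCURSED     (r_f = 15 Å; inside the protein)
    d > r_f          →  FREE         (left the protein)

**Site assignment & transitions.** Ion → nearest site center within that
site's capture radius (5 Å), else unassigned; an assignment change counts
as a transition only after a minimum dwell (5 frames = 0.5 ns at
10 frames/ns). **Census.** Counts per species and net formal charge
Q = Σᵢ qᵢ of all non-protein particles within 10 Å of the M1–M2 midpoint,
per frame and averaged. **RMSD.** Least-squares rigid superposition
(Kabsch, proper rotations only) against a reference frame.

**Generator.** Overdamped Langevin dynamics
x ← x − (D/kT)∇U Δt + √(2DΔt)·ξ with U = Gaussian site wells (scaled by
charge compatibility with each site's bias) + screened Coulomb
qᵢqⱼ·A·e^(−s/λ)/s + reflective walls; scenario presets reproduce the study
configurations (full occupancy, electroneutral M1/M2, no bicarbonate, and
D318A/E343A/D410A charge-removal mutants as weakened wells). See
`docs/methods.md` for parameters and rationale.

## Worked example

Simulate a destabilized-M2 mutant without bicarbonate (the configuration in
which the metal ion relocates from M2 to the M4 site), then run the full
analysis:

```python
import numpy as np
from ionsite import run_analysis
from ionsite.structure import BindingSite, SiteSet
from ionsite.synthetic import SITE_LAYOUT, scenario, simulate

traj, truth = simulate(scenario("mutant_E343A", n_frames=200, seed=3, hco3=False))
sites = SiteSet(sites=[BindingSite(name=n, center=np.array(c))
                       for n, c in SITE_LAYOUT.items()])
report = run_analysis(traj, sites)
```

Printing the stability table, the transition list and the census summary:

```
 ion_id species  bound_fraction  excursed_fraction  free_fraction  left_protein
      1      ZN            0.57               0.43            0.0         False

ion 1: M2 -> M4 at 11.3 ns (frame 113)

mean Na+ in census sphere : 0.835
mean net charge           : +0.830 e
mean protein RMSD         : 0.115 A
```

Reading: the Zn²⁺ stayed within 5 Å of its starting position for 57% of the
20 ns run, then moved beyond the bound zone but never left the protein
(free fraction 0, `left_protein` False); the dwell-filtered transition list
shows a single relocation from M2 to M4 at 11.3 ns; on average 0.8 Na⁺ ions
sat inside the 10 Å census sphere for a mean net charge of +0.8 e; and the
protein scaffold was rigid (mean RMSD 0.1 Å).

The same stages are available from the shell:

```
ionsite simulate --scenario full_occupancy --frames 200 --seed 42 --out traj.tsv
ionsite states  --traj traj.tsv --sites sites.json --out states.json
ionsite census  --traj traj.tsv --sites sites.json --out census.csv
ionsite rmsd    --traj traj.tsv --out rmsd.csv
```

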