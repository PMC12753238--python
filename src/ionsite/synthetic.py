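"""Ground-truth-labeled synthetic ion trajectories.

Since no real trajectories are available at desk scale, this module
generates stand-in data with the statistical structure the analysis layer
assumes: tracked ions fluctuating in Gaussian potential wells at named
sites (M1, M2, M4, BCT1, BCT2), stochastic escape and site-to-site
relocation, a background electrolyte at bulk density, and screened-Coulomb
coupling so that a bound anion lengthens the residence of a nearby metal
ion and a negative site region draws in Na⁺.

The process is overdamped Langevin dynamics integrated with the
Euler–Maruyama scheme,

    x ← x − (D/kT) ∇U Δt + √(2 D Δt) ξ,   ξ ~ N(0, I),

with U the sum of negative Gaussian wells (scaled per particle by
sign-compatibility with the well's charge bias), pairwise screened
Coulomb q_i q_j · A · exp(−s/λ)/s on a soft-core distance
s = √(r² + a²), and reflective box walls.  It is deliberately NOT a
force-field MD engine: it is the simplest process exhibiting
bound/escape/transition phenomenology, fast enough that every analysis
stage can be validated against known ground truth.

Energies are in units of kT, lengths in Å, times in ns, diffusion
coefficients in Å²/ns.  Identical configs and seeds give bit-identical
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .trajectory import DEFAULT_CHARGES, ParticleTable, Trajectory

__all__ = [
    "Well",
    "TrackedIon",
    "SimulationConfig",
    "GroundTruthLabels",
    "simulate",
    "scenario",
    "toy_structure_pdb",
    "SITE_LAYOUT",
    "REGION_CENTER",
    "SCENARIOS",
]

# Toy site layout (Å), artifact constants scaled from the described site
# topology: M1–M2 separation 6 Å, M4 below M2 toward the cytoplasmic side
# (6 Å, so the M2 and M4 capture spheres overlap and a departing metal ion
# is handed over rather than lost to an unassigned gap), anion positions
# BCT1/BCT2 adjacent to M1/M2.  All inter-site separations are ≥ 4× the
# default well width.  These coordinates are package defaults, not
# measured geometry.
SITE_LAYOUT: dict[str, tuple[float, float, float]] = {
    "M1": (17.0, 20.0, 20.0),
    "M2": (23.0, 20.0, 20.0),
    "M4": (23.0, 20.0, 14.0),
    "BCT1": (17.0, 26.0, 20.0),
    "BCT2": (23.0, 26.0, 20.0),
}
REGION_CENTER: tuple[float, float, float] = (20.0, 20.0, 20.0)

#: Free-solution-like diffusion coefficients, Å²/ns.
DEFAULT_DIFFUSION: dict[str, float] = {"ZN": 70.0, "NA": 133.0, "CL": 203.0, "BCT": 118.0}


class Well(BaseModel):
    """Gaussian attractive well at a named site.

    ``charge_bias`` (elementary charges) mimics the net coordinating-
    residue charge: a particle of charge q feels an effective depth
    depth · max(0, −q·bias)/2, so cations are attracted to negative-bias
    (metal) wells, anions to positive-bias (bicarbonate) wells, and
    charge-removing mutants weaken both by shrinking |bias| and depth.

    ``species`` optionally restricts the well to named species.  The anion
    positions use this (species=("BCT",)) because bicarbonate recognition
    there is specific hydrogen-bonding chemistry, not bulk electrostatics —
    without the restriction background Cl⁻ would occupy the anion sites
    and erase the with/without-bicarbonate contrast the generator exists
    to produce.
    """

    name: str
    center: tuple[float, float, float]
    depth: float = Field(ge=0.0)  # kT
    width: float = Field(gt=0.0)  # Å
    charge_bias: float = -1.0
    species: tuple[str, ...] | None = None

    def effective_depth(self, charge: float, species: str | None = None) -> float:
        if self.species is not None and species not in self.species:
            return 0.0
        return self.depth * max(0.0, -charge * self.charge_bias) / 2.0


class TrackedIon(BaseModel):
    """A ligand ion with a defined start (well name or explicit coords)."""

    species: str
    start: str | tuple[float, float, float]
    charge: int | None = None


class SimulationConfig(BaseModel):
    """Full parameterization of one synthetic run."""

    box: tuple[float, float, float] = (40.0, 40.0, 40.0)
    wells: list[Well] = []
    tracked: list[TrackedIon] = []
    background: dict[str, int] = {"NA": 6, "CL": 6}  # ~150 mM in a 40 Å box
    coupling: float = 16.0      # screened-Coulomb prefactor A, kT·Å
    screening: float = 8.0      # λ, Å
    soft_core: float = 2.0      # a, Å
    diffusion: dict[str, float] = dict(DEFAULT_DIFFUSION)
    kT: float = 1.0
    dt: float = 1e-3            # ns
    n_frames: int = 2000        # 200 ns at 10 frames/ns
    frames_per_ns: float = 10.0
    seed: int = 0
    noise_scale: float = 1.0    # 0 → zero-temperature (deterministic descent)
    n_protein_atoms: int = 12
    protein_shell_radius: float = 9.0
    protein_jitter: float = 0.05   # Å, per recorded frame
    drift_translation: float = 0.0  # Å per frame, rigid lab-frame drift
    drift_rotation: float = 0.0     # rad per frame
    min_dwell: int = 5          # frames, for ground-truth transition filtering

    @model_validator(mode="after")
    def _check(self):
        if self.dt <= 0:
            raise ValueError("time step must be positive")
        steps = 1.0 / (self.frames_per_ns * self.dt)
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError(
                "output rate inconsistent with time step: 1/(frames_per_ns*dt) "
                f"= {steps} is not an integer number of steps per frame"
            )
        names = [w.name for w in self.wells]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate well names {names}")
        for ion in self.tracked:
            sp = ion.species
            if ion.charge is None and sp not in DEFAULT_CHARGES:
                raise ValueError(f"tracked species {sp!r} needs an explicit charge")
            if isinstance(ion.start, str) and ion.start not in names:
                raise ValueError(f"tracked ion start {ion.start!r} is not a well name")
        for sp in list(self.background) + [i.species for i in self.tracked]:
            if sp not in self.diffusion:
                raise ValueError(f"species {sp!r} has no diffusion coefficient")
        return self

    @property
    def steps_per_frame(self) -> int:
        return round(1.0 / (self.frames_per_ns * self.dt))


@dataclass
class GroundTruthLabels:
    """Generator-side truth for the tracked ions (never from the analysis).

    ``membership[ion_id][f]`` is the well the ion truly occupies at frame
    f — within 2× well width of a center, ties broken by lowest well
    energy — or None.  ``transitions`` lists (from, to, frame) after
    dwell filtering at ``min_dwell`` frames; ``escape_frames`` are the
    frames of filtered departures from a well.
    """

    membership: dict[int, np.ndarray]
    transitions: dict[int, list[tuple[str | None, str | None, int]]]
    escape_frames: dict[int, list[int]]
    min_dwell: int


def _fibonacci_shell(n: int, radius: float, center: np.ndarray) -> np.ndarray:
    """Deterministic quasi-uniform points on a sphere (pseudo-protein atoms)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    return center + radius * pts


class _Field:
    """Vectorized energies/forces for one particle set."""

    def __init__(self, cfg: SimulationConfig, charges: np.ndarray,
                 species: list[str] | None = None):
        self.q = charges.astype(float)
        if species is None:
            species = [None] * len(self.q)
        self.centers = (
            np.array([w.center for w in cfg.wells], float)
            if cfg.wells else np.zeros((0, 3))
        )
        self.widths = np.array([w.width for w in cfg.wells], float)
        self.depth_eff = np.array(
            [[w.effective_depth(qi, sp) for w in cfg.wells]
             for qi, sp in zip(self.q, species)],
            float,
        )  # (M, K)
        self.A = cfg.coupling
        self.lam = cfg.screening
        self.a2 = cfg.soft_core**2
        self.qq = np.outer(self.q, self.q)

    def forces(self, x: np.ndarray) -> np.ndarray:
        f = np.zeros_like(x)
        if self.centers.shape[0]:
            diff = x[:, None, :] - self.centers[None, :, :]         # (M, K, 3)
            r2 = np.einsum("mkd,mkd->mk", diff, diff)
            g = np.exp(-r2 / (2.0 * self.widths**2))
            coef = self.depth_eff * g / self.widths**2              # (M, K)
            f -= np.einsum("mk,mkd->md", coef, diff)
        if self.A != 0.0 and len(x) > 1:
            d = x[:, None, :] - x[None, :, :]
            s = np.sqrt(np.einsum("ijd,ijd->ij", d, d) + self.a2)
            e = np.exp(-s / self.lam)
            dUds = -self.A * self.qq * e * (1.0 / (self.lam * s) + 1.0 / s**2)
            np.fill_diagonal(dUds, 0.0)
            f -= np.einsum("ij,ijd->id", dUds / s, d)
        return f

    def potential(self, x: np.ndarray) -> float:
        u = 0.0
        if self.centers.shape[0]:
            diff = x[:, None, :] - self.centers[None, :, :]
            r2 = np.einsum("mkd,mkd->mk", diff, diff)
            u -= float(np.sum(self.depth_eff * np.exp(-r2 / (2.0 * self.widths**2))))
        if self.A != 0.0 and len(x) > 1:
            d = x[:, None, :] - x[None, :, :]
            s = np.sqrt(np.einsum("ijd,ijd->ij", d, d) + self.a2)
            pair = self.A * self.qq * np.exp(-s / self.lam) / s
            u += float(np.sum(np.triu(pair, k=1)))
        return u


def _truth_membership(x: np.ndarray, field: _Field, wells: list[Well]) -> list:
    """Well membership of the first len(x) particles: within 2×width of a
    center, lowest well energy wins."""
    if not wells:
        return [None] * len(x)
    centers = field.centers
    widths = field.widths
    depth_eff = field.depth_eff[: len(x)]
    d = np.linalg.norm(x[:, None, :] - centers[None, :, :], axis=2)
    candidate = (d <= 2.0 * widths[None, :]) & (depth_eff > 0.0)
    energy = -depth_eff * np.exp(-(d**2) / (2.0 * widths[None, :] ** 2))
    out = []
    for m in range(len(x)):
        cand = np.flatnonzero(candidate[m])
        if cand.size == 0:
            out.append(None)
        else:
            out.append(wells[int(cand[np.argmin(energy[m, cand])])].name)
    return out


def _filter_runs(labels: list, min_dwell: int):
    """Dwell-filtered occupancy changes: list of (from, to, first_frame).

    Independent, loop-based run-length scan kept separate from the
    analysis layer's transition detector so ground truth never depends on
    the code under test.
    """
    events = []
    current = None
    have = False
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        if j - i >= min_dwell:
            if not have:
                current, have = labels[i], True
            elif labels[i] != current:
                events.append((current, labels[i], i))
                current = labels[i]
        i = j
    return events


def _small_rotation(rng: np.random.Generator, sigma: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(rng.normal(0.0, sigma, 3)).as_matrix()


def simulate(config: SimulationConfig) -> tuple[Trajectory, GroundTruthLabels]:
    """Run the overdamped Langevin process and label the truth.

    Returns a Trajectory (tracked ions, background ions, pseudo-protein
    shell atoms; box left unset because the walls are reflective, not
    periodic) and the GroundTruthLabels for the tracked ions.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    box = np.asarray(cfg.box, float)

    species: list[str] = []
    charges: list[int] = []
    starts: list[np.ndarray] = []
    wells_by_name = {w.name: w for w in cfg.wells}
    for ion in cfg.tracked:
        species.append(ion.species)
        charges.append(
            ion.charge if ion.charge is not None else DEFAULT_CHARGES[ion.species]
        )
        if isinstance(ion.start, str):
            starts.append(np.asarray(wells_by_name[ion.start].center, float))
        else:
            starts.append(np.asarray(ion.start, float))
    n_tracked = len(species)
    for sp, count in cfg.background.items():
        for _ in range(count):
            species.append(sp)
            charges.append(DEFAULT_CHARGES.get(sp, 0))
            starts.append(rng.uniform(0.0, 1.0, 3) * box)
    n_ions = len(species)
    x = np.array(starts, float).reshape(n_ions, 3)
    q = np.array(charges, float)
    D = np.array([cfg.diffusion[sp] for sp in species], float)

    field = _Field(cfg, q, species)
    mobility = (D / cfg.kT)[:, None]
    noise_amp = (cfg.noise_scale * np.sqrt(2.0 * D * cfg.dt))[:, None]
    diag = float(np.linalg.norm(box))
    spf = cfg.steps_per_frame

    protein_base = _fibonacci_shell(
        cfg.n_protein_atoms, cfg.protein_shell_radius, np.asarray(REGION_CENTER)
    )

    n_total = n_ions + cfg.n_protein_atoms
    coords = np.empty((cfg.n_frames, n_total, 3))
    membership_rows: list[list] = []
    R_cum = np.eye(3)
    t_cum = np.zeros(3)
    drifting = cfg.drift_translation > 0 or cfg.drift_rotation > 0

    for f in range(cfg.n_frames):
        if f > 0:
            for _ in range(spf):
                step = mobility * field.forces(x) * cfg.dt
                if cfg.noise_scale:
                    step = step + noise_amp * rng.standard_normal((n_ions, 3))
                if np.max(np.abs(step)) > diag:
                    raise RuntimeError(
                        f"divergent step at frame {f}: displacement "
                        f"{np.max(np.abs(step)):.1f} Å exceeds the box diagonal; "
                        f"reduce dt (currently {cfg.dt} ns) or the forces"
                    )
                x = x + step
                # reflective walls
                x = np.abs(x)
                x = box - np.abs(box - x)
        membership_rows.append(_truth_membership(x[:n_tracked], field, cfg.wells))
        prot = protein_base
        if cfg.protein_jitter:
            prot = prot + cfg.protein_jitter * rng.standard_normal(prot.shape)
        frame = np.vstack([x, prot])
        if drifting:
            if f > 0:
                R_cum = _small_rotation(rng, cfg.drift_rotation) @ R_cum
                t_cum = t_cum + rng.normal(0.0, cfg.drift_translation, 3)
            center = np.asarray(REGION_CENTER)
            frame = (frame - center) @ R_cum.T + center + t_cum
        coords[f] = frame

    ids = np.arange(1, n_total + 1)
    roles = ["tracked"] * n_tracked + ["background"] * (n_ions - n_tracked) \
        + ["protein"] * cfg.n_protein_atoms
    table = pd.DataFrame(
        {
            "id": ids,
            "species": species + ["PRT"] * cfg.n_protein_atoms,
            "charge": charges + [0] * cfg.n_protein_atoms,
            "role": roles,
        }
    )
    times = np.arange(cfg.n_frames) / cfg.frames_per_ns
    traj = Trajectory(
        particles=ParticleTable(table),
        coords=coords,
        times=times,
        frame_rate=cfg.frames_per_ns,
        box=None,  # reflective walls; no periodic treatment downstream
    )

    membership: dict[int, np.ndarray] = {}
    transitions: dict[int, list] = {}
    escapes: dict[int, list[int]] = {}
    for m in range(n_tracked):
        lab = [row[m] for row in membership_rows]
        ion_id = int(ids[m])
        membership[ion_id] = np.array(lab, dtype=object)
        ev = _filter_runs(lab, cfg.min_dwell)
        transitions[ion_id] = ev
        escapes[ion_id] = [frame for frm, to, frame in ev if frm is not None]
    truth = GroundTruthLabels(
        membership=membership,
        transitions=transitions,
        escape_frames=escapes,
        min_dwell=cfg.min_dwell,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# scenario presets

def _default_wells(scale: dict[str, tuple[float, float]] | None = None) -> list[Well]:
    """Wild-type wells; ``scale`` maps well name → (depth, bias) factors.

    Metal-well depths are set so a Zn²⁺ sits for hundreds of ns (Kramers
    time ≈ prefactor·e^(0.87·depth) with these widths and diffusivities),
    matching the observed all-ions-stay behaviour of the wild-type runs,
    while mutant reductions bring the destabilized well down to a few ns.
    """
    scale = scale or {}
    base = {
        "M1": (18.0, -1.0, None),
        "M2": (18.0, -1.0, None),
        "M4": (18.0, -1.0, None),
        "BCT1": (16.0, 2.0, ("BCT",)),
        "BCT2": (16.0, 2.0, ("BCT",)),
    }
    wells = []
    for name, (depth, bias, species) in base.items():
        ds, bs = scale.get(name, (1.0, 1.0))
        wells.append(
            Well(name=name, center=SITE_LAYOUT[name], depth=depth * ds,
                 width=1.5, charge_bias=bias * bs, species=species)
        )
    return wells


# Charge-removing mutants, modelled as (depth, charge-bias) reduction
# factors.  The directly mutated well is reduced hardest; the binuclear
# partner well is also weakened because the bridging electrostatics are
# shared.  Factors are package defaults (docs/methods.md), chosen from
# Kramers-time reasoning so the destabilized well empties within tens of
# ns; they are not measured quantities.
_MUTANT_SCALES: dict[str, dict[str, tuple[float, float]]] = {
    "mutant_D318A": {"M1": (0.7, 0.9), "M2": (0.7, 0.9)},  # bridging: both wells
    "mutant_E343A": {"M1": (0.55, 0.9), "M2": (0.7, 0.9)},
    "mutant_D410A": {"M1": (0.65, 0.9), "M2": (0.85, 0.95)},
}

#: Scenario name → (occupancy sites for Zn, bicarbonate present by default)
SCENARIOS: dict[str, tuple[tuple[str, ...], bool]] = {
    "full_occupancy": (("M1", "M2"), True),
    "electroneutral_M1": (("M1",), True),
    "electroneutral_M2": (("M2",), True),
    "no_bicarbonate": (("M1", "M2"), False),
    "mutant_D318A": (("M2",), True),
    "mutant_E343A": (("M2",), True),
    "mutant_D410A": (("M2",), True),
}


def scenario(
    name: str,
    n_frames: int = 2000,
    seed: int = 0,
    hco3: bool | None = None,
    **overrides,
) -> SimulationConfig:
    """Fully-populated config for a named study scenario.

    Zn²⁺ ions start at their metal-well centers and HCO₃⁻ at BCT1/BCT2;
    ``hco3`` overrides whether bicarbonate is present; further keyword
    overrides are applied to the config fields verbatim.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}")
    occupancy, hco3_default = SCENARIOS[name]
    with_bct = hco3_default if hco3 is None else hco3
    wells = _default_wells(_MUTANT_SCALES.get(name))
    tracked = [TrackedIon(species="ZN", start=site) for site in occupancy]
    if with_bct:
        tracked += [
            TrackedIon(species="BCT", start="BCT1"),
            TrackedIon(species="BCT", start="BCT2"),
        ]
    return SimulationConfig(
        wells=wells, tracked=tracked, n_frames=n_frames, seed=seed, **overrides
    )


def coupling_experiment(
    coupling: float, seed: int = 0, n_frames: int = 200
) -> SimulationConfig:
    """Two-particle config for the metal–anion coupling experiment.

    One Zn²⁺ in a moderate well with a strongly held bicarbonate 3 Å away;
    sweeping ``coupling`` (including 0) probes whether the bound anion
    lengthens the Zn residence in its starting zone — the synthetic
    analogue of bicarbonate stabilizing the metal in the binding region.
    The Zn well is shallower than the scenario wells so escapes are
    common within a 20 ns window even at high coupling.
    """
    wells = [
        Well(name="ZNW", center=(20.0, 20.0, 20.0), depth=10.0, width=1.5,
             charge_bias=-1.0),
        Well(name="BCTW", center=(20.0, 23.0, 20.0), depth=18.0, width=1.5,
             charge_bias=2.0, species=("BCT",)),
    ]
    return SimulationConfig(
        wells=wells,
        tracked=[
            TrackedIon(species="ZN", start="ZNW"),
            TrackedIon(species="BCT", start="BCTW"),
        ],
        background={},
        coupling=coupling,
        n_frames=n_frames,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# toy structure matching the well layout

def toy_structure_pdb() -> str:
    """PDB text of a toy structure carrying the ten site residues.

    Synthetic stand-in for the (undeposited) homology model: each
    coordinating residue contributes N/CA backbone atoms plus a single
    side-chain atom placed so that the side-chain centroid of each site's
    residues equals the packaged well center.  Lets the structure-derived
    SiteSet line up with the generator's wells for end-to-end runs.
    """
    residues = {
        "M1": [("HIS", 314), ("GLU", 343), ("HIS", 347), ("ASP", 410)],
        "M2": [("ASN", 315), ("GLU", 344), ("ASP", 318)],
        "M4": [("ASP", 311), ("GLU", 348), ("ASP", 351)],
    }
    # zero-mean offset sets so the centroid lands exactly on the center
    offsets = {
        4: np.array([[1.2, 1.2, 1.2], [-1.2, -1.2, 1.2],
                     [-1.2, 1.2, -1.2], [1.2, -1.2, -1.2]]),
        3: np.array([[1.4, 0.0, -0.7], [-0.7, 1.2, -0.7], [-0.7, -1.2, 1.4]]),
    }
    lines = ["TITLE     SYNTHETIC TOY SITE SCAFFOLD (NOT A REAL STRUCTURE)"]
    serial = 1
    for site, res_list in residues.items():
        center = np.asarray(SITE_LAYOUT[site])
        offs = offsets[len(res_list)]
        for (resname, resnum), off in zip(res_list, offs):
            sc = center + off
            bb = sc + np.array([3.0, 0.0, 0.0])
            for atom_name, element, pos in (
                ("N", "N", bb + [0.0, 1.0, 0.0]),
                ("CA", "C", bb),
                ("CG", "C", sc),
            ):
                lines.append(
                    f"ATOM  {serial:5d}  {atom_name:<3s} {resname:>3s} A{resnum:4d}    "
                    f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00"
                    f"          {element:>2s}"
                )
                serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
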