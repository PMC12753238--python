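"""End-to-end orchestration: sites → alignment → states → transitions →
census → RMSD → report, plus scenario comparison.

``run`` executes the stages in a fixed order on one trajectory and
returns a RunReport whose every number is recomputable from the inputs
and the provenance block (parameters, input hashes, seed, version).  The
protein superposition is computed once (the RMSD stage) and its
transforms are reused by the state classifier and site assignment, so no
stage recomputes another's output.

``compare_scenarios`` turns census means from several reports into
paired differences against a baseline, with block-bootstrap confidence
intervals over frames (the underlying per-frame censuses are strongly
autocorrelated, hence blocks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel

from . import __version__
from .census import CensusRegion, ChargeCensus, census_trajectory
from .rmsd import RMSDSeries, rmsd_series
from .states import (
    IonStateSeries,
    StabilitySummary,
    TransitionEvent,
    ZoneRule,
    assign_sites,
    classify_states,
    detect_transitions,
    summarize_stability,
)
from .structure import SiteSet, load_siteset_config, load_structure
from .trajectory import Trajectory, file_sha256, read_trajectory, write_report

__all__ = ["RunConfig", "RunReport", "run", "run_analysis", "compare_scenarios"]


class RunConfig(BaseModel):
    """File-facing configuration of one pipeline run."""

    trajectory: str
    sites: str                      # site-config JSON
    structure: str | None = None    # PDB, needed for residue-based sites
    bound_radius: float = 5.0
    free_radius: float = 15.0
    reference: str = "initial"      # "initial" or a site name
    reference_frame: int = 0
    census_radius: float = 10.0
    census_center: tuple[float, float, float] | None = None  # default: region center
    align: bool = True
    min_dwell: int = 5
    skip_frames: int = 0
    seed: int = 0                   # used only by resampling (compare)
    output_dir: str | None = None

    def validate_paths(self) -> None:
        for p in (self.trajectory, self.sites, self.structure):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


@dataclass
class RunReport:
    """All pipeline products plus provenance."""

    stability: pd.DataFrame
    census: ChargeCensus
    transitions: list[TransitionEvent]
    rmsd: RMSDSeries
    state_series: list[IonStateSeries]
    site_labels: dict[int, np.ndarray]
    provenance: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self):
        stability = self.stability.astype(object).where(
            self.stability.notna(), None)
        return {
            "stability": stability.to_dict(orient="records"),
            "census": self.census.to_dict(),
            "transitions": [t.to_dict() for t in self.transitions],
            "rmsd": {
                "mean": float(np.mean(self.rmsd.rmsd)),
                "max": float(np.max(self.rmsd.rmsd)),
                "series": self.rmsd.rmsd.tolist(),
            },
            "states": [s.to_dict() for s in self.state_series],
            "warnings": self.warnings,
            "provenance": self.provenance,
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_report(self.stability, outdir / "stability.csv", "csv")
        write_report(self.census, outdir / "census.csv", "csv")
        write_report(self.rmsd, outdir / "rmsd.csv", "csv")
        payload = self.to_dict()
        prov = payload.pop("provenance")
        write_report(payload, outdir / "report.json", "json", provenance=prov)


def run_analysis(
    traj: Trajectory,
    sites: SiteSet,
    rule: ZoneRule = ZoneRule(),
    census_region: CensusRegion | None = None,
    align: bool = True,
    min_dwell: int = 5,
    skip_frames: int = 0,
    provenance: dict | None = None,
) -> RunReport:
    """Run all analysis stages on an in-memory trajectory."""
    warnings: list[str] = []
    if not align:
        warnings.append("protein alignment disabled; distances include protein drift")
    if skip_frames == 0:
        warnings.append("no equilibration frames skipped (skip_frames=0)")

    # stage 1: protein stability / superposition (transforms reused below)
    rmsd = rmsd_series(traj, "protein", rule.reference_frame)
    transforms = rmsd.transforms if align else None

    ion_ids = [int(i) for i in traj.particles.ids[traj.particles.roles == "tracked"]]
    # stage 2: zone states of the tracked ions
    series = classify_states(traj, ion_ids, rule, sites=sites, align=align,
                             transforms=transforms)
    # stage 3: site assignment and transitions
    labels = assign_sites(traj, ion_ids, sites, align=align,
                          reference_frame=rule.reference_frame, transforms=transforms)
    transitions = detect_transitions(labels, min_dwell, traj.frame_rate)
    # stage 4: per-ion stability summaries
    rows = []
    for s in series:
        summ = summarize_stability(s, labels[s.ion_id], traj.frame_rate)
        sp = traj.particles.species[traj.particles.index_of(s.ion_id)]
        rows.append(
            {
                "ion_id": s.ion_id,
                "species": sp,
                "bound_fraction": summ.state_fractions["BOUND"],
                "excursed_fraction": summ.state_fractions["EXCURSED"],
                "free_fraction": summ.state_fractions["FREE"],
                "final_state": summ.final_state,
                "left_protein": summ.left_protein,
                "first_exit_time_ns": summ.first_exit_time_ns,
                **{f"residence_{k}_ns": v for k, v in summ.mean_residence_ns.items()},
            }
        )
    stability = pd.DataFrame(rows)
    # stage 5: ion/charge census around the binding site
    region = census_region or CensusRegion(center=tuple(sites.region_center))
    census = census_trajectory(traj, region, skip_frames)

    prov = {
        "tool": "ionsite",
        "version": __version__,
        "parameters": {
            "bound_radius": rule.bound_radius,
            "free_radius": rule.free_radius,
            "reference": rule.reference,
            "reference_frame": rule.reference_frame,
            "align": align,
            "min_dwell": min_dwell,
            "skip_frames": skip_frames,
            "census_center": list(region.center_array),
            "census_radius": region.radius,
            "site_centers": {s.name: s.center.tolist() for s in sites},
        },
    }
    if provenance:
        prov.update(provenance)
    return RunReport(
        stability=stability,
        census=census,
        transitions=transitions,
        rmsd=rmsd,
        state_series=series,
        site_labels=labels,
        provenance=prov,
        warnings=warnings,
    )


def run(config: RunConfig) -> RunReport:
    """File-based pipeline entry point."""
    config.validate_paths()
    structure = load_structure(config.structure) if config.structure else None
    sites = load_siteset_config(config.sites, structure)
    traj = read_trajectory(config.trajectory)
    rule = ZoneRule(
        bound_radius=config.bound_radius,
        free_radius=config.free_radius,
        reference=config.reference,
        reference_frame=config.reference_frame,
    )
    center = config.census_center or tuple(sites.region_center)
    region = CensusRegion(center=tuple(center), radius=config.census_radius)
    prov = {
        "inputs": {
            "trajectory": {"path": config.trajectory,
                           "sha256": file_sha256(config.trajectory)},
            "sites": {"path": config.sites, "sha256": file_sha256(config.sites)},
        },
        "seed": config.seed,
    }
    report = run_analysis(
        traj, sites, rule, region, config.align, config.min_dwell,
        config.skip_frames, provenance=prov,
    )
    if config.output_dir:
        report.write(config.output_dir)
    return report


def _block_bootstrap_mean(values: np.ndarray, n_boot: int, block: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Bootstrap distribution of the mean, resampling frame blocks."""
    n = len(values)
    block = max(1, min(block, n))
    n_blocks = int(np.ceil(n / block))
    starts_max = max(1, n - block + 1)
    out = np.empty(n_boot)
    for b in range(n_boot):
        starts = rng.integers(0, starts_max, n_blocks)
        sample = np.concatenate([values[s:s + block] for s in starts])[:n]
        out[b] = sample.mean()
    return out


def compare_scenarios(
    reports: list[RunReport],
    baseline: int = 0,
    n_boot: int = 1000,
    block: int = 10,
    seed: int = 0,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Paired differences of census means against a baseline report.

    One row per non-baseline report: Δ mean count per species and Δ mean
    net charge (report − baseline), each with a 95% block-bootstrap
    confidence interval over frames.  Requires matching census regions.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    base = reports[baseline]
    ref_params = (tuple(base.census.region.center_array), base.census.region.radius)
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"report_{i}" for i in range(len(reports))]
    rows = []
    for i, rep in enumerate(reports):
        if i == baseline:
            continue
        if (tuple(rep.census.region.center_array), rep.census.region.radius) != ref_params:
            raise ValueError("census regions differ between reports; cannot compare")
        row: dict = {"scenario": labels[i], "baseline": labels[baseline]}
        all_species = sorted(set(base.census.species) | set(rep.census.species))
        for sp in all_species:
            a = rep.census.frames.get(sp, pd.Series(0, index=rep.census.frames.index))
            b = base.census.frames.get(sp, pd.Series(0, index=base.census.frames.index))
            a, b = a.to_numpy(float), b.to_numpy(float)
            delta = a.mean() - b.mean()
            boot = (_block_bootstrap_mean(a, n_boot, block, rng)
                    - _block_bootstrap_mean(b, n_boot, block, rng))
            lo, hi = np.percentile(boot, [2.5, 97.5])
            row[f"delta_{sp}_count"] = delta
            row[f"delta_{sp}_ci_low"], row[f"delta_{sp}_ci_high"] = lo, hi
        a = rep.census.frames["net_charge"].to_numpy(float)
        b = base.census.frames["net_charge"].to_numpy(float)
        boot = (_block_bootstrap_mean(a, n_boot, block, rng)
                - _block_bootstrap_mean(b, n_boot, block, rng))
        lo, hi = np.percentile(boot, [2.5, 97.5])
        row["delta_net_charge"] = a.mean() - b.mean()
        row["delta_net_charge_ci_low"], row["delta_net_charge_ci_high"] = lo, hi
        row["bootstrap_seed"] = seed
        rows.append(row)
    return pd.DataFrame(rows)
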