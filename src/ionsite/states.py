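"""Zone-based ion-state classification, site assignment and transitions.

Each tracked ion is classified per frame by its distance to a reference
point — its own initial position by default, or a named site center —
using a two-zone rule: within the bound radius (default 5 Å, inclusive)
the ion is BOUND; beyond the free radius (default 15 Å, exclusive
boundary) it has left the protein and is FREE; in between it is EXCURSED,
i.e. out of the binding site but still inside the protein.

Because a membrane protein drifts over a trajectory, the protein atoms
are superposed onto the reference frame before distances are measured
(alignment ON by default, recorded in reports); the same rigid transform
is applied to the ion coordinates.

Site assignment is nearest-site-within-capture-radius; transitions are
extracted from the per-frame site labels with run-length (minimum dwell)
filtering so single-frame flickers at a zone boundary do not register as
events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rmsd import apply_transform, rmsd_series
from .structure import SiteSet
from .trajectory import Trajectory

__all__ = [
    "ZoneRule",
    "IonStateSeries",
    "TransitionEvent",
    "StabilitySummary",
    "classify_states",
    "assign_sites",
    "detect_transitions",
    "summarize_stability",
    "classify_distances",
]

BOUND, EXCURSED, FREE = "BOUND", "EXCURSED", "FREE"


@dataclass(frozen=True)
class ZoneRule:
    """Two-zone distance rule.

    distance ≤ bound_radius → BOUND; distance > free_radius → FREE;
    otherwise EXCURSED.  ``reference`` is "initial" (the ion's position at
    ``reference_frame``) or the name of a site in the SiteSet.
    """

    bound_radius: float = 5.0
    free_radius: float = 15.0
    reference: str = "initial"
    reference_frame: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.bound_radius < self.free_radius:
            raise ValueError("need 0 < bound radius < free radius")


def classify_distances(distances: np.ndarray, rule: ZoneRule) -> np.ndarray:
    """Vector of state labels for a vector of distances (pure function)."""
    d = np.asarray(distances, float)
    out = np.full(d.shape, EXCURSED, dtype=object)
    out[d <= rule.bound_radius] = BOUND
    out[d > rule.free_radius] = FREE
    return out


@dataclass
class IonStateSeries:
    """Per-ion per-frame distance, zone state and assigned site."""

    ion_id: int
    distances: np.ndarray
    states: np.ndarray
    rule: ZoneRule
    sites: np.ndarray | None = None  # per-frame site label or None
    aligned: bool = True

    def __post_init__(self) -> None:
        bad = (self.states == BOUND) & (self.distances > self.rule.bound_radius)
        if bad.any():
            raise ValueError("BOUND frame with distance above the bound radius")

    def to_dict(self):
        return {
            "ion_id": int(self.ion_id),
            "aligned": self.aligned,
            "bound_radius": self.rule.bound_radius,
            "free_radius": self.rule.free_radius,
            "reference": self.rule.reference,
            "states": self.states.tolist(),
            "distances": self.distances.tolist(),
            "sites": None if self.sites is None else [s for s in self.sites],
        }


@dataclass(frozen=True)
class TransitionEvent:
    """A site-change event; ``from_site``/``to_site`` may be None."""

    ion_id: int
    from_site: str | None
    to_site: str | None
    frame: int
    time_ns: float

    def to_dict(self):
        return {
            "ion_id": int(self.ion_id),
            "from_site": self.from_site,
            "to_site": self.to_site,
            "frame": int(self.frame),
            "time_ns": float(self.time_ns),
        }


@dataclass
class StabilitySummary:
    """Trajectory-level stability summary for one ion."""

    ion_id: int
    state_fractions: dict[str, float]
    final_state: str
    left_protein: bool
    first_exit_time_ns: float | None
    mean_residence_ns: dict[str, float] = field(default_factory=dict)

    def to_dict(self):
        return {
            "ion_id": int(self.ion_id),
            "state_fractions": self.state_fractions,
            "final_state": self.final_state,
            "left_protein": self.left_protein,
            "first_exit_time_ns": self.first_exit_time_ns,
            "mean_residence_ns": self.mean_residence_ns,
        }


def _pbc_distances(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Euclidean norms, minimum-image if an orthorhombic box is declared."""
    if box is not None:
        delta = delta - box * np.round(delta / box)
    return np.linalg.norm(delta, axis=-1)


def _alignment_transforms(traj: Trajectory, reference_frame: int):
    """Per-frame rigid transforms superposing protein atoms onto the reference."""
    if traj.protein_indices().size < 3:
        raise ValueError("alignment requested but fewer than 3 protein atoms present")
    series = rmsd_series(traj, "protein", reference_frame)
    return series.transforms


def _aligned_coords(traj: Trajectory, align: bool, reference_frame: int,
                    transforms=None) -> np.ndarray:
    if not align:
        return traj.coords
    if transforms is None:
        transforms = _alignment_transforms(traj, reference_frame)
    out = np.empty_like(traj.coords)
    for f, (R, t) in enumerate(transforms):
        out[f] = apply_transform(traj.coords[f], R, t)
    return out


def classify_states(
    traj: Trajectory,
    ion_ids: list[int] | None = None,
    rule: ZoneRule = ZoneRule(),
    sites: SiteSet | None = None,
    align: bool = True,
    transforms=None,
) -> list[IonStateSeries]:
    """Classify each tracked ion per frame into BOUND / EXCURSED / FREE.

    With ``align`` the protein atoms of every frame are superposed onto
    the rule's reference frame and the same transform is applied to the
    ion coordinates; pass cached ``transforms`` (from an RMSDSeries) to
    reuse an existing alignment.
    """
    if ion_ids is None:
        ion_ids = [int(i) for i in traj.particles.ids[traj.ion_indices()]]
    coords = _aligned_coords(traj, align, rule.reference_frame, transforms)
    out: list[IonStateSeries] = []
    for ion in ion_ids:
        k = traj.particles.index_of(ion)  # raises for unknown ids
        pos = coords[:, k, :]
        if rule.reference == "initial":
            ref = pos[rule.reference_frame]
        else:
            if sites is None:
                raise ValueError(f"reference site {rule.reference!r} but no SiteSet given")
            ref = sites[rule.reference].center
        d = _pbc_distances(pos - ref, traj.box)
        out.append(
            IonStateSeries(
                ion_id=ion,
                distances=d,
                states=classify_distances(d, rule),
                rule=rule,
                aligned=align,
            )
        )
    return out


def assign_sites(
    traj: Trajectory,
    ion_ids: list[int] | None = None,
    sites: SiteSet | None = None,
    align: bool = True,
    reference_frame: int = 0,
    transforms=None,
) -> dict[int, np.ndarray]:
    """Per-ion per-frame site labels (nearest site within capture radius).

    Ties are broken by smallest distance, then by SiteSet order.  Frames
    where no site center lies within its capture radius get None.
    """
    if sites is None or len(sites) == 0:
        raise ValueError("empty SiteSet")
    if ion_ids is None:
        ion_ids = [int(i) for i in traj.particles.ids[traj.ion_indices()]]
    coords = _aligned_coords(traj, align, reference_frame, transforms)
    centers = sites.centers()  # (S, 3)
    radii = np.array([s.capture_radius for s in sites])
    names = np.array(sites.names, dtype=object)
    out: dict[int, np.ndarray] = {}
    for ion in ion_ids:
        k = traj.particles.index_of(ion)
        pos = coords[:, k, :]  # (F, 3)
        d = _pbc_distances(pos[:, None, :] - centers[None, :, :], traj.box)  # (F, S)
        within = d <= radii[None, :]
        d_masked = np.where(within, d, np.inf)
        # argmin returns the first (SiteSet-order) index on exact ties
        best = np.argmin(d_masked, axis=1)
        labels = np.where(within.any(axis=1), names[best], None)
        out[ion] = labels
    return out


def detect_transitions(
    labels: dict[int, np.ndarray] | np.ndarray,
    min_dwell: int = 5,
    frame_rate: float = 10.0,
    ion_id: int | None = None,
) -> list[TransitionEvent]:
    """Extract site-change events from per-frame site labels.

    A run of a new label counts as an occupancy change only if it lasts at
    least ``min_dwell`` frames; shorter runs (flickers) are absorbed into
    the surrounding assignment.  Unassigned (None) runs of at least
    ``min_dwell`` frames produce events to/from None.  The event is stamped
    at the first frame of the accepted run.
    """
    if min_dwell < 1:
        raise ValueError("min dwell must be ≥ 1")
    if isinstance(labels, dict):
        events: list[TransitionEvent] = []
        for ion, lab in labels.items():
            events.extend(detect_transitions(lab, min_dwell, frame_rate, ion_id=ion))
        events.sort(key=lambda e: (e.time_ns, e.ion_id))
        return events

    lab = list(labels)
    if not lab:
        return []
    # run-length encode
    runs: list[tuple[object, int, int]] = []  # (label, start, length)
    start = 0
    for i in range(1, len(lab) + 1):
        if i == len(lab) or lab[i] != lab[start]:
            runs.append((lab[start], start, i - start))
            start = i
    events = []
    current: object = None
    have_state = False
    for label, s, length in runs:
        if length < min_dwell:
            continue  # absorbed flicker
        if not have_state:
            current, have_state = label, True  # initial occupancy, no event
            continue
        if label != current:
            events.append(
                TransitionEvent(
                    ion_id=-1 if ion_id is None else ion_id,
                    from_site=current,
                    to_site=label,
                    frame=s,
                    time_ns=s / frame_rate,
                )
            )
            current = label
    return events


def _runs(seq) -> list[tuple[object, int]]:
    out = []
    seq = list(seq)
    if not seq:
        return out
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            out.append((seq[start], i - start))
            start = i
    return out


def summarize_stability(
    series: IonStateSeries,
    site_labels: np.ndarray | None = None,
    frame_rate: float = 10.0,
) -> StabilitySummary:
    """State fractions, exit time and per-site residence for one ion.

    Residence times are raw dwell-run lengths divided by the frame rate
    (1-frame quantization); the first exit time is the first FREE frame
    over the frame rate, or None if the ion never left the protein.
    """
    states = series.states
    n = len(states)
    if n == 0:
        raise ValueError("empty state series")
    fractions = {s: float(np.mean(states == s)) for s in (BOUND, EXCURSED, FREE)}
    free_frames = np.flatnonzero(states == FREE)
    left = free_frames.size > 0
    first_exit = float(free_frames[0] / frame_rate) if left else None
    residence: dict[str, float] = {}
    if site_labels is not None:
        per_site: dict[str, list[float]] = {}
        for label, length in _runs(site_labels):
            if label is not None:
                per_site.setdefault(str(label), []).append(length / frame_rate)
        residence = {k: float(np.mean(v)) for k, v in per_site.items()}
    else:
        bound_runs = [l / frame_rate for lab, l in _runs(states) if lab == BOUND]
        if bound_runs:
            residence = {"bound": float(np.mean(bound_runs))}
    return StabilitySummary(
        ion_id=series.ion_id,
        state_fractions=fractions,
        final_state=str(states[-1]),
        left_protein=bool(left),
        first_exit_time_ns=first_exit,
        mean_residence_ns=residence,
    )
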