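"""Least-squares rigid superposition and RMSD stability monitoring.

``superpose`` finds the proper rotation + translation minimizing the
root-mean-square deviation between two corresponded point sets (the
classic Kabsch problem, solved here through scipy's SVD-based
``Rotation.align_vectors``, which already rejects reflections).  The
per-frame transforms are cached on the RMSDSeries so the ion-state
classifier can reuse the same alignment instead of recomputing it.

RMSD is unweighted; a Cα-only (or any named-subset) selection is available
through ``rmsd_series``'s selection argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .trajectory import Trajectory

__all__ = ["superpose", "rmsd_series", "RMSDSeries", "apply_transform"]


def superpose(reference: np.ndarray, mobile: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid fit of ``mobile`` onto ``reference`` (N×3 each, Å).

    Returns (rotation 3×3, translation 3-vector, RMSD in Å) such that
    ``mobile @ R.T + t`` best matches ``reference`` in the least-squares
    sense.  The rotation is proper (det +1).  Degenerate (collinear or
    coincident) point sets are reported as errors because the rotation is
    then not unique.
    """
    ref = np.asarray(reference, float)
    mob = np.asarray(mobile, float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("point sets must both be N×3")
    n = ref.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    # rank of either centered cloud < 2 => collinear/coincident points
    if min(np.linalg.matrix_rank(ref_c, tol=1e-9), np.linalg.matrix_rank(mob_c, tol=1e-9)) < 2:
        raise ValueError("degenerate (collinear) point set; superposition not unique")
    rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    t = ref.mean(axis=0) - rot.apply(mob.mean(axis=0))
    rmsd = float(rssd / np.sqrt(n))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Apply a rigid transform to an (..., 3) coordinate array."""
    return np.asarray(coords, float) @ np.asarray(R).T + np.asarray(t)


@dataclass
class RMSDSeries:
    """Per-frame superposed RMSD against a reference frame.

    ``transforms[i]`` is the (R, t) pair mapping frame i's selected atoms
    onto the reference frame.
    """

    reference_frame: int
    selection: str
    rmsd: np.ndarray
    transforms: list[tuple[np.ndarray, np.ndarray]] = field(repr=False, default_factory=list)
    times: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd

        d = {"frame": np.arange(len(self.rmsd)), "rmsd": self.rmsd}
        if self.times is not None:
            d["time_ns"] = self.times
        return pd.DataFrame(d)

    def to_dict(self):
        return {
            "reference_frame": self.reference_frame,
            "selection": self.selection,
            "rmsd": self.rmsd.tolist(),
        }


def rmsd_series(
    traj: Trajectory,
    selection: str = "protein",
    reference_frame: int = 0,
) -> RMSDSeries:
    """Superposed RMSD of the selected atoms against a reference frame.

    ``selection`` is "protein" (all protein atoms, the default) or a
    species name present in the particle table.
    """
    if selection == "protein":
        idx = traj.protein_indices()
    else:
        idx = np.flatnonzero(traj.particles.species == selection)
    if idx.size == 0:
        raise ValueError(f"selection {selection!r} matches no particles")
    if not 0 <= reference_frame < traj.n_frames:
        raise ValueError(f"reference frame {reference_frame} out of range")
    ref = traj.coords[reference_frame, idx, :]
    out = np.empty(traj.n_frames)
    transforms: list[tuple[np.ndarray, np.ndarray]] = []
    for f in range(traj.n_frames):
        R, t, r = superpose(ref, traj.coords[f, idx, :])
        out[f] = r
        transforms.append((R, t))
    return RMSDSeries(
        reference_frame=reference_frame,
        selection=selection,
        rmsd=out,
        transforms=transforms,
        times=traj.times.copy(),
    )
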