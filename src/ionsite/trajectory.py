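"""Trajectory containers and plain-text I/O.

The canonical interchange format is a tab-separated frame table with a
declared header ``frame  time_ns  particle_id  species  charge  x  y  z``
(one row per particle per frame, coordinates in Å, times in ns, frame
indices 0-based).  Multi-model PDB is supported for interoperability:
each MODEL block becomes one frame, HETATM ion records become tracked or
background ions and everything else is a protein atom.

Species whose formal charge the file omits fall back to the built-in map
{ZN:+2, NA:+1, CL:-1, BCT:-1}; unknown species without a charge are an
error, because the charge census would silently miscount them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ParticleTable",
    "Trajectory",
    "read_trajectory",
    "write_trajectory",
    "write_report",
    "DEFAULT_CHARGES",
    "FRAME_TABLE_COLUMNS",
]

DEFAULT_CHARGES: dict[str, int] = {"ZN": 2, "NA": 1, "CL": -1, "BCT": -1}
#: Species treated as tracked ligand ions (reported separately from background).
TRACKED_SPECIES = frozenset({"ZN", "BCT"})
BACKGROUND_SPECIES = frozenset({"NA", "CL"})
FRAME_TABLE_COLUMNS = ("frame", "time_ns", "particle_id", "species", "charge", "x", "y", "z")


def _role_for(species: str) -> str:
    if species in TRACKED_SPECIES:
        return "tracked"
    if species in BACKGROUND_SPECIES:
        return "background"
    return "protein"


@dataclass
class ParticleTable:
    """Per-particle identity: id, species, formal charge, role."""

    table: pd.DataFrame  # columns: id, species, charge, role

    def __post_init__(self) -> None:
        t = self.table
        if t["id"].duplicated().any():
            raise ValueError("particle ids are not unique")
        incons = t.groupby("species")["charge"].nunique()
        bad = incons[incons > 1]
        if len(bad):
            raise ValueError(f"inconsistent species→charge mapping for {list(bad.index)}")

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    @property
    def species(self) -> np.ndarray:
        return self.table["species"].to_numpy()

    @property
    def charges(self) -> np.ndarray:
        return self.table["charge"].to_numpy(int)

    @property
    def roles(self) -> np.ndarray:
        return self.table["role"].to_numpy()

    def index_of(self, particle_id: int) -> int:
        pos = np.flatnonzero(self.ids == particle_id)
        if pos.size == 0:
            raise KeyError(f"unknown particle id {particle_id}")
        return int(pos[0])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class Trajectory:
    """Ordered frames of particle coordinates with a particle table.

    coords has shape (n_frames, n_particles, 3) in Å; times are in ns and
    strictly increasing; ``box`` (optional) holds orthorhombic box lengths
    in Å — when absent no periodic treatment is applied.
    """

    particles: ParticleTable
    coords: np.ndarray
    times: np.ndarray
    frame_rate: float  # frames per ns
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        self.times = np.asarray(self.times, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_particles, 3)")
        if self.coords.shape[0] != self.times.shape[0]:
            raise ValueError("times and frames disagree in length")
        if self.coords.shape[1] != len(self.particles):
            raise ValueError("coords and particle table disagree in particle count")
        if len(self.times) > 1:
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("frame times are not strictly increasing")
            implied = 1.0 / np.median(np.diff(self.times))
            if abs(implied - self.frame_rate) > 1e-6 * max(1.0, self.frame_rate):
                raise ValueError(
                    f"frame rate {self.frame_rate}/ns inconsistent with times "
                    f"(implied {implied:.6f}/ns)"
                )
        if self.box is not None:
            self.box = np.asarray(self.box, float).reshape(3)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def coords_of(self, particle_id: int) -> np.ndarray:
        """(n_frames, 3) positions of one particle."""
        return self.coords[:, self.particles.index_of(particle_id), :]

    def protein_indices(self) -> np.ndarray:
        return np.flatnonzero(self.particles.roles == "protein")

    def ion_indices(self) -> np.ndarray:
        return np.flatnonzero(self.particles.roles != "protein")


# ---------------------------------------------------------------------------
# readers / writers

def _resolve_roles_and_charges(
    species: pd.Series, charge: pd.Series, role: pd.Series | None
) -> tuple[np.ndarray, np.ndarray]:
    """Fill roles and formal charges from the default maps.

    An unknown species with neither an explicit charge nor a role column is
    an error — silently counting it as a protein atom would corrupt the
    charge census.
    """
    roles, charges = [], []
    for i in species.index:
        sp = species[i]
        q = charge[i]
        r = role[i] if role is not None else None
        if pd.isna(q):
            if sp in DEFAULT_CHARGES:
                q = DEFAULT_CHARGES[sp]
            elif sp == "PRT" or r == "protein":
                q = 0
            else:
                raise ValueError(
                    f"species {sp!r} has no charge in file or default map"
                )
        q = int(q)
        if r is None:
            r = _role_for(sp) if sp in DEFAULT_CHARGES or sp == "PRT" else (
                "tracked" if q != 0 else "protein")
        roles.append(r)
        charges.append(q)
    return np.array(roles), np.array(charges)


def read_frame_table(path: str | Path, frame_rate: float | None = None,
                     box: np.ndarray | None = None) -> Trajectory:
    """Read the canonical TSV frame-table dialect."""
    # keep_default_na: the sodium species code "NA" must not parse as NaN
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False,
                     na_values=[""], dtype={"species": str})
    missing_cols = set(FRAME_TABLE_COLUMNS[:4]) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: frame table missing columns {sorted(missing_cols)}")
    if "charge" not in df.columns:
        df["charge"] = np.nan
    frames = np.sort(df["frame"].unique())
    first = df[df["frame"] == frames[0]].sort_values("particle_id")
    ids = first["particle_id"].to_numpy()
    indexed = first.set_index("particle_id")
    roles, charges = _resolve_roles_and_charges(
        indexed["species"],
        pd.to_numeric(indexed["charge"], errors="coerce"),
        indexed["role"] if "role" in indexed.columns else None,
    )
    ptable = ParticleTable(
        pd.DataFrame(
            {
                "id": ids,
                "species": first["species"].to_numpy(),
                "charge": charges,
                "role": roles,
            }
        )
    )
    n = len(ids)
    coords = np.empty((len(frames), n, 3))
    times = np.empty(len(frames))
    id_order = {pid: k for k, pid in enumerate(ids)}
    for fi, f in enumerate(frames):
        sub = df[df["frame"] == f]
        if len(sub) != n or set(sub["particle_id"]) != set(ids):
            missing = sorted(set(ids) - set(sub["particle_id"]))
            raise ValueError(
                f"{path}: frame {f} missing particle(s) {missing or 'or has extras'}"
            )
        rows = sub["particle_id"].map(id_order).to_numpy()
        coords[fi, rows, :] = sub[["x", "y", "z"]].to_numpy(float)
        times[fi] = sub["time_ns"].iloc[0]
    if frame_rate is None:
        frame_rate = 1.0 / np.median(np.diff(times)) if len(times) > 1 else 10.0
    return Trajectory(particles=ptable, coords=coords, times=times,
                      frame_rate=float(frame_rate), box=box)


def read_multimodel_pdb(path: str | Path, frame_rate: float = 10.0,
                        box: np.ndarray | None = None) -> Trajectory:
    """Read a multi-model PDB: one MODEL block per frame.

    Particle ids are atom serials; HETATM residue names ZN/NA/CL/BCT map to
    ion species with default charges, everything else is a protein atom.
    """
    import gemmi

    from .structure import _prevalidate_pdb

    text = Path(path).read_text()
    _prevalidate_pdb(text, str(path))
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise ValueError(f"{path}: no MODEL blocks found")
    records = []
    for chain in st[0]:
        for res in chain:
            for atom in res:
                sp = res.name.strip().upper()
                # ion residues keep their species code; protein atoms carry
                # the atom name so RMSD selections like "CA" stay possible
                species = sp if sp in DEFAULT_CHARGES else atom.name
                records.append((atom.serial, species))
    ids = np.array([r[0] for r in records])
    species = pd.Series([r[1] for r in records])
    pdb_roles = pd.Series(
        [_role_for(s) if s in DEFAULT_CHARGES else "protein" for s in species]
    )
    roles, charges = _resolve_roles_and_charges(
        species, pd.Series([np.nan] * len(species)), pdb_roles
    )
    ptable = ParticleTable(
        pd.DataFrame({"id": ids, "species": species.to_numpy(),
                      "charge": charges, "role": roles})
    )
    coords = np.empty((len(st), len(ids), 3))
    for mi, model in enumerate(st):
        k = 0
        for chain in model:
            for res in chain:
                for atom in res:
                    coords[mi, k] = (atom.pos.x, atom.pos.y, atom.pos.z)
                    k += 1
        if k != len(ids):
            raise ValueError(f"{path}: MODEL {mi + 1} has {k} atoms, expected {len(ids)}")
    times = np.arange(len(st)) / frame_rate
    return Trajectory(particles=ptable, coords=coords, times=times,
                      frame_rate=frame_rate, box=box)


def read_trajectory(path: str | Path, fmt: str | None = None, **kwargs) -> Trajectory:
    """Read a trajectory; format inferred from the extension unless given.

    fmt is "tsv" (frame table) or "pdb" (multi-model PDB).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "pdb" if path.suffix.lower() in {".pdb", ".ent"} else "tsv"
    if fmt == "tsv":
        return read_frame_table(path, **kwargs)
    if fmt == "pdb":
        return read_multimodel_pdb(path, **kwargs)
    raise ValueError(f"unknown trajectory format {fmt!r}")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write the canonical TSV frame table (read ∘ write is the identity)."""
    p = traj.particles
    n = len(p)
    rows = {
        "frame": np.repeat(np.arange(traj.n_frames), n),
        "time_ns": np.repeat(traj.times, n),
        "particle_id": np.tile(p.ids, traj.n_frames),
        "species": np.tile(p.species, traj.n_frames),
        "charge": np.tile(p.charges, traj.n_frames),
        "role": np.tile(p.roles, traj.n_frames),
        "x": traj.coords[:, :, 0].ravel(),
        "y": traj.coords[:, :, 1].ravel(),
        "z": traj.coords[:, :, 2].ravel(),
    }
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.9f")


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_report(result, path: str | Path, fmt: str = "json",
                 provenance: dict | None = None) -> None:
    """Write an analysis product loss-free as CSV or JSON.

    Result types expose ``to_frame()`` (tabular) and/or ``to_dict()``
    (nested); plain DataFrames, dicts and lists are written as-is.  JSON
    output carries a provenance block (parameters, seed, hashes, version)
    when one is supplied.
    """
    path = Path(path)
    if fmt == "csv":
        if hasattr(result, "to_frame_table"):
            df = result.to_frame_table()
        elif hasattr(result, "to_frame"):
            df = result.to_frame()
        elif isinstance(result, pd.DataFrame):
            df = result
        else:
            raise TypeError(f"cannot write {type(result).__name__} as CSV")
        df.to_csv(path, index=False, float_format="%.12g")
        return
    if fmt == "json":
        if hasattr(result, "to_dict"):
            payload = result.to_dict()
        elif isinstance(result, pd.DataFrame):
            payload = result.to_dict(orient="records")
        elif isinstance(result, (dict, list)):
            payload = result
        else:
            raise TypeError(f"cannot write {type(result).__name__} as JSON")
        doc = {"result": payload}
        if provenance is not None:
            doc["provenance"] = provenance
        path.write_text(json.dumps(doc, indent=2, cls=_NumpyEncoder) + "\n")
        return
    raise ValueError(f"unknown report format {fmt!r}")
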