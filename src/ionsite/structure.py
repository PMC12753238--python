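"""Structures and named binding-site definitions.

Reads PDB coordinate files and builds named binding sites (M1, M2, M4,
BCT1, BCT2) either from coordinating-residue selections or from explicit
centers.  The ZIP8 binuclear metal center is the packaged default: M1 is
formed by H314, E343, H347 and D410, M2 by N315, E344 and the bridging
D318, and the cytoplasmic-side M4 by D311, E348 and D351.  The two
bicarbonate positions BCT1/BCT2 have no coordinating-residue definition of
their own (they come from docking poses) and are supplied as explicit
centers.

A site center is operationalized as the unweighted centroid of the
side-chain heavy atoms of its coordinating residues; this is a package
convention, recorded in every report, not a measured quantity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
from pydantic import BaseModel, field_validator

__all__ = [
    "StructureModel",
    "ResidueSelector",
    "BindingSite",
    "SiteSet",
    "load_structure",
    "build_site",
    "default_zip8_siteset",
    "load_siteset_config",
    "ZIP8_SITE_RESIDUES",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Coordinating residues of the ZIP8 metal-binding sites (resname, resnum).
ZIP8_SITE_RESIDUES: dict[str, list[tuple[str, int]]] = {
    "M1": [("HIS", 314), ("GLU", 343), ("HIS", 347), ("ASP", 410)],
    "M2": [("ASN", 315), ("GLU", 344), ("ASP", 318)],
    "M4": [("ASP", 311), ("GLU", 348), ("ASP", 351)],
}


@dataclass(frozen=True)
class ResidueSelector:
    """Select atoms of one residue.

    ``atom_subset`` is one of ``"sidechain"`` (side-chain heavy atoms,
    the default), ``"heavy"`` (all heavy atoms) or an explicit tuple of
    atom names.  Glycine/alanine-like residues with no side-chain heavy
    atoms fall back to CB, then CA, so mutant structures still define a
    geometric site.
    """

    resnum: int
    resname: str | None = None
    chain: str | None = None
    atom_subset: str | tuple[str, ...] = "sidechain"

    def resolve(self, structure: "StructureModel") -> np.ndarray:
        """Indices (into ``structure.atoms``) of the selected atoms."""
        atoms = structure.atoms
        mask = atoms["resnum"] == self.resnum
        if self.resname is not None:
            mask &= atoms["resname"] == self.resname.upper()
        if self.chain is not None:
            mask &= atoms["chain"] == self.chain
        else:
            chains = sorted(set(atoms.loc[mask, "chain"]))
            if len(chains) > 1:
                raise ValueError(
                    f"residue {self.resname} {self.resnum} found in multiple "
                    f"chains {chains}; specify a chain"
                )
        idx = np.flatnonzero(mask.to_numpy())
        if idx.size == 0:
            raise ValueError(
                f"selector resolves to 0 atoms: residue {self.resname} "
                f"{self.resnum} (chain {self.chain or 'any'})"
            )
        names = atoms["name"].to_numpy()[idx]
        elements = atoms["element"].to_numpy()[idx]
        if isinstance(self.atom_subset, tuple):
            keep = np.isin(names, list(self.atom_subset))
        elif self.atom_subset == "heavy":
            keep = elements != "H"
        elif self.atom_subset == "sidechain":
            keep = (~np.isin(names, list(BACKBONE_ATOMS))) & (elements != "H")
            if not keep.any():  # GLY/ALA-style fallback: CB, then CA
                keep = names == "CB"
            if not keep.any():
                keep = names == "CA"
        else:
            raise ValueError(f"unknown atom subset {self.atom_subset!r}")
        idx = idx[keep]
        if idx.size == 0:
            raise ValueError(
                f"selector resolves to 0 atoms after atom-subset filter: "
                f"residue {self.resname} {self.resnum}, subset {self.atom_subset!r}"
            )
        return idx


@dataclass
class StructureModel:
    """Atoms of one coordinate model, in file order.

    ``atoms`` is a DataFrame with columns serial, name, element, resname,
    resnum, chain, x, y, z (coordinates in Å, author residue numbering
    preserved).
    """

    atoms: "object"  # pandas.DataFrame
    title: str = ""

    def __post_init__(self) -> None:
        xyz = self.coords
        if not np.all(np.isfinite(xyz)):
            raise ValueError("structure contains non-finite coordinates")
        key = self.atoms[["chain", "resnum", "name"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(
                f"duplicate atom record: chain {dup['chain']} residue "
                f"{dup['resnum']} atom {dup['name']}"
            )

    @property
    def coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(float)

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class BindingSite:
    """A named site with a derived or explicit center (Å)."""

    name: str
    center: np.ndarray
    capture_radius: float = 5.0
    census_radius: float = 10.0
    selectors: tuple[ResidueSelector, ...] = ()

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, float).reshape(3)
        if not np.all(np.isfinite(self.center)):
            raise ValueError(f"site {self.name}: non-finite center")
        if self.capture_radius <= 0 or self.census_radius <= 0:
            raise ValueError(f"site {self.name}: radii must be positive")


@dataclass
class SiteSet:
    """Ordered collection of binding sites plus the census reference point.

    ``region_center`` defaults to the midpoint of the M1 and M2 centers
    when both exist, matching the convention that the ion/charge census is
    taken in a sphere around the binuclear center.
    """

    sites: list[BindingSite]
    region_center: np.ndarray | None = None

    def __post_init__(self) -> None:
        names = [s.name for s in self.sites]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate site names in SiteSet: {names}")
        if self.region_center is None:
            by_name = {s.name: s for s in self.sites}
            if "M1" in by_name and "M2" in by_name:
                self.region_center = 0.5 * (by_name["M1"].center + by_name["M2"].center)
            elif self.sites:
                self.region_center = np.mean([s.center for s in self.sites], axis=0)
            else:
                raise ValueError("empty SiteSet")
        self.region_center = np.asarray(self.region_center, float).reshape(3)

    def __iter__(self):
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    def __getitem__(self, name: str) -> BindingSite:
        for s in self.sites:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sites]

    def centers(self) -> np.ndarray:
        return np.stack([s.center for s in self.sites])


def _prevalidate_pdb(text: str, path: str) -> None:
    """Reject malformed ATOM/HETATM numeric fields with a line number.

    gemmi silently zero-fills unparsable coordinate columns, which would
    corrupt downstream geometry, so the numeric columns are checked first.
    """
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fld = line[lo:hi].strip()
            try:
                float(fld)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: malformed {what} coordinate field "
                    f"{fld!r} in {line[:6].strip()} record"
                ) from None


def load_structure(path: str | Path, model_index: int = 1) -> StructureModel:
    """Read one MODEL block of a PDB coordinate file (1-based index)."""
    import pandas as pd

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    _prevalidate_pdb(text, str(path))
    st = gemmi.read_pdb_string(text)
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no coordinate models found")
    if not 1 <= model_index <= len(st):
        raise ValueError(
            f"{path}: requested model {model_index}, file has {len(st)} model(s)"
        )
    model = st[model_index - 1]
    rows = []
    for chain in model:
        for res in chain:
            for atom in res:
                rows.append(
                    (
                        atom.serial,
                        atom.name,
                        atom.element.name.upper(),
                        res.name,
                        res.seqid.num,
                        chain.name,
                        atom.pos.x,
                        atom.pos.y,
                        atom.pos.z,
                    )
                )
    atoms = pd.DataFrame(
        rows,
        columns=["serial", "name", "element", "resname", "resnum", "chain", "x", "y", "z"],
    )
    title = " ".join(
        line[10:].strip() for line in text.splitlines() if line.startswith("TITLE")
    )
    return StructureModel(atoms=atoms, title=title)


def build_site(
    structure: StructureModel,
    name: str,
    selectors: Sequence[ResidueSelector],
    capture_radius: float = 5.0,
    census_radius: float = 10.0,
) -> BindingSite:
    """Build a site whose center is the centroid of the selected atoms."""
    if capture_radius <= 0:
        raise ValueError("capture radius must be positive")
    if not selectors:
        raise ValueError(f"site {name}: no selectors and no explicit center")
    idx = np.concatenate([sel.resolve(structure) for sel in selectors])
    center = structure.coords[idx].mean(axis=0)
    return BindingSite(
        name=name,
        center=center,
        capture_radius=capture_radius,
        census_radius=census_radius,
        selectors=tuple(selectors),
    )


def default_zip8_siteset(
    structure: StructureModel,
    bct_centers: dict[str, Sequence[float]] | None = None,
    capture_radius: float = 5.0,
    census_radius: float = 10.0,
) -> SiteSet:
    """ZIP8 default: M1/M2/M4 from residues, BCT1/BCT2 from explicit centers.

    ``bct_centers`` maps "BCT1"/"BCT2" to explicit coordinates (e.g. docking
    poses); sites with no center supplied are omitted.  Raises if a
    residue-derived site cannot be built, naming the site.
    """
    sites: list[BindingSite] = []
    for name, residues in ZIP8_SITE_RESIDUES.items():
        try:
            sels = [ResidueSelector(resnum=num, resname=rn) for rn, num in residues]
            sites.append(build_site(structure, name, sels, capture_radius, census_radius))
        except ValueError as exc:
            raise ValueError(f"cannot build site {name}: {exc}") from exc
    for name in ("BCT1", "BCT2"):
        if bct_centers and name in bct_centers:
            sites.append(
                BindingSite(
                    name=name,
                    center=np.asarray(bct_centers[name], float),
                    capture_radius=capture_radius,
                    census_radius=census_radius,
                )
            )
    return SiteSet(sites=sites)


class _SiteEntry(BaseModel):
    name: str
    residues: list[dict] | None = None
    center: list[float] | None = None
    capture_radius: float = 5.0
    census_radius: float = 10.0

    @field_validator("center")
    @classmethod
    def _len3(cls, v):
        if v is not None and len(v) != 3:
            raise ValueError("center must have 3 components")
        return v


class SiteConfig(BaseModel):
    """Schema of the site-definition JSON file.

    A list of entries, each either residue-based::

        {"name": "M1", "residues": [{"resname": "HIS", "resnum": 314}],
         "capture_radius": 5.0, "census_radius": 10.0}

    or an explicit center::

        {"name": "BCT1", "center": [x, y, z]}
    """

    sites: list[_SiteEntry]
    region_center: list[float] | None = None


def load_siteset_config(
    source: str | Path | dict, structure: StructureModel | None = None
) -> SiteSet:
    """Build a SiteSet from a JSON file or an already-parsed dict."""
    if isinstance(source, (str, Path)):
        raw = json.loads(Path(source).read_text())
    else:
        raw = source
    cfg = SiteConfig.model_validate(raw)
    sites: list[BindingSite] = []
    for entry in cfg.sites:
        if entry.center is not None:
            sites.append(
                BindingSite(
                    name=entry.name,
                    center=np.asarray(entry.center, float),
                    capture_radius=entry.capture_radius,
                    census_radius=entry.census_radius,
                )
            )
        elif entry.residues:
            if structure is None:
                raise ValueError(
                    f"site {entry.name} is residue-based but no structure given"
                )
            sels = [
                ResidueSelector(
                    resnum=r["resnum"],
                    resname=r.get("resname"),
                    chain=r.get("chain"),
                )
                for r in entry.residues
            ]
            sites.append(
                build_site(structure, entry.name, sels, entry.capture_radius, entry.census_radius)
            )
        else:
            raise ValueError(f"site {entry.name}: neither residues nor center given")
    region = np.asarray(cfg.region_center, float) if cfg.region_center else None
    return SiteSet(sites=sites, region_center=region)
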