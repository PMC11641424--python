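"""Structure reading/writing, pLDDT extraction and residue correspondence.

Coordinates are handled as :class:`biotite.structure.AtomArray` objects
wrapped in a thin :class:`StructureModel` that remembers whether the model is
experimental or predicted.  Predicted models carry per-residue pLDDT
(0-100 confidence) in the B-factor column, the convention used by
AlphaFold-style predictors.

Residues are matched between two structures by author residue number plus
insertion code (optionally with a declared numbering offset), restricted to
residues whose Cα is resolved in both — crystal structures routinely have
unresolved stretches, so the correspondence is what every downstream metric
operates on.
"""

from __future__ import annotations

import urllib.request
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io import pdb as pdb_io
from biotite.structure.io import pdbx as pdbx_io
from scipy.spatial.distance import cdist

from .exceptions import CorrespondenceError, InputError, SelectionError

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Residue key: (author residue number, insertion code)
ResKey = tuple[int, str]


@dataclass
class StructureModel:
    """A single-model protein structure (one chain unless none was selected)."""

    id: str
    atoms: struc.AtomArray
    source: str = "experimental"  # experimental | predicted

    def __post_init__(self):
        if self.source not in ("experimental", "predicted"):
            raise InputError(f"unknown source {self.source!r}")
        if not np.all(np.isfinite(self.atoms.coord)):
            raise InputError(f"{self.id}: non-finite coordinates")

    @property
    def protein_atoms(self) -> struc.AtomArray:
        return self.atoms[~self.atoms.hetero]

    @property
    def hetero_atoms(self) -> struc.AtomArray:
        return self.atoms[self.atoms.hetero]

    def residue_keys(self) -> list[ResKey]:
        """Keys of protein residues that have a Cα atom, in chain order."""
        prot = self.protein_atoms
        ca = prot[prot.atom_name == "CA"]
        return [(int(r), str(i)) for r, i in zip(ca.res_id, ca.ins_code)]

    def n_residues(self) -> int:
        return len(self.residue_keys())

    def atom_coord(self, key: ResKey, atom_name: str) -> np.ndarray | None:
        """Coordinate of one named atom in one residue, or None if absent."""
        prot = self.protein_atoms
        mask = (
            (prot.res_id == key[0])
            & (prot.ins_code == key[1])
            & (prot.atom_name == atom_name)
        )
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return None
        return prot.coord[idx[0]]

    def residue_atoms(self, key: ResKey) -> struc.AtomArray:
        prot = self.protein_atoms
        return prot[(prot.res_id == key[0]) & (prot.ins_code == key[1])]


def read_structure(
    path: str | Path,
    format: str | None = None,
    chain: str | None = None,
    source: str = "experimental",
) -> StructureModel:
    """Read a PDB or mmCIF file (first model).

    Heteroatoms are retained (flagged via the ``hetero`` annotation), altlocs
    are resolved to the highest-occupancy conformer, and insertion codes are
    preserved.

    Parameters
    ----------
    format
        ``"pdb"`` or ``"mmcif"``; inferred from the suffix when ``None``.
    chain
        Author chain id to select; ``None`` keeps all chains.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "mmcif" if suffix in (".cif", ".mmcif") else "pdb"
    extra = ["b_factor", "occupancy"]
    if format == "pdb":
        f = pdb_io.PDBFile.read(str(path))
        atoms = pdb_io.get_structure(f, model=1, altloc="occupancy", extra_fields=extra)
    elif format == "mmcif":
        f = pdbx_io.CIFFile.read(str(path))
        atoms = pdbx_io.get_structure(f, model=1, altloc="occupancy", extra_fields=extra)
    else:
        raise InputError(f"unknown structure format {format!r}")
    if chain is not None:
        mask = atoms.chain_id == chain
        if not mask.any():
            raise SelectionError(
                f"{path}: chain {chain!r} not found "
                f"(available: {sorted(set(atoms.chain_id))})"
            )
        atoms = atoms[mask]
    return StructureModel(id=path.stem, atoms=atoms, source=source)


def write_structure(model: StructureModel, path: str | Path) -> Path:
    """Write a model to PDB (B-factor column preserved, e.g. pLDDT)."""
    path = Path(path)
    f = pdb_io.PDBFile()
    pdb_io.set_structure(f, model.atoms)
    f.write(str(path))
    return path


def extract_plddt(model: StructureModel) -> np.ndarray:
    """Per-residue pLDDT from the B-factor of each residue's Cα.

    Residues without a Cα are skipped with a warning; values outside
    [0, 100] are reported as-is with a warning (they indicate the file is
    not an AlphaFold-style prediction).
    """
    prot = model.protein_atoms
    values = []
    res_starts = struc.get_residue_starts(prot, add_exclusive_stop=True)
    for lo, hi in zip(res_starts[:-1], res_starts[1:]):
        res = prot[lo:hi]
        ca = res[res.atom_name == "CA"]
        if len(ca) == 0:
            warnings.warn(
                f"{model.id}: residue {res.res_id[0]} has no CA; skipped in pLDDT extraction"
            )
            continue
        values.append(float(ca.b_factor[0]))
    out = np.asarray(values, dtype=float)
    if out.size and (out.min() < 0.0 or out.max() > 100.0):
        warnings.warn(
            f"{model.id}: B-factor values outside [0, 100] "
            f"(min {out.min():.1f}, max {out.max():.1f}); reported as-is"
        )
    return out


@dataclass(frozen=True)
class Correspondence:
    """Matched residues between two structures.

    ``keys_a[i]`` in structure A pairs with ``keys_b[i]`` in structure B.
    """

    keys_a: tuple[ResKey, ...]
    keys_b: tuple[ResKey, ...]
    n_dropped_a: int
    n_dropped_b: int

    def __len__(self) -> int:
        return len(self.keys_a)


def build_correspondence(
    a: StructureModel,
    b: StructureModel,
    offset_b: int = 0,
    min_matched: int = 30,
) -> Correspondence:
    """Pair residues of ``a`` and ``b`` by author numbering.

    A residue of A numbered ``n`` matches the residue of B numbered
    ``n + offset_b`` (same insertion code); only residues with a resolved Cα
    on both sides are paired.

    Raises
    ------
    CorrespondenceError
        If fewer than ``min_matched`` residues match (the default 30 is the
        point below which a superposition becomes unreliable).
    """
    keys_a = a.residue_keys()
    keys_b = b.residue_keys()
    set_b = set(keys_b)
    pairs = [
        (ka, (ka[0] + offset_b, ka[1]))
        for ka in keys_a
        if (ka[0] + offset_b, ka[1]) in set_b
    ]
    if len(pairs) < min_matched:
        raise CorrespondenceError(
            f"only {len(pairs)} residues matched between {a.id} and {b.id} "
            f"(minimum {min_matched}); check chain selection / numbering offset"
        )
    matched_a = tuple(p[0] for p in pairs)
    matched_b = tuple(p[1] for p in pairs)
    return Correspondence(
        keys_a=matched_a,
        keys_b=matched_b,
        n_dropped_a=len(keys_a) - len(pairs),
        n_dropped_b=len(keys_b) - len(pairs),
    )


def define_pocket(
    holo: StructureModel,
    ligand: str = "auto",
    cutoff: float = 4.5,
) -> frozenset[ResKey]:
    """Residues forming the binding pocket around a ligand in the holo form.

    A residue belongs to the pocket if any of its protein heavy atoms lies
    within ``cutoff`` Å (inclusive) of any ligand heavy atom.  Waters are
    never considered ligands.

    Parameters
    ----------
    ligand
        Heteroatom residue name (e.g. ``"RIB"``); ``"auto"`` picks the
        largest non-water heteroatom group.
    """
    het = holo.hetero_atoms
    het = het[~np.isin(het.res_name, list(WATER_NAMES))]
    het = het[het.element != "H"]
    if len(het) == 0:
        raise SelectionError(f"{holo.id}: no non-water heteroatoms to define a pocket")
    if ligand == "auto":
        names, counts = np.unique(het.res_name, return_counts=True)
        ligand = str(names[np.argmax(counts)])
    lig = het[het.res_name == ligand]
    if len(lig) == 0:
        raise SelectionError(
            f"{holo.id}: ligand {ligand!r} not found "
            f"(heteroatom groups: {sorted(set(het.res_name))})"
        )
    prot = holo.protein_atoms
    prot = prot[prot.element != "H"]
    d = cdist(prot.coord, lig.coord)
    near = d.min(axis=1) <= cutoff
    keys = {
        (int(r), str(i))
        for r, i in zip(prot.res_id[near], prot.ins_code[near])
    }
    return frozenset(keys)


@dataclass
class ReferencePair:
    """Apo and holo reference structures with their residue correspondence."""

    apo: StructureModel
    holo: StructureModel
    correspondence: Correspondence
    pocket: frozenset[ResKey] | None = None  # defined on the holo structure

    @classmethod
    def from_models(
        cls,
        apo: StructureModel,
        holo: StructureModel,
        offset_holo: int = 0,
        ligand: str | None = None,
        pocket_cutoff: float = 4.5,
        min_matched: int = 30,
    ) -> "ReferencePair":
        corr = build_correspondence(apo, holo, offset_b=offset_holo, min_matched=min_matched)
        pocket = None
        if ligand is not None:
            pocket = define_pocket(holo, ligand=ligand, cutoff=pocket_cutoff)
            pocket = frozenset(pocket & set(corr.keys_b))
        return cls(apo=apo, holo=holo, correspondence=corr, pocket=pocket)


RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


def fetch_structure(
    pdb_id: str,
    dest_dir: str | Path,
    allow_download: bool = False,
    timeout: float = 30.0,
) -> Path:
    """Download a PDB entry from the RCSB archive.

    Downloads are opt-in (``allow_download=True``); the default workflow is
    fully offline.  Returns the local file path (cached file reused if
    present).
    """
    dest_dir = Path(dest_dir)
    dest_dir.mkdir(parents=True, exist_ok=True)
    out = dest_dir / f"{pdb_id.lower()}.pdb"
    if out.exists():
        return out
    if not allow_download:
        raise InputError(
            f"{pdb_id}: not cached in {dest_dir} and downloads are disabled "
            "(pass allow_download=True / --allow-download)"
        )
    url = RCSB_URL.format(pdb_id=pdb_id.upper())
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        data = resp.read()
    out.write_bytes(data)
    return out
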