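"""Synthetic two-basin hinge protein and desk-scale test inputs.

Many ligand-binding proteins (periplasmic binding proteins, kinases, T4
lysozyme cavity mutants) interconvert between an *open* (apo) and a *closed*
(holo) conformation related by a rigid hinge-bending motion of one domain.
This module builds an idealized such system entirely in silico:

* a two-domain backbone (N, CA, C, O, CB per residue, poly-alanine) laid out
  on an α-helical curve,
* a *closed* basin obtained by rotating the second domain about a hinge
  axis, with the rotation angle solved so the open/closed backbone RMSD hits
  a requested value (3.5 Å by default — the regime of the large hinge
  motions in real apo/holo benchmark pairs),
* an optional pseudo-ligand placed in the interdomain cleft of the closed
  form so pocket definition is exercised,
* random query sequences and synthetic MSAs to drive the masking and
  subsampling stages.

The geometry is idealized (no physical force field, no side chains beyond
CB); it is a coordinate test object for superposition, clustering and
classification machinery, not a model of any real protein.
"""

from __future__ import annotations

import numpy as np
import biotite.structure as struc
from scipy.spatial.transform import Rotation

from .masking import QuerySequence
from .msa import AlignmentStack
from .structure_io import StructureModel

_HELIX_RISE = 1.5       # Å per residue along the helix axis
_HELIX_RADIUS = 2.3     # Å
_HELIX_TURN = np.deg2rad(100.0)  # per residue

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _ca_trace(n_res: int) -> np.ndarray:
    """Idealized α-helical Cα trace along +x."""
    i = np.arange(n_res)
    return np.stack(
        [
            _HELIX_RISE * i,
            _HELIX_RADIUS * np.cos(_HELIX_TURN * i),
            _HELIX_RADIUS * np.sin(_HELIX_TURN * i),
        ],
        axis=1,
    )


def _bend_trace(ca: np.ndarray, hinge: int, angle_deg: float) -> np.ndarray:
    """Rotate residues >= hinge about the y axis through the hinge Cα."""
    rot = Rotation.from_euler("y", angle_deg, degrees=True)
    out = ca.copy()
    pivot = ca[hinge]
    out[hinge:] = rot.apply(ca[hinge:] - pivot) + pivot
    return out


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _backbone_atoms(ca: np.ndarray) -> list[tuple[str, str, np.ndarray]]:
    """Place N, CA, C, O, CB around each Cα using a local chain frame."""
    n_res = ca.shape[0]
    atoms: list[tuple[str, str, np.ndarray]] = []
    for i in range(n_res):
        lo, hi = max(i - 1, 0), min(i + 1, n_res - 1)
        t = _unit(ca[hi] - ca[lo])
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(t, ref)) > 0.95:
            ref = np.array([0.0, 1.0, 0.0])
        u = _unit(np.cross(t, ref))
        v = _unit(np.cross(t, u))
        atoms.append(("N", "N", ca[i] - 1.2 * t + 0.8 * u))
        atoms.append(("CA", "C", ca[i]))
        atoms.append(("C", "C", ca[i] + 1.2 * t + 0.8 * u))
        atoms.append(("O", "O", ca[i] + 1.2 * t + 2.0 * u))
        atoms.append(("CB", "C", ca[i] + 1.53 * v))
    return atoms


def _model_from_ca(ca: np.ndarray, model_id: str, source: str = "experimental") -> StructureModel:
    records = _backbone_atoms(ca)
    n = len(records)
    arr = struc.AtomArray(n)
    arr.coord = np.array([r[2] for r in records], dtype=np.float32)
    arr.chain_id = np.full(n, "A")
    arr.res_id = np.repeat(np.arange(1, ca.shape[0] + 1), 5)
    arr.ins_code = np.full(n, "")
    arr.res_name = np.full(n, "ALA")
    arr.hetero = np.full(n, False)
    arr.atom_name = np.array([r[0] for r in records])
    arr.element = np.array([r[1] for r in records])
    arr.set_annotation("b_factor", np.zeros(n))
    arr.set_annotation("occupancy", np.ones(n))
    return StructureModel(id=model_id, atoms=arr, source=source)


def _backbone_rmsd(a: StructureModel, b: StructureModel) -> float:
    # local import avoids a module cycle (metrics imports structure_io only)
    from .metrics import kabsch_superpose
    from .structure_io import BACKBONE_ATOMS

    mask_a = np.isin(a.atoms.atom_name, BACKBONE_ATOMS) & ~a.atoms.hetero
    mask_b = np.isin(b.atoms.atom_name, BACKBONE_ATOMS) & ~b.atoms.hetero
    return kabsch_superpose(a.atoms.coord[mask_a], b.atoms.coord[mask_b]).rmsd


def make_hinge_conformer(
    n_res: int = 80,
    hinge_angle_deg: float = 0.0,
    model_id: str = "hinge",
) -> StructureModel:
    """One conformer of the hinge system at a given bending angle."""
    ca = _bend_trace(_ca_trace(n_res), hinge=n_res // 2, angle_deg=hinge_angle_deg)
    return _model_from_ca(ca, model_id)


def _attach_ligand(model: StructureModel, hinge: int) -> StructureModel:
    """Place a 4-atom pseudo-ligand in the interdomain cleft."""
    prot = model.atoms
    ca_mask = prot.atom_name == "CA"
    ca = prot.coord[ca_mask]
    center = ca[hinge - 2 : hinge + 3].mean(axis=0)
    # nudge off the backbone so it sits in the cleft, not on top of it
    offset = _unit(ca.mean(axis=0) - center) * 3.0
    pos = center + offset
    lig_coords = pos + np.array(
        [[0, 0, 0], [1.4, 0, 0], [0, 1.4, 0], [0, 0, 1.4]], dtype=float
    )
    n = 4
    lig = struc.AtomArray(n)
    lig.coord = lig_coords.astype(np.float32)
    lig.chain_id = np.full(n, "A")
    lig.res_id = np.full(n, 900)
    lig.ins_code = np.full(n, "")
    lig.res_name = np.full(n, "LIG")
    lig.hetero = np.full(n, True)
    lig.atom_name = np.array(["C1", "C2", "C3", "C4"])
    lig.element = np.full(n, "C")
    lig.set_annotation("b_factor", np.zeros(n))
    lig.set_annotation("occupancy", np.ones(n))
    return StructureModel(id=model.id, atoms=prot + lig, source=model.source)


def make_two_basin_pair(
    n_res: int = 80,
    target_rmsd: float = 3.5,
    with_ligand: bool = True,
) -> tuple[StructureModel, StructureModel, float]:
    """Open (apo) and closed (holo) basins at a prescribed backbone RMSD.

    The closing angle is solved by bisection so that the backbone RMSD
    between the two basins equals ``target_rmsd`` to 0.001 Å.  Returns
    ``(apo, holo, closing_angle_deg)``.  The holo form carries a pseudo-
    ligand in the cleft when ``with_ligand`` is set.
    """
    apo = make_hinge_conformer(n_res, 0.0, model_id="synthetic_apo")

    def rmsd_at(angle: float) -> float:
        return _backbone_rmsd(apo, make_hinge_conformer(n_res, angle, "tmp"))

    lo, hi = 0.0, 10.0
    while rmsd_at(hi) < target_rmsd:
        hi *= 2.0
        if hi > 360.0:
            raise ValueError(f"target RMSD {target_rmsd} unreachable by hinge bending")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if rmsd_at(mid) < target_rmsd:
            lo = mid
        else:
            hi = mid
    angle = 0.5 * (lo + hi)
    holo = make_hinge_conformer(n_res, angle, model_id="synthetic_holo")
    if with_ligand:
        holo = _attach_ligand(holo, hinge=n_res // 2)
    return apo, holo, angle


def make_query_sequence(n_res: int = 80, seed: int = 0, seq_id: str = "synthetic_query") -> QuerySequence:
    """Random 20-letter query sequence of the hinge protein's length."""
    rng = np.random.default_rng(seed)
    letters = rng.choice(list(_AA20), size=n_res)
    return QuerySequence(id=seq_id, residues="".join(letters))


def make_synthetic_msa(
    query: QuerySequence,
    depth: int = 64,
    mutation_rate: float = 0.15,
    seed: int = 0,
) -> AlignmentStack:
    """Gapless synthetic MSA: the query plus point-mutated homolog rows."""
    rng = np.random.default_rng(seed)
    rows = [query.residues]
    ids = [query.id]
    for k in range(depth - 1):
        chars = list(query.residues)
        hit = rng.random(len(chars)) < mutation_rate
        for i in np.flatnonzero(hit):
            chars[i] = rng.choice(list(_AA20))
        rows.append("".join(chars))
        ids.append(f"homolog_{k:04d}")
    return AlignmentStack(ids=ids, rows=rows, dialect="a3m")
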