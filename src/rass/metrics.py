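"""Superposition and structural-similarity metrics.

* Kabsch least-squares rigid superposition (SVD, reflection-corrected) over
  a selectable atom set.
* TM-score with the TM-align distance scale
  ``d0 = 1.24 (L_ref - 15)^(1/3) - 1.8`` (floored at 0.5) and an iterative
  fragment-seeded optimizer — the residue correspondence is given, so no
  sequence alignment is involved.
* Paired apo/holo characterization combining Cα, backbone and
  pocket-side-chain RMSDs with TM-scores under both normalizations.

All distances are in Å.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InputError, MetricError
from .structure_io import (
    BACKBONE_ATOMS,
    Correspondence,
    ReferencePair,
    ResKey,
    StructureModel,
)

ATOM_SETS = ("ca", "backbone", "pocket_sidechain_heavy")


@dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares rigid map of a mobile onto a fixed point set.

    ``apply`` maps mobile coordinates: ``x' = R (x - centroid_mobile) +
    centroid_fixed``.
    """

    rotation: np.ndarray        # 3x3 proper rotation
    translation: np.ndarray     # centroid_fixed - R @ centroid_mobile
    rmsd: float
    n_atoms: int
    degenerate: bool = False    # collinear/planar input; solution still valid

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(coords_fixed: np.ndarray, coords_mobile: np.ndarray) -> SuperpositionResult:
    """Optimal rigid superposition of ``coords_mobile`` onto ``coords_fixed``.

    Uses the SVD solution of the cross-covariance matrix with determinant
    correction so reflections are never returned.  Degenerate (rank < 3)
    point sets are still solved but flagged.

    Raises
    ------
    InputError
        Fewer than 3 points, unequal counts, or non-finite coordinates.
    """
    a = np.asarray(coords_fixed, dtype=float)
    b = np.asarray(coords_mobile, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise InputError(f"coordinate shapes differ or are not Nx3: {a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise InputError(f"need >= 3 points, got {a.shape[0]}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InputError("non-finite coordinates")

    ca_, cb_ = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca_, b - cb_
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    moved = b0 @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a0) ** 2, axis=1))))
    degenerate = np.linalg.matrix_rank(np.vstack([a0, b0]), tol=1e-9) < 3
    return SuperpositionResult(
        rotation=rot,
        translation=ca_ - rot @ cb_,
        rmsd=rmsd,
        n_atoms=a.shape[0],
        degenerate=bool(degenerate),
    )


# ---------------------------------------------------------------------------
# Atom pairing over a residue correspondence
# ---------------------------------------------------------------------------

def _coord_lookup(model: StructureModel) -> dict[tuple[int, str, str], np.ndarray]:
    prot = model.protein_atoms
    return {
        (int(r), str(i), str(n)): c
        for r, i, n, c in zip(prot.res_id, prot.ins_code, prot.atom_name, prot.coord)
    }


def _sidechain_names(model: StructureModel, key: ResKey) -> list[str]:
    res = model.residue_atoms(key)
    heavy = res[(res.element != "H")]
    return [n for n in heavy.atom_name if n not in BACKBONE_ATOMS]


def paired_coords(
    model_a: StructureModel,
    model_b: StructureModel,
    correspondence: Correspondence,
    atom_set: str = "backbone",
    pocket: frozenset[ResKey] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Matched coordinate arrays for the selected atom set.

    Atoms are matched by name within each corresponding residue pair; atoms
    missing on either side are dropped pairwise.  For
    ``pocket_sidechain_heavy`` the residues are restricted to the pocket
    (keys on the B side, where the pocket is defined on the holo structure).
    """
    if atom_set not in ATOM_SETS:
        raise InputError(f"unknown atom_set {atom_set!r}; choose from {ATOM_SETS}")
    lut_a, lut_b = _coord_lookup(model_a), _coord_lookup(model_b)
    xa, xb = [], []
    for ka, kb in zip(correspondence.keys_a, correspondence.keys_b):
        if atom_set == "ca":
            names = ["CA"]
        elif atom_set == "backbone":
            names = list(BACKBONE_ATOMS)
        else:
            if pocket is None:
                raise MetricError("pocket_sidechain_heavy requires a pocket residue set")
            if kb not in pocket:
                continue
            names = _sidechain_names(model_b, kb)
        for name in names:
            pa = lut_a.get((ka[0], ka[1], name))
            pb = lut_b.get((kb[0], kb[1], name))
            if pa is not None and pb is not None:
                xa.append(pa)
                xb.append(pb)
    if not xa:
        raise MetricError(f"no paired atoms for atom_set {atom_set!r}")
    return np.asarray(xa, dtype=float), np.asarray(xb, dtype=float)


def rmsd_between(
    model_a: StructureModel,
    model_b: StructureModel,
    correspondence: Correspondence,
    atom_set: str = "backbone",
    pocket: frozenset[ResKey] | None = None,
) -> float:
    """Least-squares RMSD on the selected atom set.

    The superposition is fitted on the same atoms the RMSD is reported on.
    """
    xa, xb = paired_coords(model_a, model_b, correspondence, atom_set, pocket)
    if xa.shape[0] < 3:
        raise MetricError(f"only {xa.shape[0]} paired atoms for atom_set {atom_set!r}")
    return kabsch_superpose(xa, xb).rmsd


# ---------------------------------------------------------------------------
# TM-score
# ---------------------------------------------------------------------------

def tm_d0(l_ref: int) -> float:
    """TM-align distance scale, floored at 0.5 Å."""
    if l_ref <= 15:
        return 0.5
    return max(0.5, 1.24 * (l_ref - 15) ** (1.0 / 3.0) - 1.8)


def _tm_from_superposition(
    xa: np.ndarray, xb: np.ndarray, sup: SuperpositionResult, d0: float, l_ref: int
) -> tuple[float, np.ndarray]:
    d = np.linalg.norm(xa - sup.apply(xb), axis=1)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_ref), d


def tm_score(
    model_a: StructureModel,
    model_b: StructureModel,
    correspondence: Correspondence,
    normalize_by: str | int = "b",
) -> float:
    """TM-score of the Cα traces under the given residue correspondence.

    ``TM = max over superpositions of (1/L_ref) Σ_i 1 / (1 + (d_i/d0)²)``
    with ``d0 = 1.24 (L_ref-15)^{1/3} - 1.8`` floored at 0.5.  The maximum is
    searched with fragment-seeded superpositions (full length, halves,
    sliding windows) followed by iterative reselection of close residues
    until the selected set is stable — the strategy TM-align uses once the
    equivalence is fixed.

    Parameters
    ----------
    normalize_by
        ``"a"`` or ``"b"`` (that model's full residue count) or an explicit
        integer length.  Default is the second model, conventionally the
        reference (holo) structure.
    """
    if len(correspondence) < 3:
        raise InputError("need >= 3 corresponding residues for TM-score")
    if normalize_by == "a":
        l_ref = model_a.n_residues()
    elif normalize_by == "b":
        l_ref = model_b.n_residues()
    else:
        l_ref = int(normalize_by)
    if l_ref < 3:
        raise InputError(f"reference length {l_ref} < 3")
    xa, xb = paired_coords(model_a, model_b, correspondence, atom_set="ca")
    n = xa.shape[0]
    d0 = tm_d0(l_ref)

    # seed windows: full length, halves, and sliding fragments
    win = max(5, n // 8)
    seeds: list[np.ndarray] = [np.arange(n)]
    if n >= 6:
        seeds.append(np.arange(n // 2))
        seeds.append(np.arange(n // 2, n))
    step = max(1, win // 2)
    for start in range(0, max(1, n - win + 1), step):
        seeds.append(np.arange(start, min(start + win, n)))

    best = 0.0
    for seed in seeds:
        if seed.size < 3:
            continue
        subset = seed
        seen: set[frozenset[int]] = set()
        for _ in range(30):
            seen.add(frozenset(int(i) for i in subset))
            sup = kabsch_superpose(xa[subset], xb[subset])
            score, d = _tm_from_superposition(xa, xb, sup, d0, l_ref)
            best = max(best, score)
            d_cut = d0
            new = np.flatnonzero(d < d_cut)
            while new.size < 3 and d_cut < 50.0:
                d_cut += 0.5
                new = np.flatnonzero(d < d_cut)
            if new.size < 3 or frozenset(int(i) for i in new) in seen:
                break
            subset = new
    return best


# ---------------------------------------------------------------------------
# Paired apo/holo characterization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairMetrics:
    """Similarity summary for an apo/holo structure pair."""

    rmsd_ca: float
    rmsd_backbone: float
    rmsd_pocket_sidechain: float | None
    tm_score: float            # normalized by the holo reference length
    tm_score_apo_norm: float   # normalized by the apo length
    n_matched: int

    def as_dict(self) -> dict:
        return {
            "rmsd_ca": self.rmsd_ca,
            "rmsd_backbone": self.rmsd_backbone,
            "rmsd_pocket_sidechain": self.rmsd_pocket_sidechain,
            "tm_score": self.tm_score,
            "tm_score_apo_norm": self.tm_score_apo_norm,
            "n_matched": self.n_matched,
        }


def characterize_pair(pair: ReferencePair) -> PairMetrics:
    """Compute the full metric panel for an apo/holo pair.

    Pocket side-chain RMSD is included only when the pair carries a pocket
    definition.  Deterministic: repeated calls give identical values.
    """
    corr = pair.correspondence
    rmsd_ca = rmsd_between(pair.apo, pair.holo, corr, atom_set="ca")
    rmsd_bb = rmsd_between(pair.apo, pair.holo, corr, atom_set="backbone")
    rmsd_pocket = None
    if pair.pocket:
        rmsd_pocket = rmsd_between(
            pair.apo, pair.holo, corr, atom_set="pocket_sidechain_heavy", pocket=pair.pocket
        )
    tm_holo = tm_score(pair.apo, pair.holo, corr, normalize_by="b")
    tm_apo = tm_score(pair.apo, pair.holo, corr, normalize_by="a")
    return PairMetrics(
        rmsd_ca=rmsd_ca,
        rmsd_backbone=rmsd_bb,
        rmsd_pocket_sidechain=rmsd_pocket,
        tm_score=tm_holo,
        tm_score_apo_norm=tm_apo,
        n_matched=len(corr),
    )
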