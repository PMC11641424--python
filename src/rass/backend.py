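"""Structure-predictor backend contract.

The pipeline never reimplements a neural predictor; it talks to one through
:class:`PredictorBackend`.  Two implementations are provided:

* :class:`MockPredictor` — a deterministic two-basin sampler used for
  desk-scale testing: each conformer is one of two reference basins (open /
  closed) plus isotropic Gaussian coordinate noise, with synthetic
  per-residue pLDDT that decays with displacement from the basin.
* :class:`ColabFoldBackend` — a thin subprocess adapter around a local
  ``colabfold_batch`` executable (network weights are never bundled).

Count contract: one prediction request yields exactly
``num_models × num_seeds × (num_recycles + 2)`` conformers — intermediate
structures from recycle 0 through ``num_recycles`` plus one final refined
structure per model per seed, each tagged with provenance.
"""

from __future__ import annotations

import copy
import glob
import os
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np
import biotite.structure as struc

from .exceptions import BackendError, InputError
from .msa import AlignmentStack, SubsamplePartition
from .structure_io import StructureModel, read_structure

DEFAULT_NUM_MODELS = 5
DEFAULT_NUM_RECYCLES = 12
DEFAULT_NUM_SEEDS = 1


@dataclass(frozen=True)
class PredictionRequest:
    """Inputs for one replica prediction."""

    sequence: str
    alignment: AlignmentStack | None = None
    partition: SubsamplePartition | None = None
    num_models: int = DEFAULT_NUM_MODELS
    num_recycles: int = DEFAULT_NUM_RECYCLES
    num_seeds: int = DEFAULT_NUM_SEEDS
    use_dropout: bool = True
    replica_id: int = 0

    def __post_init__(self):
        if self.num_models < 1:
            raise InputError("num_models must be >= 1")
        if self.num_recycles < 0:
            raise InputError("num_recycles must be >= 0")
        if self.num_seeds < 1:
            raise InputError("num_seeds must be >= 1")

    @property
    def expected_count(self) -> int:
        """Conformers per request: recycles 0..R plus a final refined one."""
        return self.num_models * self.num_seeds * (self.num_recycles + 2)


@dataclass(frozen=True)
class Provenance:
    model_id: int
    recycle: int            # recycle index; for the final structure, num_recycles
    is_final: bool
    replica_id: int
    seed: int
    basin: str | None = None  # mock ground truth ("A"/"B"); None for real backends


@dataclass
class PredictedConformer:
    """One predicted structure with per-residue confidence."""

    structure: StructureModel
    plddt: np.ndarray
    provenance: Provenance

    def __post_init__(self):
        n_res = self.structure.n_residues()
        if len(self.plddt) != n_res:
            raise InputError(
                f"pLDDT length {len(self.plddt)} != residue count {n_res}"
            )

    @property
    def mean_plddt(self) -> float:
        return float(np.mean(self.plddt))


class PredictorBackend(Protocol):
    def predict(self, request: PredictionRequest) -> list[PredictedConformer]: ...


def run_backend(request: PredictionRequest, backend: PredictorBackend) -> list[PredictedConformer]:
    """Run a backend and enforce the conformer count contract."""
    conformers = backend.predict(request)
    if len(conformers) != request.expected_count:
        raise BackendError(
            f"backend returned {len(conformers)} conformers, expected "
            f"{request.expected_count} (= num_models x num_seeds x (num_recycles + 2))"
        )
    return conformers


# ---------------------------------------------------------------------------
# Mock two-basin predictor
# ---------------------------------------------------------------------------

class MockPredictor:
    """Deterministic stand-in predictor sampling a two-basin mixture.

    Each conformer is drawn as basin A (probability ``weight_a``) or basin B,
    plus isotropic Gaussian coordinate noise of scale ``noise_scale`` (Å).
    The synthetic confidence of residue ``i`` is
    ``pLDDT_i = clip(100 exp(-d_i / sigma), 30, 100)`` where ``d_i`` is the
    Cα displacement of that residue from its basin mean — confidence is
    therefore anti-correlated with displacement, mirroring the behaviour of
    real predictors.  The final "refined" structure is an independent draw,
    not a copy of the last recycle.

    Parameters
    ----------
    basin_a, basin_b
        Reference conformations sharing residue numbering and length.
    plddt_sigma
        Confidence decay constant (Å); the default 2.0 keeps rigid-core
        residues above ~85 while strongly displaced residues fall below 70.
    """

    def __init__(
        self,
        basin_a: StructureModel,
        basin_b: StructureModel,
        weight_a: float = 0.5,
        noise_scale: float = 0.3,
        plddt_sigma: float = 2.0,
        seed: int = 0,
    ):
        if basin_a.n_residues() != basin_b.n_residues():
            raise InputError(
                f"basin residue counts differ: {basin_a.n_residues()} vs {basin_b.n_residues()}"
            )
        if not (0.0 <= weight_a <= 1.0):
            raise InputError("weight_a must lie in [0, 1]")
        self.basin_a = basin_a
        self.basin_b = basin_b
        self.weight_a = weight_a
        self.noise_scale = noise_scale
        self.plddt_sigma = plddt_sigma
        self.seed = seed

    def _draw(
        self, rng: np.random.Generator, provenance: Provenance
    ) -> PredictedConformer:
        pick_a = rng.random() < self.weight_a
        basin = self.basin_a if pick_a else self.basin_b
        prot = basin.protein_atoms  # the ligand of a holo basin is not part of a prediction
        noise = rng.normal(0.0, self.noise_scale, size=prot.coord.shape)
        atoms = prot.copy()
        atoms.coord = (prot.coord + noise).astype(np.float32)

        ca_mask = atoms.atom_name == "CA"
        disp = np.linalg.norm(noise[ca_mask], axis=1)
        plddt = np.clip(100.0 * np.exp(-disp / self.plddt_sigma), 30.0, 100.0)
# broadcast per-residue pLDDT onto every atom of the residue
        b = np.zeros(len(atoms))
        res_starts = struc.get_residue_starts(atoms, add_exclusive_stop=True)
        for ri, (lo, hi) in enumerate(zip(res_starts[:-1], res_starts[1:])):
            b[lo:hi] = plddt[ri]
        atoms.set_annotation("b_factor", b)

        prov = Provenance(
            model_id=provenance.model_id,
            recycle=provenance.recycle,
            is_final=provenance.is_final,
            replica_id=provenance.replica_id,
            seed=provenance.seed,
            basin="A" if pick_a else "B",
        )
        structure = StructureModel(
            id=f"mock_r{prov.replica_id}_m{prov.model_id}_s{prov.seed}_"
            f"{'final' if prov.is_final else f'rec{prov.recycle}'}",
            atoms=atoms,
            source="predicted",
        )
        return PredictedConformer(structure=structure, plddt=plddt, provenance=prov)

    def predict(self, request: PredictionRequest) -> list[PredictedConformer]:
        n_res = self.basin_a.n_residues()
        if request.sequence and len(request.sequence) != n_res:
            raise InputError(
                f"query length {len(request.sequence)} != basin residue count {n_res}"
            )
        rng = np.random.default_rng([self.seed, request.replica_id])
        out: list[PredictedConformer] = []
        for m in range(request.num_models):
            for s in range(request.num_seeds):
                for r in range(request.num_recycles + 1):
                    out.append(
                        self._draw(
                            rng,
                            Provenance(m, r, False, request.replica_id, s),
                        )
                    )
                out.append(
                    self._draw(
                        rng,
                        Provenance(m, request.num_recycles, True, request.replica_id, s),
                    )
                )
        return out


# ---------------------------------------------------------------------------
# External ColabFold adapter
# ---------------------------------------------------------------------------

class ColabFoldBackend:
    """Subprocess adapter for a local ``colabfold_batch`` installation.

    Input layout: the request's subsampled alignment is written as an A3M
    with the replica sequence as query; output PDBs (with pLDDT in the
    B-factor column) are collected from the run directory, intermediate
    recycles included via ``--save-recycles``.

    Raises :class:`BackendError` carrying stdout/stderr when the executable
    is missing or exits non-zero.
    """

    def __init__(self, executable: str = "colabfold_batch", work_dir: str | None = None,
                 extra_args: tuple[str, ...] = ()):
        self.executable = executable
        self.work_dir = work_dir
        self.extra_args = extra_args

    def _write_input(self, request: PredictionRequest, run_dir: Path) -> Path:
        a3m = run_dir / "query.a3m"
        lines = [f">query_{request.replica_id}", request.sequence]
        if request.alignment is not None:
            stack = request.alignment
            indices = range(1, stack.depth)
            if request.partition is not None:
                indices = [
                    i
                    for i in (*request.partition.attention, *request.partition.extra)
                    if i != 0
                ]
            for i in indices:
                lines += [f">{stack.ids[i]}", stack.rows[i]]
        a3m.write_text("\n".join(lines) + "\n")
        return a3m

    def predict(self, request: PredictionRequest) -> list[PredictedConformer]:
        from .structure_io import extract_plddt  # deferred to keep import cheap

        run_dir = Path(self.work_dir or tempfile.mkdtemp(prefix="rass_colabfold_"))
        run_dir.mkdir(parents=True, exist_ok=True)
        a3m = self._write_input(request, run_dir)
        max_msa = ""
        if request.partition is not None:
            max_msa = f"{request.partition.max_seqs}:{request.partition.extra_seqs}"
        cmd = [
            self.executable,
            str(a3m),
            str(run_dir / "out"),
            "--num-models", str(request.num_models),
            "--num-recycle", str(request.num_recycles),
            "--num-seeds", str(request.num_seeds),
            "--save-recycles",
        ]
        if max_msa:
            cmd += ["--max-msa", max_msa]
        if request.use_dropout:
            cmd.append("--use-dropout")
        cmd += list(self.extra_args)
        try:
            proc = subprocess.run(cmd, capture_output=True, text=True)
        except FileNotFoundError as exc:
            raise BackendError(
                f"predictor executable {self.executable!r} not found", diagnostics=str(exc)
            ) from exc
        if proc.returncode != 0:
            raise BackendError(
                f"{self.executable} exited with status {proc.returncode}",
                diagnostics=(proc.stdout or "") + (proc.stderr or ""),
            )
        conformers: list[PredictedConformer] = []
        for path in sorted(glob.glob(str(run_dir / "out" / "*.pdb"))):
            model = read_structure(path, format="pdb", source="predicted")
            name = os.path.basename(path)
            is_final = ".r" not in name
            recycle = request.num_recycles
            if not is_final:
                try:
                    recycle = int(name.rsplit(".r", 1)[1].split(".")[0])
                except (IndexError, ValueError):
                    recycle = request.num_recycles
            model_id = 0
            for tok in name.split("_"):
                if tok.startswith("model") and tok[5:].isdigit():
                    model_id = int(tok[5:]) - 1
            conformers.append(
                PredictedConformer(
                    structure=model,
                    plddt=extract_plddt(model),
                    provenance=Provenance(
                        model_id=model_id,
                        recycle=recycle,
                        is_final=is_final,
                        replica_id=request.replica_id,
                        seed=0,
                    ),
                )
            )
        if not conformers:
            raise BackendError(
                f"{self.executable} produced no PDB output in {run_dir}",
                diagnostics=(proc.stdout or "") + (proc.stderr or ""),
            )
        return conformers
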