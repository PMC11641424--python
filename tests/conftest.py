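"""Shared fixtures: synthetic hinge systems and hand-written PDB text."""

from __future__ import annotations

import numpy as np
import pytest

from rass.backend import MockPredictor, PredictionRequest, run_backend
from rass.ensemble_analysis import ConformerEnsemble
from rass.structure_io import ReferencePair
from rass.synthetic import make_two_basin_pair


def pdb_line(
    serial: int,
    name: str,
    xyz: tuple[float, float, float],
    res_id: int = 1,
    res_name: str = "ALA",
    chain: str = "A",
    alt: str = " ",
    icode: str = " ",
    occ: float = 1.0,
    b: float = 0.0,
    element: str = "C",
    record: str = "ATOM",
) -> str:
    """One fixed-width PDB coordinate line."""
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:5d} {name_field:4s}{alt:1s}{res_name:>3s} {chain:1s}"
        f"{res_id:4d}{icode:1s}   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{occ:6.2f}{b:6.2f}          {element:>2s}"
    )


def write_pdb_text(path, lines: list[str]) -> None:
    path.write_text("\n".join(lines + ["END"]) + "\n")


@pytest.fixture(scope="session")
def hinge_pair() -> tuple:
    """60-residue open/closed hinge pair at 3.5 Å backbone RMSD, with ligand."""
    apo, holo, angle = make_two_basin_pair(n_res=60, target_rmsd=3.5, with_ligand=True)
    return apo, holo, angle


@pytest.fixture(scope="session")
def hinge_reference_pair(hinge_pair) -> ReferencePair:
    apo, holo, _ = hinge_pair
    return ReferencePair.from_models(apo, holo, ligand="LIG")


@pytest.fixture(scope="session")
def two_basin_ensemble(hinge_pair) -> ConformerEnsemble:
    """60 mock conformers, 50/50 basin mixture, 0.3 Å coordinate noise."""
    apo, holo, _ = hinge_pair
    mock = MockPredictor(apo, holo, weight_a=0.5, noise_scale=0.3, seed=123)
    request = PredictionRequest(sequence="", num_models=5, num_recycles=10, num_seeds=1)
    conformers = run_backend(request, mock)  # 5 x (10 + 2) = 60
    return ConformerEnsemble(conformers)


def basin_truth_labels(ensemble: ConformerEnsemble) -> np.ndarray:
    """Ground-truth generating-basin state labels of a mock ensemble."""
    return np.array(
        ["apo" if c.provenance.basin == "A" else "holo" for c in ensemble.conformers]
    )
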