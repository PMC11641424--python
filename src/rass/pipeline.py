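"""Pipeline orchestration: mask -> subsample -> predict -> analyze -> report.

Each stage reads its inputs from, and writes its artifacts into, a fixed
directory layout under the configured output directory::

    masked/        replicas.fasta, substitutions.json
    subsampled/    partitions.json, replica_###.a3m
    predictions/   conf_*.pdb (pLDDT in the B-factor column), index.json
    analysis/      ensemble_report.tsv, summary.json, report.json, report.txt
    logs/          config.json, versions.json

Stages are idempotent: re-running a completed stage is a no-op unless
``force=True``.  A stage whose upstream artifact is missing fails with a
:class:`~rass.exceptions.PipelineError` naming that artifact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .backend import (
    ColabFoldBackend,
    MockPredictor,
    PredictedConformer,
    PredictionRequest,
    Provenance,
    run_backend,
)
from .ensemble_analysis import (
    ClusterSolution,
    ConformerEnsemble,
    classify_states,
    cluster_ensemble,
    cluster_state_contingency,
    confident_fraction,
    distribution_summary,
    plddt_rmsd_scatter,
    rmsd_profile,
)
from .exceptions import InputError, PipelineError
from .masking import (
    parse_region,
    randomized_alanine_scan,
    read_query_fasta,
    write_masked_set,
)
from .metrics import characterize_pair
from .msa import AlignmentStack, SubsamplePartition, read_alignment, subsample, write_alignment
from .structure_io import ReferencePair, extract_plddt, read_structure, write_structure

ALL_STAGES = ("mask", "subsample", "predict", "analyze", "report")


@dataclass
class MaskingParams:
    n_replicas: int = 45
    p_low: float = 0.05
    p_high: float = 0.15
    region: str | None = None


@dataclass
class SubsampleParams:
    max_seqs: int = 16
    extra_seqs: int = 32


@dataclass
class BackendParams:
    kind: str = "mock"                 # mock | colabfold
    num_models: int = 5
    num_recycles: int = 12
    num_seeds: int = 1
    use_dropout: bool = True
    # mock-only knobs
    weight_a: float = 0.5
    noise_scale: float = 0.3
    plddt_sigma: float = 2.0
    # external-only knobs
    executable: str = "colabfold_batch"


@dataclass
class ReferenceParams:
    apo_path: str = ""
    holo_path: str = ""
    chain: str | None = None
    ligand: str | None = None          # heteroatom residue name, or "auto"
    offset_apo: int = 0                # prediction numbering -> apo numbering
    offset_holo: int = 0
    pocket_cutoff: float = 4.5
    min_matched: int = 30


@dataclass
class AnalysisParams:
    atom_set: str = "backbone"
    cluster_atom_set: str = "ca"
    plddt_threshold: float = 85.0
    min_fraction: float = 0.70
    k_min: int = 2
    k_max: int = 10
    margin: float = 0.5
    compute_tm: bool = True


@dataclass
class RunConfig:
    """Full pipeline configuration (defaults match the protocol settings:
    45 scan replicas, 16:32 subsampling, 5 models, 12 recycles, 1 seed)."""

    query_fasta: str
    msa_path: str
    out_dir: str
    seed: int = 7
    msa_dialect: str = "a3m"
    #: "substitute_query": one shared MSA, replica substituted as query row;
    #: "per_replica": msa_path is a directory with replica_###.a3m files.
    replica_msa_mode: str = "substitute_query"
    masking: MaskingParams = field(default_factory=MaskingParams)
    subsampling: SubsampleParams = field(default_factory=SubsampleParams)
    backend: BackendParams = field(default_factory=BackendParams)
    references: ReferenceParams = field(default_factory=ReferenceParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sub = {
            "masking": MaskingParams,
            "subsampling": SubsampleParams,
            "backend": BackendParams,
            "references": ReferenceParams,
            "analysis": AnalysisParams,
        }
        for key, typ in sub.items():
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        return asdict(self)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return {str(i): _jsonable(row.to_dict()) for i, row in obj.iterrows()}
    return obj


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing artifact {path}; run the {producer!r} stage first"
        )
    return path


class Pipeline:
    """Stage runner bound to one :class:`RunConfig`."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)

    # -- paths ------------------------------------------------------------
    @property
    def masked_dir(self) -> Path:
        return self.out / "masked"

    @property
    def subsampled_dir(self) -> Path:
        return self.out / "subsampled"

    @property
    def predictions_dir(self) -> Path:
        return self.out / "predictions"

    @property
    def analysis_dir(self) -> Path:
        return self.out / "analysis"

    @property
    def logs_dir(self) -> Path:
        return self.out / "logs"

    # -- logging -----------------------------------------------------------
    def _write_logs(self) -> None:
        self.logs_dir.mkdir(parents=True, exist_ok=True)
        _write_json(self.logs_dir / "config.json", self.config.to_dict())
        versions = {"rass": __version__}
        for mod in ("numpy", "scipy", "pandas", "sklearn", "biotite", "Bio"):
            try:
                versions[mod] = __import__(mod).__version__
            except Exception:
                versions[mod] = "unavailable"
        _write_json(self.logs_dir / "versions.json", versions)

    # -- stages ------------------------------------------------------------
    def run_mask(self, force: bool = False) -> Path:
        fasta = self.masked_dir / "replicas.fasta"
        if fasta.exists() and not force:
            return fasta
        cfg = self.config
        region = None
        query = read_query_fasta(cfg.query_fasta)
        if cfg.masking.region:
            region = parse_region(cfg.masking.region, length=len(query))
            query = read_query_fasta(cfg.query_fasta, region=region)
        masked = randomized_alanine_scan(
            query,
            n_replicas=cfg.masking.n_replicas,
            p_low=cfg.masking.p_low,
            p_high=cfg.masking.p_high,
            seed=cfg.seed,
        )
        write_masked_set(masked, self.masked_dir)
        return fasta

    def _load_replicas(self) -> list[dict]:
        sidecar = _require(self.masked_dir / "substitutions.json", "mask")
        meta = json.loads(sidecar.read_text())
        from Bio import SeqIO

        fasta = _require(self.masked_dir / "replicas.fasta", "mask")
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
        out = []
        for rep in meta["replicas"]:
            out.append({**rep, "sequence": seqs[rep["id"]]})
        return out

    def _replica_msa(self, replica: dict) -> AlignmentStack:
        cfg = self.config
        if cfg.replica_msa_mode == "per_replica":
            path = Path(cfg.msa_path) / f"replica_{replica['index']:03d}.a3m"
            if not path.exists():
                raise PipelineError(f"per-replica MSA {path} not found")
            return read_alignment(path, dialect=cfg.msa_dialect)
        stack = read_alignment(cfg.msa_path, dialect=cfg.msa_dialect)
        return stack.with_query(replica["sequence"], new_id=replica["id"])

    def run_subsample(self, force: bool = False) -> Path:
        out_json = self.subsampled_dir / "partitions.json"
        if out_json.exists() and not force:
            return out_json
        cfg = self.config
        replicas = self._load_replicas()
        self.subsampled_dir.mkdir(parents=True, exist_ok=True)
        records = []
        for rep in replicas:
            stack = self._replica_msa(rep)
            part = subsample(
                stack,
                max_seqs=cfg.subsampling.max_seqs,
                extra_seqs=cfg.subsampling.extra_seqs,
                seed=cfg.seed + rep["index"],
            )
            rows = [0, *part.attention[1:], *part.extra]
            shallow = AlignmentStack(
                ids=[stack.ids[i] for i in rows],
                rows=[stack.rows[i] for i in rows],
                dialect=stack.dialect,
            )
            write_alignment(shallow, self.subsampled_dir / f"replica_{rep['index']:03d}.a3m")
            records.append(
                {
                    "index": rep["index"],
                    "attention": list(part.attention),
                    "extra": list(part.extra),
                    "max_seqs": part.max_seqs,
                    "extra_seqs": part.extra_seqs,
                    "seed": part.seed,
                }
            )
        _write_json(out_json, {"partitions": records})
        return out_json

    def _make_backend(self):
        cfg = self.config
        if cfg.backend.kind == "mock":
            refs = cfg.references
            apo = read_structure(refs.apo_path, chain=refs.chain)
            holo = read_structure(refs.holo_path, chain=refs.chain)
            return MockPredictor(
                basin_a=apo,
                basin_b=holo,
                weight_a=cfg.backend.weight_a,
                noise_scale=cfg.backend.noise_scale,
                plddt_sigma=cfg.backend.plddt_sigma,
                seed=cfg.seed,
            )
        if cfg.backend.kind == "colabfold":
            return ColabFoldBackend(executable=cfg.backend.executable)
        raise InputError(f"unknown backend kind {cfg.backend.kind!r}")

    def run_predict(self, force: bool = False) -> Path:
        index_path = self.predictions_dir / "index.json"
        if index_path.exists() and not force:
            return index_path
        cfg = self.config
        replicas = self._load_replicas()
        partitions = json.loads(
            _require(self.subsampled_dir / "partitions.json", "subsample").read_text()
        )["partitions"]
        parts_by_index = {p["index"]: p for p in partitions}
        backend = self._make_backend()
        self.predictions_dir.mkdir(parents=True, exist_ok=True)
        index = []
        for rep in replicas:
            p = parts_by_index[rep["index"]]
            stack = read_alignment(
                self.subsampled_dir / f"replica_{rep['index']:03d}.a3m",
                dialect=cfg.msa_dialect,
            )
            part = SubsamplePartition(
                attention=tuple(range(min(len(p["attention"]), stack.depth))),
                extra=tuple(
                    range(len(p["attention"]), len(p["attention"]) + len(p["extra"]))
                ),
                max_seqs=p["max_seqs"],
                extra_seqs=p["extra_seqs"],
                seed=p["seed"],
            )
            request = PredictionRequest(
                sequence=rep["sequence"],
                alignment=stack,
                partition=part,
                num_models=cfg.backend.num_models,
                num_recycles=cfg.backend.num_recycles,
                num_seeds=cfg.backend.num_seeds,
                use_dropout=cfg.backend.use_dropout,
                replica_id=rep["index"],
            )
            for conf in run_backend(request, backend):
                prov = conf.provenance
                tag = "final" if prov.is_final else f"rec{prov.recycle:02d}"
                name = (
                    f"conf_{prov.replica_id:03d}_m{prov.model_id}_s{prov.seed}_{tag}.pdb"
                )
                write_structure(conf.structure, self.predictions_dir / name)
                index.append(
                    {
                        "file": name,
                        "replica_id": prov.replica_id,
                        "model_id": prov.model_id,
                        "seed": prov.seed,
                        "recycle": prov.recycle,
                        "is_final": prov.is_final,
                        "basin": prov.basin,
                    }
                )
        _write_json(index_path, {"conformers": index})
        return index_path

    def load_ensemble(self) -> ConformerEnsemble:
        index_path = _require(self.predictions_dir / "index.json", "predict")
        index = json.loads(index_path.read_text())["conformers"]
        conformers = []
        for entry in index:
            model = read_structure(
                self.predictions_dir / entry["file"], format="pdb", source="predicted"
            )
            conformers.append(
                PredictedConformer(
                    structure=model,
                    plddt=extract_plddt(model),
                    provenance=Provenance(
                        model_id=entry["model_id"],
                        recycle=entry["recycle"],
                        is_final=entry["is_final"],
                        replica_id=entry["replica_id"],
                        seed=entry["seed"],
                        basin=entry.get("basin"),
                    ),
                )
            )
        return ConformerEnsemble(conformers)

    def load_reference_pair(self) -> ReferencePair:
        refs = self.config.references
        if not refs.apo_path or not refs.holo_path:
            raise PipelineError("references.apo_path and references.holo_path must be set")
        apo = read_structure(refs.apo_path, chain=refs.chain)
        holo = read_structure(refs.holo_path, chain=refs.chain)
        offset = refs.offset_holo - refs.offset_apo
        return ReferencePair.from_models(
            apo,
            holo,
            offset_holo=offset,
            ligand=refs.ligand,
            pocket_cutoff=refs.pocket_cutoff,
            min_matched=refs.min_matched,
        )

    def run_analyze(self, force: bool = False) -> Path:
        summary_path = self.analysis_dir / "summary.json"
        if summary_path.exists() and not force:
            return summary_path
        cfg = self.config
        ensemble = self.load_ensemble()
        pair = self.load_reference_pair()
        ana = cfg.analysis

        profile, prof_summary = rmsd_profile(
            ensemble,
            pair,
            atom_set=ana.atom_set,
            compute_tm=ana.compute_tm,
            offset_apo=cfg.references.offset_apo,
            offset_holo=cfg.references.offset_holo,
            min_matched=cfg.references.min_matched,
        )
        profile = classify_states(profile, margin=ana.margin)
        fractions = confident_fraction(ensemble, ana.plddt_threshold)
        profile["confident_fraction"] = fractions
        profile["retained_by_rerank"] = fractions > ana.min_fraction

        clustering_note = None
        solution: ClusterSolution | None = None
        k_range = range(ana.k_min, ana.k_max + 1)
        if len(ensemble) >= max(k_range) + 1:
            solution = cluster_ensemble(ensemble, atom_set=ana.cluster_atom_set, k_range=k_range)
            profile["cluster"] = solution.labels
        else:
            clustering_note = (
                f"skipped: ensemble size {len(ensemble)} < max(k_range)+1 = {max(k_range) + 1}"
            )

        _, correlations = plddt_rmsd_scatter(profile)
        pair_metrics = characterize_pair(pair)

        summary = {
            "parameters": {
                "atom_set": ana.atom_set,
                "cluster_atom_set": ana.cluster_atom_set,
                "plddt_threshold": ana.plddt_threshold,
                "min_fraction": ana.min_fraction,
                "state_margin_angstrom": ana.margin,
                "pocket_cutoff_angstrom": cfg.references.pocket_cutoff,
            },
            "reference_pair": pair_metrics.as_dict(),
            "profile": prof_summary,
            "state_counts": profile["state"].value_counts().to_dict(),
            "n_retained_by_rerank": int(profile["retained_by_rerank"].sum()),
            "plddt_rmsd_spearman": correlations,
            "distributions": {
                "rmsd_to_apo": distribution_summary(profile["rmsd_to_apo"].to_numpy(), "rmsd"),
                "rmsd_to_holo": distribution_summary(profile["rmsd_to_holo"].to_numpy(), "rmsd"),
                "plddt": distribution_summary(
                    ensemble.plddt_matrix().ravel(), "plddt"
                ),
            },
        }
        if ana.compute_tm:
            summary["distributions"]["tm_to_holo"] = distribution_summary(
                profile["tm_to_holo"].to_numpy(), "tm"
            )
        if solution is not None:
            summary["clustering"] = {
                "k": solution.k,
                "silhouette_by_k": {
                    str(k): (None if not np.isfinite(s) else s)
                    for k, s in solution.silhouette_by_k.items()
                },
                "linkage": solution.linkage_method,
                "cluster_state_contingency": cluster_state_contingency(
                    profile, solution
                ).to_dict(),
            }
        else:
            summary["clustering"] = {"note": clustering_note}

        self.analysis_dir.mkdir(parents=True, exist_ok=True)
        tsv = self.analysis_dir / "ensemble_report.tsv"
        with tsv.open("w") as fh:
            fh.write("# per-conformer ensemble report\n")
            fh.write("# units: RMSD in Angstrom; TM-score dimensionless in (0,1];"
                     " pLDDT on 0-100; conformer indices 0-based\n")
            profile.to_csv(fh, sep="\t", index=False, float_format="%.6f")
        _write_json(summary_path, summary)
        return summary_path

    def run_report(self, force: bool = False) -> Path:
        report_path = self.analysis_dir / "report.json"
        if report_path.exists() and not force:
            return report_path
        summary = json.loads(
            _require(self.analysis_dir / "summary.json", "analyze").read_text()
        )
        payload = {"config": self.config.to_dict(), "summary": summary}
        _write_json(report_path, payload)
        lines = [
            "ensemble characterization report",
            f"  conformers: {summary['profile']['n_conformers']}",
            f"  reference pair backbone RMSD: {summary['reference_pair']['rmsd_backbone']:.2f} A",
            f"  reference pair TM-score (holo norm): {summary['reference_pair']['tm_score']:.3f}",
            f"  mean RMSD to apo:  {summary['profile']['rmsd_to_apo']['mean']:.2f} A",
            f"  mean RMSD to holo: {summary['profile']['rmsd_to_holo']['mean']:.2f} A",
            f"  state counts: {summary['state_counts']}",
            f"  retained by pLDDT rerank: {summary['n_retained_by_rerank']}",
            f"  clustering: {summary['clustering'].get('k', summary['clustering'].get('note'))}",
        ]
        (self.analysis_dir / "report.txt").write_text("\n".join(lines) + "\n")
        return report_path

    def run(self, stages: tuple[str, ...] = ALL_STAGES, force: bool = False) -> Path:
        unknown = set(stages) - set(ALL_STAGES)
        if unknown:
            raise InputError(f"unknown stages: {sorted(unknown)}")
        self.out.mkdir(parents=True, exist_ok=True)
        self._write_logs()
        runners = {
            "mask": self.run_mask,
            "subsample": self.run_subsample,
            "predict": self.run_predict,
            "analyze": self.run_analyze,
            "report": self.run_report,
        }
        for stage in ALL_STAGES:
            if stage in stages:
                runners[stage](force=force)
        return self.out


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = ALL_STAGES, force: bool = False) -> Path:
    """Run the configured stages; returns the artifact directory."""
    return Pipeline(config).run(stages=stages, force=force)
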