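"""Randomized alanine sequence scanning (RASS).

The scan perturbs the coevolutionary signal seen by an MSA-based structure
predictor: each replica of the query sequence has a random subset of its
positions replaced by alanine, where position ``i`` of replica ``r`` is
substituted with probability ``p_i ~ Uniform(p_low, p_high)`` drawn
independently per position and per replica.  Marginally every eligible
position is therefore a Bernoulli draw with success probability
``(p_low + p_high) / 2`` (0.10 at the defaults 0.05/0.15).

Replicas are reproducible: replica ``r`` uses its own PRNG stream seeded
with ``seed + r``, so partial re-runs regenerate identical sequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import InputError, ParameterError

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")
#: Letters accepted in a query sequence.  'X' marks an unknown residue and is
#: never substituted (we do not fabricate identity for unknowns).
ALLOWED_LETTERS = CANONICAL_AA | {"X"}

#: Default number of scan replicas; the protocol runs the scan ~40-50 times.
DEFAULT_N_REPLICAS = 45
DEFAULT_P_LOW = 0.05
DEFAULT_P_HIGH = 0.15


@dataclass(frozen=True)
class QuerySequence:
    """A query protein sequence with an optional scan-region restriction.

    Parameters
    ----------
    id
        Record identifier (FASTA header word).
    residues
        One-letter amino-acid string, canonical alphabet plus ``X``.
    region
        0-based positions eligible for substitution; ``None`` means all.
    """

    id: str
    residues: str
    region: frozenset[int] | None = None

    def __post_init__(self):
        if len(self.residues) == 0:
            raise InputError("query sequence is empty")
        bad = set(self.residues.upper()) - ALLOWED_LETTERS
        if bad:
            raise InputError(f"non-amino-acid letters in sequence: {sorted(bad)}")
        if self.region is not None:
            out = [i for i in self.region if not (0 <= i < len(self.residues))]
            if out:
                raise InputError(f"region positions outside [0, L): {sorted(out)[:5]}")

    def __len__(self) -> int:
        return len(self.residues)

    def eligible_positions(self) -> np.ndarray:
        """Positions the scan may touch: inside the region and not 'X'."""
        if self.region is None:
            idx = np.arange(len(self.residues))
        else:
            idx = np.array(sorted(self.region), dtype=int)
        keep = np.array([self.residues[i].upper() != "X" for i in idx], dtype=bool)
        return idx[keep]


@dataclass(frozen=True)
class MaskedReplica:
    """One alanine-scanned copy of the query."""

    sequence: str
    substituted: tuple[int, ...]          # 0-based positions replaced by 'A'
    position_probabilities: tuple[float, ...]  # p_i draw per eligible position
    seed: int


@dataclass
class MaskedSequenceSet:
    """The full set of scan replicas plus the parameters that produced them."""

    source: QuerySequence
    replicas: list[MaskedReplica]
    p_low: float = DEFAULT_P_LOW
    p_high: float = DEFAULT_P_HIGH

    def __len__(self) -> int:
        return len(self.replicas)

    def substitution_fractions(self) -> np.ndarray:
        """Fraction of eligible positions substituted, per replica."""
        n_elig = len(self.source.eligible_positions())
        return np.array([len(r.substituted) / n_elig for r in self.replicas])


def randomized_alanine_scan(
    query: QuerySequence,
    n_replicas: int = DEFAULT_N_REPLICAS,
    p_low: float = DEFAULT_P_LOW,
    p_high: float = DEFAULT_P_HIGH,
    seed: int = 0,
) -> MaskedSequenceSet:
    """Run the randomized alanine scan.

    For each replica and each eligible position ``i`` an independent
    probability ``p_i ~ Uniform(p_low, p_high)`` is drawn, then the position
    is replaced by ``'A'`` with probability ``p_i``.  Alanine positions in
    the source remain eligible (an A->A substitution is recorded but is a
    string no-op), keeping the process uniform over positions.

    Raises
    ------
    ParameterError
        If ``p_low > p_high``, probabilities are outside [0, 1], or
        ``n_replicas < 1``.
    """
    if not (0.0 <= p_low <= 1.0 and 0.0 <= p_high <= 1.0):
        raise ParameterError("p_low and p_high must lie in [0, 1]")
    if p_low > p_high:
        raise ParameterError(f"p_low ({p_low}) > p_high ({p_high})")
    if n_replicas < 1:
        raise ParameterError("n_replicas must be >= 1")

    eligible = query.eligible_positions()
    replicas: list[MaskedReplica] = []
    for r in range(n_replicas):
        stream_seed = seed + r
        rng = np.random.default_rng(stream_seed)
        p = rng.uniform(p_low, p_high, size=eligible.size)
        hit = rng.random(eligible.size) < p
        subs = tuple(int(i) for i in eligible[hit])
        chars = list(query.residues)
        for i in subs:
            chars[i] = "A"
        replicas.append(
            MaskedReplica(
                sequence="".join(chars),
                substituted=subs,
                position_probabilities=tuple(float(x) for x in p),
                seed=stream_seed,
            )
        )
    return MaskedSequenceSet(source=query, replicas=replicas, p_low=p_low, p_high=p_high)


# ---------------------------------------------------------------------------
# FASTA / JSON plumbing
# ---------------------------------------------------------------------------

def read_query_fasta(path: str | Path, region: Iterable[int] | None = None) -> QuerySequence:
    """Read a single-record FASTA into a :class:`QuerySequence`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise InputError(f"no FASTA records in {path}")
    if len(records) > 1:
        raise InputError(f"expected a single record in {path}, found {len(records)}")
    rec = records[0]
    return QuerySequence(
        id=rec.id,
        residues=str(rec.seq).upper(),
        region=frozenset(region) if region is not None else None,
    )


def replica_record_id(query_id: str, replica_index: int) -> str:
    return f"{query_id}|rass_{replica_index:03d}"


def write_masked_set(masked: MaskedSequenceSet, out_dir: str | Path) -> tuple[Path, Path]:
    """Write replicas as multi-record FASTA plus a JSON sidecar.

    The sidecar records, per replica, the seed, the substituted positions
    and the scan parameters, so any replica can be regenerated or audited.
    Returns ``(fasta_path, json_path)``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta_path = out_dir / "replicas.fasta"
    json_path = out_dir / "substitutions.json"

    records = [
        SeqRecord(Seq(rep.sequence), id=replica_record_id(masked.source.id, i), description="")
        for i, rep in enumerate(masked.replicas)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")

    sidecar = {
        "query_id": masked.source.id,
        "query_sequence": masked.source.residues,
        "region": sorted(masked.source.region) if masked.source.region is not None else None,
        "p_low": masked.p_low,
        "p_high": masked.p_high,
        "replicas": [
            {
                "index": i,
                "id": replica_record_id(masked.source.id, i),
                "seed": rep.seed,
                "substituted_positions": list(rep.substituted),
                "n_substituted": len(rep.substituted),
            }
            for i, rep in enumerate(masked.replicas)
        ],
    }
    json_path.write_text(json.dumps(sidecar, indent=2))
    return fasta_path, json_path


def parse_region(spec: str, length: int | None = None) -> frozenset[int]:
    """Parse a region string like ``"10-120"`` or ``"3,7,10-12"`` (0-based, inclusive)."""
    positions: set[int] = set()
    for token in spec.split(","):
        token = token.strip()
        if not token:
            continue
        if "-" in token:
            lo, hi = token.split("-", 1)
            positions.update(range(int(lo), int(hi) + 1))
        else:
            positions.add(int(token))
    if length is not None:
        bad = [p for p in positions if not (0 <= p < length)]
        if bad:
            raise InputError(f"region positions outside sequence: {sorted(bad)[:5]}")
    return frozenset(positions)
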