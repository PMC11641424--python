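"""MSA reading/writing and shallow subsampling.

Two dialects are supported:

* ``a3m`` — lowercase letters are insertions relative to the query and carry
  no alignment column; ``-`` is a deletion.  Removing lowercase letters
  ("uppercase projection") must leave all rows the same length.
* ``aligned-fasta`` — plain FASTA where every row has equal length already.

Subsampling implements the shallow-MSA perturbation: a ``max_seqs``-row
attention set (always containing the query) and an ``extra_seqs``-row extra
set, drawn uniformly without replacement from the remaining rows.  Very
shallow settings such as 16:32 maximise conformational diversity of the
downstream predictor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import FormatError, ParameterError

#: Preset that produced the greatest ensemble diversity in the protocol.
DEFAULT_MAX_SEQS = 16
DEFAULT_EXTRA_SEQS = 32


def _project_uppercase(row: str) -> str:
    """Drop lowercase insertion states (A3M convention)."""
    return "".join(c for c in row if not c.islower())


@dataclass
class AlignmentStack:
    """An MSA with the query as row 0.

    ``rows`` keep lowercase insertion states verbatim so that writing the
    stack back out round-trips byte-identically.
    """

    ids: list[str]
    rows: list[str]
    dialect: str = "a3m"

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise FormatError("ids and rows length mismatch")
        if self.depth == 0:
            raise FormatError("empty alignment")
        lengths = {len(_project_uppercase(r)) for r in self.rows}
        if len(lengths) != 1:
            raise FormatError(
                f"ragged alignment after uppercase projection: lengths {sorted(lengths)}"
            )

    @property
    def depth(self) -> int:
        return len(self.rows)

    @property
    def query_id(self) -> str:
        return self.ids[0]

    @property
    def query_row(self) -> str:
        return self.rows[0]

    @property
    def n_columns(self) -> int:
        return len(_project_uppercase(self.rows[0]))

    def with_query(self, new_query: str, new_id: str | None = None) -> "AlignmentStack":
        """Return a copy whose query row is replaced (e.g. by a scan replica).

        The replacement must have the query's ungapped length; gap/insertion
        structure of the original query row is preserved.
        """
        old = self.rows[0]
        residue_positions = [i for i, c in enumerate(old) if c not in "-"]
        if len(residue_positions) != len(new_query):
            raise ParameterError(
                f"replacement query length {len(new_query)} != "
                f"original ungapped length {len(residue_positions)}"
            )
        chars = list(old)
        for pos, aa in zip(residue_positions, new_query):
            chars[pos] = aa.lower() if old[pos].islower() else aa.upper()
        ids = [new_id if new_id is not None else self.ids[0]] + self.ids[1:]
        return AlignmentStack(ids=ids, rows=["".join(chars)] + self.rows[1:], dialect=self.dialect)


def read_alignment(path: str | Path, dialect: str = "a3m") -> AlignmentStack:
    """Read an A3M or aligned-FASTA file; row 0 is taken as the query."""
    if dialect not in ("a3m", "aligned-fasta"):
        raise ParameterError(f"unknown dialect {dialect!r}")
    text = Path(path).read_text()
    ids: list[str] = []
    rows: list[str] = []
    current: list[str] | None = None
    for line in text.splitlines():
        if line.startswith("#"):        # A3M metadata line (e.g. from hhblits)
            continue
        if line.startswith(">"):
            if current is not None:
                rows.append("".join(current))
            ids.append(line[1:].split()[0] if len(line) > 1 else "")
            current = []
        elif line.strip():
            if current is None:
                raise FormatError(f"{path}: sequence data before first header")
            current.append(line.strip())
    if current is not None:
        rows.append("".join(current))
    if not rows:
        raise FormatError(f"{path}: no alignment records")
    if dialect == "aligned-fasta":
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise FormatError(f"{path}: aligned-fasta rows have unequal lengths {sorted(lengths)}")
    return AlignmentStack(ids=ids, rows=rows, dialect=dialect)


def write_alignment(stack: AlignmentStack, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for rid, row in zip(stack.ids, stack.rows):
            fh.write(f">{rid}\n{row}\n")
    return path


@dataclass(frozen=True)
class SubsamplePartition:
    """Row indices passed to the predictor.

    ``attention`` rows feed the row/column attention track (size <=
    ``max_seqs``, always containing the query at index 0); ``extra`` rows are
    additionally processed by the main stack (size <= ``extra_seqs``).
    """

    attention: tuple[int, ...]
    extra: tuple[int, ...]
    max_seqs: int
    extra_seqs: int
    seed: int

    def __post_init__(self):
        if set(self.attention) & set(self.extra):
            raise ParameterError("attention and extra sets overlap")
        if 0 not in self.attention:
            raise ParameterError("query row (0) missing from attention set")
        if len(self.attention) > self.max_seqs or len(self.extra) > self.extra_seqs:
            raise ParameterError("partition exceeds declared bounds")


def subsample(
    msa: AlignmentStack,
    max_seqs: int = DEFAULT_MAX_SEQS,
    extra_seqs: int = DEFAULT_EXTRA_SEQS,
    seed: int = 0,
) -> SubsamplePartition:
    """Draw the shallow-MSA partition.

    Uniform sampling without replacement over non-query rows; the query is
    always placed in the attention set.  If the MSA is no deeper than
    ``max_seqs`` the attention set is simply all rows and the extra set is
    empty.
    """
    if max_seqs < 1:
        raise ParameterError("max_seqs must be >= 1")
    if extra_seqs < 0:
        raise ParameterError("extra_seqs must be >= 0")
    depth = msa.depth
    if depth <= max_seqs:
        return SubsamplePartition(
            attention=tuple(range(depth)),
            extra=(),
            max_seqs=max_seqs,
            extra_seqs=extra_seqs,
            seed=seed,
        )
    rng = np.random.default_rng(seed)
    others = rng.permutation(np.arange(1, depth))
    attention = (0,) + tuple(int(i) for i in others[: max_seqs - 1])
    extra = tuple(int(i) for i in others[max_seqs - 1 : max_seqs - 1 + extra_seqs])
    return SubsamplePartition(
        attention=attention,
        extra=extra,
        max_seqs=max_seqs,
        extra_seqs=extra_seqs,
        seed=seed,
    )
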