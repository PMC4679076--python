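"""Genome domain-assignment tables and architecture-count matrices.

A protein's *domain architecture* is the N→C ordered sequence of SCOP-style
superfamily domains and unassigned gap regions along its sequence.  For a
genome ``g`` and a superfamily ``d``, ``N_d(g)`` is the number of *distinct*
architectures in ``g`` that contain ``d`` at least once — the per-domain
architecture plasticity potential.  This module parses assignment tables and
builds the superfamily × genome count matrix those counts live in.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Literal token marking an unassigned (gap) region in an architecture string.
GAP = "_gap_"

ASSIGNMENT_COLUMNS = ("genome_id", "protein_id", "architecture")


class MalformedArchitectureError(ValueError):
    """Architecture string empty or containing no superfamily token."""


class DuplicateRecordError(ValueError):
    """Two assignment rows share the same (genome, protein) pair."""


class FormatError(ValueError):
    """Input table does not match the expected schema."""


class UnknownGenomeError(KeyError):
    """Genome id not present in a count matrix."""


Architecture = tuple[str, ...]
"""An architecture is an immutable token sequence, N-terminus first.

Tokens are superfamily identifiers or :data:`GAP`.  Equality is exact
token-sequence equality: gaps and domain repeats are significant.
"""


def canonicalize_architecture(
    raw: str | Sequence[str], *, ignore_gaps: bool = False
) -> Architecture:
    """Normalise a raw architecture string into canonical token form.

    Runs of consecutive gap tokens collapse to a single gap (the length of an
    unassigned stretch is not informative at this level); superfamily tokens
    are preserved verbatim and in order, including repeats.  Leading and
    trailing gaps are retained.  With ``ignore_gaps=True`` gap tokens are
    stripped entirely before comparison.

    Raises
    ------
    MalformedArchitectureError
        If the input is empty or contains only gap tokens.
    """
    if isinstance(raw, str):
        tokens = [t.strip() for t in raw.split(",")]
    else:
        tokens = [str(t).strip() for t in raw]
    tokens = [t for t in tokens if t]
    if not any(t != GAP for t in tokens):
        raise MalformedArchitectureError(
            f"architecture has no superfamily token: {raw!r}"
        )
    out: list[str] = []
    for t in tokens:
        if t == GAP:
            if ignore_gaps:
                continue
            if out and out[-1] == GAP:
                continue  # collapse gap runs
        out.append(t)
    return tuple(out)


def architecture_to_string(arch: Architecture) -> str:
    """Inverse of :func:`canonicalize_architecture` for canonical inputs."""
    return ",".join(arch)


@dataclass(frozen=True)
class GenomeAssignmentTable:
    """Per-protein architecture assignments for one or more genomes.

    ``records`` maps ``(genome_id, protein_id)`` → canonical
    :data:`Architecture`.  The (genome, protein) key is unique by
    construction; duplicated input rows are an error upstream, never a
    silent overwrite.
    """

    records: Mapping[tuple[str, str], Architecture] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def genome_ids(self) -> tuple[str, ...]:
        return tuple(sorted({g for g, _ in self.records}))

    def architectures_of(self, genome_id: str) -> list[Architecture]:
        """All architectures (with protein multiplicity) of one genome."""
        return [a for (g, _), a in self.records.items() if g == genome_id]

    @staticmethod
    def from_rows(
        rows: Iterable[tuple[str, str, str | Sequence[str]]],
        *,
        ignore_gaps: bool = False,
    ) -> "GenomeAssignmentTable":
        records: dict[tuple[str, str], Architecture] = {}
        for genome_id, protein_id, raw in rows:
            key = (str(genome_id), str(protein_id))
            if key in records:
                raise DuplicateRecordError(
                    f"duplicate assignment row for genome={key[0]!r} "
                    f"protein={key[1]!r}"
                )
            records[key] = canonicalize_architecture(raw, ignore_gaps=ignore_gaps)
        return GenomeAssignmentTable(records)

    def merged_with(self, other: "GenomeAssignmentTable") -> "GenomeAssignmentTable":
        overlap = self.records.keys() & other.records.keys()
        if overlap:
            raise DuplicateRecordError(
                f"tables share {len(overlap)} (genome, protein) pairs"
            )
        return GenomeAssignmentTable({**self.records, **other.records})


def parse_assignments(
    source, *, ignore_gaps: bool = False
) -> GenomeAssignmentTable:
    """Read a tab-separated assignment table.

    Expected header: ``genome_id<TAB>protein_id<TAB>architecture`` with
    architecture tokens comma-separated and gaps spelled ``_gap_``.
    ``source`` may be a path or an open text handle.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ASSIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"assignment table missing column(s): {missing}")
    return GenomeAssignmentTable.from_rows(
        df[list(ASSIGNMENT_COLUMNS)].itertuples(index=False, name=None),
        ignore_gaps=ignore_gaps,
    )


@dataclass(frozen=True)
class ArchCountMatrix:
    """Superfamily × genome matrix of distinct-architecture counts.

    ``data`` is an integer DataFrame indexed by superfamily id with one
    column per genome (extant) or tree node (ancestral); entry (d, g) is
    ``N_d(g)``.  Zero means the superfamily occurs in no architecture of
    that genome.  ``kind`` tags the genome axis as ``"extant"`` or
    ``"ancestral"``.
    """

    data: pd.DataFrame
    kind: str = "extant"

    def __post_init__(self):
        if self.kind not in ("extant", "ancestral"):
            raise ValueError(f"kind must be extant|ancestral, got {self.kind!r}")

    @property
    def genome_ids(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def superfamily_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    def counts_for(self, genome_id: str) -> pd.Series:
        """Per-superfamily N_d for one genome, zeros included."""
        if genome_id not in self.data.columns:
            raise UnknownGenomeError(
                f"genome {genome_id!r} not in this {self.kind} matrix"
            )
        return self.data[genome_id]

    def present_domains(self, genome_id: str) -> set[str]:
        counts = self.counts_for(genome_id)
        return set(counts.index[counts > 0])

    def to_long_tsv(self, path_or_buf=None):
        """Export as long-format TSV; zero entries are omitted."""
        id_col = "node_id" if self.kind == "ancestral" else "genome_id"
        long = (
            self.data.rename_axis("superfamily_id")
            .reset_index()
            .melt(id_vars="superfamily_id", var_name=id_col, value_name="n_architectures")
        )
        long = long[long["n_architectures"] > 0].sort_values(
            ["superfamily_id", id_col], kind="mergesort"
        )
        return long.to_csv(path_or_buf, sep="\t", index=False)

    @staticmethod
    def from_long_tsv(source, kind: str = "extant") -> "ArchCountMatrix":
        df = pd.read_csv(source, sep="\t", dtype={"n_architectures": int})
        id_col = "node_id" if kind == "ancestral" else "genome_id"
        if not {"superfamily_id", id_col, "n_architectures"} <= set(df.columns):
            raise FormatError(
                f"count matrix TSV needs columns superfamily_id, {id_col}, n_architectures"
            )
        wide = (
            df.pivot_table(
                index="superfamily_id", columns=id_col,
                values="n_architectures", aggfunc="sum", fill_value=0,
            )
            .astype(int)
            .sort_index()
        )
        wide.columns.name = None
        return ArchCountMatrix(wide, kind=kind)


def build_arch_count_matrix(
    table: GenomeAssignmentTable, kind: str = "extant"
) -> ArchCountMatrix:
    """Count, per genome, the distinct architectures containing each domain.

    Every protein row contributes its architecture once per genome; a
    domain repeated within one architecture still counts that architecture
    once; no length or score filtering is applied.
    """
    per_genome: dict[str, set[Architecture]] = {}
    for (g, _), arch in table.records.items():
        per_genome.setdefault(g, set()).add(arch)
    counts: dict[str, dict[str, int]] = {}
    for g, archs in per_genome.items():
        col: dict[str, int] = {}
        for arch in archs:
            for d in set(arch):
                if d == GAP:
                    continue
                col[d] = col.get(d, 0) + 1
        counts[g] = col
    data = (
        pd.DataFrame(counts).fillna(0).astype(int).sort_index()
        if counts
        else pd.DataFrame(dtype=int)
    )
    data = data.reindex(sorted(data.columns), axis=1)
    return ArchCountMatrix(data, kind=kind)
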