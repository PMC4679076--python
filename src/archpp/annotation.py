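"""Domain-centric ontology annotations (dcGO-style flat files).

A *term* stands for the set of superfamily domains it annotates, at one of
four specificity levels.  Per genome, the *annotatable universe* is the set
of domains both present in the genome and annotated by at least one term —
the sampling support of the randomisation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome_model import ArchCountMatrix, FormatError

#: The four-level specificity classification, least to most specific.
SPECIFICITY_LEVELS = (
    "highly-general",
    "general",
    "specific",
    "highly-specific",
)

ANNOTATION_COLUMNS = ("term_id", "term_name", "level", "superfamily_id")


@dataclass(frozen=True)
class Term:
    term_id: str
    name: str
    level: str
    members: frozenset[str]
    namespace: str = "molecular-function"

    def __post_init__(self):
        if self.level not in SPECIFICITY_LEVELS:
            raise FormatError(
                f"unknown specificity level {self.level!r}; "
                f"expected one of {SPECIFICITY_LEVELS}"
            )
        if not self.members:
            raise FormatError(f"term {self.term_id} has no member superfamilies")


@dataclass(frozen=True)
class AnnotatableUniverse:
    """Domains of one genome that carry at least one annotation."""

    genome_id: str
    domains: frozenset[str] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.domains)


def parse_annotations(source) -> list[Term]:
    """Read a dcGO-style annotation TSV into one Term per term id.

    Expected header: ``term_id<TAB>term_name<TAB>level<TAB>superfamily_id``,
    one row per (term, superfamily) pair.  Rows for the same term aggregate
    into a single member set; annotating a domain twice is a no-op.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation table missing column(s): {missing}")
    terms: list[Term] = []
    for term_id, grp in df.groupby("term_id", sort=True):
        names = grp["term_name"].unique()
        levels = grp["level"].unique()
        if len(levels) > 1:
            raise FormatError(
                f"term {term_id} annotated at conflicting levels {sorted(levels)}"
            )
        terms.append(
            Term(
                term_id=str(term_id),
                name=str(names[0]),
                level=str(levels[0]),
                members=frozenset(grp["superfamily_id"]),
            )
        )
    return terms


def annotatable_universe(
    genome_id: str,
    matrix: ArchCountMatrix,
    terms: list[Term] | tuple[Term, ...],
) -> AnnotatableUniverse:
    """Domains with N_d(g) > 0 that appear in at least one term's members.

    All terms pool into one universe regardless of namespace or level;
    restricting to a term subset is done by the caller passing fewer terms.
    """
    present = matrix.present_domains(genome_id)
    annotated: set[str] = set()
    for t in terms:
        annotated |= t.members
    return AnnotatableUniverse(genome_id, frozenset(present & annotated))


def resolve_domain_set(
    term: Term, universe: AnnotatableUniverse
) -> tuple[frozenset[str], int]:
    """Effective domain set of a term within one genome's universe.

    Members absent from the genome (or unannotatable) are dropped rather
    than scored as zero-count, so the observed set and the null samples
    share the same support.  An empty result is valid and flagged
    not-scoreable downstream.
    """
    eff = term.members & universe.domains
    return eff, len(eff)
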