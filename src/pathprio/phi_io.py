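"""BLAST-vs-PHI-base parsing and per-pathway virulence-hit counting.

Homology to PHI-base entries — genes with experimentally verified
pathogen–host interaction phenotypes — is the direct virulence evidence
dimension of the scoring framework. This module consumes standard BLAST
tabular output (outfmt 6, as emitted by blastp, DIAMOND or TBtools),
filters hits on e-value and percent identity, and intersects the surviving
query set with per-pathway protein membership to obtain ``n_phi``.

Only hit/no-hit per protein matters downstream: hits are deduplicated to a
protein set, with no bitscore ranking and no interpretation of PHI
phenotype classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .annotation_io import FormatError

logger = logging.getLogger(__name__)

#: Default credibility thresholds for retaining a PHI-base hit. Conventional
#: homology-screening cutoffs; both are exposed in the CLI and config.
DEFAULT_EVALUE_MAX = 1e-5
DEFAULT_PIDENT_MIN = 30.0

_N_BLAST_COLUMNS = 12


@dataclass(frozen=True)
class BlastHit:
    """One row of BLAST tabular output (outfmt 6)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent identity {self.percent_identity} outside [0, 100]"
            )
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue}")


@dataclass(frozen=True)
class PhiHitSet:
    """Protein ids with at least one retained PHI-base hit."""

    hit_protein_ids: frozenset[str]

    def __len__(self) -> int:
        return len(self.hit_protein_ids)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.hit_protein_ids


def parse_blast_tab(path: str | Path) -> list[BlastHit]:
    """Parse 12-column BLAST tabular output (outfmt 6).

    Column order: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore. Numeric fields are validated; a row with
    the wrong column count or a non-numeric value raises
    :class:`~pathprio.annotation_io.FormatError` with its line number.
    """
    path = Path(path)
    hits: list[BlastHit] = []
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _N_BLAST_COLUMNS:
                raise FormatError(
                    f"{path}: line {lineno}: expected {_N_BLAST_COLUMNS} "
                    f"tab-separated columns, got {len(fields)}"
                )
            try:
                hit = BlastHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            hits.append(hit)
    return hits


def filter_hits(
    hits: Iterable[BlastHit],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    pident_min: float = DEFAULT_PIDENT_MIN,
) -> PhiHitSet:
    """Reduce hits to the set of proteins with at least one credible match.

    A protein is retained iff it has >= 1 hit with
    ``evalue <= evalue_max`` and ``percent_identity >= pident_min``.
    Relaxing either threshold can only grow the returned set.
    """
    if evalue_max <= 0:
        raise ValueError(f"evalue_max must be positive, got {evalue_max}")
    if not 0.0 <= pident_min <= 100.0:
        raise ValueError(f"pident_min must be in [0, 100], got {pident_min}")
    retained = frozenset(
        hit.query_id
        for hit in hits
        if hit.evalue <= evalue_max and hit.percent_identity >= pident_min
    )
    return PhiHitSet(hit_protein_ids=retained)


def virulence_counts(
    phi: PhiHitSet, membership: Mapping[str, set[str]]
) -> dict[str, int]:
    """Count PHI-hit proteins per pathway: ``n_phi(p) = |hits ∩ members(p)|``."""
    return {
        pathway_id: len(phi.hit_protein_ids & members)
        for pathway_id, members in membership.items()
    }


def restrict_to_annotated(
    phi: PhiHitSet, annotated_ids: Iterable[str]
) -> PhiHitSet:
    """Drop hit queries absent from the annotation set (logged, not fatal).

    Pathway denominators come from the annotation table, so a BLAST query
    with no annotation row cannot contribute to any pathway count.
    """
    annotated = frozenset(annotated_ids)
    unknown = phi.hit_protein_ids - annotated
    if unknown:
        logger.warning(
            "%d PHI-hit query id(s) absent from the annotation set were "
            "ignored (e.g. %s)",
            len(unknown),
            sorted(unknown)[0],
        )
    return PhiHitSet(hit_protein_ids=phi.hit_protein_ids & annotated)
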