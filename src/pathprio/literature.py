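"""Literature-support scoring: mean evidence score x research breadth.

Each curated publication linking a pathway to fungal virulence carries an
integer evidence score on a 0–3 rubric (3 = functional validation by gene
knockout/overexpression, 2 = mechanistic association, 1 = expression-level
evidence only, 0 = no support). Per pathway, the supporting publications
(score >= 1) are averaged and the mean is discounted by a research breadth
coefficient G — a step function of the number of supporting publications N
that down-weights evidence drawn from few studies:

    G = 1.0 if N >= 10; 0.8 if 5 <= N < 10; 0.6 if 2 <= N < 5;
        0.4 if N == 1; 0 if N == 0

    literature support score = mean evidence score x G

Publications scored 0 are excluded from both N and the mean: N counts
*supporting* publications, and pathways without support score 0 on this
dimension. A publication whose primary hit is an umbrella pathway (e.g.
"Metabolic pathways") may be reattributed to a specific sub-pathway; the
original hit is preserved in ``original_pathway`` for provenance.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .annotation_io import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Valid publication evidence scores (the 0–3 rubric).
EVIDENCE_SCORES = frozenset({0, 1, 2, 3})

#: The values the breadth coefficient can take.
BREADTH_VALUES = (0.0, 0.4, 0.6, 0.8, 1.0)


@dataclass(frozen=True)
class LiteratureRecord:
    """One curated publication scored for one pathway."""

    pathway: str
    publication_id: str
    evidence_score: int
    original_pathway: str | None = None

    def __post_init__(self) -> None:
        if self.evidence_score not in EVIDENCE_SCORES:
            raise ValidationError(
                f"evidence score {self.evidence_score} outside "
                f"{sorted(EVIDENCE_SCORES)}"
            )


@dataclass(frozen=True)
class LiteratureSummary:
    """Per-pathway literature evidence: N, mean score, G and final score."""

    pathway: str
    n_supporting: int
    mean_evidence: float
    breadth_g: float
    support_score: float

    @classmethod
    def empty(cls, pathway: str) -> "LiteratureSummary":
        return cls(pathway, 0, 0.0, 0.0, 0.0)


def breadth_coefficient(n: int) -> float:
    """Research breadth coefficient G as a step function of N."""
    if n < 0:
        raise ValueError(f"publication count must be non-negative, got {n}")
    if n >= 10:
        return 1.0
    if n >= 5:
        return 0.8
    if n >= 2:
        return 0.6
    if n == 1:
        return 0.4
    return 0.0


def mean_evidence_score(
    records: Sequence[LiteratureRecord],
) -> tuple[int, float]:
    """Return (N, mean) over the supporting records (evidence score >= 1).

    All records must share one pathway; zero-score records are excluded
    from both the count and the mean. With no supporting records the
    result is (0, 0.0).
    """
    pathways = {record.pathway for record in records}
    if len(pathways) > 1:
        raise ValidationError(
            f"records span multiple pathways: {sorted(pathways)}"
        )
    supporting = [r.evidence_score for r in records if r.evidence_score >= 1]
    if not supporting:
        return 0, 0.0
    return len(supporting), sum(supporting) / len(supporting)


def literature_support_score(mean: float, n: int) -> float:
    """Final literature dimension score: ``mean x G(n)``."""
    if not 0.0 <= mean <= 3.0:
        raise ValueError(f"mean evidence score {mean} outside [0, 3]")
    return mean * breadth_coefficient(n)


def summarize(
    records: Iterable[LiteratureRecord],
) -> dict[str, LiteratureSummary]:
    """Group records by pathway and compute each pathway's summary."""
    by_pathway: dict[str, list[LiteratureRecord]] = {}
    for record in records:
        by_pathway.setdefault(record.pathway, []).append(record)
    summaries: dict[str, LiteratureSummary] = {}
    for pathway, group in by_pathway.items():
        n, mean = mean_evidence_score(group)
        summaries[pathway] = LiteratureSummary(
            pathway=pathway,
            n_supporting=n,
            mean_evidence=mean,
            breadth_g=breadth_coefficient(n),
            support_score=literature_support_score(mean, n),
        )
    return summaries


def parse_literature(path: str | Path) -> list[LiteratureRecord]:
    """Parse the curated literature evidence CSV.

    Required columns: ``pathway``, ``publication_id``, ``evidence_score``;
    optional ``original_pathway`` (umbrella-pathway reattribution
    provenance). A publication scores at most once per pathway; duplicates
    and out-of-rubric scores are rejected with the offending row number.
    """
    path = Path(path)
    records: list[LiteratureRecord] = []
    seen: set[tuple[str, str]] = set()
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle)
        required = {"pathway", "publication_id", "evidence_score"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(
                f"{path}: expected CSV header with columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for rownum, row in enumerate(reader, start=2):
            pathway = row["pathway"].strip()
            publication_id = row["publication_id"].strip()
            try:
                score = int(row["evidence_score"])
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: row {rownum}: evidence score "
                    f"{row['evidence_score']!r} is not an integer"
                ) from None
            if score not in EVIDENCE_SCORES:
                raise ValidationError(
                    f"{path}: row {rownum}: evidence score {score} outside "
                    f"{sorted(EVIDENCE_SCORES)}"
                )
            key = (pathway.lower(), publication_id)
            if key in seen:
                raise ValidationError(
                    f"{path}: row {rownum}: publication {publication_id!r} "
                    f"scored twice for pathway {pathway!r}"
                )
            seen.add(key)
            original = (row.get("original_pathway") or "").strip() or None
            records.append(
                LiteratureRecord(
                    pathway=pathway,
                    publication_id=publication_id,
                    evidence_score=score,
                    original_pathway=original,
                )
            )
    if any(r.original_pathway for r in records):
        n_reattributed = sum(1 for r in records if r.original_pathway)
        logger.info(
            "%d literature record(s) reattributed from an umbrella pathway",
            n_reattributed,
        )
    return records
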