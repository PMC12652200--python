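"""Four-dimensional pathway scoring: coverages, binned points, total.

Each candidate pathway is scored on four evidence dimensions:

1. **Protein coverage** (0–2 pts): Gene Count / KO Total — annotated
   proteins mapped to the pathway over the pathway's total defined KEGG
   Ortholog count. May exceed 1 under gene-family expansion. Binned at
   0.2 / 0.5.
2. **GO-BP coverage** (0–2 pts): n_bp / n_total — pathway proteins carrying
   at least one Biological Process GO term over all pathway proteins.
   Binned at 0.4 / 0.8.
3. **PHI virulence coverage** (0–3 pts): n_phi / n_total — pathway proteins
   with credible PHI-base homology over all pathway proteins. Binned at
   0.3 / 0.6, with exactly zero coverage scoring 0.
4. **Literature support** (0–3 pts): the continuous mean-evidence x breadth
   score from :mod:`pathprio.literature`, entered without re-binning.

All bands are closed on the left of the upper band (``>=``) and open on
the right (``<``). The dimensions carrying direct experimental virulence
evidence (PHI, literature) max at 3 points; the indirect annotation
dimensions max at 2, and the total is their plain sum, bounded by 10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .annotation_io import PathwayRef, ValidationError
from .literature import LiteratureSummary

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdConfig:
    """Binning edges and per-dimension point caps for the scoring rubric.

    Defaults are the framework's published thresholds; they can be
    overridden from a YAML file but the defaults are what the worked
    examples assume.
    """

    protein_edges: tuple[float, float] = (0.2, 0.5)
    bp_edges: tuple[float, float] = (0.4, 0.8)
    phi_edges: tuple[float, float] = (0.3, 0.6)
    protein_max: int = 2
    bp_max: int = 2
    phi_max: int = 3
    literature_max: int = 3

    def __post_init__(self) -> None:
        for name in ("protein_edges", "bp_edges", "phi_edges"):
            low, high = getattr(self, name)
            if not low < high:
                raise ValidationError(
                    f"{name} must be strictly increasing, got ({low}, {high})"
                )

    @property
    def total_max(self) -> float:
        return self.protein_max + self.bp_max + self.phi_max + self.literature_max

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdConfig":
        """Load edge overrides from a flat YAML mapping."""
        with Path(path).open() as handle:
            raw = yaml.safe_load(handle) or {}
        kwargs = {}
        for key in ("protein_edges", "bp_edges", "phi_edges"):
            if key in raw:
                kwargs[key] = tuple(float(v) for v in raw[key])
        return cls(**kwargs)


@dataclass(frozen=True)
class PathwayEvidence:
    """Raw per-pathway evidence feeding the four scoring dimensions.

    ``gene_count`` doubles as the coverage denominator n_total for the
    GO-BP and PHI dimensions: all three quantities count proteins mapped
    to the pathway.
    """

    pathway: PathwayRef
    gene_count: int
    n_bp: int
    n_phi: int
    literature: LiteratureSummary

    def __post_init__(self) -> None:
        if self.gene_count < 0:
            raise ValidationError(f"negative gene count for {self.pathway.pathway_id}")
        if self.n_bp > self.gene_count:
            raise ValidationError(
                f"{self.pathway.pathway_id}: n_bp ({self.n_bp}) exceeds "
                f"gene count ({self.gene_count})"
            )
        if self.n_phi > self.gene_count:
            raise ValidationError(
                f"{self.pathway.pathway_id}: n_phi ({self.n_phi}) exceeds "
                f"gene count ({self.gene_count})"
            )


@dataclass(frozen=True)
class DimensionScores:
    """The four coverages, binned points and total for one pathway."""

    pathway_id: str
    name: str
    protein_coverage: float
    protein_score: int
    bp_coverage: float
    bp_score: int
    phi_coverage: float
    phi_score: int
    lit_n: int
    lit_mean: float
    lit_g: float
    literature_score: float
    total: float


def protein_coverage(gene_count: int, ko_total: int) -> float:
    """Gene Count / KO Total; 0 (with warning) for an undefined denominator.

    Values above 1 are legitimate: paralog expansion can map more proteins
    to a pathway than the pathway has defined KO entries.
    """
    if gene_count < 0 or ko_total < 0:
        raise ValueError(
            f"counts must be non-negative, got ({gene_count}, {ko_total})"
        )
    if ko_total == 0:
        if gene_count:
            logger.warning(
                "KO total is 0 but gene count is %d; protein coverage "
                "reported as 0",
                gene_count,
            )
        return 0.0
    return gene_count / ko_total


def bin_protein_coverage(cov: float, cfg: ThresholdConfig = ThresholdConfig()) -> int:
    """Bin protein coverage: 2 if >= high edge, 1 if in [low, high), else 0."""
    if cov < 0:
        raise ValueError(f"coverage must be non-negative, got {cov}")
    low, high = cfg.protein_edges
    if cov >= high:
        return cfg.protein_max
    if cov >= low:
        return 1
    return 0


def _ratio_or_zero(numerator: int, denominator: int) -> float:
    return numerator / denominator if denominator else 0.0


def bp_coverage_score(
    n_bp: int, n_total: int, cfg: ThresholdConfig = ThresholdConfig()
) -> tuple[float, int]:
    """GO-BP coverage and its binned score (2 if >= 0.8, 1 if in [0.4, 0.8))."""
    if not 0 <= n_bp:
        raise ValueError(f"n_bp must be non-negative, got {n_bp}")
    if n_bp > n_total:
        raise ValidationError(f"n_bp ({n_bp}) exceeds n_total ({n_total})")
    cov = _ratio_or_zero(n_bp, n_total)
    low, high = cfg.bp_edges
    if cov >= high:
        score = cfg.bp_max
    elif cov >= low:
        score = 1
    else:
        score = 0
    return cov, score


def phi_coverage_score(
    n_phi: int, n_total: int, cfg: ThresholdConfig = ThresholdConfig()
) -> tuple[float, int]:
    """PHI virulence coverage and its binned score.

    3 if coverage >= 0.6, 2 if in [0.3, 0.6), 1 if in (0, 0.3); a pathway
    with no PHI hits at all scores 0.
    """
    if not 0 <= n_phi:
        raise ValueError(f"n_phi must be non-negative, got {n_phi}")
    if n_phi > n_total:
        raise ValidationError(f"n_phi ({n_phi}) exceeds n_total ({n_total})")
    cov = _ratio_or_zero(n_phi, n_total)
    low, high = cfg.phi_edges
    if cov >= high:
        score = cfg.phi_max
    elif cov >= low:
        score = 2
    elif cov > 0:
        score = 1
    else:
        score = 0
    return cov, score


def score_pathway(
    evidence: PathwayEvidence, cfg: ThresholdConfig = ThresholdConfig()
) -> DimensionScores:
    """Compute all four dimension scores and their total for one pathway.

    The literature dimension enters as its continuous value (e.g. 1.76),
    not re-binned to an integer; full precision is kept and only reports
    round for display.
    """
    p_cov = protein_coverage(evidence.gene_count, evidence.pathway.ko_total)
    p_score = bin_protein_coverage(p_cov, cfg)
    bp_cov, bp_score = bp_coverage_score(evidence.n_bp, evidence.gene_count, cfg)
    phi_cov, phi_score = phi_coverage_score(evidence.n_phi, evidence.gene_count, cfg)
    lit = evidence.literature
    total = p_score + bp_score + phi_score + lit.support_score
    return DimensionScores(
        pathway_id=evidence.pathway.pathway_id,
        name=evidence.pathway.name,
        protein_coverage=p_cov,
        protein_score=p_score,
        bp_coverage=bp_cov,
        bp_score=bp_score,
        phi_coverage=phi_cov,
        phi_score=phi_score,
        lit_n=lit.n_supporting,
        lit_mean=lit.mean_evidence,
        lit_g=lit.breadth_g,
        literature_score=lit.support_score,
        total=total,
    )


def score_all(
    evidence_table: Iterable[PathwayEvidence],
    cfg: ThresholdConfig = ThresholdConfig(),
) -> list[DimensionScores]:
    """Score every pathway in the table; pathway ids must be unique."""
    seen: set[str] = set()
    scores: list[DimensionScores] = []
    for evidence in evidence_table:
        pathway_id = evidence.pathway.pathway_id
        if pathway_id in seen:
            raise ValidationError(f"duplicate pathway id {pathway_id!r}")
        seen.add(pathway_id)
        scores.append(score_pathway(evidence, cfg))
    return scores
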