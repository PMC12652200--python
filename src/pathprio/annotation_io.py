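"""Parsers for functional-annotation inputs and annotation-level summaries.

This module turns the three annotation-side inputs of the prioritization
pipeline into the internal data model:

* an eggNOG-mapper v2 ``.emapper.annotations`` table (one row per annotated
  protein, carrying KEGG Ortholog ids, GO terms and KEGG pathway
  memberships),
* a pathway reference table giving each KEGG pathway's total defined KO
  count (the denominator of protein coverage), and
* a GO id -> namespace map (two-column TSV or a minimal OBO file), used to
  restrict GO support to the Biological Process namespace.

It also provides the annotation summaries the pipeline reports: whole-set
KO coverage, per-pathway gene counts, per-term GO counts and generic
"top N categories by count" selection.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

_KO_RE = re.compile(r"^K\d{5}$")
_GO_RE = re.compile(r"^GO:\d{7}$")
_PATHWAY_RE = re.compile(r"^(ko|map)\d{5}$")

#: OBO namespace strings -> short namespace tokens.
OBO_NAMESPACES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}

VALID_NAMESPACES = frozenset(OBO_NAMESPACES.values())


class FormatError(ValueError):
    """An input file does not have the expected layout."""


class ValidationError(ValueError):
    """An input file parses but violates a content invariant."""


def normalize_pathway_id(pathway_id: str) -> str:
    """Collapse KEGG pathway id variants onto the canonical ``ko#####`` form.

    eggNOG-mapper emits both ``ko04010`` and ``map04010`` for the same
    pathway; the ``map`` prefix is rewritten to ``ko`` so the two collapse.
    """
    pathway_id = pathway_id.strip()
    if pathway_id.startswith("map"):
        return "ko" + pathway_id[3:]
    return pathway_id


@dataclass(frozen=True)
class ProteinAnnotation:
    """One annotated protein with its KO ids, GO terms and pathway memberships."""

    protein_id: str
    ko_ids: frozenset[str] = field(default_factory=frozenset)
    go_terms: frozenset[str] = field(default_factory=frozenset)
    pathway_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("protein_id must be non-empty")


@dataclass(frozen=True)
class PathwayRef:
    """A KEGG pathway's identity and its total defined KO count."""

    pathway_id: str
    name: str
    ko_total: int

    def __post_init__(self) -> None:
        if self.ko_total < 0:
            raise ValidationError(
                f"ko_total must be non-negative, got {self.ko_total} "
                f"for {self.pathway_id}"
            )


@dataclass
class AnnotationSet:
    """The full annotated proteome: one :class:`ProteinAnnotation` per protein."""

    proteins: list[ProteinAnnotation]

    @property
    def n_annotated(self) -> int:
        return len(self.proteins)

    def membership(self) -> dict[str, set[str]]:
        """Map each pathway id to the set of protein ids annotated to it."""
        out: dict[str, set[str]] = {}
        for protein in self.proteins:
            for pathway_id in protein.pathway_ids:
                out.setdefault(pathway_id, set()).add(protein.protein_id)
        return out


def _split_multivalue(raw: str) -> list[str]:
    """Split an emapper comma-separated multi-value field; '-' means empty."""
    raw = raw.strip()
    if raw in ("", "-"):
        return []
    return [token.strip() for token in raw.split(",") if token.strip()]


def parse_emapper(path: str | Path) -> AnnotationSet:
    """Parse an eggNOG-mapper v2 ``.emapper.annotations`` table.

    The header row (starting with ``#query``) keys the columns, so extra or
    reordered columns across emapper releases are tolerated; only the
    ``query``/``GOs``/``KEGG_ko``/``KEGG_Pathway`` columns are read.
    ``##`` comment lines are skipped and ``-`` fields yield empty sets.
    Every data row counts as an annotated protein, even when all annotation
    fields are missing.

    Raises
    ------
    FormatError
        If no ``#query`` header line is present, or a data row is too short.
    ValidationError
        If a protein id occurs more than once.
    """
    path = Path(path)
    header: list[str] | None = None
    proteins: list[ProteinAnnotation] = []
    seen: set[str] = set()

    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("##"):
                continue
            if header is None:
                if line.startswith("#query"):
                    header = line.lstrip("#").split("\t")
                    try:
                        idx = {
                            "query": header.index("query"),
                            "GOs": header.index("GOs"),
                            "KEGG_ko": header.index("KEGG_ko"),
                            "KEGG_Pathway": header.index("KEGG_Pathway"),
                        }
                    except ValueError as exc:
                        raise FormatError(
                            f"{path}: header is missing a required column: {exc}"
                        ) from None
                    continue
                raise FormatError(
                    f"{path}: expected a '#query' header line before data "
                    f"(line {lineno})"
                )
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) <= max(idx.values()):
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} columns, "
                    f"fewer than the header requires"
                )
            protein_id = fields[idx["query"]].strip()
            if protein_id in seen:
                raise ValidationError(
                    f"{path}: duplicate protein id {protein_id!r}"
                )
            seen.add(protein_id)

            ko_ids = frozenset(
                token[3:] if token.startswith("ko:") else token
                for token in _split_multivalue(fields[idx["KEGG_ko"]])
            )
            go_terms = frozenset(_split_multivalue(fields[idx["GOs"]]))
            pathway_ids = frozenset(
                normalize_pathway_id(token)
                for token in _split_multivalue(fields[idx["KEGG_Pathway"]])
                if _PATHWAY_RE.match(token.strip())
            )
            proteins.append(
                ProteinAnnotation(
                    protein_id=protein_id,
                    ko_ids=ko_ids,
                    go_terms=go_terms,
                    pathway_ids=pathway_ids,
                )
            )

    if header is None:
        raise FormatError(f"{path}: no '#query' header line found")
    return AnnotationSet(proteins=proteins)


def parse_pathway_ref(path: str | Path) -> dict[str, PathwayRef]:
    """Parse the pathway reference TSV (``pathway_id``, ``name``, ``ko_total``).

    Pathway ids are normalized (``map`` -> ``ko``). Duplicate ids and
    non-integer KO totals are rejected with the offending row number.
    """
    path = Path(path)
    refs: dict[str, PathwayRef] = {}
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"pathway_id", "name", "ko_total"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(
                f"{path}: expected tab-separated header with columns "
                f"{sorted(required)}, got {reader.fieldnames}"
            )
        for rownum, row in enumerate(reader, start=2):
            pathway_id = normalize_pathway_id(row["pathway_id"])
            try:
                ko_total = int(row["ko_total"])
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: row {rownum}: ko_total {row['ko_total']!r} "
                    f"is not an integer"
                ) from None
            if pathway_id in refs:
                raise ValidationError(
                    f"{path}: row {rownum}: duplicate pathway id {pathway_id!r}"
                )
            refs[pathway_id] = PathwayRef(
                pathway_id=pathway_id, name=row["name"].strip(), ko_total=ko_total
            )
    if not refs:
        logger.warning("%s: pathway reference table is empty", path)
    return refs


def _parse_go_namespace_obo(path: Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    current_id: str | None = None
    in_term = False
    with path.open() as handle:
        for line in handle:
            line = line.strip()
            if line == "[Term]":
                in_term = True
                current_id = None
            elif line.startswith("["):
                in_term = False
            elif in_term and line.startswith("id:"):
                current_id = line[3:].strip()
            elif in_term and line.startswith("namespace:"):
                raw = line[len("namespace:"):].strip()
                if raw not in OBO_NAMESPACES:
                    raise ValidationError(
                        f"{path}: unknown namespace {raw!r} for term {current_id}"
                    )
                if current_id:
                    mapping[current_id] = OBO_NAMESPACES[raw]
    return mapping


def parse_go_namespace(path: str | Path) -> dict[str, str]:
    """Parse a GO id -> namespace map from a TSV or a minimal OBO file.

    The TSV form has two columns (go_id, namespace) with namespace one of
    ``BP``/``MF``/``CC`` or the long OBO names. The OBO form is scanned for
    ``[Term]`` stanzas with ``id:`` and ``namespace:`` lines only; graph
    structure and obsolete handling are out of scope. GO ids absent from
    the returned map are treated as non-BP by downstream consumers.
    """
    path = Path(path)
    with path.open() as handle:
        head = handle.read(4096)
    if "[Term]" in head or head.startswith("format-version"):
        return _parse_go_namespace_obo(path)

    mapping: dict[str, str] = {}
    with path.open(newline="") as handle:
        for rownum, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise FormatError(
                    f"{path}: row {rownum}: expected two columns (go_id, namespace)"
                )
            go_id, raw = row[0].strip(), row[1].strip()
            if go_id == "go_id":  # optional header
                continue
            namespace = OBO_NAMESPACES.get(raw, raw)
            if namespace not in VALID_NAMESPACES:
                raise ValidationError(
                    f"{path}: row {rownum}: unknown namespace {raw!r}"
                )
            mapping[go_id] = namespace
    return mapping


def ko_coverage_summary(
    annotations: AnnotationSet,
    go_namespace: Mapping[str, str] | None = None,
) -> dict[str, float | int]:
    """Summarize KO/GO assignment rates over the annotated proteome.

    ``ko_coverage_percent`` is ``100 * n_ko_assigned / n_annotated`` rounded
    to two decimals (0 for an empty set). GO-annotated proteins are counted
    both across all namespaces (``n_go_assigned``) and, when a namespace map
    is supplied, restricted to Biological Process (``n_go_bp_assigned``).
    """
    n_annotated = annotations.n_annotated
    n_ko = sum(1 for p in annotations.proteins if p.ko_ids)
    n_go = sum(1 for p in annotations.proteins if p.go_terms)
    summary: dict[str, float | int] = {
        "n_annotated": n_annotated,
        "n_ko_assigned": n_ko,
        "n_go_assigned": n_go,
    }
    if n_annotated == 0:
        logger.warning("annotation set is empty; KO coverage reported as 0")
        summary["ko_coverage_percent"] = 0.0
    else:
        summary["ko_coverage_percent"] = round(100.0 * n_ko / n_annotated, 2)
    if go_namespace is not None:
        summary["n_go_bp_assigned"] = sum(
            1
            for p in annotations.proteins
            if any(go_namespace.get(term) == "BP" for term in p.go_terms)
        )
    return summary


def pathway_gene_counts(annotations: AnnotationSet) -> dict[str, int]:
    """Count annotated proteins per pathway (the pathway "Gene Count").

    Each protein contributes at most one to each pathway it maps to, no
    matter how many of its KOs belong to that pathway.
    """
    return {
        pathway_id: len(members)
        for pathway_id, members in annotations.membership().items()
    }


def go_term_counts(
    annotations: AnnotationSet,
    go_namespace: Mapping[str, str] | None = None,
    namespace: str = "BP",
) -> dict[str, int]:
    """Count proteins per GO term, optionally restricted to one namespace."""
    counts: dict[str, int] = {}
    for protein in annotations.proteins:
        for term in protein.go_terms:
            if go_namespace is not None and go_namespace.get(term) != namespace:
                continue
            counts[term] = counts.get(term, 0) + 1
    return counts


def top_terms_by_count(
    counts: Mapping[str, int], n: int
) -> list[tuple[str, int]]:
    """Return the top-``n`` (id, count) pairs, descending by count.

    Ties are broken by id ascending, so the result is a deterministic
    function of the mapping's contents regardless of insertion order.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    ranked = sorted(counts.items(), key=lambda item: (-item[1], item[0]))
    return ranked[:n]
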