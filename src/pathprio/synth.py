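"""Synthetic input bundles with known ground truth, plus the worked example.

The scoring framework is deterministic, so its test surface is sharpest
when the generated evidence is *constructed exactly* rather than sampled:
for each synthetic pathway the generator emits exactly ``gene_count``
proteins, exactly ``round(bp_fraction x gene_count)`` of them carrying a
Biological Process GO term, and exactly ``round(phi_fraction x
gene_count)`` of them appearing as BLAST queries with hits passing the
default credibility cutoffs. Randomness (seeded) touches only nuisance
structure: protein id order, e-values, identities, decoy hits.

Each bundle ships a manifest of expected coverages and dimension scores
computed by an independent in-module calculation (plain band arithmetic,
not the scoring module), so end-to-end pipeline runs can be checked for
exact recovery.

:func:`table2_fixture` writes a synthetic stand-in for the published
curated literature-evidence table for the 20 most protein-rich KEGG
pathways of *Metarhizium brunneum*: per pathway it constructs an integer
score multiset with exactly the published publication count and mean, so
the literature module reproduces every published final score.
"""

from __future__ import annotations

import csv
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .annotation_io import ValidationError

#: Published per-pathway literature evidence (pathway name, N supporting
#: publications, mean evidence score) for the 20 candidate pathways.
CANDIDATE_PATHWAY_LITERATURE: tuple[tuple[str, int, float], ...] = (
    ("Metabolic pathways", 0, 0.0),
    ("Biosynthesis of secondary metabolites", 5, 2.2),
    ("Biosynthesis of antibiotics", 0, 0.0),
    ("Microbial metabolism in diverse environments", 0, 0.0),
    ("Biosynthesis of cofactors", 0, 0.0),
    ("Carbon metabolism", 10, 2.0),
    ("Ribosome", 0, 0.0),
    ("Purine metabolism", 0, 0.0),
    ("Neuroactive ligand-receptor interaction", 0, 0.0),
    ("Apoptosis", 3, 2.0),
    ("Spliceosome", 0, 0.0),
    ("RNA transport", 0, 0.0),
    ("Oxidative phosphorylation", 2, 1.0),
    ("Huntington disease", 0, 0.0),
    ("Protein processing in endoplasmic reticulum", 0, 0.0),
    ("MAPK signaling pathway", 26, 2.5),
    ("Endocytosis", 2, 2.0),
    ("Pyrimidine metabolism", 0, 0.0),
    ("Circadian rhythm—plant", 0, 0.0),
    ("Autophagy—animal", 1, 3.0),
)

_BP_TERMS = ("GO:0006915", "GO:0016192", "GO:0006914", "GO:0000165", "GO:0005975")
_NON_BP_TERMS = (("GO:0003824", "MF"), ("GO:0005737", "CC"), ("GO:0016301", "MF"))

# Inline copies of the default rubric edges: the manifest must be computed
# independently of the scoring module it is later checked against.
_PROTEIN_EDGES = (0.2, 0.5)
_BP_EDGES = (0.4, 0.8)
_PHI_EDGES = (0.3, 0.6)


def round_half_up(x: float) -> int:
    """Round to nearest integer with exact halves rounding up."""
    return math.floor(x + 0.5)


@dataclass(frozen=True)
class SynthPathwaySpec:
    """Ground-truth structure for one synthetic pathway."""

    pathway_id: str
    name: str
    ko_total: int
    gene_count: int
    bp_fraction: float
    phi_fraction: float
    publications: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.gene_count < 0 or self.ko_total < 0:
            raise ValidationError(f"{self.pathway_id}: negative counts")
        for name in ("bp_fraction", "phi_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(
                    f"{self.pathway_id}: {name} {value} outside [0, 1]"
                )
        if any(s not in (0, 1, 2, 3) for s in self.publications):
            raise ValidationError(
                f"{self.pathway_id}: publication scores must be in 0..3"
            )

    @property
    def n_bp(self) -> int:
        return round_half_up(self.bp_fraction * self.gene_count)

    @property
    def n_phi(self) -> int:
        return round_half_up(self.phi_fraction * self.gene_count)


@dataclass(frozen=True)
class SynthConfig:
    """A full synthetic study: pathway specs plus denominator stressors."""

    pathways: tuple[SynthPathwaySpec, ...]
    n_unmapped_proteins: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [spec.pathway_id for spec in self.pathways]
        if len(ids) != len(set(ids)):
            raise ValidationError("pathway ids in a SynthConfig must be unique")
        if self.n_unmapped_proteins < 0:
            raise ValidationError("n_unmapped_proteins must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        with Path(path).open() as handle:
            raw = yaml.safe_load(handle)
        pathways = tuple(
            SynthPathwaySpec(
                pathway_id=p["pathway_id"],
                name=p["name"],
                ko_total=int(p["ko_total"]),
                gene_count=int(p["gene_count"]),
                bp_fraction=float(p["bp_fraction"]),
                phi_fraction=float(p["phi_fraction"]),
                publications=tuple(int(s) for s in p.get("publications", ())),
            )
            for p in raw.get("pathways", [])
        )
        return cls(
            pathways=pathways,
            n_unmapped_proteins=int(raw.get("n_unmapped_proteins", 0)),
            seed=int(raw.get("seed", 0)),
        )


@dataclass(frozen=True)
class SynthBundle:
    """Paths of one generated input bundle plus its ground-truth manifest."""

    annotations: Path
    blast: Path
    literature: Path
    pathway_ref: Path
    go_namespace: Path
    manifest: Path


def _band2(cov: float, edges: tuple[float, float], top: int) -> int:
    low, high = edges
    if cov >= high:
        return top
    if cov >= low:
        return 1
    return 0


def _band_phi(cov: float) -> int:
    if cov >= _PHI_EDGES[1]:
        return 3
    if cov >= _PHI_EDGES[0]:
        return 2
    if cov > 0:
        return 1
    return 0


def _breadth(n: int) -> float:
    if n >= 10:
        return 1.0
    if n >= 5:
        return 0.8
    if n >= 2:
        return 0.6
    if n == 1:
        return 0.4
    return 0.0


def _expected_row(spec: SynthPathwaySpec) -> dict:
    """Expected coverages and scores, by direct band arithmetic."""
    p_cov = spec.gene_count / spec.ko_total if spec.ko_total else 0.0
    bp_cov = spec.n_bp / spec.gene_count if spec.gene_count else 0.0
    phi_cov = spec.n_phi / spec.gene_count if spec.gene_count else 0.0
    supporting = [s for s in spec.publications if s >= 1]
    lit_n = len(supporting)
    lit_mean = sum(supporting) / lit_n if lit_n else 0.0
    lit_g = _breadth(lit_n)
    lit_score = lit_mean * lit_g
    p_score = _band2(p_cov, _PROTEIN_EDGES, 2)
    bp_score = _band2(bp_cov, _BP_EDGES, 2)
    phi_score = _band_phi(phi_cov)
    return {
        "pathway_id": spec.pathway_id,
        "name": spec.name,
        "gene_count": spec.gene_count,
        "ko_total": spec.ko_total,
        "n_bp": spec.n_bp,
        "n_phi": spec.n_phi,
        "protein_coverage": p_cov,
        "protein_score": p_score,
        "bp_coverage": bp_cov,
        "bp_score": bp_score,
        "phi_coverage": phi_cov,
        "phi_score": phi_score,
        "lit_n": lit_n,
        "lit_mean": lit_mean,
        "lit_g": lit_g,
        "literature_score": lit_score,
        "total": p_score + bp_score + phi_score + lit_score,
    }


MANIFEST_COLUMNS = tuple(
    _expected_row(
        SynthPathwaySpec("ko00000", "x", 1, 1, 0.0, 0.0)
    ).keys()
)

_MANIFEST_FLOATS = {
    "protein_coverage", "bp_coverage", "phi_coverage",
    "lit_mean", "lit_g", "literature_score", "total",
}


def validate_config(config: SynthConfig) -> None:
    """Reject specs whose fraction-to-count rounding crosses a band edge.

    The manifest promises the score implied by the *fraction*; if rounding
    ``fraction x gene_count`` lands the realized coverage in a different
    band, the promise cannot hold and the spec is unrealizable as stated.
    """
    for spec in config.pathways:
        if spec.gene_count == 0:
            if spec.bp_fraction or spec.phi_fraction:
                raise ValidationError(
                    f"{spec.pathway_id}: nonzero fractions with gene_count 0"
                )
            continue
        bp_real = spec.n_bp / spec.gene_count
        if _band2(bp_real, _BP_EDGES, 2) != _band2(spec.bp_fraction, _BP_EDGES, 2):
            raise ValidationError(
                f"{spec.pathway_id}: rounding bp_fraction {spec.bp_fraction} "
                f"to {spec.n_bp}/{spec.gene_count} crosses a scoring edge"
            )
        phi_real = spec.n_phi / spec.gene_count
        if _band_phi(spec.phi_fraction) != _band_phi(phi_real):
            raise ValidationError(
                f"{spec.pathway_id}: rounding phi_fraction {spec.phi_fraction} "
                f"to {spec.n_phi}/{spec.gene_count} crosses a scoring edge"
            )


def generate(config: SynthConfig, outdir: str | Path) -> SynthBundle:
    """Write the five input files plus the ground-truth manifest.

    Deterministic: the same config (including seed) yields byte-identical
    files. Raises :class:`~pathprio.annotation_io.ValidationError` for
    unrealizable specs.
    """
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(config.seed)

    bundle = SynthBundle(
        annotations=outdir / "proteome.emapper.annotations",
        blast=outdir / "phi_hits.outfmt6.tsv",
        literature=outdir / "literature_synthetic.csv",
        pathway_ref=outdir / "pathway_ref.tsv",
        go_namespace=outdir / "go_namespace.tsv",
        manifest=outdir / "manifest.tsv",
    )

    # ---- assign proteins to pathways (disjoint blocks, ids shuffled later)
    protein_counter = 0
    ko_counter = 1
    annotation_rows: list[tuple[str, str, str, str]] = []  # query, GOs, ko, pathway
    phi_queries: list[str] = []
    non_phi_queries: list[str] = []

    for spec in config.pathways:
        members = []
        for _ in range(spec.gene_count):
            protein_counter += 1
            members.append(f"MBR_{protein_counter:05d}")
        bp_members = set(members[: spec.n_bp])
        phi_members = set(rng.sample(members, spec.n_phi))
        for i, protein_id in enumerate(members):
            gos = []
            if protein_id in bp_members:
                gos.append(rng.choice(_BP_TERMS))
            if rng.random() < 0.5:  # nuisance non-BP annotation
                gos.append(rng.choice(_NON_BP_TERMS)[0])
            ko = f"ko:K{ko_counter:05d}"
            ko_counter += 1
            # every third row also carries the "map" id variant to exercise
            # pathway-id normalization in the parser
            pathway_field = (
                f"{spec.pathway_id},map{spec.pathway_id[2:]}"
                if i % 3 == 0
                else spec.pathway_id
            )
            annotation_rows.append(
                (protein_id, ",".join(gos) or "-", ko, pathway_field)
            )
            if protein_id in phi_members:
                phi_queries.append(protein_id)
            else:
                non_phi_queries.append(protein_id)

    for _ in range(config.n_unmapped_proteins):
        protein_counter += 1
        annotation_rows.append((f"MBR_{protein_counter:05d}", "-", "-", "-"))

    rng.shuffle(annotation_rows)
    with bundle.annotations.open("w") as handle:
        handle.write("## synthetic eggNOG-mapper style annotation table\n")
        handle.write("#query\tseed_ortholog\tevalue\tGOs\tKEGG_ko\tKEGG_Pathway\n")
        for query, gos, ko, pathway in annotation_rows:
            handle.write(f"{query}\tsynth.1\t1e-50\t{gos}\t{ko}\t{pathway}\n")

    # ---- BLAST hits: passing hits for PHI proteins, failing decoys otherwise
    blast_rows: list[str] = []
    for query in phi_queries:
        for _ in range(rng.randint(1, 2)):
            pident = round(rng.uniform(35.0, 95.0), 1)
            length = rng.randint(80, 400)
            evalue = f"{10 ** -rng.uniform(6.0, 50.0):.2e}"
            bits = round(rng.uniform(60.0, 400.0), 1)
            blast_rows.append(
                f"{query}\tPHI:{rng.randint(1, 9999)}\t{pident}\t{length}\t"
                f"{rng.randint(0, 40)}\t{rng.randint(0, 5)}\t1\t{length}\t1\t"
                f"{length}\t{evalue}\t{bits}"
            )
    for query in rng.sample(non_phi_queries, min(3, len(non_phi_queries))):
        # decoy hits failing the default e-value cutoff
        blast_rows.append(
            f"{query}\tPHI:{rng.randint(1, 9999)}\t"
            f"{round(rng.uniform(35.0, 95.0), 1)}\t100\t10\t1\t1\t100\t1\t100\t"
            f"1e-02\t{round(rng.uniform(20.0, 40.0), 1)}"
        )
    bundle.blast.write_text("\n".join(blast_rows) + ("\n" if blast_rows else ""))

    # ---- literature CSV (synthetic records; zero-score rows included)
    with bundle.literature.open("w", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["pathway", "publication_id", "evidence_score", "original_pathway"])
        pub = 0
        for spec in config.pathways:
            for score in spec.publications:
                pub += 1
                writer.writerow([spec.name, f"SYN:{pub:04d}", score, ""])

    with bundle.pathway_ref.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["pathway_id", "name", "ko_total"])
        for spec in config.pathways:
            writer.writerow([spec.pathway_id, spec.name, spec.ko_total])

    with bundle.go_namespace.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["go_id", "namespace"])
        for term in _BP_TERMS:
            writer.writerow([term, "BP"])
        for term, namespace in _NON_BP_TERMS:
            writer.writerow([term, namespace])

    with bundle.manifest.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(MANIFEST_COLUMNS)
        for spec in config.pathways:
            row = _expected_row(spec)
            writer.writerow(
                [repr(row[col]) if col in _MANIFEST_FLOATS else row[col]
                 for col in MANIFEST_COLUMNS]
            )
    return bundle


def read_manifest(path: str | Path) -> list[dict]:
    """Read a ground-truth manifest back into typed records."""
    records: list[dict] = []
    with Path(path).open(newline="") as handle:
        for raw in csv.DictReader(handle, delimiter="\t"):
            record: dict = {}
            for key, value in raw.items():
                if key in _MANIFEST_FLOATS:
                    record[key] = float(value)
                elif key in ("pathway_id", "name"):
                    record[key] = value
                else:
                    record[key] = int(value)
            records.append(record)
    return records


def scores_with_mean(n: int, mean: float) -> list[int]:
    """Construct an integer score multiset of size ``n`` with exact mean.

    Used to realize a published (N, mean) pair as individual publication
    records: ``n x mean`` must be (numerically) an integer and the scores
    must fit the 1..3 supporting range.
    """
    if n == 0:
        return []
    total = round(mean * n)
    if abs(total - mean * n) > 1e-9:
        raise ValidationError(f"mean {mean} is not realizable over {n} records")
    base, extra = divmod(total, n)
    scores = [base + 1] * extra + [base] * (n - extra)
    if any(not 1 <= s <= 3 for s in scores):
        raise ValidationError(
            f"(n={n}, mean={mean}) needs scores outside the 1..3 rubric"
        )
    return scores


def table2_fixture(path: str | Path) -> Path:
    """Write the synthetic literature CSV realizing the published worked example.

    For each of the 20 candidate pathways this emits exactly N publication
    records whose integer scores average to the published mean (e.g. 26
    records averaging 2.5 as 13 threes + 13 twos); pathways with N = 0
    emit none. One carbon-metabolism record is marked as reattributed from
    the umbrella "Metabolic pathways" hit, as the published table's
    provenance rule describes. Publication ids are synthetic placeholders.
    """
    path = Path(path)
    pub = 0
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["pathway", "publication_id", "evidence_score", "original_pathway"])
        for name, n, mean in CANDIDATE_PATHWAY_LITERATURE:
            for i, score in enumerate(scores_with_mean(n, mean)):
                pub += 1
                original = (
                    "Metabolic pathways"
                    if name == "Carbon metabolism" and i == 0
                    else ""
                )
                writer.writerow([name, f"SYN:{pub:04d}", score, original])
    return path


def random_config(seed: int) -> SynthConfig:
    """A randomized, always-realizable config for round-trip recovery tests.

    Gene counts are multiples of ten and fractions multiples of 0.1, so
    fraction-to-count conversion is exact and the band validator never
    fires; everything else (pathway count, KO totals, publication lists)
    varies with the seed.
    """
    rng = random.Random(seed)
    n_pathways = rng.randint(2, 5)
    pathways = []
    for i in range(n_pathways):
        gene_count = rng.choice((10, 20, 30))
        pathways.append(
            SynthPathwaySpec(
                pathway_id=f"ko{10 + i:03d}10",
                name=f"Synthetic pathway {i + 1}",
                ko_total=rng.choice((gene_count // 2, gene_count, gene_count * 2,
                                     gene_count * 4)),
                gene_count=gene_count,
                bp_fraction=rng.randint(0, 10) / 10,
                phi_fraction=rng.randint(0, 10) / 10,
                publications=tuple(
                    rng.randint(0, 3) for _ in range(rng.randint(0, 12))
                ),
            )
        )
    return SynthConfig(
        pathways=tuple(pathways),
        n_unmapped_proteins=rng.randint(0, 15),
        seed=seed,
    )
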