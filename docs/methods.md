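# Methods

## The scoring framework

`pathprio` scores each candidate KEGG pathway of an annotated proteome on
four evidence dimensions and ranks pathways by their summed score. The
framework assumes a finished functional annotation (eggNOG-mapper style),
a homology screen of the proteome against PHI-base, and a human-curated
literature table; it performs no annotation, alignment or retrieval
itself. The candidate set is the top-N pathways by annotated protein
count (default N = 20) — prioritization is only meaningful among pathways
with substantial proteome representation.

**Protein coverage** (0–2 pts) = Gene Count / KO Total. Gene Count is the
number of annotated proteins mapped to the pathway, counting each protein
once per pathway regardless of how many of its KOs belong to it. KO Total
comes from the pathway reference table and is the number of KO entries
KEGG defines for the pathway, so coverage above 1 is meaningful (paralog
expansion) and is preserved, not clipped. A KO Total of 0 (pathway absent
from the reference) yields coverage 0 with a warning rather than an
error, so one missing reference row cannot abort a run.

**GO-BP support** (0–2 pts) = n_bp / n_total, where n_bp counts pathway
proteins carrying at least one GO term in the Biological Process
namespace and n_total is the pathway's Gene Count. GO terms absent from
the supplied namespace map count as non-BP; this is deliberately
conservative and can only lower BP coverage, never inflate it.

**PHI-base virulence support** (0–3 pts) = n_phi / n_total. A protein
counts toward n_phi if it has at least one BLASTp hit against PHI-base
passing e-value ≤ 1e-5 and identity ≥ 30% (the published method names
only the search tool, so these conventional homology-screening defaults
are used; both are CLI/config options). Only hit/no-hit per protein
matters — no bitscore ranking, no PHI phenotype classes. Queries absent
from the annotation table are logged and dropped, because all coverage
denominators come from the annotation table.

**Literature support** (0–3 pts, continuous) = mean evidence score × G(N).
Each publication is scored 0–3 (3 = functional validation by
knockout/overexpression, 2 = mechanistic association, 1 = expression-only
evidence, 0 = no support). Publications scored 0 are excluded from both
the mean and the count N: N is the number of *supporting* publications,
and the published per-pathway table is only coherent under this reading
(unsupported pathways print N = 0, mean 0). The breadth coefficient
G(N) ∈ {0, 0.4, 0.6, 0.8, 1.0} steps up at N = 1, 2, 5, 10 and discounts
means derived from thin literatures. A publication whose primary hit is
an umbrella pathway may be reattributed to a specific sub-pathway; the
original hit is kept in the record's `original_pathway` field as
provenance and has no effect on arithmetic. Full precision is kept
internally; reports round to two decimals (e.g. 2.2 × 0.8 prints as
1.76).

## Binning and aggregation choices

All coverage bands are closed on the left of their upper edge: coverage
exactly at an edge (0.2, 0.5, 0.4, 0.8, 0.3, 0.6) takes the higher score.
The PHI dimension additionally distinguishes "no hits" (0 pts) from "any
hits below 0.3 coverage" (1 pt). The total is the unweighted sum of the
four dimension scores, bounded by 10; the published account describes
ranking by "highest cumulative support" without writing the aggregation
formula, and a plain sum of the already-weighted dimensions (2+2+3+3) is
the only aggregation consistent with the stated weighting rationale. The
literature dimension enters the sum as its continuous value rather than
re-binned to an integer, since the published per-pathway finals are
continuous and no re-binning rule exists. Ranking ties are broken by PHI
score descending, then literature score descending, then pathway name
ascending — direct virulence evidence first, then alphabetic determinism;
the chain makes ranking a total order, so input order never matters.

Bin edges live in `ThresholdConfig` and can be overridden from YAML, but
the defaults are the published rubric and everything documented here
assumes them.

## Synthetic data

The generator (`pathprio.synth`) emulates the five input files with
*constructed*, not sampled, ground truth: a pathway spec'd with
`gene_count` g, `bp_fraction` b, `phi_fraction` f yields exactly g
annotation rows for that pathway, exactly round(b·g) of them with a BP GO
term, and exactly round(f·g) of them as BLAST queries whose hits pass the
default cutoffs. Fraction-to-count conversion rounds half up, and the
config validator rejects specs where that rounding would move the
realized coverage across a scoring edge, so the manifest's promised
scores are always attainable. Seeded randomness touches only nuisance
structure: protein id shuffling, e-values and identities, decoy BLAST
rows that fail the e-value cutoff, and optional unmapped proteins that
stress the whole-proteome denominators. Every bundle carries a manifest
of expected coverages and scores computed by independent in-module band
arithmetic (deliberately not by calling the scoring module), so
end-to-end recovery tests compare two separate derivations.

What the generator does **not** emulate: real protein sequences, orthology
inference noise, annotation errors, partial or ragged emapper columns
beyond the "-" convention, multi-pathway protein membership, or biased
PHI-base representation. Passing the recovery tests therefore shows the
pipeline's arithmetic and plumbing are exact, not that the framework's
biological rankings are robust to annotation noise — the published
discussion itself flags database and literature bias as the method's main
limitation.

`table2_fixture` realizes the published 20-pathway literature table as
individual records: each (N, mean) pair becomes an integer score multiset
of size N with exactly that mean (e.g. 26 publications averaging 2.5 as
13 threes + 13 twos). Publication ids are synthetic placeholders; the
file is named `literature_synthetic.csv` accordingly.

## Numerical and degenerate-input conventions

- Ratios with zero denominators (empty pathway, empty proteome, KO Total
  0) are defined as 0, with a warning where it indicates likely input
  trouble.
- The machine-readable scores TSV stores floats at full `repr` precision
  so re-reading reproduces the ranked table exactly; two-decimal rounding
  is applied only in the figure companion TSVs, which are the display
  artifacts.
- Figures are deterministic given the table, and every number shown in a
  figure is also present in its companion TSV; tests assert on the TSVs,
  never on pixels.
- Parsers fail loudly with file/row context (duplicate protein or pathway
  ids, out-of-rubric evidence scores, malformed BLAST rows, unknown GO
  namespaces); empty-but-well-formed inputs parse to empty results with a
  warning.

## Test-suite problem sizes

The acceptance-level checks run at desk scale: the 20-pathway literature
worked example, a 10,517-protein synthetic annotation set for the KO
coverage summary, boundary and property tests over the binning functions
(hypothesis, derandomized), and 50 seeded synthetic studies of 2–5
pathways with 10–30 genes each for exact end-to-end recovery. The whole
suite completes in a few seconds on one CPU.
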