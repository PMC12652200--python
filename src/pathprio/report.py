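"""Ranking, tabular output and deterministic figure rendering.

Scored pathways are ranked descending by total score, with ties broken by
PHI score (direct virulence evidence first), then literature score, then
pathway name — a total order, so permuting the input never changes the
output. Every figure is backed by a companion TSV carrying the same
numbers: the TSVs are the testable artifacts, pixel output is not.

The machine-readable scores TSV stores floats at full (repr) precision so
that re-reading it reproduces the ranked table exactly; the figure
companion TSVs round to two decimals for display.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .scoring import DimensionScores, ThresholdConfig

#: Column layout of the machine-readable scores TSV.
SCORE_COLUMNS = (
    "rank",
    "pathway_id",
    "name",
    "protein_coverage",
    "protein_score",
    "bp_coverage",
    "bp_score",
    "phi_coverage",
    "phi_score",
    "lit_n",
    "lit_mean",
    "lit_g",
    "literature_score",
    "total",
)

_FLOAT_FIELDS = {
    "protein_coverage",
    "bp_coverage",
    "phi_coverage",
    "lit_mean",
    "lit_g",
    "literature_score",
    "total",
}
_INT_FIELDS = {"rank", "protein_score", "bp_score", "phi_score", "lit_n"}

#: Figure dimension labels and the DimensionScores fields behind them.
HEATMAP_DIMENSIONS = (
    ("Protein coverage", "protein_score"),
    ("GO-BP support", "bp_score"),
    ("PHI-base", "phi_score"),
    ("Literature", "literature_score"),
)


@dataclass(frozen=True)
class RankedTable:
    """Pathways in final priority order; rank i+1 is ``rows[i]``."""

    rows: tuple[DimensionScores, ...]

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def names(self) -> list[str]:
        return [row.name for row in self.rows]


def _rank_key(row: DimensionScores) -> tuple:
    return (-row.total, -row.phi_score, -row.literature_score, row.name)


def rank_pathways(scores: Sequence[DimensionScores]) -> RankedTable:
    """Order pathways by total desc; ties by PHI desc, literature desc, name asc."""
    return RankedTable(rows=tuple(sorted(scores, key=_rank_key)))


def write_score_matrix(table: RankedTable, path: str | Path) -> Path:
    """Write the ranked score table as a TSV (full float precision).

    The file is a pure function of the table: no timestamps, stable column
    order, so identical inputs give byte-identical files.
    """
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(SCORE_COLUMNS)
        for rank, row in enumerate(table.rows, start=1):
            record = {"rank": rank, **row.__dict__}
            writer.writerow(
                [repr(record[col]) if col in _FLOAT_FIELDS else record[col]
                 for col in SCORE_COLUMNS]
            )
    return path


def read_score_matrix(path: str | Path) -> RankedTable:
    """Re-read a scores TSV written by :func:`write_score_matrix`."""
    path = Path(path)
    rows: list[DimensionScores] = []
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for record in reader:
            kwargs = {}
            for key, value in record.items():
                if key == "rank":
                    continue
                if key in _FLOAT_FIELDS:
                    kwargs[key] = float(value)
                elif key in _INT_FIELDS:
                    kwargs[key] = int(value)
                else:
                    kwargs[key] = value
            rows.append(DimensionScores(**kwargs))
    return RankedTable(rows=tuple(rows))


def _write_display_tsv(
    path: Path, header: Sequence[str], rows: Sequence[Sequence]
) -> None:
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for row in rows:
            writer.writerow(
                [f"{v:.2f}" if isinstance(v, float) else v for v in row]
            )


def render_heatmap(
    table: RankedTable,
    path: str | Path,
    cfg: ThresholdConfig = ThresholdConfig(),
) -> tuple[Path, Path]:
    """Render the four-dimension score heatmap plus its companion matrix TSV.

    Rows are pathways in ranked order, columns the four dimensions. Each
    column's color scale is fixed over [0, that dimension's point cap] so
    renders are comparable across runs; cell values are printed. Returns
    (image path, matrix TSV path).
    """
    if len(table) == 0:
        raise ValueError("cannot render a heatmap for an empty table")
    path = Path(path)
    labels = [label for label, _ in HEATMAP_DIMENSIONS]
    maxima = np.array(
        [cfg.protein_max, cfg.bp_max, cfg.phi_max, cfg.literature_max],
        dtype=float,
    )
    values = np.array(
        [[getattr(row, attr) for _, attr in HEATMAP_DIMENSIONS]
         for row in table.rows],
        dtype=float,
    )

    matrix_path = path.with_name(path.stem + "_matrix.tsv")
    _write_display_tsv(
        matrix_path,
        ["pathway", *labels],
        [[row.name, *map(float, vals)] for row, vals in zip(table.rows, values)],
    )

    fig, ax = plt.subplots(
        figsize=(7, max(2.0, 0.38 * len(table) + 1.2))
    )
    # normalize each column by its point cap so one [0, 1] color scale serves all
    im = ax.imshow(values / maxima, cmap="YlOrRd", vmin=0.0, vmax=1.0, aspect="auto")
    ax.set_xticks(range(len(labels)), labels, rotation=30, ha="right")
    ax.set_yticks(range(len(table)), table.names)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            ax.text(
                j, i, f"{values[i, j]:.2f}".rstrip("0").rstrip("."),
                ha="center", va="center", fontsize=8,
                color="black" if values[i, j] / maxima[j] < 0.6 else "white",
            )
    fig.colorbar(im, ax=ax, label="score / dimension max")
    ax.set_title("Pathway priority scores by evidence dimension")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path, matrix_path


def render_top_counts(
    counts: Sequence[tuple[str, int]],
    path: str | Path,
    title: str = "Top categories by annotated protein count",
) -> tuple[Path, Path]:
    """Render a horizontal bar chart of top categories plus a companion TSV."""
    if not counts:
        raise ValueError("cannot render a bar chart for an empty list")
    path = Path(path)
    tsv_path = path.with_name(path.stem + ".tsv")
    _write_display_tsv(tsv_path, ["category", "protein_count"], list(counts))

    names = [name for name, _ in counts]
    values = [count for _, count in counts]
    fig, ax = plt.subplots(figsize=(7, max(2.0, 0.32 * len(counts) + 1.0)))
    positions = range(len(counts))
    ax.barh(positions, values, color="#4878a8")
    ax.set_yticks(positions, names)
    ax.invert_yaxis()  # largest on top
    ax.set_xlabel("annotated proteins")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path, tsv_path
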