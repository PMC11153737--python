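"""Input tables, validation and the CPM low-expression filter.

Three plain-text inputs drive the pipeline: a gene x sample expression
matrix (TSV, genes in rows), a sample -> group label table (TSV) and an
undirected protein-protein interaction edge list in the STRING
physical-links dialect (whitespace separated, optional score column).
All three must share one gene-identifier namespace; an optional two-column
mapping can be applied to the PPI to translate protein ids to gene symbols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Return the unordered gene pair in canonical (lexicographic) order."""
    if a == b:
        raise ValueError(f"self-pair {a!r} has no canonical form")
    return (a, b) if a < b else (b, a)


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance table.

    ``data`` is a pandas DataFrame indexed by gene id with sample-id columns;
    ``unit`` tags the scale ("counts", "cpm" or "normalized"). Counts must be
    finite and non-negative.
    """

    data: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in {"counts", "cpm", "normalized"}:
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            raise ValueError("expression values must all be finite")
        if self.unit == "counts" and (values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class GroupLabels:
    """Sample -> group assignment with a designated reference (normal) group."""

    assignments: dict[str, str]
    reference_group: str

    def __post_init__(self) -> None:
        if self.reference_group not in set(self.assignments.values()):
            raise ValueError(
                f"reference group {self.reference_group!r} has no samples in the label table"
            )

    @property
    def groups(self) -> list[str]:
        """Non-reference group names in sorted order."""
        return sorted(set(self.assignments.values()) - {self.reference_group})

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == group]

    @property
    def reference_samples(self) -> list[str]:
        return self.samples_in(self.reference_group)

    def subset(self, samples: Iterable[str]) -> "GroupLabels":
        keep = {s: self.assignments[s] for s in samples if s in self.assignments}
        return GroupLabels(keep, self.reference_group)

    def restrict_to(self, matrix: ExpressionMatrix) -> "GroupLabels":
        """Drop labelled samples missing from the matrix (with a warning) and
        check the invariants needed downstream (reference group >= 3 samples,
        every non-reference group non-empty)."""
        present = set(matrix.sample_ids)
        missing = [s for s in self.assignments if s not in present]
        if missing:
            logger.warning(
                "%d labelled sample(s) absent from the expression matrix and excluded: %s",
                len(missing), missing[:5],
            )
        out = self.subset(s for s in self.assignments if s in present)
        if len(out.reference_samples) < 3:
            raise ValueError(
                "reference group needs >= 3 samples to define Pearson correlations, "
                f"got {len(out.reference_samples)}"
            )
        if not out.groups:
            raise ValueError("no non-reference group present")
        return out


@dataclass
class PPINetwork:
    """Undirected protein-protein interaction edge set.

    Pairs are stored once, in canonical order, without self-loops; ``scores``
    optionally carries a non-negative confidence per edge.
    """

    edges: set[Pair]
    scores: dict[Pair, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a > b:
                raise ValueError(f"pair ({a!r}, {b!r}) not in canonical order")

    def __contains__(self, pair: Pair) -> bool:
        return pair in self.edges

    def __len__(self) -> int:
        return len(self.edges)

    def restrict_to_genes(self, genes: Iterable[str]) -> "PPINetwork":
        keep = set(genes)
        edges = {e for e in self.edges if e[0] in keep and e[1] in keep}
        return PPINetwork(edges, {e: s for e, s in self.scores.items() if e in edges})


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_matrix(path, unit: str = "counts") -> ExpressionMatrix:
    """Read a TSV expression table: first column gene ids, header sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        numeric = df.astype(float)
    except ValueError:
        # locate the offending cell for a useful error message
        for gene, row in df.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"malformed numeric cell at gene {gene!r}, sample {sample!r}: {cell!r}"
                    ) from None
        raise
    return ExpressionMatrix(numeric, unit=unit)


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    m.data.to_csv(path, sep="\t")


_HEADER_TOKENS = {"protein1", "protein2", "node1", "node2", "gene1", "gene2",
                  "combined_score", "score"}


def read_ppi_edges(path, score_min: float = 0.0,
                   id_map: Mapping[str, str] | None = None) -> PPINetwork:
    """Read a STRING-style physical-links edge list.

    Rows are whitespace-separated ``id1 id2 [score]``; a single header row is
    auto-detected. Self-loops are dropped, duplicate/reversed rows collapse to
    one canonical pair, and edges scoring below ``score_min`` are discarded.
    ``id_map`` optionally translates identifiers (e.g. STRING protein ids to
    gene symbols) before canonicalization; unmapped ids pass through.
    """
    edges: set[Pair] = set()
    scores: dict[Pair, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected >= 2 columns, got {len(fields)}")
            if lineno == 1 and _looks_like_header(fields):
                continue
            a, b = fields[0], fields[1]
            score = 0.0
            if len(fields) >= 3:
                try:
                    score = float(fields[2])
                except ValueError:
                    raise ValueError(
                        f"line {lineno}: malformed score {fields[2]!r}"
                    ) from None
            if id_map is not None:
                a = id_map.get(a, a)
                b = id_map.get(b, b)
            if a == b:
                continue
            if score < score_min:
                continue
            pair = canonical_pair(a, b)
            edges.add(pair)
            scores[pair] = max(score, scores.get(pair, 0.0))
    return PPINetwork(edges, scores)


def _looks_like_header(fields: list[str]) -> bool:
    if any(f.lower() in _HEADER_TOKENS for f in fields):
        return True
    if len(fields) >= 3:
        try:
            float(fields[2])
        except ValueError:
            return True
    return False


def write_ppi_edges(ppi: PPINetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for a, b in sorted(ppi.edges):
            fh.write(f"{a} {b} {ppi.scores.get((a, b), 0):g}\n")


def read_group_labels(path, reference_group: str) -> GroupLabels:
    """Read a two-column TSV of sample_id, group (optional header)."""
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected 2 columns")
            sample, group = fields[0].strip(), fields[1].strip()
            if lineno == 1 and group.lower() in {"group", "label", "stage", "subtype"}:
                continue
            if sample in assignments and assignments[sample] != group:
                raise ValueError(
                    f"sample {sample!r} listed with conflicting groups "
                    f"{assignments[sample]!r} and {group!r}"
                )
            assignments[sample] = group
    if reference_group not in set(assignments.values()):
        raise ValueError(
            f"reference group {reference_group!r} absent from the label table"
        )
    return GroupLabels(assignments, reference_group)


def write_group_labels(labels: GroupLabels, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s, g in labels.assignments.items():
            fh.write(f"{s}\t{g}\n")


# ---------------------------------------------------------------------------
# CPM filter


def cpm(m: ExpressionMatrix) -> pd.DataFrame:
    """Counts-per-million table; errors on a zero library size."""
    lib = m.data.sum(axis=0)
    zero = lib.index[lib <= 0].tolist()
    if zero:
        raise ValueError(f"zero library size for sample(s): {zero}")
    return m.data / lib * 1e6


def log_cpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(CPM + 1) transform; the correlation substrate for count input.

    Pearson correlations on raw counts are confounded by the per-sample
    library-size factor (a shared multiplier correlates every gene pair), so
    counts are library-normalized and log-transformed before any PCC is
    computed, matching standard RNA-seq practice.
    """
    return ExpressionMatrix(np.log2(cpm(m) + 1.0), unit="normalized")


def cpm_filter(m: ExpressionMatrix, threshold: float = 2.0,
               fraction: float = 0.5) -> ExpressionMatrix:
    """Drop low-expression genes.

    A gene is retained iff its CPM is strictly greater than ``threshold`` in
    at least ``fraction`` of the samples (real-valued comparison, so 1 of 2
    samples passes fraction 0.5). Retained rows keep their original values
    and the sample set is unchanged.
    """
    if m.unit != "counts":
        raise ValueError(f"CPM filtering applies to counts, matrix unit is {m.unit!r}")
    table = cpm(m)
    n_samples = table.shape[1]
    passing = (table > threshold).sum(axis=1)
    keep = passing >= fraction * n_samples
    logger.info("CPM filter: %d of %d genes retained", int(keep.sum()), len(keep))
    return ExpressionMatrix(m.data.loc[keep], unit=m.unit)
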