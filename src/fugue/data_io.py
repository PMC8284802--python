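"""Readers, writers and the validated in-memory data model.

All genomic intervals use the BED-native convention: 0-based, half-open
``[start, end)``.  Gene identifiers are opaque strings matched exactly
(case-sensitive) across files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = {"+", "-", "."}


class DataError(ValueError):
    """Raised when an input file violates the format or the data model."""


@dataclass
class ExpressionMatrix:
    """Genes x samples of nonnegative normalized expression (e.g. TPM).

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    sample_tissue
        Series mapping each sample id to its tissue label.
    """

    values: pd.DataFrame
    sample_tissue: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene ids: {dups[:5]}")
        if v.columns.duplicated().any():
            raise DataError("duplicate sample ids")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise DataError("non-numeric expression values")
        if not np.isfinite(arr).all():
            raise DataError("non-finite expression values")
        if (arr < 0).any():
            raise DataError("negative expression values")
        unmapped = [s for s in v.columns if s not in self.sample_tissue.index]
        if unmapped:
            raise DataError(f"samples missing from tissue map: {unmapped[:5]}")
        self.sample_tissue = self.sample_tissue.reindex(v.columns)
        counts = self.sample_tissue.value_counts()
        small = counts[counts < 2]
        if len(small):
            raise DataError(
                f"tissues with fewer than 2 samples: {small.index.tolist()}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def tissues(self) -> list[str]:
        return sorted(self.sample_tissue.unique())

    def tissue_samples(self, tissue: str) -> pd.Index:
        samples = self.sample_tissue.index[self.sample_tissue == tissue]
        if len(samples) == 0:
            raise DataError(f"unknown tissue: {tissue!r}")
        return samples


@dataclass
class GlobalNetwork:
    """Undirected simple protein-interaction graph over gene ids."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise DataError(f"self-loops present: {loops[:5]}")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}


@dataclass
class GeneAnnotation:
    """One genomic interval per gene: chrom, [start, end), strand."""

    table: pd.DataFrame  # index gene_id; columns chrom, start, end, strand

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            raise DataError("duplicate gene ids in annotation")
        if (t["start"] >= t["end"]).any():
            bad = t.index[t["start"] >= t["end"]].tolist()
            raise DataError(f"start >= end for genes: {bad[:5]}")
        bad_strand = set(t["strand"]) - STRANDS
        if bad_strand:
            raise DataError(f"invalid strand values: {bad_strand}")
        self.table = t.sort_values(["chrom", "start"])

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class TadSet:
    """Non-overlapping topologically associating domains, [start, end)."""

    intervals: pd.DataFrame  # columns chrom, start, end

    def __post_init__(self) -> None:
        t = self.intervals
        if (t["start"] >= t["end"]).any():
            raise DataError("TAD with start >= end")
        t = t.sort_values(["chrom", "start"]).reset_index(drop=True)
        for chrom, grp in t.groupby("chrom", sort=False):
            ends = grp["end"].to_numpy()[:-1]
            starts = grp["start"].to_numpy()[1:]
            if (starts < ends).any():
                raise DataError(f"overlapping TADs on {chrom}")
        self.intervals = t

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class GeneClassFlags:
    """TF / kinase membership; genes absent from both sets carry false flags."""

    tfs: frozenset[str] = field(default_factory=frozenset)
    kinases: frozenset[str] = field(default_factory=frozenset)

    def is_tf(self, gene: str) -> bool:
        return gene in self.tfs

    def is_kinase(self, gene: str) -> bool:
        return gene in self.kinases


# ---------------------------------------------------------------------------
# readers


def read_expression(matrix_path, tissue_map_path) -> ExpressionMatrix:
    """Read a genes x samples matrix (TSV or GCT 1.2) plus a sample→tissue map.

    TSV layout: first column gene id, header row of sample ids.  GCT 1.2:
    ``#1.2`` version line, dimensions line, then Name/Description + samples.
    Every sample in the matrix must appear in the two-column tissue map.
    """
    with open(matrix_path) as fh:
        first = fh.readline().rstrip("\n")
    if first.startswith("#1.2"):
        values = _read_gct(matrix_path)
    else:
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    tmap = pd.read_csv(
        tissue_map_path, sep="\t", header=None, names=["sample", "tissue"],
        dtype=str, comment="#",
    )
    if tmap["sample"].duplicated().any():
        raise DataError("duplicate samples in tissue map")
    sample_tissue = tmap.set_index("sample")["tissue"]
    return ExpressionMatrix(values=values.astype(float), sample_tissue=sample_tissue)


def _read_gct(path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise DataError(f"unsupported GCT version line: {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise DataError("malformed GCT dimensions line")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        body = pd.read_csv(fh, sep="\t")
    if body.shape[0] != n_genes or body.shape[1] - 2 != n_samples:
        raise DataError(
            f"GCT dimensions line ({n_genes} x {n_samples}) disagrees with body "
            f"({body.shape[0]} x {body.shape[1] - 2})"
        )
    body = body.set_index(body.columns[0])
    return body.drop(columns=body.columns[0])  # drop Description


def read_edge_list(path) -> GlobalNetwork:
    """Read a two-column TSV of interacting gene symbols.

    Extra columns (e.g. confidence scores) are ignored.  Duplicate and
    reversed edges are collapsed; self-loops are dropped with a logged count.
    """
    g = nx.Graph()
    n_loops = 0
    n_rows = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[1]:
                raise DataError(f"line {line_no}: expected two columns")
            a, b = parts[0], parts[1]
            n_rows += 1
            if a == b:
                n_loops += 1
                g.add_node(a)
                continue
            g.add_edge(a, b)
    if n_rows == 0:
        raise DataError(f"empty edge list: {path}")
    if n_loops:
        logger.info("dropped %d self-loop(s) from %s", n_loops, path)
    return GlobalNetwork(graph=g)


def read_bed(path, kind: str = "genes") -> GeneAnnotation | TadSet:
    """Read BED3/BED4 intervals as a gene annotation or a TAD set.

    ``kind='genes'`` requires the 4th (name) column and returns a
    :class:`GeneAnnotation`; ``kind='tads'`` returns a :class:`TadSet` and
    rejects overlapping intervals.
    """
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"line {line_no}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise DataError(f"line {line_no}: start >= end ({start} >= {end})")
            name = parts[3] if len(parts) > 3 else None
            strand = parts[5] if len(parts) > 5 and parts[5] in STRANDS else "."
            rows.append((chrom, start, end, name, strand))
    if kind == "tads":
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
        return TadSet(intervals=df[["chrom", "start", "end"]])
    if kind != "genes":
        raise ValueError(f"kind must be 'genes' or 'tads', got {kind!r}")
    if any(r[3] is None for r in rows):
        raise DataError("gene annotation BED requires a 4th (name) column")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "strand"])
    return GeneAnnotation(table=df.set_index("gene_id"))


def read_gmt(path) -> dict[str, set[str]]:
    """Read named gene sets in GMT format (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"line {line_no}: GMT rows need name, description, members")
            name = parts[0]
            if name in sets:
                raise DataError(f"duplicate gene-set name: {name!r}")
            sets[name] = {m for m in parts[2:] if m}
    return sets


def read_class_flags(path) -> GeneClassFlags:
    """Read TF/kinase membership from a GMT with sets named 'TF' and 'Kinase'."""
    sets = read_gmt(path)
    return GeneClassFlags(
        tfs=frozenset(sets.get("TF", set())),
        kinases=frozenset(sets.get("Kinase", set())),
    )


# ---------------------------------------------------------------------------
# score table serialization

SCORE_COLUMNS = ["gene", "tissue", "label", "score", "normalized_rank"]


def write_scores(score_table: pd.DataFrame, path) -> None:
    """Write a score table as TSV in deterministic order.

    Rows are sorted by tissue, then descending score, then gene id
    (the tie-break), so identical tables serialize byte-identically.
    """
    df = score_table[SCORE_COLUMNS].copy()
    df = df.sort_values(
        ["tissue", "score", "gene"], ascending=[True, False, True]
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


def read_scores(path) -> pd.DataFrame:
    """Parse a TSV written by :func:`write_scores`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "tissue": str, "label": str})
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"score table missing columns: {sorted(missing)}")
    return df
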