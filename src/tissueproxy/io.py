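"""Readers and writers for the plain-text formats the tool exchanges.

GCT 1.2 for expression matrices (the dialect GTEx median-TPM releases
use), TSV for gene lists, phenotype-to-gene annotation tables, PPI edge
lists, GO annotations and stage matrices.  Readers reject structural
corruption (wrong version literal, dimension mismatches, non-numeric
cells, malformed rows) with the offending line number rather than
silently repairing it, and are agnostic to LF/CRLF line endings.  Writers
round-trip values exactly.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .core import ExpressionMatrix, GeneSet, SampleMatrix
from .enrichment import PpiNetwork
from .stages import StageMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GctParseError",
    "PhenotypeAnnotationTable",
    "read_gct",
    "write_gct",
    "read_gene_list",
    "read_phenotype_table",
    "select_phenotype",
    "read_ppi_edges",
    "read_go_annotations",
    "read_sample_map",
    "read_stage_matrix",
    "write_stage_matrix",
]

GCT_VERSION = "#1.2"


class GctParseError(ValueError):
    """Structural problem in a GCT file; the message carries the line number."""


def _lines(path) -> list[str]:
    # splitlines handles both LF and CRLF
    return Path(path).read_text().splitlines()


def read_gct(
    path,
    level: str = "gene",
    feature_to_gene: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Parse a GCT 1.2 expression matrix.

    Line 1 must be the literal ``#1.2`` (1.3 files are rejected
    explicitly, not half-parsed); line 2 declares rows and columns; line 3
    is the header (``Name``, ``Description``, then tissue labels); the
    body is tab-separated.  Declared dimensions must match the content
    exactly, feature identifiers must be unique, and every data cell must
    be numeric -- violations raise :class:`GctParseError` with the line
    number.  The Description column is preserved as metadata.
    """
    lines = _lines(path)
    if not lines:
        raise GctParseError(f"{path}: empty file")
    version = lines[0].strip()
    if version != GCT_VERSION:
        if version.startswith("#1.3"):
            raise GctParseError(
                f"{path}, line 1: GCT 1.3 is not supported; expected version literal '#1.2'"
            )
        raise GctParseError(
            f"{path}, line 1: expected version literal '#1.2', found {version!r}"
        )
    if len(lines) < 3:
        raise GctParseError(f"{path}: truncated file (need version, dimensions, header)")
    dims = lines[1].split("\t")
    try:
        n_rows, n_cols = (int(d) for d in dims[:2])
        if len(dims) != 2:
            raise ValueError
    except ValueError:
        raise GctParseError(
            f"{path}, line 2: expected two tab-separated integers, found {lines[1]!r}"
        ) from None
    header = lines[2].split("\t")
    if len(header) != n_cols + 2:
        raise GctParseError(
            f"{path}, line 3: header has {len(header) - 2} data columns, "
            f"but line 2 declares {n_cols}"
        )
    tissues = header[2:]
    body = [(i + 4, ln) for i, ln in enumerate(lines[3:]) if ln.strip() != ""]
    if len(body) != n_rows:
        raise GctParseError(
            f"{path}: line 2 declares {n_rows} rows but the body contains {len(body)}"
        )
    ids, descriptions, data = [], {}, []
    for lineno, ln in body:
        fields = ln.split("\t")
        if len(fields) != n_cols + 2:
            raise GctParseError(
                f"{path}, line {lineno}: expected {n_cols + 2} fields, found {len(fields)}"
            )
        ids.append(fields[0])
        descriptions[fields[0]] = fields[1]
        row = []
        for j, cell in enumerate(fields[2:], start=3):
            try:
                row.append(float(cell))
            except ValueError:
                raise GctParseError(
                    f"{path}, line {lineno}, column {j}: non-numeric cell {cell!r}"
                ) from None
        data.append(row)
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise GctParseError(f"{path}: duplicate feature identifiers {dup[:5]}")
    df = pd.DataFrame(data, index=ids, columns=tissues)
    return ExpressionMatrix(
        df, level=level, feature_to_gene=feature_to_gene, description=descriptions
    )


def write_gct(matrix: ExpressionMatrix, path) -> None:
    """Write GCT 1.2; the numeric round trip through read_gct is exact."""
    df = matrix.df
    if df.empty:
        raise ValueError("refusing to write an empty expression matrix")
    desc = matrix.description or {}
    with open(path, "w", newline="\n") as fh:
        fh.write(f"{GCT_VERSION}\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        fh.write("Name\tDescription\t" + "\t".join(df.columns) + "\n")
        for feature, row in zip(df.index, df.to_numpy()):
            cells = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{feature}\t{desc.get(feature, 'na')}\t{cells}\n")


def read_gene_list(path, name: str | None = None) -> GeneSet:
    """One identifier per line (first column if tab-separated).

    Blank lines and ``#`` comments are ignored; duplicates are dropped with
    a warning.  An empty list after filtering is an error.
    """
    entries = []
    for ln in _lines(path):
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        entries.append(ln.split("\t")[0].strip())
    if not entries:
        raise ValueError(f"{path}: no gene identifiers found")
    return GeneSet.from_iterable(name or Path(path).stem, entries)


@dataclass(frozen=True)
class PhenotypeAnnotationTable:
    """Rows of (phenotype identifier, phenotype name, gene), HPO-style."""

    rows: pd.DataFrame

    def phenotype_labels(self) -> list[str]:
        ids = self.rows["phenotype_id"].unique().tolist()
        names = self.rows["phenotype_name"].unique().tolist()
        return ids + names


def read_phenotype_table(path) -> PhenotypeAnnotationTable:
    """Read a 3-column TSV (with header): phenotype id, name, gene."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=0)
    if df.shape[1] != 3:
        raise ValueError(
            f"{path}: expected exactly 3 columns (phenotype id, name, gene), "
            f"found {df.shape[1]}"
        )
    df.columns = ["phenotype_id", "phenotype_name", "gene"]
    n_before = len(df)
    df = df.drop_duplicates().reset_index(drop=True)
    if len(df) != n_before:
        logger.warning("%s: dropped %d fully duplicated rows", path, n_before - len(df))
    return PhenotypeAnnotationTable(rows=df)


def select_phenotype(table: PhenotypeAnnotationTable, phenotype: str) -> GeneSet:
    """Genes annotated to a phenotype, matched by identifier or by name."""
    df = table.rows
    hit = df[(df["phenotype_id"] == phenotype) | (df["phenotype_name"] == phenotype)]
    if hit.empty:
        close = difflib.get_close_matches(phenotype, table.phenotype_labels(), n=5, cutoff=0.3)
        raise KeyError(
            f"unknown phenotype {phenotype!r}; closest labels: {close or table.phenotype_labels()[:5]}"
        )
    name = hit["phenotype_name"].iloc[0]
    return GeneSet.from_iterable(name, hit["gene"].tolist())


def _tsv_rows(path, n_fields: int):
    for lineno, ln in enumerate(_lines(path), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        fields = [f.strip() for f in ln.split("\t")]
        if len(fields) != n_fields or any(not f for f in fields):
            raise ValueError(
                f"{path}, line {lineno}: expected {n_fields} non-empty tab-separated "
                f"fields, found {ln!r}"
            )
        yield fields


def read_ppi_edges(path) -> PpiNetwork:
    """Two-column TSV of interacting gene pairs.

    Edges are undirected and deduplicated ((a, b) and (b, a) are the same
    edge); self-loops are dropped with a warning.
    """
    edges = set()
    nodes = set()
    n_self = 0
    for a, b in _tsv_rows(path, 2):
        if a == b:
            n_self += 1
            continue
        nodes.update((a, b))
        edges.add((min(a, b), max(a, b)))
    if n_self:
        logger.warning("%s: dropped %d self-loop(s)", path, n_self)
    return PpiNetwork(edges=sorted(edges), nodes=sorted(nodes))


def read_go_annotations(path) -> dict[str, frozenset]:
    """Two-column TSV (gene, GO term) -> gene -> set-of-terms map."""
    out: dict[str, set[str]] = {}
    for gene, term in _tsv_rows(path, 2):
        out.setdefault(gene, set()).add(term)
    return {g: frozenset(t) for g, t in out.items()}


def read_sample_map(path) -> dict[str, str]:
    """Two-column TSV (sample, tissue) -> sample-to-tissue map."""
    out: dict[str, str] = {}
    for sample, tissue in _tsv_rows(path, 2):
        if sample in out and out[sample] != tissue:
            raise ValueError(f"{path}: sample {sample!r} mapped to two tissues")
        out[sample] = tissue
    return out


def read_sample_gct(path, sample_map_path) -> SampleMatrix:
    """A GCT of per-sample TPMs plus a sample-to-tissue TSV."""
    matrix = read_gct(path)
    mapping = read_sample_map(sample_map_path)
    return SampleMatrix(matrix.df, mapping)


def read_stage_matrix(path) -> StageMatrix:
    """Genes-by-stages TSV with a header; column order is the stage order."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return StageMatrix(df)


def write_stage_matrix(m: StageMatrix, path) -> None:
    m.df.to_csv(path, sep="\t", lineterminator="\n")
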