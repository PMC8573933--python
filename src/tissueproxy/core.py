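"""Expression containers and tissue-correlation primitives.

Everything in this package operates on feature-by-tissue matrices of median
TPM (or RPKM) values, the shape in which bulk RNA-seq references such as
GTEx publish their data.  Two conventions run through every analysis:

* a feature (gene or transcript) is called *expressed* in a tissue when its
  median TPM passes an :class:`ExpressionThreshold` (default: TPM >= 1.5);
* similarity between a tissue of interest (TI) and a candidate tissue of
  analysis (TA) is the Pearson correlation of the two tissue columns,
  restricted to a phenotype gene list and to genes passing the threshold.

Correlations that cannot be computed (fewer than three qualifying genes, or
a zero-variance column) are *flagged* as NaN rather than raised, so that
batch scans over many candidate tissues never abort.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionThreshold",
    "DEFAULT_THRESHOLD",
    "GeneSet",
    "ExpressionMatrix",
    "SampleMatrix",
    "CorrelationResult",
    "TissueExpressionSummary",
    "GeneProfile",
    "GENE_SELECTION_RULES",
    "median_per_tissue",
    "filter_expressed",
    "pearson_r",
    "correlate_tissues",
    "gene_profile",
    "saturation_scatter",
]

#: Rules deciding which genes of a list enter a TI-vs-TA correlation:
#: pass the threshold in at least one of the two tissues (default), in the
#: TI only, or in both tissues.
GENE_SELECTION_RULES = ("either_tissue", "ti_only", "both_tissues")


@dataclass(frozen=True)
class ExpressionThreshold:
    """Cutoff deciding whether a feature counts as expressed in a tissue.

    Parameters
    ----------
    value
        TPM (or RPKM) cutoff, strictly positive.  Default 1.5.
    comparator
        ``"ge"`` (expressed when value >= cutoff, the default) or ``"gt"``.
    """

    value: float = 1.5
    comparator: str = "ge"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.value) and self.value > 0):
            raise ValueError(f"threshold value must be finite and > 0, got {self.value}")
        if self.comparator not in ("ge", "gt"):
            raise ValueError(f"comparator must be 'ge' or 'gt', got {self.comparator!r}")

    def passes(self, values) -> np.ndarray:
        """Boolean mask of which ``values`` count as expressed."""
        arr = np.asarray(values, dtype=float)
        return arr >= self.value if self.comparator == "ge" else arr > self.value


DEFAULT_THRESHOLD = ExpressionThreshold()


@dataclass(frozen=True)
class GeneSet:
    """A named, order-stable list of unique gene identifiers.

    Identifiers are opaque case-sensitive strings (symbols or Ensembl IDs);
    no mapping between identifier schemes is attempted.
    """

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        genes = tuple(str(g) for g in self.genes)
        if not genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(genes)) != len(genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate identifiers")
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "_frozen", frozenset(genes))

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str]) -> "GeneSet":
        """Build a set from an iterable, dropping duplicates (first kept)."""
        seen: dict[str, None] = {}
        n_dup = 0
        for g in genes:
            g = str(g)
            if g in seen:
                n_dup += 1
            else:
                seen[g] = None
        if n_dup:
            logger.warning("gene set %r: dropped %d duplicate identifiers", name, n_dup)
        return cls(name=name, genes=tuple(seen))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: object) -> bool:
        return gene in self.as_set()

    def as_set(self) -> frozenset:
        return self._frozen


def _check_unique(labels, what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dup[:5]}")


def _check_values(values: np.ndarray) -> None:
    if not np.isfinite(values).all():
        raise ValueError("expression values must all be finite")
    if (values < 0).any():
        raise ValueError("expression values must all be >= 0")


class ExpressionMatrix:
    """Non-negative median TPM values, features (rows) by tissues (columns).

    Parameters
    ----------
    values
        DataFrame with feature identifiers as index and tissue labels as
        columns.  All entries must be finite and >= 0.
    level
        ``"gene"`` or ``"transcript"``.
    feature_to_gene
        Required when ``level="transcript"``: maps every transcript
        identifier to its parent gene.
    description
        Optional per-feature free-text annotation (the GCT Description
        column), preserved through I/O round trips.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        *,
        level: str = "gene",
        feature_to_gene: Mapping[str, str] | None = None,
        description: Mapping[str, str] | None = None,
    ) -> None:
        if level not in ("gene", "transcript"):
            raise ValueError(f"level must be 'gene' or 'transcript', got {level!r}")
        df = values.copy()
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        _check_unique(df.index, "feature identifiers")
        _check_unique(df.columns, "tissue labels")
        arr = df.to_numpy(dtype=float)
        _check_values(arr)
        df = pd.DataFrame(arr, index=df.index, columns=df.columns)
        if level == "transcript":
            if feature_to_gene is None:
                raise ValueError("transcript-level matrices require feature_to_gene")
            missing = [f for f in df.index if f not in feature_to_gene]
            if missing:
                raise ValueError(
                    f"{len(missing)} transcripts lack a gene mapping, e.g. {missing[:5]}"
                )
        self._df = df
        self.level = level
        self.feature_to_gene = dict(feature_to_gene) if feature_to_gene is not None else None
        self.description = dict(description) if description is not None else None

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def feature_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def tissue_values(self, tissue: str) -> np.ndarray:
        """Expression column for one tissue (raises listing valid labels)."""
        if tissue not in self._df.columns:
            raise KeyError(
                f"unknown tissue {tissue!r}; available tissues: {self.tissue_ids}"
            )
        return self._df[tissue].to_numpy()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, m = self.shape
        return f"ExpressionMatrix({n} {self.level}s x {m} tissues)"


class SampleMatrix:
    """Per-sample TPM values plus a sample -> tissue assignment.

    Every sample column must map to exactly one tissue; an unmapped sample
    is an error naming the sample, raised at construction.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        sample_to_tissue: Mapping[str, str],
        *,
        level: str = "gene",
        feature_to_gene: Mapping[str, str] | None = None,
    ) -> None:
        df = values.copy()
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        _check_unique(df.index, "feature identifiers")
        _check_unique(df.columns, "sample identifiers")
        _check_values(df.to_numpy(dtype=float))
        mapping = {str(k): str(v) for k, v in sample_to_tissue.items()}
        for sample in df.columns:
            if sample not in mapping:
                raise ValueError(f"sample {sample!r} has no tissue mapping")
        self._df = df.astype(float)
        self.sample_to_tissue = {s: mapping[s] for s in df.columns}
        self.level = level
        self.feature_to_gene = dict(feature_to_gene) if feature_to_gene is not None else None

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def feature_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.columns)

    def tissues(self) -> list[str]:
        """Distinct tissue labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self._df.columns:
            seen.setdefault(self.sample_to_tissue[s], None)
        return list(seen)

    def samples_of(self, tissue: str) -> list[str]:
        return [s for s in self._df.columns if self.sample_to_tissue[s] == tissue]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, m = self._df.shape
        return f"SampleMatrix({n} {self.level}s x {m} samples, {len(self.tissues())} tissues)"


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between a TI and a TA over a gene list.

    ``r`` is NaN (with :attr:`defined` False) when fewer than three genes
    qualify or either column has zero variance.
    """

    ti: str
    ta: str
    r: float
    n_genes: int
    gene_selection_rule: str

    @property
    def defined(self) -> bool:
        return not math.isnan(self.r)


@dataclass(frozen=True)
class TissueExpressionSummary:
    """Per-tissue summary backing a single-gene violin panel."""

    tissue: str
    n_samples: int
    median: float
    standard_deviation: float  # NaN when n_samples < 2
    values: tuple[float, ...]


@dataclass(frozen=True)
class GeneProfile:
    gene: str
    per_tissue: tuple[TissueExpressionSummary, ...]


# ---------------------------------------------------------------------------
# operations


def median_per_tissue(samples: SampleMatrix) -> ExpressionMatrix:
    """Collapse a sample-level matrix to per-tissue medians.

    One output column per distinct tissue (order of first appearance);
    feature order is preserved.  The median of an even number of samples is
    the mean of the two middle order statistics.
    """
    if samples.df.empty:
        raise ValueError("cannot aggregate an empty sample matrix")
    cols = {}
    for tissue in samples.tissues():
        members = samples.samples_of(tissue)
        cols[tissue] = samples.df[members].median(axis=1)
    out = pd.DataFrame(cols, index=samples.df.index)
    return ExpressionMatrix(
        out, level=samples.level, feature_to_gene=samples.feature_to_gene
    )


def filter_expressed(
    matrix: ExpressionMatrix,
    tissue: str,
    threshold: ExpressionThreshold = DEFAULT_THRESHOLD,
) -> set[str]:
    """Features whose value in ``tissue`` passes the expression threshold."""
    col = matrix.tissue_values(tissue)
    mask = threshold.passes(col)
    return {f for f, ok in zip(matrix.feature_ids, mask) if ok}


def pearson_r(x, y) -> float:
    """Pearson correlation r = cov(x, y) / (SDx * SDy).

    Covariance and standard deviations both use the sample (n - 1)
    convention; r is invariant to that choice as long as it is applied
    consistently.  Returns NaN (the undefined flag) for vectors shorter
    than three or with zero variance; raises only on mismatched lengths.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError(f"x and y must be 1-D of equal length, got {xa.shape} vs {ya.shape}")
    n = xa.size
    if n < 3:
        return math.nan
    if np.array_equal(xa, ya) and np.ptp(xa) > 0:
        return 1.0  # identical columns correlate exactly, free of rounding
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    cov = float(xc @ yc) / (n - 1)
    sdx = math.sqrt(float(xc @ xc) / (n - 1))
    sdy = math.sqrt(float(yc @ yc) / (n - 1))
    if sdx == 0.0 or sdy == 0.0:
        return math.nan
    return cov / (sdx * sdy)


def _selection_mask(
    x: np.ndarray,
    y: np.ndarray,
    threshold: ExpressionThreshold,
    rule: str,
) -> np.ndarray:
    if rule not in GENE_SELECTION_RULES:
        raise ValueError(f"unknown gene selection rule {rule!r}; choose from {GENE_SELECTION_RULES}")
    px, py = threshold.passes(x), threshold.passes(y)
    if rule == "either_tissue":
        return px | py
    if rule == "ti_only":
        return px
    return px & py


def correlate_tissues(
    matrix: ExpressionMatrix,
    ti: str,
    ta: str,
    genes: GeneSet,
    threshold: ExpressionThreshold = DEFAULT_THRESHOLD,
    rule: str = "either_tissue",
    log_transform: bool = False,
) -> CorrelationResult:
    """Correlate two tissue columns over the genes of a phenotype list.

    Only genes passing ``threshold`` under ``rule`` (default: expressed in
    at least one of the two tissues) enter the computation.  With
    ``log_transform`` the correlation is computed on log2(TPM + 1) instead
    of raw TPM.
    """
    if ti == ta:
        raise ValueError(f"TI and TA must differ, both are {ti!r}")
    x_all = matrix.tissue_values(ti)
    y_all = matrix.tissue_values(ta)
    present = np.array([f in genes.as_set() for f in matrix.feature_ids], dtype=bool)
    mask = present & _selection_mask(x_all, y_all, threshold, rule)
    n_genes = int(mask.sum())
    x, y = x_all[mask], y_all[mask]
    if log_transform:
        x, y = np.log2(x + 1.0), np.log2(y + 1.0)
    r = pearson_r(x, y) if n_genes >= 3 else math.nan
    if n_genes < 3:
        warnings.warn(
            f"correlation {ti!r} vs {ta!r}: only {n_genes} qualifying genes; r undefined",
            stacklevel=2,
        )
    return CorrelationResult(ti=ti, ta=ta, r=r, n_genes=n_genes, gene_selection_rule=rule)


def gene_profile(samples: SampleMatrix, gene: str) -> GeneProfile:
    """Per-tissue n, median, sample SD and raw values for one gene.

    The SD uses the n - 1 convention and is NaN for single-sample tissues.
    """
    if gene not in samples.df.index:
        raise KeyError(f"unknown gene {gene!r}")
    row = samples.df.loc[gene]
    summaries = []
    for tissue in samples.tissues():
        vals = row[samples.samples_of(tissue)].to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=1)) if vals.size >= 2 else math.nan
        summaries.append(
            TissueExpressionSummary(
                tissue=tissue,
                n_samples=int(vals.size),
                median=float(np.median(vals)),
                standard_deviation=sd,
                values=tuple(float(v) for v in vals),
            )
        )
    return GeneProfile(gene=gene, per_tissue=tuple(summaries))


def saturation_scatter(
    samples: SampleMatrix,
    threshold: ExpressionThreshold = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Expressed-gene count as a function of sample count, per tissue.

    Returns a DataFrame with columns ``tissue``, ``n_samples`` and
    ``n_expressed_genes`` (features whose per-tissue median passes the
    threshold).  Used to judge when an expression reference saturates --
    empirically the count plateaus once a tissue exceeds ~100 samples.
    """
    medians = median_per_tissue(samples)
    rows = []
    for tissue in medians.tissue_ids:
        rows.append(
            {
                "tissue": tissue,
                "n_samples": len(samples.samples_of(tissue)),
                "n_expressed_genes": len(filter_expressed(medians, tissue, threshold)),
            }
        )
    return pd.DataFrame(rows, columns=["tissue", "n_samples", "n_expressed_genes"])
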