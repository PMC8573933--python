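"""Expressed-gene and expressed-transcript overlap between TI and TAs.

Correlation says how *similar* two tissues are; overlap says how many of
the phenotype genes an accessible tissue actually expresses.  With several
TI or TA tissues the at-least-one rule applies: a feature counts as
expressed on a side if it passes the threshold in any tissue of that side.
A phenotype gene expressed in at least one TA is *captured* (testable by
RNA-seq of that TA); one expressed in no TA is *not covered*.  Features in
the input list but absent from the expression matrix are never silently
dropped -- they are reported in ``not_in_matrix``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .core import (
    DEFAULT_THRESHOLD,
    ExpressionMatrix,
    ExpressionThreshold,
    GeneSet,
    filter_expressed,
)

__all__ = [
    "OverlapResult",
    "MAX_VENN_TISSUES",
    "expressed_overlap",
    "transcript_overlap",
    "best_covering_tissue",
    "venn_regions",
]

#: Region decomposition is enumerated for at most this many tissues (2^k
#: regions); beyond it only per-tissue sets, unions and capture statistics
#: are reported.
MAX_VENN_TISSUES = 5


@dataclass(frozen=True)
class OverlapResult:
    """Set algebra of expressed features across TI and TA tissues.

    ``venn_regions`` maps an exclusive region signature -- the frozenset of
    tissues a feature is expressed in -- to that region's features; regions
    are pairwise disjoint and their union is the union of all per-tissue
    expressed sets.  Empty when more than :data:`MAX_VENN_TISSUES` tissues
    are involved.
    """

    input_set: GeneSet
    ti_tissues: tuple[str, ...]
    ta_tissues: tuple[str, ...]
    per_tissue_expressed: Mapping[str, frozenset]
    ti_expressed: frozenset
    ta_expressed: frozenset
    venn_regions: Mapping[frozenset, frozenset]
    captured: frozenset
    not_covered: frozenset
    not_in_ti: frozenset
    not_in_matrix: frozenset
    level: str = "gene"


def venn_regions(per_tissue: Mapping[str, frozenset]) -> dict[frozenset, frozenset]:
    """Exclusive region decomposition of up to MAX_VENN_TISSUES sets.

    Each feature of the union lands in exactly one region, keyed by the
    frozenset of tissues containing it.
    """
    tissues = list(per_tissue)
    if len(tissues) > MAX_VENN_TISSUES:
        return {}
    union = frozenset().union(*per_tissue.values()) if per_tissue else frozenset()
    regions: dict[frozenset, set] = {}
    for f in union:
        sig = frozenset(t for t in tissues if f in per_tissue[t])
        regions.setdefault(sig, set()).add(f)
    return {sig: frozenset(members) for sig, members in regions.items()}


def _as_tuple(x) -> tuple[str, ...]:
    if isinstance(x, str):
        return (x,)
    return tuple(x)


def _overlap(
    matrix: ExpressionMatrix,
    ti: tuple[str, ...],
    tas: tuple[str, ...],
    features: GeneSet,
    threshold: ExpressionThreshold,
) -> OverlapResult:
    if not ti or not tas:
        raise ValueError("need at least one TI and one TA tissue")
    if set(ti) & set(tas):
        raise ValueError(f"tissues cannot be both TI and TA: {sorted(set(ti) & set(tas))}")
    wanted = features.as_set()
    present = wanted & set(matrix.feature_ids)
    not_in_matrix = frozenset(wanted - present)
    per_tissue = {
        t: frozenset(filter_expressed(matrix, t, threshold) & present) for t in ti + tas
    }
    ti_expressed = frozenset().union(*(per_tissue[t] for t in ti))
    ta_expressed = frozenset().union(*(per_tissue[t] for t in tas))
    return OverlapResult(
        input_set=features,
        ti_tissues=ti,
        ta_tissues=tas,
        per_tissue_expressed=per_tissue,
        ti_expressed=ti_expressed,
        ta_expressed=ta_expressed,
        venn_regions=venn_regions(per_tissue),
        captured=frozenset(present & ta_expressed),
        not_covered=frozenset(present - ta_expressed),
        not_in_ti=frozenset(present - ti_expressed),
        not_in_matrix=not_in_matrix,
        level=matrix.level,
    )


def expressed_overlap(
    matrix: ExpressionMatrix,
    ti,
    tas,
    genes: GeneSet,
    threshold: ExpressionThreshold = DEFAULT_THRESHOLD,
) -> OverlapResult:
    """Gene-level overlap of a phenotype list between TI and TA tissues."""
    return _overlap(matrix, _as_tuple(ti), _as_tuple(tas), genes, threshold)


def transcript_overlap(
    tmatrix: ExpressionMatrix,
    ti,
    tas,
    genes: GeneSet,
    threshold: ExpressionThreshold = DEFAULT_THRESHOLD,
) -> OverlapResult:
    """Transcript-level overlap: same set algebra on isoforms.

    Only transcripts whose parent gene is in the input list are
    considered; a transcript passes on its own TPM (the parent gene is not
    additionally required to pass the gene-level threshold).
    """
    if tmatrix.level != "transcript" or tmatrix.feature_to_gene is None:
        raise ValueError("transcript_overlap requires a transcript-level matrix with feature_to_gene")
    gene_set = genes.as_set()
    transcripts = [t for t in tmatrix.feature_ids if tmatrix.feature_to_gene[t] in gene_set]
    if not transcripts:
        raise ValueError(
            f"no transcripts in the matrix belong to genes of {genes.name!r}"
        )
    tset = GeneSet.from_iterable(f"{genes.name} (transcripts)", transcripts)
    return _overlap(tmatrix, _as_tuple(ti), _as_tuple(tas), tset, threshold)


def best_covering_tissue(
    matrix: ExpressionMatrix,
    tissues: Sequence[str],
    genes: GeneSet,
    threshold: ExpressionThreshold = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Rank tissues by how many of the input genes they express.

    Returns a DataFrame (tissue, n_expressed, fraction_of_input) sorted by
    descending n_expressed (ties alphabetical); the fraction is relative
    to the input genes present in the matrix.
    """
    present = genes.as_set() & set(matrix.feature_ids)
    denom = len(present)
    rows = []
    for t in tissues:
        n = len(filter_expressed(matrix, t, threshold) & present)
        rows.append(
            {
                "tissue": t,
                "n_expressed": n,
                "fraction_of_input": n / denom if denom else float("nan"),
            }
        )
    out = pd.DataFrame(rows, columns=["tissue", "n_expressed", "fraction_of_input"])
    return out.sort_values(
        ["n_expressed", "tissue"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
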