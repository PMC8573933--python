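"""Developmental-stage expression analysis.

Genes silent in an adult tissue of interest can still be active during
organogenesis; for those genes RNA-seq on any adult tissue is blind.  This
module works on a gene-by-stage matrix of RPKM values (stages in explicit
ontogenetic order, e.g. prenatal first, adult last; a stage value is the
maximum over the structures/donors measured within the stage -- that
pre-aggregation is the loader's job, :meth:`StageMatrix.from_structures`
provides it with ``max`` as the default reducer).

Three questions are answered: which stage holds each gene's maximum
expression (:func:`stage_max_assign`); whether expression differs between
stages at all, via one-way ANOVA with Tukey HSD pairwise comparisons
(:func:`anova_tukey`); and whether maxima pile up in the prenatal stage
more than the uniform 1/n_stages share would predict, via an exact
one-sided binomial test (:func:`prenatal_enrichment`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .proxy import binomial_tail_p

logger = logging.getLogger(__name__)

__all__ = [
    "StageMatrix",
    "StageTestResult",
    "UNEXPRESSED",
    "stage_max_assign",
    "anova_tukey",
    "prenatal_enrichment",
]

#: Pseudo-stage assigned to genes with all-zero expression; such genes are
#: excluded from stage counts and enrichment.
UNEXPRESSED = "unexpressed"


class StageMatrix:
    """Gene-by-stage matrix of non-negative RPKM values.

    Column order *is* the declared ontogenetic stage order.
    """

    def __init__(self, values: pd.DataFrame) -> None:
        df = values.copy()
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if df.index.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        if df.columns.has_duplicates:
            raise ValueError("duplicate stage labels")
        if df.shape[1] < 2:
            raise ValueError("need at least two stages")
        arr = df.to_numpy(dtype=float)
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ValueError("stage values must be finite and >= 0")
        self._df = df.astype(float)

    @classmethod
    def from_structures(
        cls,
        long: pd.DataFrame,
        stage_order: Sequence[str],
        reducer: str | Callable = "max",
    ) -> "StageMatrix":
        """Collapse a long table (gene, stage, value) over structures/donors.

        ``reducer`` is applied within each (gene, stage) group; the default
        ``max`` records the peak expression reached anywhere in the tissue
        during that stage.
        """
        required = {"gene", "stage", "value"}
        if not required.issubset(long.columns):
            raise ValueError(f"long table needs columns {sorted(required)}")
        wide = long.pivot_table(index="gene", columns="stage", values="value", aggfunc=reducer)
        missing = [s for s in stage_order if s not in wide.columns]
        if missing:
            raise ValueError(f"stages absent from the table: {missing}")
        return cls(wide[list(stage_order)].fillna(0.0))

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def gene_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def stages(self) -> list[str]:
        return list(self._df.columns)

    @property
    def n_stages(self) -> int:
        return self._df.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"StageMatrix({self._df.shape[0]} genes x {self.n_stages} stages)"


@dataclass(frozen=True)
class StageTestResult:
    """ANOVA + Tukey HSD over stages, plus stage-of-maximum statistics."""

    F: float
    p: float
    pairwise: tuple[tuple[str, str, float, float], ...]  # (stage_i, stage_j, meandiff, p_adj)
    max_stage_counts: Mapping[str, int]
    n_ties: int
    enrichment_p: float
    prenatal_stage: str
    degenerate: bool = False


def stage_max_assign(m: StageMatrix) -> dict[str, str]:
    """Map each gene to the stage holding its maximum expression.

    Ties go to the earliest stage in the declared order (tie count is
    logged); all-zero genes are assigned the :data:`UNEXPRESSED`
    pseudo-stage.  The assignment is invariant to any common monotone
    rescaling of a gene's values.
    """
    arr = m.df.to_numpy()
    stages = m.stages
    out: dict[str, str] = {}
    n_ties = 0
    for gene, row in zip(m.gene_ids, arr):
        top = row.max()
        if top == 0.0:
            out[gene] = UNEXPRESSED
            continue
        hits = np.flatnonzero(row == top)
        if hits.size > 1:
            n_ties += 1
        out[gene] = stages[hits[0]]
    if n_ties:
        logger.info("stage_max_assign: %d genes tied across stages (earliest kept)", n_ties)
    return out


def _count_ties(m: StageMatrix) -> int:
    arr = m.df.to_numpy()
    tops = arr.max(axis=1, keepdims=True)
    return int((((arr == tops).sum(axis=1) > 1) & (tops[:, 0] > 0)).sum())


def prenatal_enrichment(
    assignments: Mapping[str, str],
    n_stages: int,
    prenatal_stage: str = "prenatal",
) -> float:
    """Exact one-sided binomial p for an excess of prenatal-max genes.

    Tests the count of genes whose maximum falls in ``prenatal_stage``
    against the uniform null probability 1/n_stages, over all assigned
    genes (the :data:`UNEXPRESSED` pseudo-stage is excluded).
    """
    assigned = [s for s in assignments.values() if s != UNEXPRESSED]
    if not assigned:
        raise ValueError("no assigned genes: every gene is unexpressed")
    k = sum(1 for s in assigned if s == prenatal_stage)
    return binomial_tail_p(k, len(assigned), 1.0 / n_stages)


def anova_tukey(m: StageMatrix, prenatal_stage: str | None = None) -> StageTestResult:
    """One-way ANOVA across stages with genes as observations, plus Tukey HSD.

    Groups are the stages; each gene contributes one observation per
    stage.  The result also reports the stage-of-maximum counts and the
    prenatal enrichment p-value (``prenatal_stage`` defaults to the first
    stage in the declared order).  When every group has zero within-group
    variance the ANOVA is degenerate and flagged (F = NaN).
    """
    if m.df.shape[0] < 2:
        raise ValueError("need at least two genes")
    prenatal = prenatal_stage if prenatal_stage is not None else m.stages[0]
    if prenatal not in m.stages:
        raise KeyError(f"unknown stage {prenatal!r}; stages are {m.stages}")
    groups = [m.df[s].to_numpy() for s in m.stages]
    degenerate = all(np.ptp(g) == 0.0 for g in groups)
    if degenerate:
        F, p = math.nan, math.nan
        pairwise: tuple = ()
    else:
        F, p = stats.f_oneway(*groups)
        F, p = float(F), float(p)
        values = np.concatenate(groups)
        labels = np.repeat(m.stages, m.df.shape[0])
        res = pairwise_tukeyhsd(values, labels)
        order = list(res.groupsunique)
        pairs = [
            (order[i], order[j])
            for i in range(len(order))
            for j in range(i + 1, len(order))
        ]
        pairwise = tuple(
            (a, b, float(d), float(q))
            for (a, b), d, q in zip(pairs, res.meandiffs, res.pvalues)
        )
    assignments = stage_max_assign(m)
    counts = {s: 0 for s in m.stages}
    for s in assignments.values():
        if s != UNEXPRESSED:
            counts[s] += 1
    enrichment = prenatal_enrichment(assignments, m.n_stages, prenatal)
    return StageTestResult(
        F=F,
        p=p,
        pairwise=pairwise,
        max_stage_counts=counts,
        n_ties=_count_ties(m),
        enrichment_p=enrichment,
        prenatal_stage=prenatal,
        degenerate=degenerate,
    )
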