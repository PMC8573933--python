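"""Seeded generators emulating the external resources the tool consumes.

Nothing here is downloaded: GTEx-like median-TPM matrices, transcript
tables, protein-protein interaction (PPI) networks with GO labels, and
developmental-stage matrices are all simulated with controllable
statistical structure so every analysis stage can be exercised and
validated end to end.

Expression model
----------------
Per gene, log TPM in the tissue of interest is drawn as
z ~ Normal(mu, sigma^2); each candidate tissue j with latent correlation
rho_j gets rho_j * z + sqrt(1 - rho_j^2) * eps with an independent
eps ~ Normal(mu, sigma^2), and values are exponentiated to the TPM scale.
rho is therefore the correlation of *log* expression; the TPM-scale
Pearson correlation of log-normal values is systematically lower.  A
per-tissue "silent" fraction of genes is forced to a small fixed value
(one tenth of the expression cutoff, not exact zero, so that
threshold-boundary logic is exercised).  Defaults (mu = 1.0, sigma = 2.0
on the natural-log scale, 30% silent genes per tissue) give a wide,
heavy-tailed TPM distribution with a realistic non-expressed mass.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DEFAULT_THRESHOLD, ExpressionMatrix, GeneSet, SampleMatrix
from .enrichment import PpiNetwork
from .stages import StageMatrix

__all__ = [
    "TissuePlan",
    "SyntheticSpec",
    "SyntheticNetwork",
    "gen_expression",
    "gen_transcripts",
    "gen_ppi_go",
    "gen_stage_matrix",
    "load_table1_fixture",
]


@dataclass(frozen=True)
class TissuePlan:
    """One candidate tissue: latent log-scale correlation to the TI and the
    fraction of genes silenced in this tissue."""

    name: str
    rho: float = 0.0
    silent_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")
        if not 0.0 <= self.silent_fraction <= 1.0:
            raise ValueError(f"silent_fraction must be in [0, 1], got {self.silent_fraction}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic expression reference.  ``seed`` is mandatory."""

    n_genes: int
    tissues: tuple[TissuePlan, ...]
    seed: int
    ti_name: str = "TI"
    ti_silent_fraction: float = 0.3
    log_mean: float = 1.0
    log_sd: float = 2.0
    n_samples_per_tissue: int | None = None
    sample_log_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not self.tissues:
            raise ValueError("need at least one candidate tissue")
        names = [self.ti_name] + [t.name for t in self.tissues]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate tissue names in {names}")
        if self.log_sd <= 0:
            raise ValueError("log_sd must be > 0")
        if not 0.0 <= self.ti_silent_fraction <= 1.0:
            raise ValueError("ti_silent_fraction must be in [0, 1]")
        object.__setattr__(self, "tissues", tuple(self.tissues))


_SILENT_VALUE_FACTOR = 0.1  # silent genes sit at threshold/10, not exact zero


def gen_expression(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, SampleMatrix | None]:
    """Generate a median-TPM matrix (and optionally per-sample values).

    Deterministic given ``spec`` (including its seed).  When
    ``spec.n_samples_per_tissue`` is set, a :class:`SampleMatrix` is also
    returned whose samples scatter log-normally around each tissue value.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    genes = [f"G{i:05d}" for i in range(n)]
    z = rng.normal(spec.log_mean, spec.log_sd, size=n)
    columns: dict[str, np.ndarray] = {spec.ti_name: np.exp(z)}
    for plan in spec.tissues:
        if plan.rho == 1.0:
            log_col = z.copy()
        else:
            eps = rng.normal(spec.log_mean, spec.log_sd, size=n)
            log_col = plan.rho * z + math.sqrt(1.0 - plan.rho**2) * eps
        columns[plan.name] = np.exp(log_col)
    silent_value = DEFAULT_THRESHOLD.value * _SILENT_VALUE_FACTOR
    silent_fracs = {spec.ti_name: spec.ti_silent_fraction}
    silent_fracs.update({t.name: t.silent_fraction for t in spec.tissues})
    for tissue, frac in silent_fracs.items():
        n_silent = int(round(frac * n))
        if n_silent:
            idx = rng.choice(n, size=n_silent, replace=False)
            columns[tissue][idx] = silent_value
    medians = pd.DataFrame(columns, index=genes)
    matrix = ExpressionMatrix(medians)
    samples = None
    if spec.n_samples_per_tissue is not None:
        k = spec.n_samples_per_tissue
        if k < 1:
            raise ValueError("n_samples_per_tissue must be >= 1")
        data = {}
        mapping = {}
        for tissue in medians.columns:
            base = np.log(medians[tissue].to_numpy())
            for j in range(k):
                sid = f"{tissue}.s{j}"
                data[sid] = np.exp(base + rng.normal(0.0, spec.sample_log_sd, size=n))
                mapping[sid] = tissue
        samples = SampleMatrix(pd.DataFrame(data, index=genes), mapping)
    return matrix, samples


def gen_transcripts(
    matrix: ExpressionMatrix,
    max_isoforms: int = 3,
    seed: int = 0,
    alpha: float = 1.0,
) -> ExpressionMatrix:
    """Split each gene's TPM across 1..max_isoforms transcripts.

    Isoform counts are uniform on {1..max_isoforms}; per-gene expression is
    divided by a single Dirichlet(alpha) weight vector shared across
    tissues, so transcript TPMs sum exactly to the gene TPM in every
    tissue.
    """
    if matrix.level != "gene":
        raise ValueError("gen_transcripts expects a gene-level matrix")
    if max_isoforms < 1:
        raise ValueError("max_isoforms must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    index = []
    mapping = {}
    values = matrix.df
    for gene in values.index:
        k = int(rng.integers(1, max_isoforms + 1))
        if k == 1:
            weights = np.array([1.0])
        else:
            weights = rng.dirichlet(np.full(k, alpha))
        gene_row = values.loc[gene].to_numpy()
        parts = np.outer(weights, gene_row)
        # make the split exactly conservative despite rounding
        parts[-1] = np.maximum(gene_row - parts[:-1].sum(axis=0), 0.0)
        for i in range(k):
            tid = f"{gene}.t{i + 1}"
            index.append(tid)
            mapping[tid] = gene
            rows.append(parts[i])
    tdf = pd.DataFrame(rows, index=index, columns=values.columns)
    return ExpressionMatrix(tdf, level="transcript", feature_to_gene=mapping)


@dataclass(frozen=True)
class SyntheticNetwork:
    """A simulated PPI network with GO labels and a designated study set."""

    network: PpiNetwork
    annotations: Mapping[str, frozenset]
    study: GeneSet
    planted_term: str | None = None


def gen_ppi_go(
    n_genes: int = 300,
    n_edges: int = 1200,
    n_terms: int = 30,
    genes_per_term: int = 15,
    seed: int = 0,
    study_size: int = 10,
    plant: bool = False,
    plant_study_genes: int = 5,
    plant_density: float = 0.6,
) -> SyntheticNetwork:
    """Scale-free-ish random PPI graph with random GO term labels.

    With ``plant=True`` one extra term ("GO:PLANTED") is added whose genes
    are a mix of study genes and their direct partners, wired densely
    (each pair with probability ``plant_density``) and attached to the
    study genes, so that by construction the term is over-represented both
    in genes and in functional edges within the extended study set.
    """
    if n_edges > n_genes * (n_genes - 1) // 2:
        raise ValueError("n_edges exceeds the number of possible pairs")
    rng = np.random.default_rng(seed)
    genes = [f"P{i:04d}" for i in range(n_genes)]
    # preferential-attachment-flavoured degree weights for a heavy-tailed
    # degree sequence (exact scale-freeness is not needed by any consumer)
    weights = rng.pareto(2.0, size=n_genes) + 1.0
    weights /= weights.sum()
    edges: set[tuple[str, str]] = set()
    while len(edges) < n_edges:
        a, b = rng.choice(n_genes, size=2, replace=False, p=weights)
        e = (genes[min(a, b)], genes[max(a, b)])
        edges.add(e)
    annotations: dict[str, set[str]] = {g: set() for g in genes}
    for t in range(n_terms):
        term = f"GO:{t:07d}"
        members = rng.choice(n_genes, size=min(genes_per_term, n_genes), replace=False)
        for m in members:
            annotations[genes[m]].add(term)
    study_idx = rng.choice(n_genes, size=study_size, replace=False)
    study_genes = [genes[i] for i in study_idx]
    planted_term = None
    if plant:
        planted_term = "GO:PLANTED"
        core = study_genes[: min(plant_study_genes, study_size)]
        others = [g for g in genes if g not in set(core)]
        n_extra = max(genes_per_term - len(core), 0)
        extra = list(rng.choice(others, size=n_extra, replace=False))
        module = core + extra
        for g in module:
            annotations[g].add(planted_term)
        # attach every module gene to a study gene so it enters the
        # extended study set, then densify the module itself
        for g in extra:
            anchor = core[int(rng.integers(len(core)))]
            if g != anchor:
                edges.add((min(g, anchor), max(g, anchor)))
        for i in range(len(module)):
            for j in range(i + 1, len(module)):
                if rng.random() < plant_density:
                    a, b = module[i], module[j]
                    edges.add((min(a, b), max(a, b)))
    network = PpiNetwork(edges=sorted(edges), nodes=genes)
    return SyntheticNetwork(
        network=network,
        annotations={g: frozenset(t) for g, t in annotations.items()},
        study=GeneSet.from_iterable("study", study_genes),
        planted_term=planted_term,
    )


DEFAULT_STAGES = ("prenatal", "infant", "child", "adolescent", "adult")


def gen_stage_matrix(
    n_genes: int = 200,
    stages: Sequence[str] = DEFAULT_STAGES,
    prenatal_fraction: float = 0.0,
    effect_size: float = 2.0,
    seed: int = 0,
    log_mean: float = 1.0,
    log_sd: float = 1.0,
) -> StageMatrix:
    """Developmental-stage RPKM matrix with a plantable prenatal-max subset.

    A ``prenatal_fraction`` of genes get their first-stage value multiplied
    by 2**effect_size; the remaining genes are exchangeable across stages
    (log-normal i.i.d.), so under ``prenatal_fraction=0`` no stage is
    preferred.
    """
    if not 0.0 <= prenatal_fraction <= 1.0:
        raise ValueError("prenatal_fraction must be in [0, 1]")
    stages = list(stages)
    if len(stages) < 2:
        raise ValueError("need at least two stages")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    vals = np.exp(rng.normal(log_mean, log_sd, size=(n_genes, len(stages))))
    n_bump = int(round(prenatal_fraction * n_genes))
    if n_bump:
        idx = rng.choice(n_genes, size=n_bump, replace=False)
        vals[idx, 0] *= 2.0**effect_size
    return StageMatrix(pd.DataFrame(vals, index=genes, columns=stages))


def _read_fixture(name: str) -> list[str]:
    text = importlib.resources.files("tissueproxy.data").joinpath(name).read_text()
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


def load_table1_fixture() -> tuple[GeneSet, GeneSet]:
    """The two packaged phenotype gene lists of TI-silent genes.

    Returns the list of cardiac-arrhythmia genes not expressed in heart
    (median TPM < 1.5) and the list of neurodevelopmental-disorder genes
    not expressed in adult brain, as published.  SCN10A appears in both.
    """
    cardiac = GeneSet("cardiac_not_in_heart", tuple(_read_fixture("table1_cardiac.txt")))
    ndd = GeneSet("ndd_not_in_adult_brain", tuple(_read_fixture("table1_ndd.txt")))
    return cardiac, ndd
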