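"""Transcriptome QC utilities around an external differential-expression test.

Covers the in-house steps of a staged anther RNA-seq comparison (tetrad,
microspore, young pollen; wild type vs mutant): TPM normalization, selection
of the top-K genes by cumulative expression, Z-score Euclidean
complete-linkage biclustering to screen replicate consistency, the 7-region
overlap partition of three per-stage DE gene lists, and ΔΔCt relative
expression for qPCR validation.  The DE test itself (e.g. a DESeq2 Wald
test) is consumed, not computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from skbio import TreeNode

__all__ = [
    "CountsMatrix",
    "DEListSet",
    "ConsistencyResult",
    "OverlapResult",
    "tpm",
    "replicate_consistency",
    "stage_overlap",
    "ddct",
]

STAGES = ("tetrad", "microspore", "young_pollen")


@dataclass
class CountsMatrix:
    """Gene × sample raw counts with per-gene effective length and sample
    metadata (stage, genotype, replicate)."""

    counts: pd.DataFrame  # genes x samples, non-negative
    lengths: pd.Series  # bp per gene
    meta: pd.DataFrame  # index = samples; columns stage, genotype, replicate

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be >= 0")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any() or (self.lengths <= 0).any():
            raise ValueError("every gene needs a positive effective length")
        if self.counts.columns.duplicated().any():
            raise ValueError("sample labels must be unique")
        if not self.counts.columns.isin(self.meta.index).all():
            missing = set(self.counts.columns) - set(self.meta.index)
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")

    def group(self, sample: str) -> tuple[str, str]:
        row = self.meta.loc[sample]
        return (row["stage"], row["genotype"])


@dataclass
class DEListSet:
    """Per-stage differentially expressed genes with direction (up/down);
    a gene appears at most once per stage."""

    stages: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        for stage, genes in self.stages.items():
            bad = {d for d in genes.values()} - {"up", "down"}
            if bad:
                raise ValueError(f"{stage}: directions must be up/down, got {bad}")


@dataclass
class ConsistencyResult:
    selected_genes: list[str]
    zscores: pd.DataFrame  # selected genes x samples
    sample_linkage: np.ndarray
    gene_linkage: np.ndarray
    samples: list[str]
    flagged: dict[str, bool]
    sample_newick: str
    gene_newick: str


@dataclass
class OverlapResult:
    """Full 7-region partition of three DE lists plus direction consistency
    for the triple intersection."""

    regions: dict[frozenset[str], set[str]]
    counts: dict[frozenset[str], int] = field(init=False)
    triple_directions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = {k: len(v) for k, v in self.regions.items()}

    def union_size(self) -> int:
        return sum(self.counts.values())


def tpm(matrix: CountsMatrix) -> pd.DataFrame:
    """Transcripts-per-million: per sample, length-normalized count rates
    rescaled to sum to 10⁶."""
    rates = matrix.counts.div(matrix.lengths, axis=0)
    totals = rates.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    return rates.div(totals, axis=1) * 1e6


def _first_merge_partners(Z: np.ndarray, n: int) -> list[set[int]]:
    """For each leaf, the leaves of the sibling cluster at its first merge."""
    members: dict[int, set[int]] = {i: {i} for i in range(n)}
    partners: list[set[int] | None] = [None] * n
    for k, (a, b, _, _) in enumerate(Z):
        a, b = int(a), int(b)
        for leaf in members[a]:
            if partners[leaf] is None:
                partners[leaf] = set(members[b])
        for leaf in members[b]:
            if partners[leaf] is None:
                partners[leaf] = set(members[a])
        members[n + k] = members[a] | members[b]
    return [p if p is not None else set() for p in partners]


def _to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = TreeNode.from_linkage_matrix(Z, labels)
    return str(tree)


def replicate_consistency(matrix: CountsMatrix, top_k: int = 5000) -> ConsistencyResult:
    """Replicate-consistency screen by Z-score biclustering.

    Selects the ``top_k`` genes with the highest cumulative TPM across all
    samples (ties broken by gene id), standardizes each gene across samples
    (Z-score), and clusters both samples and genes with complete linkage on
    Euclidean distance.  A replicate is flagged when the sibling cluster of
    its first merge in the sample dendrogram contains no sample from its own
    (stage, genotype) group — the operational form of "clusters away from
    its replicates" used to discard inconsistent libraries.
    """
    for grp, sub in matrix.meta.loc[list(matrix.counts.columns)].groupby(
        ["stage", "genotype"]
    ):
        if len(sub) < 2:
            raise ValueError(f"group {grp} has fewer than 2 samples")
    expr = tpm(matrix)
    if top_k > len(expr):
        warnings.warn(
            f"top_k={top_k} exceeds gene count {len(expr)}; using all genes",
            stacklevel=2,
        )
        top_k = len(expr)
    cumulative = expr.sum(axis=1)
    # stable sort on gene id first makes ties break lexicographically
    ranked = cumulative.loc[sorted(cumulative.index)].sort_values(
        ascending=False, kind="stable"
    )
    selected = list(ranked.index[:top_k])
    sub = expr.loc[selected]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0).replace(0, 1.0)  # constant genes -> z = 0
    z = sub.sub(mu, axis=0).div(sd, axis=0)

    samples = list(z.columns)
    sample_Z = linkage(pdist(z.T.values, metric="euclidean"), method="complete")
    gene_Z = linkage(pdist(z.values, metric="euclidean"), method="complete")

    partners = _first_merge_partners(sample_Z, len(samples))
    groups = [matrix.group(s) for s in samples]
    flagged = {}
    for i, s in enumerate(samples):
        flagged[s] = not any(groups[j] == groups[i] for j in partners[i])
    return ConsistencyResult(
        selected_genes=selected,
        zscores=z,
        sample_linkage=sample_Z,
        gene_linkage=gene_Z,
        samples=samples,
        flagged=flagged,
        sample_newick=_to_newick(sample_Z, samples),
        gene_newick=_to_newick(gene_Z, selected),
    )


def stage_overlap(de: DEListSet) -> OverlapResult:
    """Exclusive 7-region partition of three per-stage DE gene lists.

    Region keys are frozensets of stage names; a gene lands in exactly one
    region (the set of stages that report it), so region counts sum to the
    union cardinality.  For genes shared by all three stages, a direction-
    consistency table records the per-stage directions.
    """
    stages = list(de.stages)
    if len(stages) != 3:
        raise ValueError(f"need exactly three stage lists, got {len(stages)}")
    sets = {s: set(de.stages[s]) for s in stages}
    regions: dict[frozenset[str], set[str]] = {}
    for r in range(1, 4):
        for combo in combinations(stages, r):
            inside = set.intersection(*(sets[s] for s in combo))
            outside = set.union(
                *(sets[s] for s in stages if s not in combo), set()
            ) if len(combo) < 3 else set()
            regions[frozenset(combo)] = inside - outside

    triple = sorted(regions[frozenset(stages)])
    table = pd.DataFrame(
        {s: [de.stages[s][g] for g in triple] for s in stages}, index=triple
    )
    table["consistent"] = table[stages].nunique(axis=1) == 1 if triple else []
    return OverlapResult(regions=regions, triple_directions=table)


def ddct(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the ΔΔCt method: fold = 2^(−ΔΔCt) with
    ΔΔCt = (Ct_target − Ct_reference)_test − (Ct_target − Ct_reference)_calibrator."""
    for ct in (ct_target_test, ct_ref_test, ct_target_calibrator, ct_ref_calibrator):
        if not np.isfinite(ct):
            raise ValueError("Ct values must be finite")
    delta_delta = (ct_target_test - ct_ref_test) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return float(2.0 ** (-delta_delta))
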