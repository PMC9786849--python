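"""Pooled allele-frequency mapping of a causal locus from two-bulk VCFs.

Workflow: read a two-sample (WT bulk, mutant bulk) VCF keeping biallelic
SNVs with a minimum per-sample depth, compute the per-pool allele-frequency
ratio (non-reference reads / total reads), average it in sliding windows of
fixed variant count along each chromosome, and flag the region where the
mutant bulk is depleted of non-reference alleles — the signature of a
recessive causal locus in a reference-background mutant crossed to a
divergent accession.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .popsim import PooledVariant

__all__ = [
    "Window",
    "WindowProfile",
    "CandidateRegion",
    "read_pooled_vcf",
    "allele_frequency",
    "window_profile",
    "detect_candidate_region",
    "region_variants",
    "export_profile",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 1000  # variants per window
DEFAULT_STEP = 100  # variants per step
DEFAULT_MIN_DEPTH = 10  # reads per sample
DEFAULT_MUT_AF_MAX = 0.2
DEFAULT_DELTA_MIN = 0.25


@dataclass(frozen=True)
class Window:
    """One sliding window in variant-rank space (ranks are 1-based)."""

    start_index: int
    end_index: int
    start_bp: int
    end_bp: int
    mean_af_wt: float
    mean_af_mut: float
    n_variants: int
    partial: bool = False


@dataclass(frozen=True)
class WindowProfile:
    """Per-chromosome sequence of sliding-window mean allele frequencies."""

    chrom: str
    windows: tuple[Window, ...]


@dataclass(frozen=True)
class CandidateRegion:
    """A merged run of windows flagged as harboring the causal locus."""

    chrom: str
    start_bp: int
    end_bp: int
    start_index: int
    end_index: int
    n_windows: int
    min_mut_af: float
    mean_delta: float
    variant_ids: tuple[str, ...] = ()

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start_bp <= pos <= self.end_bp


def read_pooled_vcf(
    path: str,
    min_depth: int = DEFAULT_MIN_DEPTH,
    wt_sample: str = "wt_pool",
    mut_sample: str = "mut_pool",
) -> list[PooledVariant]:
    """Read biallelic SNVs with per-pool AD, dropping records where either
    pool's total depth is below ``min_depth`` (depth exactly ``min_depth``
    is retained).  Drop reasons are counted and logged.
    """
    dropped = {"multiallelic": 0, "not_snv": 0, "low_depth": 0}
    out: list[PooledVariant] = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for name in (wt_sample, mut_sample):
            if name not in samples:
                raise ValueError(f"sample {name!r} not in VCF (has {samples})")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                dropped["multiallelic"] += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                dropped["not_snv"] += 1
                continue
            ads = {}
            for name in (wt_sample, mut_sample):
                ad = rec.samples[name].get("AD")
                if ad is None or ad[0] is None:
                    raise ValueError(
                        f"record {rec.chrom}:{rec.pos} lacks AD for sample {name!r}"
                    )
                ads[name] = (int(ad[0]), int(ad[1]))
            if any(sum(ads[n]) < min_depth for n in (wt_sample, mut_sample)):
                dropped["low_depth"] += 1
                continue
            out.append(
                PooledVariant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt,
                    wt_ref=ads[wt_sample][0],
                    wt_alt=ads[wt_sample][1],
                    mut_ref=ads[mut_sample][0],
                    mut_alt=ads[mut_sample][1],
                    in_known_catalog="KNOWN" in rec.info,
                )
            )
    logger.info(
        "read_pooled_vcf: kept %d variants, dropped %s", len(out), dropped
    )
    return out


def allele_frequency(v: PooledVariant, pool: str) -> float:
    """Non-reference allele frequency: alt reads / total reads in one pool."""
    if pool == "wt":
        ref, alt = v.wt_ref, v.wt_alt
    elif pool == "mut":
        ref, alt = v.mut_ref, v.mut_alt
    else:
        raise ValueError(f"pool must be 'wt' or 'mut', got {pool!r}")
    total = ref + alt
    if total == 0:
        raise ValueError(
            f"{v.chrom}:{v.pos} has zero depth in {pool} pool; apply the depth filter first"
        )
    return alt / total


def _check_sorted(variants: list[PooledVariant]) -> None:
    order: dict[str, int] = {}
    last: tuple[int, int] | None = None
    for v in variants:
        key = (order.setdefault(v.chrom, len(order)), v.pos)
        if last is not None and key < last:
            raise ValueError(f"variants not sorted at {v.chrom}:{v.pos}")
        last = key


def window_profile(
    variants: list[PooledVariant],
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> list[WindowProfile]:
    """Sliding-window mean allele frequency per chromosome.

    Windows advance in variant-rank space by ``step`` and each full window
    holds exactly ``window_size`` variants; the mean is the unweighted mean
    of per-variant frequency ratios.  Trailing variants that cannot fill a
    final full window are covered only by the last full window; a
    chromosome with fewer variants than one window yields a single window
    flagged partial.  bp bounds are derived from member variants and never
    drive the windowing.
    """
    if not (window_size >= step >= 1):
        raise ValueError("require window_size >= step >= 1")
    _check_sorted(variants)
    by_chrom: dict[str, list[PooledVariant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)

    profiles = []
    for chrom, vs in by_chrom.items():
        n = len(vs)
        af_wt = np.array([allele_frequency(v, "wt") for v in vs])
        af_mut = np.array([allele_frequency(v, "mut") for v in vs])
        pos = np.array([v.pos for v in vs])
        windows = []
        if n < window_size:
            windows.append(
                Window(1, n, int(pos[0]), int(pos[-1]),
                       float(af_wt.mean()), float(af_mut.mean()), n, partial=True)
            )
        else:
            cum_wt = np.concatenate([[0.0], np.cumsum(af_wt)])
            cum_mut = np.concatenate([[0.0], np.cumsum(af_mut)])
            for start in range(0, n - window_size + 1, step):
                end = start + window_size
                windows.append(
                    Window(
                        start + 1,
                        end,
                        int(pos[start]),
                        int(pos[end - 1]),
                        float((cum_wt[end] - cum_wt[start]) / window_size),
                        float((cum_mut[end] - cum_mut[start]) / window_size),
                        window_size,
                    )
                )
        profiles.append(WindowProfile(chrom, tuple(windows)))
    return profiles


def detect_candidate_region(
    profiles: list[WindowProfile],
    mut_af_max: float = DEFAULT_MUT_AF_MAX,
    delta_min: float = DEFAULT_DELTA_MIN,
    variants: list[PooledVariant] | None = None,
) -> list[CandidateRegion]:
    """Flag windows depleted of non-reference alleles in the mutant bulk
    (mean_af_mut <= mut_af_max and mean_af_wt - mean_af_mut >= delta_min),
    merge flagged windows that overlap or abut in rank space, and rank the
    merged regions by mean WT-minus-mutant difference, descending.  Ties
    break by larger window count, then chromosome name.  Returns an empty
    list when nothing passes.
    """
    regions: list[CandidateRegion] = []
    for prof in profiles:
        flagged = [
            w
            for w in prof.windows
            if w.mean_af_mut <= mut_af_max and (w.mean_af_wt - w.mean_af_mut) >= delta_min
        ]
        if not flagged:
            continue
        runs: list[list[Window]] = [[flagged[0]]]
        for w in flagged[1:]:
            if w.start_index <= runs[-1][-1].end_index + 1:
                runs[-1].append(w)
            else:
                runs.append([w])
        for run in runs:
            region = CandidateRegion(
                chrom=prof.chrom,
                start_bp=run[0].start_bp,
                end_bp=run[-1].end_bp,
                start_index=run[0].start_index,
                end_index=run[-1].end_index,
                n_windows=len(run),
                min_mut_af=min(w.mean_af_mut for w in run),
                mean_delta=float(np.mean([w.mean_af_wt - w.mean_af_mut for w in run])),
            )
            if variants is not None:
                ids = tuple(
                    f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}"
                    for v in region_variants(variants, region)
                )
                region = CandidateRegion(**{**region.__dict__, "variant_ids": ids})
            regions.append(region)
    regions.sort(key=lambda r: (-r.mean_delta, -r.n_windows, r.chrom))
    return regions


def region_variants(
    variants: list[PooledVariant], region: CandidateRegion
) -> list[PooledVariant]:
    """Member variants of a region (1-based inclusive bp bounds)."""
    return [v for v in variants if region.contains(v.chrom, v.pos)]


def export_profile(
    profiles: list[WindowProfile],
    tsv_path: str | None = None,
    plot_path: str | None = None,
) -> pd.DataFrame:
    """One row per window (plot-ready); optionally write TSV and a
    per-chromosome line plot of both pools."""
    if not profiles or all(not p.windows for p in profiles):
        raise ValueError("no windows to export")
    rows = [
        {
            "chrom": p.chrom,
            "start_index": w.start_index,
            "end_index": w.end_index,
            "start_bp": w.start_bp,
            "end_bp": w.end_bp,
            "mean_af_wt": w.mean_af_wt,
            "mean_af_mut": w.mean_af_mut,
            "n_variants": w.n_variants,
            "partial": w.partial,
        }
        for p in profiles
        for w in p.windows
    ]
    df = pd.DataFrame(rows)
    if tsv_path is not None:
        df.to_csv(tsv_path, sep="\t", index=False)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        chroms = [p.chrom for p in profiles]
        ncol = min(4, len(chroms))
        nrow = -(-len(chroms) // ncol)
        fig, axes = plt.subplots(
            nrow, ncol, figsize=(3.2 * ncol, 2.4 * nrow), squeeze=False, sharey=True
        )
        for ax, chrom in zip(axes.flat, chroms):
            sub = df[df.chrom == chrom]
            mid = (sub.start_bp + sub.end_bp) / 2e6
            ax.plot(mid, sub.mean_af_wt, color="tab:blue", label="WT pool")
            ax.plot(mid, sub.mean_af_mut, color="tab:red", label="mutant pool")
            ax.set_title(chrom, fontsize=9)
            ax.set_ylim(0, 1)
            ax.set_xlabel("Mb")
        axes.flat[0].set_ylabel("mean allele frequency")
        axes.flat[0].legend(fontsize=7)
        for ax in axes.flat[len(chroms):]:
            ax.set_visible(False)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return df
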