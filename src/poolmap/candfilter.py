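"""Candidate-variant filtering inside a mapped region.

Two criteria nominate the causal mutation among region variants: (i) the
alternative allele must look heterozygous (0/1) in the wild-type bulk and
homozygous (1/1) in the mutant bulk, and (ii) it must be novel, i.e. absent
from a catalog of previously reported variants.  Pool "genotypes" are called
from pooled allele frequencies with configurable thresholds, since a bulk of
many plants has no true diploid genotype.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import pysam

from .afmap import DEFAULT_MIN_DEPTH
from .popsim import PooledVariant

__all__ = [
    "PoolGenotypeCall",
    "CandidateVariant",
    "call_pool_state",
    "filter_candidates",
    "report_candidates",
    "load_catalog",
    "HET_LOW",
    "HET_HIGH",
]

# Defaults separate the expected WT-bulk frequency at the causal site (1/3,
# from the 2:1 het:hom-ref mix of phenotypically wild-type plants) from the
# mutant bulk's ~1.0 with margin at depth >= 20.
HET_LOW = 0.15
HET_HIGH = 0.85

STATES = ("hom_ref", "het", "hom_alt", "no_call")


@dataclass(frozen=True)
class PoolGenotypeCall:
    state: str  # hom_ref | het | hom_alt | no_call
    alt_frequency: float | None
    depth: int


@dataclass(frozen=True)
class CandidateVariant:
    variant: PooledVariant
    wt_call: PoolGenotypeCall
    mut_call: PoolGenotypeCall
    novel: bool
    passes: bool
    fail_reasons: tuple[str, ...]


def call_pool_state(
    v: PooledVariant,
    pool: str,
    het_low: float = HET_LOW,
    het_high: float = HET_HIGH,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> PoolGenotypeCall:
    """Call a pooled pseudo-genotype from the pool's alt-allele frequency:
    below ``het_low`` -> hom_ref, within [het_low, het_high] -> het, above
    -> hom_alt; insufficient depth -> no_call."""
    if het_low >= het_high:
        raise ValueError("het_low must be < het_high")
    if pool == "wt":
        ref, alt = v.wt_ref, v.wt_alt
    elif pool == "mut":
        ref, alt = v.mut_ref, v.mut_alt
    else:
        raise ValueError(f"pool must be 'wt' or 'mut', got {pool!r}")
    depth = ref + alt
    if depth < min_depth:
        af = alt / depth if depth else None
        return PoolGenotypeCall("no_call", af, depth)
    af = alt / depth
    if af < het_low:
        state = "hom_ref"
    elif af <= het_high:
        state = "het"
    else:
        state = "hom_alt"
    return PoolGenotypeCall(state, af, depth)


def filter_candidates(
    variants: list[PooledVariant],
    known_catalog: set[tuple[str, int, str, str]] | None = None,
    het_low: float = HET_LOW,
    het_high: float = HET_HIGH,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> list[CandidateVariant]:
    """Annotate every region variant against both criteria.

    A variant passes iff the WT bulk is called het, the mutant bulk hom_alt,
    and the variant is novel.  Novelty is checked against ``known_catalog``
    (exact chrom/pos/ref/alt match) when given, else against the variant's
    own catalog flag.  Output is sorted passing-first, then by position.
    The filter is a pure per-variant function: idempotent and independent of
    input order.
    """
    out = []
    for v in variants:
        wt_call = call_pool_state(v, "wt", het_low, het_high, min_depth)
        mut_call = call_pool_state(v, "mut", het_low, het_high, min_depth)
        if known_catalog is not None:
            novel = v.key not in known_catalog
        else:
            novel = not v.in_known_catalog
        reasons = []
        if wt_call.state != "het":
            reasons.append(f"wt_not_het({wt_call.state})")
        if mut_call.state != "hom_alt":
            reasons.append(f"mut_not_hom_alt({mut_call.state})")
        if not novel:
            reasons.append("known_variant")
        out.append(
            CandidateVariant(
                variant=v,
                wt_call=wt_call,
                mut_call=mut_call,
                novel=novel,
                passes=not reasons,
                fail_reasons=tuple(reasons),
            )
        )
    out.sort(key=lambda c: (not c.passes, c.variant.chrom, c.variant.pos))
    return out


def report_candidates(candidates: list[CandidateVariant], path: str) -> None:
    """TSV report: summary block (comment lines), then one row per variant."""
    n_pass = sum(c.passes for c in candidates)
    reason_counts: dict[str, int] = {}
    for c in candidates:
        for r in c.fail_reasons:
            base = r.split("(")[0]
            reason_counts[base] = reason_counts.get(base, 0) + 1
    with open(path, "w") as fh:
        fh.write(f"#total\t{len(candidates)}\n")
        fh.write(f"#passing\t{n_pass}\n")
        for reason in sorted(reason_counts):
            fh.write(f"#fail_{reason}\t{reason_counts[reason]}\n")
        fh.write(
            "chrom\tpos\tref\talt\twt_state\twt_af\tmut_state\tmut_af\t"
            "novel\tpasses\tfail_reasons\n"
        )
        for c in candidates:
            v = c.variant
            wt_af = "NA" if c.wt_call.alt_frequency is None else f"{c.wt_call.alt_frequency:.4f}"
            mut_af = "NA" if c.mut_call.alt_frequency is None else f"{c.mut_call.alt_frequency:.4f}"
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t"
                f"{c.wt_call.state}\t{wt_af}\t{c.mut_call.state}\t{mut_af}\t"
                f"{int(c.novel)}\t{int(c.passes)}\t"
                f"{';'.join(c.fail_reasons) or '.'}\n"
            )


def load_catalog(path: str) -> set[tuple[str, int, str, str]]:
    """Load a known-variant catalog from a VCF or a 4-column TSV
    (chrom, pos, ref, alt); matching downstream requires all four fields."""
    p = Path(path)
    if p.suffix in {".vcf", ".bcf"} or str(p).endswith(".vcf.gz"):
        catalog: set[tuple[str, int, str, str]] = set()
        with pysam.VariantFile(path) as vcf:
            for rec in vcf:
                for alt in rec.alts or ():
                    catalog.add((rec.chrom, rec.pos, rec.ref, alt))
        return catalog
    catalog = set()
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "chrom":
                continue
            chrom, pos, ref, alt = row[:4]
            catalog.add((chrom, int(pos), ref, alt))
    return catalog
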