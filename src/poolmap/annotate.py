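"""Protein-level consequence prediction for coding SNVs.

Projects a genomic position onto a gene's spliced CDS (strand-aware),
substitutes the variant base, and classifies the codon change under the
standard nuclear genetic code — the step that turns a G→A hit in a lectin
receptor kinase gene into "Arg→Gln at residue 268".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = ["GeneModel", "VariantEffect", "project_to_cds", "predict_effect", "NONCODING"]

NONCODING = "noncoding"

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class GeneModel:
    """A gene with its spliced CDS and genomic exon intervals.

    exons: ordered, non-overlapping 1-based inclusive genomic intervals in
    ascending genomic order regardless of strand; their total length must
    equal the CDS length.  The CDS string is 5'→3' in the coding direction.
    """

    gene_id: str
    cds: str
    strand: str  # "+" or "-"
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        last_end = 0
        for start, end in self.exons:
            if start < 1 or end < start:
                raise ValueError(f"malformed exon interval ({start}, {end})")
            if start <= last_end:
                raise ValueError("exons must be ordered and non-overlapping")
            last_end = end
        exon_len = sum(e - s + 1 for s, e in self.exons)
        if exon_len != len(self.cds):
            raise ValueError(
                f"exon span ({exon_len} bp) does not match CDS length ({len(self.cds)})"
            )
        if len(self.cds) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")
        cds = self.cds.upper()
        if not cds.startswith("ATG"):
            warnings.warn(f"{self.gene_id}: CDS does not start with ATG", stacklevel=2)
        if cds[-3:] not in standard_dna_table.stop_codons:
            warnings.warn(f"{self.gene_id}: CDS does not end with a stop codon", stacklevel=2)

    @property
    def protein(self) -> str:
        return str(Seq(self.cds).translate())


@dataclass(frozen=True)
class VariantEffect:
    gene_id: str
    cds_pos: int
    codon_index: int  # 1-based residue number from the initiator Met
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    effect_class: str  # synonymous | missense | stop_gain | stop_loss | start_loss


def project_to_cds(model: GeneModel, chrom_pos: int) -> int | str:
    """Map a genomic bp to its 1-based CDS offset, or ``"noncoding"``.

    For minus-strand genes CDS position 1 is the 3'-most genomic base of the
    last exon, counting backwards through the exon chain.
    """
    if chrom_pos < 1:
        raise ValueError("chrom_pos must be >= 1")
    offset = 0
    for start, end in model.exons:
        if start <= chrom_pos <= end:
            plus_pos = offset + (chrom_pos - start + 1)
            if model.strand == "+":
                return plus_pos
            return len(model.cds) - plus_pos + 1
        offset += end - start + 1
    return NONCODING


def predict_effect(
    model: GeneModel, cds_pos: int, ref_base: str, alt_base: str
) -> VariantEffect:
    """Classify the codon change caused by substituting ``alt_base`` for
    ``ref_base`` at ``cds_pos``.

    Bases are given on the forward genomic strand (VCF convention) and
    complemented internally for minus-strand genes.  Errors if ``ref_base``
    disagrees with the CDS.
    """
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    for b in (ref_base, alt_base):
        if b not in "ACGT":
            raise ValueError(f"base must be one of A,C,G,T, got {b!r}")
    if not 1 <= cds_pos <= len(model.cds):
        raise ValueError(f"cds_pos {cds_pos} outside CDS of length {len(model.cds)}")
    if model.strand == "-":
        ref_base = _COMPLEMENT[ref_base]
        alt_base = _COMPLEMENT[alt_base]
    cds = model.cds.upper()
    if cds[cds_pos - 1] != ref_base:
        raise ValueError(
            f"reference mismatch at CDS position {cds_pos}: "
            f"CDS has {cds[cds_pos - 1]!r}, variant says {ref_base!r}"
        )
    codon_index = math.ceil(cds_pos / 3)
    codon_start = (codon_index - 1) * 3
    ref_codon = cds[codon_start:codon_start + 3]
    within = cds_pos - 1 - codon_start
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())

    if codon_index == 1 and ref_codon == "ATG" and alt_codon != "ATG":
        effect = "start_loss"
    elif ref_aa == alt_aa:
        effect = "synonymous"
    elif alt_aa == "*":
        effect = "stop_gain"
    elif ref_aa == "*":
        effect = "stop_loss"
    else:
        effect = "missense"
    return VariantEffect(
        gene_id=model.gene_id,
        cds_pos=cds_pos,
        codon_index=codon_index,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        effect_class=effect,
    )
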