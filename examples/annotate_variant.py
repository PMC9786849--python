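"""Predict the protein consequence of a coding G→A SNV.

Builds a single-exon toy lectin-receptor-kinase-like gene whose codon 268 is
CGG (arginine) and asks what a G→A substitution at the middle codon base
(CDS position 803) does: CGG→CAG, an Arg→Gln missense at residue 268.
"""

from poolmap.annotate import GeneModel, predict_effect, project_to_cds

FILL = ["GCT", "GAA", "TTC", "GGA", "CTT", "AAA", "CCG", "TCA"]
codons = ["ATG"] + [FILL[i % 8] for i in range(298)] + ["TAA"]
codons[267] = "CGG"  # residue 268
cds = "".join(codons)
gene = GeneModel("toyLecRK", cds, strand="+", exons=((101, 100 + len(cds)),))

genomic_pos = 101 + 802  # CDS position 803 on the chromosome
cds_pos = project_to_cds(gene, genomic_pos)
effect = predict_effect(gene, cds_pos, "G", "A")
print(f"genomic {genomic_pos} -> CDS position {cds_pos} "
      f"(codon {effect.codon_index})")
print(f"{effect.ref_codon} -> {effect.alt_codon}: "
      f"{effect.ref_aa}{effect.codon_index}{effect.alt_aa}, "
      f"{effect.effect_class}")
# R268Q: the arginine-to-glutamine substitution class of causal missense hit.
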