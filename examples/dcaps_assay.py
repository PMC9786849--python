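"""Judge a ClaI dCAPS genotyping assay from its two allelic amplicons.

The 96 bp wild-type amplicon carries one ClaI site (AT/CGAT) and cleaves
into 72 + 24 bp; the mutant allele ablates the site by a G→A change and
stays uncut, so the two alleles separate on a 2% agarose gel.
"""

from poolmap import markers

wt, mut = markers.dcaps_example_amplicons()
cla = markers.get_enzyme("ClaI")

for name, amplicon in (("wild-type", wt), ("mutant", mut)):
    res = markers.digest(amplicon, cla)
    print(f"{name} allele: fragments {list(res.fragments)} bp "
          f"(cuts after base {list(res.cut_positions) or 'none'})")

verdict = markers.evaluate_marker(wt, mut, cla, min_diff_bp=10)
print(f"marker usable: {verdict.usable} "
      f"(smallest distinguishing fragment difference {verdict.distinguishing_diff} bp)")
# 72+24 vs uncut 96 differ by 24 bp — comfortably resolvable on a gel.
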