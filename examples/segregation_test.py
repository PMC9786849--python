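"""Test observed phenotype counts against Mendelian segregation ratios.

A fully penetrant recessive mutation segregates 3:1 (wild type : mutant) in
a selfed heterozygote's offspring; the chi-square goodness-of-fit test asks
whether observed counts are consistent with that expectation.
"""

from poolmap.segtest import bh_adjust, chi_square_gof

for observed in ([55, 15], [94, 23], [75, 25]):
    res = chi_square_gof(observed, [3, 1])
    print(res)
# P well above 0.05 in each case: no evidence against 3:1 recessive
# inheritance.

p_adj = bh_adjust([0.001, 0.012, 0.03, 0.2, 0.6])
print("BH-adjusted p-values:", [float(round(p, 4)) for p in p_adj])
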