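# poolmap

A toolkit for **mapping-by-sequencing** of recessive mutations by bulk
segregant analysis (BSA-seq), built around the workflow that localizes an
induced tomato mutation from two pooled DNA libraries: a mutant line in a
reference-like background (*Solanum lycopersicum* cv. Moneymaker) crossed to
the wild relative *S. pimpinellifolium*, the F1 selfed, and DNA bulks of
phenotypically wild-type and mutant F2 plants sequenced and compared.

It is intended for geneticists who want to prototype, teach, or sanity-check
BSA-seq designs: every stage runs at desk scale on synthetic data with known
ground truth, and the mapping stages accept any two-sample VCF with
per-pool allele depths.

## What it computes

For each biallelic variant with pooled read counts, the **allele-frequency
ratio** in pool *p* is

&nbsp;&nbsp;&nbsp;&nbsp;AF_p = alt reads / (ref reads + alt reads),

averaged in sliding windows of 1000 variants advancing by 100 variants along
each chromosome. In an F2 from a reference-background recessive mutant
crossed to a divergent accession, the mutant bulk is *depleted* of
non-reference alleles around the causal locus (mutant plants are homozygous
for the mutant parent's chromosome there), while unlinked regions sit near
AF ≈ 0.5 in both bulks. Windows with AF_mut ≤ 0.2 and AF_wt − AF_mut ≥ 0.25
are merged into candidate regions; region variants are then nominated as
causal when (i) the alternative allele is heterozygous-like (0/1) in the
wild-type bulk and homozygous (1/1) in the mutant bulk, and (ii) the variant
is absent from a catalog of previously reported variants.

Around that core the package provides:

- `poolmap.popsim` — F2 cross simulator (Haldane map, Poisson crossovers,
  fully penetrant recessive phenotype, pooled Poisson/binomial read
  sampling) with VCF 4.2 output and a ground-truth sidecar;
- `poolmap.afmap` — VCF reading/filtering, window profiles, region
  detection, TSV/plot export;
- `poolmap.candfilter` — pooled pseudo-genotype calls and the two-criterion
  candidate filter;
- `poolmap.annotate` — strand-aware CDS projection and codon-level
  consequence prediction (e.g. a G→A that turns CGG into CAG: Arg→Gln);
- `poolmap.markers` — CAPS/dCAPS restriction assays: IUPAC site scanning,
  in-silico digestion, marker-usability verdicts;
- `poolmap.segtest` — Mendelian segregation χ² tests and Benjamini–Hochberg
  FDR adjustment;
- `poolmap.expression_qc` — TPM normalization, top-K cumulative-expression
  selection, Z-score complete-linkage biclustering for replicate screening,
  three-way DE-list overlap, ΔΔCt relative expression.

## Worked example

`examples/simulate_and_map.py` simulates the default cross (12 chromosomes ×
2000 markers, 117 F2 plants, bulks of 25 + 16, ~40× pooled depth, causal SNP
mid-chromosome 4) and runs the full mapping stage:

```
simulated F2: 117 plants, 39 mutant phenotype (expected ~29 under 3:1 segregation)
24000 biallelic variants pass the min-depth-10 filter
top candidate region: ch04:2500-4750000 (10 windows, mean WT-mutant AF difference 0.437)
true causal locus ch04:2502500 inside: True
passing candidate: ch04:2502500 G>A  WT pool het (AF 0.41), mutant pool hom_alt (AF 1.00)
```

The top-ranked region is on the causal chromosome and contains the true
locus, and the only variant passing both candidate criteria is the injected
causal SNP: ~1/3 alternative-allele frequency in the wild-type bulk (the 2:1
heterozygote:homozygote mix among phenotypically wild-type plants), fixed in
the mutant bulk, and absent from the known-variant catalog.

The other example scripts each print one capability: `dcaps_assay.py` (the
96 bp ClaI amplicon cutting 72 + 24 bp for the wild-type allele and staying
uncut for the mutant), `annotate_variant.py` (G→A at CDS position 803 →
R268Q missense), `segregation_test.py` (55:15 vs 3:1 → χ²=0.48, P=0.49;
94:23 → χ²=1.78, P=0.18) and `expression_qc.py` (TPM sums of 10⁶, a planted
inconsistent replicate flagged, the three-stage DE overlap and a ΔΔCt fold
of 16).

A thin CLI mirrors the library: `poolmap simulate | map | filter | annotate
| dcaps | segtest | tpm` (see `poolmap --help`).

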