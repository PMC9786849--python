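# Methods

## The mapping model

The pipeline targets the classic bulk-segregant design for a recessive
mutation: a mutant isolated in a reference-like background is crossed to a
divergent accession, the F1 is selfed, and two DNA bulks are sequenced — one
of phenotypically wild-type F2 plants, one of mutant plants. Because mutant
plants must be homozygous for the mutant parent's chromosome at the causal
locus, the mutant bulk is locally depleted of the divergent accession's
alleles, while unlinked loci segregate 1:2:1 and give pooled allele
frequencies near 0.5 in both bulks. The causal site itself is coded the
other way round: its alternative allele is the induced mutation (alternative
to the reference assembly), so the mutant bulk is *fixed* for ALT there and
the wild-type bulk shows the 1/3 frequency of the 2:1
heterozygote:homozygous-reference mix among phenotypically wild-type
plants. Both allele-coding conventions coexist in one VCF; the candidate
filter depends on that asymmetry and must not conflate them.

## Cross simulator (`popsim`)

Meiosis uses the Haldane model: crossovers per chromosome per gamete are
Poisson with mean = genetic length / 100 Morgans, positions uniform in
genetic distance, no interference; marker genetic positions come from a
linear bp→cM map. Phenotype is fully penetrant recessive at the causal
marker. Pools are drawn without replacement from the phenotype classes.
Pooled sequencing draws per-marker, per-pool depth from Poisson(mean_depth)
and alt read counts from Binomial(depth, p(1−e)+(1−p)e), where p is the
pool's alt-haplotype fraction and e the per-read miscall rate — exactly
equivalent to drawing each read from a uniformly chosen pool haplotype and
flipping it with probability e.

Defaults define the study conditions: 117 F2 plants, bulks of 25 wild-type
and 16 mutant plants, depth 40×, base error 10⁻³. The default genome is
desk-scale but tomato-shaped: 12 chromosomes of 5 Mb / 100 cM with 2000
evenly spaced markers each, so the 1000/100 window defaults yield 11 windows
per chromosome. Depth and error rate are simulator choices on the scale of
pooled HiSeq-class data; no published per-pool depth was available to copy.
80% of non-causal markers are placed in the known-variant catalog (natural
interspecific polymorphisms are mostly previously reported); the causal site
never is. A single seed governs all sampling through three spawned
sub-streams (meiosis, pool selection, read sampling) with documented draw
order, so a given seed and config reproduce the VCF byte for byte.

What the simulator does **not** emulate: read-level errors with quality
scores, alignment and variant-calling artifacts, indels and structural
variants, segregation distortion (real interspecific tomato crosses show
some), phenotyping error, and non-uniform marker density or recombination
landscapes. Passing recovery tests therefore show the statistical logic is
sound under clean Mendelian sampling, not that the pipeline is robust to
caller artifacts.

## Windowing and region detection (`afmap`)

Variants are filtered to biallelic SNVs with ≥ 10 reads in *each* pool
(boundary inclusive). Windows are defined in variant-rank space — 1000
variants advancing by 100 — because the statistic's density should follow
marker density, not physical distance; bp bounds are derived from member
variants only for reporting. Window means are unweighted means of
per-variant frequency ratios, not ratios of pooled counts. Trailing
variants that cannot fill a final full window get no extra window; a
chromosome shorter than one window yields a single window flagged partial.

Detection thresholds (mutant-bulk window AF ≤ 0.2 and WT−mutant difference
≥ 0.25) are package choices exposed in the API/CLI: no numeric cutoff was
published for calling the depleted region, so these were set once to
separate the fully linked expectation (mutant bulk ≈ 0, WT ≈ 2/3) from the
unlinked 0.5/0.5 background with margin at 40× depth. One consequence of
the desk-scale genome is worth stating: with 2000 markers per 100 cM
chromosome, a 1000-variant window spans ~50 cM, so even the window centred
on the causal locus averages Haldane recombination fractions up to 25 cM
away and has expected mutant-bulk AF ≈ 0.107 (measured 0.10 ± 0.03 across
seeds), not ≈ 0. The 0.2 threshold absorbs this; on a real-genome marker
density the causal window would sit far lower. Flagged windows overlapping
or abutting in rank space merge into regions, ranked by mean WT−mutant
difference (ties: more windows, then chromosome name). Coordinates are
1-based inclusive in memory and in TSVs, converted to 0-based half-open
only at the BED boundary.

## Candidate filter (`candfilter`)

Bulk DNA has no diploid genotype, so "0/1" and "1/1" states are called from
pooled alt frequency with thresholds het_low = 0.15 and het_high = 0.85
(boundaries inclusive for het): chosen once to separate the expected 1/3
(WT bulk at the causal site) and 1.0 (mutant bulk) at depth ≥ 20 with
margin. With 25 wild-type plants at 40×, the WT-bulk frequency has
σ ≈ 0.09 (pool composition + read sampling), so roughly 2% of simulations
put the causal site below 0.15 and fail criterion (i) — visible as the
rare missed seed in recovery runs. Novelty (criterion ii) matches
chrom/pos/ref/alt exactly against a user-supplied catalog (VCF or 4-column
TSV); which reference variant lists to use is deliberately left to the
user.

## Consequence prediction (`annotate`)

Single-nucleotide substitutions on a spliced CDS only, standard nuclear
code, residue numbering 1-based from the initiator methionine. Variants are
specified on the forward genomic strand (VCF convention) and complemented
internally for minus-strand genes. The worked R268Q example fixes codon 268
as CGG: an exhaustive codon-table scan (in the test suite) shows CGG→CAG
and CGA→CAA are the only Arg→Gln changes reachable by a single G→A, so the
choice is unique up to that pair.

## Restriction markers (`markers`)

Linear amplicons, top-strand scanning only (all bundled enzymes have
palindromic sites), IUPAC ambiguity allowed in recognition sequences but
not amplicons, overlapping sites counted. A cut at offset o of a site
starting at s falls after base s−1+o; cuts on the amplicon ends are
no-ops. The gel model is fragment-size arithmetic: a marker is usable when
the allele digests differ as multisets and the smallest distinguishing
fragment difference is ≥ min_diff_bp (default 10 bp ≈ 2% agarose
resolution in this size range). The bundled 96 bp amplicon pair is
synthetic — it reproduces the assay arithmetic (72+24 vs uncut 96, site
ablated by G→A), not any real gene sequence.

## Segregation statistics (`segtest`)

χ² goodness of fit with expected counts total × ratioᵢ/Σratio, df = k−1,
**no Yates correction** — the continuity-corrected statistic would not
reproduce the standard worked values (55:15 vs 3:1 → 0.476…, printed 0.48).
Full precision is kept internally; display rounds to 2 dp. The χ²
approximation is poor for expected counts below ~5; the type-I error
property test uses class totals well above that, and users with tiny counts
should prefer exact tests (out of scope here). BH adjustment delegates to
statsmodels.

## Expression QC (`expression_qc`)

TPM: per-sample length-normalized rates rescaled to 10⁶ (identity enforced
to 10⁻⁶ relative). Replicate screening selects the top-K genes by
cumulative TPM across all samples (K = 5000 by default; ties break by gene
id), Z-scores each gene across **all** retained samples (matching heatmap
convention, not per group), and clusters samples and genes with complete
linkage on Euclidean distance. A replicate is flagged when the sibling
cluster of its first merge in the sample dendrogram contains no sample of
its own (stage, genotype) group — an operational form of "clusters away
from its replicates" that captures the realistic failure mode (a library
resembling another condition) but not a library so aberrant it joins the
tree last at the root. Dendrograms export as Newick. The DE test itself is
out of scope: `stage_overlap` consumes externally produced per-stage DE
lists and returns the exclusive 7-region partition plus a
direction-consistency table for the triple intersection. ΔΔCt returns
2^(−ΔΔCt) with no efficiency correction.

## Numerical and testing choices

Window means use cumulative sums (exact to ~10⁻¹² against brute force);
all stochastic tests fix seeds; property tests (hypothesis) are
derandomized. Test problem sizes are scaled to the desk: recovery runs use
the default 12×2000-marker genome across 20 seeds, Mendelian-ratio checks
use 10,000 plants on a 2-chromosome genome, and the type-I error simulation
uses 10⁴ multinomial replicates. The acceptance script reports the dCAPS
fragment length (n = 96 bp amplicon) and the F2 segregation ratio
(n = 10,000 plants).

## Known limitations

Two pools only; SNVs only; no confidence bands on AF differences (QTL-seq
style simulation intervals) and no G-statistic smoothing; no mismatch-primer
dCAPS design; no splice/UTR effect classes; TPM is the only expression
transform offered (variance-stabilizing transforms used by DE packages are
intentionally not reimplemented).
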