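"""Synthetic bulk-segregant datasets from a simulated interspecific F2 cross.

Emulates the design used to map a recessive tomato mutation: a mutant line in
a reference-like background (cv. Moneymaker) crossed to *Solanum
pimpinellifolium*, the F1 selfed, and two phenotype pools (wild-type-looking
and mutant plants) sequenced as DNA bulks.  The simulator tracks parental
ancestry at dense biallelic markers through meiosis (Haldane map, no
interference), assigns phenotypes by a fully penetrant recessive rule at the
causal site, and samples pooled short-read allele counts per marker.

Allele coding matches the real data's asymmetry: at background markers the
VCF ALT allele is the *S. pimpinellifolium* allele, while at the causal site
the ALT allele is the induced mutation (alternative to the reference
assembly, carried by the Moneymaker-background mutant parent).  Downstream
filters must cope with both conventions coexisting in one VCF.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

__all__ = [
    "GenomeMap",
    "CrossConfig",
    "CrossSimTruth",
    "PooledVariant",
    "toy_tomato_genome",
    "simulate_f2",
    "sample_pooled_reads",
    "write_sim_vcf",
    "write_truth",
    "write_known_catalog",
]

# Deterministic REF/ALT base pairs cycled over marker rank; the causal site is
# always REF=G ALT=A (an EMS-like G->A transition).
_BASE_CYCLE = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))
CAUSAL_REF, CAUSAL_ALT = "G", "A"


@dataclass(frozen=True)
class GenomeMap:
    """Marker landscape of a reduced, tomato-shaped genome.

    chromosomes: list of (name, length_bp, genetic_length_cM).
    marker_positions: per-chromosome sorted 1-based bp positions.
    known_catalog: per-chromosome frozenset of marker positions flagged as
        previously reported variants (the novelty-filter catalog).
    """

    chromosomes: tuple[tuple[str, int, float], ...]
    marker_positions: dict[str, np.ndarray]
    known_catalog: dict[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length_bp, length_cm in self.chromosomes:
            if length_cm <= 0:
                raise ValueError(f"{name}: genetic length must be > 0")
            pos = np.asarray(self.marker_positions[name])
            if pos.size < 2:
                raise ValueError(f"{name}: need >= 2 markers")
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"{name}: marker positions must be strictly increasing")
            if pos[0] < 1 or pos[-1] > length_bp:
                raise ValueError(f"{name}: marker positions outside [1, {length_bp}]")

    def chrom_names(self) -> list[str]:
        return [c[0] for c in self.chromosomes]

    def chrom_info(self, name: str) -> tuple[int, float]:
        for n, lb, lc in self.chromosomes:
            if n == name:
                return lb, lc
        raise KeyError(name)

    def marker_cm(self, name: str) -> np.ndarray:
        """Genetic positions of markers, assuming a linear bp->cM map."""
        length_bp, length_cm = self.chrom_info(name)
        return self.marker_positions[name] / length_bp * length_cm


@dataclass(frozen=True)
class CrossConfig:
    """Parameters of the simulated cross and pooled sequencing."""

    causal_chrom: str
    causal_pos: int
    n_f2: int = 117
    n_wt_pool: int = 25
    n_mut_pool: int = 16
    mean_depth: float = 40.0
    base_error: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wt_pool + self.n_mut_pool > self.n_f2:
            raise ValueError("pool sizes exceed population size")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0 <= self.base_error < 0.5:
            raise ValueError("base_error must be in [0, 0.5)")


@dataclass
class CrossSimTruth:
    """Ground truth of one simulated cross.

    ``gametes[chrom]`` has shape (n_f2, 2, n_markers) holding parental
    ancestry per haplotype: 0 = Moneymaker (mutant parent, reference-like),
    1 = pimpinellifolium.  At the causal site ancestry 0 carries the induced
    mutant allele, which is the VCF ALT there.
    """

    genome: GenomeMap
    config: CrossConfig
    gametes: dict[str, np.ndarray]
    is_mutant: np.ndarray  # bool per plant (fully penetrant recessive)
    pool: np.ndarray  # per plant: "wt", "mut" or "" (unpooled)

    @property
    def causal_index(self) -> int:
        pos = self.genome.marker_positions[self.config.causal_chrom]
        return int(np.searchsorted(pos, self.config.causal_pos))

    def causal_genotypes(self) -> np.ndarray:
        """Per-plant count of mutant alleles (ancestry-0 haplotypes) at the causal site."""
        g = self.gametes[self.config.causal_chrom][:, :, self.causal_index]
        return (g == 0).sum(axis=1)

    def pool_indices(self, pool: str) -> np.ndarray:
        return np.flatnonzero(self.pool == pool)


@dataclass(frozen=True)
class PooledVariant:
    """One biallelic site with per-pool ref/alt read counts."""

    chrom: str
    pos: int
    ref: str
    alt: str
    wt_ref: int
    wt_alt: int
    mut_ref: int
    mut_alt: int
    in_known_catalog: bool = False

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if min(self.wt_ref, self.wt_alt, self.mut_ref, self.mut_alt) < 0:
            raise ValueError("read counts must be >= 0")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def toy_tomato_genome(
    n_chrom: int = 12,
    chrom_length_bp: int = 5_000_000,
    genetic_length_cm: float = 100.0,
    markers_per_chrom: int = 2000,
    known_fraction: float = 0.8,
    catalog_seed: int = 0,
) -> GenomeMap:
    """Default desk-scale genome: 12 chromosomes, 5 Mb / 100 cM / 2000 evenly
    spaced markers each.  2000 markers per chromosome gives >= 11 windows at
    the default 1000/100 window settings.

    ``known_fraction`` of markers are placed in the known-variant catalog
    (natural interspecific polymorphisms are mostly previously reported);
    the catalog never includes the causal site by construction downstream.
    """
    rng = np.random.default_rng(catalog_seed)
    spacing = chrom_length_bp // markers_per_chrom
    chromosomes = []
    positions: dict[str, np.ndarray] = {}
    catalog: dict[str, frozenset[int]] = {}
    for i in range(1, n_chrom + 1):
        name = f"ch{i:02d}"
        chromosomes.append((name, chrom_length_bp, genetic_length_cm))
        pos = np.arange(1, markers_per_chrom + 1, dtype=np.int64) * spacing
        positions[name] = pos
        keep = rng.random(markers_per_chrom) < known_fraction
        catalog[name] = frozenset(int(p) for p in pos[keep])
    return GenomeMap(tuple(chromosomes), positions, catalog)


def default_cross_config(genome: GenomeMap, seed: int = 0, **kw) -> CrossConfig:
    """Place the causal SNP mid-chromosome-4 of the given genome."""
    chrom = "ch04" if "ch04" in genome.chrom_names() else genome.chrom_names()[0]
    pos_arr = genome.marker_positions[chrom]
    causal_pos = int(pos_arr[len(pos_arr) // 2])
    return CrossConfig(causal_chrom=chrom, causal_pos=causal_pos, seed=seed, **kw)


def _sample_gametes(
    rng: np.random.Generator,
    n_gametes: int,
    marker_cm: np.ndarray,
    length_cm: float,
    chunk: int = 2048,
) -> np.ndarray:
    """Sample ancestry vectors for F1 gametes on one chromosome.

    Crossover count ~ Poisson(length/100 Morgans), positions uniform in
    genetic distance (Haldane model, no interference).  Ancestry at a marker
    is the starting haplotype flipped once per crossover to its left.
    """
    out = np.empty((n_gametes, marker_cm.size), dtype=np.int8)
    for lo in range(0, n_gametes, chunk):
        hi = min(lo + chunk, n_gametes)
        m = hi - lo
        n_xo = rng.poisson(length_cm / 100.0, size=m)
        kmax = max(int(n_xo.max(initial=0)), 1)
        pos = rng.uniform(0.0, length_cm, size=(m, kmax))
        pos[np.arange(kmax)[None, :] >= n_xo[:, None]] = np.inf
        start = rng.integers(0, 2, size=m, dtype=np.int8)
        # parity of crossovers left of each marker
        parity = (pos[:, :, None] <= marker_cm[None, None, :]).sum(axis=1) & 1
        out[lo:hi] = (start[:, None] + parity) & 1
    return out


def simulate_f2(genome: GenomeMap, config: CrossConfig) -> CrossSimTruth:
    """Simulate an F2 population by selfing the fully heterozygous F1.

    Each plant receives two independent gametes per chromosome; expected
    single-marker genotype frequencies are 1:2:1.  Phenotype is mutant iff
    both causal-site haplotypes are of mutant-parent (Moneymaker) ancestry.
    Pools are drawn without replacement from the phenotype classes.

    Stream order of the seeded RNG (documented for reproducibility): one
    spawn for meiosis, one for pool selection, one reserved for read
    sampling; within meiosis, chromosomes in genome order, and per chunk of
    gametes: crossover counts, positions, starting haplotypes.
    """
    pos = genome.marker_positions.get(config.causal_chrom)
    if pos is None or config.causal_pos not in pos:
        raise ValueError(
            f"causal_pos {config.causal_pos} is not a marker on {config.causal_chrom}"
        )
    ss = np.random.SeedSequence(config.seed)
    meiosis_ss, pool_ss, _reads_ss = ss.spawn(3)
    rng = np.random.default_rng(meiosis_ss)

    gametes: dict[str, np.ndarray] = {}
    for name in genome.chrom_names():
        _, length_cm = genome.chrom_info(name)
        g = _sample_gametes(rng, 2 * config.n_f2, genome.marker_cm(name), length_cm)
        gametes[name] = g.reshape(config.n_f2, 2, -1)

    causal_idx = int(np.searchsorted(pos, config.causal_pos))
    causal = gametes[config.causal_chrom][:, :, causal_idx]
    is_mutant = (causal == 0).all(axis=1)

    pool_rng = np.random.default_rng(pool_ss)
    pool = np.full(config.n_f2, "", dtype="U3")
    wt_class = np.flatnonzero(~is_mutant)
    mut_class = np.flatnonzero(is_mutant)
    if wt_class.size < config.n_wt_pool:
        raise ValueError(
            f"wild-type phenotype class has {wt_class.size} plants, "
            f"fewer than the requested pool size {config.n_wt_pool}"
        )
    if mut_class.size < config.n_mut_pool:
        raise ValueError(
            f"mutant phenotype class has {mut_class.size} plants, "
            f"fewer than the requested pool size {config.n_mut_pool}"
        )
    pool[pool_rng.choice(wt_class, size=config.n_wt_pool, replace=False)] = "wt"
    pool[pool_rng.choice(mut_class, size=config.n_mut_pool, replace=False)] = "mut"
    return CrossSimTruth(genome, config, gametes, is_mutant, pool)


def sample_pooled_reads(
    truth: CrossSimTruth, genome: GenomeMap, config: CrossConfig
) -> Iterator[PooledVariant]:
    """Sample pooled read counts per marker and pool.

    Per marker and pool, depth ~ Poisson(mean_depth); each read comes from a
    uniformly chosen pool haplotype and is miscalled with ``base_error``
    (implemented as the exactly equivalent Binomial(depth, p(1-e)+(1-p)e)
    draw on the pool's ALT-haplotype fraction p).  At background markers ALT
    is the pimpinellifolium allele; at the causal site ALT is the mutant
    allele, so its pool frequencies invert.  The causal site is never in the
    known catalog.

    RNG stream order: chromosomes in genome order; per chromosome WT depth,
    WT alt counts, mutant depth, mutant alt counts.
    """
    ss = np.random.SeedSequence(config.seed)
    _, _, reads_ss = ss.spawn(3)
    rng = np.random.default_rng(reads_ss)

    wt_idx = truth.pool_indices("wt")
    mut_idx = truth.pool_indices("mut")
    err = config.base_error

    for name in genome.chrom_names():
        positions = genome.marker_positions[name]
        catalog = genome.known_catalog.get(name, frozenset())
        n_mark = positions.size
        # ALT-haplotype fraction per pool: pimpinellifolium ancestry fraction,
        # inverted at the causal column where ALT is the mutant allele.
        frac = {}
        for key, idx in (("wt", wt_idx), ("mut", mut_idx)):
            anc = truth.gametes[name][idx]  # (n_pool, 2, n_mark)
            p = anc.sum(axis=(0, 1)) / (2 * idx.size)
            if name == config.causal_chrom:
                ci = truth.causal_index
                p = p.copy()
                p[ci] = 1.0 - p[ci]
            frac[key] = p

        counts = {}
        for key in ("wt", "mut"):
            depth = rng.poisson(config.mean_depth, size=n_mark)
            p_eff = frac[key] * (1 - err) + (1 - frac[key]) * err
            alt = rng.binomial(depth, p_eff)
            counts[key] = (depth - alt, alt)

        for i in range(n_mark):
            pos_i = int(positions[i])
            if name == config.causal_chrom and pos_i == config.causal_pos:
                ref, alt_base = CAUSAL_REF, CAUSAL_ALT
                known = False
            else:
                ref, alt_base = _BASE_CYCLE[i % 4]
                known = pos_i in catalog
            yield PooledVariant(
                chrom=name,
                pos=pos_i,
                ref=ref,
                alt=alt_base,
                wt_ref=int(counts["wt"][0][i]),
                wt_alt=int(counts["wt"][1][i]),
                mut_ref=int(counts["mut"][0][i]),
                mut_alt=int(counts["mut"][1][i]),
                in_known_catalog=known,
            )


def _vcf_header(genome: GenomeMap | None, variants: Sequence[PooledVariant]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    if genome is not None:
        for name, length_bp, _ in genome.chromosomes:
            header.add_line(f"##contig=<ID={name},length={length_bp}>")
    else:
        seen: dict[str, int] = {}
        for v in variants:
            seen[v.chrom] = max(seen.get(v.chrom, 0), v.pos)
        for name, maxpos in seen.items():
            header.add_line(f"##contig=<ID={name},length={maxpos}>")
    header.add_line(
        '##INFO=<ID=KNOWN,Number=0,Type=Flag,Description="Previously reported variant">'
    )
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">'
    )
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_sample("wt_pool")
    header.add_sample("mut_pool")
    return header


def write_sim_vcf(
    variants: Iterable[PooledVariant],
    path: str,
    genome: GenomeMap | None = None,
    truth: CrossSimTruth | None = None,
    truth_path: str | None = None,
) -> None:
    """Write pooled variants as an uncompressed VCF 4.2 with samples
    ``wt_pool`` and ``mut_pool`` carrying AD and DP; optionally write the
    ground-truth sidecar alongside.  Input must be sorted by (chrom, pos)
    with chromosomes grouped; same seed and config give byte-identical
    output.
    """
    variants = list(variants)
    order: dict[str, int] = {}
    last: tuple[int, int] | None = None
    for v in variants:
        rank = order.setdefault(v.chrom, len(order))
        key = (rank, v.pos)
        if last is not None and key <= last:
            raise ValueError(f"variants not sorted at {v.chrom}:{v.pos}")
        last = key

    header = _vcf_header(genome, variants)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for v in variants:
            rec = vcf.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            if v.in_known_catalog:
                rec.info["KNOWN"] = True
            rec.samples["wt_pool"]["AD"] = (v.wt_ref, v.wt_alt)
            rec.samples["wt_pool"]["DP"] = v.wt_ref + v.wt_alt
            rec.samples["mut_pool"]["AD"] = (v.mut_ref, v.mut_alt)
            rec.samples["mut_pool"]["DP"] = v.mut_ref + v.mut_alt
            vcf.write(rec)
    if truth is not None and truth_path is not None:
        write_truth(truth, truth_path)


def write_truth(truth: CrossSimTruth, path: str) -> None:
    """Ground-truth sidecar: key-value header plus one row per plant."""
    cfg = truth.config
    causal_geno = truth.causal_genotypes()
    with open(path, "w") as fh:
        fh.write(f"#causal_chrom\t{cfg.causal_chrom}\n")
        fh.write(f"#causal_pos\t{cfg.causal_pos}\n")
        fh.write(f"#seed\t{cfg.seed}\n")
        fh.write("plant\tpool\tphenotype\tcausal_genotype\n")
        for i in range(cfg.n_f2):
            pheno = "mutant" if truth.is_mutant[i] else "wild_type"
            pool = truth.pool[i] or "none"
            fh.write(f"F2_{i + 1:04d}\t{pool}\t{pheno}\t{int(causal_geno[i])}\n")


def write_known_catalog(variants: Iterable[PooledVariant], path: str) -> int:
    """Write flagged variants as the 4-column known-variant catalog TSV."""
    n = 0
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for v in variants:
            if v.in_known_catalog:
                fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\n")
                n += 1
    return n
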