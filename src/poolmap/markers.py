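"""In-silico CAPS/dCAPS genotyping: restriction-site scanning, digestion and
marker-usability verdicts.

A dCAPS assay genotypes a SNP by PCR-amplifying a short fragment and
digesting it with an enzyme whose recognition site is present in one allele
and ablated in the other; alleles are then distinguished by fragment sizes
on a gel.  The model here is purely arithmetic: linear amplicons, top-strand
scanning (all bundled enzymes have palindromic sites), and a minimum
resolvable fragment-size difference standing in for gel resolution.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass
from importlib import resources

__all__ = [
    "Enzyme",
    "DigestResult",
    "MarkerVerdict",
    "load_enzymes",
    "get_enzyme",
    "scan_sites",
    "digest",
    "evaluate_marker",
    "dcaps_example_amplicons",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class Enzyme:
    """A restriction endonuclease: recognition sequence (IUPAC-ambiguous
    allowed) and top-strand cut offset within the site (ClaI AT/CGAT has
    offset 2)."""

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.site.upper()
        if len(site) < 4:
            raise ValueError("recognition sequence must be >= 4 bases")
        if any(b not in IUPAC for b in site):
            raise ValueError(f"non-IUPAC base in recognition sequence {site!r}")
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError("cut offset must lie within the recognition site")
        object.__setattr__(self, "site", site)

    @property
    def pattern(self) -> re.Pattern:
        # lookahead so overlapping matches are found
        body = "".join(b if len(IUPAC[b]) == 1 else f"[{IUPAC[b]}]" for b in self.site)
        return re.compile(f"(?={body})")


@dataclass(frozen=True)
class DigestResult:
    """Ordered outcome of digesting one linear amplicon."""

    amplicon_length: int
    cut_positions: tuple[int, ...]  # 1-based, cut falls after this base
    fragments: tuple[int, ...]  # left-to-right lengths; sum == amplicon_length


@dataclass(frozen=True)
class MarkerVerdict:
    usable: bool
    distinguishing_diff: int | None  # bp; None when digests are identical
    wt_digest: DigestResult
    mut_digest: DigestResult
    min_diff_bp: int


def load_enzymes() -> dict[str, Enzyme]:
    """Built-in enzyme catalog (editable TSV shipped with the package)."""
    text = resources.files("poolmap").joinpath("data/enzymes.tsv").read_text()
    out = {}
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        out[row["name"]] = Enzyme(row["name"], row["site"], int(row["cut_offset"]))
    return out


def get_enzyme(name: str) -> Enzyme:
    enzymes = load_enzymes()
    try:
        return enzymes[name]
    except KeyError:
        raise KeyError(f"unknown enzyme {name!r}; catalog has {sorted(enzymes)}") from None


def scan_sites(sequence: str, enzyme: Enzyme) -> list[int]:
    """All 1-based top-strand start positions of the recognition site,
    overlapping matches included; case-insensitive."""
    seq = sequence.upper()
    return [m.start() + 1 for m in enzyme.pattern.finditer(seq)]


def digest(amplicon: str, enzyme: Enzyme) -> DigestResult:
    """Cut a linear amplicon at every recognition site.

    Each site starting at 1-based position s cuts after base s-1+cut_offset;
    cuts falling on the fragment boundary (position 0 or the full length)
    produce no new fragment.
    """
    n = len(amplicon)
    cuts = sorted(
        {
            s - 1 + enzyme.cut_offset
            for s in scan_sites(amplicon, enzyme)
            if 0 < s - 1 + enzyme.cut_offset < n
        }
    )
    bounds = [0, *cuts, n]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestResult(n, tuple(cuts), fragments)


def evaluate_marker(
    wt_amplicon: str, mut_amplicon: str, enzyme: Enzyme, min_diff_bp: int = 10
) -> MarkerVerdict:
    """Judge whether an enzyme distinguishes two allelic amplicons.

    Usable iff the two digests yield different fragment multisets and the
    smallest distinguishing difference — the minimum, over fragments unique
    to either allele, of the distance to the nearest fragment of the other
    allele — is at least ``min_diff_bp`` (default 10 bp, roughly what a 2%
    agarose gel resolves in this size range).
    """
    if len(wt_amplicon) != len(mut_amplicon):
        raise ValueError("allelic amplicons must have equal length")
    if wt_amplicon.upper() == mut_amplicon.upper():
        raise ValueError("amplicons are identical; no variant to genotype")
    wt_dig = digest(wt_amplicon, enzyme)
    mut_dig = digest(mut_amplicon, enzyme)
    wt_frags, mut_frags = Counter(wt_dig.fragments), Counter(mut_dig.fragments)
    if wt_frags == mut_frags:
        return MarkerVerdict(False, None, wt_dig, mut_dig, min_diff_bp)
    diffs = []
    for uniq, other in ((wt_frags - mut_frags, mut_dig), (mut_frags - wt_frags, wt_dig)):
        for frag in uniq:
            diffs.append(min(abs(frag - g) for g in other.fragments))
    dist = min(diffs)
    return MarkerVerdict(dist >= min_diff_bp, dist, wt_dig, mut_dig, min_diff_bp)


def dcaps_example_amplicons() -> tuple[str, str]:
    """Synthetic 96 bp allele pair for the ClaI dCAPS worked example.

    The wild-type allele carries a single ATCGAT site positioned so the ClaI
    cut falls after base 72 (fragments 72 + 24 bp); the mutant allele
    ablates the site by the causal G→A change and stays uncut (96 bp).
    The flanking sequence is synthetic — only the fragment arithmetic is
    meaningful.
    """
    prefix = ("ACCTGGAGTC" * 7)[:70]
    suffix = ("GTGGACCTTA" * 2)[:20]
    wt = prefix + "ATCGAT" + suffix
    mut = prefix + "ATCAAT" + suffix  # G->A at the 4th site base
    assert len(wt) == len(mut) == 96
    return wt, mut
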