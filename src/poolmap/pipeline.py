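"""End-to-end convenience: simulate or load pooled variants, build window
profiles, detect the candidate region, and filter candidates within it."""

from __future__ import annotations

from dataclasses import dataclass

from . import afmap, candfilter
from .afmap import CandidateRegion, WindowProfile
from .candfilter import CandidateVariant
from .popsim import PooledVariant

__all__ = ["MappingResult", "run_mapping"]


@dataclass
class MappingResult:
    variants: list[PooledVariant]
    profiles: list[WindowProfile]
    regions: list[CandidateRegion]
    candidates: list[CandidateVariant]

    @property
    def top_region(self) -> CandidateRegion | None:
        return self.regions[0] if self.regions else None

    def passing(self) -> list[CandidateVariant]:
        return [c for c in self.candidates if c.passes]


def run_mapping(
    variants: list[PooledVariant],
    window_size: int = afmap.DEFAULT_WINDOW,
    step: int = afmap.DEFAULT_STEP,
    mut_af_max: float = afmap.DEFAULT_MUT_AF_MAX,
    delta_min: float = afmap.DEFAULT_DELTA_MIN,
    known_catalog: set[tuple[str, int, str, str]] | None = None,
    het_low: float = candfilter.HET_LOW,
    het_high: float = candfilter.HET_HIGH,
    min_depth: int = afmap.DEFAULT_MIN_DEPTH,
) -> MappingResult:
    """Window profiling, region detection and candidate filtering on
    depth-filtered pooled variants.  Candidates are filtered within the
    top-ranked region only; empty region list yields no candidates."""
    profiles = afmap.window_profile(variants, window_size, step)
    regions = afmap.detect_candidate_region(profiles, mut_af_max, delta_min)
    candidates: list[CandidateVariant] = []
    if regions:
        members = afmap.region_variants(variants, regions[0])
        candidates = candfilter.filter_candidates(
            members, known_catalog, het_low, het_high, min_depth
        )
    return MappingResult(variants, profiles, regions, candidates)
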