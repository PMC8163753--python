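"""End-to-end convenience: reads -> coverage -> composite -> array features."""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import (
    AlignedMatrix,
    CompositeProfile,
    composite_profile,
    extract_aligned_matrix,
    normalize_per_site,
)
from .coverage import CoverageTrack, compute_coverage, shift_reads_to_dyads
from .features import (
    ArrayFeatures,
    PeakCallParams,
    PeakSet,
    call_composite_peaks,
    quantify_array_features,
)
from .genome import BarrierSite, GenomeDef
from .synthetic import MappedRead


@dataclass
class QuantifyResult:
    """Everything the quantification pipeline produces for one sample."""

    coverage: CoverageTrack
    matrix: AlignedMatrix
    profile: CompositeProfile
    peaks: PeakSet
    features: ArrayFeatures | None
    n_reads_dropped: int


def quantify_reads(
    reads: list[MappedRead],
    genome: GenomeDef,
    sites: list[BarrierSite],
    flank: int = 1000,
    peak_params: PeakCallParams | None = None,
    normalize: bool = True,
    replicate_id: str = "",
) -> QuantifyResult:
    """Run the full quantification chain on mapped reads.

    Reads are recentered on dyads and extended to 50 bp fragments, coverage
    is computed, extracted in site-aligned orientation-flipped windows,
    per-site normalized, averaged into a composite, peak-called, and
    summarized as distance-to-barrier plus linker lengths.
    """
    shifted = shift_reads_to_dyads(reads, genome)
    coverage = compute_coverage(shifted.fragments, genome)
    matrix = extract_aligned_matrix(coverage, sites, flank=flank)
    if normalize:
        matrix = normalize_per_site(matrix)
    profile = composite_profile(matrix)
    peaks = call_composite_peaks(profile, peak_params)
    features = None
    if not peaks.is_empty:
        kinds = {s.kind for s in sites}
        features = quantify_array_features(
            peaks,
            barrier_kind=kinds.pop() if len(kinds) == 1 else "mixed",
            n_sites=profile.n_sites,
            replicate_id=replicate_id,
        )
    return QuantifyResult(
        coverage=coverage,
        matrix=matrix,
        profile=profile,
        peaks=peaks,
        features=features,
        n_reads_dropped=shifted.n_dropped,
    )
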