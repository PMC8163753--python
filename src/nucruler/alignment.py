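"""Site-aligned coverage matrices, composite profiles and site selection.

Coverage is extracted in a 2001 bp window (offsets -1000..+1000) centered on
each barrier site, orientation-flipped for minus-strand sites so "+offset"
always means downstream of the site. Each row is normalized to its own mean
(per-site normalization), and the composite profile is the column-wise mean
— the standard aggregate plot of phased-array analyses.

Site selection mirrors the common practice of ranking alignment points by an
external binding signal (e.g. an anti-GRF ChIP track) in a fixed window
upstream of the +1 nucleosome and keeping the top fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .genome import BarrierSite

DEFAULT_FLANK = 1000


@dataclass
class AlignedMatrix:
    """Sites x offsets coverage matrix with per-site metadata.

    ``values[i, j]`` is coverage at ``offsets[j]`` relative to site i's
    center, in the site's own orientation. ``row_meta`` carries site_id,
    kind, strand and score; ``n_excluded`` counts sites whose window did not
    fit their chromosome.
    """

    values: np.ndarray
    offsets: np.ndarray
    row_meta: pd.DataFrame
    n_excluded: int = 0
    n_zero_dropped: int = 0

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]


@dataclass
class CompositeProfile:
    """Mean per-offset normalized coverage over aligned sites."""

    offsets: np.ndarray
    values: np.ndarray
    n_sites: int

    def value_at(self, offset: int) -> float:
        return float(self.values[int(offset) - int(self.offsets[0])])


@dataclass
class SiteGroups:
    """Partition of GRF sites by promoter orientation.

    group1: motif on the sense strand of the downstream gene; group2: motif
    antisense to it; group3: sites at bidirectional (divergent) promoters;
    other: no gene within reach.
    """

    group1: list[str] = field(default_factory=list)
    group2: list[str] = field(default_factory=list)
    group3: list[str] = field(default_factory=list)
    other: list[str] = field(default_factory=list)


def extract_aligned_matrix(
    coverage: CoverageTrack,
    sites: list[BarrierSite],
    flank: int = DEFAULT_FLANK,
) -> AlignedMatrix:
    """Stack coverage windows centered on sites, flipping minus-strand rows.

    For a plus or unstranded site the row at offset o holds
    ``coverage[center + o]``; a minus-strand site is mirrored
    (``coverage[center - o]``). Sites within ``flank`` bp of a chromosome
    end are excluded rather than zero-padded, and counted.
    """
    if not sites:
        raise ValueError("empty site list")
    rows, meta, n_excluded = [], [], 0
    for site in sites:
        vec = coverage[site.chrom]
        center = site.center
        if center - flank < 0 or center + flank + 1 > len(vec):
            n_excluded += 1
            continue
        window = vec[center - flank: center + flank + 1]
        if site.strand == "-":
            window = window[::-1]
        rows.append(np.asarray(window, dtype=float))
        meta.append((site.site_id, site.kind, site.strand,
                     np.nan if site.score is None else site.score))
    if not rows:
        raise ValueError("no site window fits its chromosome")
    return AlignedMatrix(
        values=np.vstack(rows),
        offsets=np.arange(-flank, flank + 1),
        row_meta=pd.DataFrame(meta, columns=["site_id", "kind", "strand", "score"]),
        n_excluded=n_excluded,
    )


def normalize_per_site(matrix: AlignedMatrix) -> AlignedMatrix:
    """Divide each row by its own mean; drop (and count) all-zero rows."""
    means = matrix.values.mean(axis=1)
    keep = means > 0
    if not keep.any():
        raise ValueError("all rows have zero coverage")
    values = matrix.values[keep] / means[keep, None]
    return AlignedMatrix(
        values=values,
        offsets=matrix.offsets,
        row_meta=matrix.row_meta.loc[keep].reset_index(drop=True),
        n_excluded=matrix.n_excluded,
        n_zero_dropped=int((~keep).sum()),
    )


def composite_profile(matrix: AlignedMatrix) -> CompositeProfile:
    """Column-wise arithmetic mean of the aligned matrix."""
    if matrix.n_sites < 1:
        raise ValueError("need at least one row")
    return CompositeProfile(
        offsets=matrix.offsets.copy(),
        values=matrix.values.mean(axis=0),
        n_sites=matrix.n_sites,
    )


def score_sites_by_window(
    matrix: AlignedMatrix,
    window_start_offset: int = -280,
    window_len: int = 120,
    top_fraction: float = 0.125,
) -> tuple[pd.Series, list[str]]:
    """Score sites by mean signal in an upstream window; keep the top slice.

    The default window [-280, -160) is 120 bp wide ending 160 bp upstream of
    the alignment point. Returns per-site scores (indexed by site_id) and
    the site_ids of the top ``ceil(top_fraction * n)`` scorers, ties broken
    by site_id so selection is permutation-invariant.
    """
    lo = window_start_offset
    hi = window_start_offset + window_len
    first, last = int(matrix.offsets[0]), int(matrix.offsets[-1])
    if lo < first or hi > last + 1:
        raise ValueError(f"window [{lo}, {hi}) outside matrix offsets")
    cols = slice(lo - first, hi - first)
    scores = pd.Series(
        matrix.values[:, cols].mean(axis=1),
        index=matrix.row_meta["site_id"].tolist(),
        name="score",
    )
    n_keep = int(np.ceil(top_fraction * len(scores)))
    order = sorted(scores.index, key=lambda sid: (-scores[sid], sid))
    return scores, order[:n_keep]


def group_sites_by_orientation(
    sites: list[BarrierSite],
    gene_annotations: list[tuple[str, int, str]],
    max_upstream: int = 400,
) -> SiteGroups:
    """Partition GRF sites by orientation of the promoter they sit in.

    ``gene_annotations`` are (chrom, TSS, strand) triples. A site serves a
    gene when it lies within ``max_upstream`` bp upstream of that gene's
    TSS. A site upstream of two divergent genes is group3 (bidirectional
    promoter); otherwise motif strand equal to the gene strand is group1,
    opposite is group2; sites serving no gene fall into "other".
    """
    groups = SiteGroups()
    for site in sites:
        center = site.center
        plus_gene = any(
            chrom == site.chrom and 0 < tss - center <= max_upstream
            for chrom, tss, strand in gene_annotations if strand == "+"
        )
        minus_gene = any(
            chrom == site.chrom and 0 < center - tss <= max_upstream
            for chrom, tss, strand in gene_annotations if strand == "-"
        )
        if plus_gene and minus_gene:
            groups.group3.append(site.site_id)
        elif plus_gene or minus_gene:
            gene_strand = "+" if plus_gene else "-"
            if site.strand == gene_strand:
                groups.group1.append(site.site_id)
            else:
                groups.group2.append(site.site_id)
        else:
            groups.other.append(site.site_id)
    return groups


def sort_matrix_rows(
    matrix: AlignedMatrix, by: str = "score", descending: bool = True
) -> AlignedMatrix:
    """Reorder rows by a row_meta column (heat-map ordering).

    Typical keys: an external binding score, or an NFR length carried in as
    extra metadata. NaNs sort last either way.
    """
    if by not in matrix.row_meta.columns:
        raise KeyError(f"row_meta has no column {by!r}")
    order = matrix.row_meta[by].sort_values(
        ascending=not descending, na_position="last", kind="mergesort"
    ).index.to_numpy()
    return AlignedMatrix(
        values=matrix.values[order],
        offsets=matrix.offsets,
        row_meta=matrix.row_meta.loc[order].reset_index(drop=True),
        n_excluded=matrix.n_excluded,
        n_zero_dropped=matrix.n_zero_dropped,
    )


def write_matrix_tsv(matrix: AlignedMatrix, path) -> None:
    frame = pd.DataFrame(
        matrix.values,
        index=matrix.row_meta["site_id"],
        columns=[str(o) for o in matrix.offsets],
    )
    frame.to_csv(path, sep="\t")


def write_profile_tsv(profile: CompositeProfile, path) -> None:
    pd.DataFrame({"offset": profile.offsets, "value": profile.values}).to_csv(
        path, sep="\t", header=True, index=False
    )


def write_matrix_npz(matrix: AlignedMatrix, path) -> None:
    """Compact binary twin of the TSV matrix dump."""
    np.savez_compressed(
        path,
        values=matrix.values,
        offsets=matrix.offsets,
        site_id=matrix.row_meta["site_id"].to_numpy(dtype=object),
        kind=matrix.row_meta["kind"].to_numpy(dtype=object),
        strand=matrix.row_meta["strand"].to_numpy(dtype=object),
        score=matrix.row_meta["score"].to_numpy(dtype=float),
    )


def read_matrix_npz(path) -> AlignedMatrix:
    with np.load(path, allow_pickle=True) as data:
        meta = pd.DataFrame(
            {
                "site_id": data["site_id"],
                "kind": data["kind"],
                "strand": data["strand"],
                "score": data["score"],
            }
        )
        return AlignedMatrix(
            values=data["values"], offsets=data["offsets"], row_meta=meta
        )
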