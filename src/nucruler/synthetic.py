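"""Synthetic barrier-anchored nucleosome arrays and MNase-seq-like reads.

The generator builds the ground truth that the quantification pipeline is
tested against: barrier sites placed on a toy genome, phased regular arrays
of nucleosome dyads around each site, and 50 bp single-end reads whose 5'
ends sit 73 bp outside each dyad — the exact inverse of the dyad-recentering
step applied to real MNase-seq reads.

Array geometry (all bp):

* the first nucleosome's proximal flank sits ``phasing_distance`` from the
  barrier center, so its dyad mean is ``center + phasing + (footprint-1)/2``;
* subsequent dyads follow at a constant repeat of ``footprint + linker``;
* optionally mirrored upstream of the barrier;
* independent Gaussian jitter (sd = ``jitter_sd``) is added per nucleosome
  and rounded to integer bp, so the expected spacing stays equal to the
  parameter; overlapping jittered dyads are pushed apart symmetrically to
  exactly one footprint of separation, preserving order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import SITE_KINDS, BarrierSite, GenomeDef

# motif widths used when synthesizing sites: a Reb1-like GRF motif and the
# palindromic BamHI recognition site; +1 sites are single-bp dyad marks
_SITE_WIDTH = {"GRF": 8, "DSB": 6, "plus1": 1}

EDGE_MARGIN = 1000  # min distance of site centers from chromosome ends, bp


@dataclass(frozen=True)
class ArrayParams:
    """Geometry of a phased regular array around one barrier."""

    phasing_distance: int = 80
    linker: int = 60
    n_per_side: int = 3
    jitter_sd: float = 15.0
    footprint: int = 147
    both_sides: bool = True
    cumulative_jitter: bool = False

    def __post_init__(self) -> None:
        if self.phasing_distance < 0 or self.linker < 0:
            raise ValueError("phasing_distance and linker must be >= 0")
        if self.n_per_side < 1:
            raise ValueError("n_per_side must be >= 1")
        if self.footprint < 1:
            raise ValueError("footprint must be positive")

    @property
    def half_footprint(self) -> int:
        return (self.footprint - 1) // 2

    @property
    def repeat(self) -> int:
        return self.footprint + self.linker


@dataclass(frozen=True)
class Dyad:
    """A single nucleosome dyad position with provenance."""

    chrom: str
    pos: int
    site_id: str = ""


@dataclass(frozen=True)
class MappedRead:
    """A mapped single-end read, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"read strand must be + or -, got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError("read end must exceed start")


def make_synthetic_genome(
    n_chrom: int,
    chrom_length: int,
    n_sites: int,
    site_kind: str = "GRF",
    min_separation: int = 3000,
    seed: int = 0,
) -> tuple[GenomeDef, list[BarrierSite]]:
    """Place ``n_sites`` barrier sites uniformly on a toy genome.

    Sites are spread as evenly as possible across chromosomes, keep at least
    ``min_separation`` bp between centers and a 1000 bp margin from each
    chromosome end. GRF and +1 sites get random strands; DSB sites are
    unstranded. Deterministic for a fixed seed.

    Raises
    ------
    ValueError
        If the requested sites cannot be packed into the genome.
    """
    if site_kind not in SITE_KINDS:
        raise ValueError(f"invalid site kind: {site_kind!r}")
    if n_chrom < 1 or n_sites < 1:
        raise ValueError("need at least one chromosome and one site")
    rng = np.random.default_rng(seed)
    genome = GenomeDef(
        tuple(f"chrSim{i + 1}" for i in range(n_chrom)),
        tuple([chrom_length] * n_chrom),
    )

    per_chrom = [n_sites // n_chrom + (1 if i < n_sites % n_chrom else 0)
                 for i in range(n_chrom)]
    width = _SITE_WIDTH[site_kind]
    sites: list[BarrierSite] = []
    idx = 0
    for chrom, k in zip(genome.chrom_names, per_chrom):
        if k == 0:
            continue
        lo, hi = EDGE_MARGIN, chrom_length - EDGE_MARGIN
        # place k centers with pairwise gaps >= min_separation by sampling
        # uniform order statistics on the slack interval and re-inflating
        slack = (hi - lo) - (k - 1) * min_separation
        if slack <= 0:
            raise ValueError(
                f"cannot place sites: {k} sites with separation {min_separation} "
                f"do not fit in [{lo}, {hi}) on {chrom}"
            )
        offsets = np.sort(rng.integers(0, slack, size=k))
        centers = lo + offsets + min_separation * np.arange(k)
        for center in centers:
            strand = "." if site_kind == "DSB" else ("+" if rng.random() < 0.5 else "-")
            start = int(center) - width // 2
            sites.append(
                BarrierSite(
                    chrom=chrom,
                    start=start,
                    end=start + width,
                    strand=strand,
                    kind=site_kind,
                    site_id=f"site_{idx:05d}",
                )
            )
            idx += 1
    return genome, sites


def _mean_dyads(center: int, strand: str, params: ArrayParams) -> list[int]:
    """Jitter-free dyad positions for one site, downstream first.

    Downstream means increasing coordinate for "+"/"." sites and decreasing
    for "-" sites, so one-sided arrays follow the site's orientation.
    """
    sign = -1 if strand == "-" else 1
    first = params.phasing_distance + params.half_footprint
    down = [center + sign * (first + k * params.repeat) for k in range(params.n_per_side)]
    if not params.both_sides:
        return down
    up = [center - sign * (first + k * params.repeat) for k in range(params.n_per_side)]
    return down + up


def _resolve_overlaps(positions: np.ndarray, footprint: int) -> np.ndarray:
    """Push colliding dyads apart to exactly ``footprint`` separation.

    Operates on a sorted array; symmetric pairwise pushes, iterated until no
    adjacent pair is closer than one footprint. Order-preserving and
    deterministic.
    """
    pos = positions.astype(float)
    for _ in range(1000):
        gaps = np.diff(pos)
        bad = gaps < footprint
        if not bad.any():
            break
        for i in np.flatnonzero(bad):
            push = (footprint - (pos[i + 1] - pos[i])) / 2.0
            pos[i] -= push
            pos[i + 1] += push
    else:  # fall back to a left-to-right sweep; guaranteed to terminate
        for i in range(1, len(pos)):
            pos[i] = max(pos[i], pos[i - 1] + footprint)
    return np.rint(pos).astype(int)


def sample_array_dyads(
    genome: GenomeDef,
    sites: list[BarrierSite],
    params: ArrayParams,
    seed: int = 0,
) -> list[Dyad]:
    """Draw jittered nucleosome dyads for phased arrays around each site.

    Sites whose complete array (including footprints) would leave the
    chromosome are dropped; the number dropped is emitted as a warning.
    """
    rng = np.random.default_rng(seed)
    dyads: list[Dyad] = []
    n_dropped = 0
    h = params.half_footprint
    for site in sites:
        chrom_len = genome.length_of(site.chrom)
        means = np.array(sorted(_mean_dyads(site.center, site.strand, params)))
        jitter = rng.normal(0.0, params.jitter_sd, size=means.size)
        if params.cumulative_jitter:
            # accumulate along each side outward from the barrier
            order = np.argsort(np.abs(means - site.center), kind="stable")
            side = np.sign(means - site.center)
            acc = np.zeros_like(jitter)
            running: dict[float, float] = {}
            for j in order:
                running[side[j]] = running.get(side[j], 0.0) + jitter[j]
                acc[j] = running[side[j]]
            jitter = acc
        pos = np.sort(np.rint(means + jitter).astype(int))
        pos = _resolve_overlaps(pos, params.footprint)
        if pos[0] - h < 0 or pos[-1] + h >= chrom_len:
            n_dropped += 1
            continue
        dyads.extend(Dyad(site.chrom, int(p), site.site_id) for p in pos)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} sites whose arrays left the chromosome")
    return dyads


def dyads_to_reads(
    dyads: list[Dyad],
    genome: GenomeDef,
    reads_per_dyad: int = 100,
    strand_balance: float = 0.5,
    read_length: int = 50,
    seed: int = 0,
) -> list[MappedRead]:
    """Emit single-end reads whose 5' ends flank each dyad by 73 bp.

    A plus-strand read starts at ``pos - 73``; a minus-strand read's 5' end
    is at ``pos + 73`` (so its half-open end is ``pos + 74``). Strands are
    drawn Bernoulli(``strand_balance`` = probability of plus). Reads running
    past a chromosome end are dropped and counted in a warning.
    """
    if reads_per_dyad < 1:
        raise ValueError("reads_per_dyad must be >= 1")
    if not 0.0 <= strand_balance <= 1.0:
        raise ValueError("strand_balance must be in [0, 1]")
    rng = np.random.default_rng(seed)
    reads: list[MappedRead] = []
    n_dropped = 0
    for dyad in dyads:
        chrom_len = genome.length_of(dyad.chrom)
        plus = rng.random(reads_per_dyad) < strand_balance
        for is_plus in plus:
            if is_plus:
                start = dyad.pos - 73
                end = start + read_length
            else:
                end = dyad.pos + 74
                start = end - read_length
            if start < 0 or end > chrom_len:
                n_dropped += 1
                continue
            reads.append(MappedRead(dyad.chrom, start, end, "+" if is_plus else "-"))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} reads extending past chromosome ends")
    return reads


def reads_to_frame(reads: list[MappedRead]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in reads],
            "start": [r.start for r in reads],
            "end": [r.end for r in reads],
            "name": ".",
            "score": 0,
            "strand": [r.strand for r in reads],
        }
    )


def write_reads_bed(reads: list[MappedRead], path) -> None:
    reads_to_frame(reads).to_csv(path, sep="\t", header=False, index=False)


def read_reads_bed(path) -> list[MappedRead]:
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "strand": str},
    )
    return [
        MappedRead(str(c), int(s), int(e), str(st))
        for c, s, e, st in zip(frame.chrom, frame.start, frame.end, frame.strand)
    ]
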