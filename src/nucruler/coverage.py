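"""Dyad-centered fragment conversion and per-base genome coverage.

Mapped single-end MNase-seq reads are converted to nucleosome-dyad-centered
signal in two steps: each read is shifted 73 bp 3'-ward from its 5' end
(half the 147 bp nucleosome core footprint) to land on the inferred dyad,
then replaced by a 50 bp fragment centered on that dyad. Per-base coverage
of the fragments is the dyad-density track that all downstream alignment
and quantification consumes.

The 50 bp window is ``[dyad - 25, dyad + 25)`` — the dyad sits just left of
center; the 1 bp asymmetry of an even window cancels when up- and downstream
features are averaged. Fragments that would run off a chromosome are dropped
(not clipped) so total coverage remains exactly 50 x retained fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeDef
from .synthetic import Dyad, MappedRead

DYAD_SHIFT = 73
FRAGMENT_LENGTH = 50


@dataclass(frozen=True)
class DyadFragment:
    """A 50 bp dyad-centered fragment, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start != FRAGMENT_LENGTH:
            raise ValueError("dyad fragments are exactly 50 bp")


@dataclass
class ShiftResult:
    """Dyads and fragments retained by :func:`shift_reads_to_dyads`."""

    dyads: list[Dyad]
    fragments: list[DyadFragment]
    n_dropped: int = 0


@dataclass
class CoverageTrack:
    """Dense per-chromosome coverage vectors, one value per bp."""

    genome: GenomeDef
    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.genome.sizes.items():
            if chrom not in self.data:
                self.data[chrom] = np.zeros(length, dtype=float)

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))


def dyad_of(read: MappedRead) -> int:
    """Infer the dyad a read reports: 5' end shifted 73 bp inward."""
    if read.strand == "+":
        return read.start + DYAD_SHIFT
    return (read.end - 1) - DYAD_SHIFT


def shift_reads_to_dyads(
    reads: list[MappedRead], genome: GenomeDef | None = None
) -> ShiftResult:
    """Shift every read by 73 bp to its dyad and extend to a 50 bp fragment.

    Plus-strand reads shift right from their start, minus-strand reads shift
    left from their 5' end (``end - 1``); a read pair encoding the same dyad
    therefore yields an identical fragment. If ``genome`` is given, fragments
    extending past a chromosome end are dropped and counted.
    """
    half = FRAGMENT_LENGTH // 2
    result = ShiftResult([], [])
    for read in reads:
        pos = dyad_of(read)
        start, end = pos - half, pos + half
        if genome is not None:
            if start < 0 or end > genome.length_of(read.chrom):
                result.n_dropped += 1
                continue
        elif start < 0:
            result.n_dropped += 1
            continue
        result.dyads.append(Dyad(read.chrom, pos))
        result.fragments.append(DyadFragment(read.chrom, start, end))
    return result


def compute_coverage(
    fragments: list[DyadFragment], genome: GenomeDef
) -> CoverageTrack:
    """Exact integer per-base coverage of fragments over the genome."""
    track = CoverageTrack(genome)
    # difference-array accumulation: O(fragments + genome)
    for chrom in genome.chrom_names:
        starts = np.array([f.start for f in fragments if f.chrom == chrom], dtype=int)
        if starts.size == 0:
            continue
        ends = starts + FRAGMENT_LENGTH
        length = genome.length_of(chrom)
        if starts.min() < 0 or ends.max() > length:
            raise ValueError(f"fragment outside chromosome {chrom}")
        diff = np.zeros(length + 1, dtype=float)
        np.add.at(diff, starts, 1.0)
        np.add.at(diff, ends, -1.0)
        track.data[chrom] = np.cumsum(diff[:-1])
    unknown = {f.chrom for f in fragments} - set(genome.chrom_names)
    if unknown:
        raise ValueError(f"unknown chromosome(s): {sorted(unknown)}")
    return track


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Run-length encode the track as bedGraph with bit-exact integers."""
    rows = []
    for chrom in track.genome.chrom_names:
        vec = track.data[chrom]
        change = np.flatnonzero(np.diff(vec)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(vec)]))
        for s, e in zip(starts, ends):
            val = vec[s]
            if val != 0:
                out = int(val) if float(val).is_integer() else float(val)
                rows.append((chrom, int(s), int(e), out))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_bigwig(track: CoverageTrack, path) -> None:
    """Optional bigWig export; requires pyBigWig."""
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover
        raise ImportError("bigWig output needs the pyBigWig package") from exc
    bw = pyBigWig.open(str(path), "w")
    bw.addHeader(list(track.genome.sizes.items()))
    for chrom in track.genome.chrom_names:
        vec = track.data[chrom]
        bw.addEntries(chrom, 0, values=vec.astype(float).tolist(),
                      span=1, step=1)
    bw.close()


def read_bedgraph(path, genome: GenomeDef) -> CoverageTrack:
    frame = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    track = CoverageTrack(genome)
    for row in frame.itertuples(index=False):
        track.data[row.chrom][int(row.start):int(row.end)] = row.value
    return track
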