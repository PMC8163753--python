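"""Genome definitions, barrier sites, and their on-disk interchange formats.

Coordinates are 0-based half-open throughout, matching BED. A *barrier site*
is any genomic alignment point that phased nucleosome arrays are measured
against: a general regulatory factor (GRF) motif such as a Reb1 site, a
double-strand break (DSB) end such as a BamHI cut site, or an annotated +1
nucleosome dyad.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

SITE_KINDS = ("GRF", "DSB", "plus1")


@dataclass(frozen=True)
class GenomeDef:
    """A set of named chromosomes with lengths in bp."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def sizes(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.sizes[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome: {chrom!r}") from None


@dataclass(frozen=True)
class BarrierSite:
    """A genomic alignment point with strand, kind and optional score.

    ``center`` is the floor midpoint of the interval; for even-length motifs
    (e.g. the palindromic BamHI GGATCC) this is the base just left of the
    true midpoint. DSB sites carry strand ".".
    """

    chrom: str
    start: int
    end: int
    strand: str
    kind: str
    score: float | None = None
    site_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand: {self.strand!r}")
        if self.kind not in SITE_KINDS:
            raise ValueError(f"invalid site kind: {self.kind!r}")
        if self.kind == "DSB" and self.strand != ".":
            raise ValueError("DSB sites are unstranded (strand must be '.')")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def sites_to_frame(sites: list[BarrierSite]) -> pd.DataFrame:
    """Tabulate sites as a BED6-shaped DataFrame (name column = kind)."""
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "start": [s.start for s in sites],
            "end": [s.end for s in sites],
            "name": [s.kind for s in sites],
            "score": [0.0 if s.score is None else s.score for s in sites],
            "strand": [s.strand for s in sites],
            "site_id": [s.site_id for s in sites],
        }
    )


def write_sites_bed(sites: list[BarrierSite], path) -> None:
    """Write sites as BED6; the name column carries the site kind."""
    frame = sites_to_frame(sites).drop(columns="site_id")
    frame.to_csv(path, sep="\t", header=False, index=False)


def read_sites_bed(path) -> list[BarrierSite]:
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    return [
        BarrierSite(
            chrom=str(row["chrom"]),
            start=int(row["start"]),
            end=int(row["end"]),
            strand=str(row["strand"]),
            kind=str(row["name"]),
            score=float(row["score"]),
            site_id=f"site_{i:05d}",
        )
        for i, (_, row) in enumerate(frame.iterrows())
    ]


def write_chrom_sizes(genome: GenomeDef, path) -> None:
    """Two-column TSV in the UCSC chrom.sizes dialect."""
    pd.DataFrame(
        {"chrom": genome.chrom_names, "size": genome.chrom_lengths}
    ).to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path) -> GenomeDef:
    frame = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "size"], dtype={"chrom": str}
    )
    return GenomeDef(tuple(frame["chrom"]), tuple(int(s) for s in frame["size"]))
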