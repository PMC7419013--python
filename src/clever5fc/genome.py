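"""Core genomic containers: CpG registries, interval annotations, window grids.

Coordinate conventions
----------------------
CpG sites are identified by the 1-based coordinate of the plus-strand C of the
CpG dyad.  Interval annotations use BED-style 0-based half-open coordinates.
Conversions between the two live in the readers/writers (:mod:`clever5fc.io`)
and in the few operations that mix the two (window assignment, flank export).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd
from intervaltree import IntervalTree

from .errors import InvalidParameterError

Site = tuple[str, int]

#: Repeat subfamilies the synthetic annotation generator knows about, with the
#: family each belongs to (mirrors RepeatMasker's family/subfamily hierarchy).
REPEAT_FAMILIES: dict[str, str] = {
    "L1": "LINE",
    "L2": "LINE",
    "Alu": "SINE",
    "MIR": "SINE",
    "ERVK": "LTR",
    "ERV1": "LTR",
    "ERVL": "LTR",
    "ERVL-MaLR": "LTR",
    "SVA": "SVA",
    "ALR": "satellite",
}

#: Non-repeat element classes used for single-label site assignment.
ELEMENT_PRECEDENCE: tuple[str, ...] = (
    "promoter",
    "exon",
    "intron",
    "TTS-region",
    "intergenic",
)


@dataclass(frozen=True)
class GenomeMap:
    """Chromosome sizes plus the ordered registry of CpG sites.

    Parameters
    ----------
    chromosomes
        Mapping of chromosome name to length in bp.
    cpg_sites
        Ordered (chrom, pos) pairs; ``pos`` is the 1-based coordinate of the
        plus-strand C of the dyad.  Must be strictly increasing within each
        chromosome and inside chromosome bounds.
    """

    chromosomes: dict[str, int]
    cpg_sites: tuple[Site, ...]

    def __post_init__(self):
        last: dict[str, int] = {}
        for chrom, pos in self.cpg_sites:
            if chrom not in self.chromosomes:
                raise InvalidParameterError(f"CpG site on unknown chromosome {chrom!r}")
            if not 1 <= pos < self.chromosomes[chrom]:
                raise InvalidParameterError(
                    f"CpG position {chrom}:{pos} outside chromosome bounds"
                )
            if chrom in last and pos <= last[chrom]:
                raise InvalidParameterError(
                    f"CpG positions not strictly increasing at {chrom}:{pos}"
                )
            last[chrom] = pos

    @property
    def n_sites(self) -> int:
        return len(self.cpg_sites)

    def site_frame(self) -> pd.DataFrame:
        """CpG registry as a DataFrame with columns chrom, pos."""
        return pd.DataFrame(self.cpg_sites, columns=["chrom", "pos"])

    def __iter__(self) -> Iterator[Site]:
        return iter(self.cpg_sites)


@dataclass
class Interval:
    """A labeled genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    family: str | None = None
    subfamily: str | None = None

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise InvalidParameterError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )


class AnnotationSet:
    """Named interval classes with fast point-containment queries.

    Classes may overlap each other (a CpG can sit in an exon and a repeat at
    once); consumers choose between multi-label and precedence-resolved
    assignment via :func:`clever5fc.annotation.assign_sites`.
    """

    def __init__(self, classes: Mapping[str, Iterable[Interval]] | None = None):
        self._classes: dict[str, list[Interval]] = {}
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        if classes:
            for name, ivs in classes.items():
                for iv in ivs:
                    self.add(name, iv)

    def add(self, name: str, interval: Interval) -> None:
        self._classes.setdefault(name, []).append(interval)
        tree = self._trees.setdefault((name, interval.chrom), IntervalTree())
        tree.addi(interval.start, interval.end, interval)

    @property
    def class_names(self) -> list[str]:
        return sorted(self._classes)

    def intervals(self, name: str) -> list[Interval]:
        return list(self._classes.get(name, []))

    def __contains__(self, name: str) -> bool:
        return name in self._classes

    def contains_site(self, name: str, site: Site) -> bool:
        """Whether the 1-based point ``site`` falls in class ``name``."""
        chrom, pos = site
        tree = self._trees.get((name, chrom))
        # 1-based point pos corresponds to 0-based offset pos-1
        return bool(tree is not None and tree.overlaps_point(pos - 1))

    def classes_at(self, site: Site) -> list[str]:
        """All classes containing the site, sorted by name."""
        return sorted(n for n in self._classes if self.contains_site(n, site))

    def total_span(self, name: str) -> int:
        """Total bp covered by a class (overlaps within the class merged)."""
        span = 0
        by_chrom: dict[str, list[Interval]] = {}
        for iv in self._classes.get(name, []):
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            ivs = sorted(ivs, key=lambda i: i.start)
            cur_s, cur_e = ivs[0].start, ivs[0].end
            for iv in ivs[1:]:
                if iv.start > cur_e:
                    span += cur_e - cur_s
                    cur_s, cur_e = iv.start, iv.end
                else:
                    cur_e = max(cur_e, iv.end)
            span += cur_e - cur_s
        return span


@dataclass(frozen=True)
class WindowGrid:
    """Non-overlapping tiling of every chromosome with fixed-size windows.

    The last window of a chromosome may be partial.  Window ids are
    ``(chrom, start)`` with 0-based start.
    """

    window_size: int
    chromosomes: dict[str, int] = field(compare=True)

    def __post_init__(self):
        if self.window_size <= 0:
            raise InvalidParameterError("window_size must be positive")

    def window_of(self, site: Site) -> tuple[str, int]:
        """Window containing a 1-based site coordinate."""
        chrom, pos = site
        return (chrom, ((pos - 1) // self.window_size) * self.window_size)

    def windows(self) -> Iterator[tuple[str, int]]:
        for chrom, length in self.chromosomes.items():
            for start in range(0, length, self.window_size):
                yield (chrom, start)

    @property
    def n_windows(self) -> int:
        return sum(
            -(-length // self.window_size) for length in self.chromosomes.values()
        )
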