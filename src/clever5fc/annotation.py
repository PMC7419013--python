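"""Interval machinery: site-to-element assignment, promoter CpG-density
classes, window grids, 5fC-marked windows, and site-flank export."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, InvalidParameterError
from .genome import (
    ELEMENT_PRECEDENCE,
    AnnotationSet,
    GenomeMap,
    Interval,
    Site,
    WindowGrid,
)

__all__ = [
    "assign_sites",
    "classify_promoter",
    "MarkedWindows",
    "mark_windows",
    "export_flanks",
    "WindowGrid",
]

# Weber-style promoter CpG-density criteria, evaluated over 500-bp windows:
# HCP needs one window with GC >= 0.55 and CpG observed/expected >= 0.75;
# LCP means no window reaches observed/expected 0.48; the rest are ICP.
HCP_GC_MIN = 0.55
HCP_OE_MIN = 0.75
LCP_OE_MAX = 0.48


def assign_sites(
    sites: Iterable[Site],
    annotation: AnnotationSet,
    mode: str = "precedence",
    precedence: Sequence[str] = ELEMENT_PRECEDENCE,
) -> dict[Site, list[str]] | dict[Site, str]:
    """Label sites with the annotation classes that contain them.

    ``all_overlaps`` returns every containing class per site (the right input
    for enrichment); ``precedence`` returns exactly one label per site using
    the fixed element order promoter > exon > intron > TTS-region, with
    "intergenic" as the residual, so label fractions sum to 1.
    Sites on chromosomes absent from every annotated interval still resolve
    (to "intergenic" / empty list); a site is only flagged "unassigned" when
    its chromosome is unknown to the caller-supplied genome check upstream.
    """
    if mode not in ("all_overlaps", "precedence"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    if mode == "all_overlaps":
        return {site: annotation.classes_at(site) for site in sites}
    out: dict[Site, str] = {}
    order = [c for c in precedence if c != "intergenic"]
    for site in sites:
        label = "intergenic"
        for cls in order:
            if cls in annotation and annotation.contains_site(cls, site):
                label = cls
                break
        out[site] = label
    return out


def assign_sites_checked(
    sites: Iterable[Site],
    annotation: AnnotationSet,
    genome: GenomeMap,
    mode: str = "precedence",
) -> dict[Site, str] | dict[Site, list[str]]:
    """Like :func:`assign_sites` but labels sites on chromosomes unknown to
    ``genome`` as "unassigned" with a warning."""
    known, unknown = [], []
    for site in sites:
        (known if site[0] in genome.chromosomes else unknown).append(site)
    for site in unknown:
        warnings.warn(f"site on unknown chromosome: {site[0]}:{site[1]}",
                      stacklevel=2)
    labels = assign_sites(known, annotation, mode=mode)
    for site in unknown:
        labels[site] = "unassigned" if mode == "precedence" else ["unassigned"]
    return labels


def classify_promoter(
    window_stats: Sequence[tuple[float, float]],
) -> str:
    """Classify one promoter as HCP, ICP or LCP from its 500-bp windows.

    ``window_stats`` holds (GC fraction, CpG observed/expected) per sliding
    500-bp window across the promoter (TSS -1 kb to TSS +0.5 kb).
    """
    if not window_stats:
        raise InvalidParameterError("no window statistics for promoter")
    for gc, oe in window_stats:
        if not (0 <= gc <= 1) or oe < 0:
            raise InvalidParameterError(f"bad window stats (gc={gc}, oe={oe})")
    if any(gc >= HCP_GC_MIN and oe >= HCP_OE_MIN for gc, oe in window_stats):
        return "HCP"
    if all(oe < LCP_OE_MAX for _, oe in window_stats):
        return "LCP"
    return "ICP"


@dataclass(frozen=True)
class MarkedWindows:
    """Set of 5fC-marked windows, tied to the grid that defined them."""

    window_size: int
    windows: frozenset[tuple[str, int]]

    def __len__(self) -> int:
        return len(self.windows)

    def __contains__(self, window: tuple[str, int]) -> bool:
        return window in self.windows


def mark_windows(fc_sites: Iterable[Site], grid: WindowGrid) -> MarkedWindows:
    """Windows containing at least one 5fCpG site (half-open containment).

    Invariant to site order and to duplicate sites.
    """
    marked = frozenset(grid.window_of(site) for site in fc_sites)
    return MarkedWindows(window_size=grid.window_size, windows=marked)


def export_flanks(
    fc_sites: Iterable[Site], flank: int, genome: GenomeMap
) -> list[Interval]:
    """BED-style intervals covering ``flank`` bp on each side of every site.

    A site at 1-based position p maps to the 0-based half-open interval
    [p - flank - 1, p + flank), clipped to chromosome bounds — the region an
    external motif tool consumes.
    """
    if flank <= 0:
        raise InvalidParameterError("flank must be positive")
    out: list[Interval] = []
    for chrom, pos in fc_sites:
        length = genome.chromosomes.get(chrom)
        if length is None:
            warnings.warn(f"site on unknown chromosome: {chrom}:{pos}", stacklevel=2)
            continue
        start = max(0, pos - flank - 1)
        end = min(length, pos + flank)
        out.append(Interval(chrom, start, end))
    return out


def window_class_map(
    grid: WindowGrid,
    annotation: AnnotationSet,
    classes: Sequence[str] | None = None,
) -> dict[tuple[str, int], str]:
    """Assign each window the first class (in the given order) overlapping
    its midpoint; residual windows get "intergenic"."""
    classes = list(classes) if classes is not None else [
        c for c in ELEMENT_PRECEDENCE if c != "intergenic"
    ]
    out: dict[tuple[str, int], str] = {}
    for chrom, start in grid.windows():
        mid_1based = start + grid.window_size // 2 + 1
        label = "intergenic"
        for cls in classes:
            if cls in annotation and annotation.contains_site(cls, (chrom, mid_1based)):
                label = cls
                break
        out[(chrom, start)] = label
    return out
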