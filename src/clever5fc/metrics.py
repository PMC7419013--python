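"""Downstream landscape statistics over called 5fCpG sites.

Everything here consumes per-cell call sets (:class:`~clever5fc.calling.FcCallSet`)
and interval annotations; nothing re-touches raw counts.  The central
quantity is the 5fCpG *level* of a scope: called 5fC sites over called 5fC
plus unmodified-C sites, i.e. the modified fraction among confidently
genotyped CpGs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .annotation import MarkedWindows
from .calling import FcCallSet
from .errors import ConfigurationError, InvalidParameterError
from .genome import AnnotationSet, GenomeMap, Interval, Site, WindowGrid


# ---------------------------------------------------------------------------
# scope helpers

def _trees(intervals: Iterable[Interval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def sites_in_intervals(
    sites: Iterable[Site], intervals: Iterable[Interval]
) -> frozenset[Site]:
    """Sites whose 1-based position falls inside any interval (0-based
    half-open)."""
    trees = _trees(intervals)
    out = []
    for chrom, pos in sites:
        tree = trees.get(chrom)
        if tree is not None and tree.overlaps_point(pos - 1):
            out.append((chrom, pos))
    return frozenset(out)


# ---------------------------------------------------------------------------
# levels

def fc_level(
    calls: FcCallSet, scope: Iterable[Interval] | None = None
) -> float:
    """5fCpG level: n_fc / (n_fc + n_unmod) within ``scope`` (whole genome
    when ``scope`` is None).  NaN when no site of either kind lies in scope."""
    fc = calls.fc_sites
    unmod = calls.unmod_sites
    if scope is not None:
        intervals = list(scope)
        fc = sites_in_intervals(fc, intervals)
        unmod = sites_in_intervals(unmod, intervals)
    denom = len(fc) + len(unmod)
    if denom == 0:
        return float("nan")
    return len(fc) / denom


# ---------------------------------------------------------------------------
# stage merging

@dataclass
class StageCallSet:
    """Per-stage aggregate of the member cells' call sets.

    ``merged_fc`` is the union of per-cell 5fC calls; ``common_covered`` the
    CpGs at depth >= 3 in *every* member cell; ``stage_fc_fraction`` the
    share of commonly covered CpGs that were 5fC in at least one cell.
    """

    stage: str
    cells: list[FcCallSet] = field(repr=False)
    merged_fc: frozenset[Site] = field(init=False)
    common_covered: frozenset[Site] = field(init=False)

    def __post_init__(self):
        if not self.cells:
            raise InvalidParameterError("a stage needs at least one cell")
        self.merged_fc = frozenset().union(*(c.fc_sites for c in self.cells))
        common = self.cells[0].covered3
        for c in self.cells[1:]:
            common = common & c.covered3
        self.common_covered = common

    @property
    def stage_fc_fraction(self) -> float:
        if not self.common_covered:
            return float("nan")
        return len(self.merged_fc & self.common_covered) / len(self.common_covered)


def merge_stage(stage: str, cells: Sequence[FcCallSet]) -> StageCallSet:
    return StageCallSet(stage=stage, cells=list(cells))


def stage_transition(
    earlier: StageCallSet, later: StageCallSet
) -> dict[str, int]:
    """Classify each of the later stage's merged 5fC sites as inherited,
    newly generated, or undetermined.

    inherited: also 5fC in the earlier stage's merged set.  newly_generated:
    confidently unmodified (depth >= 3, never 5fC) in at least one earlier
    cell.  undetermined: not informatively covered earlier.  The three
    counts partition ``later.merged_fc`` exactly.
    """
    earlier_fc = earlier.merged_fc
    earlier_unmod = frozenset().union(*(c.unmod_sites for c in earlier.cells))
    counts = {"inherited": 0, "newly_generated": 0, "undetermined": 0}
    for site in later.merged_fc:
        if site in earlier_fc:
            counts["inherited"] += 1
        elif site in earlier_unmod:
            counts["newly_generated"] += 1
        else:
            counts["undetermined"] += 1
    return counts


# ---------------------------------------------------------------------------
# enrichment

def relative_enrichment(
    fc_sites: frozenset[Site] | set[Site],
    background: frozenset[Site] | set[Site],
    annotation: AnnotationSet,
    classes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-class log2 relative enrichment of 5fC sites over background.

    For each class, log2[(n_fc_in / n_fc_total) / (n_bg_in / n_bg_total)]
    where background is the covered-CpG universe the calls were drawn from.
    Classes with zero background occupancy, or zero 5fC occupancy, get NaN
    enrichment rather than +/- infinity.
    """
    fc_sites = frozenset(fc_sites)
    background = frozenset(background)
    if not fc_sites:
        raise InvalidParameterError("no 5fC sites: enrichment undefined")
    if not fc_sites <= background:
        raise InvalidParameterError("fc_sites must be a subset of background")
    names = list(classes) if classes is not None else annotation.class_names
    columns = ["class", "n_fc_in", "n_fc_total", "n_bg_in", "n_bg_total",
               "log2_enrichment"]
    if not names:
        return pd.DataFrame(columns=columns).set_index("class")
    rows = []
    n_fc, n_bg = len(fc_sites), len(background)
    for name in names:
        intervals = annotation.intervals(name)
        fc_in = len(sites_in_intervals(fc_sites, intervals))
        bg_in = len(sites_in_intervals(background, intervals))
        if bg_in == 0 or fc_in == 0:
            enr = float("nan")
        else:
            enr = math.log2((fc_in / n_fc) / (bg_in / n_bg))
        rows.append(
            {
                "class": name,
                "n_fc_in": fc_in,
                "n_fc_total": n_fc,
                "n_bg_in": bg_in,
                "n_bg_total": n_bg,
                "log2_enrichment": enr,
            }
        )
    return pd.DataFrame(rows).set_index("class")


# ---------------------------------------------------------------------------
# window profiles, variance, clustering

@dataclass
class WindowProfile:
    """Per-window 5fC level for one cell or one stage.

    ``counts`` maps window id -> (n_fc, n_unmod); the level n_fc /
    (n_fc + n_unmod) is defined only where the denominator is positive.
    """

    owner: str
    window_size: int
    counts: dict[tuple[str, int], tuple[int, int]] = field(repr=False)

    def level(self, window: tuple[str, int]) -> float:
        n_fc, n_unmod = self.counts.get(window, (0, 0))
        if n_fc + n_unmod == 0:
            return float("nan")
        return n_fc / (n_fc + n_unmod)

    def marked_windows(self) -> frozenset[tuple[str, int]]:
        return frozenset(w for w, (f, _) in self.counts.items() if f > 0)


def window_profile(
    fc_sites: Iterable[Site],
    unmod_sites: Iterable[Site],
    grid: WindowGrid,
    owner: str = "",
) -> WindowProfile:
    """Aggregate called sites into per-window (n_fc, n_unmod) counts."""
    counts: dict[tuple[str, int], list[int]] = {}
    for site in fc_sites:
        counts.setdefault(grid.window_of(site), [0, 0])[0] += 1
    for site in unmod_sites:
        counts.setdefault(grid.window_of(site), [0, 0])[1] += 1
    return WindowProfile(
        owner=owner,
        window_size=grid.window_size,
        counts={w: (f, u) for w, (f, u) in counts.items()},
    )


def retained_windows(profiles: Sequence[WindowProfile]) -> list[tuple[str, int]]:
    """Windows with a 5fCpG site identified in at least one profile — the
    retention rule used for both variance and clustering."""
    kept: set[tuple[str, int]] = set()
    for p in profiles:
        kept |= p.marked_windows()
    return sorted(kept)


def window_stats(
    profiles: Sequence[WindowProfile],
    class_map: Mapping[tuple[str, int], str] | None = None,
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Cross-cell variance of window 5fC levels over retained windows.

    Returns a per-window table (n_cells with a defined level, sample
    variance with the n-1 convention) and, when ``class_map`` is given, the
    median variance per class.  Windows with fewer than two defined levels
    are skipped.
    """
    if len(profiles) < 2:
        raise InvalidParameterError("need at least two profiles")
    rows = []
    for window in retained_windows(profiles):
        levels = np.array([p.level(window) for p in profiles])
        levels = levels[~np.isnan(levels)]
        if len(levels) < 2:
            continue
        rows.append(
            {
                "chrom": window[0],
                "start": window[1],
                "n_cells": len(levels),
                "variance": float(np.var(levels, ddof=1)),
            }
        )
    table = pd.DataFrame(rows, columns=["chrom", "start", "n_cells", "variance"])
    medians = None
    if class_map is not None and len(table):
        cls = [
            class_map.get((r.chrom, r.start), "intergenic")
            for r in table.itertuples()
        ]
        medians = table.assign(cls=cls).groupby("cls")["variance"].median()
        medians.name = "median_variance"
    return table, medians


@dataclass
class CorrelationResult:
    owners: list[str]
    rho: pd.DataFrame
    leaf_order: list[str] | None
    undefined_pairs: list[tuple[str, str]]


def correlation_cluster(
    profiles: Sequence[WindowProfile], min_joint_windows: int = 3
) -> CorrelationResult:
    """Pairwise Spearman correlation of window 5fC levels plus average-linkage
    hierarchical clustering on distance 1 - rho.

    Correlations use the windows where both profiles have a defined level;
    pairs with fewer than ``min_joint_windows`` such windows are flagged
    undefined and clustering is skipped if any pair is undefined.
    """
    if len(profiles) < 2:
        raise InvalidParameterError("need at least two profiles")
    windows = retained_windows(profiles)
    owners = [p.owner for p in profiles]
    mat = np.array([[p.level(w) for w in windows] for p in profiles])
    n = len(profiles)
    rho = np.eye(n)
    undefined: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            joint = ~np.isnan(mat[i]) & ~np.isnan(mat[j])
            if joint.sum() < min_joint_windows:
                rho[i, j] = rho[j, i] = np.nan
                undefined.append((owners[i], owners[j]))
                continue
            r = stats.spearmanr(mat[i, joint], mat[j, joint]).statistic
            # constant vectors give NaN; treat as undefined
            if np.isnan(r):
                undefined.append((owners[i], owners[j]))
            rho[i, j] = rho[j, i] = r
    rho_df = pd.DataFrame(rho, index=owners, columns=owners)
    leaf_order = None
    if not undefined and n >= 2:
        dist = squareform(1.0 - rho, checks=False)
        order = leaves_list(linkage(dist, method="average"))
        leaf_order = [owners[i] for i in order]
    return CorrelationResult(owners, rho_df, leaf_order, undefined)


# ---------------------------------------------------------------------------
# shared regions and paired differences

def shared_regions(
    a: MarkedWindows, b: MarkedWindows
) -> dict[str, frozenset | int]:
    """Partition two marked-window sets into a-specific / shared / b-specific."""
    if a.window_size != b.window_size:
        raise ConfigurationError("marked-window sets come from different grids")
    shared = a.windows & b.windows
    return {
        "a_specific": a.windows - shared,
        "b_specific": b.windows - shared,
        "shared": shared,
        "n_a_specific": len(a.windows - shared),
        "n_b_specific": len(b.windows - shared),
        "n_shared": len(shared),
    }


@dataclass
class PairedDiff:
    """Per-scope 5fCpG level difference between two paired cells
    (e.g. male minus female pronucleus, or blastomere A minus B)."""

    pair_id: str
    diffs: dict[str, float]


def paired_difference(
    member_a: FcCallSet,
    member_b: FcCallSet,
    scopes: Mapping[str, Iterable[Interval]] | None = None,
    pair_id: str = "",
) -> PairedDiff:
    """level(a) - level(b) genome-wide and per named scope; NaN propagates
    when either member's level is undefined.  Antisymmetric under swapping
    the members."""
    diffs = {"whole_genome": fc_level(member_a) - fc_level(member_b)}
    for name, intervals in (scopes or {}).items():
        ivs = list(intervals)
        diffs[name] = fc_level(member_a, ivs) - fc_level(member_b, ivs)
    return PairedDiff(pair_id=pair_id, diffs=diffs)


# ---------------------------------------------------------------------------
# signal metaplot

def signal_profile(
    fc_sites: Iterable[Site],
    track: pd.DataFrame,
    flank: int,
    n_bins: int,
    genome: GenomeMap,
) -> np.ndarray:
    """Mean signal in ``n_bins`` bins across [center - flank, center + flank)
    around each site, averaged over sites.

    ``track`` is bedGraph-like: columns chrom, start, end, value (0-based
    half-open).  Bin means are coverage-weighted within the track; bins with
    no track coverage at a site are missing for that site, and the profile
    is the across-site nanmean.  n_bins must be odd so a center bin exists.
    """
    if flank <= 0:
        raise InvalidParameterError("flank must be positive")
    if n_bins < 1 or n_bins % 2 == 0:
        raise InvalidParameterError("n_bins must be odd and >= 1")
    trees: dict[str, IntervalTree] = {}
    for row in track.itertuples():
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end, row.value
        )
    sums = np.zeros(n_bins)
    hits = np.zeros(n_bins)
    width = 2.0 * flank / n_bins
    for chrom, pos in fc_sites:
        length = genome.chromosomes.get(chrom)
        if length is None:
            continue
        tree = trees.get(chrom)
        center = pos - 0.5  # continuous 0-based center of the C base
        for b in range(n_bins):
            lo = max(0.0, center - flank + b * width)
            hi = min(float(length), center - flank + (b + 1) * width)
            if hi <= lo or tree is None:
                continue
            wsum = vsum = 0.0
            for iv in tree.overlap(lo, hi):
                ov = min(hi, iv.end) - max(lo, iv.begin)
                if ov > 0:
                    wsum += ov
                    vsum += ov * iv.data
            if wsum > 0:
                sums[b] += vsum / wsum
                hits[b] += 1
    with np.errstate(invalid="ignore"):
        return np.where(hits > 0, sums / np.maximum(hits, 1), np.nan)


# ---------------------------------------------------------------------------
# matched-control repeat comparison

def rpkm(count: float, length_bp: float, total_mapped_reads: float) -> float:
    """Reads per kilobase per million mapped reads."""
    if length_bp <= 0 or total_mapped_reads <= 0:
        raise InvalidParameterError("length and library size must be positive")
    return count / ((length_bp / 1000.0) * (total_mapped_reads / 1e6))


@dataclass
class MatchedComparison:
    marked_mean: float
    control_mean: float
    t_statistic: float
    p_value: float
    control_ids: list


def matched_repeat_comparison(
    marked: Sequence,
    unmarked: Sequence,
    values: Mapping,
    seed: int = 0,
) -> MatchedComparison:
    """Compare a per-repeat quantity (RPKM, methylation level, ...) between
    5fC-marked repeats and an equal-sized random draw of unmarked repeats.

    Controls are drawn uniformly without replacement (seeded, reproducible);
    significance is the standard two-tailed two-sample Student t test.
    """
    if len(marked) < 2:
        raise InvalidParameterError("need at least two marked repeats")
    if len(unmarked) < len(marked):
        raise InvalidParameterError("not enough unmarked repeats to match")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC7]))
    idx = rng.choice(len(unmarked), size=len(marked), replace=False)
    controls = [unmarked[i] for i in sorted(idx.tolist())]
    x = np.array([values[m] for m in marked], dtype=float)
    y = np.array([values[c] for c in controls], dtype=float)
    t = stats.ttest_ind(x, y)
    return MatchedComparison(
        marked_mean=float(x.mean()),
        control_mean=float(y.mean()),
        t_statistic=float(t.statistic),
        p_value=float(t.pvalue),
        control_ids=list(controls),
    )
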