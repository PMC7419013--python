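"""Single-cell 5fCpG identification.

The scheme, per treated cell:

1. estimate the labeling (conversion) efficiency from the spike-in model DNA
   and the random C-to-T background rate from lambda DNA;
2. build a *candidate pool* of CpG sites whose C-to-T ratio is >= 0.65 in at
   least two treated cells, and a *noise pool* built the same way from
   untreated (negative-control) cells;
3. in the cell, take CpG sites covered >= 3x with ratio >= 0.65 that are in
   the candidate pool, not in the noise pool, and not known SNPs;
4. test each against Binomial(NT + NC, background rate) — the upper-tail
   probability of seeing at least NT conversion reads by chance — and keep
   sites with Holm-Bonferroni adjusted p < 0.01;
5. call CpG sites covered >= 3x with ratio <= 0.25 as unmodified C.

`5fCpG abundance` is called sites over all sequenced CpG sites; running the
same procedure on untreated cells and taking the abundance ratio gives the
false-positive detection rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import CallingConfig
from .counts import ControlCounts, SiteCounts
from .errors import ConfigurationError, InvalidParameterError, UndefinedRateError
from .genome import Site

__all__ = [
    "SiteCounts",
    "ControlCounts",
    "CellQC",
    "SitePool",
    "FcCallSet",
    "estimate_conversion_rate",
    "estimate_background_rate",
    "build_pool",
    "binomial_pvalue",
    "holm_bonferroni",
    "call_cell",
    "false_positive_detection_rate",
]


@dataclass(frozen=True)
class CellQC:
    """Per-cell control-derived rates."""

    cell_id: str
    treatment: str  # "treated" | "untreated"
    conversion_rate: float
    background_rate: float

    @property
    def usable(self) -> bool:
        """A treated cell is usable when labeling beats the background."""
        return self.background_rate < self.conversion_rate


@dataclass(frozen=True)
class SitePool:
    """A whitelist (candidate) or blacklist (noise) of CpG sites."""

    kind: str  # "candidate" | "noise"
    sites: frozenset[Site]

    def __post_init__(self):
        if self.kind not in ("candidate", "noise"):
            raise InvalidParameterError(f"unknown pool kind {self.kind!r}")

    def __contains__(self, site: Site) -> bool:
        return site in self.sites

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class FcCallSet:
    """Called 5fCpG and unmodified-C sites for one cell.

    ``fc`` is a DataFrame indexed by (chrom, pos) with columns nt, nc,
    raw_p, adj_p.  ``covered3`` (sites at depth >= min_depth_call) is kept so
    stage-level merging can reconstruct common coverage.
    """

    cell_id: str
    fc: pd.DataFrame = field(repr=False)
    unmod_sites: frozenset[Site]
    covered3: frozenset[Site]
    sequenced_cpg: int
    attrition: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.fc_sites & self.unmod_sites:
            raise InvalidParameterError(
                "a site cannot be both 5fC-called and unmodified-called"
            )

    @property
    def fc_sites(self) -> frozenset[Site]:
        return frozenset(self.fc.index)

    @property
    def abundance(self) -> float:
        """Called 5fCpG sites over all sequenced CpG sites (depth >= 1)."""
        if self.sequenced_cpg == 0:
            return float("nan")
        return len(self.fc) / self.sequenced_cpg


def estimate_conversion_rate(spikein: ControlCounts) -> float:
    """Labeling efficiency: T reads over total reads at the spike-in's
    known-5fC positions."""
    if spikein.kind != "spike_in":
        raise InvalidParameterError("conversion rate needs spike-in counts")
    at_5fc = spikein.data[spikein.data["is_5fc"].astype(bool)]
    total = int(at_5fc["n_t"].sum() + at_5fc["n_c"].sum())
    if total == 0:
        raise UndefinedRateError("no reads over true-5fC spike-in positions")
    return float(at_5fc["n_t"].sum() / total)


def estimate_background_rate(
    lambda_counts: ControlCounts, cfg: CallingConfig = CallingConfig()
) -> float:
    """Random C-to-T rate: T readouts over all readouts at lambda C sites
    covered at least ``cfg.min_depth_lambda`` times."""
    if lambda_counts.kind != "lambda":
        raise InvalidParameterError("background rate needs lambda counts")
    df = lambda_counts.data
    ok = (df["n_t"] + df["n_c"]) >= cfg.min_depth_lambda
    total = int(df.loc[ok, "n_t"].sum() + df.loc[ok, "n_c"].sum())
    if total == 0:
        raise UndefinedRateError(
            f"no lambda C site covered >= {cfg.min_depth_lambda} times"
        )
    return float(df.loc[ok, "n_t"].sum() / total)


def build_pool(
    cells: Sequence[SiteCounts], kind: str, cfg: CallingConfig = CallingConfig()
) -> SitePool:
    """Pool of sites whose C-to-T ratio is >= ``cfg.ratio_min`` in at least
    ``cfg.min_cells_pool`` of the given cells.

    Ratios count at any depth >= 1; the per-cell depth gate applies later, at
    calling time.  Build the candidate pool from treated cells and the noise
    pool from untreated cells.
    """
    if kind not in ("candidate", "noise"):
        raise InvalidParameterError(f"unknown pool kind {kind!r}")
    if not cells:
        warnings.warn(f"building {kind} pool from zero cells: pool is empty",
                      stacklevel=2)
        return SitePool(kind, frozenset())
    hits: pd.Series | None = None
    for cell in cells:
        passing = cell.ratio >= cfg.ratio_min
        idx = cell.data.index[passing]
        s = pd.Series(1, index=idx)
        hits = s if hits is None else hits.add(s, fill_value=0)
    assert hits is not None
    pool_idx = hits.index[hits >= cfg.min_cells_pool]
    return SitePool(kind, frozenset(pool_idx))


def binomial_pvalue(nt: int, nc: int, p0: float) -> float:
    """Upper-tail binomial probability P(X >= nt) with X ~ B(nt + nc, p0):
    the chance of observing at least this many conversion reads from
    background error alone."""
    if not 0 < p0 < 1:
        raise InvalidParameterError("p0 must lie strictly inside (0, 1)")
    if nt < 0 or nc < 0 or nt + nc < 1:
        raise InvalidParameterError("need nt, nc >= 0 with depth >= 1")
    return float(stats.binom.sf(nt - 1, nt + nc, p0))


def holm_bonferroni(pvals: Iterable[float]) -> list[float]:
    """Holm's step-down adjusted p-values, returned in input order.

    Sorted ascending, adjusted_(i) = max_{j <= i} (m - j + 1) * p_(j),
    capped at 1.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise InvalidParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.maximum.accumulate((m - np.arange(m)) * p[order])
    np.minimum(adj, 1.0, out=adj)
    out = np.empty(m)
    out[order] = adj
    return out.tolist()


def call_cell(
    cell: SiteCounts,
    candidate: SitePool,
    noise: SitePool,
    snp_mask: frozenset[Site] | set[Site],
    qc: CellQC,
    cfg: CallingConfig = CallingConfig(),
) -> FcCallSet:
    """Run the full per-cell calling scheme and return the call set.

    The Holm-Bonferroni family is this cell's candidate sites.  An attrition
    log records how many sites each gate removed.
    """
    if not np.isfinite(qc.background_rate) or not 0 < qc.background_rate < 1:
        raise ConfigurationError(
            f"cell {cell.cell_id}: background rate {qc.background_rate!r} "
            "unusable as a binomial null"
        )
    snp_mask = frozenset(snp_mask)
    depth = cell.depth
    ratio = cell.ratio
    idx = cell.data.index

    deep = depth >= cfg.min_depth_call
    high = ratio >= cfg.ratio_min
    in_cand = idx.isin(candidate.sites)
    in_noise = idx.isin(noise.sites)
    in_snp = idx.isin(snp_mask)

    attrition = {
        "sequenced": len(idx),
        f"depth_ge_{cfg.min_depth_call}": int(deep.sum()),
        "ratio_pass": int((deep & high).sum()),
        "in_candidate_pool": int((deep & high & in_cand).sum()),
        "after_noise_pool": int((deep & high & in_cand & ~in_noise).sum()),
    }
    cand_mask = deep & high & in_cand & ~in_noise & ~in_snp
    attrition["after_snp_mask"] = int(cand_mask.sum())

    cand = cell.data[cand_mask].copy()
    if len(cand):
        n = (cand["nt"] + cand["nc"]).to_numpy()
        raw = stats.binom.sf(cand["nt"].to_numpy() - 1, n, qc.background_rate)
        cand["raw_p"] = raw
        cand["adj_p"] = holm_bonferroni(raw)
        fc = cand[cand["adj_p"] < cfg.adj_p_max]
    else:
        fc = cand.reindex(columns=["nt", "nc", "raw_p", "adj_p"])
    attrition["hb_pass"] = len(fc)

    unmod_mask = deep & (ratio <= cfg.ratio_unmod_max) & ~in_snp
    unmod = frozenset(idx[unmod_mask])
    return FcCallSet(
        cell_id=cell.cell_id,
        fc=fc,
        unmod_sites=unmod,
        covered3=frozenset(idx[deep]),
        sequenced_cpg=cell.sequenced_cpg,
        attrition=attrition,
    )


def false_positive_detection_rate(
    treated: Sequence[FcCallSet], untreated: Sequence[FcCallSet]
) -> float:
    """Mean untreated 5fCpG abundance over mean treated abundance."""
    if not treated or not untreated:
        raise InvalidParameterError("need at least one call set in each group")
    mean_t = float(np.mean([c.abundance for c in treated]))
    mean_u = float(np.mean([c.abundance for c in untreated]))
    if not np.isfinite(mean_t) or mean_t == 0:
        raise UndefinedRateError("treated abundance is zero or undefined")
    return mean_u / mean_t
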