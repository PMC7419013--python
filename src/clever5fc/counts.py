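"""Per-cell count containers: CpG site counts and control-molecule counts.

A :class:`SiteCounts` holds, for one cell, the number of reads supporting T
(``nt``, conversion events) and supporting C (``nc``) at every CpG site with
at least one read.  The C-to-T ratio ``nt / (nt + nc)`` is the per-site
conversion readout everything downstream gates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .genome import Site


def _site_index(sites) -> pd.MultiIndex:
    return pd.MultiIndex.from_tuples(list(sites), names=["chrom", "pos"])


@dataclass
class SiteCounts:
    """Read counts per CpG site for a single cell.

    ``data`` is indexed by (chrom, pos) — 1-based plus-strand C coordinate of
    the dyad — with integer columns ``nt`` and ``nc``.  Only sites with depth
    >= 1 are stored.
    """

    cell_id: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.data
        if list(df.columns) != ["nt", "nc"]:
            raise InvalidParameterError("SiteCounts data must have columns nt, nc")
        if (df[["nt", "nc"]].to_numpy() < 0).any():
            raise InvalidParameterError("negative read counts")
        depth = df["nt"] + df["nc"]
        if (depth == 0).any():
            self.data = df[depth > 0]
        if not self.data.index.is_unique:
            raise InvalidParameterError("duplicate (chrom, pos) rows")
        self.data = self.data.sort_index()

    @classmethod
    def from_arrays(cls, cell_id: str, sites, nt, nc) -> "SiteCounts":
        df = pd.DataFrame(
            {"nt": np.asarray(nt, dtype=np.int64), "nc": np.asarray(nc, dtype=np.int64)},
            index=_site_index(sites),
        )
        return cls(cell_id, df)

    @property
    def depth(self) -> pd.Series:
        return self.data["nt"] + self.data["nc"]

    @property
    def ratio(self) -> pd.Series:
        """C-to-T conversion ratio nt/(nt+nc); defined only where depth > 0."""
        d = self.depth
        return self.data["nt"] / d

    @property
    def sequenced_cpg(self) -> int:
        """Number of CpG sites with depth >= 1."""
        return len(self.data)

    def sites(self) -> frozenset[Site]:
        return frozenset(self.data.index)

    def sites_with_depth(self, min_depth: int) -> frozenset[Site]:
        return frozenset(self.data.index[self.depth >= min_depth])


@dataclass
class ControlCounts:
    """Counts over control-molecule C positions (spike-in or lambda).

    ``data`` has columns ``pos`` (1-based position on the control molecule),
    ``n_t``, ``n_c`` and, for the spike-in, a boolean ``is_5fc`` flagging the
    positions that carry a genuine 5fC in the synthesized model DNA.
    """

    kind: str  # "spike_in" | "lambda"
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        if self.kind not in ("spike_in", "lambda"):
            raise InvalidParameterError(f"unknown control kind {self.kind!r}")
        required = {"pos", "n_t", "n_c"}
        if not required <= set(self.data.columns):
            raise InvalidParameterError("ControlCounts needs columns pos, n_t, n_c")
        if (self.data[["n_t", "n_c"]].to_numpy() < 0).any():
            raise InvalidParameterError("negative control counts")
        if self.kind == "spike_in" and "is_5fc" not in self.data.columns:
            raise InvalidParameterError("spike-in controls need an is_5fc flag")

    @property
    def depth(self) -> pd.Series:
        return self.data["n_t"] + self.data["n_c"]
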