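from pathlib import Path

import pytest

from clever5fc import make_genome
from clever5fc.counts import SiteCounts

REPO = Path(__file__).resolve().parents[1]


@pytest.fixture(scope="session")
def demo_config_path() -> Path:
    return REPO / "configs" / "demo.yaml"


@pytest.fixture(scope="session")
def golden_dir() -> Path:
    return REPO / "tests" / "golden"


@pytest.fixture(scope="module")
def small_genome():
    """100 kb toy genome, ~1,000 CpG sites, default annotation mix."""
    return make_genome(1, 100_000, 10.0, seed=7)


def make_counts(cell_id: str, rows: dict) -> SiteCounts:
    """Build SiteCounts from {(chrom, pos): (nt, nc)}."""
    sites = list(rows)
    nt = [rows[s][0] for s in sites]
    nc = [rows[s][1] for s in sites]
    return SiteCounts.from_arrays(cell_id, sites, nt, nc)
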