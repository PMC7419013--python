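"""Synthetic CLEVER-seq-like data with known ground truth.

The generator produces (i) a toy genome with a CpG registry and overlapping
interval annotations, (ii) a ground-truth formylation map with class-specific
5fC rates, and (iii) per-cell count tables plus spike-in and lambda control
counts, under the generative model the calling scheme assumes:

* per site per cell, sequencing depth ~ Poisson(``coverage_mean``),
  independent across cells (optionally zero-truncated);
* in a malononitrile-treated cell, each read over a formylated C reads out T
  with probability ``conversion_eff`` (labeling efficiency, ~0.8 in real
  libraries) and over any other C with probability ``background_rate`` (the
  random C-to-T error, ~0.0115);
* in an untreated (negative-control) cell every C reads out T with the
  background rate only — treated and untreated cells share one noise model;
* spike-in model-DNA positions flagged as true 5fC convert with
  ``conversion_eff`` in treated cells; lambda positions always convert at the
  background rate.

True 5fC is sparse: defaults place it at a few 1e-4 of CpGs, matching the
rarity of 5fC in mammalian genomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import ControlCounts, SiteCounts
from .errors import InvalidParameterError
from .genome import REPEAT_FAMILIES, AnnotationSet, GenomeMap, Interval, Site

STATE_UNMODIFIED = 0
STATE_METHYLATED = 1
STATE_FORMYLATED = 2
STATE_NAMES = {
    STATE_UNMODIFIED: "unmodified",
    STATE_METHYLATED: "methylated_unoxidized",
    STATE_FORMYLATED: "formylated",
}

#: Default genome fraction and typical interval length (bp) per class.
DEFAULT_ANNOTATION_SPEC: dict[str, float] = {
    "promoter": 0.03,
    "exon": 0.03,
    "intron": 0.35,
    "TTS-region": 0.03,
    "CGI": 0.01,
    "L1": 0.17,
    "L2": 0.03,
    "Alu": 0.10,
    "MIR": 0.03,
    "ERVK": 0.01,
    "ERV1": 0.03,
    "ERVL": 0.02,
    "ERVL-MaLR": 0.04,
    "SVA": 0.005,
    "ALR": 0.03,
}

_MEAN_LENGTH: dict[str, int] = {
    "promoter": 1500,
    "exon": 200,
    "intron": 4000,
    "TTS-region": 2000,
    "CGI": 800,
    "L1": 3000,
    "L2": 500,
    "Alu": 300,
    "MIR": 200,
    "ERVK": 1500,
    "ERV1": 1000,
    "ERVL": 800,
    "ERVL-MaLR": 500,
    "SVA": 1500,
    "ALR": 2000,
}

#: Order used to resolve overlapping classes into the single class whose 5fC
#: rate applies to a site: repeat subfamilies first, then CpG islands and
#: gene elements, with "intergenic" as the residual.
TRUTH_PRECEDENCE: tuple[str, ...] = tuple(REPEAT_FAMILIES) + (
    "CGI",
    "promoter",
    "exon",
    "intron",
    "TTS-region",
)

#: Number of C positions on the 137-bp spike-in model DNA and the fixed
#: subset carrying a genuine 5fC modification.
SPIKEIN_LENGTH = 137
SPIKEIN_5FC_POSITIONS: tuple[int, ...] = (11, 23, 37, 49, 61, 73, 89, 101, 113, 127)


def make_genome(
    n_chrom: int,
    chrom_len: int,
    cpg_density: float,
    annotation_spec: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[GenomeMap, AnnotationSet]:
    """Generate a toy genome: CpG registry plus overlapping annotations.

    Parameters
    ----------
    n_chrom, chrom_len
        Number of chromosomes and their common length in bp (>= 10 kb).
    cpg_density
        CpG sites per kb (may be 0 for a vacuous genome).
    annotation_spec
        Mapping class name -> target genome fraction.  Defaults to a
        roughly genome-like mix of gene elements, CpG islands, and repeat
        subfamilies.  Classes may overlap.
    """
    if n_chrom <= 0 or chrom_len < 10_000:
        raise InvalidParameterError("need n_chrom >= 1 and chrom_len >= 10 kb")
    if cpg_density < 0:
        raise InvalidParameterError("cpg_density must be >= 0")
    spec = DEFAULT_ANNOTATION_SPEC if annotation_spec is None else annotation_spec
    for name, frac in spec.items():
        if not 0 <= frac <= 1:
            raise InvalidParameterError(f"fraction for {name!r} outside [0, 1]")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chromosomes = {f"chr{i + 1}": chrom_len for i in range(n_chrom)}

    sites: list[Site] = []
    n_per_chrom = int(round(chrom_len * cpg_density / 1000.0))
    for chrom in chromosomes:
        if n_per_chrom == 0:
            continue
        pos = rng.choice(np.arange(1, chrom_len), size=n_per_chrom, replace=False)
        pos.sort()
        sites.extend((chrom, int(p)) for p in pos)
    genome = GenomeMap(chromosomes=chromosomes, cpg_sites=tuple(sites))

    annotation = AnnotationSet()
    for name in sorted(spec):
        frac = spec[name]
        if frac == 0:
            continue
        mean_len = _MEAN_LENGTH.get(name, 1000)
        fam = REPEAT_FAMILIES.get(name)
        for chrom, length in chromosomes.items():
            n_iv = max(1, int(round(frac * length / mean_len)))
            starts = rng.integers(0, length - 1, size=n_iv)
            lens = rng.integers(max(1, mean_len // 2), mean_len + mean_len // 2, size=n_iv)
            for s, l in zip(starts.tolist(), lens.tolist()):
                e = min(s + l, length)
                if e > s:
                    annotation.add(
                        name,
                        Interval(chrom, s, e, family=fam,
                                 subfamily=name if fam else None),
                    )
    return genome, annotation


@dataclass
class SyntheticTruth:
    """Ground-truth modification state for every CpG site plus the
    generative parameters used to simulate reads from it."""

    genome: GenomeMap
    true_state: np.ndarray = field(repr=False)  # int8, aligned to genome.cpg_sites
    assigned_class: np.ndarray = field(repr=False)  # object array of class names
    class_rates: dict[str, float] = field(default_factory=dict)
    conversion_eff: float = 0.8
    background_rate: float = 0.0115
    coverage_mean: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if len(self.true_state) != self.genome.n_sites:
            raise InvalidParameterError("true_state length != number of CpG sites")
        for p in (self.conversion_eff, self.background_rate):
            if not 0 <= p <= 1:
                raise InvalidParameterError("probabilities must lie in [0, 1]")

    @property
    def formylated_mask(self) -> np.ndarray:
        return self.true_state == STATE_FORMYLATED

    def formylated_sites(self) -> frozenset[Site]:
        mask = self.formylated_mask
        return frozenset(s for s, m in zip(self.genome.cpg_sites, mask) if m)

    def to_frame(self) -> pd.DataFrame:
        df = self.genome.site_frame()
        df["state"] = [STATE_NAMES[s] for s in self.true_state]
        df["assigned_class"] = self.assigned_class
        return df


def make_truth(
    genome: GenomeMap,
    annotation: AnnotationSet,
    class_rates: dict[str, float] | None = None,
    seed: int = 0,
    *,
    base_rate: float = 3e-4,
    methylated_fraction: float = 0.75,
    conversion_eff: float = 0.8,
    background_rate: float = 0.0115,
    coverage_mean: float = 5.0,
) -> SyntheticTruth:
    """Draw a ground-truth formylation map with class-specific 5fC rates.

    Each CpG is assigned one class by the fixed precedence
    ``repeat subfamily > CGI > promoter > exon > intron > TTS-region >
    intergenic`` and is formylated with that class's rate (``base_rate`` for
    classes without an entry in ``class_rates``).  Non-formylated sites are
    split into methylated-unoxidized and unmodified; only the formylated /
    not-formylated distinction matters to read simulation.
    """
    class_rates = dict(class_rates or {})
    for name, rate in class_rates.items():
        if name != "intergenic" and name not in annotation:
            raise InvalidParameterError(f"class_rates names unknown class {name!r}")
        if not 0 <= rate <= 1:
            raise InvalidParameterError(f"rate for {name!r} outside [0, 1]")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7]))
    labels = np.empty(genome.n_sites, dtype=object)
    precedence = [c for c in TRUTH_PRECEDENCE if c in annotation]
    for i, site in enumerate(genome.cpg_sites):
        labels[i] = "intergenic"
        for cls in precedence:
            if annotation.contains_site(cls, site):
                labels[i] = cls
                break

    rates = np.array([class_rates.get(c, base_rate) for c in labels])
    u = rng.random(genome.n_sites)
    state = np.where(
        u < rates,
        STATE_FORMYLATED,
        np.where(rng.random(genome.n_sites) < methylated_fraction,
                 STATE_METHYLATED, STATE_UNMODIFIED),
    ).astype(np.int8)
    return SyntheticTruth(
        genome=genome,
        true_state=state,
        assigned_class=labels,
        class_rates=class_rates,
        conversion_eff=conversion_eff,
        background_rate=background_rate,
        coverage_mean=coverage_mean,
        seed=seed,
    )


@dataclass
class SimulatedCell:
    cell_id: str
    treatment: str  # "treated" | "untreated"
    counts: SiteCounts
    spikein: ControlCounts
    lambda_counts: ControlCounts


def simulate_cells(
    truth: SyntheticTruth,
    n_treated: int,
    n_untreated: int,
    seed: int = 0,
    *,
    zero_truncated: bool = False,
    spikein_depth_mean: float = 20.0,
    n_lambda_sites: int = 2000,
    lambda_depth_mean: float = 8.0,
    cell_ids: list[str] | None = None,
    treatments: list[str] | None = None,
) -> list[SimulatedCell]:
    """Simulate per-cell CpG count tables plus spike-in and lambda controls.

    Treated cells convert formylated Cs with ``truth.conversion_eff`` and all
    other Cs with ``truth.background_rate``; untreated cells convert every C
    at the background rate.  Control molecules are drawn with the same two
    rates, so downstream rate estimators can be validated against truth.
    """
    if n_treated < 0 or n_untreated < 0:
        raise InvalidParameterError("cell counts must be >= 0")
    if n_treated < 2:
        warnings.warn(
            "fewer than 2 treated cells: the candidate pool will be empty "
            "by construction",
            stacklevel=2,
        )
    if cell_ids is None:
        cell_ids = [f"t{i:02d}" for i in range(n_treated)] + [
            f"u{i:02d}" for i in range(n_untreated)
        ]
    if treatments is None:
        treatments = ["treated"] * n_treated + ["untreated"] * n_untreated
    if len(cell_ids) != n_treated + n_untreated or len(treatments) != len(cell_ids):
        raise InvalidParameterError("cell_ids/treatments length mismatch")

    n_sites = truth.genome.n_sites
    site_arr = np.array(truth.genome.cpg_sites, dtype=object) if n_sites else None
    p_treated = np.where(
        truth.formylated_mask, truth.conversion_eff, truth.background_rate
    )
    p_untreated = np.full(n_sites, truth.background_rate)

    spike_pos = np.arange(1, SPIKEIN_LENGTH + 1)
    spike_is_5fc = np.isin(spike_pos, SPIKEIN_5FC_POSITIONS)

    root = np.random.SeedSequence([seed, 0x51])
    cells: list[SimulatedCell] = []
    for child, cell_id, treatment in zip(
        root.spawn(len(cell_ids)), cell_ids, treatments
    ):
        rng = np.random.default_rng(child)
        # genomic CpG counts
        if n_sites:
            depth = rng.poisson(truth.coverage_mean, size=n_sites)
            if zero_truncated:
                while (zero := depth == 0).any():
                    depth[zero] = rng.poisson(truth.coverage_mean, size=int(zero.sum()))
            p = p_treated if treatment == "treated" else p_untreated
            nt = rng.binomial(depth, p)
            covered = depth > 0
            counts = SiteCounts.from_arrays(
                cell_id,
                [tuple(s) for s in site_arr[covered]],
                nt[covered],
                depth[covered] - nt[covered],
            )
        else:
            counts = SiteCounts.from_arrays(cell_id, [], [], [])

        # spike-in model DNA: known 5fC positions convert only when treated
        sdepth = rng.poisson(spikein_depth_mean, size=SPIKEIN_LENGTH)
        p_spike = np.where(
            spike_is_5fc & (treatment == "treated"),
            truth.conversion_eff,
            truth.background_rate,
        )
        s_nt = rng.binomial(sdepth, p_spike)
        spike = ControlCounts(
            "spike_in",
            pd.DataFrame(
                {
                    "pos": spike_pos,
                    "n_t": s_nt,
                    "n_c": sdepth - s_nt,
                    "is_5fc": spike_is_5fc,
                }
            ),
        )

        # lambda DNA: fully unmodified, background conversion only
        ldepth = rng.poisson(lambda_depth_mean, size=n_lambda_sites)
        l_nt = rng.binomial(ldepth, truth.background_rate)
        lam = ControlCounts(
            "lambda",
            pd.DataFrame(
                {
                    "pos": np.arange(1, n_lambda_sites + 1),
                    "n_t": l_nt,
                    "n_c": ldepth - l_nt,
                }
            ),
        )
        cells.append(SimulatedCell(cell_id, treatment, counts, spike, lam))
    return cells
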