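# Methods

## Model and procedure

The caller treats each CpG site in each cell as a binomial experiment. Reads
are exchangeable: at a 5fC site in a labeled (treated) cell each read
converts C→T with probability *e* (labeling efficiency); at any other C, and
at every C in an untreated cell, a read converts with the random background
probability *p₀*. Both rates are estimated per cell from co-sequenced
controls: *e* from a 137-bp spike-in model DNA whose 5fC positions are
known, *p₀* from unmodified lambda DNA restricted to C sites covered ≥ 4×
(shallower lambda sites are too error-prone to calibrate on). When a cell
has no qualifying lambda site, the pooled across-cell lambda rate is used
instead; the per-cell rate is preferred because amplification chemistry
varies cell to cell.

A site is called 5fC in a cell when it passes, in order: depth ≥ 3; C-to-T
ratio ≥ 0.65; membership in the candidate pool (ratio ≥ 0.65 in ≥ 2 treated
cells — suppresses recurrent PCR errors); absence from the noise pool
(ratio ≥ 0.65 in ≥ 2 untreated cells — removes shared background); absence
from the SNP mask; and a Holm–Bonferroni-adjusted upper-tail binomial
p-value < 0.01 against Binomial(NT + NC, *p₀*). The adjustment family is
the cell's own candidate sites: calls are statements about one cell, so the
family-wise error is controlled per cell. The test is one-sided upward — a
point probability (the density at NT alone) is not a significance measure
for "at least this much conversion by chance", so the tail sum is used.
Sites at depth ≥ 3 with ratio ≤ 0.25 are called unmodified C; the gap
between 0.25 and 0.65 is deliberately uncalled.

Pool membership uses the ratio at any depth ≥ 1. The depth ≥ 3 gate applies
where a call is made, not where corroborating evidence is collected; pooling
across cells already supplies the replication the shallow sites lack. This
is configurable (`CallingConfig.min_cells_pool`, and the depth gates).

## Downstream statistics

* **Abundance vs level.** Abundance (calls / sequenced CpGs) is a per-cell
  detection summary and the basis of the false-positive detection rate
  (mean untreated abundance / mean treated abundance). Level
  (n_5fC / (n_5fC + n_unmod)) conditions on confidently genotyped sites and
  is the quantity compared across scopes, stages, and pair members.
* **Stage aggregation.** A stage's merged set is the union of member-cell
  calls; the stage 5fC fraction restricts to CpGs covered ≥ 3× in every
  member cell so stages with different coverage are comparable.
* **Transitions.** Each later-stage merged site is inherited (5fC earlier),
  newly generated (confidently unmodified in ≥ 1 earlier cell and never 5fC
  earlier), or undetermined (not informatively covered earlier). The
  residual class is explicit rather than folded into either category,
  because sparse single-cell coverage makes it large by construction.
* **Enrichment.** log₂[(fc fraction in class) / (background fraction in
  class)], background being the covered-CpG universe the calls were drawn
  from. Classes with zero background or zero 5fC occupancy are reported as
  missing, not ±∞.
* **Windows.** Non-overlapping fixed-size tilings (default 1 kb; 10 kb–10 Mb
  for coarser profiles). Only windows with a 5fC site in at least one
  profile are retained for variance and clustering; windows with no called
  site of either kind are missing, not zero — zero-filling would conflate
  absence of modification with absence of coverage. Cross-cell variance is
  the sample variance (n−1); clustering is average linkage on 1 − Spearman ρ
  over jointly defined windows (ρ undefined below 3 joint windows).
* **Promoter classes.** TSS −1 kb to +0.5 kb, classified by 500-bp-window
  CpG density with the standard high/intermediate/low criteria (HCP: any
  window with GC ≥ 0.55 and CpG obs/exp ≥ 0.75; LCP: no window reaching
  obs/exp 0.48; ICP otherwise). Thresholds are module constants.
* **Matched repeat controls.** Expression/methylation of 5fC-marked repeats
  is compared against an equal-sized uniform draw (seeded, without
  replacement) of repeats with only unmodified CpGs, by two-tailed
  two-sample Student t test; RPKM = count / (kb × million mapped reads).
* **Metaplots.** Mean signal per bin across sites, bins spanning
  ±flank around the site center; bin values are coverage-weighted means of
  a bedGraph track, and bins without track coverage are missing for that
  site (nan-mean across sites).

## Synthetic data generator

The generator emulates the count structure the caller assumes, not the
sequences: per site per cell, depth ~ Poisson(mean coverage, default 5,
optionally zero-truncated), independent across cells; conversion reads are
Bernoulli draws at *e* = 0.8 (formylated sites, treated cells) or
*p₀* = 0.0115 (everything else, and all sites in untreated cells); spike-in
(137 positions, 10 flagged 5fC, mean depth 20) and lambda (2,000 C sites,
mean depth 8) controls are drawn with the same two rates. True 5fC is
sparse — the default base rate is 3×10⁻⁴ per CpG, with class-specific rates
assignable per annotation class under a fixed precedence (repeat subfamily >
CGI > promoter > exon > intron > TTS-region > intergenic), so that every
site has exactly one generating class and stacked class fractions sum to 1.

What it does **not** model: MALBAC amplification correlation between reads
(reads are independent, matching the caller's own exchangeability
assumption), locus-dependent coverage bias, copy-number variation,
strand-specific or allele-specific effects, and sequence content. Passing
tests therefore demonstrate correctness of the calling arithmetic and its
statistical behavior under the stated generative model — not robustness to
amplification artifacts in real libraries, which the pool gates address
only empirically.

Annotation intervals are placed uniformly at class-typical lengths to hit
target genome fractions (defaults roughly genome-like: L1 17%, Alu 10%,
intron 35%, ERVK 1%, …); classes may overlap, as real tracks do.

## Numerical and scale choices

Binomial tail probabilities come from `scipy.stats.binom.sf` (regularized
incomplete beta; agrees with exhaustive enumeration to < 10⁻¹² for depths
up to 12 — single-cell depths live far below that bound). The Holm
adjustment is the stepwise definition implemented directly (stable argsort,
running max, cap at 1); it is cross-checked against statsmodels in the test
suite. Result tables are written with a fixed `%.10g` float format so
identical runs are byte-identical.

Validation experiments run at desk scale: ~10⁴ CpG sites on a 1 Mb
chromosome, 10–14 cells, with 4×10⁴ sites for enrichment checks — enough
for the binomial concentration bounds used in the tests while keeping the
full suite in tens of seconds. Sample sizes (10 treated + 4 untreated),
depth 5×, efficiency 0.8 and background 0.0115 are the package's reference
conditions throughout.

## Known limitations

* The background rate is treated as site-independent; real libraries have
  context-dependent error.
* Pool construction at depth ≥ 1 lets very shallow sites into the pools;
  the per-cell depth gate prevents shallow *calls*, but pool composition is
  coverage-dependent.
* The unmodified call ignores 5mC/5hmC (both read as C here); "unmodified"
  means "not formylated" only to the extent the chemistry is 5fC-specific.
* With no untreated cells the noise pool is empty and the false-positive
  detection rate is unavailable; calls are then only PCR-error-filtered.
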