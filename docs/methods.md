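# Methods

## The problem

A single deeply sequenced diploid genome carries a readable record of its
owner's inbreeding history. Where the two haplotypes descend from the same
recent ancestor — identity by descent (IBD) — heterozygosity collapses to
the genotyping-error floor over megabase-scale tracts, the *runs of
homozygosity* (ROH). `rohscan` implements the windowed-heterozygosity
version of this analysis for one individual: per-window heterozygosity
with missing-data-aware denominators, an error threshold calibrated on the
haploid X chromosome of a male, segmentation of homozygous window runs
with a rescue rule, the ROH-based inbreeding coefficient F_ROH with its
length spectrum, and dating of the inbreeding event from tract lengths.

## Windowed heterozygosity

For fixed windows (default w = 50 kb) the estimator is

    het = n_het / n_callable

`n_callable` is the number of positions inside the callable mask minus
positions with a missing genotype; missing sites leave numerator and
denominator together, so the estimator is unbiased under random
missingness (tested by paired thinning runs). Windows with fewer than
`min_callable` callable sites (default w/10) carry no estimate: a masked
repeat desert is "no data", never "homozygous". Terminal partial windows
are kept but may enter ROH only when at least half the full window width
is callable, to avoid chromosome-edge artifacts. Any genotype with two
distinct called alleles counts as heterozygous (multi-allelic included);
an `--snv-only` switch restricts to single-base alleles.

## X-chromosome error calibration

In a male the X is haploid, so apparent X heterozygosity is sequencing and
mapping error. The strict homozygosity threshold is the 99th percentile of
the defined X-window het distribution (linear interpolation between order
statistics — the convention is stated because percentile conventions
differ); the rescue threshold defaults to twice the strict one, matching
the reference pair 0.0002/0.0004 per site. Calibration requires at least
50 defined X windows and refuses degenerate (all-zero) distributions;
`fixed_thresholds` reproduces the reference values directly. The defining
property — about 1% of error-only X windows exceed the threshold — holds
because callable denominators vary across windows (missingness, mask
gaps), making the het distribution effectively continuous; with a constant
denominator the distribution is a lattice of count/denominator atoms and
no percentile can cut it exactly.

## ROH segmentation

A window is *strict* if its het is defined and `< t_strict`; it is
*rescuable* if `het < t_rescue` and the callable-weighted mean het of the
surrounding 1 Mb (centered on the window, including it, clipped at
chromosome ends) is `< t_strict`. Segments are maximal runs of strict
windows absorbing isolated rescuable windows, with three structural
rules: rescued windows are never adjacent to each other, never form a
segment endpoint, and runs never cross chromosome boundaries or no-data
windows (a `bridge_nodata` option can span short no-data gaps). This is
the strictest reading under which rescues can extend but never create a
run of homozygosity. Comparisons are strict `<`; segments shorter than
the reporting cutoff (default 1 Mb) are dropped; all boundaries are
window boundaries. The X is never segmented by default (haploid in a
male; `include_x` for female samples).

A second, independent implementation (`roh_oracle`) enumerates every
candidate window interval and checks the run definition directly, with
its own classification loop. The two are compared exhaustively over all
het-class strings up to 7 windows, over seeded 12-window strings, and
over 1,000 random 200-window fixtures with varying callability; the
problem sizes keep the quadratic reference affordable while covering
every local rule interaction (the rules are local within the 1 Mb
neighborhood, so short strings exercise them completely).

## Summaries

F_ROH(c) is ROH bp at length >= c divided by autosomal bp in windows with
a defined estimate — a window-based denominator, so that uncallable
regions drop out of both sides. The length spectrum assigns each
segment's full length to the left-closed 1 Mb bin containing it, and its
total equals reported ROH bp exactly. Inside/outside-ROH heterozygosity,
the fraction of homozygous windows (het < t_strict), and the share of
those in long (>= 5 Mb) ROH are reported with explicit denominators.
Reported precision: het and F_ROH to 4 significant figures, pHt to two
decimals. The microsatellite statistic pHt is simply heterozygous /
genotyped loci.

## Dating inbreeding from tract lengths

An IBD tract from an event g generations back survives 2g meioses; with a
map scale of m MB per Morgan (default 100) its length is exponential with
mean m/(2g) MB, so a tract of L MB dates the event to g = m/(2L):
5 MB -> 10 generations, 50 MB -> 1.

Estimating the mean tract length from called ROH uses the exponential
maximum-likelihood estimator under left truncation and right censoring:

    mean = sum_i (L_i - c) / #uncensored

where c is the reporting cutoff and a segment touching a chromosome end
is censored (numerator only). The naive mean is badly biased whenever
chromosomes are not much longer than tracts: on the 10 Mb test
chromosomes the naive mean of >= 1 Mb segments is ~3.5 MB for a true
5 MB scale, while the corrected estimator recovers ~4–5 MB. The residual
downward bias has two identified sources, both inherent rather than
estimator defects: tract placement rejects overlaps, so realized tracts
crowd and shorten at high coverage; and a true tract is occasionally
split by a pair of adjacent marginal windows that the rescue rule (by
design) refuses to bridge, inflating the segment count.

## The simulator

The generator emulates the three heterozygosity regimes of an inbred
genome at moderate sequencing depth, with per-site independent events:

| parameter | default | meaning |
|---|---|---|
| `theta_bg` | 2.7e-3 | per-site heterozygosity outside IBD tracts |
| `epsilon` | 1e-4 | per-site false-heterozygote rate, everywhere (X included) |
| `miss_rate` | 0.05 | per-site probability a position is uncallable |
| `g` | 10 | generations since the inbreeding event |
| `f_target` | 0.18 | intended autosomal IBD fraction |
| `map_mb_per_morgan` | 100 | genetic map scale |

`theta_bg` and `epsilon` are set so that 50 kb windows average ~135
heterozygous sites outside tracts and ~5 inside, an order-of-magnitude
separation, and so the X 99th percentile lands near 2e-4 — the regimes a
windowed scan of a recently inbred rodent genome actually shows.
`miss_rate` 0.05 is a typical callable-site loss for short reads mapped
to a repeat-rich assembly. The default karyotype is 28 autosomes with a
linear size gradient totaling ~1.9 Gb plus a 95 Mb X, all multiplied by
an explicit `scale` factor (default 0.01 for desk-scale work).

Tract lengths are exponential with mean m/(2g) MB; start positions are
uniform over the autosomes, overlapping draws are rejected, tracts are
truncated at chromosome ends (their truncated length counts toward the
realized fraction `f_true`, as real ROH are measured), and placement
stops when coverage first reaches `f_target` — so `f_true >= f_target`
with overshoot below one tract length. Bernoulli site events are realized
by geometric inter-arrival gaps: exact per-site independence without
materializing the genome. Everything is deterministic given the config
seed, down to byte-identical fixture files (VCF with contig headers,
callable-mask BED, truth-tract BED, config echo).

What the simulator does *not* model — and therefore what passing
recovery tests do not show about real data: no coalescent background
genealogy (background het is i.i.d., real diversity is autocorrelated),
no recombination-rate heterogeneity, no clustered mapping error in
repeat-rich regions (real error concentrates where depth collapses), no
pedigree structure behind the tracts, and no read-level artifacts. The
recovery tests certify the estimator chain — windows, calibration,
segmentation, F_ROH, dating — against a known truth, not the variant
caller upstream of it.

## Validation experiment sizes

Recovery runs use 19 autosomes of 10 Mb plus a 10 Mb X (3,800 autosomal
windows), 20 seeded replicates cycling f_target through {0.05, 0.18,
0.30} at g = 10; calibration checks use 10,000 error-only X windows.
These sizes give binomial standard errors comfortably inside the asserted
tolerances while keeping the full suite fast.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere internally and in BED
  outputs; VCF positions are converted on ingest.
- The surrounding-1 Mb mean for the rescue rule sums raw `n_het` and
  `n_callable` over all windows intersecting the region (defined or
  not); a region with zero callable sites cannot rescue.
- Percentile ties: with discrete het values the exceedance of the
  calibrated threshold is reported as measured, not forced to nominal.
- `f_target = 0` is the explicit no-inbreeding case (no tracts,
  `f_true = 0`); unreachable coverage targets fail with the chromosome
  budget in the message rather than looping.
- Empty segment lists propagate as empty spectra, zero F_ROH, and an
  undefined inside-ROH het (`null` in the JSON summary).
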