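# rohscan

Runs of homozygosity (ROH) and inbreeding summaries from a **single
diploid genome**: missing-data-aware windowed heterozygosity, an error
threshold calibrated on the haploid X chromosome, ROH segmentation with a
rescue rule for isolated marginal windows, the inbreeding coefficient
F_ROH with its length spectrum, and tract-length dating of the inbreeding
event. A built-in simulator of inbred genomes with known identity-by-
descent (IBD) tracts makes the whole chain testable without sequencing
data.

Intended for conservation and population genomicists who have one
well-sequenced individual — often the reference individual of a new
genome assembly — and want to quantify how inbred it is and how recently
the inbreeding happened.

## The method

Per fixed-width window (default 50 kb), heterozygosity is

    het = n_het / n_callable

with missing-genotype sites excluded from numerator *and* denominator.
In a male, the haploid X cannot be truly heterozygous, so the 99th
percentile of X-window het is a data-driven error threshold `t_strict`
(reference value 2 × 10⁻⁴ per site, i.e. 0.2 variants/kb); windows below
it are operationally homozygous. ROH are maximal runs of consecutive
homozygous windows, in which a *single* window with het < `t_rescue`
(= 2 × `t_strict`) is tolerated when the surrounding 1 Mb averages below
`t_strict` — so sequencing-error blips do not break megabase-scale runs,
but marginal windows can never create or terminate one.

From the called segments:

- **F_ROH(c)** = ROH bp at length ≥ c / autosomal bp with a defined
  estimate (cutoffs default to 1 and 5 Mb);
- the **length spectrum** in 1 Mb bins;
- **dating**: an IBD tract of L MB under a 100 MB/Morgan map points to
  g = 100/(2L) generations since the inbreeding event (5 MB → 10
  generations). Mean tract length is estimated with the exponential MLE
  under left truncation (reporting cutoff) and right censoring
  (chromosome ends): `mean = Σ(Lᵢ − c) / #uncensored`;
- **pHt**, the proportion of heterozygous loci in a small marker panel.

See `docs/methods.md` for assumptions, parameter rationale, and known
limitations.

## Worked example

Simulate a recently inbred genome (19 × 10 Mb autosomes + 10 Mb X,
inbreeding 10 generations back targeting 18% IBD coverage) and run the
full pipeline, calibrating thresholds on the X:

```bash
rohscan run --sim-config examples/demo_sim.txt --out demo --seed 1
```

where `examples/demo_sim.txt` contains `g = 10`, `f_target = 0.18`,
`theta_bg = 0.0027`, `epsilon = 0.0001`, `miss_rate = 0.05` and the
chromosome table. Printed output:

```
{
  "f_true": 0.20686033157894737,
  "n_windows": 4000,
  "n_defined_windows": 4000,
  "t_strict": 0.00021104839800121733,
  "t_rescue": 0.00042209679600243465,
  "n_segments": 11,
  "n_rescued_windows": 3
}
F_ROH: >1MB = 0.1821, >5MB = 0.0937
```

Reading it: the simulator realized 20.7% of the autosomes inside IBD
tracts; the X calibration landed at 2.1 × 10⁻⁴ (the injected error rate
was 10⁻⁴ per site); 11 ROH ≥ 1 Mb were called, three of them held
together by a rescued window. F_ROH>1MB = 0.182 recovers the true IBD
fraction to within 0.025 — the shortfall is tracts below the 1 Mb
cutoff plus window-boundary quantization. `demo/summary.json` adds
heterozygosity outside ROH 2.71 × 10⁻³ vs 9.9 × 10⁻⁵ inside (the error
floor), the longest run (6.9 Mb on chr3), and a dating estimate of
~13 generations from the corrected mean tract length of 3.9 Mb (true
value: 10 generations; the bias sources are discussed in the methods
note).

The same verbs work stage by stage (`simulate`, `windows`, `calibrate`,
`callroh`, `summarize`) on real inputs: a single-sample VCF, a callable-
sites BED, and a chromosome table. Every stage is also a plain library
call (`rohscan.build_windows`, `rohscan.calibrate`, `rohscan.call_roh`,
`rohscan.summarize`, ...).

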