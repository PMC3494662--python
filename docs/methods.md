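# Methods

## The generative model

All analyses assume, and the synthetic cohort implements, the following
model of a mosaic founder sire:

- The founder carries a large hemizygous deletion in a fraction `m` of his
  germline (and soma); his own constitutional array genotype is diploid and
  unaffected by the mosaicism — only *transmission* is mosaic. Each mosaic
  germ cell is heterozygous for the deletion, so the carrier fraction among
  spermatozoa is `m/2`, and germline mosaicism is estimated from a sperm
  count as `m̂ = 2k/n` (capped at 1).
- A carrier offspring is hemizygous across the deleted interval: the array
  reports the remaining maternal allele as a *homozygous* call (arrays
  cannot see hemizygosity), with a small no-call rate. This is what creates
  sire–offspring opposite-homozygote Mendelian errors clustered over the
  deletion, and the depletion of heterozygous calls in carriers.
- Fertilization and early development are unselective: blastocysts sample
  conceptions with the conception-cell probabilities
  `((1−m/2)/2, (m/2)/2)` per sex. Between blastocyst and birth each *male
  carrier* independently dies with probability `λ` (a single Bernoulli;
  death-timing detail enters only through the insemination-record bound).
  Births are a multinomial over the surviving-category distribution.
- After a conceptus dies on day `d` post-insemination, the dam returns to
  heat within one sexual cycle, so the interval from the failed
  insemination to the next recorded event, minus the mean cycle length
  (and, when the next event is a calving, the mean gestation length), is an
  upper bound on `d`.

## Parameter defaults and why

| parameter | default | rationale |
|---|---|---|
| germline mosaicism `m` | 0.68 | midpoint of the 66–70% range implied by the two sperm counts |
| male-carrier lethality `λ` | 0.86 | deficit of carrier males at birth (2 observed vs the 14 carrier females expected pre-lethality) |
| deletion flanks | 49,422,588 / 53,130,732 (chr2) | the characterized breakpoints; retained-flank convention gives 3,708,143 deleted bases |
| micro-insertion | `ACAT` | the 4-bp non-template junction insertion |
| genotyped cohort | sire + 19 unaffected + 3 affected progeny + affected dams | the real mapping design |
| births / blastocysts / sperm | 76 / 165 / 2×1000 | the real stage sample sizes |
| markers | 6,000 on a 120 Mb chromosome, MAF ~ U(0.05, 0.5) | 50K-array-like density for one chromosome |
| genotyping error | 0.002 per call (flip to a random other call) | typical array error magnitude |
| hemizygote no-call rate | 0.02 | a small fraction of hemizygous markers fail clustering |
| sequencing | 12× mean depth, 20 kb windows, 300±30 bp inserts, 100 bp reads | short-read WGS scale; windows sized so the deletion spans ~185 windows |
| AI records | 26 successes, 35 failures with 1 superovulation + 6 adjacent-AI + 8 low-fertility artifacts | the real accounting, leaving 20 usable failures |
| gestation / cycle | 285 / 21 days | standard cattle means used by the bound |
| latent death-day bound | 88 days | the first-third-of-gestation window the records imply |

All sizes and rates are `SimulationConfig` fields; the defaults *are* the
study design and are not tuned per test.

## Numerical and procedural choices

- **Coordinates** are 1-based inclusive internally; BED input/output is
  converted at the file boundary. Breakpoint flanks are the retained bases,
  so `length = right_flank − left_flank − 1` (this convention is forced by
  the printed length arithmetic).
- **Chi-square tests** are plain Pearson statistics without continuity
  correction (the corrected 2×2 statistic would be ≈5.3, not the 6.7 the
  observed table gives). Goodness of fit uses df = k−1. Cross-stage
  comparisons use the *earlier* stage as reference proportions and the
  later stage as observed — a category can only be lost, never gained,
  between stages; the direction is config-overridable in spirit but fixed
  here. A reference with an empty cell is pooled over sex into wt/carrier
  before testing.
- **Region calling**: seed markers need ≥2 affected errors and zero
  unaffected errors; seeds within 1 Mb merge; clusters under 5 seeds are
  dropped; bounds extend to midpoints toward the flanking clean markers;
  score = seeds − (markers with any affected het inside); ties rank
  leftmost. Because only markers where the sire is homozygous opposite the
  transmitted maternal allele can seed (~a fifth of in-deletion markers),
  the mapped region is strictly interior to the deletion — the array scan
  localizes, the sequencing evidence delimits.
- **Depth segmentation**: ratio bands nullizygous [0, 0.25), hemizygous
  [0.25, 0.75), diploid [0.75, ∞); median-of-5 smoothing; runs shorter than
  5 windows are absorbed into their left neighbor. At 12× with
  per-window Poisson noise, isolated spurious hemizygous runs of a few
  windows can survive smoothing; downstream evidence merging therefore
  keys on the junction call and the overlapping/largest hemizygous segment
  rather than assuming a unique segment.
- **Junction assembly**: right-clipped reads vote (majority) for the left
  flank; their clipped tails form a per-column consensus requiring a 60%
  majority (conflict → explicit ambiguous-junction error, never a guessed
  coordinate); left-clipped reads vote for the right flank; the consensus
  prefix that fails to match the resumed reference is the inserted
  sequence. Minimum support 3 clipped reads — the smallest value that makes
  toy-scale recovery deterministic while rejecting conflicts.
- **AI filtering** applies rules in fixed order (success → superovulation →
  adjacent-AI → low-fertility), attributing each discard to the first
  matching rule so category counts are disjoint. Non-positive survival
  bounds are flagged inconsistent and excluded from the maximum.
- **Randomness**: one `SeedSequence` per cohort, spawned into fixed-order
  component substreams, so the same seed reproduces a bit-identical bundle
  and adding a component never perturbs earlier ones.

## What the generator does and does not emulate

It emulates the *signals* each analysis consumes: apparent homozygosity and
Mendelian-error clustering over a transmitted deletion, depth halving,
insert-size inflation and junction-crossing clipped reads (with both clip
sides, as an aligner anchoring on the longer match would produce),
stage-wise category counts under mosaic transmission and male-specific
death, and reproduction records with the three documented artifact classes.

It does **not** emulate linkage disequilibrium or haplotype structure,
array intensity/clustering chemistry, GC- or mappability-dependent
coverage, repeat-mediated mis-mapping, or read-level sequencing error.
Passing tests therefore demonstrate correctness of the *methods* under the
stated model at the study's design scale, not robustness to every artifact
of real array or sequencing data. The synthetic reference sequence is
hash-generated with uniform base composition and no repeats, so junction
placement is easier than in a repetitive genome.

## Known limitations

- Power at the real design scale is modest: with 76 births, the
  sperm-vs-birth four-cell comparison has noncentrality ≈ 10.9 (df 3),
  i.e. ~80% power at α = 0.05 and ~59% at α = 0.01; single-cohort
  significance is expected but not guaranteed.
- The lethality estimator `1 − n(M,del)/n(F,del)` is a ratio of small
  counts at n = 76; its usefulness is demonstrated at a 10× scaled cohort
  (recovery within 0.1).
- The founder's own array calls at deleted markers are modelled as
  constitutional diploid; an allele-ratio-shifted no-call model for
  high-mosaicism soma would be a config extension.
- The depth model draws each window's mean coverage as Poisson with the
  per-base mean, which overstates window-level variance relative to real
  aggregated coverage; it is the conservative choice for testing the
  segmentation.
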