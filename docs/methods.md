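# Methods

## The problem

Genome-wide SNP-array molecular karyotyping of a rare-disease cohort
produces thousands of copy-number-variant (CNV) calls per study, almost all
of which are common polymorphisms, artifacts of failed arrays, or
low-confidence segmentation noise. `cnvcascade` implements the standard
case/control prioritization cascade for such a screen — here modelled on a
screen of 450 individuals with anorectal malformations against 4392 healthy
controls — together with the two downstream steps that turn surviving calls
into reportable findings: ΔΔCt qPCR copy-number confirmation and trio
inheritance classification.

## The cascade

Calls enter in the segmentation caller's one-line-per-call text format
(region, SNP count, copy state, confidence as a maximum log Bayes factor).
All internal coordinates are 1-based inclusive on hg19 labels; a CNV's size
is `end − start + 1`, the span between the first and last affected array
probe.  BED tracks are converted at the boundary (`start+1`, `end`), so an
internal size always equals the BED length.

Sample-level exclusions, in order, separately within cases and controls:

| step | rule | default |
|------|------|---------|
| I | recorded sex ≠ array-called sex | — |
| II | genotyping call rate below threshold (strict) | 0.98 |
| III | CNV count > mean + k·SD of the cohort (strict, one-sided) | k = 2 |

Step III uses the sample (n−1) standard deviation, computed over the
survivors of I–II only; it is deliberately *not* idempotent (trimming
changes the mean and SD), which the tests assert.  The trim is one-sided
because an excess of calls indicates a failed array; a deficit does not.
Samples with an unknown sex field are retained by default (an unknown
cannot demonstrate a mismatch); a strict policy flag flips this.

Call-level gates and comparative filters:

| step | rule | default |
|------|------|---------|
| IV | confidence (max log Bayes factor) below threshold → drop; missing confidence → drop | 30 |
| V | fewer supporting SNPs than threshold → drop | 3 |
| VI | case call overlapped (≥ 1 bp) by any control call of any type → drop | any-overlap |
| VII | loss overlapping a catalogued population loss, or gain overlapping a catalogued population gain → drop | type-matched |
| VIII | call overlapping no coding gene and no promoter → drop | 2 kb window |
| IX | externally flagged as failing visual review → drop | all pass |

Step VI follows the literal any-overlap, any-type rule; type-matched and
reciprocal-overlap variants are exposed as flags for sensitivity analysis.
Missing confidence fails step IV because a threshold on an absent value
cannot be certified.  Promoters are derived strand-aware when no explicit
promoter track is given: for a `+` gene `[start−w, start−1]`, for a `−`
gene `[end+1, end+w]`, clipped at position 1; a strandless gene is an error
rather than a silent 0-length promoter.  Step IX is a manual
intensity-review step and enters the pipeline only as a pass-through flag
set, but it still appears in the trace so the accounting is complete.

Every filter returns a conservation-checked trace entry
(`n_in = n_out + n_excluded`, enforced at construction), and each step's
output is a subset of its input, so the cascade is auditable end to end.
Steps VII and VIII are independent exclusions and commute (asserted as a
test).

### Interval indexing

The any-overlap query of step VI runs against per-chromosome merged
disjoint unions of the control intervals, queried by bisection.  Control
cohorts at this scale carry heavy duplication (the same common-CNV
interval called in hundreds of individuals), which degrades generic
interval trees badly; the merged union is O((n+m) log n) and exact.
Interval trees (`intervaltree`) are retained for the small annotation
tracks of steps VII/VIII.  Both paths are pinned against a brute-force
all-pairs oracle on randomized instances in the test suite.

## Prioritization report

Surviving calls from different samples are unified into one *event* when
they match exactly in interval, type and category — the criterion under
which an affected sib-pair with identical printed coordinates contributes
one event with two carriers.  Category participates in the key because a
terminal translocation segment can share printed coordinates with an
unrelated interstitial deletion (this occurs in the bundled fixture:
del22q11.21 appears both as a translocation segment and as a de novo
interstitial deletion) and must not be merged with it.  Exact matching is
the only computable criterion: array breakpoints are probe-limited, so
true breakpoint identity is unknowable from these data.

Per event the report computes:

* **size**: `end − start + 1` bp;
* **genes**: names of overlapping coding-gene features, deduplicated,
  lexicographically sorted;
* **category**: *microscopic* iff the event is terminal (reaches a
  chromosome end or derives from an unbalanced translocation) or ≥ 5 Mb;
  otherwise *submicroscopic*.  The terminal flag overrides size because a
  sub-megabase terminal rearrangement is karyotype-visible while an equally
  sized interstitial event is not;
* **inheritance**: from parental presence calls — both absent → *de novo*;
  exactly one present → *maternal*/*paternal*; none present but any parent
  untested → *unknown*; both present → an explicit ambiguity error;
* **control frequency bound**: observing k carriers among n screened
  controls bounds the population frequency strictly below (k+1)/n
  (1/n for an absent CNV: 1/4066 ≈ 2.46×10⁻⁴ in the reference screen);
* **summary**: counts over distinct events plus
  `pct_of_cases = round(100 · carriers / n_enrolled)`.  The denominator is
  the enrolled cohort (450 in the reference screen, giving 14/450 → 3%),
  not the QC-passed cohort; callers wanting the post-QC denominator pass it
  explicitly.

## ΔΔCt copy-number confirmation

With target Ct replicates and three housekeeping reference genes:

    ΔCt  = mean(target) − mean_g( mean(replicates of gene g) )
    ΔΔCt = ΔCt(sample) − ΔCt(diploid calibrator)
    RQ   = E^(−ΔΔCt),   E = 2 by default (configurable efficiency)

The reference is the mean of per-gene means, not the pooled replicate mean,
so unequal replicate counts across reference genes cannot bias the
normalization.  The calibrator is a diploid sample on the same plate.  A
target that never amplifies yields ΔCt = +∞ and RQ = 0 (zero copies).

Integer copy number is `2·RQ` binned around the theoretical RQ values
0, 0.5, 1, 1.5, 2 with edges at 0.25/0.75/1.25/1.75 and a ±0.05 guard band
at each edge in which no call is made.  Confirmation of an array prediction
requires the child's call to deviate from 2 in the predicted direction;
a parent deviating the same way counts as carrying the CNV, a parent at
CN 2 as non-carrying, and inheritance follows the trio rule above.

**Asymmetry of the RQ scale.**  Because Ct is logarithmic, the one-copy
bin is wide in cycle units (its edges sit ≥ 3.5 noise SD from RQ = 0.5 at
0.15 Ct well noise with 3 replicates) while the three-copy window
(1.30–1.70 after guard bands) is only ≈ 1.4 SD wide.  Deletion calls are
therefore near-perfect under realistic noise, whereas duplications degrade
— predominantly into no-calls rather than confident miscalls (the guard
bands absorb most deviations; measured at 0.15 Ct: CN3 ≈ 83% correct,
13% no-call, 4% miscall).  The qPCR benchmark and the acceptance
Monte-Carlo accordingly use the canonical deletion-confirmation setting
(200 heterozygous-deletion trios; ≈ 98% strictly correct calls, and the
inheritance label matches the simulated truth in every fully-called trio);
duplication behaviour is characterized separately and is a stated
limitation.  Wet-lab practice mirrors this: duplications need more
replicates or digital PCR for the same certainty.

## Synthetic cohorts

The generator emulates the statistical structure the cascade assumes,
calibrated once to the reference screen's reported scale:

| parameter | default | basis |
|-----------|---------|-------|
| CNV calls per sample | NB(mean 16, dispersion 4) | ≈ 6316 calls / 396 individuals |
| call rate | truncated N(0.99, 0.008) on [0,1] | ≈ 9% of samples below the 0.98 threshold |
| sex-mismatch rate | 0.005 | ≈ 2 / 450 |
| outlier samples | 3% at 4× call count | ≈ 12 / 408 at step III |
| common-CNV pool | 30 loci, carried at 0.15 per sample | exercises step VI at scale |

Counts use a negative-binomial model because only an overdispersed count
distribution makes the mean + 2 SD trim meaningful.  Spiked CNVs carry
ground truth: a *clean* spike (case-only, non-catalogued, genic,
confidence ≥ 30, ≥ 3 SNPs) is guaranteed recoverable — the generator
places it in a QC-clean case sample whose realized call count is at or
below the cohort mean, so the spike cannot be lost to the count trim by
carrier lottery — and spikes seeded into controls or into a type-matched
population track are rejected at exactly steps VI and VII.  Tracks are
generated consistently with the cohort (every common-pool locus covered by
a same-type population feature; genes non-overlapping, stranded, placed
over genic spikes and kept clear, including derived promoter windows, of
non-genic ones).  Each component draws from its own child of one seed
sequence, so outputs are byte-identical under a fixed seed.

What the generator does **not** model: per-probe intensity/allele-frequency
signal, genotyping batch effects, linkage structure, or realistic CNV
length/frequency spectra.  Passing spike-recovery tests therefore
demonstrates the correctness of the filtering logic under the assumed
structure, not the sensitivity of the upstream segmentation caller on real
arrays.

## The bundled validation fixture

`cnvcascade.fixture` packages the final validated yield of the reference
screen — 13 events (4 microscopic anomalies, 9 submicroscopic CNVs:
7 microdeletions, 2 microduplications) in 14 individuals including one
affected sib-pair — with published coordinates, types, gene content and
parental observations.  Unpublished attributes (SNP counts, confidence
scores, gene-track spans) are synthetic placeholders and marked as such.
Unbalanced translocations are represented by their deleted segment; the
reciprocal duplicated segment belongs to the same anomaly and is not a
separate event.  Everything derived (sizes, categories, inheritance
labels, gene lists, summary counts, the 3% yield) is computed by the
report builder at run time, not stored.

## Numerical and degenerate-input choices

* All thresholds compare strictly in the direction their rule states:
  call rate exactly at 0.98, confidence exactly 30 and exactly 3 SNPs are
  retained; a single shared base with a control call excludes.
* Fewer than two samples make a cohort SD undefined: step III raises, and
  the cascade skips sample QC for degenerate (<2-sample) cohorts.
* `round()` (banker's rounding) on the summary percentage; 14/450 → 3.
* Ties in event assembly are broken deterministically (reports sorted by
  chromosome order then coordinates; carriers sorted lexicographically).
* Seeds are plain integers; every stochastic component takes one.

## Known limitations

* Sex is taken from the metadata table, never recomputed from genotypes;
  X/Y calls in sex-discordant samples receive no special handling.
* Step VI's any-type rule means a common duplication can eliminate a rare
  overlapping deletion; the type-matched flag exists precisely to measure
  that effect, but the default follows the screen's stated rule.
* Duplication copy-number calling at realistic qPCR noise is no-call-prone
  (see above).
* The qPCR model assumes 100% amplification efficiency by default and has
  no melt-curve or efficiency-curve QC.
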