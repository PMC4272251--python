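# Methods

## Scope and model

`mthet` analyses single-nucleotide variation on the human mitochondrial
genome from strand-collapsed per-base allele counts (samtools mpileup text
or equivalent). The underlying read-count model is binomial: at a site with
true minor-allele fraction `p` and usable depth `n`, the variant read count
is treated as `v ~ Binomial(n, p)`. Everything downstream — the `v/n`
heteroplasmy estimate, its exact confidence interval, the detection
behaviour of the caller, and the simulator — follows from that assumption.
The model ignores strand bias, mapping artifacts, and contamination; those
are handled operationally (filter flags, recurrent-artifact detection,
region masks) rather than probabilistically.

Indels, structural variants and mtDNA depletion are out of scope: the
pileup parser skips indel blocks entirely and the callers reject non-SNV
alleles.

## Coordinates and the reference model

All coordinates are 1-based inclusive rCRS positions (`m.` notation);
BED input is converted explicitly at the boundary. Regions may wrap the
origin (`start > end`), as the control region does. When annotated features
overlap, a position's primary feature is resolved by the precedence
tRNA > rRNA > protein-coding > control (smallest-feature-wins, the
convention of mtDNA annotators); positions in the short intergenic spacers
are treated as control/noncoding. Coding consequences are computed by
translating the containing codon before and after substitution under the
vertebrate mitochondrial genetic code (NCBI table 2), honouring gene strand;
trailing partial codons (incomplete stops completed by polyadenylation) are
reported as noncoding. Position 3107, the historic rCRS placeholder base,
is rejected everywhere as a callable or annotatable site.

The packaged reference FASTA is a deterministic **synthetic stand-in** for
NC_012920.1 (the real sequence is not redistributable from this build
environment): exact length 16,569; `N` at 3107; the canonical gene map with
overlapping boundaries trimmed so each protein-coding gene owns one reading
frame; stop-free frames with ATG/ATA starts; poly-C tract `CCCCCTCCCC` at
16184–16193; and the documented bases at positions used as worked examples
(m.250 T, m.2905 A, m.5009 A as the third base of a leucine codon). Tests
exercising annotation therefore validate the machinery on a reference with
the documented structure, not the real base string; users analysing real
data should supply the real rCRS via `--ref-fasta`.

## Calling thresholds

| parameter | default | meaning |
|---|---|---|
| `min_total_depth` | 5 reads | minimum usable depth to call (and to deem a base assessable) |
| `min_variant_reads` | 3 reads | minimum variant-supporting reads |
| `min_vaf` | 0.10 | minimum variant allele fraction |
| `het_band` | 0.10–0.90 | point-estimate band classified heteroplasmic |
| `background_max_reads` | 2 reads | at or below this, a call is background noise |
| `het_screen_mean_depth` | 30× | samples screened for heteroplasmy only above this mean depth (strict >) |
| `qc_mean_depth` | 20× | mean-coverage floor for trusting a sample's call set |
| `recurrent_min_samples` | 3 | heteroplasmic in this many samples ⇒ recurrent artifact |
| `min_base_quality` | Q20 | pileup bases below this are dropped from counts **and** depth |

`min_vaf = 0.10` aligns the caller with the heteroplasmy band; it is a
documented, configurable choice (upstream callers do not all expose the
same parameter). Classification uses the point estimate, with the CI
reported as uncertainty, not as the classifier. Multi-allelic columns emit
only the top alternate allele (alphabetical tie-break, secondaries logged).
Quality-failed bases, deletion placeholders (`*`) and `N` calls are excluded
from both counts and depth, so `n` is always the denominator actually used
for `v/n`.

## Exact statistics

*Clopper–Pearson*: bounds via the beta-quantile identity
(`Beta(v, n−v+1)` and `Beta(v+1, n−v)` quantiles), which is the closed-form
solution of the binomial tail inversions; scipy's beta quantile is accurate
to well below 1e−10 on proportions, far below reporting precision. Coverage
is guaranteed ≥ the nominal level; the test suite verifies this by
exhaustive enumeration over all `v` for every `n ≤ 50` on a p-grid.

*Exact Poisson rate-ratio test*: conditional on the total `T = a + b`,
`a ~ Binomial(T, e_a/(e_a+e_b))` under rate ratio 1. The two-sided p-value
is the **minimum-likelihood sum** — all point probabilities not exceeding
the observed one, with a `1 + 1e−7` relative guard against floating-point
ties (the same convention R's `binom.test` uses) — not tail doubling. The
equal-exposure case is not special-cased; the general conditional path
reproduces it (e.g. the 2-vs-10 split of 12 events gives exactly 158/4096).

*Pearson correlation* is reported as R² with the t-transform p-value on
`n − 2` degrees of freedom; constant vectors are an error, not NaN.

## Liftover

The position map between two mitochondrial references is derived at run
time from a global (Needleman–Wunsch) alignment computed with edlib: exact,
deterministic, unit-cost edit distance. For two mitochondrial genomes above
the 95% identity floor the optimal path is essentially unique and matches
what affine-gap scoring produces, while avoiding a 16.5 kb × 16.5 kb
dynamic-programming table in Python memory. `N` is treated as matching any
base so the rCRS placeholder never breaks a block. Aligned columns become
mapping blocks; gap columns become unmapped positions on either side.
Unmapped variants go to a drop log, never silently away. Allele handling at
a mapped position: if the target reference equals the alternate allele the
variant is a reference-strain difference and is dropped
(`dropped_ref_equals_alt`); if it equals the source reference the variant
maps unchanged; otherwise it is emitted against the target base as
`re_referenced`. A precomputed block-map TSV can be supplied instead of
aligning.

## Concordance and error rates

Every (sample, base) pair gets exactly one category; counts always
partition `n_samples × L` sample-bases (checked on every ledger). Depth
belongs to platform A (the exome-like platform); any discordant site at a
base with platform-A depth below `min_depth` is reassigned to
`low_coverage`, because such bases measure coverage, not calling error.
Error rates count **bases, not variants**: a recurrent discordance counts
once per sample-base. Replicate-confirmation status is an input column —
the tool cannot re-run the wet-lab confirmation. Region exclusion (e.g. the
poly-C tract) shrinks the denominator by `n_samples × width` and drops
false calls inside the region; with 46 samples and the 10-base tract this
takes 762,174 sample-bases to 761,714.

## Coverage

Mean depth is taken over all bases including uncovered ones. Reported
fractions-at-threshold default to ≥5×, ≥20× and ≥30× (the calling floor,
the QC floor, and the heteroplasmy-screen floor). Correlation with
qPCR-derived relative copy number is computed per requested subgroup
(tissue × kit × aligner); outlier exclusion is an explicit, config-driven
filter (e.g. drop samples above 100× mean depth or copy number above 500),
never automatic; subgroups with fewer than 3 matched samples are skipped
with notice.

## Simulator

The generator emulates the structure the analyses assume, with defaults
chosen as the typical study conditions: 46 samples across three capture-kit
shapes, baseline mean depth 25.7× with between-sample log-normal scatter
(σ = 0.6), per-base log-normal noise (σ = 0.25, mean 1) on a smooth
per-kit shape (periodic piecewise-linear curve on 24 knots, exponentiated),
a 0.35× coverage dip over the light-strand replication origin (5721–5798),
Poisson-realized integer depths, base-error rate 1e−3 elevated 20-fold in
the poly-C tract, 25 homoplasmic plus 2 heteroplasmic variants per sample,
nine shared artifact positions with per-sample fractions in 0.12–0.35, and
a Sanger-like gold-standard generator with a 1.3e−5 per-base
false-positive rate. The poly-C multiplier and artifact fractions are
fixture parameters — plausible magnitudes, not measured values.

Randomness flows from one integer seed through `SeedSequence` spawn keys
((0,) cohort, (1, kit), (2, sample)), so cohorts are bit-reproducible and
extensible without disturbing earlier samples.

What the simulator does **not** model: read-level artifacts (alignment,
strand bias, mapping quality), NUMT sequence homology (NUMT regions are
modelled only as coverage multipliers), library duplicates, and
contamination. Passing recovery tests therefore demonstrates the pipeline's
statistical behaviour under the binomial model, not robustness to every
failure mode of real capture data.

## Problem sizes in the test and acceptance runs

The suite runs small: toy genomes of 100–300 bases for liftover and
annotation properties, full-length (16,569-base) synthetic references for
pipeline closure with 1–6 samples, 400–500 simulated sites per cell of the
recovery grid (fractions 0.10–0.90 × depths 10–100×), exhaustive
enumeration for `n ≤ 50` (intervals) and totals ≤ 40 (exact test). The
acceptance script uses the cohort-scale ledger (46 × 16,569) directly,
since the exact test conditions only on counts and exposures.

## Known limitations

* The packaged reference is synthetic; annotation results on it are
  structural validations, not claims about real rCRS bases.
* The gene map trims real overlaps (e.g. the ATP8/ATP6 overlap), so
  positions inside a trimmed overlap annotate to a single gene only.
* Heteroplasmy classification by point estimate means calls near the band
  edges flip with single reads at low depth — by design, the CI carries
  the uncertainty.
* Conditional CI coverage among *detected* sites dips below nominal at the
  detection boundary (low fraction × low depth), a selection effect, not an
  interval defect; pooled coverage across the heteroplasmy band stays
  well above 93%.
* The exact rate-ratio test assumes independent per-base errors; clustered
  artifacts (the reason the poly-C tract is excluded) violate it, which is
  precisely why the excluded-region variant is reported.
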