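# Methods

## The exact conditional HWE test

The test conditions on the observed allele counts.  With `n` diploid
individuals and `m` minor alleles, the number of heterozygotes under
random union of gametes has probability mass

    P(h | n, m) = [ n! / (hr! h! ha!) · 2^h ] / Σ_h' [ ... ]

with `ha = (m − h)/2`, `hr = n − h − ha`, over the support
`h ∈ {m mod 2, m mod 2 + 2, …, min(m, 2n − m)}`.  The two-sided P value is
the sum of `P(h')` over every `h'` whose probability does not exceed the
observed outcome's (relative tolerance 1e-12 in the comparison, so ties
arising from floating-point noise fall inside the tail).  The mid-P value
subtracts half of the observed outcome's probability from that sum.  Mid-P
is strictly smaller than the two-sided P and is the screen's significance
measure throughout, at α = 0.05 by default; a monomorphic site (m = 0) is
*untestable* and raises an error rather than returning P = 1, so deviation
rates are never diluted by undefined tests.

Direction (excess/deficit) is classified against the unconditional
expectation `2·p̂·q̂·n` at the sample allele frequencies, independent of
significance; exact equality yields `none`.

### Numerical scheme

Probabilities are built by the ratio recurrence between adjacent support
points,

    P(h+2) / P(h) = 4·hr(h)·ha(h) / [(h+1)(h+2)],

anchored at the mode (located by walking the monotone ratio), so every
intermediate value lies in (0, 1] and nothing can overflow at any sample
size.  The sweep is carried in log space and normalised with a shifted
log-sum-exp, which keeps tail probabilities finite (as logs) far beyond
the ~1e-308 linear floating-point floor; tail sums are assembled from the
logs.  When a true P value falls below the smallest positive double the
result is clamped to the floor while preserving the invariants
`0 < mid_p < p_two_sided`.  The implementation is exact (to ~1e-15
relative) against full rational enumeration for all n ≤ 50 and stable at
n = 5×10⁶.

### Detectability thresholds

`min_detectable_het_af(n, alpha)` finds the smallest heterozygote count
`h` (with zero homozygotes — every minor allele carried heterozygously)
at which mid-P ≤ α, and reports `h/(2n)`.  The search bisects on `h` and
then verifies the bracket locally with a ±2 window: because the support
parity follows `h` when hom-alt = 0, adjacent odd/even carrier counts live
on different lattices and mid-P can dip below α two steps before the
bisection bracket.  The returned AF is unrounded; consumers round to the
2-significant-figure convention these thresholds are usually quoted at.
Representative values at α = 0.05: 0.0072 at n = 64,603, 0.0018 at 1
million, 0.0008 at 5 million; 0.23 at n = 104 with α = 0.001.

## Allele-balance filters

Allele balance (AB) — the fraction of reads supporting the minor allele in
a heterozygous call — is summarised per variant as carrier counts in 20
half-open bins `[k·0.05, (k+1)·0.05)`.  Two derived filters:

* **VCNAB** (% of Variant Carriers with Normal AB) sums the three bins
  spanning [0.40, 0.55) and divides by all carriers.  The candidate
  pipeline requires VCNAB ≥ 50% (a fixed, configurable operating point).
  With half-open bins, "0.40–0.55" is exactly three bins and "AB > 0.8"
  exactly four — the 0.55 and 0.80 edges are exclusive/inclusive
  respectively by construction.
* **High-AB reclassification**: carriers in bins at or above 0.8 are
  plausibly homozygotes miscalled as heterozygous.  They are moved from
  het to hom-alt and the exact test re-run.  AB histograms are published
  for the pooled population only, so the moved individuals are apportioned
  across populations proportionally to each population's heterozygote
  count, using largest-remainder rounding with a deterministic lexical
  tie-break (sums exactly, no randomness).  If the histogram total
  disagrees with the summed heterozygote counts the reclassified count is
  scaled proportionally and a warning issued; it is capped at the
  available heterozygotes.  Moving carriers from het to hom-alt raises the
  implied allele frequency and lowers observed−expected heterozygosity, so
  the re-test can only weaken or destroy an excess signal, never create
  one.

By default the AF ≤ 0.05 filter is evaluated on the *pre*-reclassification
counts and only the HWE re-test uses adjusted counts; a config switch
(`reapply_af_after_reclassification`) makes the AF rule apply to the
adjusted counts as well.

## The two-tier pipeline

Tier one (dataset quality): canonical transcript; autosome (1–22, `chr`
prefix normalised away); protein-coding VEP consequence (17-term
whitelist); AF > 0.001 in at least one population; site coverage ≥ 80% of
individuals in every panel population; PASS in every dataset the variant
appears in (appearing and passing in one dataset suffices); and no
alternate-allele collision — the summed AF of all *other* alt alleles at
the same position must stay below 0.001 in every population.

Tier two (candidates): AF ≤ 0.05 in every population; significant excess
in at least one population; excess direction in every population where
the test is defined — populations where the variant is absent or
monomorphic are treated as vacuously consistent, since alleles private to
one population are legitimate candidates (`strict_all_pops=true` restores
the blocking interpretation); outside segmental duplications and tandem
repeats (point-anchor membership: a 1-based position P is inside a 0-based
half-open BED interval iff start < P ≤ end; indels are anchored at their
leading position); VCNAB ≥ 50%; and survival of the high-AB re-test.

Stages are independent predicates applied as a funnel, so the final
survivor set is order-independent; the report records each variant's
first failing stage and per-stage survivor counts.  Sample sizes are
always the per-site genotyped counts carried by the record, not the
nominal panel sizes, since coverage varies by site.

## Group comparisons

Effects are reported as Fold Enrichment — the ratio of two group
proportions from a 2×2 table — with a two-sided Fisher exact P value
(SciPy's implementation; an enumeration oracle cross-checks it in the test
suite for all small tables).  Degenerate margins yield P = 1 and are
flagged.  No multiple-testing correction is applied.

## Synthetic data generator

`generate_dataset` draws per-population genotype counts from class-specific
genotype frequency vectors at a latent allele frequency `q` sampled
log-uniformly over [0.001, 0.05] — the band the screen targets: below it
the exact test has no power at current cohort sizes, above it alleles are
classified benign.  Population sizes default to the seven-population,
137,842-individual panel (NFE 64,603; AMR 17,720; SAS 15,308; FIN 12,562;
AFR 12,487; EAS 9,977; ASJ 5,185), scalable by a factor for cheap tests.

* `hwe`: multinomial(p², 2pq, q²).
* `het_excess`: heterozygote frequency 2pq(1+d) with both homozygote
  classes shrunk by a common factor to stay on the simplex; the default
  d = 1.5 (2.5× inflation) mirrors the carrier excess of the worked
  sickle-cell example and gives near-complete power at q = 0.03 in an
  AFR-sized population.  Infeasible (q, d) combinations raise an error.
* `het_deficit`: inbreeding-style frequencies (p²+Fpq, 2pq(1−F), q²+Fpq),
  default F = 0.1 — the magnitude of the Wahlund-style deficits seen in
  admixed or consanguineous populations.
* `ab_error`: HWE genotypes in which a fraction e = 0.5 of hom-alt
  individuals is relabelled heterozygous; their AB mass is a discretised
  Beta(18, 3) (mean ≈ 0.86, essentially all above 0.7), true heterozygotes
  a discretised Beta(30, 30) (mean 0.5, sd ≈ 0.064, ~72% inside the
  normal window).
* `segdup`: het-excess variants planted inside emitted segmental-
  duplication BED intervals, so the region filter has true positives.

All randomness derives from a single integer seed; identical seeds
reproduce datasets byte-for-byte through the TSV writer.

What the generator does *not* emulate: linkage between sites, shared
individuals across variants, population-specific allele frequencies
(classes apply the same latent q in every population), read-depth-dependent
AB, and the long-tailed site-quality structure of real call sets.  Passing
tests therefore demonstrate the statistical machinery — calibration of the
test, power against the generative excess model, removal of the planted
error class — not performance on real sequencing artefacts.

## Problem sizes in tests

The unit suite runs the panel at scale factors 0.02–0.05 with tens of
variants per class; calibration uses 10,000 null draws at n = 5,000,
q = 0.05; power uses 200 excess variants at full AFR size; exactness is
enumerated for all n ≤ 50.  These sizes give binomial noise well inside
the asserted margins while the whole suite completes in well under a
minute.

## Known limitations

* The AB reclassification assumes the pooled histogram apportions across
  populations proportionally to heterozygote counts; real error processes
  may be population-biased (e.g. reference-panel effects), which would
  shift which population loses significance first.
* The screen's rule that excess must hold in *every* testable population
  protects precision against gene-flow artefacts but costs sensitivity in
  admixed populations, where substructure pushes variants toward deficit.
* Detectability thresholds assume zero homozygotes; any observed
  homozygote raises the carrier count needed for significance.
* Consequence and canonical-transcript annotations are consumed as input;
  the package performs no annotation itself.
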