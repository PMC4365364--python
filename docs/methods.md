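# Methods

## The genetic-vector model

Each marker in a fixed, ordered panel of N markers takes one of three
exclusive states γ ∈ {1, 2, 3}. For a biallelic SNP these are the
homozygous-reference, heterozygous and homozygous-alternate genotypes; a
categorical marker (the HLA-DRB1 shared-epitope copy number: No / Single /
Double) fits the same mold. An individual's **genetic vector (GV)** is the
tuple of their N states, and individuals with identical tuples form a GV
group with `n_h` controls and `n_s` cases. All inference is on groups.

Every GV has a unique **index matrix**: the 3 × N binary matrix with a
single 1 per column marking the state of each marker. Averaging index
matrices over any set of GVs with nonnegative weights summing to 1 yields a
column-stochastic *frequency matrix*; with weights `n_ν^α / N_α` over a
whole cohort group α ∈ {h, s} it is the genotype-frequency map (per-marker
state fractions), and with weights `n_ν^α / Σ n_ν^α` over a selected GV
subset it is the genotype-content contrast matrix. Pairwise genotype rates
(the fraction of a group carrying state γ at marker i *and* γ′ at i′) come
from the same grouped representation.

Heterozygote labels are canonicalized by sorting allele characters ("CA" ≡
"AC") because genotype callers order alleles arbitrarily. Individuals with
any missing or unrecognized call are excluded from GV construction and
reported — a GV is defined only for a complete tuple — never silently
dropped. This exclusion rule is this package's choice; published analyses
rarely state how missing calls were handled.

## Exact odds-ratio inference

For a group of size `n_t = n_h + n_s` in a cohort of `N_h` controls and
`N_s` cases, the observed odds ratio is `OR = n_s(N_h − n_h)/(n_h(N_s −
n_s))`; it is algebraically identical to the odds ratio of the group's
case/control *frequencies*, and the test suite verifies that identity with
exact rational arithmetic.

The null model holds `n_t` fixed and draws the group's case count `k` from
the hypergeometric distribution (Fisher's exact-test null). The induced
distribution of `OR(k) = k(N_h − n_t + k)/((n_t − k)(N_s − k))` is discrete
and strongly right-skewed, so normal-theory confidence intervals are
inappropriate; instead the package computes:

* **mean and variance of the randomized OR**, summing k = 1 … n_t − 1 with
  raw (unrenormalized) hypergeometric weights — the k = 0 term vanishes and
  the k = n_t term has infinite OR and is excluded by the summation bounds.
  No renormalization is applied; with these conventions the worked example
  (N_h = 779, N_s = 1500, n_t = 37) gives a mean of 1.0929, matching its
  published value at printed precision.
* **α-thresholds**: the smallest support OR whose strict upper-tail mass is
  ≤ α, and symmetrically the largest support OR whose strict lower-tail
  mass is ≤ α. Candidate thresholds and their tails run over the *finite*
  support, so a threshold is always finite and the achieved tail mass never
  exceeds α; when only the empty tail qualifies, a degenerate flag is set.
  Ties (tail mass exactly α) accept the threshold. Because the support has
  at most n_t + 1 atoms, the achievable α is quantized; the achieved masses
  are always reported next to the nominal α.
* **tail probabilities** P(OR_rand > OR_obs) (strict; likewise the lower
  side). Here the infinite-OR endpoint *is* counted in the upper tail —
  the event genuinely contains it — so upper + lower + point mass = 1
  exactly; the endpoint's mass is also exposed separately
  (`ORDistribution.p_infinite`).

Probabilities use exact big-integer binomials for n_t ≤ 500 and scipy's
log-space hypergeometric pmf above (the two agree to ~10⁻¹⁰ relative where
both are cheap; the cutoff is on n_t because support size, not cohort size,
drives the big-integer cost). Groups with `n_h = 0` or `n_s = 0` ("zero
GVs") have no finite OR; they are classified (solely sick / solely healthy)
and analysed separately, never fed to the OR machinery.

No multiplicity correction is applied across GV groups; the reports carry
raw tail probabilities together with the number of groups tested so users
can adjust if they wish.

## Two-cohort comparison

The pipeline (`run_gva`) proceeds: build both GV tables → align the GV sets
(common / cohort-specific) → set aside GVs that are zero in either cohort →
per-GV exact statistics → stratify common non-zero GVs by effect direction
into Ω11 (OR > 1 in both), Ω22 (OR < 1 in both) and the inconsistent Ω12,
Ω21 → keep Ω11 GVs beyond the upper α-threshold *in both cohorts* (risk
contrast set) and Ω22 GVs beyond the lower threshold in both (protective
set) → genotype-content contrast matrices → zero-GV matrices → optional
crop-and-recompute on a marker subset.

Design choices made where the design was genuinely open:

* **OR exactly 1** (possible with integer counts) goes to the "< 1" side of
  the stratification, keeping the risk classes strict; occurrences are
  recorded on the partition (`boundary`).
* **Protective selection** mirrors the risk rule on the lower tail of each
  cohort's own null distribution rather than using a fixed 1/OR_upper —
  the two are not equivalent because the distribution is asymmetric.
* **Cohort totals** entering the per-GV null distributions default to the
  filtered totals (individuals in common, non-zero GVs), matching the
  worked example's 779/1500; `totals="raw"` switches to full cohort sizes.
  When pre-grouped subset tables already carry externally supplied totals,
  use `totals="raw"` to preserve them.
* **Output ordering** is lexicographic on the γ-tuple throughout, for
  reproducible reports.
* **Cropping to zero markers** is an error, not a degenerate single-GV
  table: a GV needs at least one marker.

## Synthetic cohorts

`gva.synthetic.generate_pair` emulates the structure observed in the real
two-cohort data: a pool of ~160 distinct GVs (few relative to cohort size),
power-law base frequencies (exponent 1.5 — heavy-tailed, a handful of
common GVs and a long tail of rare ones), most GVs shared between cohorts
with a small log-normal cross-cohort frequency perturbation (sd 0.05 on the
log scale), cohorts of order 10³ controls and cases, and optional planted
zero GVs. Cases are drawn from the control frequencies reweighted per GV by
a planted odds factor and renormalized, so a planted OR is matched in
expectation (exactly so in the small-frequency regime where group odds ≈
frequency ratios; renormalization biases large planted frequencies
slightly). Per-GV control frequencies can be pinned (`planted_freq`) to
target an expected group size, e.g. a frequency of 0.0047 gives n_t ≈ 40 in
1000/1500 cohorts for a planted OR of 5.

What the generator does *not* emulate: linkage disequilibrium between
markers (GV frequencies are assigned to tuples directly, not built from
per-marker allele frequencies), Hardy-Weinberg structure, population
stratification, genotyping error, and missingness. Passing tests therefore
show that the statistics behave correctly on data with the assumed grouped
structure, not that the method is robust to those real-data complications.

The calibration study in the test suite uses 100 replicates for planted-OR
recovery (OR = 5, expected n_t ≈ 40, paired 1000/1500 cohorts, recovery
required in ≥ 90%) and 30 replicates of 60-GV null cohorts for the
false-flag rate (required ≤ α + 3σ); these sizes keep the whole suite
under half a minute while leaving the binomial noise on the checked rates
well below the margins tested.

## Known limitations

* As the panel grows, GV groups shrink toward singletons and the exact
  machinery loses power — the method is meant for panels of roughly 5–10
  markers, and cropping exists precisely to shorten vectors.
* Multiallelic markers are not supported (three states per marker is
  structural); VCF input rejects multiallelic records and supports
  SNP-only panels.
* The bundled published tables are summary counts; cohort-level published
  results that require raw individual-level data cannot be recomputed here.
* One published caption value does not reproduce under the stated formulas:
  the upper-tail probability at the worked example's observed OR computes
  to 2.2 × 10⁻⁴, not the printed 0.04 (the same caption's threshold and
  mean do reproduce exactly). The package reports the computed value.
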