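# Methods

This note documents the models and procedures implemented in `autozyg`, the
defaults and why they were chosen, and what the synthetic-data tests do and
do not demonstrate about real data.

## ROH model and detection semantics

A run of homozygosity is treated as the observable footprint of
autozygosity: a stretch where an individual's two chromosome copies are
identical by descent. Detection is the classical sliding-window scan over
each autosome:

1. **Window flags.** A window of `window_snps` consecutive markers is
   *homozygous* when it contains at most `max_het` heterozygous and at most
   `max_missing_per_window` missing calls.
2. **SNP eligibility.** Each SNP's score is the fraction of windows
   spanning it that are homozygous; the SNP is eligible when the score is
   at least `window_threshold`. SNPs within `window_snps − 1` of a
   chromosome end are spanned by fewer windows and the fraction is taken
   over the windows that exist — no padding, no fabricated data. A
   chromosome shorter than one window is treated as a single
   whole-chromosome window.
3. **Segments.** Maximal runs of eligible SNPs are split at inter-marker
   gaps above `max_gap_bp`, then filtered: `n_snps ≥ min_snps`, SNP-span
   length ≥ `min_length_bp`, density `length/n_snps ≤ density_bp_per_snp`,
   and — by default — at most `max_het` heterozygous calls over the whole
   segment.

Defaults (50-SNP window, ≥ 100 SNPs, ≥ 1 Mb, ≤ 0.5 Mb gap, 1 SNP / 50 kb,
≤ 5 missing and ≤ 1 het per window, threshold 0.05) are the standard
livestock parameterisation for medium/high-density chips.

Deliberate semantic choices, where the conventions in the field are
ambiguous:

- **Het tolerance at two levels.** "At most one heterozygote" can be read
  as a window rule or a segment rule; both are enforced by default
  (conservative), and `segment_het_limit=False` gives the window-only
  reading. The missing-call tolerance is window-level only.
- **Segment span.** Length is `end_bp − start_bp + 1` with ends at the
  first/last marker of the run — the only data-supported choice; no
  padding to inter-marker midpoints.
- **Length classes** 1–2 / 2–4 / 4–8 / > 8 Mb are half-open `[a, b)`: a
  segment of exactly 2 Mb falls in the 2–4 class. Under 1 cM ≈ 1 Mb these
  classes date the underlying inbreeding to roughly 50, 20, 12.5 and 6
  generations.
- **Boundary behaviour.** The window score decays smoothly across a true
  autozygosity boundary, so the first/last SNP of a run sits one marker
  inside the truth when the boundary is marked by heterozygous flanking
  markers; boundary error is therefore quoted in marker intervals, not bp.

## Inbreeding coefficients

- **F_ROH** = summed ROH length / `L_total`, where `L_total` is the
  autosomal extent covered by markers. By default `L_total` is computed
  from the loaded map (sum over chromosomes of last − first position + 1);
  a fixed constant can be supplied instead — the UMD3.1 cattle
  consensus-map extent 2,510,605,962 bp ships as
  `UMD31_AUTOSOME_EXTENT_BP`. Note that published per-animal Mb and
  percentage pairs are not always mutually consistent with one single
  `L_total`; the package never forces agreement, it simply exposes both
  modes. Class-specific F_ROH uses disjoint bins by default; a
  `cumulative` flag switches to minimum-length thresholds.
- **F_GRM** = `G_ii − 1` with `G = ZZ′ / (2 Σ pᵢ(1−pᵢ))`. Allele
  frequencies default to the observed cohort frequencies (the reference
  population is rarely published); monomorphic markers are excluded from
  numerator and denominator; missing genotypes are centered to 0 (column
  mean), the standard neutral imputation. `F_GRM` is negative for animals
  less homozygous than the Hardy–Weinberg expectation.
- **F_PED** is Wright's coefficient via the recursive kinship
  (coancestry) formulation on a topologically sorted pedigree. Unknown
  parents are unrelated non-inbred founders; an animal with any unknown
  parent gets F = 0. The implementation is validated against an
  independent path-counting (loop enumeration) oracle to 1e-12 on random
  pedigrees.
- **Correlations** between coefficients are Spearman rank correlations on
  pairwise-complete animals (published per-coefficient sample sizes
  differ, so pairwise-complete is the only defensible choice); pairs with
  fewer than 3 complete cases or constant input are reported missing.
- **Trends** regress the *annual mean* coefficient on birth year (one
  point per year) by OLS with a two-sided slope test; animal-level
  regression is available behind a flag. Animals without a birth year are
  excluded, not imputed.

## Islands

The island statistic is incidence-based: for each marker, the number of
animals whose ROH cover it. Counts are transformed as `log10(count + 1)` —
the +1 keeps zero-count markers defined and cannot create upper-fence
outliers (a `drop` mode excludes zeros instead). A marker is an outlier
when its transformed count strictly exceeds the upper Tukey fence
`Q3 + 1.5·IQR` of its own autosome (islands are by definition
high-incidence regions, so only the upper tail is flagged; with constant
counts the IQR is 0 and nothing is flagged). Quartiles use linear
interpolation (numpy default, type-7) — stated because fence placement
depends on it. Runs of ≥ `min_run` (default 100) consecutive outlier
markers become islands; runs are never bridged across a single
non-outlier SNP, and no physical gap limit is imposed ("consecutive" is in
marker order), but each island's largest internal gap is reported. Island
overlap with external interval sets and between lineages uses any-overlap
(≥ 1 bp) counting; per-lineage incidence is recomputed from that lineage's
animals only, not masked from the pooled track.

Interval coordinates are 1-based inclusive internally (matching PLINK MAP
positions); BED I/O converts to/from 0-based half-open at the boundary,
and the conversion round-trips exactly.

## Synthetic data: what it emulates and what it does not

The generator emulates a reduced-scale autosomal SNP panel: uniform
jittered marker spacing (default 2 × 50 Mb at 20 kb ≈ a high-density
bovine chip scaled ~6×), MAF uniform on [0.05, 0.5], discrete-generation
pedigrees (default 84 founders, 5 generations, ~500 animals) in which
matings pair full sibs with probability `consanguinity_rate` (0.2 by
default) and otherwise avoid full/half sibs, and gene dropping with
Poisson (Haldane) recombination at 1 cM = 1 Mb. Founder haplotypes are
uniquely labelled, so true autozygosity is known exactly. There is no
mutation and no genotyping error by default; an `error_rate` knob injects
random heterozygous miscalls to exercise the caller's tolerance.

Not emulated: linkage disequilibrium among founders (no coalescent
history), imputation error structure, selection, non-uniform recombination
maps, and sex chromosomes. Passing recovery tests therefore demonstrate
the *algorithmic* correctness of the pipeline under known truth — they do
not certify behaviour on real chips, where background LD inflates chance
homozygous runs and imputation errors break long runs.

`plant_segments` flanks each planted homozygous interval with two
heterozygous sentinel markers per side (`demarcate=True`). This is a
deliberate design: against a random Hardy–Weinberg background (~0.36 het
rate) the markers adjacent to a planted segment are homozygous by chance
with probability ~0.64, so with ≥ 2 consecutive chance homozygotes (~40%
per boundary) *no* caller could locate the planted boundary to one marker
interval — the truth would simply not be observable in the genotypes.
Sentinels make boundary-recovery tests well-posed and test the caller's
actual stopping behaviour at heterozygous boundaries.

The loop-depth experiments use `loop_pedigree`: independent families whose
single inbreeding loop closes at an exact depth d, giving the final animal
expected F = 2^−(2d−2). Mean IBD segment length is compared across depths
2, 4 and 6 (~20, ~12 and ~9 Mb on a 100 Mb chromosome). Depths much
beyond 6 are not testable this way — expected autozygosity falls below
10⁻⁶ and essentially no segments arise at feasible replicate counts — and
closed random-mating populations are not a substitute: as drift removes
haplotype diversity their IBD segments fuse, so older populations show
*longer* mean segments, confounding the age–length relation.

## Problem sizes and numerical choices

The test suite and the acceptance script run desk-scale problems chosen to
give stable statistics: the default ~500-animal / 5000-marker cohort for
F_ROH truth recovery; 500 full-sib families for the 0.25-IBD check
(standard error ~0.009 against a ±0.03 band); 20 seeded replicates each
for planted-segment recovery (10 segments × 30 animals) and island
recovery (300 animals, 60% carriers); n = 500 / m = 2000 for the HWE
G-matrix null (|mean F_GRM| ≤ 0.02); 200/800/3000 loop families at depths
2/4/6. Spearman orderings between F_PED and class-specific F_ROH use a
10 kb map because the 1–2 Mb class needs ≥ 100 SNPs per 1–2 Mb to be
observable at all.

Ties and degenerate inputs: empty segment tables produce all-zero
summaries (not errors); a chromosome with constant incidence flags no
outliers; fence equality is not an outlier (strict >); an all-monomorphic
panel raises (undefined G denominator); trend regression requires ≥ 3
distinct birth years; pedigree cycles and duplicate records are rejected
at load with the offending cycle/record named. All report tables are TSV
with 6-decimal floats, and every generator is a pure function of
(config, seed), so pipeline reruns are byte-identical.

## Known limitations

- Homozygote orientation in PED files with monomorphic ACGT markers is not
  recoverable (no declared reference allele); orientation is irrelevant to
  every computation here.
- The window scan's boundary resolution is one marker interval at best;
  sub-interval boundaries are not estimated.
- No X-chromosome, consensus-ROH haplotype matching, LD pruning,
  unknown-parent groups, or enrichment analysis; interval overlap against
  user-supplied BED files stands in for annotation services.
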