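# Methods

## The experimental model

The package analyses mutation-accumulation (MA) experiments read out by
whole-genome sequencing. Each MA line passes through repeated single-colony
bottlenecks; one transfer cycle grows a colony from a single cell through
`T` doublings, so the census size at stage `i` is `2^i` and the effective
population size of the cycle is the harmonic mean over the `T+1` stages,

    Ne = (T + 1) / Σ_{i=0..T} 2^{-i},

which evaluates to 10.50 at `T = 20` and 9.00 at `T = 17`. `T` itself is
estimated from colony cell counts as `T = log2 N`, assuming exponential
growth from one cell. Because drift at `Ne ≈ 10` overwhelms selection,
mutation counts are treated as (approximately) neutral observations.

## Rate estimation

For any mutation category, the estimator is

    μ = m / Σ_i (N_i × T_i),

with `m` the category's count summed over QC-passing lines, `N_i` each
line's analyzable sites (or the category's site count: four-fold sites,
CDS sites, a context's site count, ...) and `T_i` its total divisions.
Per-genome rates use `Σ_i T_i` alone. Uncertainty comes from treating `m`
as Poisson and using the exact Garwood interval,

    low = χ²(α/2, 2m)/2   (0 when m = 0),   high = χ²(1−α/2, 2m+2)/2,

scaled by the exposure. The interval is conservative (coverage ≥ the
nominal level); the suite verifies ≥93% empirical coverage at λ = 5 and
≥90% coverage of a planted rate over 50 simulated experiments.

All count comparisons use a 1-d.f. chi-square with Yates continuity
correction, with the correction clamped to zero when |obs − exp| < 0.5:

- **NS/S goodness of fit** — observed non-synonymous/synonymous counts
  against the split expected from the genomic site composition; a
  non-significant result supports the neutrality assumption.
- **2×2 comparisons** — e.g. transitions/transversions between groups
  (Pearson χ² with Yates, via `scipy.stats.chi2_contingency`).
- **Rate-ratio test** — conditional on the total count, the split between
  two categories with exposures `e1, e2` is binomial with
  `p = e1/(e1+e2)`; the Yates goodness-of-fit χ² against that expectation
  approximates the exact conditional binomial test (agreement within 0.02
  in p is asserted in the suite).

The Yates flavour was chosen because it is the variant that reproduces,
from the printed count tables, the statistics this package's reference
analyses report; the uncorrected Pearson statistic does not. P-values are
two-sided from the χ² distribution with 1 d.f.

## Site inventory and classification

Synonymous/non-synonymous site totals are fractional, Nei–Gojobori style:
each coding position contributes `k/3` synonymous sites, where `k` of the
three alternative bases leave the encoded amino acid (or stop, treated as
the residue `*`) unchanged. Substitutions creating or destroying a stop are
therefore non-synonymous. Four-fold degenerate sites are third-codon
positions where all four bases encode the same amino acid; they are a
subset of positions with synonymous fraction 1, which the suite asserts.

Region classification uses priority CDS > intron > intergenic; where gene
models overlap, the gene with the longest total CDS owns the position.
Coding effect is decided by translating the affected codon before and after
the change (the suite cross-checks against re-translating the entire gene).
Substitution classes are strand-collapsed into the six standard classes
(A:T→G:C, G:C→A:T transitions; A:T→T:A, A:T→C:G, G:C→C:G, G:C→T:A
transversions), so classification is invariant to reverse-complementing the
genome — also asserted. Trinucleotide contexts are tabulated on the
reference strand *without* collapsing, giving the 64-cell (16 flank pairs ×
4 focal bases) rate matrix; cells with zero context sites carry NaN, never
zero. Chromosome-terminal bases have no context and are excluded from
context counts (but not from site totals). `N` bases are excluded from all
denominators.

## SSR definition

No universal convention exists for calling microsatellites, so the detector
is parameterised and defaults to a MISA-like rule scaled for short toy
genomes: primitive motifs of 1–6 bp, at least 3 full copies and at least
5 bp total tract length, maximal and non-extendable, with overlapping calls
resolved to the longest tract (ties to the shortest motif, then leftmost).
An indel counts as "in SSR" when its affected span ±1 bp (configurable
flank) intersects a tract — the flank so that an indel anchored on the base
adjacent to a tract, the typical left-aligned representation of a slippage
event, is still credited to it.

## QC rules

Dish-mate contamination: two lines grown on the same Petri dish that share
one identical call (chromosome, position, ref *and* alt — position-only
matching would over-trigger at mutational hotspots) are assumed
cross-contaminated and the line whose id ends in an even integer is
removed, once per dish regardless of how many calls are shared. Dishes with
more than two lines are a configuration error: the rule is defined only for
pairs. The depth filter removes lines with mean coverage `< 30×`
(inclusive floor: exactly 30× passes). Filters are idempotent, partition
their input, and run contamination-first so the arithmetic
`80 − 3 − 4 = 73` / `90 − 1 − 3 = 86` of a study-shaped dataset comes out
as expected. Mutations of removed lines never enter any downstream count
or exposure.

## The synthetic-data generator

The generator's job is to emulate the *structure* of the experiment, not
sequencing physics: it starts at called variants (no reads, no error
model, no false calls) and plants truth it can later be scored against.

- **Genome**: per chromosome, background bases are drawn i.i.d. with the
  requested GC content (default 0.36, a fission-yeast-like value); genes
  are placed non-overlapping with ≥30 bp gaps, CDS lengths normal around
  the mean (default 900 bp, multiple of 3), strands random, an optional
  single intron of 40–120 bp at a random offset (default probability 0.4),
  coding sequence = ATG + non-stop codons + stop. SSR tracts (default 2
  per 10 kb; motifs 1–3 bp, 5–8 copies) are planted in intergenic gaps
  with a 5 bp margin from genes. Specs that cannot fit raise a sizing
  error naming the violated budget.
- **Mutations**: each line's substitution count is Poisson(rate × sites ×
  divisions). Sites are sampled without replacement (rates ≪ 1 per site
  make multi-hits negligible), with selection probability proportional to
  the site's context multiplier and restricted to bases the spectrum can
  mutate; the alternative base is then drawn by the six-class spectrum
  weights conditioned on the reference base. Indels (lengths uniform 1–3
  bp, insertion fraction configurable) are placed inside a planted SSR
  tract with probability `ssr_bias`, otherwise ≥6 bp away from any tract;
  in-tract insertions duplicate the following bases, slippage-style.
- **Determinism**: one master seed; each line's stream is
  `default_rng([seed, line_index])` with a stable global index, so adding
  lines never perturbs earlier lines, and identical inputs give
  byte-identical FASTA/GFF3/VCF/TSV output.
- **Artifacts**: `inject_artifacts` plants one identical mutation in both
  lines of chosen dishes and pushes chosen other lines below the depth
  floor. Low-depth picks avoid contaminated dishes so the two filters act
  on disjoint lines, as in the study arithmetic above. Shared-mutation
  rows are tagged in the truth table; low-depth lines are listed in a
  side `artifacts.json` so that per-line truth rows remain exactly the
  emitted VCF records (a conservation property the suite asserts).
- **Study-shaped fixture**: `study_fixture()` reproduces the reference
  design (80/90 lines, 2 per dish, 50 transfers, division totals 1,009 and
  865, 3+1 contaminated pairs, 4+3 low-depth lines) on a 3 × 40 kb toy
  genome. Per-site rates are scaled up so the *expected mutation totals*
  over the kept lines match the study scale (62/34 control BPS/indels,
  114/23 treatment); everything downstream of the per-site rate magnitude
  (QC arithmetic, spectrum shape, SSR fractions, ratio tests) is thereby
  preserved at desk scale.

What passing tests on synthetic data do **not** show: robustness to
alignment and calling artefacts, coverage heterogeneity along the genome,
multi-nucleotide events, or selection during the MA phase — real data can
violate all of these, and only the NS/S and enrichment diagnostics would
flag the last.

## Enrichment scan and auxiliary statistics

Per gene, the expected count is `CDS length × per-site rate × Σ divisions`
and the p-value is the Poisson upper tail `P(X ≥ obs)` (exactly 1 for zero
observed); q-values are Benjamini–Hochberg and "enriched" means `q < 0.05`.
Under neutral simulation the suite asserts the flagged fraction stays at or
below the BH level. The RNAseq dispersion statistic is the moment estimator
`α = (V − μ)/μ²` with the sample (n−1) variance — 0 in expectation under
Poisson noise, `−1/μ` for identical replicates; note the *median* α is
slightly negative at small replicate counts because the sample variance is
right-skewed, so calibration checks use the mean. Efficiency of plating is
`CFU_treated / CFU_control`, with the first dose of a curve taken as the
control.

## Numerical and interface choices

- Coordinates are 1-based inclusive everywhere (GFF3/VCF convention);
  indels are left-aligned with an anchor base. Multi-nucleotide
  substitutions (len(ref) = len(alt) > 1) are rejected with a clear error,
  and a ref-allele/reference mismatch raises a data-integrity error since
  it signals a wrong genome build.
- Gene CDS intervals are stored in ascending genomic order; the coding
  strand is applied when the coding sequence is assembled.
- Ratios with zero denominators (Ts/Tv, ins/del) and χ² on degenerate
  tables are reported as NaN ("undefined"), never as zero.
- Display rounding: rates to 3 significant figures, ratios and χ² to two
  decimals; `summary.json` always keeps full precision.
- Problem sizes in the test suite are deliberately small (genomes of
  10–40 kb, 50-replicate calibration loops), chosen so the full suite runs
  in seconds while the Poisson counting statistics still give informative
  assertions.

## Known limitations

- The pipeline consumes variant calls as given; there is no evidence
  re-evaluation, no handling of heterozygous or low-confidence calls.
- Overlapping gene models are resolved by a deterministic longest-CDS rule
  rather than transcript-aware annotation.
- The SSR definition is a convention; different thresholds move the
  "indels in SSR" fraction, which is why the parameters are exposed on the
  annotator and the CLI.
- The enrichment scan assumes a uniform per-site rate within CDS; regional
  rate variation would inflate its false-positive rate on real genomes.
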