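# Methods

This note records the models, estimators, numerical choices and known
limitations behind pennyscan. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Study design the package targets

A 2 × 2 elevation design: two high-elevation (HG) and two low-elevation
(LG) populations, ~10 diploid individuals each, from a predominantly
self-pollinating crucifer. Genome-wide diversity sits around
θπ ≈ 4–6 × 10⁻⁴ per bp and between-group differentiation around
F_ST ≈ 0.18. Selection scans look for windows where the high-elevation
group shows elevated differentiation, depressed diversity, and a
sweep-distorted site-frequency spectrum simultaneously.

## Synthetic cohorts

**Model.** Linkage is modelled as independent non-recombining blocks: each
block of length ℓ receives one genealogy from a continuous-time structured
coalescent over the deme hierarchy ((H₁,H₂),(L₁,L₂)) — within-deme
coalescence at rate k(k−1)/2 · 1/(2Nₑ) per generation, symmetric lineage
migration at rate m, demes merging by group at the within-group split time
and into one ancestral population at the group split. Mutations fall on
branches as Poisson(μ · branch · ℓ) at distinct uniform positions
(infinite-sites behaviour within a block). The simulated ancestral state
becomes REF and is exported as INFO/AA, so unfolded spectra are
well-defined by construction.

**Selfing.** Modelled at equilibrium rather than generation by generation:
with probability F′ = F/(2−F) an individual's two haplotypes are copies of
one sampled lineage (instant within-individual coalescence). This
reproduces the excess homozygosity of partial selfing without simulating
reproduction explicitly.

**Defaults and why.**

| parameter | default | rationale |
|---|---|---|
| deme Nₑ | 18 000 | θ = 4Nₑμ ≈ 5 × 10⁻⁴ per bp at μ = 7 × 10⁻⁹ |
| μ | 7 × 10⁻⁹ /site/generation | the Brassicaceae rate used throughout |
| generation time | 1 yr | annual plant |
| within-group split | 2 000 gen | recent population substructure |
| group split | 8 000 gen | divergence-model F_ST ≈ 1 − e^(−T/2Nₑ) ≈ 0.2 |
| migration m | 0 | clean divergence baseline; configurable |
| selfing F | 0.8 | "mainly self-pollinated", no published rate |
| block length ℓ | 2 500 bp | the genealogy decorrelation scale ≈ 1/(4Nₑr) ≈ 1.4 kb at r = 10⁻⁸; each 20-kb window then averages ~8 genealogies, as real recombining data would |
| r_rec | 10⁻⁸ /bp/gen | typical plant recombination rate; free parameter |

**Sweep injection.** A hard sweep is overlaid on the focal group's
haplotypes under the same star-genealogy model the CLR test assumes: one
focal haplotype is chosen as the sweeper; at distance d from the centre
every focal haplotype escapes with probability p_e = 1 − exp(−α·r_rec·d)
and keeps its allele, otherwise it takes the sweeper's allele. Default
α = 10³ puts the escape half-distance ln2/(α·r_rec) at ≈ 69 kb with a
near-complete core (p_e < 0.1) of ≈ ±10 kb — a strong hard sweep whose
core spans about one gene at the test fixtures' 20-kb gene spacing.
α → ∞ recovers neutrality exactly.

**What the generator does not emulate.** Recombination is block-wise, not
crossover-based, so LD decays as a step at ℓ rather than smoothly over
~150 kb as in the real selfing populations; there is no gene conversion,
no missing data unless injected, no background selection, and demography is
a clean two-level split rather than the colonization history of a mountain
plateau. Passing tests therefore demonstrate correctness of the estimators
and the internal consistency of the scan logic under a faithful caricature
of the sampling design — not calibration against real pennycress data.

## Diversity statistics

Per-site unbiased heterozygosity 2p(1−p)·n/(n−1) with n the site's
non-missing haploid count; window θπ divides the summed heterozygosity by
the full window length (all positions treated as callable — appropriate
for synthetic data; an accessibility mask can be supplied through the
window machinery if needed). θW and Tajima's D use the window's rounded
mean n with the 1989 variance constants; D is reported NaN at S = 0.
Trailing windows shorter than the window size are dropped, not truncated,
to keep per-bp values comparable. Windows are 0-based half-open; VCF
positions 1-based.

The SFS machinery supports folded/unfolded spectra, a strict "< MAF"
exclusion (boundary kept), and either dropping sites with missing data or
projecting them to a fixed haploid size by hypergeometric downsampling
(fractional counts).

## Differentiation

Hudson's estimator with per-site components
num = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1),
den = p₁(1−p₂) + p₂(1−p₁), combined per window as a ratio of sums
(ratio of averages), which is robust for 20-kb windows with ~20 haploid
genomes. Window values are clamped to [0,1] before the composite;
F_ST(rms) is the root mean square of the four high-vs-low pairwise window
values, so a negative estimate never deflates the composite. Group θπ for
the ratio pools the two populations of each group. Windows with fewer than
5 segregating sites in either pooled group are masked from scans
(configurable). A Weir–Cockerham alternative was considered and rejected
as the default: with these sample sizes the ratio-of-averages Hudson form
has the better-understood small-window behaviour.

## CLR sweep test

Background spectrum φ: the genome-wide unfolded spectrum of the focal
group, restricted to polymorphic classes 1..n−1 and normalized
(polymorphic-only conditioning, as in the original SweepFinder).

Sweep model: each of the n lineages at a site escapes the sweep
independently with p_e(d) = max(ε, 1 − exp(−α·r_rec·d)); the B escapees
plus one sweeping ancestor form a pre-sweep sample of size B+1 whose
derived count is φ hypergeometrically downsampled; the sweeper is a
uniform member of that sample and its allele is copied onto the n−B caught
lineages; the resulting count distribution is re-conditioned on 1..n−1.
The per-B kernels are independent of p_e, so the transform for any p_e is
a binomial mixture of n+1 precomputed kernels — this keeps the scan
O(grid × α × sites) with the transform itself computed once.

Numerical choices: escape floor ε = 10⁻⁶ (p_e = 0 concentrates all mass on
monomorphic classes and is degenerate); during scans p_e is rounded to a
1001-point grid whose first entry is ε rather than 0, and the exact
transform function is exposed separately for verification; the α grid is
20 log-spaced values spanning p_e(20 kb) from 0.01 to 0.99 **plus an
infinite α** (p_e ≡ 1), which nests the neutral model exactly and
guarantees CLR ≥ 0; grid spacing 10 kb (the window step) and scan radius
200 kb by default; per-site sample sizes from missing data are handled by
downsampling φ to each observed n. Sites beyond the radius enter neither
likelihood.

Outliers: the empirical top-1% cutoff over all grid points, ties kept
(≥ cutoff). Each flagged grid position represents its surrounding
half-step cell, so regions extend grid_step/2 beyond the outer flagged
points before merging — a single flagged point otherwise only book-ends
the window that starts at the same coordinate and region-level
intersection would miss a true hit. With fewer than 100 grid points the
empirical quantile is unreliable and nothing is flagged (warning).

## Outlier calling

Top-3% outliers of F_ST(rms) and of the focal group's θπ ratio
(θπ(LG)/θπ(HG) when scanning HG) are intersected per window; joint windows
are merged overlap-or-book-ended (50%-overlapping windows would otherwise
double-count); merged regions overlapping a CLR outlier region by ≥ 1 bp
become three-evidence selection calls; genes overlapping a call span by
≥ 1 bp (gene span, not CDS) are the candidate PSGs. Quantile thresholds
use linear interpolation with ties kept — "top x%" has no printed tie
policy, and keeping ties is the conservative direction for a scan meant to
produce candidates. Intersection is done at the region level (window vs
gene level were the alternatives); the choice is recorded in output
metadata.

## LD decay

Haplotype mode computes r² = D²/(p_A p_a p_B p_b) (equivalently the
squared Pearson correlation of binary haplotype indicators); genotype mode
the squared correlation of dosages, the standard choice for unphased data,
with pairwise-complete handling of missing genotypes. The two coincide in
the complete-selfing limit. Default binning: linear edges to 300 kb in 100
bins after a 5% MAF filter.

## LTR dating

5′/3′ pairs are aligned globally with affine gaps (match 1, mismatch −2,
gap open −4, extend −1; a length-L gap costs open + extend·(L−1));
pre-aligned input is also accepted. Gap and N columns are excluded from
the mismatch proportion p; K = −¾ ln(1 − 4p/3) errors at the p ≥ 0.75
saturation bound; T = K/2r with r = 7 × 10⁻⁹ by default. The paired-copy
generator evolves both copies independently for T years under JC69, so
the expected pairwise distance is 2rT and the round trip is a genuine
statistical check, not an identity.

## Splice-donor analysis

Introns are enumerated in transcription order with strand-aware donor and
acceptor dinucleotides. Variants hitting intron bases +1/+2 are donor
disruptions; labels use the cumulative CDS length upstream of the intron
(`c.450+1 G>C` for a first-base hit after 450 coding nucleotides). The
retained-intron transcript substitutes the alternate allele and keeps the
disrupted intron; translation proceeds in frame from the CDS start and the
first stop codon at or after the mutated base is reported. The stop offset
counts nucleotides strictly after the mutated base up to the **first base
of the stop codon** — "a stop N bases downstream" is ambiguous about
whether the codon is included, so the convention is fixed here and written
into the output table, and the toy-gene generator is designed to this
convention. Only the standard codon table is used; when the frame never
meets a stop the full read-through protein is returned and `stop_found`
stays false.

## Problem sizes in tests and the acceptance script

Simulation-based checks use 1-Mb single-chromosome cohorts (≈ 3 000 SNPs
at the default diversity): 50 replicates for sweep recovery in the test
suite, 20 in the acceptance script, 10 (tests) / 5 (script) neutral
replicates for null calibration, 200 LTR pairs of 2 kb for the clock round
trip, and 20 seeds for the LD decay average. These sizes give stable rates
(binomial standard errors of a few percent) while keeping a full run in
the low minutes on one CPU.

## Known limitations

- The composite likelihood treats linked sites as independent; with
  block-coalescent backgrounds the null CLR distribution is heavy-tailed,
  which is why outlier calling is empirical-quantile based rather than
  χ²-based.
- Polymorphic-only conditioning discards the information in swept-to-
  fixation sites (the original SweepFinder 1 behaviour); invariant-site
  likelihoods and background-selection corrections are out of scope.
- The windowed estimators assume every position callable; genome
  accessibility masks are only a hook, not a tested path.
- Gene assignment uses gene spans, not CDS, and reports any ≥ 1 bp
  overlap; no functional enrichment is attempted.
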