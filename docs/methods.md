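# Methods

## Data model

KIR alleles are named `LOCUS*digits[N]`; the first three digits identify the
protein (allotype), five digits additionally separate synonymous coding
variants, and a trailing `N` marks null alleles. Truncation to three digits
keeps the null flag, so a null allele never collapses onto the expressed
allotype it resembles. The four allelic series KIR2DL2/2DL3, KIR3DL1/3DS1,
KIR2DS3/2DS5 and KIR2DL5A/B are stored as distinct genes but can be queried
jointly under the series labels KIR2DL23, KIR3DL1S1, KIR2DS35 and KIR2DL5AB,
which pool member-gene counts.

Genotype tables are TSV with one row per individual; each locus cell is
`<copy>:<allele>+<allele>...`, `NEG`/empty for copy 0, or a bare copy number
where alleles are uncalled (pseudogenes KIR2DP1/KIR3DP1 carry copy number
only). A listed-allele count that contradicts the copy number rejects the
row, not the file. Framework genes (KIR3DL3, KIR3DP1, KIR2DL4, KIR3DL2)
default to copy 2 unless a structural variant is recorded.

Copy-number handling follows two conventions. For **allele frequencies** an
individual contributes one count per carried sequence copy (a copy-3 carrier
contributes three), and frequencies are renormalized over present copies.
For **genotype-level statistics** (heterozygosity) every individual
contributes exactly two units per gene, missing copies entering as an
explicit `absent` pseudo-allele; expected heterozygosity is
`1 − Σ f_i²` on unit frequencies, with the `2n/(2n−1)` small-sample variant
also reported, and observed heterozygosity is the fraction of two-unit
genotypes with distinct units.

## Haplotype engine

The segment catalog is data, not code: a YAML file listing per-haplotype
gene content for cA01–cA03, cB01–cB04, tA01–tA02 and tB01–tB07, plus the
structural variants del6 (KIR3DP1–KIR2DL4–KIR3DS1 deletion) and ins4 (the
reciprocal duplication, encoded as copy-2 entries within one haplotype).
Because del6/ins4 cross the region boundary, those telomeric entries carry a
`boundary_adjust` on KIR3DP1 that is applied when pairing with a centromeric
segment. Users can extend or replace the catalog.

Diplotype resolution enumerates every ordered-free pair of catalog
haplotypes (centromeric x telomeric combinations), keeps the pairs whose
locus-wise copy sums reproduce the observed copy-number vector exactly, and
ranks them by the product of segment frequencies. Without a frequency table
the prior is uniform; with one, segments absent from the table score zero,
so structurally ambiguous copy vectors (e.g. tA01+tB01 versus
tA01-ins4+tB01-del6, which are copy-identical) resolve to the segments
actually present in the population. Ties break lexicographically, making
calls deterministic. No EM phasing is attempted: pattern matching plus a
frequency prior mirrors how such haplotypes are called in practice, and the
round-trip tests show it recovers the generating diplotype essentially
always when the copy vector is pair-unique.

Multiallelic LD between phased loci is summarized by the frequency-weighted
|D'| (weights p_a·p_b, each |D'_ab| normalized by its frequency-constrained
maximum) and by Wn, the Cramér's-V-style normalization of the chi-square
sum; both lie in [0,1], equal 1 under bijective association and 0 under
exact independence, and are undefined (NaN) at monomorphic loci.

## Ligand scoring

HLA alleles map to epitopes through a family-level lookup with two-field
overrides (e.g. C*16:02 is C2 although the C*16 family default is C1);
classification of an HLA-C allele with no entry is an error rather than a
silent miss, because C1/C2 status is load-bearing for every downstream
count. Motif inference from sequence is deliberately out of scope — the
lookup is the single source of truth, and the synthetic generator draws its
epitope annotations from the same lookup.

The rule set is the twelve receptor–ligand pairs: Bw4(HLA-A)–3DL1,
Bw4(HLA-B)–3DL1, A3–3DL2, A11–3DL2, A11–2DS4, C2–2DL1, C1C2–2DL2, C1–2DL3,
C2–2DS1, C16–2DS2, C2–2DS5 and HLA-C-subset–2DS4. A rule is satisfied when
the receptor gene is carried (copy ≥ 1) with a qualifying allele — non-null
for KIR3DL1, alleles *003–*008 for KIR2DS5, full-length allotypes
(default the *001 group, configurable) for KIR2DS4 — and at least one HLA
allele bears the epitope. The C1C2 rule can contribute one interaction per
epitope present, so the per-individual count is bounded by 13, not 12; this
double-count convention is configurable (`count_per_epitope`).

All population-level interaction statistics are carrier-based (fraction of
individuals, not allele dosage). The activating/inhibitory split is the
polarity-wise sum of carrier frequencies over the total; the HLA-C-mediated
share is reported on two bases — carrier-frequency and per-instance (total
HLA-C-sourced interaction instances over all instances) — because the two
differ whenever C1C2 double-counting or multi-epitope individuals are
present.

## Diversity and differentiation

Rarefied allelic richness is the exact hypergeometric expectation
`Σ_i [1 − C(N−N_i, g)/C(N, g)]` of distinct alleles in a random subsample of
g gene copies; g defaults to the smallest gene-copy total among compared
populations. Common alleles are those with frequency ≥ 1% (inclusive),
computed at three-digit resolution by default. Allele sharing reports both
the Jaccard proportion and the two directional proportions, plus the
intersection set for UpSet-style tabulation.

Differentiation uses Nei's G_ST (unweighted population means) as the
headline estimator with the Weir–Cockerham θ for gene-copy data as a
cross-check; the two agree within 0.02 on balanced simulated panels, and θ
may be slightly negative near zero differentiation (G_ST values are
truncated at zero for reporting with the raw value retained). The exact test
of differentiation holds the margins of the population x allele count table
fixed and estimates, by seeded Monte Carlo permutation of gene-copy labels,
the probability of a table at most as likely as the observed one; the
(hits+1)/(steps+1) estimator keeps P in (0,1], and the test reduces to
Fisher's exact test on 2x2 tables.

## Ewens–Watterson test

Conditional on sample size n and allele count k, the Ewens sampling formula
is free of θ: a partition with part multiplicities a_j has probability
proportional to `n!/Π_j j^{a_j} a_j!`. For n ≤ 60 the implementation
enumerates integer partitions exactly; above that it samples the
conditional law by rejection from the Chinese restaurant process with θ
solved so that E[K] = k (the conditional distribution given K = k is
θ-free, so the accepted draws are exact). Both routes are seed-controlled.

The reported P is the lower tail Pr(F ≤ F_obs) including the point mass at
F_obs (heterozygote excess → P near 0, homozygote excess → P near 1), with
two-tailed significance at P < 0.025 or P > 0.975. Monte Carlo tails use the
(hits+1)/(replicates+1) estimator at 1,000 replicates by default. k = 1 is
degenerate and returns NaN. On neutral configurations (n = 100, θ = 1) the
realized two-tailed rejection rate is ~5–6%; the mild excess over the
nominal 5% comes from the discreteness of the partition distribution (the
maximal-F configuration always has lower-tail P = 1).

## Nei–Gojobori dN/dS

Site counting is the unweighted Nei–Gojobori scheme: at each codon position
the synonymous site fraction is the share of the three possible
single-nucleotide changes that preserve the amino acid, with changes
creating a stop codon counted as nonsynonymous, and per-codon counts
averaged over the two sequences compared (so syn + nonsyn sites = sequence
length). Codons differing at 2–3 positions average synonymous/nonsynonymous
step counts over all minimal mutational pathways that avoid stop-codon
intermediates (falling back to counting stop steps as nonsynonymous in the
rare case every path crosses a stop). Gapped or ambiguous codons are
dropped pairwise. Proportions are Jukes–Cantor corrected,
`d = −(3/4)ln(1 − 4p/3)`; p ≥ 3/4 raises a saturation error that carries
the raw proportion.

The selection test uses mean pairwise dN and dS over all sequence pairs
(optionally weighted by products of allele frequencies), with variances from
resampling codon columns with replacement (1,000 bootstrap replicates by
default) and `Z = (dN − dS)/sqrt(Var(dS) + Var(dN))` referred to the
standard normal, two-tailed. Identical sequences give an undefined Z (NaN).

## Contrasts

Region contrasts (dN−dS, F_obs−F_exp, heterozygosity) take the unweighted
mean of the per-gene statistic within the centromeric and telomeric gene
sets (per-population values averaged first, unweighted) and reference the
difference of means to the permutation distribution over gene-label
reassignments — exhaustively when the label space is small (e.g. all
C(15,7) splits), by seeded Monte Carlo otherwise. The neutral-marker
contrast applies the same two-sided permutation scheme to a focal set of
loci against a background panel (Cen-vs-Msat, Tel-vs-Msat, Cen-vs-Tel).

## Synthetic data: what it emulates and what it does not

The *amerindian* preset encodes a bottlenecked, isolated pool: four
centromeric allele-level haplotypes with cA01 at 0.86 total frequency and
per-gene allele frequencies of the form (≈0.95, ≈0.05) — the skew that makes
observed homozygosity exceed its conditional Ewens expectation — against
five telomeric haplotypes with more even per-gene frequencies; HLA pools
lack A3/A11 entirely and carry Bw4 at low frequency, and the `hla_c_only`
HLA preset removes Bw4 as well, making every scored interaction HLA-C
mediated by construction. The *cosmopolitan* preset spreads 11 centromeric
and 13 telomeric haplotypes (including del6, ins4 and a null 3DL1) over
many low-frequency alleles with the full epitope range. Sampling is
Hardy–Weinberg: two independent segment draws per region per individual,
HLA alleles i.i.d. per locus; everything is determined by (config, seed).

Wright–Fisher drift is loss-only (no mutation), appropriate to the
post-founding-isolation timescale being emulated; the marker generator
drifts symmetric-Dirichlet ancestral frequencies (8 alleles per locus,
Ne = 50, 20 generations by default, chosen to leave expected heterozygosity
near 0.6, typical of genomic microsatellite panels). The codon simulator
evolves a stop-free random ancestor along a star tree, accepting synonymous
changes at relative rate 1 and nonsynonymous at rate ω; the default branch
length of 0.02 expected attempted substitutions per site yields the ~1–2%
within-locus allele divergence characteristic of KIR coding sequences, and
at that divergence the neutral (ω = 1) Z-statistic is well inside the
±1.96 band in >90% of runs. At much larger divergences a small negative
Z bias appears at neutrality because the simulator cannot realize the
stop-direction changes that the site-counting scheme books as
nonsynonymous opportunities.

What the generator does **not** emulate: linkage between the centromeric
and telomeric segments (drawn independently, i.e. free recombination at the
hotspot), KIR recombination-hotspot allele formation and hybrid genes,
mutation during drift, HLA–KIR co-segregation within families, and any
particular published population's actual frequencies. Passing pipeline
tests therefore demonstrate that the statistics recover engineered truths
under the model's assumptions — skewed versus even allele configurations,
ω < 1 versus ω = 1, reduced versus background heterozygosity — not that
any real cohort's specific values are reproduced.

## Problem sizes and numerical choices

Synthetic checks run at desk scale, chosen as the smallest sizes at which
the signatures are unambiguous: populations of 100–150 individuals,
alignments of 15–20 alleles by 300 codons, 200-locus marker panels, 1,000
Ewens replicates, 500–1,000 bootstrap replicates, 10,000+ permutations.
Exact enumeration bounds: Ewens partitions at n ≤ 60; exhaustive label
permutation when the combination count is below the Monte Carlo budget.
Floating-point tail comparisons use a 1e-9 tolerance on F so equal-F
partitions are counted inside the tail regardless of rounding. Degenerate
inputs are explicit: monomorphic loci give NaN LD and a degenerate Ewens
result, saturated JC distances give NaN within the bootstrap (pairs dropped
from the mean) or a raising error in the pairwise API, and empty regions,
empty populations and g > N rarefaction requests are errors.

## Known limitations

Diplotype resolution is bounded by the catalog: a genuinely novel segment
yields "novel"/unresolved rather than a de novo pattern. The C1/C2 lookup
covers the common two-field families shipped; rare alleles require an
override entry. The exact differentiation test permutes gene copies, which
treats copies within an individual as exchangeable (no genotypic
correlation). The Ewens test conditions on k and is therefore insensitive
to selection that changes k itself. dN/dS site counting assumes equal
mutation rates across base changes (no transition/transversion weighting,
as in the unweighted method).
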