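# Methods

This note records the statistical models, the synthetic-data model, the
numerical choices and the known limitations behind `mimiclocus`. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted from memory.

## The genetic model

A single locus with alleles H₀ < H₁ < … < H_{K−1} in a strict dominance
hierarchy controls a discrete phenotype (a wing-pattern morph): an
individual's morph is that of the higher-ranked of its two alleles. Three
consequences drive the analyses:

1. every individual of morph m carries at least one H_m allele, so an
   H_m-diagnostic variant is present in all of them;
2. no individual of a lower-ranked morph can carry H_m, so the variant is
   absent there;
3. higher-ranked individuals may carry H_m recessively — diagnostic
   variants may appear (usually heterozygously) above the focal morph
   without contradicting the model.

The association scan therefore tests each morph against the pooled
lower-ranked morphs only, and the "full association" detector requires
presence in all focal individuals, absence below, and merely *reports*
carriage above.

## Association scan

Per site and morph, genotypes are collapsed into a 2×2 genotype-group ×
case/control table under one of three codings of the minor allele m:

* `recessive` — {hom-major, het} vs {hom-m}: m must be homozygous to be
  exposed;
* `dominant` — {hom-major} vs {het, hom-m}: carriage of m;
* `allelic` — chromosome counts (2n rows).

`recessive` is the package default. The pipeline and the validation
experiments use `dominant`: under a dominance hierarchy the expected causal
signal is carriage of the diagnostic allele, typically heterozygous, which
the carrier grouping captures directly while the recessive grouping pools
the informative heterozygotes with the controls' genotype class. Both are
available because the choice is a genuine modelling fork; `allelic` is kept
as the finest-grained variant.

The statistic is G = 2 Σ O ln(O/E) (0·ln 0 ≡ 0). Significance is by
permutation of phenotype labels among called individuals. Because the
table's margins are fixed under label permutation, the permuted table is a
function of a single cell, whose exact permutation distribution is
hypergeometric (multivariate hypergeometric over the three genotype classes
for the allelic coding); the implementation samples that distribution
directly rather than materializing shuffles — mathematically identical and
orders of magnitude faster. Ties G* = G count toward the tail
(conservative) and the add-one estimator never returns 0; its floor is
1/(n_perm + 1). Bonferroni correction multiplies by the number of sites
actually tested for that morph (degenerate tables are flagged untested and
excluded from the multiplier); correction is per morph, not additionally
across morphs, matching the per-morph testing structure.

**Calibration property.** The permutation test is exact, hence valid: on
null data the rejection rate at α never exceeds α beyond Monte-Carlo error
(asserted in the unit suite). It is, however, *conservative* under strong
discreteness: with 2×2 tables at realistic minor-allele frequencies the
attainable significance levels below 0.05 average ≈ 0.03, so the measured
null rejection rate sits near 0.03 rather than 0.05 (reported by
`scripts/acceptance.py` as `assoc_null_rejection_rate`). This is a property
of exact tests on discrete tables, not an implementation artifact; the
mid-p variant was deliberately not used because validity was prioritized.

The "top associated site" per morph is the minimum permutation p with ties
broken by the larger G: perfectly associated sites all sit at the p floor,
and G separates the perfect table from lucky permutation tails. Remaining
ties (e.g. several equally perfect diagnostic sites) resolve to the first
in genome order.

## Composite linkage disequilibrium

For unphased diploid dosages x, y the composite (Burrows) coefficient

    Δ̂ = Σᵢ xᵢyᵢ / (2n) − 2 p̂ₓ p̂ᵧ

sums gametic and non-gametic associations and needs no phase. It equals the
genotype-class count formula (1/n)[2n_AABB + n_AABb + n_AaBB + ½n_AaBb] −
2p̂ₓp̂ᵧ identically (checked to 1e-12 on random matrices), and |Δ̂| ≤ ½ for
biallelic sites. The composite correlation divides by
√[(p̂q̂ + D̂)ₓ(p̂q̂ + D̂)ᵧ] with D̂ = P̂(hom-alt) − p̂² the within-locus
Hardy–Weinberg disequilibrium; r² is clamped to [0, 1] and the signed r is
kept for diagnostics. Under random mating the composite r² agrees with the
gametic (phased-known) r² to within sampling error (≤ 0.02 at n = 10⁴,
re-measured by the acceptance script).

Missing data: pairwise-complete deletion per pair, maximizing the data used
for each pair at the cost of slightly different denominators across pairs.
Permutation significance shuffles whole-individual genotypes at one site of
the pair — this preserves each site's genotype (hence HW-disequilibrium)
margins, which is the correct null for phase-unknown data, and makes the
test on Δ̂² equivalent to the test on r². Note the add-one permutation
floor: with P pairs under Bonferroni, significance requires
n_perm + 1 > P/α; the default pipeline run reports the (possibly empty)
significant mask honestly rather than inflating n_perm.

## McDonald–Kreitman machinery

Site counting is Nei–Gojobori-style: per codon position the synonymous
fraction is the share of non-stop single-base neighbours preserving the
amino acid (stop-creating neighbours leave both numerator and denominator),
so syn + nonsyn = 3 per sense codon. Codons differing at multiple positions
are resolved by averaging syn/nonsyn steps over all orderings of the
single-base changes, excluding orderings that traverse a stop codon. An
exhaustive sweep shows every sense→sense pair keeps at least one legal
pathway; fully blocked cases arise only against stop-containing hybrid
codons (an outgroup codon with in-species-polymorphic positions masked to
the consensus), which are excluded from counts and tallied with a warning.

Within/between partition: positions segregating in-species are polymorphic;
monomorphic positions differing from the outgroup are fixed; a position
both segregating and divergent counts as polymorphic only. Polymorphic
changes are classified in the codon context of the in-species consensus —
a deliberate simplification for codons with several segregating positions
(rare under the densities simulated here). Divergence may be measured to
the first outgroup sequence (default) or to the outgroup consensus.

Jukes–Cantor correction −(3/4)ln(1 − 4d̂/3) is applied separately to the
synonymous and nonsynonymous divergence proportions, each over its own site
total, then rescaled to counts and rounded half-up for the Fisher table;
per-class correction is used because the two classes saturate at very
different rates. The Fisher exact two-sided p uses the probability-mass
definition (sum of tables with point probability ≤ observed at fixed
margins) computed on exact integer numerators, so ties are handled exactly
rather than with a floating tolerance — agreement with exhaustive
enumeration is exact (reported as `mk_fisher_vs_enumeration_max_abs_diff`
over all 628,055 tables with grand total ≤ 60).

## Multilocus HKA

For locus i with nᵢ sampled sequences, aᵢ = Σ_{j<nᵢ} 1/j and
bᵢ = Σ_{j<nᵢ} 1/j², the neutral model gives E[Sᵢ] = θᵢaᵢ,
Var[Sᵢ] = θᵢaᵢ + θᵢ²bᵢ, E[Dᵢ] = θᵢ(T+1), Var[Dᵢ] = θᵢ(T+1) + θᵢ². The
goodness-of-fit statistic sums squared standardized deviations of S and D
over loci and is referred to χ²(L−1). Parameters solve the classic moment
system θᵢ = (Sᵢ+Dᵢ)/(aᵢ+T+1), T = ΣD/Σθ − 1, iterated to a fixed point;
this is the estimator of the original method. A least-squares polish
(`method="minimize"`) is available but not default: minimizing the
statistic itself pushes it below the χ² reference and makes the test
markedly conservative (null rejection ≈ 0.007 vs ≈ 0.03 for the moment
estimator at L = 5, n = 20 — both re-measured by the calibration
experiment). Exact-expectation inputs give X² = 0 with parameters recovered
to machine precision under either method. The χ² reference is itself
approximate for the coalescent (S and D are not normal), so mild
conservatism of the moment version is expected and observed.

Duplication carriers are removed before computing S and D (haplotype ids
carry an `individual/copy` naming scheme so exclusion works at the
individual level); the pipeline identifies carriers from the genotyped
deletion allele, united with read-window segment calls.

## Sliding-window duplication detection

Reads fully spanning a window are reduced to their bases at the window's
known variant positions (or the full window string when none are given),
identical strings are clustered, and clusters with ≥ `min_reads` (3) reads
and ≥ `min_fraction` (0.05) of spanning reads count as alleles. This
support-threshold counter is a deliberate simplification of probabilistic
read-error correction; its operating characteristics are established
empirically: at 30× diploid coverage, 0.5% per-base error, 500-bp reads and
150/75 windows, window sensitivity inside a duplicated span is ≈ 1.0 and
the rate of ≥ 3-allele windows outside spans is ≈ 0 (reported as
`dup_window_sensitivity` / `dup_outside_window_rate`).

Windows are anchored at the region start; the final partial window is
dropped. Segment calling merges qualifying (≥ `min_alleles`) windows,
bridging up to `max_gap` = 2 non-qualifying windows: adjacent windows share
reads, so a local coverage trough knocks out up to size/shift = 2
consecutive windows at once. Segments start and end on qualifying windows
and require ≥ `min_windows` (2) of them, so an isolated noisy window never
seeds a call. Boundary resolution is inherently one window: a window
straddling a span edge qualifies whenever it contains a copy-distinguishing
variant in the overlap, so called extents bracket the true span by ≤ 75 bp
per side under the defaults.

## Pedigree co-segregation and synteny

Markers heterozygous in the H-carrying parent are informative; the
transmitted maternal allele is deduced per offspring (ambiguous trios are
flagged and skipped; Mendel-inconsistent trios are errors naming offspring
and marker). Phase — which maternal haplotype carries H — is supplied or
inferred from the non-recombinant majority. Offspring whose discordant
markers do not form a contiguous run touching a map end violate the
single-crossover assumption and abort the interval call. The locus interval
is the maximal all-concordant marker block; each resolved flank yields a
crossover gap (last concordant, first discordant adjacent pair).

Collinearity restricts two gene orders to shared genes and extends a block
while consecutive genes remain consecutive in the other order — ascending,
or descending as an inverted segment (with strand data, descending runs
additionally require orientation flips). Within a block the direction
cannot conflict: a permutation cannot follow a +1 step with a −1 step
without revisiting a rank. Block counts match a brute-force breakpoint
oracle on all permutations of ≤ 6 genes.

## The synthetic generator

What it emulates: five morphs with exact per-morph sample sizes (defaults
28/21/20/5/23; allele frequencies back-computed from those counts under
random pairing, ≈ 0.537/0.173/0.132/0.030/0.127); allele pairs drawn
conditioned on the realized morph so margins are reproducible;
per-allele-class diagnostic SNPs in one causal gene fragment of a
12-fragment candidate region (plus 4 unlinked fragments, ≈ 0.06 SNPs/bp,
≈ 200 sites total); an 8-bp deletion diagnostic for the duplication-bearing
morph plus duplication-linked diagnostics in three neighbouring fragments;
planted recessive carriage (one hidden third-ranked and two hidden
second-ranked alleles in top-morph individuals — without carriage the
5-individual morph's diagnostics sit at 5/194 = 0.026 minor frequency and
the 0.97 major-allele filter would remove them, which is exactly why the
carriage matters); background LD via haplotype copying with probability
c(d) = c_max·exp(−λd) (c_max = 0.8, λ = 0.004/bp) from the causal-haplotype
class, zero on unlinked fragments; background frequencies from a 1/f
neutral spectrum truncated at the 0.03 filter bound.

One structural rule: a background variant whose derived state rides any
haplotype class also segregates on the two bottom (ancestral) classes.
Without it the copying model generates chance morph-private variants at
linked sites — indistinguishable from planted diagnostics — and the
ground-truth bookkeeping that validation relies on is ill-defined.
Biologically this encodes that background polymorphism predates the morph
allele radiation; morph-private variation is exactly what the explicit
diagnostics model.

Sequence evolution: Kingman coalescent (intervals Exp(i(i−1)/2), total
length Λ), S ~ Poisson(θΛ/2) placed uniformly on branches (infinite
sites), divergence D ~ Poisson(θ(T+W)), W ~ Exp(1), so E[D] = θ(T+1).
Coding alignments split θ between site classes by the base sequence's
fractional site counts, scale nonsynonymous fixation by a configurable
excess factor (5× at the causal fragment by default, 1 elsewhere), and
never emit stop codons. Reads: 500-bp substitution-error reads (0.5%)
uniform per template copy at coverage/2 per copy, so a carrier's duplicated
span shows ~1.5× depth, as real copy-number gains do; the third copy exists
inside the span, carries private variants every ~50 bp and the 8-bp
deletion rendered as `-` so coordinates stay in the reference frame.
Broods: a heterozygous H-carrying mother, homozygous father, Mendelian
transmission, and designated offspring carrying one crossover between named
adjacent markers.

What it does **not** emulate — hence what green tests do not show about
real data: population structure and admixture; linked selection and
realistic recombination (the copying model produces a monotone LD flank,
not an ancestral-recombination-graph genealogy); sequencing-depth
heterogeneity, mapping bias and indel-realignment artifacts; genotyping
error in the VCF; phase uncertainty (alignments are supplied as haplotypes;
real data would be computationally phased first); and selection at linked
background sites. Calibration numbers are under the generator's null, not
under real demography. All randomness flows from one root seed through
fixed-offset substreams, so runs are byte-reproducible and toggling one
stage does not shift another's draws.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open internally; VCF positions convert at
  the boundary. Indels are ordinary biallelic sites; no normalization.
* Missing genotypes: pairwise exclusion everywhere, never imputation.
* Frequency ties p = 0.5: the reference allele is deemed major.
* Degenerate association tables (zero margin) flag the site untested for
  that morph; monomorphic sites make LD pairs undefined (NaN), not errors.
* The major-allele filter is strictly `<` threshold (0.97 default), over
  called chromosomes.
* Fisher p-values use exact integers; HKA moment iteration stops at 1e-12;
  JC correction errors at d̂ ≥ 0.75 (saturation).
* Pipeline reports are JSON with sorted keys and no timestamps, so equality
  of runs can be checked byte-wise. Stage isolation is by toggles, not
  on-disk caching: the full run is cheap and deterministic, so re-running
  is the supported way to regenerate downstream artifacts.

## Known limitations

* The per-position consensus-context classification of polymorphic changes
  within multi-hit codons is approximate; a full per-haplotype pathway
  decomposition would be needed for dense within-codon polymorphism.
* The HKA χ² reference is asymptotic; for small L and θ the test is
  conservative (measured, see above).
* Bonferroni-corrected permutation significance is bounded by the add-one
  floor; genuinely clearing correction across many tests requires n_perm of
  order tests/α.
* The exact permutation association test is conservative on heavily
  discrete tables (small morphs, rare alleles); users wanting nominal-size
  behaviour at any cost would need mid-p or asymptotic variants, which are
  intentionally not provided.
* The duplication caller assumes known variant positions within windows
  when provided; with none it clusters full window strings and sensitivity
  at realistic error rates then depends on window length.
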