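# mimiclocus

Statistical toolkit for localizing a polyallelic Mendelian switch locus — a
mimicry "supergene" — inside a multi-gene candidate region, in a species
whose locus alleles form a strict dominance hierarchy.

The motivating system is female-limited Batesian mimicry in swallowtail
butterflies: discrete wing-pattern morphs are controlled by one locus *H*
whose alleles H₀ < H₁ < … < H₄ are totally ordered by dominance, so an
individual's phenotype is that of its highest-ranked allele. An allele
diagnostic for a morph is therefore carried by **every** individual of that
morph, by **no** individual of any lower-ranked morph, and possibly
(hidden, usually heterozygous) by individuals of higher-ranked morphs.
`mimiclocus` turns that genetic logic into a set of tests that together pin
the locus down to a single gene:

* **Dominance-aware association scan** (`mimiclocus.assoc`). Each morph is
  tested as cases against the pooled lower-ranked morphs. Genotypes at each
  SNP are collapsed into a 2×2 table under a selectable genetic model
  (recessive / dominant / allelic grouping of the minor allele), tested
  with the likelihood-ratio statistic G = 2 Σ O ln(O/E) and an exact
  permutation p-value with the add-one convention,
  p = (1 + #{G* ≥ G}) / (n_perm + 1), Bonferroni-corrected per morph.
  "Full associations" — alleles present in all focal individuals and absent
  below — are reported with their hidden higher-morph carriers.
* **Composite linkage disequilibrium** (`mimiclocus.ld`) for unphased
  diploids: Burrows' Δ̂ = Σᵢxᵢyᵢ/2n − 2p̂ₓp̂ᵧ and the composite correlation
  r = Δ̂ / √[(p̂ₓq̂ₓ + D̂ₓ)(p̂ᵧq̂ᵧ + D̂ᵧ)], with genotype-permutation
  significance and a grey-scale heat map of Bonferroni-significant pairs.
* **Neutrality tests** (`mimiclocus.molevol`): McDonald–Kreitman 2×2 Fisher
  exact tests on [[Dn, Ds], [Pn, Ps]] with Nei–Gojobori site counting,
  minimal-pathway resolution of multi-hit codons, and per-class
  Jukes–Cantor correction d = −(3/4)·ln(1 − 4d̂/3) of fixed differences;
  and the multilocus HKA test on synonymous sites, comparing per-locus
  polymorphism S (E[S] = θaₙ) and divergence D (E[D] = θ(T+1)) against a
  χ²(L−1) goodness-of-fit statistic.
* **Duplication detection from reads** (`mimiclocus.structvar`): a tandem
  duplication puts three local haplotypes into a diploid, so 150-bp
  sliding windows (shift 75) of amplicon reads are clustered into supported
  haplotype strings; runs of ≥3-allele windows are merged into duplication
  segments.
* **Pedigree mapping and synteny** (`mimiclocus.mapping`): marker–phenotype
  co-segregation scoring, single-crossover localization to an
  adjacent-marker interval, and gene-order collinearity (synteny blocks and
  breakpoints) between species.
* **Synthetic study generator** (`mimiclocus.simulate`): populations with
  exact per-morph sample sizes (default 28/21/20/5/23, total 97), planted
  diagnostic SNPs including an 8-bp deletion, distance-decaying background
  LD, recessive carriage in dominant morphs, coalescent polymorphism with
  outgroup divergence (optionally with excess nonsynonymous fixation at the
  causal gene), error-bearing reads over a duplicated span, and broods with
  planted crossovers — all with known ground truth.
* **Pipeline** (`mimiclocus.pipeline`): one seeded, byte-deterministic run
  of all stages with a consolidated JSON report, including automatic
  exclusion of duplication carriers from the neutrality tests.

## Worked example

```python
from mimiclocus.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=3, outdir="demo_run"))
for morph in ("cenea", "lamborni", "planemoides", "poultoni"):
    r = report["assoc"][morph]
    print(morph, r["locus"], f"G={r['G']:.1f}", f"p_perm={r['p_perm']:.2g}",
          f"p_bonf={r['p_bonf']:.3g}")
print(report["molevol"]["hka"])
print(report["duplication"]["segments"][0])
```

prints (seed 3):

```
cenea en_exon1 G=66.9 p_perm=0.0001 p_bonf=0.0168
lamborni en_exon1 G=83.1 p_perm=0.0001 p_bonf=0.0175
planemoides en_exon1 G=36.6 p_perm=0.0001 p_bonf=0.0178
poultoni en_exon1 G=106.3 p_perm=0.0001 p_bonf=0.0181
{'focal': 'en_exon1', 'references': ['dpp', 'RpS19', 'cdp', 'wg'],
 'X2': 2.330379, 'df': 4, 'p': 0.675..., 'T_hat': 8.412749,
 'n_after_exclusion': 140}
{'individual': 'ind049', 'start': 825, 'end': 2175, 'max_alleles': 3}
```

Every morph's strongest association lands in the planted causal gene
fragment (`en_exon1`) at the permutation floor and survives per-morph
Bonferroni correction. The McDonald–Kreitman test is significant at the
causal fragment only (seed 3: odds ratio 4.85, p = 0.025, vs. e.g. 0.80 /
p = 0.76 at the unlinked *wg*), while the synonymous-site HKA test is not
(p = 0.68) — the same qualitative pattern the method is designed to
detect: positive/balancing selection visible in coding changes without an
excess of silent diversity. The duplication segment spans 825–2175,
bracketing the planted 900–2100 span within one 75-bp window per side, and
the pedigree stage localizes the planted crossover to the true
adjacent-marker gap (M4, M5).

A command-line entry point mirrors the stages
(`mimiclocus simulate|assoc|ld|mk|hka|dupwin|pedigree|synteny|run`); see
`mimiclocus --help`.

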