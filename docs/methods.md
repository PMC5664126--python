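# Methods

This note documents the statistical model behind `famscreen`, the defaults it
ships with, and the design decisions taken where more than one reasonable
choice existed.

## Discovery model

The discovery procedure assumes a fully penetrant-enough autosomal dominant
architecture within each family: a single causal variant segregating from one
founder, so that every *definitely affected* member carries at least one copy.
The filter cascade encodes exactly that and nothing more:

1. **exonic/splicing** — consequence ∈ {missense, synonymous, nonsense,
   frameshift, inframe indel, splice site}; a transparency pre-count, since
   stage 2 is strictly stronger on everything except synonymous sites.
2. **protein-changing** — the same set minus synonymous.
3. **rare** — reference-panel allele frequency strictly `< maf_threshold`
   (default 0.01).  A *missing* panel frequency means the variant is novel
   and is kept by default (`missing_af_policy: keep`): a causal variant may
   be absent from every reference panel, and dropping novel variants would
   filter out precisely the most interesting sites.
4. **shared among affected** — every member with recorded affected status
   carries the variant (het or hom-alt).  Members with unknown status impose
   no constraint: a relative who could not be examined must not veto a
   candidate.  An affected member with a missing genotype fails the variant
   by default (`missing_genotype_policy: fail_sharing`), the conservative
   reading; `ignore` is available because upstream pipelines differ here.

Sharing is deliberately carrier-based rather than zygosity-based: real
dominant pedigrees contain homozygous carriers (e.g. from cryptic
consanguinity or common enough founder alleles), and requiring identical
zygosity would discard them.

Cross-family intersection operates at the gene level (`min_families_shared`,
default 2): different variants in the same gene in different families count,
as does the same variant.  A variant annotated to several overlapping genes
(semicolon-separated) counts once per gene.

Segregation reports use the pedigree-figure notation (−/−, +/−, +/+, n.d.)
and flag two biologically expected anomalies rather than treating them as
contradictions: **phenocopy candidates** (affected, −/−: the phenotype has
another cause if the variant is causal) and **reduced-penetrance carriers**
(unaffected or unexamined, +/− or +/+).  Members without a determined
genotype are excluded from all flags.

## Burden model

The carrier table counts alleles per variant per cohort
(`alt_alleles / 2·n_genotyped`, with missing calls removed from the
denominator).  The burden comparison counts individuals carrying at least one
qualifying variant — by default rare (panel AF < 1% or panel-absent) missense
— so a double carrier counts once.  Relatives of index patients are excluded
from burden denominators through the per-individual `is_index` flag; mixing
relatives into an unrelated-cohort comparison would inflate carrier counts
through shared descent.

Percentages are formatted with half-up decimal rounding (`decimal` module,
`ROUND_HALF_UP`), the convention of clinical reports; Python's default
banker's rounding would print some boundary fractions differently.

## Exact and asymptotic tests

The two-tailed Fisher exact test uses the **probability-mass convention**:
with all margins fixed, p is the sum of hypergeometric point probabilities of
every admissible table whose probability does not exceed the observed one.
This is the common software convention (it is also what R's `fisher.test`
and scipy's two-sided test compute) and the one under which the carrier counts of the dystonia screening study
this package emulates reproduce their reported p-values.
Implementation details:

- point probabilities are computed as `hypergeom.logpmf` (log-gamma based)
  and summed with `logsumexp`, so margins in the thousands neither overflow
  nor lose the tail;
- equally extreme tables are included with a relative tolerance of 1e−7 on
  the log scale, absorbing floating-point ties; the test suite checks exact
  agreement with an exact-rational enumeration oracle over **all** 2×2 tables
  with margins ≤ 12 (5550 tables), where the observed worst absolute
  deviation is at the 1e−15 level;
- the doubled-one-tail convention is *not* used anywhere.

The Pearson chi-square on r×c category tables uses margin-product expected
counts, (r−1)(c−1) degrees of freedom, and no continuity correction; tables
with a zero expected cell are rejected with advice to merge categories, and
degenerate tables (one row/column, all-zero margins) are rejected at
construction.

## Synthetic study generator

The generator emulates the study design the analysis targets, at desk scale:

| Parameter | Default | Meaning |
| --- | --- | --- |
| `n_families` | 2 | multiplex discovery pedigrees |
| `family_template` | 2 founders + 3 offspring | offspring counts per generation; later generations descend from the first child and a married-in founder |
| `n_background_variants` | 200 | unlinked autosomal background SNVs (two per gene symbol) |
| `af_spectrum` | 10% mass at 0, 90% log-uniform on (1e−4, 0.5] | population allele frequencies; af = 0 models panel-absent (novel) variants |
| `fraction_protein_changing` | 0.4 | probability a background variant is missense; the rest are synonymous/intronic/UTR/intergenic (0.4/0.4/0.1/0.1) |
| `penetrance` | 0.9 | P(affected \| carrier) |
| `phenocopy_rate` | 0.01 | P(affected \| non-carrier) |
| `cohort_sizes` | MD 241, WD 74, other dystonia 604, PD 512, controls 461 | screening cohorts of the emulated study (index patients) |
| `case/control_carrier_freq` | 0.01 / 0.001 | P(causal het) per cohort individual |

`STUDY_DESIGN` additionally records the assay-by-cohort composition of the
emulated study (including the 14 family relatives excluded from burden
denominators); its grand total is 1906 subjects.

The log-uniform spectrum component is a deliberately crude stand-in for the
rare-skewed site-frequency spectrum of exome panels — it has the right
qualitative shape (density ∝ 1/x) without claiming calibration to human
data.  Within families, founders draw background genotypes under
Hardy–Weinberg and offspring receive one uniformly chosen allele per parent;
the body text of the transmission model is Mendelian and unlinked, with no
LD, no de-novo mutation, and no X-linked inheritance.  Affection is sampled
independently per member given carrier status; shared-environment effects
(e.g. training exposure in task-specific dystonia) are intentionally not
modelled.  Passing tests on these fixtures therefore demonstrates the
*logic* of the cascade and burden machinery, not robustness to LD,
population stratification, relatedness among "unrelated" cohort members, or
annotation error in real exomes.

Determinism: every family member and cohort individual draws from its own
PCG64 sub-stream keyed by (seed, unit identifiers, CRC-32 of the member id),
so outputs are bit-reproducible under a fixed seed and adding families or
cohorts never perturbs existing units' draws.

## Analytic cascade expectation

`expected_background_survivors` gives the expected number of background
variants surviving the full cascade, factorized as

```
n_background × P(consequence qualifies) × E_af[ rare(af) × share(af) ]
```

`share(af)` marginalizes, for a single-generation template (two founders, k
children), over the mother's causal genotype, the children's causal
transmissions, the affection indicators these induce, and the founders'
background genotypes at frequency `af`; children are exchangeable given the
parents, so the inner sum is a binomial mixture over the affected-child
count.  The continuous spectrum component is integrated by adaptive
quadrature; an empty affected set counts as sharing vacuously (the cascade
itself refuses families with no affected members, so comparisons against
Monte-Carlo runs should use penetrance high enough to make that event
negligible — at penetrance 1 the founder carrier is always affected).
Multi-generation templates are not supported in closed form and raise.

The Monte-Carlo comparison in the test suite redraws the panel on every
replicate (the expectation is over the frequency spectrum too) and uses a
spectrum with appreciable mass just below the rarity threshold so the
expected survivor count is of order 1; with an expectation of ~0.04 nearly
all replicates are zero and a sample-variance confidence interval is
meaningless.

## Problem sizes and numerical choices

The shipped test suite and the acceptance script run entirely on generated
data at desk scale: cascades on panels of 120–800 background variants,
planted-variant recovery over 100 seeded families, the cascade expectation
over 500 seeded replicates, and the null rejection rate of the burden test
over 2000 replicates of 150-versus-150 cohorts at a 5% carrier frequency —
sizes chosen to make the binomial/normal approximations in the checks sound
while keeping a full run in well under a minute.  Indels are normalized by
suffix-then-prefix trimming (left-aligned minimal representation) before key
construction so VCF keys always match annotation keys; half-calls and
non-diploid genotypes map to missing because the model is autosomal diploid
only.  Report writers emit rows in deterministic (lexicographic) order and
manifests contain no timestamps, so identical inputs give byte-identical
output bundles.

## Known limitations

- The cascade models dominant sharing only — no recessive or
  compound-heterozygote logic, no linkage or haplotype analysis.
- Annotation is consumed from a sidecar TSV, not computed; consequence
  calling and live panel-frequency lookup are out of scope, as are
  CRAM/BAM handling and liftover.
- The generator's frequency spectrum is not calibrated to empirical human
  site-frequency spectra, and cohort individuals are truly unrelated —
  cryptic relatedness, a real confounder of burden tests, is absent.
- The exact test is conservative (discrete), as the null simulation shows
  (rejection rate ≈ 0.02 at α = 0.05); no mid-p variant is offered.
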