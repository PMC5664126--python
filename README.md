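# famscreen

Family-based rare-variant discovery and cohort burden analysis for dominantly
inherited disorders.

`famscreen` is built for the classic gene-hunting design used in small-family
studies of conditions like musician's dystonia and other task-specific
dystonias: a handful of multiplex pedigrees are exome- or genome-sequenced,
each family's variants are pushed through a filter cascade, candidate genes
are required to recur across families, and the surviving gene is then screened
in large case/control cohorts whose carrier counts feed an exact enrichment
test.  The package implements every step of that desk-side analysis as a
tested Python library with a thin CLI, together with a synthetic study
generator so the entire workflow runs, and can be validated, without any
external data.

## The analysis

**Discovery.** Within each family, called variants are filtered to keep those
that are (a) exonic or splicing, (b) protein-changing (synonymous variants are
discarded), (c) rare — reference-panel allele frequency strictly below a
threshold, 1% by default, with panel-absent (novel) variants kept — and
(d) shared by every definitely affected family member, where both
heterozygous (+/−) and homozygous (+/+) genotypes count as carrying.  A gene
is a candidate when families ≥ `min_families_shared` (default 2) each retain a
qualifying variant in it.  Segregation reports flag *phenocopy candidates*
(affected non-carriers) and *reduced-penetrance carriers* (unaffected or
unexamined carriers), both expected features of dominant dystonia pedigrees.

**Screening and burden.** Cohort screening tallies, per variant and cohort,
the carrier count and the allele fraction `alt_alleles / 2·n_genotyped`.  The
burden comparison counts *individuals* carrying ≥ 1 qualifying variant
(default: rare missense) in cases versus controls, arranges the counts as a
2×2 table

```
        carriers   non-carriers
cases      a            b
controls   c            d
```

and tests it with a two-tailed Fisher exact test in the probability-mass
convention: with margins fixed, p = Σ P(X = k) over all tables whose
hypergeometric point probability does not exceed that of the observed table.
Point probabilities are evaluated through log-gamma so cohort-scale margins
are numerically safe.  An r×c Pearson chi-square (no continuity correction)
is provided for categorized count data.

**Simulation.** The generator plants one causal missense variant in a
designated gene, transmits it through template pedigrees under Mendelian
inheritance, samples affection through a penetrance and a phenocopy rate,
draws unlinked background variants from a configurable allele-frequency
spectrum under Hardy–Weinberg, and builds case/control cohorts with
configurable carrier enrichment.  A closed-form expectation for the number of
background variants surviving the cascade serves as an analytic oracle for
the stochastic pipeline.

## Worked example

One YAML config drives every subcommand (paths resolve relative to the
config file):

```yaml
simulate:
  seed: 11
  n_families: 3
  n_background_variants: 120
  penetrance: 0.9
  phenocopy_rate: 0.01
  cohort_sizes: {MD: 200, control: 200}
  case_cohorts: [MD]
  control_cohorts: [control]
  case_carrier_freq: 0.10
  control_carrier_freq: 0.01
  out: data
discover:
  vcf: data/discovery.vcf
  ped: data/families.ped
  annotation: data/annotation.tsv
  out: reports
burden:
  vcf: data/cohorts.vcf
  annotation: data/annotation.tsv
  cohorts: data/cohorts.tsv
  case_cohorts: [MD]
  control_cohorts: [control]
  out: reports
```

```bash
famscreen simulate -c study.yaml
famscreen discover -c study.yaml
famscreen burden   -c study.yaml
```

`discover` prints the per-family cascade and the recurrent candidate genes:

```json
{
  "cascades": {"FAM1": [121, 76, 48, 27, 1],
               "FAM2": [121, 76, 48, 27, 1],
               "FAM3": [121, 76, 48, 27, 1]},
  "shared_genes": ["GENE_CAUSAL"]
}
```

Each family starts with 121 variants; 76 are exonic/splicing, 48
protein-changing, 27 rare, and exactly 1 — the planted causal variant — is
shared by all affected members, so its gene is the only cross-family
candidate.  `burden` then compares carrier counts in the screening cohorts:

```json
{
  "groups": {"cases":    {"n_carriers": 44, "n_individuals": 200, "percent": "22.0%"},
             "controls": {"n_carriers": 21, "n_individuals": 200, "percent": "10.5%"}},
  "table": [[44, 156], [21, 179]],
  "p_value": 0.002664831197423477
}
```

22.0% of cases versus 10.5% of controls carry a qualifying rare missense
variant (the planted 10% causal carrier frequency on top of the shared
background rate), an enrichment the exact test rejects at p ≈ 0.0027.

Count-table tests are also available directly:

```bash
$ famscreen stats fisher "10,906;1,972"
{"df": null, "p_value": 0.004988439704766765, "statistic": null, "test": "fisher_exact_two_tailed"}
```

## Layout

| Module | Role |
| --- | --- |
| `famscreen.cohort_io` | VCF / PED / annotation-TSV / cohort-roster readers and writers, core data model |
| `famscreen.family_filter` | Filter cascade, cross-family gene intersection, segregation reports |
| `famscreen.cohort_screen` | Carrier tallies, percent formatting, burden tables |
| `famscreen.assoc_stats` | Two-tailed Fisher exact test, Pearson chi-square |
| `famscreen.synthetic_data` | Study generator and analytic cascade expectation |
| `famscreen.pipeline`, `famscreen.cli` | Config-driven runs, manifests, CLI |

See `docs/methods.md` for the statistical model, parameter defaults, and
design notes.
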