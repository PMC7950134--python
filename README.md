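# proteoid

Reidentification analysis for longitudinal plasma proteomes.

Blinded longitudinal plasma-proteome samples can often be tied back to the
individual they came from. `proteoid` implements two independent routes and
the tooling around them:

1. **Protein-level route** — select *individual-specific* proteins (levels
   that deviate >1.5-fold from the population median in ≥25 % of
   participants with within-person CV <20 %), then assign each blinded
   sample to an individual by Pearson correlation against one reference
   time point per person.
2. **Allele-level route** — apply single-amino-acid substitutions to
   canonical protein sequences, digest each allele in silico (cleavage
   C-terminal to K/R, ≤2 missed cleavages, length ≥7), enumerate peptides
   that discriminate alleles, collapse missed-cleavage forms, run a
   five-stage consistency filter cascade over identification evidence, and
   assign samples by counting matching present/absent variant-peptide
   calls.

A synthetic-cohort generator (log-additive variance components for
intensities, Hardy–Weinberg genotypes with detection dropout for variant
peptides, optional marker spikes) makes the whole pipeline testable with no
external data. A marker-spike screen flags samples where a marker protein
exceeds a fold threshold over the individual's personal median.

## Package layout

| module | contents |
|---|---|
| `proteoid.cohort_io` | TSV/FASTA/JSON readers and writers, `SampleKey`, `IntensityMatrix`, `EvidenceTable`, `VariantRecord`, report writer |
| `proteoid.specificity` | individual-specific protein selection, within-person CV, marker-spike screen |
| `proteoid.correlation_id` | log10 transform, pairwise-complete Pearson, all-vs-all correlation matrix, correlation-based assignment and evaluation |
| `proteoid.variant_panel` | substitution application, in-silico digestion, allele-peptide enumeration, missed-cleavage grouping, five-stage filter cascade |
| `proteoid.allele_id` | present/absent match scoring and allele-based assignment |
| `proteoid.synthetic_cohort` | cohort config, intensity/genotype/evidence simulators, marker-spike injection, cohort writer |
| `proteoid.cli` | `proteoid` command-line entry point |

## CLI

```bash
# generate a synthetic cohort (42 individuals x 7 time points by default)
proteoid simulate --seed 1 --out data/

# protein-level route
proteoid select-panel --matrix data/intensity.tsv --annotations data/annotations.tsv \
    --out panel.json
proteoid corr-assign --matrix data/intensity.tsv --annotations data/annotations.tsv \
    --panel panel.json --reference-tp 1 --out report/

# allele-level route
proteoid build-panel --fasta data/canonical.fasta --variants data/variants.tsv \
    --evidence data/evidence.tsv --out allele_panel.json
proteoid allele-assign --evidence data/evidence.tsv --panel allele_panel.json \
    --reference-tp 1 --out report_allele/

# marker-spike screen
proteoid screen --matrix data/intensity.tsv --annotations data/annotations.tsv \
    --markers P0001,P0002 --fold-threshold 5 --out screen/

# everything from one YAML config
proteoid run --config pipeline.yaml
```

A minimal `pipeline.yaml`:

```yaml
out_dir: out
reference_timepoint: 1
seed: 1
simulate:          # omit and provide `inputs:` paths to use existing files
  n_individuals: 42
  n_timepoints: 7
```

All tabular formats are plain TSV: the intensity matrix is proteins ×
samples with `NA`/empty for missing, sample annotations map sample ids to
(individual, time point), evidence is long-format
(peptide, gene, accession, allele, variant site, sample, identified 0/1),
and the variant table is (accession, position, ref, alt, variant_id).

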