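# cardiacg2p

Structured gene-disease knowledge for inherited cardiac conditions
(cardiomyopathies and arrhythmia syndromes), plus a mechanism- and
allelic-requirement-aware variant prioritisation engine and the statistics
used to compare it against generic filtering pipelines.

The package bundles a curated panel of 65 gene-disease pairs (plus
unestablished entries carried for completeness). Each pair records
inheritance modes and qualifiers, allelic requirement, disease-associated
variant consequence terms (a proxy for disease mechanism), the variant
classes reported with evidence of pathogenicity, and gene-specific
restricted-repertoire constraints (variant allowlists, protein hotspot
regions, exon inclusion masks, forced-retain classes).

## Modules

| Module | Role |
| --- | --- |
| `cardiacg2p.knowledge_base` | Panel loader, validator, query engine and census statistics |
| `cardiacg2p.consequence` | Variant-class assignment, NMD triggering/escaping adjudication, class-to-mechanism mapping |
| `cardiacg2p.filtering` | The three prioritisation pipelines with per-variant decision traces |
| `cardiacg2p.vcfio` | VEP-style annotated VCF reading, transcript selection, decision tables |
| `cardiacg2p.fixtures` | Deterministic synthetic transcripts/variants/cohorts with per-pipeline truth labels |
| `cardiacg2p.evaluation` | Sensitivity with Wilson/Clopper-Pearson intervals, positive rate, two-sided Fisher exact tests |

The three pipelines:

1. **generic_pav** — gene list, gnomAD AF < 1e-4 (strict), any protein-altering
   consequence;
2. **lof_or_clinvar** — gene list, rarity, then LOFTEE high-confidence
   truncating variants or unambiguous ClinVar P/LP assertions;
3. **g2p** — gene list, rarity, then the panel's disease-associated variant
   classes and restricted repertoires, with optional per-sample
   monoallelic/biallelic (zygosity) logic.

## CLI

```bash
# panel census
cardiacg2p kb stats --json
cardiacg2p kb stats --panel LQTS,SQTS
cardiacg2p kb validate my_panel.tsv

# synthetic fixtures (truth.vcf, truth_labels.tsv, transcripts.tsv)
cardiacg2p simulate --seed 1 --out sim/            # built-in combinatorial grid
cardiacg2p simulate --spec spec.yaml --seed 1 --out sim/

# run a pipeline over an annotated VCF
cardiacg2p filter --pipeline 3 --input sim/truth.vcf \
    --transcripts sim/transcripts.tsv --output p3.tsv

# compare decision tables
cardiacg2p evaluate --decisions p1.tsv --decisions p3.tsv \
    --truth sim/truth_labels.tsv --report report.tsv
```

Input VCFs must carry a header-declared per-transcript annotation INFO field
(`CSQ`); both `SYMBOL`/`Gene` and `Feature`/`Feature_id` spellings are
accepted and the population-AF field name is configurable (`--af-field`,
default `gnomAD_AF`).

## Data notes

The bundled panel (`src/cardiacg2p/data/cardiac_panel.tsv`) is a UTF-8 TSV,
one record per row, with semicolon-joined vocabulary columns and a JSON cell
for constraints; `load_knowledge_base()`/`write_knowledge_base()` round-trip
it. Records graded below Moderate validity, or without adjudicated mechanism
terms, are excluded from filtering and statistics.
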