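# mirsnp

Allele-aware miRNA target-site analysis pipeline: a quantitative-trait
association scan, LD proxy expansion, miRNA seed-site prediction with
allele-specific rescoring of SNPs inside predicted sites, permutation-based
target-gene enrichment, eQTL regression with IQR outlier filtering, and
luciferase reporter-assay statistics. A synthetic-data module generates
inputs with the statistical structure each stage assumes, so the whole chain
runs without any download.

## Modules

| module      | purpose |
|-------------|---------|
| `core_io`   | VCF/FASTA/TSV readers & writers, domain types, YAML config |
| `synthdata` | haplotype panels with block LD, cohorts, phenotypes, 3'UTR targetomes with planted sites and site-disrupting SNPs, expression vectors, reporter plates, plus ground-truth tables |
| `assoc`     | per-variant additive OLS scan with covariates + PCs, locus clumping |
| `ldproxy`   | haplotype/genotype r², proxy-SNP search around index variants |
| `mirtarget` | canonical seed-site classes (8mer, 7mer-m8, 7mer-A1, 6mer), alignment and duplex-energy scorers, k-of-n consensus, ref-vs-alt delta scoring, genomic SNP → UTR projection |
| `enrich`    | permutation test for enrichment of associated SNPs in target genes |
| `eqtl`      | 1.5-IQR outlier filter, Shapiro–Wilk check, covariate-adjusted fit, homozygote-exclusion sensitivity analysis |
| `reporter`  | 3-SD outlier rule, scrambled-control normalization, one-sample binding test, two-sample allele test, percent-point difference |

## CLI

```bash
mirsnp simulate --out inputs/ --seed 1          # write VCF/FASTA/TSV/CSV + truth JSON
mirsnp assoc --vcf inputs/cohort.vcf --pheno inputs/phenotypes.tsv \
             --trait trait --pcs 3 --out assoc.tsv
mirsnp clump --assoc assoc.tsv --p 1e-6 --out loci.tsv
mirsnp proxies --vcf inputs/ld_panel.vcf --index idx0001 --r2 0.8 --out proxies.tsv
mirsnp sites --mirna inputs/mirnas.fa --utr inputs/utrs.fa --k 3 --out sites.tsv
mirsnp delta --mirna inputs/mirnas.fa --utr inputs/utrs.fa \
             --proxies proxies.tsv --vcf inputs/ld_panel.vcf --out delta.tsv
mirsnp enrich --assoc assoc.tsv --genes inputs/genes.tsv --sites sites.tsv \
              --perms 100000 --seed 1 --out enrich.json
mirsnp eqtl --expr inputs/expression.tsv --covars sex,population \
            --sensitivity-exclude-hom --out eqtl.json
mirsnp reporter --plates inputs/plates.csv --out reporter.json
mirsnp run-all --workdir run1/ --seed 1         # the whole chain end to end
```

Thresholds (significance cutoffs, r² minimum, windows, scorer cutoffs,
permutation count) live in a YAML config consumed via `--config`; see
`mirsnp.core_io.Config` for the defaults.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (worked reporter
values, r² and seed-site oracles, association/enrichment calibration,
eQTL and reporter parameter recovery). The external-data eQTL reproduction
runs only when the GEUVADIS E-GEUV-2 release and rs9882688 genotypes are
supplied via `MIRSNP_GEUVADIS_EXPR` (the `GD452.MirnaQuantCount...` file)
and `MIRSNP_GEUVADIS_GENO` (TSV with `sample_id`, `dosage`, `sex`,
`population`); otherwise those three tests are skipped.

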