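# pairedomics

A toolkit for analyzing paired pre-/post-treatment tumor cohorts:
mutational spectra and NMF signature extraction, APOBEC tCw enrichment
classification, control-referenced chromosomal-instability (CIN) scoring,
tumor mutation burden / MSI / neoantigen filtering, clonal-cluster
retention and mutation-sharing classes, TCRβ repertoire diversity, and the
exact nonparametric statistics used to compare groups. A seeded synthetic
cohort generator stands in for sequencing data, so every stage is testable
offline.

## Modules

| Module | Purpose |
| --- | --- |
| `pairedomics.io` | Strict readers/writers for MAF-like, SEG, AIRR-style, neoantigen, cluster, and catalog tables (round-trip identity on valid data) |
| `pairedomics.channels` | The fixed 96-channel substitution encoding (pyrimidine-normalized) |
| `pairedomics.simulate` | Seeded synthetic cohort generator (signature mixtures, strand bias, CNV, neoantigens, Zipf clonotypes, survival) |
| `pairedomics.signatures` | Spectrum building, multi-restart KL-NMF with stability/separation rank selection, catalog matching, NNLS exposure refitting, strand-bias test, APOBEC enrichment |
| `pairedomics.cin` | Per-bin control Z-scores, CIN score (signed and absolute modes), mean + 3·SD elevation threshold |
| `pairedomics.burden` | TMB per Mb (34 Mb default), MSI class bands, K_D ≤ 500 nM + mutant-tighter neoantigen filter, neoantigen percentages, per-cluster fractions |
| `pairedomics.clonality` | Cluster-retention rule and common/shared/private mutation classes |
| `pairedomics.tcr` | Productive filtering, Shannon diversity, CDR3 length spectra, abundance classes |
| `pairedomics.stats` | Exact Wilcoxon signed-rank/rank-sum (DP enumeration), Fisher exact, BH FDR, Kaplan–Meier + log-rank |
| `pairedomics.pipeline` | Config-driven end-to-end orchestration with deterministic report |

A 30-signature reference catalog (96-channel probability vectors, four of
them shaped for the etiologies the analyses key on) is packaged at
`pairedomics/data/reference_signatures.csv` and can be regenerated with
`python scripts/build_reference_catalog.py`.

## CLI

```bash
pairedomics simulate --seed 1 --outdir out/sim
pairedomics spectra   --mutations out/sim/mutations.tsv --outdir out/spec
pairedomics signatures --mutations out/sim/mutations.tsv --outdir out/sig
pairedomics apobec    --mutations out/sim/mutations.tsv --outdir out/apobec
pairedomics cin       --tumor-seg out/sim/segments.tsv \
                      --control-seg out/sim/control_segments.tsv --outdir out/cin
pairedomics burden    --mutations out/sim/mutations.tsv \
                      --neoantigens out/sim/neoantigens.tsv --outdir out/burden
pairedomics clonality --mutations out/sim/mutations.tsv --outdir out/clon
pairedomics tcr       --clonotypes out/sim/clonotypes.tsv --outdir out/tcr
pairedomics run       --seed 1 --outdir out/full     # end-to-end
```

Exit codes: 0 success, 2 validation error, 3 stage error. `run` accepts a
YAML/JSON config (`--config`); flags override the config, and the resolved
config is echoed into the output directory alongside a `report.json`
carrying the package version, config hash, and seed. Identical seeds give
byte-identical outputs.

## Tests

```bash
python -m pytest -q tests/
```

The suite pairs every implementation path with an independent oracle:
exact tests against brute-force enumeration, spectra against multinomial
resampling, NNLS against random-search optimality checks, plus hypothesis
property tests.

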