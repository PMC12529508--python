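# cysquant

Downstream analysis for competitive cysteine chemoproteomic screens.
Starting from a proteome FASTA and labeled-PSM tables (MS1 heavy/light
quantification of probe-labeled cysteine peptides, e.g. FragPipe-style
exports adapted through a column map), the pipeline:

1. parses PSM tables and classifies each PSM's modification state from
   its cysteine modification masses (probe-labeled vs
   carbamidomethyl-only vs unlabeled) for three built-in labeling
   chemistries (`biotin-azide`, `isoTOP-TEV`, `sCIP`);
2. maps probe-labeled peptides onto protein coordinates and renders
   residue identifiers (`ACC_C<pos>`, multi-cysteine peptides without
   localization as `ACC_C<p1>_C<p2>`);
3. computes per-site, per-condition, per-replicate log2(H/L) competition
   ratios (heavy = vehicle, light = compound; PSM ratios capped at 20,
   aggregated by median) and merges replicates (mean, sample SD,
   both-replicates requirement);
4. calls each site liganded / not-liganded / anti-liganded using the
   two-clause rule: mean log2(H/L) >= 2, with both replicates required
   to individually reach 2 when the replicate SD exceeds 2 (mirror rule
   at -2 for anti-liganded);
5. produces per-compound reactivity summaries, screen totals with
   promiscuous-compound exclusion, reference-database categorization and
   hit rates, stereoselectivity comparisons (Welch t-test on replicate
   ratios) and dose-response matrices.

A synthetic-screen generator (`cysquant.synthetic_data`) creates random
proteomes, strict-tryptic digests (cleave after K/R unless before P, up
to 2 missed cleavages, length 7–50, monoisotopic mass 500–5000 Da) and
labeled-PSM tables with planted per-site effects, log-normal abundances,
replicate noise, PSM multiplicity and missingness — so the whole
pipeline is testable without external data.

## Test

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests
(peptide location and digestion against brute-force oracles, identifier
render/parse bijection, ratio antisymmetry, aggregation invariances) and
`tests/test_acceptance.py` with the end-to-end acceptance criteria
(exhaustive calling-rule oracle, noise-free identity, parameter recovery
on a noisy synthetic screen, determinism).

## CLI

```sh
# generate a synthetic screen (FASTA + PSM TSV + ground truth)
cysquant simulate --config config.yaml --outdir sim/

# run the full analysis
cysquant run --proteome sim/proteome.fasta --psms sim/psms.tsv \
    --outdir results/ --exclude SO56,SO59

# human-readable summary
cysquant report results/
```

Example config:

```yaml
simulate:
  seed: 1
  n_proteins: 100
  conditions: [KB2, KB7, SO56, "BEH-1-Sa@100uM", "BEH-1-Ra@100uM"]
  plant_fraction: 0.1
  plant_effect: 3.0
run:
  scheme: biotin-azide
  threshold: 2.0
  sd_gate: 2.0
  excluded_compounds: [SO56, SO59]
  stereo_pair: ["BEH-1-Sa@100uM", "BEH-1-Ra@100uM"]
```

`run` writes `site_table.tsv`, `site_replicate.tsv`,
`compound_summary.tsv`, `mapping_report.tsv`, optional
`stereo_comparison.tsv` / `reference_categories.tsv` / `hit_rates.tsv` /
`dose_matrix.tsv`, and a `manifest.json` with a config hash and input
checksums.  Missing ratio cells render as `N.D.`.  Identical config and
inputs yield byte-identical reports.

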