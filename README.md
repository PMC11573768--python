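# bloomloci

Post-annotation analysis toolkit for bloom metagenome time series:

- **consensus cazyme filtering** — keep a CAZy annotation only when a
  PFAM/KEGG/COG co-annotation is carbohydrate-related, plus
  recall/precision evaluation against reference annotations;
- **copy numbers** — per-taxon, per-function, per-sample gene copy
  estimates normalized by the median coverage of a universal
  single-copy gene (USiCG) panel, and taxon read percentages;
- **profile ordination** — chi-squared distances between cazyme family
  profiles and classical (Torgerson) metric MDS with explained
  variance;
- **bloom correlation** — Spearman screening of family copy numbers
  against chlorophyll a with Benjamini–Hochberg FDR control (exact
  permutation p-values for n ≤ 8);
- **PUL detection** — susC/susD tandem finding, same-strand gap-rule
  locus extension (cazymes exempt from the gap limit), ≥3-cazyme
  calling with an opposite-strand veto, and a detection funnel report;
- **synthetic data** — a community simulator that plants known copy
  numbers, bloom-correlated families, spurious annotations and PUL
  layouts (true and decoy), emitting a ground-truth manifest used
  throughout the test suite.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(metric worked examples, oracle equivalences, decoy funnel, recovery
and calibration suites).

## CLI

Everything is reachable through the `bloomloci` command:

```sh
bloomloci demo --seed 7 --out demo_out      # end-to-end run on simulated data
bloomloci simulate --seed 3 --out sim       # orfs.tsv / coverage.tsv / samples.tsv / truth.json
bloomloci filter-cazymes --orfs sim/orfs.tsv --out filtered.tsv --log decisions.tsv
bloomloci copynum --orfs filtered.tsv --coverage sim/coverage.tsv \
    --samples sim/samples.tsv --functions funcs.txt --taxa taxa.txt --out copynum.tsv
bloomloci profiles --copynum copynum.tsv --cazy-class GH \
    --out-dist dist.tsv --out-mds mds.tsv
bloomloci correlate --copynum copynum.tsv --samples sim/samples.tsv \
    --taxon phylum=Bacteroidetes --out corr.tsv
bloomloci puls --orfs filtered.tsv --out puls.gff3 --funnel funnel.tsv --report puls.tsv
bloomloci evaluate --predicted pred.tsv --reference ref.tsv
bloomloci run --config pipeline.yaml        # config-driven pipeline; --dry-run validates
```

All tables are plain TSV (documented schemas in
`bloomloci.datamodel_io`); PUL calls are exported as GFF3. Function
identifier sets (USiCG panel, carbohydrate-related ids, susC/susD
domains, …) ship as a packaged YAML default and can be overridden with
`--function-sets`. The default USiCG panel is a ribosomal-COG stand-in
and should be replaced with your pipeline's panel.

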