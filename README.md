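# ogmrepeat

Detection and sizing of large short-tandem-repeat expansions (RFC1
AAGGG-type pentanucleotide locus, hg38 chr4:39343732-39350590) from optical
genome mapping molecule alignments.

Instead of a single platform-reported size, the tool uses every molecule
spanning the locus: it extracts per-molecule intermarker distances from
XMAP/CMAP alignments, removes outlier molecules with one-dimensional DBSCAN
(radius chosen automatically at the knee of the sorted k-nearest-neighbour
distance curve), fits one- and two-component univariate Gaussian mixtures,
and keeps the two-component model only when its BIC improves *and* both
component weights exceed 25%. Component means/SDs are converted from bp to
repeat units against the 6858 bp reference intermarker distance (motif
length 5), giving per-allele size, dispersion (a somatic-instability proxy)
and a normal/intermediate/expanded classification.

The package also ships:

- **concordance statistics**: rank-wise allele pairing, OLS regression of
  OGM sizes on Southern-blot sizes (with 95% CIs and r²), and relative
  deviations against long-read medians — the published 17-patient cohort
  tables are included as packaged CSVs;
- **a molecule-level simulator**: 1–2 Gaussian alleles (default SD 5% of
  the repeat count), uniform outlier contamination, synthetic cohorts with
  an affine gel-bias model, and a writer for minimal XMAP/CMAP fixtures
  that round-trip through the extraction path.

## CLI

```sh
# simulate a two-allele sample (repeats:sd, comma-separated), write TSV + truth
ogmrepeat simulate --alleles 664:24,730:22 --n 120 --seed 3 --out sim/

# size samples from a canonical distance table (TSV: sample_id, molecule_id, distance_bp)
ogmrepeat size --distances sim/distances.tsv --motif-length 5 \
    --locus chr4:39343732-39350590 --out sized/ --plot

# ... or straight from Bionano-style alignment files
ogmrepeat size --xmap mol.xmap --ref-cmap ref.cmap --qry-cmap mol.cmap \
    --motif-length 5 --out sized/

# cross-platform concordance on the packaged published cohort
ogmrepeat compare --out concordance/
```

Every output directory receives `manifest.json` recording the effective
configuration and seed; identical manifests reproduce byte-identical result
tables. Exit codes: 0 success, 2 usage/validation error, 1 unexpected
failure.

## Layout

```
src/ogmrepeat/
  locus_io.py     locus spec, CMAP/XMAP parsing, distance extraction, TSV I/O
  sizing.py       knee epsilon, DBSCAN filter, GMM EM, model selection, sizing
  concordance.py  allele pairing, OLS, deviations, cohort CSV I/O
  simulate.py     molecule/cohort simulators, alignment fixture writer
  cli.py          size / compare / simulate commands
  plotting.py     per-sample histogram with fitted components
  data/           published cohort and long-read tables (CSV)
```
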