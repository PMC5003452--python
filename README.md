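# probekit

Cross-species oligonucleotide array analysis at the probe level: automated
hybridisation-threshold selection for masking poorly hybridising probes,
species-specific CDF generation, and single-feature polymorphism (SFP)
screening on a four-chip genomic-DNA design (two parents + two F2 bulks).

## What it does

* **affyio** — reads text (v3) and binary (v4, little-endian) CEL files and
  text CDF files, extracts perfect-match (PM) intensities in canonical probe
  order, and writes masked CDF files in which probe pairs below a cut-off are
  removed (a probe-set is dropped only when none of its pairs survive).
* **preprocess** — exponential+normal convolution background correction
  (posterior-mean correction, strictly positive output) and quantile
  normalization with a deterministic tie rule; box-plot summaries for QC.
* **retention** — the retention curve: counts of probe pairs and probe-sets
  surviving each candidate cut-off (default grid 0..1000 step 1), computed on
  a single chip or on the elementwise-minimum "pseudo array" of several chips.
* **atm** — automated threshold mapping: project curve points onto the
  retained-set axis, cluster with fuzzy c-means (validity indices:
  Fukuyama–Sugeno and partition entropy), decode the hotspot between the
  first two clusters, and interpolate a suggested cut-off. Returns a 3-tuple:
  suggested cut-off, target interval, tolerance interval.
* **sfp** — dual fold-change screening (intensity floor + direction-consistent
  parental and bulk fold-changes), probe-wise leave-one-out t-tests on mean
  log2 ratios (between groups) and on intensity differences with
  gamma-trimmed/Winsorized robust statistics (within groups),
  Benjamini–Hochberg adjustment, volcano / twin-volcano filters, four-set
  Euler partitioning and a candidate-selection strategy.
* **synth** — seed-deterministic synthetic layouts, four-chip simulations
  with a bimodal (background vs. conserved) intensity structure and planted
  SFPs, plus text fixture files for every reader/writer.

## Command line

```sh
# synthetic four-chip experiment with 10 planted SFPs
probekit synth --sets 500 --pairs 11 --sfp 10 --seed 1 --out fixtures/

# retention curve on the pseudo min-array of the four chips
probekit retention --cdf fixtures/SynthChip.cdf \
    --cel fixtures/B1.cel --cel fixtures/B2.cel \
    --cel fixtures/B3.cel --cel fixtures/B4.cel --out curve.tsv

# suggested cut-off (JSON 3-tuple)
probekit atm --curve curve.tsv --seed 1

# species-specific masked CDF at a chosen cut-off
probekit mask --cdf fixtures/SynthChip.cdf --cel fixtures/B1.cel \
    --cel fixtures/B2.cel --cel fixtures/B3.cel --cel fixtures/B4.cel \
    --th 93.04 --out masked.cdf

# full SFP screen (records TSV + candidate list)
probekit sfp --cdf fixtures/SynthChip.cdf --cel fixtures/B1.cel \
    --cel fixtures/B2.cel --cel fixtures/B3.cel --cel fixtures/B4.cel \
    --no-norm --th 93.04 --out records.tsv --candidates candidates.tsv
```

`probekit --config defaults.txt <cmd> ...` reads `key=value` lines as option
defaults; explicit flags win. All subcommands are deterministic given
`--seed`.

## Notes

* Command Console (AGCC) CEL files and binary CDF files are not supported.
* MM probes are parsed and stored, but all analysis uses PM intensities only
  (an `include_mm` option exists on extraction).
* The screening examples above pass `--no-norm`: quantile normalization
  assumes identical chip distributions, which planted genotype differences
  violate in the upper tail; background correction alone is the default
  recommendation for gDNA screens.
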