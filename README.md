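# robustsig

Transcriptome–robustness phenotype matching for *Lactococcus lactis*-style
fermentation studies: from CFU-based stress-survival phenotypes and gene
expression matrices to per-strain robustness gene signatures and a
cross-strain generic signature over orthologous groups.

The package covers the full analysis chain plus seeded generators for every
input, so the pipeline is fully testable without any external data:

- **`robustsig.simulate`** — the fixed 13-fermentation factorial design
  (salt, initial pH, temperature, oxygen, run over two days), robustness
  phenotypes with paired technical-duplicate Poisson CFU counts, 2-log
  expression matrices with a planted linear robustness signal, probe-level
  two-color intensities under a two-loop hybridization design with
  intensity-dependent dye bias, and orthologous-group maps.
- **`robustsig.phenotype`** — growth-rate estimation (sliding log-linear
  windows), survival/log10-reduction arithmetic from CFU duplicates,
  dynamic ranges, assay-timepoint selection (largest dynamic range),
  Pearson correlations, and Welch t-tests per fermentation parameter.
- **`robustsig.preprocess`** — MA transform, per-array lowess dye-bias
  correction with median-centering, least-squares placement of loop-design
  samples on one relative log2 scale (zero-sum gauge), and per-ORF probe
  medians.
- **`robustsig.association`** — vectorised per-gene OLS of expression on
  robustness (two-sided slope P, n−2 df), dual-timepoint signature
  selection (P < 0.05 at both timepoints, consistent direction, ranked by
  the P-value product, flagged below 5×10⁻⁵), and parameter-wise
  differential expression with pairwise overlaps.
- **`robustsig.generic`** — cross-strain ranking of orthologous groups
  whose members associate with robustness in every strain (P < 0.2, shared
  direction), ranked on the average per-strain P-value.
- **`robustsig.cli` / `robustsig.pipeline`** — a `robustsig` command-line
  driver binding the stages into an end-to-end, seed-deterministic TSV
  pipeline.

A three-strain phenotype reference table (13 fermentations; growth and
percent survival per stress) ships in `robustsig/data/` and backs the
desk-scale statistics.

## Command-line usage

```sh
# full synthetic run: simulate -> preprocess -> associate -> generic
robustsig all --seed 7 --out-dir out/

# phenotype statistics on the packaged reference tables
robustsig phenotype --packaged --out-dir out/

# individual stages reuse the TSVs in the output directory
robustsig simulate --seed 7 --out-dir out/ --n-genes 1000
robustsig preprocess --out-dir out/ --config out/config.txt
robustsig associate --out-dir out/ --config out/config.txt
robustsig generic --out-dir out/ --config out/config.txt
```

All outputs are plain TSV with `# key=value` header metadata; logging goes
to stderr. Thresholds (`--alpha`, `--product-threshold`,
`--generic-p-threshold`, `--top-k`, `--lowess-span`) can be overridden on
the command line or in a flat `key = value` config file.

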