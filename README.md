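# shaperate

Rates of multivariate shape evolution on time-calibrated phylogenies:
generalized Procrustes analysis of 2-D landmark data, multivariate
Brownian-motion rate estimation, clade and module rate-ratio tests with
simulation nulls, and phylomorphospace projection — plus a known-truth
synthetic-data generator so the whole pipeline is testable without any
external data.

## What it does

Given an ultrametric chronogram (newick, branch lengths in Myr), a TPS file of
landmark configurations, a specimen→species map, and a species→clade map, the
pipeline:

1. parses and superimposes all specimens (full Procrustes: translation, unit
   centroid size, rotations only);
2. averages aligned coordinates per species and prunes the tree to the
   matched taxa (reporting a census of unmatched names);
3. estimates the net multivariate rate σ²_mult per clade — the mean squared
   phylogenetically whitened distance from the GLS phylogenetic mean, per
   trait dimension — and tests the clade rate ratio against a Brownian
   simulation null (p = (1+b)/(1+nsim));
4. runs the two-step module analysis: do named landmark modules (default
   head = LM 1–8, 15–18; trunk = LM 9–14) evolve at different rates tree-wide
   (R_mult), and does the clade ratio hold within each module;
5. projects tips, BM ancestral states, and tree edges into PC1–PC2
   (phylomorphospace), exporting plot data as CSV/JSON.

The simulation null draws tip data under a single common rate; by default the
pooled trait covariance of the whitened residuals is preserved (safe —
conservative rather than anticonservative when traits are correlated, which
Procrustes coordinates always are), with `isotropic_null: true` available as
the exact-under-isotropy alternative.

## CLI

```sh
# write a deterministic synthetic study (tree.nwk, specimens.tps, maps, truth.json)
shaperate simulate tiny-6taxa --out data/
# or: shaperate simulate paper-scale-44taxa --out data/

cat > config.yaml <<EOF
tree: data/tree.nwk
tps: data/specimens.tps
species_map: data/species_map.csv
group_map: data/groups.csv
output_dir: out
nsim: 9999
seed: 1
EOF

shaperate validate config.yaml     # input census (matched/unmatched taxa)
shaperate run config.yaml          # full analysis -> out/report.json + CSVs
shaperate report out/report.json   # pretty-print the rate table
```

`run` accepts `--nsim/--seed/--output-dir` overrides. Reports contain no
timestamps: the same config and seed give byte-identical output. Exit codes:
2 config error, 3 data error, 4 numerical error.

## Library sketch

```python
import shaperate as sr

tree, groups = sr.generate_chronogram(40, 4, root_age=18.02, seed=1)
configs = sr.read_tps("data/specimens.tps")
gpa = sr.align_gpa(configs)
Y = sr.species_means(gpa, species_map).reorder(tree.tip_labels)
result = sr.rate_ratio_test(Y, tree, groups, nsim=9999, seed=1)
mod = sr.modularity_rate_test(Y, tree, sr.DEFAULT_PARTITION, nsim=9999, seed=2)
space = sr.phylomorphospace(tree, Y)
```

## Layout

```
src/shaperate/
  trees.py        newick chronograms, pruning, phylogenetic covariance
  landmarks.py    TPS I/O, generalized Procrustes analysis, species means
  rates.py        sigma2_mult estimation, BM simulation, clade ratio test
  modularity.py   module partitions, R_mult test, within-module clade tests
  morphospace.py  PCA, BM ancestral states, phylomorphospace exports
  synthetic.py    known-truth study generator (chronogram + TPS + maps)
  pipeline.py     config-driven orchestration, input census, report writer
  cli.py          click CLI: simulate / validate / run / report
```
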