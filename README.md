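# hotregions

Calling and characterising **high-occupancy target (HOT) regions** —
genomic windows bound by an unusually large fraction of the profiled
ChIP-seq transcription factors — with tools to ask whether that apparent
occupancy has a sequence and chromatin basis.

## Background

When peak calls from hundreds of ChIP-seq experiments are pooled, a small
set of loci recurs in a large fraction of them. These HOT regions look like
promiscuous binding platforms, but much of the signal can be explained
without direct sequence-specific binding: HOT regions are GC- and CpG-rich
(they coincide with the densest promoter CpG islands), they show elevated
signal even in control experiments (a hallmark of "hyper-ChIPable" or
phantom-peak artefacts), and their DNA methylation is unusually static
across cell types compared with other CpG islands. This package implements
that analysis chain end to end:

1. **Region calling** — pool peak summits over experiments, count them in
   500 bp sliding windows (50 bp step), keep non-maximum-suppressed local
   maxima, rank by summit count and label the strict top percentile HOT
   (`hotregions.calling`).
2. **Sequence features** — 339 features per region (2/3/4-mer frequencies,
   GC content, CpG observed/expected, GC skew) on 2 kb midpoint-centred
   windows (`hotregions.features`, scikit-learn-style `SequenceFeaturizer`).
3. **Discrimination model** — elastic-net logistic regression (glmnet-style
   λ path, 10-fold CV) separating HOT regions from occupancy- or
   CpG-matched controls, with cross-validated AUC and variable importance
   (`hotregions.model`, scikit-learn-style `HotRegionClassifier`).
4. **Signal enrichment** — log2(IP/control) CPM ratios per region, per-bp
   tracks, and winsorized 50-bin profile heatmap matrices stratified by
   occupancy percentile (`hotregions.enrichment`).
5. **Methylation dynamics** — across-cell-type dispersion (IQR) of region
   methylation, comparing HOT regions against non-HOT CpG islands
   (`hotregions.methylation`).
6. **Synthetic data** — seeded generators that plant known HOT loci,
   enriched k-mers, a known log2 fold change and known methylation
   dispersion, and emit standard file formats (FASTA, narrowPeak, BED,
   per-CpG tables) plus a machine-readable `truth.json`
   (`hotregions.simulate`).
7. **Pipeline + CLI** — a YAML-configured pipeline that runs whichever
   stages have inputs and writes a SHA-256 manifest for reproducibility
   (`hotregions.pipeline`, `hotregions` console command).

See [docs/methods.md](docs/methods.md) for the precise models, parameters
and numerical conventions.

## Worked example

Simulate a small two-chromosome study and run the full analysis. This is
a real, reproducible run (seeds fixed):

```python
import pandas as pd
from hotregions import pipeline
from hotregions.simulate import BundleParams, make_bundle

# 1. simulate a small study: 2 chromosomes x 1 Mb, 60 ChIP-seq experiments
make_bundle(
    "bundle", seed=11,
    params=BundleParams(n_chroms=2, n_hot_loci=16, n_cgi_loci=60, n_experiments=60),
)

# 2. run the full analysis (the synthetic genome is megabase scale,
#    so the caller uses the non-human 1000 bp suppression span)
cfg = pipeline.load_config(None, {
    "outdir": "out",
    "caller": {"suppression_span": 1000},
    "paths": {
        "peak_dir": "bundle/peaks",
        "chrom_sizes": "bundle/chrom.sizes",
        "genome": "bundle/genome.fa",
        "cgi": "bundle/cgi.bed",
        "ip_reads": "bundle/ip.bed",
        "control_reads": "bundle/control.bed",
        "methylation_dir": "bundle/methylation",
    },
    "model": {"seed": 5}, "enrichment": {"seed": 9},
})
status, manifest = pipeline.run(cfg)

regions = pd.read_csv("out/regions.tsv", sep="\t")
print(regions[regions.label == "HOT"].head(3).to_string(index=False))
print("HOT regions:", (regions.label == "HOT").sum(), "of", len(regions))
```

Output:

```
2026-10-02 05:14:09,400 INFO called 1414 regions (15 HOT) from 60 experiments
2026-10-02 05:14:13,185 INFO model: cv_auc=1.000 lambda=0.0009584
2026-10-02 05:14:17,305 INFO stratified sampling shortfalls: {'0-75': 1824, '75-99': 2777, '99-100': 2985}
2026-10-02 05:14:17,410 INFO methylation IQR ratio (nonHOT CGI / HOT): 4.04
chrom  start    end  occupancy  percentile label
 chr1  81150  81650         36   99.363508   HOT
 chr1 102950 103450         36   99.363508   HOT
 chr1 427050 427550         40   99.752475   HOT
HOT regions: 15 of 1414
```

The output directory contains `regions.bed`/`regions.tsv` (called regions
with occupancy, percentile and HOT/MILD/COLD label), `features.tsv`,
`model.json` + `importance.tsv` + `pca.tsv`, `enrichment.tsv` +
`profile_matrix.tsv` + `stratum_summary.tsv`, `methylation_*.tsv` +
`methylation_summary.json`, and `manifest.json` with a SHA-256 checksum of
every output — two runs from the same seeds produce identical checksums.

The same pipeline runs from the command line:

```bash
hotregions simulate --outdir demo --seed 7        # writes demo/bundle + run config
hotregions run --config demo/run_config.json      # runs every stage
hotregions call --config my_study.yaml            # or stage by stage
```

On real data, point `paths.peak_dir` at a directory of narrowPeak files,
`paths.genome` at an indexed FASTA, `paths.ip_reads`/`control_reads` at
BED-format reads, and `paths.methylation_dir` at per-cell-type CpG
methylation tables (`chrom  pos  fraction`). For human-scale genomes keep
the default `suppression_span: 2000`.

## Layout

```
src/hotregions/     calling, features, model, enrichment, methylation,
                    simulate, intervals, io, pipeline, cli
tests/              unit + property tests; tests/test_acceptance.py holds
                    one test per acceptance criterion
scripts/acceptance.py   end-to-end seeded acceptance run
docs/methods.md     models, parameters, numerical choices, limitations
```
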