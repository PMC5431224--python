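# toxpipe

Headless toxicogenomics expression analysis. Starting from a normalized
probes × samples intensity matrix plus a sample metadata table (compound,
dose level, exposure time, organ, species, platform, test type, matched
control group), toxpipe provides:

- **core_data** — median normalization per sample, fold changes against
  matched control-group means (stored pre-log), and group tables using the
  mean-then-log2 convention (`log2(mean(folds))`, never the mean of logs).
- **genesets** — four inclusive column filter types (upper / upper-abs /
  lower / lower-abs, AND-combined), Welch's t and Mann-Whitney U test
  columns, the "fold ≤ ratio at every time point" consistency rule, and
  gene-set algebra with provenance tracking.
- **clustering** — agglomerative hierarchical clustering (ward_d2 /
  average / complete / single; Pearson or Euclidean distance) with a
  deterministic tie-break, dendrogram cutoff partitioning into
  `cluster1..K`, and a hard 1000-gene-row size limit.
- **enrichment** — one-sided hypergeometric over-representation against
  GMT collections with BH/Holm adjustment, plus the "single most enriched
  feature per cluster" summary (raw p).
- **ranking** — compound ranking by mean signed log2 fold over a query
  gene set across scoped conditions (total up/downregulation modes,
  pluggable scorer).
- **ortho** — cross-species ortholog probe-set rows as a median of
  per-group averages.
- **simulate** — a synthetic dataset generator (log-normal intensities,
  planted effect blocks, matched controls, mandatory seed) with ground
  truth for end-to-end testing, plus planted-enrichment GMT collections.
- **pipeline / CLI** — a declarative YAML pipeline chaining the stages,
  writing every intermediate gene set, partition, enrichment table and
  ranking; reruns are byte-identical for a fixed seed.

## CLI

```sh
toxpipe simulate --scenario three_cluster --seed 1 \
    --out-metadata meta.tsv --out-data data.tsv --out-truth truth.json
toxpipe groups --metadata meta.tsv --data data.tsv \
    --group "M4=compound_A/Middle/4 day" --group "M8=compound_A/Middle/8 day" \
    --out groups.csv
toxpipe filter --table groups.csv --column M4 --kind lower_abs \
    --threshold 1.5 --out degs.txt
toxpipe cluster --table groups.csv --method ward_d2 --distance pearson \
    --cutoff 4 --out-prefix clusters
toxpipe enrich --gene-set degs.txt --universe universe.txt \
    --collection pathways.gmt --out enrichment.tsv
toxpipe rank --metadata meta.tsv --data data.tsv --gene-set degs.txt \
    --mode total_downregulation --out ranking.tsv
toxpipe pipeline --config pipeline.yaml
```

See `toxpipe <command> --help` for all options, and the docstring of
`toxpipe.pipeline` for the YAML pipeline schema.

## File formats

- expression matrix: TSV, first column `probe_id`, header row of sample IDs
- metadata: TSV with columns `sample_id, compound, dose_level,
  exposure_time, organ, species, platform, test_type, control_group`
- gene sets: one ID per line, optional `# name:` / `# provenance:` headers
- collections: standard GMT (name, description, members per line)
- ortholog maps: TSV `set_id, platform, probe_id`
- cluster partitions: TSV `probe_id, cluster_id` + JSON sidecar with the
  full merge list at double precision

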