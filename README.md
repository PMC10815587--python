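# spatialcontact

Analysis pipeline for bait-anchored 4C-seq spatial genomics of
irradiated glioblastoma cells: contact-domain calling from
per-HindIII-site read counts, differential expression and kinetic
clustering over an irradiation dose/time course, and integration of the
called domains with gene density, expression clusters and γH2AX ChIP
IP/input repair signal. A synthetic-data module emulates every input at
desk scale (2 × 20 Mb genome, seconds per run), so the full pipeline is
testable offline.

## Modules

| Module | Purpose |
| --- | --- |
| `spatialcontact.fragment_map` | In-silico HindIII digestion (`AAGCTT`), fragment/cut-site grid, BED I/O |
| `spatialcontact.synthetic_data` | Seeded generators: 4C counts with distance decay + planted domains, genes, five-condition expression course, binned ChIP tracks |
| `spatialcontact.fourc_domains` | Windowed enrichment p scores, percentile thresholding, run-length domain calling, resampling-calibrated FDR |
| `spatialcontact.expression` | CPM, moderated DE test (FDR < 0.05, \|logFC\| > 0.5), k-means kinetic clustering with canonical labels |
| `spatialcontact.spatial_integration` | Gene density (genes/Mb), cluster enrichment per bait, ChIP IP/input ratios over domain unions |
| `spatialcontact.cli` / `pipeline` | `spatialcontact` CLI, YAML config, end-to-end driver with reproducible manifests |

## Domain caller

Every cut site gets a p score (−log10 of an upper-tail binomial
p-value) from the read count in a 100 kb running window centered on it.
Sites in the top 10% (cis) / 5% (trans) of scores are flagged positive
and maximal runs of more than 15 consecutive positive sites become
domains. Two additions keep the procedure calibrated against the
strongly decaying cis background:

- the expected window share is fitted from the profile itself (binned
  median of log window sum vs log bait distance) instead of a uniform
  share, and a bait-proximal exclusion zone (default ±1 Mb) is masked;
- candidate domains are gated on a score threshold calibrated by
  stratified bootstrap resampling of the counts, and the achieved
  empirical FDR is reported with every domain set.

On the default synthetic scenario (fold-5, 30-site planted domains)
this recovers domains with sensitivity and precision ≥ 0.9 at an
achieved FDR < 0.04, while calling nothing on domain-free profiles.

## CLI

```sh
# full synthetic pipeline into one directory
spatialcontact run --seed 1 --outdir out/

# individual stages on files
spatialcontact digest --fasta genome.fa --out fragments.bed
spatialcontact synth --outdir inputs/ --seed 1
spatialcontact domains --counts inputs/counts_0h.tsv \
    --fragments inputs/fragments.bed --bait chr1:10000000 \
    --top-frac-cis 0.10 --top-frac-trans 0.05 --min-run 16 \
    --fdr-permutations 40 --seed 1 --out-prefix out/domains_0h
spatialcontact expression --counts inputs/expression_counts.tsv \
    --samples inputs/samples.tsv --alpha 0.05 --lfc 0.5 --k 4 \
    --seed 1 --out-prefix out/expr
spatialcontact integrate --domains out/domains_0h.bed \
    --genes inputs/genes.tsv --clusters out/expr.clusters.tsv \
    --chrom-sizes inputs/chrom.sizes \
    --chip-ip 0h=inputs/chip_ip_0h.bedGraph \
    --chip-input 0h=inputs/chip_input_0h.bedGraph \
    --out-prefix out/integration
```

Every run writes a `manifest.json` with the config, a config hash and
sha256 checksums of all outputs; re-running with the same config and
seed reproduces the checksums exactly.

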