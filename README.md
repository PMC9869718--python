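# trendtide

Headless pairwise trend comparison of gene-based quantitative omics
datasets (e.g. transcriptome vs proteome, or two strains within one layer).

Given two abundance matrices (genes × ordered conditions, pre-normalized
units such as FPKM or log2-LFQ) sharing condition columns and a partially
overlapping gene universe, trendtide:

1. computes per-gene variance / median-abundance statistics and optional
   percentile-range pre-filters on the raw values;
2. z-scores each gene's profile per dataset;
3. splits genes into intersecting (present in both datasets) and
   non-intersecting sets; stacks the intersecting genes' two profiles into
   one matrix (early integration) and clusters it with k-means++, so each
   gene gets two trend labels in one shared label space — equal labels mean
   a **concordant** trend, unequal a **discordant** one; non-intersecting
   genes are clustered separately per dataset;
4. builds a Sankey model — nodes are (dataset, trend) gene sets, links are
   (trend_a, trend_b) intersections, at most k² links — with dynamic
   variance/abundance/link-size filters, gene-ID highlighting and node/link
   selection;
5. runs local GO enrichment on selected gene subsets (two-sided Fisher's
   exact test, Benjamini–Hochberg FDR per GO category) against a GMT or
   two-column annotation file;
6. renders static figures: centroid/profile/box trend plots, Sankey,
   overview stacked bars and enrichment bars (PNG/PDF/SVG).

A synthetic-data module generates paired datasets with planted trend
shapes, controllable concordant fraction, noise and non-intersecting
fractions, so the whole pipeline is testable without external data.

## CLI

```sh
# generate a planted synthetic pair
trendtide simulate --n-trends 4 --genes-per-cell 20 --noise-sd 0.2 --seed 1 -o simdir/

# step 1: cluster + compare all pairs into a session directory
trendtide compare --data simdir/dataset_A.tsv --data simdir/dataset_B.tsv \
    --k 4 --seed 1 --out session/

# step 2: first-level analysis — dynamic filters, highlighting, figures
trendtide firstlevel --session session/ --pair dataset_A:dataset_B \
    --filter-metric median --filter-lo 80 --filter-hi 100 \
    --highlight genes_of_interest.txt --out firstlevel/

# step 3: second-level analysis — subset extraction + GO enrichment
trendtide secondlevel --session session/ --pair dataset_A:dataset_B \
    --pick link:0:0 --pick node:dataset_A:2 \
    --annotation go.gmt --background first-level --out secondlevel/

# re-render any stored model
trendtide plot sankey --session session/ --pair dataset_A:dataset_B -o sankey.pdf
```

Abundance input is delimited text (tab or comma auto-detected): header row
of condition names, first column gene IDs, numeric cells; genes with
missing cells are dropped and reported. Picks use `node:<dataset>:<trend>`
and `link:<trend_a>:<trend_b>` identifiers. All tabular outputs are
CSV/JSON with pinned float formatting, so a session re-run from the same
inputs and seed is byte-identical.

A custom pre-clustered comparison can be supplied instead of internal
clustering as a long-format file with columns
`gene, dataset, condition, value, cluster` (see
`trendtide.io.read_custom_clustering`).

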