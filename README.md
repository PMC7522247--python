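# svhotspots

Detection of genomic **structural-variant (SV) hotspots** in cancer cohorts
and evaluation of their association with the expression of nearby genes.

Somatic structural variants — deletions (DEL), tandem duplications (DUP),
insertions (INS), inversions (INV), and translocations (BND) — can drive
tumors not only by disrupting genes but by rewiring regulatory elements, as
with recurrent tandem duplication of enhancer regions upstream of oncogenes.
`svhotspots` is for cancer genomics analysts with cohort-level WGS SV calls
(BEDPE), RNA-seq expression (TPM), and copy-number segments, who want to know
*which loci are recurrently hit across patients, and whether those hits move
the expression of nearby genes*.

## Method

**1. Detection.** Each chromosome is tiled with overlapping sliding windows
(width *w* = 100 kb, step *s* = 30 kb). For each window the pipeline counts
the number of distinct samples harboring an SV that targets it: the entire
event region for DUP/DEL (these change the copy number of everything they
contain), only the breakend positions for INS/INV/BND. A window is a
**candidate peak** when its (moving-average-smoothed) count exceeds the
robust local background of its 2*m* flanking windows,

> count ≥ median + *stdlim* · max(1.4826 · MAD, 1),   (*m* = 10, *stdlim* = 3)

and its raw count reaches a recurrence threshold *t* (default 15% of
SV-harboring samples). Adjacent candidates within distance *d* = 50 kb are
clustered; within a cluster the top peak (highest sample count) absorbs
neighbors in both directions whose counts differ relatively by less than
*delta* = 5%, stopping a direction after *k* = 1 dissimilar peaks, repeated
until the cluster is exhausted. Merged, disjoint intervals are the final
**hotspots**.

**2. Annotation.** Hotspots are annotated with overlapping regulatory
elements and with genes overlapping or within 1 Mb (configurable) of either
edge.

**3. Association.** For each (hotspot, nearby gene) pair, gene expression is
compared between samples with and without hotspot SVs — overall, per SV
type, and each again restricted to samples copy-neutral for the gene —
twelve two-sided Wilcoxon rank-sum (or Welch *t*) comparisons. Defined
p-values are combined by Fisher's method, X² = −2 Σ ln pᵢ ~ χ²(2k), and
Benjamini–Hochberg FDR is applied across all pairs. Hotspots associated with
the same gene whose sample sets overlap significantly (one-sided Fisher's
exact test) are grouped into **peak families** represented by the
highest-count member.

**4. Reporting.** Pairs are retained when the peak is < 500 kb (unless the
gene is on a supplied cancer-census list), recurs in ≥ 15% of SV samples,
reaches FDR < 0.05, has ≥ 1 individually significant comparison (p < 0.05),
and a group mean > 10 TPM in a significant comparison. Outputs: ranked
report TSV, peaks BED, per-chromosome UCSC custom tracks, BedGraph count
tracks, region/expression/genome figures.

## Worked example

The package ships a synthetic-cohort generator with known ground truth. The
built-in benchmark implants a 120-kb DUP hotspot (40% penetrance) on a 6-Mb
chromosome, with a +2 SD expression effect on a gene 300 kb downstream, over
a uniform background of 0.03 SVs/sample/Mb:

```bash
svhotspots simulate --seed 7 --out fixture
# cohort with 63 SVs written to fixture

svhotspots run --sv fixture/svs.bedpe --chrom-sizes fixture/chrom.sizes \
    --genes fixture/genes.bed --elements fixture/elements.bed \
    --cn fixture/cn_segments.tsv --expr fixture/expression.tsv --out out
# 1 hotspot(s), 1 retained peak-gene pair(s); report in out/final_report.tsv
```

`out/final_report.tsv`:

```
rank  peak_id                    chrom  start    end      length  n_samples  pct_samples  gene    combined_p  fdr       direction
1     peak_chr1_2910000_3190000  chr1   2910000  3190000  280000  41         0.745        GENE_T  1.67e-48    3.34e-48  up
```

The single reported hotspot (window-aligned, 280 kb) covers the implanted
interval chr1:3,000,000–3,120,000; 41 of the 55 SV-harboring samples hit it
(the 40 implanted plus background), and the linked gene GENE_T is
upregulated in carriers at FDR ≈ 3 × 10⁻⁴⁸. A bystander gene reaching
combined p = 0.029 is correctly dropped because none of its twelve
individual comparisons is significant at p < 0.05.

Every number is configurable by flag or YAML (`--window-size`, `--step-size`,
`--merge-distance`, `--k`, `--delta`, `--min-pct-samples`, `--max-fdr`,
`--min-tpm`, `--test-method`, ...); flags override the config file.

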