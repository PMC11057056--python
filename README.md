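# sawselect

Comparative-genomic analysis of lineage-specific adaptation in the
smalltooth sawfish (*Pristis pectinata*), rebuilt as a reusable, tested
pipeline and validated end-to-end on simulated codon evolution.

The package is aimed at molecular evolution researchers who want the full
chain — orthogroup curation, branch-specific episodic positive-selection
testing, biochemical divergence profiling, clustering of positively
selected genes (PSGs), and electrosensory-channel characterization — as
importable, unit-tested components rather than a stack of one-off scripts
around external tools.  Because the original study's sequencing data and
heavyweight externals (assembler, aligners, orthology inference) are out of
scope, every stage is driven by a synthetic-data module that generates all
inputs with known ground truth, so the whole pipeline is verifiable on one
CPU with no downloads.

## The statistical core

Genes are tested for **episodic positive selection** on individual branches
of the five-taxon chordate phylogeny (coelacanth, ghostshark, catshark,
little skate, sawfish).  Codon evolution follows a GY94-type model: only
single-nucleotide codon changes are allowed, transitions are scaled by κ,
non-synonymous changes by ω = dN/dS, and each branch's generator is
normalized to unit mean rate so branch lengths are expected substitutions
per codon.  On the branch under test, each site independently belongs to a
conserved class (ω₁ ≤ 1) or an unconstrained class (ω₂ ≤ 10⁴) with free
mixture weight — a fixed two-class simplification of the adaptive
branch-site random-effects framework.  The null model constrains ω₂ ≤ 1,
and

&nbsp;&nbsp;&nbsp;&nbsp;LRT = 2(ℓ̂_alt − ℓ̂_null)  ∼  ½χ²₁ + ½χ²₂

gives the per-branch p-value.  P-values are Holm–Bonferroni corrected
across genes per branch, and a gene is called a PSG when its sawfish-branch
corrected p ≤ 0.05 while no other terminal branch is significant
("uniquely under selection").  Likelihoods are computed by Felsenstein
pruning with one symmetric eigendecomposition per (κ, ω), which keeps a
whole-gene fit under a second.

Downstream, each PSG is summarized by (ω₂, % sites under selection,
ΔGRAVY vs. the little-skate ortholog), clustered by k-means in
standardized feature space, and cluster membership is tested for
annotation-term enrichment with a hypergeometric test.  Electrosensory
channel characterization covers exact Smith–Waterman ortholog search,
K⁺-channel selectivity-filter (T-x-G-Y-G) motif verification, FPKM
expression, and splice-junction-based exon-retention calls.

## Worked example

The numbered drivers under `analysis/` run the pipeline on the synthetic
dataset (results land under `results/pipeline/`).  With the default seed,
8 genes are simulated, the first two with episodic selection planted on the
sawfish branch (ω₂ = 9 on 30 % of sites, 200 codons):

```text
$ python analysis/04_selection_scan.py
8 genes x 5 branches tested

focal-branch results:
gene_id       lrt   p_value  corrected_p  omega2  weight2
gene000     6.192   0.02903       0.2032   12.05  0.08678
gene001     15.33 0.0002796     0.002237     8.4   0.2848
gene002         0         1            1  0.4317   0.6243
...
PSGs called (uniquely selected in P_pectinata): ['gene001']
planted selected genes: ['gene000', 'gene001']
true positives 1, false positives 0, misses 1
```

`gene001` is recovered with ω₂ ≈ 8.4 on ≈ 28 % of sites, close to the
planted values; `gene000`'s raw p of 0.029 does not survive the Holm
correction at this short alignment length — short alignments genuinely cost
power, and the run report says so rather than hiding it.  The other drivers
print coverage reconciliation (`02`), orthogroup curation tallies (`03`),
GRAVY shifts (`05`), PSG clustering and enrichment (`06`), and the
electrosensory panel — pore motifs, FPKM, and an 11-vs-3 junction-read
split giving an exon-inclusion fraction of 0.79 (`07`).

The same flow is available as a CLI (`sawselect demo`, `sawselect selscan`,
`sawselect run --config run.yaml`), with stage outputs cached by checksum.

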