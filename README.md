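# accelscan

Lineage-specific accelerated-region (AR) detection on conserved genomic
elements. The pipeline tiles conserved elements into fixed-width (default
50 bp) fragments, tests each fragment for an accelerated substitution rate
on a designated branch or subtree with a constrained phylogenetic
likelihood-ratio test, converts the statistics to empirical p-values by
parametric simulation from the neutral model, calls ARs by
Benjamini–Hochberg FDR, maps them to genes within a ±10 kb flank of each
gene's coding span, and tests gene lists for a distribution shift of
element q-values against the genome-wide background (one-sided unpaired
Welch t-test). A seeded synthetic-data module generates a complete
miniature study (tree, neutral model, MAF alignment, conserved elements,
gene models, gene lists, truth table) so the whole analysis runs at desk
scale.

## Layout

| module | role |
| --- | --- |
| `accelscan.phylo` | trees, REV nucleotide models, Felsenstein pruning likelihoods with global (`s`) and subtree (`rho`) branch scaling, column simulation |
| `accelscan.io` | phast `.mod`, MAF, BED, BED12/GFF3 gene models, gene lists, results TSV |
| `accelscan.elements` | tiling of conserved elements into fixed-width fragments; per-tile alignment attachment with a minimum-species filter |
| `accelscan.accel` | null/alternative fits, stratified simulation nulls, empirical p-values, BH FDR, AR/candidate calling |
| `accelscan.genemap` | element→gene assignment within a flank, unique-gene summaries, cross-run overlap |
| `accelscan.enrichment` | gene-list FDR-shift (Welch) tests |
| `accelscan.synth` | scenario generator with planted acceleration and an enriched gene list |
| `accelscan.cli` | `accelscan` command with `simulate / split / test / fdr / annotate / enrich / run-all / validate` subcommands |

The test statistic is one-sided by construction: both hypotheses fit a free
global scale `s ∈ [1e-3, 100]`; the alternative additionally fits
`rho ∈ [1, 100]` multiplying the branch lengths of the target subtree, so
`LRT = 2(lnL_alt − lnL_null) ≥ 0` with an atom at 0. Null distributions
are shared per (species-presence set, element length) stratum, and
empirical p-values use add-one smoothing: `p = (1 + #{sim ≥ obs})/(n+1)`.

## CLI

Run the complete miniature study (synthesize + scan + call + annotate +
enrich; writes `results.tsv`, `ars.bed`, `candidates.bed`, `ar_genes.tsv`,
`enrichment.tsv`, and a reproducibility `manifest.json`):

```sh
accelscan run-all --seed 1 --nsims 5000 --out runs/demo
```

Stage by stage on your own inputs:

```sh
accelscan split    --bed conserved.bed --width 50 --out tiles.bed
accelscan test     --mod neutral.mod --maf aln.maf --bed conserved.bed \
                   --branches leaf --nsims 100000 --seed 1 --out results.tsv
accelscan fdr      --results results.tsv --q-call 0.05 --q-candidate 0.1 --out calls/
accelscan annotate --bed calls/ars.bed --genes genes.bed12 --flank 10000 --out ar_genes.tsv
accelscan enrich   --results calls/results.tsv --genes genes.bed12 \
                   --gene-list lists/listA.txt --out enrichment.tsv
accelscan validate --mod neutral.mod --maf aln.maf
```

Defaults mirror the published analysis parameters (50 bp tiles, 100,000
simulations, ±10 kb flank, AR call at q < 0.05, candidates at q < 0.1);
desk-scale runs override `--nsims`.

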