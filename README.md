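# genosig

Alignment-free comparative genomics from **genome signatures**: the
species-specific oligonucleotide composition that is observable in almost
every fixed-size fragment of a genome. `genosig` fragments multi-FASTA
assemblies into 1-Mb or 100-kb windows, computes degenerate
(strand-merged) k-mer composition vectors, clusters them with a
batch-learning self-organizing map (BLSOM), and follows up with
composition statistics and chromosomal window scans. It is aimed at
comparative genomicists who want to separate and characterize genomes —
including incompletely assembled, scaffold-level ones — without alignment
or annotation.

## What it computes

**Degenerate k-mer composition.** Deposited assemblies carry an arbitrary
strand, so each k-mer is merged with its reverse complement into one class
(written `GA+TC`; self-complementary k-mers such as `CG` stand alone).
For width *k* there are `4^k / 2` classes when *k* is odd and
`(4^k + 4^(k/2)) / 2` when even: 10 (di), 32 (tri), 136 (tetra),
512 (penta). A fragment's
vector is the percentage of overlapping width-*k* windows in each class;
windows containing `N` are excluded. Scaffolds shorter than the analysis
window are concatenated with a single `N` separator, which is exactly
equivalent to counting the scaffolds separately.

**BLSOM.** A batch-variant self-organizing map whose result is independent
of the input order. The lattice is initialized on the plane of the first
two principal components: node (i, j) of an I×J lattice starts at

    w(i,j) = mean + pc1 · 5σ₁ · (i/(I−1) − ½) + pc2 · 5σ₂ · (j/(J−1) − ½)

with I/J following σ₁/σ₂ and I·J ≈ N/10 (ten fragments per node on
average). Each epoch assigns every fragment to its best-matching node
(smallest Euclidean distance) and replaces each node's weight with a
neighborhood-weighted mean under a shrinking truncated-Gaussian kernel.
Diagnostics reproduce the standard map readouts: **territory maps**
(nodes colored by the single species/lineage/chromosome of their
occupants, black when mixed, blank when vacant), the **U-matrix** (mean
distance to 8-neighbor weights — high values trace cluster boundaries),
per-oligonucleotide **21-division heatmaps**, and **special-zone
candidates** — satellite single-category territories separated from the
main territory by high-U boundaries.

**Statistics and scans.** G+C%, dinucleotide percentages, the CG/GC
ratio, the CG odds ratio (observed CG window frequency over p_C·p_G from
the fragment's own mononucleotide composition; < 1 means CG deficiency),
Tukey box-plot summaries with 1.5·IQR whiskers, per-chromosome frequency
tracks for any degenerate class, motif-occurrence tracks for user-supplied
fixed-length motif sets, and robust-z (median/MAD) peak flagging.

**Synthetic communities.** Because multi-Gb assemblies are impractical for
testing, `genosig.simulate` generates labeled multi-species communities
from calibrated order-1 Markov chains: exact target G+C%, tunable
dinucleotide odds ratios, scaffold-split species, and terminal zones
enriched for a chosen class (e.g. GA+TC, emulating pericentromeric
sequence of acrocentric chromosomes) at the background's G+C. Truth
tables let every downstream claim be scored against ground truth.

## Worked example

```sh
genosig make-fixtures --n-species 5 --window 100000 --seed 1 --out fixtures/
genosig run-all --k 3 --window 100000 --seqs-per-node 10 --epochs 200 \
    --fasta sp01=fixtures/sp01.fasta --fasta sp02=fixtures/sp02.fasta \
    --fasta sp03=fixtures/sp03.fasta --fasta sp04=fixtures/sp04.fasta \
    --fasta sp05=fixtures/sp05.fasta --out out/
```

prints

```json
{
 "n_fragments": 150,
 "lattice": [8, 2],
 "map_purity": 1.0,
 "vacant_nodes": 7,
 "multiple_nodes": 0,
 "n_special_zones": 0
}
```

150 fragments of 100 kb (five species × two 1.5-Mb chromosomes; the fifth
species arrives as 40-kb scaffolds and is N-concatenated) were clustered
on an 8×2 DegeTri lattice. A map purity of 1.0 means every fragment sits
on a node occupied by a single species — the unsupervised map recovered
the species boundaries from composition alone, with zero mixed ("black")
nodes and 7 vacant nodes. `out/` then contains the composition matrix,
the serialized model, territory/U-matrix/heatmap renders, per-fragment
statistics (e.g. mean CG odds ratios of 0.55 … 1.45 across the five
species, matching the generator's targets), and per-chromosome GA+TC
tracks in which `peaks.tsv` flags exactly the terminal 500-kb enriched
zones of species 1 (~19–20% GA+TC against a ~10% background, the
built-in fold-2 zones).

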