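# Methods

This note documents the models, numerical conventions, and design choices
behind `genosig`, and what the synthetic-data tests do and do not
demonstrate about real genomes.

## Fragmentation and the N convention

Assemblies are normalized to uppercase A/C/G/T/N (any IUPAC ambiguity code
becomes N). All coordinates are 0-based, half-open. Sequences are tiled
into non-overlapping windows `[0, w), [w, 2w), ...`; the trailing partial
window is discarded so that every composition vector summarizes the same
amount of sequence. Windows whose A/C/G/T fraction falls below
`min_valid_fraction` (default 0.5, inclusive threshold) are dropped and
logged; there is no principled community convention for N-rich windows, so
the threshold is exposed.

Scaffolds shorter than the analysis window would otherwise be lost, so all
sub-window scaffolds of a species are joined, in input order, with a
single `N` between neighbours. One separator suffices: every k-mer window
that crosses a junction contains that N and is excluded by the counter, so
the joined record's degenerate counts equal the sum of per-scaffold counts
exactly (this equivalence is tested against a brute-force counter over
random scaffold sets). The default pooling threshold is the analysis
window size.

## Degenerate alphabet and composition vectors

Each k-mer is merged with its reverse complement; the canonical member is
the lexicographically smaller of the pair and classes are ordered by it
(labels like `GA+TC`, canonical member first). Composition uses
overlapping windows with step 1 — required for window frequencies of
dinucleotides to be well defined — and reports percentages of valid
windows, so rows sum to 100 whenever at least one window is valid.
Fragments with no valid window are excluded from the matrix and logged.
Percentages, not raw counts, are the clustering input.

## BLSOM

The map is the batch-learning variant of the Kohonen self-organizing map:
deterministic PCA initialization, batch assignment/update epochs, and
strict input-order independence.

* **Lattice sizing.** Node count targets `n* = round(N / seqs_per_node)`
  (default 10 fragments/node). The aspect ratio follows the data:
  `J = max(2, round(sqrt(n* σ₂/σ₁)))`, `I = round(n*/J)`, where σ₁, σ₂
  are the standard deviations of the first two principal components.
  Each axis spans five standard deviations, centered on the data mean.
* **Training.** Per epoch: (1) every fragment is assigned to the node
  with the nearest weight (squared Euclidean; ties break to the smallest
  linear index `i·J + j`); (2) every node's weight becomes the
  kernel-weighted mean of fragments assigned within lattice radius
  `r(t)`, using a Gaussian kernel `exp(−d²/2r²)` truncated at `d > r`.
  `r(t)` decays linearly from `max(I, J)/2` to 1 over 200 epochs
  (defaults; all exposed in `BLSOMConfig`). Nodes receiving zero kernel
  mass keep their previous weight. The kernel shape, schedule, and epoch
  count are this package's documented choices — the original BLSOM
  literature leaves room for variation here — and changing them shifts
  map layout but not the species-level separation the tests score.
* **Order invariance, exactly.** Floating-point summation is not
  associative, so batch updates on a shuffled matrix would differ in the
  last bits. Training therefore sorts rows into a canonical
  (lexicographic) order first and maps assignments back through the
  inverse permutation; a row shuffle yields bit-identical weights.
* **Standardization.** Composition percentages are used raw (no
  per-column standardization) by default; a config flag enables z-scoring,
  in which case the transform is stored in the model and applied to all
  inputs at assignment time.

## Map diagnostics

* **Territory map**: a node is `single:<label>` when all its fragments
  share one label (species, lineage group, or chromosome), `multiple`
  (rendered black) when mixed, `vacant` when empty. **Map purity** is the
  fraction of fragments on single-label nodes.
* **U-matrix**: mean Euclidean distance between a node's weight and each
  existing 8-neighbor's weight, min–max normalized to [0, 1] (all-equal
  maps give all zeros). It is invariant under adding a constant vector to
  every weight.
* **Heatmaps**: per oligonucleotide, node frequencies are binned as
  `floor(21 (f − fmin)/(fmax − fmin))` clamped to 0..20; a constant map
  gets the neutral bin 10. Rendering offers a 21-step red/blue diverging
  palette and an orange/blue alternative for non-normal color vision.
* **Special-zone candidates**: for each label, 8-connected components of
  its single-label nodes are found; the largest is the main territory.
  A smaller component is flagged when the mean U-matrix value over the
  ring of nodes just outside it (where the boundary "black line" lives)
  reaches the chosen quantile (default 0.9) of all U values. The ring —
  rather than the component's own border nodes — carries the boundary
  signal because nodes adjacent to compositionally distinct clusters tend
  to fall vacant and absorb the large weight gradients. This flagger is a
  quantified surrogate for what is, in practice, a visual identification;
  it is a candidate generator, not a segmentation.

## Composition statistics

G+C% excludes N from numerator and denominator. The CG odds ratio is the
observed CG window frequency divided by `p_C · p_G` computed from the same
fragment's mononucleotide fractions; no end-effect correction is applied
(at ≥ 100-kb windows the end effect is O(1/L)). Overlapping windows are
used throughout, consistent with the frequency tracks. Box-plot summaries
use linearly interpolated quartiles and 1.5·IQR whiskers anchored at the
most extreme non-outlier points; they are validated against an independent
Tukey reference implementation. Hinge conventions differ slightly across
implementations for tiny samples; at the fragment counts used here the
difference is negligible.

## Window tracks and peak flagging

Frequency tracks share the tiling code path with ingestion but keep N-rich
windows as flagged-missing (NaN) values rather than dropping them, so
window indices stay aligned with genome coordinates. Motif tracks count
overlapping exact matches of every motif in a set, including reverse
complements when strand-merged; N never matches. Peaks are windows with
robust z `(v − median)/(1.4826·MAD) > 5`; MAD scaling keeps the threshold
meaningful on heavy-tailed tracks, and a zero MAD degenerates to flagging
any window above the median. The package bundles no motif catalogue:
consensus motif sets are user-supplied one-per-line text files, and any
example set in tests is synthetic and illustrative, not a curated TFBS
resource.

## Synthetic genomes

`simulate` builds order-1 Markov chains calibrated by fixed-point
iteration so that the stationary G+C% equals the target exactly and each
requested dinucleotide's stationary odds ratio equals its target (e.g.
`{"CG": 0.5}` for CG suppression). Infeasible combinations fail to
converge and raise. With no bias the chain is i.i.d. An order-1 chain is
the simplest emitter that produces species-separable di-/trinucleotide
signatures; it deliberately omits repeats, isochores, coding structure,
and long-range correlation of real chromatin, so a perfect score on
synthetic data demonstrates correctness of the machinery, not performance
on real assemblies.

Enriched zones (terminal by default, emulating pericentromeric sequence
on acrocentric chromosomes) are resampled from a modified emitter whose
member-dinucleotide odds ratios are scaled by the requested fold at the
background's G+C. Because the mononucleotide composition is preserved,
the class frequency rises by the same fold while G+C stays at background —
so detecting the zone requires dinucleotide information, not just base
composition. (A motif-insertion scheme was considered and rejected: at
fold 2 it drags zone G+C several points toward 50% because inserted pairs
are 50% G+C and over-insertion is needed to offset destroyed windows.)

The canonical community (defaults of `generate_community`): five species,
G+C targets spaced ≥ 3 points apart starting at 28%, CG odds-ratio
targets spread over 0.55–1.45 (spanning observed insect-like CG
deficiency through CG excess), two 1.5-Mb chromosomes per species at
100-kb windows, terminal fold-2 GA+TC zones on the first species, and the
last species emitted as 40-kb scaffolds. These sizes keep a full run in
seconds while leaving ~30 fragments per species, enough for a stable
8×2–4×4 lattice at ten fragments per node. Emission uses a numba-compiled
inner loop (a Markov chain is inherently sequential); everything is
deterministic under the seed.

## Determinism and degenerate inputs

All randomness flows through `numpy.random.default_rng` seeded explicitly;
the pipeline itself (given inputs) is fully deterministic, and repeated
runs produce byte-identical tables. Degenerate inputs have defined
behavior throughout: empty FASTA records, all-N fragments, sequences
shorter than k, zero-variance matrices, constant heatmaps, zero-MAD
tracks, and σ₂ = 0 lattices either raise a named error or return a
flagged value, as documented per function.

## Known limitations

* The special-zone flagger is threshold-based and map-resolution-bound;
  zones smaller than a node or butted directly against the main territory
  without a vacant/high-U separation will be missed.
* Lattices for small fragment counts can collapse to J = 2, limiting the
  geometric detail of territory maps; use more/smaller windows or a lower
  `seqs_per_node` for finer maps.
* The synthetic emitters do not model repeat families or satellite
  monomers; zone recovery results quantify detector behavior under
  controlled enrichment only.
* Motif scanning is exact-match; position-weight-matrix scanning is out
  of scope.
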