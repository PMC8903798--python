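# Methods

## Coordinates and the frameshift convention

All internal coordinates are 0-based half-open on the top strand; the
GenBank 1-based inclusive convention exists only at the I/O boundary.
Reverse-strand CDSs keep ascending intervals and carry strand −1, so one
sorting rule (ascending start, then end, then id) orders every genome.

The frameshift of an overlapping pair is derived from each CDS's *phase*,
the top-strand coordinate (mod 3) at which its codon triplets begin:

- forward strand: `(start + frame_offset) mod 3`
- reverse strand: `(end − frame_offset) mod 3`

where `frame_offset = codon_start − 1` from the annotation. For two
same-strand CDSs the shift is `(phase_downstream − phase_upstream) mod 3`,
with "upstream" taken in reading direction (for two reverse-strand genes
the pair is mirrored, so upstream is the higher-coordinate CDS and the
phase difference flips sign). For opposite strands the shift is
`(phase_reverse − phase_forward) mod 3`, rendered with a minus sign; −0 is
the perfectly codon-aligned antisense frame. No published formula exists
for this convention, so it is anchored to three motif fixtures (ATGA→+2,
T[AG]ATG→+2, CTAA→−2) and to a reverse-complement invariance property
test: mirroring a whole genome must preserve every rendered label.

`codon_start` participates in the phase so that 5′-partial CDSs classify
correctly. Frameshifts are left undefined (with a reason) for pairs
involving spliced CDSs, and for origin-wraparound CDSs of circular
genomes, whose phase is not well-defined in linear coordinates.

Detection default is the adjacent-pair scan over the sorted ORF list —
the procedure the census convention is built on; it can miss nested ORFs,
so an `all_pairs` mode (verified against a quadratic interval-intersection
oracle) is provided as a documented divergence switch. A `circular_wrap`
flag optionally adds the (last, first) pair on circular genomes; it is off
by default because the sorted scan is defined linearly.

## Clustering

k-mer counts for k ∈ {1,2,3} are pooled into a single dictionary per
protein (total 3L−3 words for length L ≥ 3), matching the single-sum
Bray–Curtis formula; `*` and `X` are ordinary symbols, and sequences
shorter than 3 residues contribute whatever k-mers exist. Bray–Curtis is
symmetric, bounded in [0,1] and zero iff the profiles coincide, but it is
not a metric — no triangle inequality is claimed, which is one reason the
matrix is re-embedded before clustering.

Embedding is t-SNE on the precomputed distance matrix (perplexity 30,
automatically reduced below (n−1)/3 for small families; the seed is an
explicit argument and defaults to 0). A deterministic alternative,
classical (Torgerson) scaling, is provided because t-SNE's stochasticity
makes exact cluster counts irreproducible across library versions; the
classical-scaling route is what the reproducibility tests use, with a
sign convention fixed so eigenvector orientation cannot flip between BLAS
builds. Ward linkage on the planar points, cut at a height chosen to
minimize (E1 − E2)²:

- E1 = mean over genomes of (#clusters hit exactly once)/(#clusters hit);
  genomes contributing zero clustered ORFs are excluded (0/0).
- E2 = mean over clusters of mean count per genome, zeros included, with
  N the full genome count — the literal reading of the defining equation.

The objective is piecewise-constant in height, so a grid over the ≤ n−1
merge heights (plus 0) is scanned before a bounded scalar refinement; ties
take the smallest height, i.e. more clusters, which favours separating
ORFans over lumping them.

## Graphs and regression

Adjacency edges are directed by genomic 5′→3′ sorted order; (u,v) and
(v,u) are distinct. Every consecutive pair contributes 1 per genome (so
tandem duplicates create self-loops and repeated pairs count repeatedly),
and the companion overlap edge increments when that pair overlaps — the
invariant `ovl(u,v) ≤ adj(u,v)` is asserted on every build. The DOT
renderer suppresses edges below a display threshold (default 5 genomes)
and can scale overlap-edge widths by mean overlap length instead of
genome count; thresholds affect display only, never the statistics, which
always see the full graph.

Node metrics (degree, triangles, local transitivity, eigenvector
centrality) are computed on the undirected simple projection of adjacency
edges — self-loops removed, weights ignored — because triangle and
transitivity statistics are standard only there. Eigenvector centrality
is obtained by power iteration (tolerance 1e−10) on A + I (the shift
breaks the period-2 oscillation of plain power iteration on bipartite
graphs without changing the leading eigenvector), L2-normalized over all
nodes, restricted to the largest connected component with zeros
elsewhere. Edge covariates are endpoint sums; the "total size" covariate
defaults to the edge's own trial count n (the number of genomes carrying
the adjacency), with a node-sum variant available.

The zero-inflated binomial likelihood uses log-sum-exp stabilization for
the y=0 mixture and an intercept-only inflation probability φ (covariates
act on p; a covariate-dependent φ would be a straightforward extension
but is not implemented). Fitting is BFGS on (β, logit φ) with the
analytic score; covariates are z-scored for optimizer stability, with the
means/sds retained so coefficients can be reported on the original scale.
Standard errors come from the numerically differentiated observed
information; non-convergence and boundary estimates (p̂ at 0/1, φ̂ at 0)
are flagged in the results, never raised. The φ=0 special case is
cross-checked in tests against a binomial GLM fit to 1e−6. Stepwise
selection is bidirectional, bounded by the intercept-only and full
models, taking the single add/drop with the lowest AIC per step and
stopping when no move strictly improves; with the standard AIC penalty of
2 per parameter a pure-noise covariate is retained with probability
P(χ²₁ > 2) ≈ 0.157, so on null data the intercept-only model is selected
in roughly 84% of replicates per candidate (≈60% with three candidates)
— an inherent property of AIC-based selection worth knowing before
interpreting marginally retained terms.

## Synthetic families

The generator emulates exactly the structure the pipeline consumes:
ancestral proteins drawn i.i.d. uniform over the 20 amino acids (so
between-cluster Bray–Curtis distances are near-maximal and planted
structure is clean — deliberately *not* a realism benchmark: no
phylogeny, no indels, no rate heterogeneity), a conserved global gene
order of core plus Bernoulli-present accessory genes, per-site point
mutations, and junction overlaps realized by sliding the downstream start
into its upstream neighbour. Defaults: 20 genomes, 8 core + 4 accessory
clusters (presence probability 0.5), gene lengths 80–250 aa, mutation
rate 0.05/site, overlap probability 0.4/junction, and a frameshift mix
dominated by +2 (0.60) and +1 (0.28) with rare antisense labels, echoing
the observed census where +2 junctions (1 nt and 4 nt motifs) dominate
and antisense overlaps are a few percent.

Because complete CDSs with codon_start=1 and codon-multiple lengths force
the junction congruence s ≡ (−L) mod 3 between overlap length L and shift
s, sampled lengths are rounded up by at most 2 nt to the nearest feasible
length for the sampled shift (and down by multiples of 3 if they would
swallow a gene; infeasible junctions are skipped and logged). The ground
truth records *realized* values, and a round-trip test asserts that
scan + classification recovers every planted (length, shift) pair exactly,
through GenBank serialization and back. Negative-shift junctions place
the downstream gene on the reverse strand; the junction after a reverse
or spliced gene never overlaps, keeping every planted junction's geometry
independent. Passing tests on these families demonstrates pipeline
correctness (coordinate arithmetic, classification, clustering recovery,
graph counts), not robustness to real-world annotation noise — that is
what `perturb_annotations` probes separately.

## Problem sizes and numerical choices

Test and demonstration runs use families of 10–14 genomes with 5–9
clusters and regression simulations of 150–500 edges — sizes chosen so
the full suite exercises every code path in seconds while leaving
parameter-recovery checks enough data to be sharp (the 500-edge ZIB
simulation recovers (φ, β) within 3 standard errors). Determinism is a
contract throughout: all randomness flows through seeded
`numpy.random.default_rng`, iteration orders are sorted, and rerunning a
pipeline configuration reproduces every artifact byte-for-byte, DOT
included.

## Known limitations

- The adjacent-pair scan undercounts overlaps among ≥3 mutually
  overlapping ORFs; use `all_pairs` when that matters.
- Cluster counts from the t-SNE route depend on the embedding seed;
  classical scaling is the reproducible alternative.
- Bray–Curtis on pooled k-mers saturates near 1 for unrelated proteins
  but compresses differences between highly divergent homologs; an
  alignment-based distance can be plugged into
  `pairwise_distance_matrix(distance=...)`.
- The ZIB model treats (u,v) and (v,u) as independent observations;
  within-genome correlation between edges is not modelled.
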