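# Methods

This note documents the models, parameter choices and numerical decisions
behind `nucleodomain`, and what the synthetic-data tests do and do not
establish about real data.

## DamID processing

Fragment boundaries are placed at GATC motif start + 2, the DpnI cleavage
point between GA and TC; the motif is palindromic, so a single forward scan
covers both strands. Reads are assigned to fragments by their 5′-most
coordinate, which is robust to read length. The per-fragment score is the
log2 ratio of library-size-normalised counts, NoLS over Dam control, with a
pseudocount ψ (default 1 read) on both samples. Fragments with fewer than
2 total reads across the two samples are masked as uninformative; both
values are configurable. Binning to the 100-kb analysis resolution is an
exact length-weighted mean over fragment–bin overlaps, and a bin is masked
when at least half its length is masked at fragment level. All coordinates
are 0-based half-open, including emitted bedgraph.

The normalisation is deliberately transparent (library size + pseudocount)
rather than model-based: the ratio is a relative contact-frequency measure
and every downstream step consumes only its ordering and contrasts.

## NAD calling

The caller thresholds the track at the `min_quant` quantile (default 0.70)
of unmasked scores, takes maximal runs of consecutive above-threshold bins
(masked bins break runs; an optional `merge_gap` can bridge sub-threshold
gaps, default 0), and ranks runs by their **summed** member score. The null
distribution of run scores comes from permuting bin scores within each
chromosome, preserving per-chromosome score distributions while destroying
contiguity. A run's FDR is the mean null count of runs scoring at least as
high divided by the observed count doing so, clamped to [0, 1] and made
monotone in rank (a q-value); runs with FDR < 0.01 are emitted at bin
resolution.

Summed run score is a deliberate choice: under a mean-score ranking a
single extreme bin in the permutation null scores as high as a broad
domain, so breadth — the defining feature of these domains, which span
tens of bins — would never reach significance. Sum scoring makes a
10-bin domain of moderate enrichment beat any shuffled singleton, while
pure-noise tracks still yield calls in ≲1% of seeds (a call requires the
top observed run to beat every run in all permutations).

Replicates are called independently and intersected at base-pair level,
with intersection pieces shorter than one analysis bin dropped; an
averaged-track mode is intentionally not the default. Boundaries are
emitted at bin resolution; no sub-bin refinement at GATC-fragment
resolution is attempted.

## rDNA-anchored Hi-C

A usable contact is a read pair with exactly one end inside the rRNA gene
unit appended to the end of one chromosome; both-inside pairs are tallied
separately and excluded, since the analysis targets contacts between the
rRNA genes and the rest of the genome. The non-rDNA end is assigned to a
5-kb bin. Knight–Ruiz balancing is implemented as the inner–outer Newton
iteration with a row-sum preconditioner; rows with fewer than 10% nonzero
entries are masked first, and a symmetric Sinkhorn iteration is the
documented fallback if the Newton iteration stalls. Balanced row sums reach
a coefficient of variation below 1e-6, and the scaling vector is invariant
(up to global scale) under symmetric permutation. Balancing weights for
contact scoring are computed per chromosome on the full cis matrix and
rescaled to mean 1 over unmasked bins.

Replicate-common contacts are bins present with raw count ≥ 1 in every
replicate (threshold configurable), scored as the mean of replicate scores.
"Unique contacts" deduplicate at the bin level. Quintile distributions
split each chromosome into five equal-length segments from coordinate 0;
in the acrocentric mouse karyotype this start is the centromere-proximal
end, so quintile 1 reads as centromere proximity.

## Compartments

Per chromosome at 100-kb bins: the cis matrix is KR-balanced, divided by
distance-stratified means (observed/expected), converted to a Pearson
correlation matrix, and eigendecomposed. Among the top three eigenvectors
the compartment eigenvector is the one with the highest absolute
correlation with a reference track (gene density or a known A/B signal),
and its sign is oriented so A is positive. Selecting rather than blindly
taking the leading eigenvector matters at modest sequencing depth, where a
coverage/sparsity component can carry the largest eigenvalue; this mirrors
the phasing-track selection used by standard compartment callers.
O/E columns with vanishing variance (a structureless map) are masked, so a
uniform matrix yields abstention rather than noise.

Switch classification between two states: sign changes are full switches
(B→A, A→B); same-sign changes of at least `delta_min` (default 0) get a
lowercase letter. Under the default `magnitude` convention the lowercase
letter marks the weaker state (|ev| closer to zero), so (−1.0, −0.2) is
"B to b"; the alternative `delta` convention places the lowercase letter on
the smaller eigenvector value instead. Published figure legends use the
lowercase notation both ways, so the convention is explicit and
parameterised rather than guessed.

## Layer algebra and signal profiles

All layer classifications are base-pair-level set algebra (NAD/LAD =
NAD ∩ LAD, etc.), so the four layers are mutually disjoint and tile the
genome exactly — an invariant the tests assert literally. Cell-type-
specific domains are set differences with pieces shorter than one analysis
bin removed to suppress boundary-jitter slivers. Gene membership uses the
gene midpoint (half-open: a midpoint on a domain start is a member), which
avoids double-counting boundary-straddling genes.

Boundary metaprofiles orient both boundaries of each domain so the interior
lies on the positive axis, sample the signal as exact length-weighted means
per position bin (defaults: 500-kb flank, 10-kb bins; published profile
plots do not state these, so they are configurable), and drop boundaries
whose flanks leave the chromosome. The 20-kb fold-change track normalises
both coverage tracks by their genome-wide totals and adds a common
pseudocount on the normalised scale (ψ/√(AB) for ψ reads, default 1),
which keeps the fold change exactly zero for proportional tracks and
bitwise antisymmetric under condition swap (computed as a difference of
logs). RPKM is count × 10⁹ / (library × union-exon length); a gene is
"expressed" iff RPKM is strictly greater than 1, so exactly 1 classes as
low.

## Synthetic studies

The generator emulates the statistical structure the analysis assumes, at a
desk scale chosen to hold ≥ 20 planted domains while keeping the full suite
in minutes: 3 × 30-Mb chromosomes, GATC motifs from a renewal process with
500-bp mean spacing (background sequence is scrubbed of chance motifs), a
45-kb rRNA unit appended to the last chromosome, 100-kb analysis bins.
DamID counts are negative binomial (var = μ + θμ², θ = 0.1, Poisson at
θ = 0) with mean proportional to fragment length, 2M reads per sample, and
a 4-fold NoLS rate inside planted NADs. Hi-C cis separations follow
P(s) ∝ s⁻¹ above 1 kb; 10% of pairs are rDNA-anchored with the other end
drawn under a 5× NAD boost and 3× centromere-proximal boost; a 2-Mb A/B
checkerboard boosts same-compartment pairs 2×. ChIP signal is gamma per
50-bp bin around layer-specific means; expression counts are Poisson around
layer-specific mean RPKM (0.2 in NADs).

The default two-cell-type layout is designed so that ~53% of NAD bp
overlaps LADs, 40% of LAD bp overlaps NADs, and 78% of cell-1-specific
NAD-only bp lies outside both compartments of cell 2 — the headline
organisation the layer algebra must recover end to end.

What the generator does **not** model: sequencing error, mappability and
PCR duplicates, diploid genotypes, trans contacts beyond the rDNA anchor,
replicate-to-replicate biological variability (replicates differ only by
count noise), and domain boundaries off the bin grid. Passing tests
therefore demonstrate the correctness and calibration of the computations
under the assumed noise models, not robustness to alignment artefacts or
copy-number structure in real libraries.

## Known limitations

- Called boundaries are bin-resolution; NADs smaller than one bin are not
  recoverable.
- The permutation null assumes exchangeable bins within a chromosome;
  strong autocorrelation in a real null (e.g. copy-number waves) would
  make the FDR anti-conservative.
- KR balancing requires total support on the unmasked submatrix; extremely
  sparse matrices fall back to Sinkhorn with a warning.
- The compartment caller operates on cis matrices only.
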