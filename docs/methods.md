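# Methods

## Problem setting

Amplicon surveys of marker genes such as 16S rRNA produce collections of
10⁵ or more short reads (here: under 200 nt) from mixed communities.
Grouping them into putative gene families via all-pairs alignment is
quadratic in the collection size twice over — once for the distance
matrix, once for the embedding used to visualize it. This package
implements that quadratic pipeline and its interpolative variant, in
which only M reads are treated quadratically and the remaining N−M are
placed into the trained embedding at linear cost per read.

## Genetic distance

Distances come from optimal global alignment with affine gaps (Gotoh
three-state dynamic program). A gap of length g costs
`gap_open + g * gap_extend`; end gaps are penalized, so reads of unequal
length accrue terminal gap cost — the deliberate behavior of a true
global aligner. The distance is

    delta = 1 - n_match / alignment_length,

one minus fractional identity with gap columns counted in the length,
which is bounded in [0, 1] and zero exactly for identical reads. The
scoring scheme is configurable; the defaults (match +5, mismatch −4, gap
open 10, gap extend 4) follow common EDNAFULL-like magnitudes for
nucleotide work. `N` is accepted on input but never scores as a match,
even against another `N` — the conservative choice for an ambiguity code.
Because alternative optimal alignments can have different identity
fractions, the traceback tie-break is fixed (diagonal > up > left), making
delta a deterministic function of the input pair.

Exact duplicates are removed before any alignment (first occurrence kept,
with a map from removed ids to their representative so labels can be
propagated back). Duplicate collapsing is exact full-string equality
only; prefix or substring collapsing would be a different algorithm.

## Full MDS (SMACOF)

The embedding minimizes raw (unweighted Kruskal) stress
σ(X) = Σ_{i<j} (δ_ij − d_ij(X))² via the Guttman transform
X′ = n⁻¹ B(X) X with b_ij = −δ_ij / max(d_ij, ε), ε = 1e−10 guarding
coincident points. Majorization guarantees σ never increases, which the
tests assert at every iteration. Uniform weights keep the update a
closed-form averaging with O(n²L) cost per sweep.

Iteration starts from Torgerson classical scaling (double-centered
squared dissimilarities, top-L eigenpairs, negative eigenvalues clipped).
Classical scaling is deterministic and, for dissimilarities that are
exactly Euclidean in L dimensions, starts at the global optimum — a lone
random start is demonstrably prone to local minima at small n, and on
near-degenerate instances (tight clusters whose internal orientation is
barely constrained by the distances) it can converge to configurations
far from the generator despite near-zero stress. A seeded uniform
[−0.5, 0.5]^L random initialization remains available (`init="random"`)
and is exercised by the determinism tests. Stopping: relative stress
change < 1e−6 or 500 sweeps (both configurable). A matrix whose
off-diagonal entries are all zero is rejected as degenerate rather than
embedded at an arbitrary point.

Reported alongside the coordinates: final raw stress, normalized stress
σ / Σ δ², iteration count, and the full stress trace.

## Interpolation

Each out-of-sample read is aligned against all M in-sample anchors (this
is the (N−M)·M term; exhaustive search is intentional — approximate
neighbor search would change the cost contract), the k nearest anchors
by genetic distance are kept (default k = 10, ties to the lower index,
k = M supported), and the point is placed by single-point majorization

    x <- (1/k) * sum_i [ p_i + (delta_i / max(d_i, eps)) * (x - p_i) ]

from the anchor centroid (jittered by 1e−9 if it coincides with an
anchor at nonzero target distance). A zero target distance
short-circuits: the read is an exact duplicate of that anchor and
inherits its coordinates. Per-point stopping is relative stress change
< 1e−8 or 100 iterations; the oracle tests that require convergence to
geometric ground truth raise the cap to 10⁴, since a point whose nearest
anchors are all far away (an entire cluster left out of sample) converges
slowly. Anchors never move, and points are mutually independent — the
basis for both the parallelism contract and the exact cost accounting.

## Clustering and evaluation

k-medoids (PAM: greedy BUILD, then steepest-descent SWAP, ties to lower
indices, hence fully deterministic) consumes the distance matrix
directly. The cluster count C is user-supplied; model selection is out
of scope. Out-of-sample reads take the label of the nearest medoid in
embedded Euclidean space, which costs no further alignments.

Embedding agreement is quantified by Procrustes superposition over
similarity transforms (translation, rotation, reflection, uniform
scale) — exactly the transforms MDS leaves undetermined. Both
configurations are standardized to unit Frobenius norm first, so the
reported RMSD is scale-free and symmetric in its arguments; the optimal
raw scale factor is reported separately. Partition agreement uses the
adjusted Rand index (delegated to scikit-learn, cross-checked in the
tests against a direct pair-enumeration computation).

## Synthetic data

Two generators, because they answer different questions.

*Sequence families* emulate a multi-family amplicon sample: C ancestors
drawn uniformly over {A,C,G,T} with lengths in 120–180 nt (under the
200 nt regime the pipeline targets), resampled until all pairwise genetic
distances reach 0.30; members derive from their ancestor by per-site
substitution (default 0.02) and single-site indels (default 0.005, insert
or delete with equal probability), giving within-family distances near
0.05 against between-family distances near 0.5 — strongly clustered but
non-trivially noisy. Rates were chosen once to mimic intra-family
divergence of marker-gene reads; exact duplicates can be injected to
exercise deduplication. Truth labels travel in FASTA headers as
`family=<int>`, so fixtures round-trip through the standard file format.
Not modeled: platform-specific error profiles (e.g. homopolymer errors),
rate-matrix substitution models, multi-base indels, and realistic family
size skew (sizes are equal unless specified). Passing tests therefore
demonstrate recovery of well-separated families under uniform noise, not
performance on reads with structured sequencing error.

*Geometric fixtures* are Gaussian blobs in R^L with their exact Euclidean
distance matrix (rescaled into [0, 1]; the stored coordinates are rescaled
identically so they remain an exact zero-stress optimum). They provide
what sequence data cannot: a known ground-truth configuration, making
exact-recovery assertions possible for both SMACOF and interpolation.

## Numerical and format choices

- Distance matrices are stored as float32, matching the binary `.dmat`
  format (magic + version + n + id block + row-major float32), so disk
  round trips are bit-exact. Float32 rounding means the geometric
  fixtures' triangle inequality holds to ~1e−6 rather than exactly.
- All-pairs and per-point work is chunked into fixed-size blocks executed
  by a thread pool over a nogil compiled kernel; chunk boundaries do not
  depend on the worker count, so results are bitwise identical for any
  worker count — the single-machine replacement for a distributed
  map-reduce deployment, kept as a result-invariance contract.
- Points files carry 6 significant digits, 0-based post-deduplication
  indices, and z-padding to three columns for 2-D embeddings so 3-D
  viewers always parse.
- Every seeded choice (split, MDS init, cluster seed) is recorded in the
  run manifest; a run can be reproduced bitwise from its manifest alone.

## Problem sizes

The test and acceptance workloads use N up to 300 reads (families of
120–180 nt) and geometric fixtures up to n = 200 — sizes at which the
full pipeline's quadratic stage still runs in seconds while all count
contracts (e.g. 19,900 alignments at N = 200; 8,725 at N = 200, M = 50)
and structure-preservation comparisons are exercised end to end. The
method itself has no such ceiling; cost grows as the stated complexity
terms.

## Known limitations

- Plain SMACOF with uniform weights; no deterministic annealing, no
  weighted stress, no nonmetric variant.
- k-medoids substitutes for the unnamed pairwise clustering of the
  original pipeline formulation; it shares the same interface (a distance
  matrix) but is a different optimizer with a user-supplied C.
- The genetic-distance formula and scoring scheme are declared defaults,
  not community standards; both are configurable and all quantitative
  claims in the tests use the defaults.
- Interpolation quality degrades when an entire neighborhood is absent
  from the in-sample set — visible in the fixture studies as larger
  positional error at M = N/10 than at M = N/2.
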