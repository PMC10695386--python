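# Methods

## Model and procedure

`promarch` treats a set of n equal-length (L nt), TSS-aligned DNA sequences
as a sparse one-hot matrix **V** (p × n): p = 4L rows for mononucleotide
profiles or p = 16(L−1) for overlapping dinucleotide profiles (the default;
dinucleotides capture neighbour dependencies such as YR initiators). Rows
are grouped in position blocks with alphabet order inside each block
(position 1: A,C,G,T or AA..TT; then position 2; ...), so every row of the
basis matrix is a (symbol, position) feature. A length-L sequence has only
L−1 overlapping dinucleotides, hence 16(L−1) rather than 16L features.

NMF (scikit-learn, coordinate-descent solver, NNDSVD initialisation,
relative tolerance 1e−4, ≤200 iterations by default) factorises V ≈ WH with
W, H ≥ 0. After each fit, basis vectors are rescaled to unit maximum (with
the inverse absorbed into H) so vectors are comparable across runs and
chunks; the product WH is unchanged. Reconstruction accuracy is defined as
1 − ‖V − WH‖_F/‖V‖_F, clipped to [0, 1]: the phrase "reconstruction
accuracy" admits many formalisations and this one is scale-free and
bounded.

### Run-to-run variability

NNDSVD is deterministic, so repeated runs would be identical without a
controlled noise source. The seed enters through the coordinate-descent
solver's shuffling of coordinate update order. This perturbation is
infinitesimal when the factorisation is well determined — repeated runs
then agree to ~1e−10 in basis-vector correlation — and macroscopic when the
rank exceeds the structure in the data, which is exactly the contrast the
stability criterion needs. Bootstrap resampling of sequences was considered
and rejected: its sampling noise keeps instability orders of magnitude
above any usable bound even at the true rank.

### Rank selection

*Stability.* For each candidate rank k, `n_runs` seeded fits yield
dictionaries (basis-vector sets). For two dictionaries with K vectors, C is
the K×K matrix of Pearson correlations between vectors (negative entries
clipped to 0 — an anti-correlated vector is no match — keeping the result
in [0,1]), and

diss(R,R′) = (2K − Σ_j max_k C_kj − Σ_k max_j C_kj)/2K.

Instability at k is the mean dissimilarity over all unordered run pairs.
The selected rank is the **largest scanned k with instability below the
bound** (default 1e−6; 1e−7/1e−8 are stricter alternatives; default
n_runs = 100, reducible for small studies). Instability is not monotone in
k: a rank just below the true one is often unstable too (which merge of the
true clusters is learned varies run to run), then the true rank is stable
again. The upward scan therefore stops only after **two consecutive**
bound violations rather than the first one; a `scan_all` option evaluates
the whole range. If even k = 2 violates the bound, the chunk is declared
homogeneous (k = 1) — the only coherent outcome for a structureless chunk,
and empirically what uniform-background chunks produce (instability
1e−4–0.3 at k = 2).

*Bi-cross-validation.* Rows and columns are partitioned into `folds` groups
(seeded). Fold f holds out block V11 = V[rows_f, cols_f], fits NMF on the
retained block V22, and predicts V11 ≈ V12 · pinv(W22H22) · V21. Mean
held-out accuracy and its standard error over the folds × runs pool are
computed per k and the smallest k within one standard error of the best
mean is selected (parsimony). Defaults: 5 folds, runs per fold
configurable.

### Clustering, overfit control, collation

Sequences join the basis vector with their largest coefficient (ties to the
lowest index); basis vectors winning no sequences are dropped with a
warning. A cluster is *overfit* when its coefficient distribution is
dominated by a few members: coefficient of variation of the members'
winning coefficients > 1.0 (configurable) or cluster size < 5. Flagged
clusters are merged into the first unflagged cluster of the same chunk; if
all are flagged the chunk collapses to one cluster.

Collation builds a hierarchical tree (Ward linkage by default) on basis
vectors using Euclidean distance on unit-max-scaled vectors or correlation
distance (1 − Pearson; Ward+correlation is allowed but logged as a
non-metric pairing). The dendrogram cut is the genuinely open design point:
the **largest-gap rule** places the cut at the biggest jump in the sequence
of merge heights, with the jump from leaf level (height 0) to the first
merge as a candidate, so "merge nothing" is a possible outcome. Duplicated
architectures from different chunks join at small heights while distinct
architectures join far higher, and the rule is idempotent. A
silhouette-maximising cut was tried first and discarded: whenever the input
is already one cluster per true architecture, some grouping of related
architectures (e.g. those sharing a GAGAG element) always scores a positive
silhouette, so it merges clusters that must stay separate (final ARI
dropped from ~0.99 to 0.30 on the benchmark). Fixed group counts and fixed
cut heights remain available (`cut=n` / `cut=height`), and exact group
counts are honoured even with tied merge heights. Merged clusters take the
member-count-weighted mean of their basis vectors as representative. A
mechanical curation helper (`apply_mapping`, CLI `collate`) re-groups final
clusters by a user-supplied map, supporting manual curation of the
uncollated last-iteration clusters, which are always retained alongside the
collated final solution.

### The iterative driver

Iteration 0 treats the input as one outer chunk, split into inner chunks of
`chunk_size` (contiguous in input order; a seeded shuffle flag exists for
sorted inputs; trailing remainders smaller than max(2·k_min, 50) merge into
the previous chunk). Each later iteration's outer chunks are the previous
iteration's clusters, re-chunked when larger than `chunk_size`. Per-
iteration collation is controlled by `set_ocollation`; the final collation
after the last iteration always happens and is independent of those flags.
All seeds derive deterministically from the master seed and the (iteration,
outer, inner) coordinates, so a run is reproducible from its config alone.

## Synthetic data

The generator plants position-fixed motifs into i.i.d. uniform background
sequences. The standard benchmark: 1000 sequences of 100 nt in four
clusters — A: AT repeat at 1-based starts 10, 20, ..., 90 (200 sequences,
always verbatim), B: GATTACA@40 + GAGAG@60 (350), C: GAGAG@60 (150), D:
TCAT@40 + GAGAG@80 (300). Mutation model: per motif instance, `positions`
(1–3) distinct sites are chosen uniformly; each mutates with probability
`rate` (0.1–0.5) to a base drawn uniformly from the other three (a
"mutation" that keeps the base would understate the nominal rate). The
A-repeat's extent (through position 90) is configurable since a repeat
"every 10 nt" admits either endpoint reading. Output order is a seeded
global shuffle so every chunk sees every cluster. A second spec
(`disjoint_motif_spec`) plants four disjoint 8-mers at non-overlapping
positions — the cleanest recoverable structure, used for exact-recovery
checks. The benchmark grid crosses 5 rates × 3 position settings × 3 chunk
sizes (45 configurations, 10 repeats by default).

What the generator does *not* emulate: positional jitter of motifs,
composition-based (non-motif) architectures, shared background biases
(CpG islands, nucleosome periodicity), or unequal cluster separability.
Passing benchmarks therefore demonstrate correct mechanics and noise
robustness of the factorisation pipeline, not performance on real promoter
sequences, where bound/iteration/collation choices matter and curation is
expected.

## Numerical choices and edge cases

- Assignment ties break to the lowest basis index; argmax is deterministic.
- `best_of_runs` derives run r's seed as master + r; ties in accuracy keep
  the lowest run index.
- Pearson correlation on a zero-variance vector raises rather than
  returning NaN; dictionaries reject all-zero basis vectors.
- `basis_to_pwm` collapses a dinucleotide weight onto *both* constituent
  bases (first base at i, second at i+1), preserving edge-position
  information; zero-weight columns become uniform 0.25 with a warning.
- Information content uses pseudocount 1e−3 per base by default; 0·log 0 is
  treated as 0.
- MEME export defaults `nsites` to 1e6 — parsers reconstruct counts as
  probability × nsites, so a large value preserves probability resolution.
- Ambiguous bases (N) are a hard error by default; `drop_invalid` skips the
  offending records with a logged warning (never zero-fills, which would
  break the one-hot contract).

## Problem sizes

Tests and the reproduction script run the full pipeline on 1000-sequence
datasets with `n_runs = 30` and 1–3 seeds per condition, which recovers the
same selections as larger run counts on this data while keeping a complete
run in the minutes range; n_runs = 100 remains the default for real
analyses.

## Known limitations

- One global bound for all chunks and iterations (an adaptive bound is a
  natural extension).
- The overfit criterion is a simple CV-plus-size rule; the thresholds are
  exposed but heuristic.
- Architectures are full-length profiles; motif extraction/trimming from
  profiles is out of scope.
- Fixed-position premise: features shifted by even a few bp across
  sequences dilute into neighbouring positions; collation does not align or
  reverse-complement.
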