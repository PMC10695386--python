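# promarch

De novo discovery of **position-fixed promoter sequence architectures** by
chunked, iterative non-negative matrix factorisation (NMF).

## The problem

Core promoters are not built from one universal motif grammar. Around a
dominant transcription start site (TSS) different promoter classes carry
different combinations of sequence features at characteristic distances — a
TATA-box ~30 bp upstream here, a downstream promoter element there, CG-rich
stretches or nucleosome-positioning periodicity elsewhere. Given a gapless
alignment of equal-length sequences anchored at the TSS (e.g. from CAGE),
`promarch` clusters the sequences by their shared positional features and
reports each cluster's *architecture*, without being told the number of
clusters, the number of motifs, their lengths, or their spacing.

## The method

Each sequence is one-hot encoded — mononucleotide (4L features) or, by
default, overlapping dinucleotide (16(L−1) features) — giving a sparse (0,1)
matrix **V** (p × n). NMF factorises it:

    V ≈ W H,   W ∈ R^(p×k)≥0,  H ∈ R^(k×n)≥0

Columns of **W** (basis vectors) are candidate architectures; column j of
**H** holds sequence j's coefficients on them. Sequences are processed in
*chunks*; per chunk the rank k is chosen by the **stability criterion**: with
dictionaries R, R′ (basis-vector sets from repeated seeded runs) and C their
K×K cross-correlation matrix,

    diss(R, R′) = (2K − Σ_j max_k C_kj − Σ_k max_j C_kj) / 2K

and the *instability* at rank k is the mean dissimilarity over all run pairs.
The selected k is the largest whose instability stays under a bound (default
1e−6; r-fold bi-cross-validation with the one-standard-error rule is
available as an alternative). Each sequence joins the cluster of its
highest-coefficient basis vector; overfit clusters (coefficient mass on a few
sequences) are re-merged into their parent; similar clusters from different
chunks are collated by hierarchical clustering (Ward + Euclidean by default)
of their basis vectors. Subsequent iterations treat each cluster as a new
outer chunk and repeat, and the last iteration's clusters are collated once
more for the final report. Clusters are visualised as position frequency
matrices (information-content logos) or as PWM-like matrices derived from the
basis vectors, and exported in MEME minimal format.

## Worked example

`examples/03_cluster_simulated.py` generates the simulated benchmark — 1000
uniform-background sequences of 100 nt in four clusters: A (AT repeat every
10 nt from position 10, 200 sequences), B (GATTACA@40 + GAGAG@60, 350),
C (GAGAG@60, 150), D (TCAT@40 + GAGAG@80, 300); motifs in B–D planted with a
mutation rate of 0.1 at one motif position — and clusters it:

```text
iteration 0 chunk (0,0): n=500 selected k=4
iteration 0 chunk (0,1): n=500 selected k=4
iteration 1 chunk (0,0): n=348 selected k=1
iteration 1 chunk (1,0): n=300 selected k=1
iteration 1 chunk (2,0): n=152 selected k=1
iteration 1 chunk (3,0): n=200 selected k=1
final cluster sizes: [348, 300, 152, 200]
ARI vs truth: 0.995
```

Both chunks of 500 find four architectures; collation merges the duplicates
across chunks; the second iteration confirms each cluster is homogeneous
(k=1). The final partition agrees with the planted clusters at an adjusted
Rand index (ARI) of 0.995 — near-perfect recovery, with the 348/152 split
reflecting a handful of B sequences whose GATTACA was mutated into
C-lookalikes.

The other examples cover encoding (`01`), rank selection (`02`), profiles
and MEME export (`04`), and a miniature benchmark grid (`05`). The same
functionality is available from the shell:

```bash
promarch simulate --rate 0.1 --positions 1 --seed 7 --out sim.fa
promarch run sim.fa --chunk-size 500 --n-runs 30 --iters 2 --collate 1,1 --seed 7 --out-dir out/
promarch evaluate out/clusters.tsv sim.labels.tsv
```

## Scope

`promarch` expects pre-aligned sequences; CAGE tag clustering, TSS calling,
genome annotation, and downstream biological interpretation are out of
scope. Collation distances are position-wise by design — the method's
premise is position-fixed features, so shifted or reverse-complement motif
matching is intentionally absent.
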