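"""Full clustering run on the simulated four-architecture benchmark.

Generates 1000 sequences (clusters A-D with planted motifs, mutation
rate 0.1 at one motif position), runs the chunked iterative clustering,
and compares the final partition with the ground truth.
"""

from promarch import (
    MutationModel,
    RunConfig,
    adjusted_rand_index,
    encode,
    four_cluster_spec,
    generate_dataset,
    run_clustering,
)

seqs, truth = generate_dataset(
    four_cluster_spec(), MutationModel(rate=0.1, positions=1), seed=11
)
V = encode(seqs, order="di")
config = RunConfig(
    chunk_size=500, bound=1e-6, n_runs=30,
    total_itr=2, set_ocollation=[True, True], seed=11,
)
result = run_clustering(V, config)

for rec in result.report["chunks"]:
    print(
        f"iteration {rec['iteration']} chunk ({rec['outer_chunk']},"
        f"{rec['inner_chunk']}): n={rec['size']} selected k={rec['selected_k']}"
    )
sizes = [len(c) for c in result.final.clusters]
print("final cluster sizes:", sizes)
print("ARI vs truth:", round(adjusted_rand_index(truth, result.final.labels(V.n)), 3))

# Iteration 0 processes two chunks of 500 and finds ~4 architectures in
# each; collation merges duplicates across chunks. Iteration 1 re-checks
# each cluster separately (homogeneous clusters stay whole). An ARI near
# 1 means the planted clusters were recovered almost exactly.
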