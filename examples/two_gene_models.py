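"""Classify stochastic two-gene regulatory models from moment time-courses.

Three model classes are simulated exactly (Gillespie with a rising birth
rate): No-I (independent genes), Mono-I (gene B represses gene A), and
Bi-I (mutual repression).  Each instance contributes the mean, variance
and skewness time-courses of both genes, estimated over 200 trajectories;
gene A goes to X and gene B to Y.  Interacting genes of one instance
share a true cluster, the two independent No-I genes get separate ones
(4 classes).  Similarity is the Euclidean distance between min-max
normalized moment courses; association is the mean Granger-causality
p-value over the three moments.
"""

import jointclust as jc

pair = jc.generate_two_gene_data(n_per_model=10, n_trajectories=200, seed=0)
triplet, _ = jc.assembled_for_problem(pair)
joint, coords = jc.qee_transform(triplet)

print(f"dataset: |X| = {pair.m}, |Y| = {pair.n}, true classes = {pair.n_true_clusters}")
result = jc.cluster_embedding(coords, k=4)
score, components = jc.score_result(pair, result.predicted_labels)
print(f"composite ARI = {score:.3f}  "
      f"(X: {components['ari_X']:.3f}, Y: {components['ari_Y']:.3f}, "
      f"pairing: {components['ari_pairing']:.3f})")
print(
    "\nScores around 0.55-0.7 are expected: the unregulated genes (both No-I "
    "genes and Mono-I's gene B) share identical dynamics, so parts of the "
    "partition are only constrained by the weaker association signal."
)
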