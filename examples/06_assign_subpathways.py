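"""Assign candidate genes to sub-pathways by KNN voting on developmental
stage profiles, and cluster the profiles."""

import numpy as np

from pathextend import (
    gen_stage_profiles, hierarchical_cluster, knn_assign, zscore_profiles,
)

seed_prof, seeds, cand_prof, truth = gen_stage_profiles(
    n_seeds_per_class=8, n_candidates=50, noise_sd=0.2, rng_seed=5
)
assignments = knn_assign(cand_prof, seed_prof, seeds, k=5)
acc = np.mean([a.label == truth[a.gene] for a in assignments])
print(f"assigned {len(assignments)} candidates, accuracy vs archetype truth "
      f"= {acc:.2f}")
a = assignments[0]
print(f"example: {a.gene} -> {a.label} "
      f"(votes {a.votes}, nearest seed {a.neighbors[0]})")

clusters = hierarchical_cluster(zscore_profiles(cand_prof), n_clusters=5)
sizes = np.bincount(list(clusters.values()))[1:]
print(f"hierarchical clustering of z-scored profiles: sizes {sizes.tolist()}")
# Each sub-pathway fires at a different developmental window; a candidate
# inherits the label voted for by its 5 nearest seed genes in Euclidean
# distance on z-scored profiles.
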