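"""Cluster samples by their CAZyme profiles with Spearman distances.

log10(x+1) -> Z score per family -> 1 - Spearman rho between samples ->
average-linkage dendrogram.  With disjoint oral/gut strain pools the cut
at k = 2 recovers the body sites.
"""

import pandas as pd

from cazytyping import projection, synthetic_data as sd, transforms

config = sd.SimulationConfig(seed=3, n_subjects_per_phenotype=8)
panel = sd.simulate_reference_panel(config)
cohort = sd.simulate_cohort(config, panel)
matrix = projection.build_abundance_matrix(panel.table, cohort.profile)

logged = transforms.log_transform(matrix.values)
std = transforms.z_standardize(logged)
print(f"{len(std.degenerate)} invariant families flagged (z set to 0)")

x = std.values.drop(columns=std.degenerate)
dist = transforms.spearman_distance(x, axis=0)
dendro = transforms.hierarchical_cluster(dist, method="average")
clusters = dendro.cut(2)

agreement = pd.crosstab(clusters, cohort.metadata["body_site"])
print("\ncluster membership vs body site at k=2:")
print(agreement)
print("\nA clean diagonal means the community split between mouth and gut "
      "dominates the CAZyme profile, as expected with site-specific strains.")
print("\nNewick export (first 120 chars):")
print(dendro.to_newick()[:120], "...")
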