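"""Project genome CAZyme repertoires onto metagenome taxonomic profiles.

The family abundance in a sample is the panel aggregate of
N (gene copies) x R (strain relative abundance) x T (sample read depth).
A tiny two-strain example is worked by hand, then a full synthetic cohort
is projected in one call.
"""

import pandas as pd

from cazytyping import projection, synthetic_data as sd
from cazytyping.annotation_io import GenomeCazymeTable

# hand-sized example: two strains, two families, one sample
idx = pd.Index(["strainA", "strainB"], name="strain_id")
table = GenomeCazymeTable(
    pd.DataFrame({"GH13": [2, 0], "GT2": [1, 4]}, index=idx),
    pd.DataFrame({"genus": "G", "phylum": "P", "genome_size_bp": 3_000_000}, index=idx),
)
abundances = pd.DataFrame({"strainA": [0.5], "strainB": [0.25]},
                          index=pd.Index(["sample1"], name="sample_id"))
profile = projection.TaxonomicProfile(abundances, pd.Series({"sample1": 1_000_000.0}))

matrix = projection.build_abundance_matrix(table, profile, divisor_mode="sum")
print("per-strain contribution of GH13 in sample1:")
print("  strainA: N=2, R=0.5, T=1e6 ->", projection.project_strain(2, 0.5, 1e6))
print("  strainB: N=0, R=0.25       ->", projection.project_strain(0, 0.25, 1e6))
print("sample-level GH13 abundance (sum mode):",
      float(matrix.values.loc["sample1", "GH13"]))

# the same machinery on a full synthetic cohort
config = sd.SimulationConfig(seed=7)
panel = sd.simulate_reference_panel(config)
cohort = sd.simulate_cohort(config, panel)
full = projection.build_abundance_matrix(panel.table, cohort.profile)
print(f"\ncohort matrix: {full.values.shape[0]} samples x "
      f"{full.values.shape[1]} families (divisor mode {full.divisor_mode}, "
      f"panel size {full.panel_size})")
print("Each cell is a read-count-scale abundance; downstream stages "
      "log-transform and standardize it or round it into a count model.")
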