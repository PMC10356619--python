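"""Same-cell density scores and cross-group composition tests.

The density score of a cell type is the mean distance to each cell's 5
nearest same-type neighbours divided by sqrt(area / N_t), the spacing of a
maximally dispersed arrangement: ~0 means tightly aggregated (e.g. follicle
B cells), ~1 means close to maximally spread out.
"""

import pandas as pd

from histoarch.composition import (
    compare_groups, compartment_percentages, same_cell_density,
)
from histoarch.synthetic import default_cohort_config, generate_cohort

maps, _ = generate_cohort(default_cohort_config(n_donors=4, intensity=0.005,
                                                seed=2))

dens = pd.concat([same_cell_density(m).per_type for m in maps])
by_type = dens.groupby("cell_type")["mean_score"].mean().sort_values()
print("mean same-cell density score (low = aggregated):")
print(by_type.round(3).to_string())
print("\nb_cell sits lowest: the follicle packs B cells together, while "
      "enterocytes tile the mucosa almost uniformly.")

comp = compartment_percentages(maps)
donor_vals = (comp[comp["category"] == "all"]
              .groupby(["donor_id", "group", "cell_type"], sort=True)
              ["percentage"].mean().reset_index())
test = compare_groups(donor_vals)
sig = test[test["p"] < 0.05]
print("\ncell types differing between SB and CL (Welch t, raw p < 0.05):")
print(sig[["cell_type", "mean_SB", "mean_CL", "p", "p_adj"]]
      .round(4).to_string(index=False))
print("\nThese are exactly the planted group shifts (smooth muscle, "
      "endothelium, plasma).")
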