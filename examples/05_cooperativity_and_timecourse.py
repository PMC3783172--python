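"""Site-count cooperativity and per-gene time-course normalization.

Simulates genes whose induction strength grows with the number of
elements in their promoter (an additive/cooperative model), tests the
count-vs-induction association, and shows the per-gene centering used
for time-course heat maps.
"""

import numpy as np
import pandas as pd

from crescan import cooperativity, per_gene_normalize

rng = np.random.default_rng(40)
genes = [f"g{i:03d}" for i in range(120)]
site_counts = {g: int(c) for g, c in zip(genes, rng.poisson(1.0, len(genes)))}
log2fc = [1.0 + 0.8 * site_counts[g] + rng.normal(0, 0.5) for g in genes]
table = pd.DataFrame(
    {"gene_id": genes, "condition": "IFN", "time_window": "30-60",
     "log2fc": log2fc, "p_adj": 0.001}
)

res = cooperativity(site_counts, table)
print("median log2 fold change by number of sites in the promoter:")
for cls in ("0", "1", ">1"):
    print(f"  {cls:>2} sites: {res.medians[cls]:.2f}")
print(f"Spearman rho = {res.rho:.2f}, p = {res.p_value:.2g} (n = {res.n})")
print(
    "\nRising medians with site count plus a small correlation p indicate\n"
    "additive/cooperative action of the element.\n"
)

tc = pd.DataFrame(
    rng.normal(8, 1, size=(5, 1))
    + np.sin(np.linspace(0, np.pi, 6))[None, :] * rng.uniform(0.5, 2, size=(5, 1)),
    index=[f"g{i}" for i in range(5)],
    columns=[f"{t}h" for t in range(6)],
)
norm = per_gene_normalize(tc)
print("per-gene normalized log2 values (each row centered on its mean):")
print(norm.round(2).to_string())
print("\nrow sums:", norm.sum(axis=1).round(12).tolist())
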