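"""Digital count normalization and repression calling.

Simulates a treated-vs-mock nCounter-style run with 20 genes carrying
planted 40% repression, applies negative-control background correction
(mean + 2 SD per sample), normalizes on the 7 most stable reference
genes (geometric mean), calls >20% repression, and Fisher-tests the
association between gene class and repression call.
"""

from crescan import call_repression, fisher_exact_test, normalize_run
from crescan.ncounter import dependence_table
from crescan.simulate import generate_ncounter_run

run, truth = generate_ncounter_run(n_targets=40, n_repressed=20, repression=0.4, seed=30)
normalized, refs = normalize_run(run)
print(f"selected reference genes: {', '.join(refs)}")

targets = run.genes_with_role("target")
calls = call_repression(
    normalized, truth["treated_samples"], truth["mock_samples"], genes=targets
)
planted = {g: calls[g] for g in targets if g in truth["repressed"]}
null = {g: calls[g] for g in targets if g not in truth["repressed"]}
print(f"planted repressed genes called: {sum(bool(v) for v in planted.values())}/20")
print(f"null genes mis-called         : {sum(bool(v) for v in null.values())}/20")

table = dependence_table(planted, null)
odds, p = fisher_exact_test(table)
print(f"Fisher exact test             : table {[ [table.a, table.b], [table.c, table.d] ]}, "
      f"p = {p:.3g}")
print(
    "\nA small p says repression calls concentrate in the planted class --\n"
    "the same test used to show IFN-gamma-mediated repression depends on STAT1."
)

# the published tables, for comparison
_, p_dep = fisher_exact_test([[11, 8], [2, 19]])
print(f"\npublished 11/19-vs-2/21 dependence table reproduces p = {p_dep:.4f}")
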