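"""Per-promoter site-count enrichment: regulated set vs background.

Plants the ISRE-like matrix at 2.0 sites/promoter in 60 'regulated'
promoters and 0.5 in 1000 background promoters, scans, counts sites
per promoter in the proximal window, and runs the Mann-Whitney /
Benjamini-Hochberg / pass-criteria stack.
"""

from crescan import enrichment_table, plant_motifs, scan_promoters
from crescan.simulate import generate_promoters, isre_like_pwm

pwm = isre_like_pwm()
proms = generate_promoters(1060, seed=10)
fg, man_fg = plant_motifs(proms[:60], pwm, lam=2.0, seed=11)
bg, man_bg = plant_motifs(proms[60:], pwm, lam=0.5, seed=12)

hits = scan_promoters(pwm, fg + bg)
(result,) = enrichment_table(
    hits, [p.gene_id for p in fg], [p.gene_id for p in bg], matrix_ids=[pwm.matrix_id]
)

print(f"matrix                 : {result.matrix_id}")
print(f"mean sites/promoter (d): {result.d:.3f} in the regulated set")
print(f"mean sites/promoter (b): {result.b:.3f} in the background")
print(f"log2(d/b) enrichment   : {result.enrichment:.2f}  (2.0 = 4-fold)")
print(f"promoters with sites   : {result.genes_with_sites_fg}/{result.n_fg} "
      f"({result.pct_with_sites:.0f}%)")
print(f"MWW p (BH-adjusted)    : {result.p_adj:.3g}")
print(f"passes all criteria    : {result.passes}")
print(
    "\nThe pass flag needs >=2-fold enrichment, corrected p < 0.005, and\n"
    "sites in >=5 promoters covering >=25% of the regulated set."
)
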