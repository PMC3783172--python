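"""Cumulative positional distribution of sites upstream of the TSS.

Plants TSS-proximal (exponentially decaying) sites in a regulated set
and uniformly distributed sites in a background set over 20 kb
upstream regions, then profiles the cumulative fraction of genes with
at least one site within each 200-bp distance bin.
"""

from crescan import plant_motifs, positional_profile, scan_promoters
from crescan.simulate import generate_promoters, isre_like_pwm

pwm = isre_like_pwm()
window = (-20_000, 100)
fg = generate_promoters(80, seed=20, window=window, prefix="reg")
bg = generate_promoters(200, seed=21, window=window, prefix="bgd")

fg, _ = plant_motifs(fg, pwm, lam=1.2, seed=22, positional="exponential", decay_bp=1500)
bg, _ = plant_motifs(bg, pwm, lam=1.2, seed=23, positional="uniform")

hits = scan_promoters(pwm, fg + bg)
prof = positional_profile(hits, [p.gene_id for p in fg], [p.gene_id for p in bg])

print("upstream distance   regulated   background   difference")
for k in (0, 4, 9, 24, 49, 99):
    print(
        f"  <= {int(prof.bin_edges[k]):6d} bp      "
        f"{100 * prof.cum_fg[k]:5.1f}%      {100 * prof.cum_bg[k]:5.1f}%      "
        f"{100 * prof.diff[k]:+5.1f}%"
    )
print(
    "\nThe regulated set accumulates sites close to the TSS (the curves'\n"
    "difference peaks in the proximal bins), while uniform background\n"
    "sites build up only gradually over the full 20 kb."
)
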