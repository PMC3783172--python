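"""Thin matplotlib renderers for logos, positional profiles and
time-course heat maps.  These are presentation helpers over tested
numeric outputs; nothing here computes statistics."""

from __future__ import annotations

import numpy as np

from .motifs import ALPHABET, information_vector

_LOGO_COLORS = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}


def plot_logo(counts: np.ndarray, ax=None):
    """Information-content sequence logo from an L x 4 count matrix
    (e.g. the a-posteriori counts over matched windows).

    Letters are drawn as stacked bars scaled by the column's
    information content in bits; a proper glyph-stretching logo needs a
    dedicated renderer, but the bar form preserves the quantitative
    content.
    """
    import matplotlib.pyplot as plt

    counts = np.asarray(counts, dtype=float)
    sums = counts.sum(axis=1)
    freqs = np.divide(
        counts, sums[:, None], out=np.full_like(counts, 0.25), where=sums[:, None] > 0
    )
    info_bits = information_vector(freqs) / np.log(2.0)
    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, counts.shape[0] * 0.5), 2.5))
    for pos in range(counts.shape[0]):
        bottom = 0.0
        order = np.argsort(freqs[pos])
        for b in order:
            h = freqs[pos, b] * info_bits[pos]
            if h <= 0:
                continue
            ax.bar(
                pos + 1, h, bottom=bottom, width=0.85,
                color=_LOGO_COLORS[ALPHABET[b]], edgecolor="none",
            )
            if h > 0.15:
                ax.text(
                    pos + 1, bottom + h / 2, ALPHABET[b],
                    ha="center", va="center", fontsize=8, color="white",
                )
            bottom += h
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    ax.set_ylim(0, 2)
    ax.set_xticks(range(1, counts.shape[0] + 1))
    return ax


def plot_positional_profile(profile, ax=None):
    """Cumulative fraction curves (foreground, background, difference)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    kb = profile.bin_edges / 1000.0
    ax.plot(kb, 100 * profile.cum_fg, label="regulated genes")
    ax.plot(kb, 100 * profile.cum_bg, label="random background")
    ax.plot(kb, 100 * profile.diff, "--", label="difference")
    ax.set_xlabel("distance upstream of TSS (kb)")
    ax.set_ylabel("% genes with >=1 site")
    ax.legend()
    ax.set_title(profile.matrix_id)
    return ax


def plot_timecourse_heatmap(per_gene_normalized, ax=None, method="average"):
    """Heat map of per-gene-normalized log2 values with genes ordered by
    Euclidean-distance hierarchical clustering."""
    import matplotlib.pyplot as plt
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import pdist

    mat = per_gene_normalized.to_numpy()
    if mat.shape[0] > 2:
        order = hierarchy.leaves_list(
            hierarchy.linkage(pdist(mat, metric="euclidean"), method=method)
        )
    else:
        order = np.arange(mat.shape[0])
    if ax is None:
        _, ax = plt.subplots()
    vmax = np.abs(mat).max() or 1.0
    im = ax.imshow(mat[order], aspect="auto", cmap="RdYlBu_r", vmin=-vmax, vmax=vmax)
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels(per_gene_normalized.index[order], fontsize=6)
    ax.set_xticks(range(mat.shape[1]))
    ax.set_xticklabels(per_gene_normalized.columns, rotation=90, fontsize=6)
    ax.figure.colorbar(im, ax=ax, label="per-gene normalized log2")
    return ax
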