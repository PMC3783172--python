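"""Per-promoter site-count enrichment statistics and positional profiles.

The central comparison: for one matrix, count predicted sites per
promoter in a regulated gene set (foreground) and in background
promoters, compare the two count distributions with a two-sided
Mann-Whitney-Wilcoxon test, adjust p-values across matrices by
Benjamini-Hochberg, and report the enrichment log2(d/b) where d and b
are the mean sites per promoter in foreground and background.  A matrix
"passes" when enrichment >= 1 (i.e. at least 2-fold), adjusted
P < 0.005, and sites occur in at least 5 foreground promoters covering
at least 25% of the set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .motifs import MotifHit
from .promoters import PROXIMAL_WINDOW

# the published pass criteria: 2-fold enrichment, corrected P < 0.005,
# sites in >= 5 promoters and >= 25% of the gene subset
PASS_MIN_LOG2_ENRICHMENT = 1.0
PASS_MAX_P_ADJ = 0.005
PASS_MIN_GENES_WITH_SITES = 5
PASS_MIN_PCT_WITH_SITES = 25.0


def count_sites(
    hits: list[MotifHit],
    gene_set: list[str],
    window: tuple[int, int] = PROXIMAL_WINDOW,
) -> dict[str, int]:
    """Sites per gene for already-thresholded hits whose start offset
    lies in the half-open window; genes without hits get 0."""
    counts = {g: 0 for g in gene_set}
    lo, hi = window
    for h in hits:
        if h.promoter_id in counts and lo <= h.offset < hi:
            counts[h.promoter_id] += 1
    return counts


@dataclass
class EnrichmentStats:
    p_raw: float
    d: float  # mean sites/promoter, foreground
    b: float  # mean sites/promoter, background
    enrichment: float  # log2(d/b); NaN when b == 0
    pct_with_sites: float
    genes_with_sites_fg: int
    n_fg: int
    # diagnostic ratio with the background mean floored at one site over
    # the whole background set, reported when b == 0
    diagnostic_enrichment: float = math.nan


def motif_enrichment(
    fg: dict[str, int],
    bg: dict[str, int],
    method: str = "auto",
) -> EnrichmentStats:
    """Two-sided MWW comparison of per-promoter site counts.

    ``method``: 'auto' uses exact enumeration when both sets have at
    most 8 genes and the pooled counts are tie-free, otherwise the
    normal approximation with tie-corrected variance (counts are heavily
    tied in practice); 'exact'/'asymptotic' force a choice.
    """
    if len(fg) < 2 or len(bg) < 2:
        raise ValueError("need at least 2 genes in each of fg and bg")
    x = np.fromiter(fg.values(), dtype=float)
    y = np.fromiter(bg.values(), dtype=float)
    if method == "auto":
        untied = len(set(x) | set(y)) == x.size + y.size
        method = "exact" if (x.size <= 8 and y.size <= 8 and untied) else "asymptotic"
    p_raw = float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )
    d = float(x.mean())
    b = float(y.mean())
    if b > 0:
        enr = float(np.log2(d / b)) if d > 0 else -math.inf
        diag = enr
    else:
        enr = math.nan
        diag = float(np.log2(d / (1.0 / y.size))) if d > 0 else math.nan
    with_sites = int((x > 0).sum())
    return EnrichmentStats(
        p_raw=p_raw,
        d=d,
        b=b,
        enrichment=enr,
        pct_with_sites=100.0 * with_sites / x.size,
        genes_with_sites_fg=with_sites,
        n_fg=x.size,
        diagnostic_enrichment=diag,
    )


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EnrichmentResult:
    """Foreground-vs-background summary for one matrix (one table row)."""

    matrix_id: str
    n_fg: int
    genes_with_sites_fg: int
    pct_with_sites: float
    d: float
    b: float
    enrichment: float
    p_raw: float
    p_adj: float = math.nan
    passes: bool = False


def apply_pass_criteria(
    results: list[EnrichmentResult],
    min_enrichment: float = PASS_MIN_LOG2_ENRICHMENT,
    max_p_adj: float = PASS_MAX_P_ADJ,
    min_genes: int = PASS_MIN_GENES_WITH_SITES,
    min_pct: float = PASS_MIN_PCT_WITH_SITES,
) -> list[EnrichmentResult]:
    """Set the ``passes`` flag; an undefined (NaN) enrichment never passes."""
    out = []
    for r in results:
        ok = (
            not math.isnan(r.enrichment)
            and r.enrichment >= min_enrichment
            and r.p_adj < max_p_adj
            and r.genes_with_sites_fg >= min_genes
            and r.pct_with_sites >= min_pct
        )
        out.append(replace(r, passes=bool(ok)))
    return out


def default_factor_groups(matrix_ids) -> dict[str, str]:
    """Group matrices by factor-name prefix of the matrix ID.

    'V$NFKB_Q6_01' and 'V$NFKB_C' share the group 'NFKB'; IDs without
    an underscore are their own group.  The published grouping of
    redundant matrices was editorial, so callers may pass their own
    mapping instead.
    """
    groups = {}
    for mid in matrix_ids:
        stem = mid.split("$", 1)[-1]
        groups[mid] = stem.split("_", 1)[0]
    return groups


def collapse_redundant(
    results: list[EnrichmentResult],
    factor_groups: dict[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Keep one result per redundancy group: smallest p_adj, ties broken
    by smallest p_raw then matrix_id."""
    if factor_groups is None:
        factor_groups = default_factor_groups(r.matrix_id for r in results)
    best: dict[str, EnrichmentResult] = {}
    for r in results:
        g = factor_groups.get(r.matrix_id, r.matrix_id)
        cur = best.get(g)
        key = (r.p_adj, r.p_raw, r.matrix_id)
        if cur is None or key < (cur.p_adj, cur.p_raw, cur.matrix_id):
            best[g] = r
    return sorted(best.values(), key=lambda r: r.matrix_id)


def enrichment_table(
    hits: list[MotifHit],
    fg_genes: list[str],
    bg_genes: list[str],
    window: tuple[int, int] = PROXIMAL_WINDOW,
    matrix_ids: list[str] | None = None,
    method: str = "auto",
) -> list[EnrichmentResult]:
    """Full per-matrix enrichment summary with BH adjustment and pass flags.

    ``matrix_ids`` fixes the set of matrices tested (matrices with no
    hits at all still enter the FDR correction); by default the
    matrices observed in ``hits`` are used.
    """
    by_matrix: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_matrix.setdefault(h.matrix_id, []).append(h)
    if matrix_ids is None:
        matrix_ids = sorted(by_matrix)
    results = []
    for mid in matrix_ids:
        mh = by_matrix.get(mid, [])
        st = motif_enrichment(
            count_sites(mh, fg_genes, window),
            count_sites(mh, bg_genes, window),
            method=method,
        )
        results.append(
            EnrichmentResult(
                matrix_id=mid,
                n_fg=st.n_fg,
                genes_with_sites_fg=st.genes_with_sites_fg,
                pct_with_sites=st.pct_with_sites,
                d=st.d,
                b=st.b,
                enrichment=st.enrichment,
                p_raw=st.p_raw,
            )
        )
    adj = adjust_fdr([r.p_raw for r in results])
    results = [replace(r, p_adj=float(a)) for r, a in zip(results, adj)]
    return apply_pass_criteria(results)


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.matrix_id,
                r.n_fg,
                r.genes_with_sites_fg,
                r.pct_with_sites,
                r.d,
                r.b,
                r.enrichment,
                r.p_raw,
                r.p_adj,
                r.passes,
            )
            for r in results
        ],
        columns=[
            "matrix_id",
            "n_fg",
            "genes_with_sites_fg",
            "pct_with_sites",
            "d",
            "b",
            "log2_enrichment",
            "p_raw",
            "p_adj",
            "passes",
        ],
    )


# ---------------------------------------------------------------------------
# Positional profiling over deep upstream regions


@dataclass
class PositionalProfile:
    """Cumulative fraction of genes with >=1 site within each distance
    of the TSS, in 200-bp bins over 20 kb upstream, for foreground and
    background, plus their difference."""

    matrix_id: str
    bin_edges: np.ndarray
    cum_fg: np.ndarray
    cum_bg: np.ndarray

    @property
    def diff(self) -> np.ndarray:
        return self.cum_fg - self.cum_bg


def _cumulative_fraction(
    hits: list[MotifHit], genes: list[str], edges: np.ndarray
) -> np.ndarray:
    # distance of a hit = bases upstream of the TSS of its start; hits at
    # or downstream of the TSS count at distance 0 (first bin onwards)
    nearest: dict[str, float] = {}
    gene_set = set(genes)
    for h in hits:
        if h.promoter_id not in gene_set:
            continue
        dist = max(0, -h.offset)
        if dist < nearest.get(h.promoter_id, math.inf):
            nearest[h.promoter_id] = dist
    if not genes:
        return np.zeros(edges.size)
    dists = np.array([nearest.get(g, math.inf) for g in genes])
    return (dists[None, :] <= edges[:, None]).mean(axis=1)


def positional_profile(
    hits: list[MotifHit],
    fg_genes: list[str],
    bg_genes: list[str],
    bin_size: int = 200,
    depth: int = 20_000,
    matrix_id: str | None = None,
) -> PositionalProfile:
    """Cumulative abundance curves from hits on deep upstream regions."""
    if matrix_id is not None:
        hits = [h for h in hits if h.matrix_id == matrix_id]
    else:
        ids = {h.matrix_id for h in hits}
        matrix_id = ids.pop() if len(ids) == 1 else "combined"
    edges = np.arange(bin_size, depth + 1, bin_size, dtype=float)
    return PositionalProfile(
        matrix_id=matrix_id,
        bin_edges=edges,
        cum_fg=_cumulative_fraction(hits, fg_genes, edges),
        cum_bg=_cumulative_fraction(hits, bg_genes, edges),
    )


def profile_to_frame(profile: PositionalProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "upstream_bp": profile.bin_edges.astype(int),
            "cum_fg": profile.cum_fg,
            "cum_bg": profile.cum_bg,
            "diff": profile.diff,
        }
    )


# ---------------------------------------------------------------------------
# Gene-set selection, induction-strength cross-tabs, cooperativity


def select_regulated(
    table: pd.DataFrame,
    min_fold: float = 2.0,
    max_p: float = 0.01,
    direction: str = "both",
) -> list[str]:
    """Genes significantly regulated: |log2fc| > log2(min_fold) and
    adjusted p < max_p, optionally restricted to one direction.

    ``table`` needs columns gene_id, log2fc, p_adj (condition and
    time_window columns pass through untouched; filter beforehand to
    restrict them).
    """
    cut = math.log2(min_fold)
    sig = table["p_adj"] < max_p
    if direction == "up":
        keep = sig & (table["log2fc"] > cut)
    elif direction == "down":
        keep = sig & (table["log2fc"] < -cut)
    elif direction == "both":
        keep = sig & (table["log2fc"].abs() > cut)
    else:
        raise ValueError(f"direction must be up/down/both, got {direction!r}")
    return sorted(table.loc[keep, "gene_id"].unique())


def strength_time_crosstab(
    table: pd.DataFrame,
    element_sites: dict[str, dict[str, int]],
    fold_cuts: tuple[float, ...] = (2, 4, 8, 16),
) -> pd.DataFrame:
    """Percent of genes above each induction cut that carry each element.

    For every (time_window, cut): among genes with log2fc > log2(cut),
    the percentage harbouring >=1 site of each element in the proximal
    window.  Strata with no gene above the cut are emitted as NaN with
    a warning.  ``element_sites`` maps element name -> per-gene site
    counts (a SiteCountVector).
    """
    rows = []
    for tw, sub in table.groupby("time_window", sort=True):
        for cut in fold_cuts:
            above = sub.loc[sub["log2fc"] > math.log2(cut), "gene_id"].unique()
            row: dict[str, object] = {"time_window": tw, "fold_cut": cut, "n_genes": len(above)}
            for name, counts in element_sites.items():
                if len(above) == 0:
                    warnings.warn(
                        f"no genes induced >{cut}-fold in window {tw}; "
                        f"percentage undefined"
                    )
                    row[name] = math.nan
                else:
                    row[name] = 100.0 * sum(
                        1 for g in above if counts.get(g, 0) >= 1
                    ) / len(above)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CooperativityResult:
    medians: dict[str, float]  # log2fc medians for site-count classes 0, 1, >1
    rho: float
    p_value: float
    n: int


def cooperativity(
    site_counts: dict[str, int], table: pd.DataFrame
) -> CooperativityResult:
    """Induction strength versus number of elements in the promoter.

    Genes are classed by site count (0, 1, >1) and the median log2 fold
    change per class is reported, alongside a two-sided Spearman rank
    correlation between the raw site count and log2fc.  Degenerate
    inputs (constant counts or constant fold changes) are reported as
    rho = 0, p = 1.
    """
    sub = table[table["gene_id"].isin(site_counts)]
    genes = sub["gene_id"].to_numpy()
    fc = sub["log2fc"].to_numpy(dtype=float)
    counts = np.array([site_counts[g] for g in genes], dtype=float)
    medians = {}
    for label, mask in (
        ("0", counts == 0),
        ("1", counts == 1),
        (">1", counts > 1),
    ):
        medians[label] = float(np.median(fc[mask])) if mask.any() else math.nan
    if counts.size < 2 or np.all(counts == counts[0]) or np.all(fc == fc[0]):
        rho, p = 0.0, 1.0
    else:
        res = stats.spearmanr(counts, fc)
        rho, p = float(res.statistic), float(res.pvalue)
    return CooperativityResult(medians=medians, rho=rho, p_value=p, n=int(counts.size))


def per_gene_normalize(log2_matrix: pd.DataFrame, method: str = "center") -> pd.DataFrame:
    """Per-gene normalization of a gene x timepoint log2 expression matrix.

    'center' subtracts each gene's row mean (every output row sums to
    0); 'zscore' additionally divides by the row standard deviation
    (ddof=1; constant rows stay at 0).
    """
    centered = log2_matrix.sub(log2_matrix.mean(axis=1), axis=0)
    if method == "center":
        return centered
    if method == "zscore":
        sd = log2_matrix.std(axis=1, ddof=1).replace(0.0, 1.0)
        return centered.div(sd, axis=0)
    raise ValueError(f"method must be 'center' or 'zscore', got {method!r}")
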