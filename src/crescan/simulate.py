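"""Synthetic inputs with known ground truth for every pipeline stage.

Everything downstream of this module is testable without external
downloads: random genomes with annotated TSSs, promoters with
PWM-sampled motifs planted at controlled Poisson densities and
positional distributions, differential-expression tables with
designated induced/repressed gene sets, and nCounter-style count runs
with negative controls, reference genes and planted repression.  Every
generator is fully deterministic given its seed and records a manifest
sufficient to predict expected pipeline outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motifs import PWM, reverse_complement
from .ncounter import (
    ROLE_NEGATIVE,
    ROLE_REFERENCE,
    ROLE_TARGET,
    NCounterRun,
)
from .promoters import PROXIMAL_WINDOW, PromoterRecord, TssRecord

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Study-condition defaults for a full synthetic input bundle.

    The planted-motif densities (2.0 sites/promoter in regulated genes
    vs 0.5 in background), set sizes (60 regulated vs 1000 background
    promoters), the (-600, +100) promoter window and the DE selection
    structure mirror the conditions the enrichment statistics are
    designed for.
    """

    n_fg: int = 60
    n_bg: int = 1000
    window: tuple[int, int] = PROXIMAL_WINDOW
    gc: float = 0.5
    lam_fg: float = 2.0
    lam_bg: float = 0.5
    positional: str = "uniform"  # or "exponential"
    decay_bp: float = 2000.0
    de_effect: float = 1.5
    de_noise_sd: float = 0.3
    ncounter_background_mean: float = 8.0
    ncounter_noise_cv: float = 0.1
    seed: int = 0


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def random_pwm(
    length: int,
    seed: int,
    matrix_id: str = "V$SYN_01",
    dominance: float = 0.7,
    total: float = 100.0,
) -> PWM:
    """A random count matrix with one dominant base per position."""
    rng = np.random.default_rng(seed)
    counts = np.full((length, 4), total * (1 - dominance) / 3)
    for i, b in enumerate(rng.integers(0, 4, size=length)):
        counts[i, b] = total * dominance
    return PWM(matrix_id=matrix_id, counts=counts, factor_name=matrix_id)


def _fixed_pwm(matrix_id: str, factor: str, consensus: str, dominance: float) -> PWM:
    lut = {b: i for i, b in enumerate("ACGT")}
    counts = np.full((len(consensus), 4), 100.0 * (1 - dominance) / 3)
    for i, b in enumerate(consensus):
        counts[i, lut[b]] = 100.0 * dominance
    return PWM(matrix_id=matrix_id, counts=counts, factor_name=factor)


def isre_like_pwm() -> PWM:
    """A sharp 12-position matrix shaped like an IFN-stimulated response
    element (consensus AGTTTCACTTTC); the package's standard planted
    fixture."""
    return _fixed_pwm("V$ISRE_01", "ISRE/IRF", "AGTTTCACTTTC", 0.97)


def gas_like_pwm() -> PWM:
    """A gamma-activated-sequence-like palindromic matrix (TTCCGGGAA)."""
    return _fixed_pwm("V$GAS_01", "GAS/STAT1", "TTCCGGGAA", 0.95)


def nfkb_like_pwm() -> PWM:
    return _fixed_pwm("V$NFKB_01", "NF-kB", "GGGACTTTCC", 0.95)


def generate_matrix_collection(n: int = 639, seed: int = 0) -> list[PWM]:
    """A TRANSFAC-style collection of n distinct random matrices."""
    rng = np.random.default_rng(seed)
    pwms = []
    for i in range(n):
        length = int(rng.integers(8, 16))
        dom = float(rng.uniform(0.6, 0.95))
        pwms.append(
            random_pwm(
                length,
                seed=int(rng.integers(0, 2**31 - 1)),
                matrix_id=f"V$SYN{i:04d}_01",
                dominance=dom,
            )
        )
    return pwms


# ---------------------------------------------------------------------------
# Genomes, TSS tables and promoters


def generate_genome_and_tss(
    n_genes: int,
    seed: int,
    gc: float = 0.5,
    window: tuple[int, int] = PROXIMAL_WINDOW,
    spacing: int = 500,
    chrom: str = "chr1",
) -> tuple[dict[str, str], list[TssRecord]]:
    """An i.i.d.-base contig with non-overlapping genes on both strands.

    Genes are laid out with at least one full window plus ``spacing``
    between consecutive TSSs, so every promoter is extractable without
    truncation and the deduplication step keeps all of them.
    """
    rng = np.random.default_rng(seed)
    # a gene's window lies within [tss - reach, tss + reach] on either
    # strand, so this TSS separation guarantees pairwise non-overlap
    reach = max(abs(window[0]), abs(window[1])) + 1
    margin = 2 * reach + spacing
    length = margin * (n_genes + 1)
    seq = _random_bases(rng, length, gc)
    records = []
    for i in range(n_genes):
        strand = "+" if i % 2 == 0 else "-"
        tss = margin * (i + 1)
        records.append(TssRecord(f"gene{i:04d}", chrom, tss, strand))
    return {chrom: seq}, records


def generate_promoters(
    n: int,
    seed: int,
    gc: float = 0.5,
    window: tuple[int, int] = PROXIMAL_WINDOW,
    prefix: str = "gene",
    chrom: str = "synthetic",
) -> list[PromoterRecord]:
    """Standalone random promoters (no genome), already in gene orientation."""
    rng = np.random.default_rng(seed)
    span = window[1] - window[0]
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=(n, span), p=p)
    out = []
    for i in range(n):
        out.append(
            PromoterRecord(
                gene_id=f"{prefix}{i:04d}",
                chrom=chrom,
                tss=0,
                strand="+",
                start_rel=window[0],
                end_rel=window[1],
                sequence=_BASES[idx[i]].tobytes().decode("ascii"),
            )
        )
    return out


def write_fasta(genome: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_bed6(tss_records: list[TssRecord], path) -> None:
    """BED6 where the interval [tss, tss+1) marks the TSS base; the
    strand-aware 5' end of that interval is the TSS on both strands."""
    with open(path, "w") as fh:
        for r in tss_records:
            fh.write(f"{r.chrom}\t{r.tss}\t{r.tss + 1}\t{r.gene_id}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# Motif planting


@dataclass(frozen=True)
class PlantedSite:
    gene_id: str
    matrix_id: str
    offset: int  # TSS-relative start, gene orientation
    strand: str
    sequence: str  # as written into the promoter (gene orientation)


@dataclass
class PlantManifest:
    """Ground truth for planted motifs; sufficient to predict expected
    per-gene site counts and positional profiles."""

    plants: list[PlantedSite] = field(default_factory=list)
    lam: float = 0.0
    seed: int = 0

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.plants:
            out[p.gene_id] = out.get(p.gene_id, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.gene_id, p.matrix_id, p.offset, p.strand, p.sequence) for p in self.plants],
            columns=["gene_id", "matrix_id", "offset", "strand", "sequence"],
        )


def _sample_site(rng: np.random.Generator, pwm: PWM) -> str:
    idx = [rng.choice(4, p=row) for row in pwm.frequencies]
    return "".join("ACGT"[i] for i in idx)


def plant_motifs(
    promoters: list[PromoterRecord],
    pwm: PWM,
    lam: float,
    seed: int,
    positional: str = "uniform",
    decay_bp: float = 2000.0,
    consensus_only: bool = False,
    max_tries: int = 50,
) -> tuple[list[PromoterRecord], PlantManifest]:
    """Plant Poisson(lam) PWM-sampled instances per promoter.

    Offsets are drawn uniformly over the promoter window, or with
    TSS-proximal exponentially decaying upstream distances
    (``positional='exponential'`` with mean ``decay_bp``).  Instances
    never overwrite one another; an instance that cannot be placed
    without overlap after ``max_tries`` draws is dropped (and so absent
    from the manifest).  Input records are not mutated.
    """
    if positional not in ("uniform", "exponential"):
        raise ValueError(f"unknown positional distribution {positional!r}")
    rng = np.random.default_rng(seed)
    L = len(pwm)
    manifest = PlantManifest(lam=lam, seed=seed)
    out = []
    for prom in promoters:
        n_sites = int(rng.poisson(lam))
        seq = list(prom.sequence)
        occupied: list[tuple[int, int]] = []
        lo, hi = 0, len(seq) - L  # inclusive start range within the sequence
        if hi < lo:
            out.append(prom)
            continue
        for _ in range(n_sites):
            for _try in range(max_tries):
                if positional == "uniform":
                    j = int(rng.integers(lo, hi + 1))
                else:
                    dist = rng.exponential(decay_bp)
                    # map an upstream distance to a sequence index
                    j = int(np.clip(-prom.start_rel - dist - L, lo, hi))
                if all(j + L <= s or j >= e for s, e in occupied):
                    break
            else:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            site = pwm.consensus if consensus_only else _sample_site(rng, pwm)
            written = site if strand == "+" else reverse_complement(site)
            seq[j : j + L] = written
            occupied.append((j, j + L))
            manifest.plants.append(
                PlantedSite(
                    gene_id=prom.gene_id,
                    matrix_id=pwm.matrix_id,
                    offset=prom.start_rel + j,
                    strand=strand,
                    sequence=written,
                )
            )
        out.append(
            PromoterRecord(
                gene_id=prom.gene_id,
                chrom=prom.chrom,
                tss=prom.tss,
                strand=prom.strand,
                start_rel=prom.start_rel,
                end_rel=prom.end_rel,
                sequence="".join(seq),
                truncated=prom.truncated,
            )
        )
    return out, manifest


# ---------------------------------------------------------------------------
# Differential-expression tables


def generate_de_table(
    n_up: int = 30,
    n_down: int = 20,
    n_null: int = 950,
    effect: float = 1.5,
    noise_sd: float = 0.3,
    seed: int = 0,
    condition: str = "IFN",
    time_window: str = "30-60",
    gene_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """A DE table with designated induced/repressed truth sets.

    Up/down genes get log2fc ~ Normal(+/-effect, noise_sd) and small
    adjusted p; nulls get log2fc ~ Normal(0, noise_sd) and large p, so
    at zero noise the >2-fold / p<0.01 selection recovers the truth
    sets exactly.
    """
    rng = np.random.default_rng(seed)
    n = n_up + n_down + n_null
    if gene_ids is None:
        gene_ids = [f"gene{i:04d}" for i in range(n)]
    if len(gene_ids) != n:
        raise ValueError(f"need {n} gene ids, got {len(gene_ids)}")
    up = set(gene_ids[:n_up])
    down = set(gene_ids[n_up : n_up + n_down])
    mu = np.concatenate([np.full(n_up, effect), np.full(n_down, -effect), np.zeros(n_null)])
    log2fc = mu + (rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0)
    p_adj = np.concatenate(
        [rng.uniform(1e-6, 0.005, size=n_up + n_down), rng.uniform(0.02, 1.0, size=n_null)]
    )
    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "condition": condition,
            "time_window": time_window,
            "log2fc": log2fc,
            "p_adj": p_adj,
        }
    )
    return table, {"up": up, "down": down}


# ---------------------------------------------------------------------------
# Benchmark experiments under the standard study conditions


def planted_enrichment_replicates(
    n_replicates: int,
    seed: int,
    lam_fg: float = 2.0,
    lam_bg: float = 0.5,
    n_fg: int = 60,
    n_bg: int = 1000,
    gc: float = 0.5,
):
    """Replicate the planted-motif enrichment experiment end to end.

    Each replicate plants Poisson-density sites of the ISRE-like fixture
    matrix in fresh random promoters (density lam_fg in the n_fg
    foreground set, lam_bg in the n_bg background), scans both strands
    at the default thresholds, and runs the full count/MWW/FDR/criteria
    stack.  Returns one EnrichmentResult per replicate.
    """
    from .enrichment import enrichment_table
    from .motifs import scan_promoters

    pwm = isre_like_pwm()
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_replicates):
        s1, s2, s3 = (int(x) for x in child.generate_state(3) % (2**31 - 1))
        proms = generate_promoters(n_fg + n_bg, seed=s1, gc=gc)
        fg_recs, _ = plant_motifs(proms[:n_fg], pwm, lam_fg, seed=s2)
        bg_recs, _ = plant_motifs(proms[n_fg:], pwm, lam_bg, seed=s3)
        hits = scan_promoters(pwm, fg_recs + bg_recs)
        res = enrichment_table(
            hits,
            [p.gene_id for p in fg_recs],
            [p.gene_id for p in bg_recs],
            matrix_ids=[pwm.matrix_id],
        )
        out.append(res[0])
    return out


def null_mww_type1_rate(
    n_replicates: int = 500,
    seed: int = 0,
    lam: float = 1.0,
    n_fg: int = 50,
    n_bg: int = 500,
    alpha: float = 0.05,
) -> float:
    """Fraction of null replicates with MWW p below alpha.

    Foreground and background per-promoter site counts are drawn from
    the same Poisson(lam), so the rejection rate estimates the test's
    type-I error at the study's typical set sizes.
    """
    from .enrichment import motif_enrichment

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        fg = {f"f{i}": int(c) for i, c in enumerate(rng.poisson(lam, n_fg))}
        bg = {f"b{i}": int(c) for i, c in enumerate(rng.poisson(lam, n_bg))}
        if motif_enrichment(fg, bg).p_raw < alpha:
            hits += 1
    return hits / n_replicates


# ---------------------------------------------------------------------------
# nCounter runs


def generate_ncounter_run(
    n_targets: int = 40,
    n_repressed: int = 19,
    repression: float = 0.4,
    n_negatives: int = 6,
    n_ref_candidates: int = 10,
    n_stable_refs: int = 7,
    n_replicates: int = 4,
    background_mean: float = 8.0,
    noise_cv: float = 0.1,
    ref_noisy_cv: float = 0.5,
    scale_range: tuple[float, float] = (0.7, 1.4),
    seed: int = 0,
    cell_line: str = "NIH-3T3",
) -> tuple[NCounterRun, dict]:
    """A treated-vs-mock digital counting run with planted repression.

    Counts = Poisson background + per-sample scale factor x log-normal
    signal.  ``n_repressed`` target genes lose ``repression`` of their
    baseline in treated samples.  ``n_stable_refs`` reference
    candidates vary only with the global noise CV; the rest get
    ``ref_noisy_cv``.  In the noiseless limit (noise_cv = 0) the
    background is deterministic and normalization recovers the planted
    repression fractions exactly.
    """
    if not 0 <= n_repressed <= n_targets:
        raise ValueError("n_repressed must not exceed n_targets")
    rng = np.random.default_rng(seed)
    samples = [f"{t}_{r + 1}" for t in ("treated", "mock") for r in range(n_replicates)]
    treatments = ["treated"] * n_replicates + ["mock"] * n_replicates

    targets = [f"tgt{i:03d}" for i in range(n_targets)]
    refs = [f"ref{i:02d}" for i in range(n_ref_candidates)]
    negs = [f"neg{i:02d}" for i in range(n_negatives)]
    repressed = set(targets[:n_repressed])

    base_t = 2.0 ** rng.uniform(7, 12, size=n_targets)
    base_r = 2.0 ** rng.uniform(8, 11, size=n_ref_candidates)
    scales = rng.uniform(*scale_range, size=len(samples))

    def lognorm(cv, size):
        if cv <= 0:
            return np.ones(size)
        sigma = float(np.sqrt(np.log1p(cv**2)))
        return rng.lognormal(-0.5 * sigma**2, sigma, size=size)

    n_samples = len(samples)
    expect_t = np.tile(base_t[:, None], (1, n_samples))
    for i, g in enumerate(targets):
        if g in repressed:
            for j, tr in enumerate(treatments):
                if tr == "treated":
                    expect_t[i, j] *= 1.0 - repression
    sig_t = expect_t * lognorm(noise_cv, expect_t.shape)
    ref_cv = np.where(np.arange(n_ref_candidates) < n_stable_refs, noise_cv, ref_noisy_cv)
    sig_r = np.empty((n_ref_candidates, n_samples))
    for i in range(n_ref_candidates):
        sig_r[i] = base_r[i] * lognorm(float(ref_cv[i]), n_samples)

    signal = np.vstack([sig_t, sig_r]) * scales[None, :]
    if noise_cv > 0:
        bg_all = rng.poisson(background_mean, size=(n_targets + n_ref_candidates, n_samples))
        bg_neg = rng.poisson(background_mean, size=(n_negatives, n_samples))
    else:
        bg_all = np.full((n_targets + n_ref_candidates, n_samples), background_mean)
        bg_neg = np.full((n_negatives, n_samples), background_mean)

    counts = pd.DataFrame(
        np.vstack([signal + bg_all, bg_neg]),
        index=targets + refs + negs,
        columns=samples,
    )
    roles = (
        {g: ROLE_TARGET for g in targets}
        | {g: ROLE_REFERENCE for g in refs}
        | {g: ROLE_NEGATIVE for g in negs}
    )
    meta = pd.DataFrame(
        {
            "cell_line": cell_line,
            "treatment": treatments,
            "replicate": [int(s.split("_")[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    truth = {
        "repressed": repressed,
        "repression": repression,
        "scale_factors": dict(zip(samples, scales)),
        "stable_references": refs[:n_stable_refs],
        "treated_samples": samples[:n_replicates],
        "mock_samples": samples[n_replicates:],
    }
    return NCounterRun(counts=counts, gene_roles=roles, sample_meta=meta), truth
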