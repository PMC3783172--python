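"""End-to-end orchestration: file-based runs of the enrichment and
nCounter stages, plus a one-call synthetic input bundle.

Every run writes a resolved copy of its configuration (including SHA-256
checksums of the inputs) beside the outputs, so results are traceable
to exact inputs and parameters.  Stage outputs are pure functions of
(inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment as enr
from . import motifs, ncounter, promoters, simulate

log = logging.getLogger("crescan")


@dataclass
class PipelineConfig:
    """Paths, thresholds and window definitions for a pipeline run.

    Thresholds default to the published analysis parameters: MSS 0.85,
    core 0.99, >2-fold / p<0.01 gene selection, 1000 background
    promoters, 2-fold / corrected p<0.005 / >=5 promoters / >=25% pass
    criteria, 20% repression cut, 7 reference genes.
    """

    outdir: str = "crescan_out"
    genome: str | None = None
    tss: str | None = None
    matrices: str | None = None
    de_table: str | None = None
    ncounter_counts: str | None = None
    ncounter_roles: str | None = None
    ncounter_meta: str | None = None
    window: tuple[int, int] = promoters.PROXIMAL_WINDOW
    upstream_depth: int = promoters.UPSTREAM_DEPTH
    min_mss: float = 0.85
    min_core: float = 0.99
    min_fold: float = 2.0
    max_p: float = 0.01
    direction: str = "up"
    background_size: int = 1000
    repression_threshold: float = 0.20
    k_references: int = 7
    seed: int = 0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        if "window" in kwargs:
            kwargs["window"] = tuple(kwargs["window"])
        return cls(**kwargs)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(config: PipelineConfig, *names: str) -> None:
    missing = []
    for name in names:
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            missing.append(f"{name}={p}")
    if missing:
        raise FileNotFoundError(f"missing inputs: {', '.join(missing)}")


def _write_resolved_config(config: PipelineConfig, outdir: Path, inputs: list[str]) -> None:
    resolved = asdict(config)
    resolved["input_sha256"] = {
        name: _sha256(getattr(config, name)) for name in inputs
    }
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)
    for key, val in sorted(resolved.items()):
        log.info("config %s = %r", key, val)


def _load_genome(path):
    import pyfaidx

    return pyfaidx.Fasta(str(path), sequence_always_upper=True)


def run_enrichment(config: PipelineConfig) -> list[enr.EnrichmentResult]:
    """extract -> dedupe -> scan -> count -> MWW -> BH -> criteria -> collapse.

    Writes hits.tsv, enrichment.tsv, enrichment_collapsed.tsv and the
    resolved config to the output directory and returns the collapsed
    result list.
    """
    _require(config, "genome", "tss", "matrices", "de_table")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_resolved_config(config, outdir, ["genome", "tss", "matrices", "de_table"])

    genome = _load_genome(config.genome)
    tss = promoters.read_tss_bed(config.tss)
    proms = promoters.deduplicate_promoters(
        promoters.extract_promoters(genome, tss, config.window)
    )
    universe = [p.gene_id for p in proms]
    log.info("%d promoters after deduplication", len(proms))

    de = pd.read_csv(config.de_table, sep="\t")
    fg = [
        g
        for g in enr.select_regulated(de, config.min_fold, config.max_p, config.direction)
        if g in set(universe)
    ]
    bg = promoters.sample_background(
        universe, fg, min(config.background_size, len(universe) - len(fg)), config.seed
    )
    log.info("foreground %d genes, background %d genes", len(fg), len(bg))

    with open(config.matrices) as fh:
        pwms = motifs.parse_transfac(fh.read())
    thresholds = motifs.ScanThresholds(config.min_mss, config.min_core)
    keep = set(fg) | set(bg)
    hits = motifs.scan_promoters(pwms, [p for p in proms if p.gene_id in keep], thresholds)
    motifs.hits_to_frame(hits).to_csv(outdir / "hits.tsv", sep="\t", index=False)

    results = enr.enrichment_table(
        hits, fg, bg, window=config.window, matrix_ids=[p.matrix_id for p in pwms]
    )
    enr.results_to_frame(results).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    collapsed = enr.collapse_redundant(results)
    enr.results_to_frame(collapsed).to_csv(
        outdir / "enrichment_collapsed.tsv", sep="\t", index=False
    )
    log.info("%d matrices tested, %d pass after collapsing",
             len(results), sum(r.passes for r in collapsed))
    return collapsed


def run_positional(config: PipelineConfig, matrix_ids: list[str] | None = None):
    """Cumulative positional profiles over deep upstream regions."""
    _require(config, "genome", "tss", "matrices", "de_table")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = _load_genome(config.genome)
    tss = promoters.read_tss_bed(config.tss)
    regions = promoters.deduplicate_promoters(
        promoters.extract_upstream_regions(genome, tss, config.upstream_depth)
    )
    universe = [p.gene_id for p in regions]
    de = pd.read_csv(config.de_table, sep="\t")
    fg = [
        g
        for g in enr.select_regulated(de, config.min_fold, config.max_p, config.direction)
        if g in set(universe)
    ]
    bg = promoters.sample_background(
        universe, fg, min(config.background_size, len(universe) - len(fg)), config.seed
    )
    with open(config.matrices) as fh:
        pwms = motifs.parse_transfac(fh.read())
    if matrix_ids:
        pwms = [p for p in pwms if p.matrix_id in set(matrix_ids)]
    thresholds = motifs.ScanThresholds(config.min_mss, config.min_core)
    keep = set(fg) | set(bg)
    profiles = []
    for pwm in pwms:
        hits = motifs.scan_promoters(pwm, [p for p in regions if p.gene_id in keep], thresholds)
        prof = enr.positional_profile(
            hits, fg, bg, depth=config.upstream_depth, matrix_id=pwm.matrix_id
        )
        enr.profile_to_frame(prof).to_csv(
            outdir / f"positional_{pwm.matrix_id.replace('$', '_')}.tsv",
            sep="\t",
            index=False,
        )
        profiles.append(prof)
    return profiles


def run_ncounter(config: PipelineConfig) -> dict:
    """background-correct -> select references -> normalize -> call
    repression -> Fisher dependence report."""
    _require(config, "ncounter_counts", "ncounter_roles", "ncounter_meta")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_resolved_config(
        config, outdir, ["ncounter_counts", "ncounter_roles", "ncounter_meta"]
    )

    run = ncounter.read_ncounter_tsv(
        config.ncounter_counts, config.ncounter_roles, config.ncounter_meta
    )
    normalized, refs = ncounter.normalize_run(run, k_references=config.k_references)
    normalized.to_csv(outdir / "normalized.tsv", sep="\t")
    log.info("reference genes: %s", ", ".join(refs))

    meta = run.sample_meta
    treated = list(meta.index[meta["treatment"] == "treated"])
    mock = list(meta.index[meta["treatment"] == "mock"])
    targets = run.genes_with_role(ncounter.ROLE_TARGET)
    calls = ncounter.call_repression(
        normalized, treated, mock, config.repression_threshold, genes=targets
    )
    pd.DataFrame(
        [(g, c) for g, c in calls.items()], columns=["gene_id", "repressed"]
    ).to_csv(outdir / "repression_calls.tsv", sep="\t", index=False)

    report: dict = {"references": refs, "n_repressed": sum(1 for c in calls.values() if c)}
    roles_df = pd.read_csv(config.ncounter_roles, sep="\t")
    if "gene_class" in roles_df.columns:
        classes = roles_df.dropna(subset=["gene_class"])
        by_class = classes.groupby("gene_class")["gene_id"].apply(list).to_dict()
        labels = sorted(by_class)
        if len(labels) >= 2:
            c1 = {g: calls[g] for g in by_class[labels[0]] if g in calls}
            c2 = {g: calls[g] for g in by_class[labels[1]] if g in calls}
            table = ncounter.dependence_table(c1, c2)
            odds, p = ncounter.fisher_exact_test(table)
            report["fisher"] = {
                "classes": labels[:2],
                "table": [[table.a, table.b], [table.c, table.d]],
                "odds_ratio": odds,
                "p_value": p,
            }
            log.info("Fisher exact p = %.4g for %s vs %s", p, labels[0], labels[1])
    with open(outdir / "ncounter_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def simulate_bundle(cfg: simulate.SimConfig, outdir) -> dict:
    """Write a complete synthetic input bundle for the pipeline.

    Emits genome.fa, tss.bed, matrices.transfac, de_table.tsv, the
    nCounter TSV triple and plant_manifest.tsv.  Foreground promoters
    (the DE table's 'up' truth set) carry planted sites of the
    ISRE-like fixture matrix at density lam_fg; the rest at lam_bg.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_genes = cfg.n_fg + cfg.n_bg
    genome, tss = simulate.generate_genome_and_tss(
        n_genes, seed=cfg.seed, gc=cfg.gc, window=cfg.window
    )
    proms = promoters.extract_promoters(genome, tss, cfg.window)
    pwm = simulate.isre_like_pwm()
    fg_planted, man_fg = simulate.plant_motifs(
        proms[: cfg.n_fg], pwm, cfg.lam_fg, seed=cfg.seed + 1,
        positional=cfg.positional, decay_bp=cfg.decay_bp,
    )
    bg_planted, man_bg = simulate.plant_motifs(
        proms[cfg.n_fg :], pwm, cfg.lam_bg, seed=cfg.seed + 2,
        positional=cfg.positional, decay_bp=cfg.decay_bp,
    )
    chrom = next(iter(genome))
    seq = list(genome[chrom])
    for rec in fg_planted + bg_planted:
        gs, ge = rec.genomic_interval
        s = rec.sequence if rec.strand == "+" else motifs.reverse_complement(rec.sequence)
        seq[gs:ge] = s
    genome[chrom] = "".join(seq)

    simulate.write_fasta(genome, outdir / "genome.fa")
    simulate.write_bed6(tss, outdir / "tss.bed")
    extra = [simulate.gas_like_pwm(), simulate.nfkb_like_pwm()] + [
        simulate.random_pwm(10, seed=cfg.seed + 10 + i, matrix_id=f"V$RND{i}_01")
        for i in range(3)
    ]
    motifs.write_transfac([pwm] + extra, outdir / "matrices.transfac")

    gene_ids = [r.gene_id for r in tss]
    de, truth = simulate.generate_de_table(
        n_up=cfg.n_fg, n_down=0, n_null=cfg.n_bg,
        effect=cfg.de_effect, noise_sd=cfg.de_noise_sd,
        seed=cfg.seed + 3, gene_ids=gene_ids,
    )
    de.to_csv(outdir / "de_table.tsv", sep="\t", index=False)

    run, nc_truth = simulate.generate_ncounter_run(
        background_mean=cfg.ncounter_background_mean,
        noise_cv=cfg.ncounter_noise_cv,
        seed=cfg.seed + 4,
    )
    run.counts.to_csv(outdir / "ncounter_counts.tsv", sep="\t")
    targets = run.genes_with_role(ncounter.ROLE_TARGET)
    roles_rows = []
    for g in run.counts.index:
        role = run.gene_roles[g]
        cls = ""
        if role == ncounter.ROLE_TARGET:
            cls = "classA" if g in nc_truth["repressed"] else "classB"
        roles_rows.append((g, role, cls))
    pd.DataFrame(roles_rows, columns=["gene_id", "role", "gene_class"]).to_csv(
        outdir / "ncounter_roles.tsv", sep="\t", index=False
    )
    run.sample_meta.to_csv(outdir / "ncounter_meta.tsv", sep="\t")

    manifest = simulate.PlantManifest(
        plants=man_fg.plants + man_bg.plants, lam=cfg.lam_fg, seed=cfg.seed
    )
    manifest.to_frame().to_csv(outdir / "plant_manifest.tsv", sep="\t", index=False)
    summary = {
        "n_fg": cfg.n_fg,
        "n_bg": cfg.n_bg,
        "planted_matrix": pwm.matrix_id,
        "fg_genes": gene_ids[: cfg.n_fg],
        "n_plants_fg": len(man_fg.plants),
        "n_plants_bg": len(man_bg.plants),
        "n_ncounter_targets": len(targets),
        "seed": cfg.seed,
    }
    with open(outdir / "bundle_manifest.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
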