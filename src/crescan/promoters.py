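"""Promoter and upstream-region extraction in a TSS-relative frame.

Coordinates are 0-based half-open throughout.  TSS-relative position 0
is the TSS base itself; upstream positions are negative.  The default
proximal promoter window is (-600, +100).  Promoter sequences are
always stored in gene orientation, so a minus-strand promoter is the
reverse complement of the corresponding genomic slice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .motifs import reverse_complement

PROXIMAL_WINDOW = (-600, 100)
UPSTREAM_DEPTH = 20_000


@dataclass(frozen=True)
class TssRecord:
    gene_id: str
    chrom: str
    tss: int  # 0-based genomic coordinate of the TSS base
    strand: str


@dataclass
class PromoterRecord:
    """A gene-oriented promoter slice.

    ``start_rel``/``end_rel`` give the half-open TSS-relative window the
    sequence actually covers (they shrink from the requested window when
    the slice runs off a contig end, in which case ``truncated`` is set).
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    start_rel: int
    end_rel: int
    sequence: str
    truncated: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end_rel - self.start_rel:
            raise ValueError(
                f"{self.gene_id}: sequence length {len(self.sequence)} != "
                f"window span {self.end_rel - self.start_rel}"
            )

    @property
    def genomic_interval(self) -> tuple[int, int]:
        """Half-open genomic interval covered by this record."""
        if self.strand == "+":
            return (self.tss + self.start_rel, self.tss + self.end_rel)
        return (self.tss - self.end_rel + 1, self.tss - self.start_rel + 1)


def _contig_length(genome, chrom: str) -> int:
    return len(genome[chrom])


def _slice(genome, chrom: str, start: int, end: int) -> str:
    piece = genome[chrom][start:end]
    return str(piece).upper() if not isinstance(piece, str) else piece.upper()


def read_tss_bed(path) -> list[TssRecord]:
    """Read a BED6 table; the interval's strand-aware 5' end is the TSS."""
    import pandas as pd

    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=range(6),
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    records = []
    for row in bed.itertuples(index=False):
        tss = int(row.start) if row.strand == "+" else int(row.end) - 1
        records.append(TssRecord(row.name, row.chrom, tss, row.strand))
    return records


def extract_promoters(
    genome,
    tss_table: list[TssRecord],
    window: tuple[int, int] = PROXIMAL_WINDOW,
) -> list[PromoterRecord]:
    """Extract gene-oriented promoter slices for every TSS.

    ``genome`` is any mapping of chromosome name to sequence supporting
    slicing (a dict of strings or a ``pyfaidx.Fasta``).  Slices clipped
    at contig ends are returned with ``truncated=True``; a TSS outside
    its contig is skipped with a warning; unknown chromosomes raise.
    """
    start_rel, end_rel = window
    if end_rel <= start_rel:
        raise ValueError(f"empty window {window}")
    known = set()
    unknown = set()
    for rec in tss_table:
        if rec.chrom in known:
            continue
        try:
            genome[rec.chrom]
            known.add(rec.chrom)
        except KeyError:
            unknown.add(rec.chrom)
    if unknown:
        raise KeyError(f"chromosomes absent from genome: {sorted(unknown)}")

    out: list[PromoterRecord] = []
    for rec in tss_table:
        clen = _contig_length(genome, rec.chrom)
        if not 0 <= rec.tss < clen:
            warnings.warn(f"{rec.gene_id}: TSS {rec.tss} outside contig; skipped")
            continue
        if rec.strand == "+":
            gstart, gend = rec.tss + start_rel, rec.tss + end_rel
        else:
            gstart, gend = rec.tss - end_rel + 1, rec.tss - start_rel + 1
        cstart, cend = max(gstart, 0), min(gend, clen)
        truncated = (cstart, cend) != (gstart, gend)
        seq = _slice(genome, rec.chrom, cstart, cend)
        if rec.strand == "+":
            eff = (cstart - rec.tss, cend - rec.tss)
        else:
            seq = reverse_complement(seq)
            eff = (rec.tss - cend + 1, rec.tss - cstart + 1)
        out.append(
            PromoterRecord(
                gene_id=rec.gene_id,
                chrom=rec.chrom,
                tss=rec.tss,
                strand=rec.strand,
                start_rel=eff[0],
                end_rel=eff[1],
                sequence=seq,
                truncated=truncated,
            )
        )
    return out


def extract_upstream_regions(
    genome, tss_table: list[TssRecord], depth: int = UPSTREAM_DEPTH
) -> list[PromoterRecord]:
    """Deep upstream slices, window (-depth, +100)."""
    return extract_promoters(genome, tss_table, window=(-depth, 100))


def deduplicate_promoters(promoters: list[PromoterRecord]) -> list[PromoterRecord]:
    """Keep one promoter per gene and drop genomically overlapping windows.

    Within a gene, the record with the leftmost genomic start survives.
    Across genes, overlapping windows are resolved by a left-to-right
    sweep: the survivor of any conflict is the record whose window
    starts leftmost on the genome, ties broken by gene_id.  The result
    is pairwise non-overlapping and one-per-gene.
    """
    by_gene: dict[str, PromoterRecord] = {}
    for p in promoters:
        cur = by_gene.get(p.gene_id)
        if cur is None or (p.genomic_interval, p.gene_id) < (
            cur.genomic_interval,
            cur.gene_id,
        ):
            by_gene[p.gene_id] = p
    ordered = sorted(
        by_gene.values(), key=lambda p: (p.chrom, p.genomic_interval, p.gene_id)
    )
    out: list[PromoterRecord] = []
    last_end = -1
    last_chrom = None
    for p in ordered:
        gstart, gend = p.genomic_interval
        if p.chrom != last_chrom or gstart >= last_end:
            out.append(p)
            last_chrom, last_end = p.chrom, gend
    return out


def sample_background(
    universe: list[str], foreground: list[str], n: int, seed: int
) -> list[str]:
    """Uniform sample of n genes from universe minus foreground.

    Reproducible for a given seed; raises when fewer than n genes remain.
    """
    pool = sorted(set(universe) - set(foreground))
    if n > len(pool):
        raise ValueError(f"requested {n} background genes, only {len(pool)} available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


def promoters_to_fasta(promoters: list[PromoterRecord], path) -> None:
    """Write promoters as FASTA with '>gene_id|chrom|tss|strand' headers."""
    with open(path, "w") as fh:
        for p in promoters:
            fh.write(f">{p.gene_id}|{p.chrom}|{p.tss}|{p.strand}\n")
            for i in range(0, len(p.sequence), 80):
                fh.write(p.sequence[i : i + 80] + "\n")
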