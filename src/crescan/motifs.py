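"""Position weight matrices, TRANSFAC parsing and MATCH-style scanning.

A :class:`PWM` holds per-position base counts from a TRANSFAC record,
the derived frequency matrix, an information-weight vector and the
location of the 5-position "core" (the window of maximal summed
information).  Matches are scored with the matrix similarity score
(MSS): a min-max-normalized, information-weighted sum over the window,

    MSS = (Current - Min) / (Max - Min),
    Current = sum_i I(i) * f(i, s_i),
    Min/Max = sum_i I(i) * min_b / max_b f(i, b),
    I(i)    = sum_b f(i, b) * ln(4 f(i, b)),

so a consensus window scores exactly 1.  The core score is the same
statistic restricted to the core positions.  Both strands are scanned;
default thresholds are MSS >= 0.85 and core score >= 0.99.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

ALPHABET = "ACGT"
CORE_WIDTH = 5

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte -> base index; anything outside ACGT (case-insensitive) maps to 4 ("N")
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 indices (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class TransfacParseError(ValueError):
    """Raised on a malformed TRANSFAC matrix record."""


def information_vector(frequencies: np.ndarray) -> np.ndarray:
    """Per-position information weights I(i) = sum_b f*ln(4f), with 0*ln0 = 0.

    Zero for a uniform row, ln(4) for a fully certain one.
    """
    f = np.asarray(frequencies, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log(4.0 * f), 0.0)
    info = terms.sum(axis=1)
    # clip tiny negative round-off from rows very close to uniform
    return np.where(np.abs(info) < 1e-15, 0.0, info)


def core_start_of(info: np.ndarray, width: int = CORE_WIDTH) -> int:
    """Start of the ``width`` consecutive positions of maximal summed
    information; leftmost wins ties."""
    info = np.asarray(info, dtype=float)
    if info.size < width:
        raise ValueError(f"matrix length {info.size} < core width {width}")
    sums = sliding_window_view(info, width).sum(axis=1)
    return int(np.argmax(sums))  # argmax is leftmost on ties


@dataclass
class PWM:
    """A TRANSFAC-style position count matrix with derived scoring arrays."""

    matrix_id: str
    counts: np.ndarray
    factor_name: str = ""
    frequencies: np.ndarray = field(init=False, repr=False)
    info: np.ndarray = field(init=False, repr=False)
    core_start: int = field(init=False)
    core_is_whole_matrix: bool = field(init=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError(f"{self.matrix_id}: counts must be L x 4")
        if (counts < 0).any():
            raise ValueError(f"{self.matrix_id}: negative counts")
        sums = counts.sum(axis=1)
        if (sums <= 0).any():
            raise ValueError(f"{self.matrix_id}: zero row sum")
        self.counts = counts
        self.frequencies = counts / sums[:, None]
        self.info = information_vector(self.frequencies)
        if len(self) >= CORE_WIDTH:
            self.core_start = core_start_of(self.info)
            self.core_is_whole_matrix = False
        else:
            self.core_start = 0
            self.core_is_whole_matrix = True

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def core_positions(self) -> slice:
        if self.core_is_whole_matrix:
            return slice(0, len(self))
        return slice(self.core_start, self.core_start + CORE_WIDTH)

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.frequencies.argmax(axis=1))


@dataclass(frozen=True)
class ScanThresholds:
    """Match acceptance thresholds on the full-window and core scores."""

    min_mss: float = 0.85
    min_core: float = 0.99

    def __post_init__(self) -> None:
        for name in ("min_mss", "min_core"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class MotifHit:
    """One above-threshold match, in the promoter's TSS-relative frame.

    ``offset`` is the match start relative to the TSS (negative =
    upstream) in gene orientation; ``strand`` is relative to the gene.
    """

    promoter_id: str
    matrix_id: str
    offset: int
    strand: str
    mss: float
    core_score: float


# ---------------------------------------------------------------------------
# TRANSFAC flat-file I/O


def parse_transfac(text: str) -> list[PWM]:
    """Parse TRANSFAC flat-file matrix records into :class:`PWM` objects.

    Each record carries AC/ID (and optionally DE) lines followed by
    numbered count rows ``pos  A  C  G  T  [consensus]`` and a ``//``
    terminator.  Records whose count table contains a zero row sum are
    rejected with a warning; malformed rows raise
    :class:`TransfacParseError`.
    """
    pwms: list[PWM] = []
    acc = ""
    name = ""
    rows: list[list[float]] = []
    saw_content = False
    line_no = 0

    def finish(line_no: int) -> None:
        nonlocal acc, name, rows, saw_content
        if not saw_content:
            return
        if not rows:
            raise TransfacParseError(
                f"record {acc or name or '?'} ending at line {line_no}: no count rows"
            )
        try:
            pwms.append(PWM(matrix_id=acc or name, counts=np.array(rows), factor_name=name))
        except ValueError as exc:
            warnings.warn(f"rejected TRANSFAC record: {exc}", stacklevel=3)
        acc, name, rows, saw_content = "", "", [], False

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line or line.startswith("XX"):
            continue
        if line.startswith("//"):
            finish(line_no)
            continue
        tag, _, rest = line.partition(" ")
        rest = rest.strip()
        if tag == "AC":
            acc, saw_content = rest, True
        elif tag == "ID":
            name, saw_content = (name or rest), True
            if not acc:
                acc = rest
        elif tag == "DE":
            name, saw_content = rest, True
        elif tag in ("P0", "PO"):
            saw_content = True
        elif tag[:1].isdigit():
            fields = line.split()
            if len(fields) not in (5, 6):
                raise TransfacParseError(
                    f"record {acc or '?'}, line {line_no}: expected "
                    f"'pos A C G T [consensus]', got {len(fields)} fields"
                )
            try:
                vals = [float(x) for x in fields[1:5]]
            except ValueError as exc:
                raise TransfacParseError(
                    f"record {acc or '?'}, line {line_no}: non-numeric count"
                ) from exc
            if any(v < 0 for v in vals):
                raise TransfacParseError(
                    f"record {acc or '?'}, line {line_no}: negative count"
                )
            rows.append(vals)
            saw_content = True
        # other tags (BF, CC, ...) are ignored
    finish(line_no)
    return pwms


def write_transfac(pwms: list[PWM], path) -> None:
    """Write matrices in TRANSFAC flat-file format."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f"AC  {pwm.matrix_id}\nXX\nID  {pwm.matrix_id}\nXX\n")
            if pwm.factor_name:
                fh.write(f"DE  {pwm.factor_name}\nXX\n")
            fh.write("P0      A      C      G      T\n")
            cons = pwm.consensus
            for i, row in enumerate(pwm.counts):
                cells = "  ".join(f"{v:8.3f}" for v in row)
                fh.write(f"{i + 1:02d}  {cells}  {cons[i]}\n")
            fh.write("XX\n//\n")


# ---------------------------------------------------------------------------
# Scoring and scanning


def mss_score(pwm: PWM, window: str, positions: slice | None = None) -> float:
    """Matrix similarity score of one window (0..1); windows containing
    any non-ACGT base score 0; a zero-information matrix scores 1."""
    if len(window) != len(pwm):
        raise ValueError(
            f"window length {len(window)} != matrix length {len(pwm)}"
        )
    enc = encode_sequence(window)
    if (enc >= 4).any():
        return 0.0
    sl = positions if positions is not None else slice(0, len(pwm))
    f = pwm.frequencies[sl]
    w = pwm.info[sl]
    cur = float((w * f[np.arange(f.shape[0]), enc[sl]]).sum())
    lo = float((w * f.min(axis=1)).sum())
    hi = float((w * f.max(axis=1)).sum())
    if hi == lo:
        return 1.0
    return (cur - lo) / (hi - lo)


def core_score(pwm: PWM, window: str) -> float:
    """MSS restricted to the matrix core positions."""
    return mss_score(pwm, window, positions=pwm.core_positions)


def _strand_scores(pwm: PWM, enc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (mss, core) scores for every window start on one strand."""
    L = len(pwm)
    n = enc.size
    if n < L:
        return np.empty(0), np.empty(0)
    win = sliding_window_view(enc, L)
    valid = (win < 4).all(axis=1)
    # pad a 5th frequency column so N indexes cleanly, then mask via `valid`
    fpad = np.concatenate([pwm.frequencies, np.zeros((L, 1))], axis=1)
    w = pwm.info

    def minmax_scores(sl: slice) -> np.ndarray:
        ws = w[sl]
        fs = pwm.frequencies[sl]
        cur = (ws * fpad[sl][np.arange(fs.shape[0]), win[:, sl]]).sum(axis=1)
        lo = float((ws * fs.min(axis=1)).sum())
        hi = float((ws * fs.max(axis=1)).sum())
        if hi == lo:
            scores = np.ones(win.shape[0])
        else:
            scores = (cur - lo) / (hi - lo)
        return np.where(valid, scores, 0.0)

    return minmax_scores(slice(0, L)), minmax_scores(pwm.core_positions)


def scan_sequence(
    pwm: PWM,
    promoter,
    thresholds: ScanThresholds = ScanThresholds(),
) -> list[MotifHit]:
    """Scan both strands of a promoter for above-threshold matches.

    ``promoter`` needs ``gene_id``, ``sequence`` and ``start_rel``
    attributes (see :class:`crescan.promoters.PromoterRecord`).  A
    minus-strand hit means the matrix matches the reverse complement of
    the window; it is reported at the window's start offset in gene
    orientation.  Hits are sorted by offset, plus strand first.
    """
    seq = promoter.sequence
    enc = encode_sequence(seq)
    L = len(pwm)
    n = enc.size
    if n < L:
        return []

    mss_p, core_p = _strand_scores(pwm, enc)
    # minus strand: score the reverse-complemented sequence, then map the
    # rc window start i back to forward-strand start n - L - i
    enc_rc = np.where(enc < 4, 3 - enc, 4)[::-1]
    mss_m_rc, core_m_rc = _strand_scores(pwm, enc_rc)
    mss_m = mss_m_rc[::-1]
    core_m = core_m_rc[::-1]

    hits: list[MotifHit] = []
    start_rel = promoter.start_rel
    for strand, mss_arr, core_arr in (("+", mss_p, core_p), ("-", mss_m, core_m)):
        keep = np.flatnonzero(
            (core_arr >= thresholds.min_core) & (mss_arr >= thresholds.min_mss)
        )
        for j in keep:
            hits.append(
                MotifHit(
                    promoter_id=promoter.gene_id,
                    matrix_id=pwm.matrix_id,
                    offset=start_rel + int(j),
                    strand=strand,
                    mss=float(mss_arr[j]),
                    core_score=float(core_arr[j]),
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand != "+"))
    return hits


def scan_promoters(
    pwms,
    promoters,
    thresholds: ScanThresholds = ScanThresholds(),
) -> list[MotifHit]:
    """Scan every promoter with every matrix; concatenated hit list."""
    pwms = [pwms] if isinstance(pwms, PWM) else list(pwms)
    hits: list[MotifHit] = []
    for pwm in pwms:
        for prom in promoters:
            hits.extend(scan_sequence(pwm, prom, thresholds))
    return hits


def logo_counts(pwm: PWM, hits: list[MotifHit], promoters) -> np.ndarray:
    """A-posteriori L x 4 base counts over the actual matched windows.

    Minus-strand windows are reverse-complemented before counting, so
    the matrix is built in motif orientation.  ``promoters`` maps
    gene_id -> promoter record.  An empty hit list yields a zero matrix
    with a warning.
    """
    L = len(pwm)
    counts = np.zeros((L, 4), dtype=float)
    if not hits:
        warnings.warn(f"{pwm.matrix_id}: no hits; logo counts are all zero")
        return counts
    ids = {h.matrix_id for h in hits}
    if ids != {pwm.matrix_id}:
        raise ValueError(f"hits from matrices {ids}, expected {pwm.matrix_id}")
    for h in hits:
        prom = promoters[h.promoter_id]
        j = h.offset - prom.start_rel
        window = prom.sequence[j : j + L]
        if h.strand == "-":
            window = reverse_complement(window)
        enc = encode_sequence(window)
        for pos, base in enumerate(enc):
            if base < 4:
                counts[pos, base] += 1
    return counts


def hits_to_frame(hits: list[MotifHit]):
    """Hit list as a DataFrame (promoter_id, matrix_id, offset, strand,
    mss, core_score), the package's hit-table TSV schema."""
    import pandas as pd

    return pd.DataFrame(
        [
            (h.promoter_id, h.matrix_id, h.offset, h.strand, h.mss, h.core_score)
            for h in hits
        ],
        columns=["promoter_id", "matrix_id", "offset", "strand", "mss", "core_score"],
    )


def frame_to_hits(frame) -> list[MotifHit]:
    return [
        MotifHit(
            promoter_id=str(r.promoter_id),
            matrix_id=str(r.matrix_id),
            offset=int(r.offset),
            strand=str(r.strand),
            mss=float(r.mss),
            core_score=float(r.core_score),
        )
        for r in frame.itertuples(index=False)
    ]
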