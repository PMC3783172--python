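"""nCounter-style digital count processing.

Background correction subtracts, per sample, the mean + 2 SD of the
negative-control counts (clamped at zero).  Targets are then scaled so
that the geometric mean of a set of stable reference (house-keeping)
genes is equal across samples; the seven most stable candidates,
ranked by coefficient of variation of log2 counts, are used by
default.  Downstream calls: >20% reduction of the treated mean versus
the mock mean flags a gene as repressed, and 2x2 gene-class vs outcome
tables are tested with Fisher's exact test (two-sided,
minimum-likelihood convention).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ROLE_TARGET = "target"
ROLE_NEGATIVE = "negative_control"
ROLE_REFERENCE = "reference_candidate"
DEFAULT_N_REFERENCES = 7
DEFAULT_REPRESSION_THRESHOLD = 0.20


@dataclass
class NCounterRun:
    """Raw gene x sample counts with gene-role and sample annotations.

    ``counts``: DataFrame, genes in rows, samples in columns.
    ``gene_roles``: gene -> one of target / negative_control /
    reference_candidate.  ``sample_meta``: DataFrame indexed by sample
    with columns cell_line, treatment, replicate.
    """

    counts: pd.DataFrame
    gene_roles: dict[str, str]
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        roles = set(self.gene_roles.values())
        bad = roles - {ROLE_TARGET, ROLE_NEGATIVE, ROLE_REFERENCE}
        if bad:
            raise ValueError(f"unknown gene roles: {sorted(bad)}")
        if len(self.genes_with_role(ROLE_NEGATIVE)) < 1:
            raise ValueError("need at least one negative control")
        if len(self.genes_with_role(ROLE_REFERENCE)) < 2:
            raise ValueError("need at least two reference candidates")

    def genes_with_role(self, role: str) -> list[str]:
        return [g for g in self.counts.index if self.gene_roles.get(g) == role]


def background_correct(run: NCounterRun) -> pd.DataFrame:
    """Subtract each sample's negative-control mean + 2 SD from every
    gene's count in that sample, clamping at zero.

    The SD uses the n-1 denominator, so at least two negative controls
    are required.
    """
    negatives = run.genes_with_role(ROLE_NEGATIVE)
    if len(negatives) < 2:
        raise ValueError("background correction needs >=2 negative controls")
    neg = run.counts.loc[negatives]
    threshold = neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1)
    return (run.counts - threshold).clip(lower=0.0)


def select_stable_references(
    corrected: pd.DataFrame,
    candidates: list[str],
    k: int = DEFAULT_N_REFERENCES,
) -> list[str]:
    """The k candidates with the smallest coefficient of variation of
    log2(count + 1) across samples; ties broken by gene id."""
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds the {len(candidates)} candidates")
    logs = np.log2(corrected.loc[candidates] + 1.0)
    mean = logs.mean(axis=1)
    sd = logs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = (sd / mean).where(mean > 0, np.inf)
    order = sorted(candidates, key=lambda g: (cv[g], g))
    return order[:k]


def reference_normalize(corrected: pd.DataFrame, references: list[str]) -> pd.DataFrame:
    """Scale each sample so reference-gene geometric means agree.

    scale_s = (mean over samples of the per-sample reference geometric
    mean) / (geometric mean in sample s); anchoring on the mean keeps
    values on the original count scale.  A reference at zero in any
    sample is an error naming the gene and sample.
    """
    ref = corrected.loc[references]
    zero = ref <= 0
    if zero.to_numpy().any():
        gene = ref.index[zero.any(axis=1)][0]
        sample = ref.columns[zero.loc[gene]][0]
        raise ValueError(
            f"reference gene {gene!r} has non-positive corrected count in "
            f"sample {sample!r}"
        )
    geomeans = stats.gmean(ref, axis=0)
    scale = geomeans.mean() / geomeans
    return corrected * scale


def call_repression(
    normalized: pd.DataFrame,
    treated_samples: list[str],
    mock_samples: list[str],
    threshold: float = DEFAULT_REPRESSION_THRESHOLD,
    genes: list[str] | None = None,
) -> dict[str, bool | None]:
    """Flag genes whose treated mean falls >threshold below the mock mean.

    Means are taken over the replicate sample columns within each
    condition.  A gene with mock mean 0 gets ``None`` (undefined) with
    a warning.
    """
    if genes is None:
        genes = list(normalized.index)
    mock = normalized.loc[genes, mock_samples].mean(axis=1)
    treated = normalized.loc[genes, treated_samples].mean(axis=1)
    calls: dict[str, bool | None] = {}
    for g in genes:
        if mock[g] <= 0:
            warnings.warn(f"{g}: mock mean is 0; repression call undefined")
            calls[g] = None
        else:
            calls[g] = bool((mock[g] - treated[g]) / mock[g] > threshold)
    return calls


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b) / (c, d): rows = gene classes, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        vals = (self.a, self.b, self.c, self.d)
        if any(v < 0 for v in vals):
            raise ValueError("contingency counts must be non-negative")
        if sum(vals) < 1:
            raise ValueError("empty contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact_test(table) -> tuple[float, float]:
    """Two-sided Fisher exact test of a 2x2 table -> (odds_ratio, p).

    Two-sided by the minimum-likelihood convention: the p-value sums
    the hypergeometric probabilities of every table with the observed
    margins that is no more probable than the observed one.
    """
    if isinstance(table, ContingencyTable2x2):
        table = table.as_array()
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    res = stats.fisher_exact(arr, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def dependence_table(
    calls_class1: dict[str, bool | None], calls_class2: dict[str, bool | None]
) -> ContingencyTable2x2:
    """Build the 2x2 'class x outcome' table from two call mappings,
    skipping undefined calls."""

    def tally(calls):
        yes = sum(1 for v in calls.values() if v is True)
        no = sum(1 for v in calls.values() if v is False)
        return yes, no

    a, b = tally(calls_class1)
    c, d = tally(calls_class2)
    return ContingencyTable2x2(a, b, c, d)


def read_ncounter_tsv(counts_path, roles_path, meta_path) -> NCounterRun:
    """Assemble a run from a counts TSV (gene rows x sample columns) and
    gene-role / sample-metadata sidecar TSVs."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    roles_df = pd.read_csv(roles_path, sep="\t")
    roles = dict(zip(roles_df["gene_id"].astype(str), roles_df["role"].astype(str)))
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return NCounterRun(counts=counts, gene_roles=roles, sample_meta=meta)


def normalize_run(
    run: NCounterRun, k_references: int = DEFAULT_N_REFERENCES
) -> tuple[pd.DataFrame, list[str]]:
    """background_correct -> select references -> reference_normalize."""
    corrected = background_correct(run)
    refs = select_stable_references(
        corrected, run.genes_with_role(ROLE_REFERENCE), k=k_references
    )
    return reference_normalize(corrected, refs), refs
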