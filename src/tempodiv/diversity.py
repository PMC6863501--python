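"""Diversity statistics for temporally grouped mitogenome alignments.

Estimators follow the standard population-genetic definitions:

* segregating sites ``S``: analyzed columns with more than one state,
* nucleotide diversity ``pi``: mean per-site pairwise difference over all
  C(n, 2) sequence pairs (standard error by a seeded bootstrap over columns),
* haplotype diversity ``Hd = n/(n-1) (1 - sum p_i^2)`` with Nei's analytic
  sampling variance,
* a Welch (or pooled) two-sample t-test for a decline between periods,
* haplotype accumulation curves by random permutation subsampling without
  replacement.

The low-level kernels (:func:`hd_from_counts`, :func:`pi_from_hap_counts`)
are shared with the coalescent simulation path, so observed and simulated
summary statistics are produced by literally the same code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .alignment_io import (
    HaplotypeTable,
    TemporalAlignment,
    collapse_haplotypes,
    usable_columns,
)

__all__ = [
    "DiversityEstimate",
    "DeclineTest",
    "AccumulationCurve",
    "hd_from_counts",
    "pi_from_hap_counts",
    "segregating_sites",
    "nucleotide_diversity",
    "haplotype_diversity",
    "n_haplotypes",
    "compare_diversity",
    "haplotype_accumulation",
]


@dataclass(frozen=True)
class DiversityEstimate:
    statistic: str  # haplotype_diversity | nucleotide_diversity | segregating_sites | n_haplotypes
    value: float
    se: float | None
    n: int
    L_eff: int
    group: str = ""

    def __post_init__(self) -> None:
        if self.se is not None and self.se < 0:
            raise ValueError("standard error must be non-negative")


@dataclass(frozen=True)
class DeclineTest:
    t_statistic: float
    df: float
    p_value: float
    method: str  # welch | pooled


@dataclass(frozen=True)
class AccumulationCurve:
    sizes: np.ndarray
    mean_haplotypes: np.ndarray
    sd: np.ndarray
    n_permutations: int
    seed: int


# ---------------------------------------------------------------------------
# shared kernels (used identically on observed and simulated data)

def hd_from_counts(counts: np.ndarray) -> tuple[float, float]:
    """Haplotype diversity and its standard error from a count vector.

    Hd = n/(n-1) (1 - sum p_i^2); the variance is Nei's
    2/(n(n-1)) { 2(n-2) [sum p_i^3 - (sum p_i^2)^2] + sum p_i^2 - (sum p_i^2)^2 }.
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    n = counts.sum()
    if n < 2:
        raise ValueError("haplotype diversity needs at least 2 samples")
    p = counts / n
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    hd = n / (n - 1) * (1.0 - s2)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (s3 - s2**2) + s2 - s2**2)
    return float(hd), float(np.sqrt(max(var, 0.0)))


def pi_from_hap_counts(dist: np.ndarray, counts: np.ndarray, L: int) -> float:
    """Nucleotide diversity from haplotype counts and pairwise differences.

    ``dist[i, j]`` is the number of differing sites between haplotypes i and
    j; pairs within a haplotype contribute zero. Averages over all C(n, 2)
    sequence pairs and divides by the number of analyzed sites ``L``.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("nucleotide diversity needs at least 2 samples")
    if L < 1:
        raise ValueError("no analyzed columns")
    total = counts @ np.asarray(dist, dtype=float) @ counts / 2.0
    return float(total / (n * (n - 1) / 2.0) / L)


# ---------------------------------------------------------------------------
# alignment-level estimators

def _subset_matrix(
    aln: TemporalAlignment, subset: Sequence[str] | None
) -> tuple[np.ndarray, np.ndarray]:
    if subset is None:
        subset = aln.sample_ids
    if len(subset) < 2:
        raise ValueError("need at least 2 samples")
    cols = usable_columns(aln, subset)
    rows = aln.data[np.ix_(aln.row_index(subset), cols - 1)]
    return rows, cols


def _per_column_mismatches(rows: np.ndarray) -> np.ndarray:
    """Number of differing sequence pairs at each column.

    With per-column base counts c_b the number of mismatching pairs is
    (n^2 - sum c_b^2) / 2; complete deletion guarantees only A/C/G/T occur.
    """
    n = rows.shape[0]
    codes = rows.view(np.uint8)
    counts = np.vstack([(codes == b).sum(axis=0) for b in b"ACGT"])
    return (n * n - (counts.astype(np.int64) ** 2).sum(axis=0)) / 2.0


def segregating_sites(
    aln: TemporalAlignment, subset: Sequence[str] | None = None, group: str = ""
) -> DiversityEstimate:
    """Count analyzed columns with at least two distinct states in the subset."""
    rows, cols = _subset_matrix(aln, subset)
    s = int(np.count_nonzero(_per_column_mismatches(rows)))
    return DiversityEstimate(
        statistic="segregating_sites", value=float(s), se=None,
        n=rows.shape[0], L_eff=len(cols), group=group,
    )


def nucleotide_diversity(
    aln: TemporalAlignment,
    subset: Sequence[str] | None = None,
    group: str = "",
    bootstrap: int = 1000,
    seed: int = 0,
) -> DiversityEstimate:
    """Mean per-site pairwise difference, with a bootstrap-over-columns SE."""
    rows, cols = _subset_matrix(aln, subset)
    m = len(cols)
    if m == 0:
        raise ValueError("no usable columns in subset (all masked or missing)")
    n = rows.shape[0]
    npairs = n * (n - 1) / 2.0
    d = _per_column_mismatches(rows)
    pi = float(d.sum() / npairs / m)
    se = None
    if bootstrap and bootstrap > 0:
        rng = np.random.default_rng(seed)
        picks = rng.integers(0, m, size=(bootstrap, m))
        reps = d[picks].sum(axis=1) / npairs / m
        se = float(reps.std(ddof=1))
    return DiversityEstimate(
        statistic="nucleotide_diversity", value=pi, se=se,
        n=n, L_eff=m, group=group,
    )


def haplotype_diversity(table: HaplotypeTable, group: str) -> DiversityEstimate:
    """Haplotype diversity for one group of a collapsed haplotype table."""
    counts = table.counts(group)
    hd, se = hd_from_counts(counts)
    return DiversityEstimate(
        statistic="haplotype_diversity", value=hd, se=se,
        n=int(counts.sum()), L_eff=table.n_analyzed_columns, group=group,
    )


def n_haplotypes(table: HaplotypeTable, group: str) -> DiversityEstimate:
    counts = table.counts(group)
    return DiversityEstimate(
        statistic="n_haplotypes", value=float(np.count_nonzero(counts)), se=None,
        n=int(counts.sum()), L_eff=table.n_analyzed_columns, group=group,
    )


def compare_diversity(
    a: DiversityEstimate,
    b: DiversityEstimate,
    method: str = "welch",
    df: float | None = None,
) -> DeclineTest:
    """Two-sample t-test for a difference between two diversity estimates.

    ``welch`` uses t = (a - b) / sqrt(se_a^2 + se_b^2) with the
    Welch–Satterthwaite degrees of freedom; ``pooled`` uses the classical
    two-sample form with df = n_a + n_b - 2. The df can be overridden (some
    published analyses report a df matching neither convention exactly).
    P-values are two-sided.
    """
    if a.se is None or b.se is None:
        raise ValueError("both estimates must carry a standard error")
    if method not in ("welch", "pooled"):
        raise ValueError(f"unknown method {method!r}")
    va, vb = a.se**2, b.se**2
    if va + vb == 0:
        raise ValueError("both standard errors are zero; test undefined")
    if method == "welch":
        t = (a.value - b.value) / np.sqrt(va + vb)
        if df is None:
            df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    else:
        # se's are SEs of the group means; recover pooled variance
        sa2, sb2 = va * a.n, vb * b.n
        sp2 = ((a.n - 1) * sa2 + (b.n - 1) * sb2) / (a.n + b.n - 2)
        t = (a.value - b.value) / np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
        if df is None:
            df = a.n + b.n - 2
    p = 2.0 * sps.t.sf(abs(t), df)
    return DeclineTest(t_statistic=float(t), df=float(df), p_value=float(p), method=method)


def haplotype_accumulation(
    source: HaplotypeTable | TemporalAlignment,
    subset: Sequence[str] | None = None,
    n_perm: int = 100,
    seed: int = 0,
) -> AccumulationCurve:
    """Haplotype accumulation curve by permutation subsampling without replacement.

    For each subsample size k in 1..n, reports the mean and SD (over
    ``n_perm`` random sample orderings) of the number of distinct haplotypes
    among the first k samples. At k = n the mean equals the total haplotype
    count with SD exactly zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(source, TemporalAlignment):
        source = collapse_haplotypes(source, subset)
        subset = None
    ids = list(source.assignment) if subset is None else list(subset)
    haps = np.array([source.assignment[s] for s in ids], dtype=int)
    n = len(haps)
    rng = np.random.default_rng(seed)
    curves = np.empty((n_perm, n), dtype=float)
    for r in range(n_perm):
        order = rng.permutation(n)
        seen: set[int] = set()
        k_distinct = 0
        for pos, h in enumerate(haps[order]):
            if h not in seen:
                seen.add(h)
                k_distinct += 1
            curves[r, pos] = k_distinct
    sd = curves.std(axis=0, ddof=1) if n_perm > 1 else np.zeros(n)
    return AccumulationCurve(
        sizes=np.arange(1, n + 1),
        mean_haplotypes=curves.mean(axis=0),
        sd=sd,
        n_permutations=n_perm,
        seed=seed,
    )
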