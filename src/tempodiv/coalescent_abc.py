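"""Serial-sampling coalescent simulation and rejection ABC.

The demographic model is a single instantaneous decline in haploid female
effective population size: looking backward in time the population has size
``n_cur`` until ``t_decline`` generations before present and size ``n_anc``
earlier. Mitochondrial DNA is maternally inherited and effectively haploid,
so with k active lineages in an epoch of constant size N the waiting time
to the next coalescence is exponential with rate k(k-1)/(2N) — no factor
of two. Samples may be heterochronous: lineages activate at their sampling
times (e.g. modern tips at t = 0, historical tips at t = 40 generations).

Mutations are dropped on the genealogy under an infinite-sites model with
total rate mu * L per generation of branch length, and summary statistics
(per-period haplotype count, haplotype diversity and nucleotide diversity,
plus the number of haplotypes shared between periods) are computed with the
same kernels used for observed alignments.

Inference is plain rejection ABC: draw parameters from the prior, simulate,
standardize each summary statistic by its standard deviation across the
reference table, and retain the draws with the smallest Euclidean distance
to the observed summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment_io import TemporalAlignment, collapse_haplotypes
from .diversity import hd_from_counts, pi_from_hap_counts

__all__ = [
    "DemographicModel",
    "PriorConfig",
    "Genealogy",
    "MutationResult",
    "ReferenceTable",
    "ABCResult",
    "SUMMARY_NAMES",
    "sample_prior",
    "simulate_genealogy",
    "drop_mutations",
    "compute_summaries",
    "summaries_from_genotypes",
    "simulate_summaries",
    "build_reference_table",
    "abc_reject",
    "posterior_summary",
]

PARAM_NAMES = ("n_cur", "n_anc", "t_decline", "mu")

#: default seven summary statistics, in fixed order
SUMMARY_NAMES = (
    "n_hap_historical",
    "hd_historical",
    "pi_historical",
    "n_hap_modern",
    "hd_modern",
    "pi_modern",
    "n_shared",
)


@dataclass(frozen=True)
class DemographicModel:
    """Single-decline haploid demography with a serial sampling scheme.

    Sizes are in haploid female lineages; ``t_decline`` and sampling times
    are in generations before present; ``mu`` is per site per generation;
    ``g`` (years per generation) is carried for year/generation conversion.
    ``sampling`` is a sequence of (time_generations, n_samples) pulses.
    """

    n_cur: float
    n_anc: float
    t_decline: float
    mu: float
    L: int
    g: float = 3.0
    sampling: tuple[tuple[float, int], ...] = ((0.0, 21), (40.0, 16))

    def __post_init__(self) -> None:
        if self.n_cur <= 0 or self.n_anc <= 0:
            raise ValueError("population sizes must be positive")
        if self.t_decline < 0:
            raise ValueError("t_decline must be >= 0")
        if self.mu < 0:
            raise ValueError("mutation rate must be non-negative")
        if self.L < 1:
            raise ValueError("sequence length must be >= 1")
        if any(t < 0 or n < 0 for t, n in self.sampling):
            raise ValueError("sampling times and sizes must be non-negative")

    @property
    def n_tips(self) -> int:
        return sum(n for _, n in self.sampling)

    def size_at(self, t: float) -> float:
        """Population size t generations before present."""
        return self.n_cur if t < self.t_decline else self.n_anc

    @property
    def fold_decline(self) -> float:
        return self.n_anc / self.n_cur


@dataclass(frozen=True)
class PriorConfig:
    """Priors and run settings for the ABC reference table.

    ``n_cur`` and ``n_anc`` get bounded log-uniform priors (wide and
    scale-free); the decline time is uniform over a year interval converted
    to generations with ``g``; the per-generation mutation rate is uniform.
    """

    n_cur_bounds: tuple[float, float] = (20.0, 20_000.0)
    n_anc_bounds: tuple[float, float] = (100.0, 100_000.0)
    decline_years: tuple[float, float] = (90.0, 120.0)
    mu_bounds: tuple[float, float] = (1.85e-7, 3.00e-7)
    g: float = 3.0
    L: int = 13_224
    sampling: tuple[tuple[float, int], ...] = ((0.0, 21), (40.0, 16))
    n_sims: int = 100_000
    retention: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cur_bounds", "n_anc_bounds", "decline_years", "mu_bounds"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi and np.isfinite(hi)):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi < inf, got ({lo}, {hi})")
        if not (0 < self.retention <= 1):
            raise ValueError("retention must be in (0, 1]")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")

    @property
    def t_decline_bounds(self) -> tuple[float, float]:
        return (self.decline_years[0] / self.g, self.decline_years[1] / self.g)


@dataclass(frozen=True)
class Genealogy:
    """Coalescent tree over serially sampled tips.

    Nodes 0..n-1 are tips; internal nodes follow in coalescence order.
    ``times`` are generations before present; ``parent`` is -1 for the root.
    """

    times: np.ndarray
    parent: np.ndarray
    children: np.ndarray  # (n-1, 2) child ids of each internal node
    n_tips: int

    @property
    def n_nodes(self) -> int:
        return len(self.times)

    @property
    def tmrca(self) -> float:
        return float(self.times[-1])

    @property
    def branch_lengths(self) -> np.ndarray:
        """Length in generations of the branch above each non-root node."""
        bl = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        bl[has_parent] = self.times[self.parent[has_parent]] - self.times[has_parent]
        return bl

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths.sum())

    def tip_descendants(self) -> np.ndarray:
        """Boolean (n_nodes, n_tips) matrix: tips below each node."""
        n = self.n_tips
        desc = np.zeros((self.n_nodes, n), dtype=bool)
        desc[np.arange(n), np.arange(n)] = True
        for k in range(self.children.shape[0]):
            node = n + k
            c1, c2 = self.children[k]
            desc[node] = desc[c1] | desc[c2]
        return desc


def sample_prior(prior: PriorConfig, rng: np.random.Generator) -> DemographicModel:
    """Draw one demographic model from the prior."""
    lo, hi = prior.n_cur_bounds
    n_cur = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    lo, hi = prior.n_anc_bounds
    n_anc = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    t_dec = float(rng.uniform(*prior.t_decline_bounds))
    mu = float(rng.uniform(*prior.mu_bounds))
    return DemographicModel(
        n_cur=n_cur, n_anc=n_anc, t_decline=t_dec, mu=mu,
        L=prior.L, g=prior.g, sampling=prior.sampling,
    )


def simulate_genealogy(model: DemographicModel, rng: np.random.Generator) -> Genealogy:
    """Simulate one heterochronous coalescent genealogy.

    Backward in time: lineages activate at their sampling times; with k
    active lineages in an epoch of constant size N the next coalescence is
    exponential with rate k(k-1)/(2N); the size switches from ``n_cur`` to
    ``n_anc`` at ``t_decline``. Runs until a single lineage remains after
    all activations.
    """
    pulses = sorted(model.sampling)
    n = model.n_tips
    if n < 2:
        raise ValueError("need at least 2 tips")

    times = np.zeros(2 * n - 1)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    children = np.zeros((n - 1, 2), dtype=np.int64)

    # assign tip ids pulse by pulse in time order
    tip_ids_per_pulse = []
    next_tip = 0
    for t_s, k in pulses:
        ids = list(range(next_tip, next_tip + k))
        times[ids] = t_s
        tip_ids_per_pulse.append((t_s, ids))
        next_tip += k

    t = tip_ids_per_pulse[0][0]
    active = list(tip_ids_per_pulse[0][1])
    pulse_idx = 1
    next_internal = n

    while len(active) > 1 or pulse_idx < len(pulses):
        boundaries = []
        if pulse_idx < len(pulses):
            boundaries.append(tip_ids_per_pulse[pulse_idx][0])
        if t < model.t_decline:
            boundaries.append(model.t_decline)
        bound = min(boundaries) if boundaries else np.inf

        k = len(active)
        if k >= 2:
            N = model.size_at(t)
            wait = rng.exponential(2.0 * N / (k * (k - 1)))
            if t + wait < bound:
                t += wait
                i = rng.integers(k)
                j = rng.integers(k - 1)
                if j >= i:
                    j += 1
                a, b = active[i], active[j]
                node = next_internal
                next_internal += 1
                times[node] = t
                parent[a] = parent[b] = node
                children[node - n] = (a, b)
                # replace the two coalesced lineages with their parent
                hi_idx, lo_idx = (i, j) if i > j else (j, i)
                active[lo_idx] = node
                active.pop(hi_idx)
                continue
        if not np.isfinite(bound):
            break
        t = bound
        if pulse_idx < len(pulses) and tip_ids_per_pulse[pulse_idx][0] == bound:
            active.extend(tip_ids_per_pulse[pulse_idx][1])
            pulse_idx += 1

    return Genealogy(times=times, parent=parent, children=children, n_tips=n)


@dataclass(frozen=True)
class MutationResult:
    """Mutations dropped on a genealogy under infinite sites.

    ``genotypes`` is (n_mutations, n_tips) boolean: which tips carry each
    derived allele. ``sites`` are the 0-based positions hit (distinct unless
    the finite-sites fallback fired).
    """

    genotypes: np.ndarray
    sites: np.ndarray
    L: int

    @property
    def n_mutations(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_tips(self) -> int:
        return self.genotypes.shape[1]

    def to_alignment(self, rng: np.random.Generator | None = None) -> np.ndarray:
        """Expand to an (n_tips, L) ACGT character matrix (dtype S1).

        With an rng, the ancestral sequence is drawn uniformly over ACGT and
        each derived allele is a cyclic shift of the ancestral base; without
        one the ancestral sequence is all-A with derived alleles G.
        """
        bases = np.frombuffer(b"ACGT", dtype="S1")
        if rng is None:
            anc = np.zeros(self.L, dtype=np.int8)
        else:
            anc = rng.integers(0, 4, size=self.L).astype(np.int8)
        mat = np.tile(anc, (self.n_tips, 1))
        for m in range(self.n_mutations):
            s = self.sites[m]
            derived = (anc[s] + 1 + (m % 3 if rng is not None else 1)) % 4
            mat[self.genotypes[m], s] = derived
        return bases[mat]


def drop_mutations(
    tree: Genealogy, mu: float, L: int, rng: np.random.Generator
) -> MutationResult:
    """Drop Poisson mutations on a genealogy under infinite sites.

    The number of mutations is Poisson(mu * L * total branch length); each
    mutation lands on a branch with probability proportional to its length
    and hits a distinct site. If a pathological draw yields more mutations
    than sites, sites are resampled with replacement (finite-sites fallback)
    with a warning.
    """
    bl = tree.branch_lengths
    total = bl.sum()
    n_mut = int(rng.poisson(mu * L * total))
    if n_mut == 0:
        return MutationResult(
            genotypes=np.zeros((0, tree.n_tips), dtype=bool),
            sites=np.zeros(0, dtype=np.int64),
            L=L,
        )
    branches = rng.choice(tree.n_nodes, size=n_mut, p=bl / total)
    if n_mut <= L:
        sites = rng.choice(L, size=n_mut, replace=False)
    else:
        warnings.warn(
            f"{n_mut} mutations exceed {L} sites; resampling sites with replacement",
            RuntimeWarning,
        )
        sites = rng.integers(0, L, size=n_mut)
    genotypes = tree.tip_descendants()[branches]
    return MutationResult(genotypes=genotypes, sites=sites.astype(np.int64), L=L)


# ---------------------------------------------------------------------------
# summary statistics — one code path for observed and simulated data

def _summaries_from_group_data(
    hap_keys: Sequence[object],
    group_of_sample: Sequence[str],
    dist_fn,
    L: int,
) -> dict[str, float]:
    """Seven summaries from per-sample haplotype keys and group labels.

    ``dist_fn(key_a, key_b)`` returns the number of differing sites between
    two haplotypes. Shared kernels :func:`hd_from_counts` and
    :func:`pi_from_hap_counts` do the statistics.
    """
    out: dict[str, float] = {}
    keys_by_group: dict[str, list[object]] = {}
    for key, grp in zip(hap_keys, group_of_sample):
        keys_by_group.setdefault(grp, []).append(key)
    for grp in ("historical", "modern"):
        if grp not in keys_by_group:
            raise ValueError(f"period {grp!r} absent from data")
        keys = keys_by_group[grp]
        uniq: list[object] = []
        index: dict[object, int] = {}
        counts: list[int] = []
        for k in keys:
            if k not in index:
                index[k] = len(uniq)
                uniq.append(k)
                counts.append(0)
            counts[index[k]] += 1
        cvec = np.array(counts, dtype=float)
        H = len(uniq)
        dist = np.zeros((H, H))
        for i in range(H):
            for j in range(i + 1, H):
                dist[i, j] = dist[j, i] = dist_fn(uniq[i], uniq[j])
        hd, _ = hd_from_counts(cvec)
        out[f"n_hap_{grp}"] = float(H)
        out[f"hd_{grp}"] = hd
        out[f"pi_{grp}"] = pi_from_hap_counts(dist, cvec, L)
    shared = set(map(_hashable, keys_by_group["historical"])) & set(
        map(_hashable, keys_by_group["modern"])
    )
    out["n_shared"] = float(len(shared))
    return out


def _hashable(key):
    return key if isinstance(key, (str, bytes)) else bytes(key)


def summaries_from_genotypes(
    genotypes: np.ndarray,
    period_of_tip: Sequence[str],
    L: int,
    statistics: Sequence[str] = SUMMARY_NAMES,
) -> np.ndarray:
    """Summary vector from a (n_mutations, n_tips) boolean genotype matrix."""
    n_tips = genotypes.shape[1]
    gt = np.ascontiguousarray(genotypes.T)  # (n_tips, S)
    keys = [gt[t].tobytes() for t in range(n_tips)]
    carriers = {k: gt[t] for t, k in enumerate(keys)}

    def dist_fn(a: bytes, b: bytes) -> float:
        return float(np.count_nonzero(carriers[a] != carriers[b]))

    vals = _summaries_from_group_data(keys, period_of_tip, dist_fn, L)
    return np.array([vals[s] for s in statistics])


def compute_summaries(
    aln: TemporalAlignment,
    statistics: Sequence[str] = SUMMARY_NAMES,
) -> np.ndarray:
    """Summary vector from an observed alignment with period metadata.

    Haplotypes are collapsed over the usable columns of the combined
    historical + modern subset (complete deletion), so haplotype identity
    and per-site diversity are directly comparable between the two periods
    and with simulated data.
    """
    subset = [
        s.sample_id for s in aln.samples if s.period in ("historical", "modern")
    ]
    table = collapse_haplotypes(aln, subset, group_by="period")
    keys = [table.haplotypes[table.assignment[s]] for s in subset]
    periods = [aln.record(s).period for s in subset]

    def dist_fn(a: str, b: str) -> float:
        return float(sum(x != y for x, y in zip(a, b)))

    vals = _summaries_from_group_data(keys, periods, dist_fn, table.n_analyzed_columns)
    return np.array([vals[s] for s in statistics])


def simulate_summaries(
    model: DemographicModel,
    rng: np.random.Generator,
    statistics: Sequence[str] = SUMMARY_NAMES,
) -> np.ndarray:
    """Simulate one dataset and return its summary vector (lean path).

    Computes summaries directly from the mutation genotype matrix without
    materializing an ACGT alignment.
    """
    tree = simulate_genealogy(model, rng)
    muts = drop_mutations(tree, model.mu, model.L, rng)
    periods = tip_periods(model)
    return summaries_from_genotypes(muts.genotypes, periods, model.L, statistics)


def tip_periods(model: DemographicModel) -> list[str]:
    """Period label of each tip: time 0 is modern, older pulses historical.

    Tip order matches :func:`simulate_genealogy` (pulses in ascending time).
    """
    labels: list[str] = []
    for t_s, k in sorted(model.sampling):
        labels.extend(["modern" if t_s == 0 else "historical"] * k)
    return labels


# ---------------------------------------------------------------------------
# reference table and rejection

@dataclass(frozen=True)
class ReferenceTable:
    """Prior draws paired with their simulated summary vectors."""

    params: pd.DataFrame  # columns PARAM_NAMES
    stats: np.ndarray  # (n_sims, n_stats)
    statistics: tuple[str, ...]
    seed: int

    @property
    def n_sims(self) -> int:
        return len(self.params)

    def to_csv(self, path) -> None:
        df = self.params.copy()
        for i, s in enumerate(self.statistics):
            df[s] = self.stats[:, i]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, seed: int = -1) -> "ReferenceTable":
        df = pd.read_csv(path)
        stat_cols = [c for c in df.columns if c not in PARAM_NAMES]
        return cls(
            params=df[list(PARAM_NAMES)].copy(),
            stats=df[stat_cols].to_numpy(float),
            statistics=tuple(stat_cols),
            seed=seed,
        )


@dataclass(frozen=True)
class ABCResult:
    """Accepted draws of a rejection-ABC run."""

    accepted: pd.DataFrame  # accepted parameter draws (with distance column)
    distances: np.ndarray  # all distances, table row order
    retention: float
    statistics: tuple[str, ...]

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)


def build_reference_table(
    prior: PriorConfig,
    statistics: Sequence[str] = SUMMARY_NAMES,
    progress: bool = False,
) -> ReferenceTable:
    """Run ``prior.n_sims`` independent (draw, simulate, summarize) records.

    A master :class:`numpy.random.SeedSequence` built from ``prior.seed``
    spawns one child stream per simulation, so the table is reproducible
    and trivially parallelizable.
    """
    children = np.random.SeedSequence(prior.seed).spawn(prior.n_sims)
    rows = np.empty((prior.n_sims, len(PARAM_NAMES)))
    stats = np.empty((prior.n_sims, len(statistics)))
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        model = sample_prior(prior, rng)
        rows[i] = (model.n_cur, model.n_anc, model.t_decline, model.mu)
        stats[i] = simulate_summaries(model, rng, statistics)
        if progress and (i + 1) % 10_000 == 0:
            print(f"  {i + 1}/{prior.n_sims} simulations", flush=True)
    params = pd.DataFrame(rows, columns=list(PARAM_NAMES))
    return ReferenceTable(
        params=params, stats=stats, statistics=tuple(statistics), seed=prior.seed
    )


def abc_reject(
    observed: np.ndarray,
    table: ReferenceTable,
    retention: float = 0.01,
) -> ABCResult:
    """Retain the prior draws closest to the observed summaries.

    Each statistic is standardized by its standard deviation across the
    reference table (zero-variance statistics are dropped with a warning);
    distances are Euclidean; exactly ``round(retention * n_sims)`` rows are
    accepted, ties at the cutoff broken by row index.
    """
    if not (0 < retention <= 1):
        raise ValueError("retention must be in (0, 1]")
    observed = np.asarray(observed, dtype=float)
    if observed.shape != (table.stats.shape[1],):
        raise ValueError(
            f"observed vector has {observed.shape} entries, "
            f"table has {table.stats.shape[1]} statistics"
        )
    if not np.all(np.isfinite(observed)):
        raise ValueError("observed summaries must be finite")
    sd = table.stats.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [s for s, k in zip(table.statistics, keep) if not k]
        warnings.warn(f"dropping zero-variance statistics: {dropped}", RuntimeWarning)
    z = (table.stats[:, keep] - observed[keep]) / sd[keep]
    distances = np.sqrt((z**2).sum(axis=1))
    n_accept = int(round(retention * table.n_sims))
    if n_accept < 1:
        raise ValueError(
            f"retention {retention} of {table.n_sims} simulations accepts none; "
            "increase retention or the table size"
        )
    order = np.argsort(distances, kind="stable")
    idx = order[:n_accept]
    accepted = table.params.iloc[idx].copy()
    accepted["distance"] = distances[idx]
    return ABCResult(
        accepted=accepted,
        distances=distances,
        retention=retention,
        statistics=table.statistics,
    )


POSTERIOR_QUANTILES = (0.025, 0.25, 0.50, 0.75, 0.975)


def posterior_summary(result: ABCResult) -> pd.DataFrame:
    """Posterior quantiles per parameter plus the fold-decline n_anc/n_cur."""
    if result.n_accepted == 0:
        raise ValueError("no accepted draws")
    acc = result.accepted
    rows = {}
    for p in PARAM_NAMES:
        rows[p] = np.quantile(acc[p], POSTERIOR_QUANTILES)
    rows["fold_decline"] = np.quantile(
        acc["n_anc"] / acc["n_cur"], POSTERIOR_QUANTILES
    )
    df = pd.DataFrame(
        rows, index=[f"q{100 * q:g}" for q in POSTERIOR_QUANTILES]
    ).T
    df.index.name = "parameter"
    return df
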