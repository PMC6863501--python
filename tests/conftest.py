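import numpy as np
import pytest

from tempodiv import collapse_haplotypes, generate_toy_alignment
from tempodiv.alignment_io import SampleRecord, TemporalAlignment


@pytest.fixture(scope="session")
def toy_bundle():
    return generate_toy_alignment()


@pytest.fixture(scope="session")
def toy_aln(toy_bundle):
    return toy_bundle.alignment()


@pytest.fixture(scope="session")
def toy_table(toy_aln):
    return collapse_haplotypes(toy_aln)


def make_alignment(rows, periods=None, populations=None, masked=frozenset()):
    """Build a TemporalAlignment from a list of equal-length strings."""
    n = len(rows)
    if periods is None:
        periods = ["historical" if i < n // 2 else "modern" for i in range(n)]
    if populations is None:
        populations = ["pop"] * n
    samples = tuple(
        SampleRecord(sample_id=f"s{i + 1}", population=populations[i], period=periods[i])
        for i in range(n)
    )
    data = np.frombuffer("".join(rows).encode(), dtype="S1").reshape(n, len(rows[0]))
    return TemporalAlignment(data=data.copy(), samples=samples, masked_columns=masked)


def random_alignment(rng, n, L, alphabet="ACGT", periods=None):
    rows = ["".join(rng.choice(list(alphabet), size=L)) for _ in range(n)]
    return make_alignment(rows, periods=periods)


@pytest.fixture
def aln_factory():
    return make_alignment


@pytest.fixture(scope="session")
def recovery_experiment():
    """Shared parameter-recovery experiment: one reference table, 20 pseudo-
    observed single-locus datasets simulated at known truth, rejection ABC
    posteriors for each. Built once per session (the table is the expensive
    part)."""
    from tempodiv.coalescent_abc import (
        DemographicModel,
        PriorConfig,
        abc_reject,
        build_reference_table,
        posterior_summary,
        simulate_summaries,
    )

    truth = DemographicModel(
        n_cur=220.0, n_anc=3650.0, t_decline=35.0, mu=2.4e-7, L=13_224,
        sampling=((0.0, 21), (40.0, 16)),
    )
    prior = PriorConfig(n_sims=100_000, seed=42)
    table = build_reference_table(prior)
    posteriors = []
    for r in range(20):
        rng = np.random.default_rng(1000 + r)
        observed = simulate_summaries(truth, rng)
        result = abc_reject(observed, table, retention=0.01)
        posteriors.append(posterior_summary(result))
    return {"truth": truth, "posteriors": posteriors}
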