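"""Self-contained synthetic datasets for the temporal diversity pipeline.

Three generators:

* :func:`generate_bottleneck_dataset` — simulates a two-period mitogenome
  alignment under a known single-decline demography (coalescent genealogy +
  infinite-sites mutations), writes FASTA, metadata TSV and a truth JSON
  recording the generating parameters and realized summaries. The default
  model emulates a Scandinavian-style dataset: 16 historical samples taken
  40 generations ago and 21 modern samples at present, 13 224 usable sites,
  an ancestral female effective size of 3650 collapsing to 220 around 35
  generations before present, mu = 2.4e-7 per site per generation, 3-year
  generations.
* :func:`generate_toy_alignment` — a fixed 4 x 8 worked example (two
  historical, two modern samples; 3 haplotypes) used across the test suite.
* :func:`generate_structured_dataset` — a deterministic dataset with exactly
  10 historical and 5 modern haplotypes, 3 shared and 2 modern-private,
  with group sizes 16 and 21 and haplotype count configurations giving
  Hd = 0.917 (historical) and 0.762 (modern).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignment_io import SampleRecord, TemporalAlignment, read_alignment
from .coalescent_abc import (
    SUMMARY_NAMES,
    DemographicModel,
    compute_summaries,
    drop_mutations,
    simulate_genealogy,
    tip_periods,
)

__all__ = [
    "DEFAULT_MODEL",
    "DatasetBundle",
    "generate_bottleneck_dataset",
    "generate_toy_alignment",
    "generate_structured_dataset",
]

#: study-condition default: two-period Scandinavian-style bottleneck
DEFAULT_MODEL = DemographicModel(
    n_cur=220.0,
    n_anc=3650.0,
    t_decline=35.0,
    mu=2.4e-7,
    L=13_224,
    g=3.0,
    sampling=((0.0, 21), (40.0, 16)),
)

#: calendar year treated as the present for metadata ages
PRESENT_YEAR = 2015


@dataclass(frozen=True)
class DatasetBundle:
    """In-memory dataset: FASTA text, metadata TSV text and truth record."""

    fasta: str
    metadata: str
    truth: dict

    def write(self, out_dir: str | Path, stem: str = "dataset") -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / f"{stem}.fasta",
            "metadata": out / f"{stem}.meta.tsv",
            "truth": out / f"{stem}.truth.json",
        }
        paths["fasta"].write_text(self.fasta)
        paths["metadata"].write_text(self.metadata)
        paths["truth"].write_text(json.dumps(self.truth, indent=2, sort_keys=True) + "\n")
        return paths

    def alignment(self, tmp_dir: str | Path | None = None) -> TemporalAlignment:
        """Parse the bundle back through the standard reader."""
        import tempfile

        with tempfile.TemporaryDirectory(dir=tmp_dir) as td:
            paths = self.write(td)
            return read_alignment(paths["fasta"], paths["metadata"])


def _metadata_text(records: list[SampleRecord]) -> str:
    lines = ["sample_id\tpopulation\tperiod\tage\tage_units\tsampling_generation"]
    for r in records:
        age = "" if r.age is None else f"{r.age:g}"
        lines.append(
            f"{r.sample_id}\t{r.population}\t{r.period}\t{age}\t"
            f"{r.age_units or ''}\t{r.sampling_generation}"
        )
    return "\n".join(lines) + "\n"


def _fasta_text(ids: list[str], seqs: list[str], width: int = 70) -> str:
    buf = io.StringIO()
    for sid, seq in zip(ids, seqs):
        buf.write(f">{sid}\n")
        for i in range(0, len(seq), width):
            buf.write(seq[i : i + width] + "\n")
    return buf.getvalue()


def _records_for_model(model: DemographicModel) -> list[SampleRecord]:
    records = []
    counters: dict[str, int] = {}
    for t_s, k in sorted(model.sampling):
        period = "modern" if t_s == 0 else "historical"
        for _ in range(k):
            counters[period] = counters.get(period, 0) + 1
            records.append(
                SampleRecord(
                    sample_id=f"{period}_{counters[period]:02d}",
                    population="scandinavia",
                    period=period,
                    age=float(PRESENT_YEAR - model.g * t_s),
                    age_units="CE",
                    sampling_generation=int(round(t_s)),
                )
            )
    return records


def generate_bottleneck_dataset(
    model: DemographicModel = DEFAULT_MODEL,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> DatasetBundle:
    """Simulate one two-period dataset under a known demography.

    Runs the serial coalescent and infinite-sites mutation machinery, maps
    the mutations onto a random ACGT ancestral sequence and labels samples
    by sampling pulse. ``missing_rate`` optionally replaces that fraction
    of matrix cells with N to exercise complete-deletion handling. The
    truth record holds the generating parameters, the seed and the realized
    summary statistics; the same seed reproduces byte-identical output.
    """
    rng = np.random.default_rng(seed)
    tree = simulate_genealogy(model, rng)
    muts = drop_mutations(tree, model.mu, model.L, rng)
    mat = muts.to_alignment(rng)
    if missing_rate > 0:
        mask = rng.random(mat.shape) < missing_rate
        mat[mask] = b"N"

    records = _records_for_model(model)
    # tip order from simulate_genealogy follows ascending pulse time,
    # matching _records_for_model
    seqs = [mat[i].tobytes().decode("ascii") for i in range(mat.shape[0])]
    ids = [r.sample_id for r in records]
    fasta = _fasta_text(ids, seqs)
    metadata = _metadata_text(records)

    aln = TemporalAlignment(data=mat, samples=tuple(records))
    realized = dict(zip(SUMMARY_NAMES, compute_summaries(aln).tolist()))
    truth = {
        "model": {
            "n_cur": model.n_cur,
            "n_anc": model.n_anc,
            "t_decline": model.t_decline,
            "mu": model.mu,
            "L": model.L,
            "g": model.g,
            "sampling": [[t, n] for t, n in model.sampling],
            "fold_decline": model.fold_decline,
        },
        "seed": seed,
        "missing_rate": missing_rate,
        "tip_periods": tip_periods(model),
        "realized_summaries": realized,
    }
    return DatasetBundle(fasta=fasta, metadata=metadata, truth=truth)


# ---------------------------------------------------------------------------
# fixed worked example

_TOY_ROWS = ("ACGTACGT", "ACGTACGT", "ACGAACGT", "TCGTACGT")
_TOY_PERIODS = ("historical", "historical", "modern", "modern")


def generate_toy_alignment() -> DatasetBundle:
    """The fixed 4 x 8 worked example: 3 haplotypes, S = 2, pi = 0.125.

    Samples s1, s2 are historical (identical sequences); s3, s4 are modern
    and both differ from the shared historical haplotype. Output is
    byte-stable across calls.
    """
    ids = [f"s{i + 1}" for i in range(4)]
    records = [
        SampleRecord(
            sample_id=sid,
            population="toyland",
            period=per,
            age=float(PRESENT_YEAR if per == "modern" else PRESENT_YEAR - 120),
            age_units="CE",
            sampling_generation=0 if per == "modern" else 40,
        )
        for sid, per in zip(ids, _TOY_PERIODS)
    ]
    truth = {
        "n_haplotypes": 3,
        "haplotype_counts": [2, 1, 1],
        "segregating_sites": 2,
        "nucleotide_diversity": 0.125,
        "seed": None,
    }
    return DatasetBundle(
        fasta=_fasta_text(ids, list(_TOY_ROWS)),
        metadata=_metadata_text(records),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# deterministic two-period structure

#: historical haplotype counts (n = 16, 10 haplotypes, Hd = 0.917)
_HIST_COUNTS = (4, 3, 2, 1, 1, 1, 1, 1, 1, 1)
#: modern haplotype counts (n = 21, 5 haplotypes, Hd = 0.762)
_MOD_COUNTS = (8, 6, 4, 2, 1)
#: which modern haplotypes reuse a historical one (3 shared, 2 private)
_MOD_SOURCE = (0, 1, 2, None, None)


def generate_structured_dataset(L: int = 64) -> DatasetBundle:
    """Deterministic dataset with 10 historical / 5 modern haplotypes.

    Three modern haplotypes are shared with the historical group and two
    are modern-private (so seven historical haplotypes are lost). Haplotype
    sequences differ from a common backbone at distinct sites, making all
    pairwise distances positive. Byte-stable across calls.
    """
    n_hap_total = len(_HIST_COUNTS) + sum(1 for s in _MOD_SOURCE if s is None)
    if L < n_hap_total + 1:
        raise ValueError(f"L must be at least {n_hap_total + 1}")
    backbone = list("ACGT" * (L // 4 + 1))[:L]
    hap_seqs: list[str] = []
    for h in range(n_hap_total):
        seq = backbone.copy()
        # haplotype h carries a private substitution at site h (0-based)
        seq[h] = {"A": "G", "C": "T", "G": "A", "T": "C"}[seq[h]]
        hap_seqs.append("".join(seq))

    ids: list[str] = []
    seqs: list[str] = []
    records: list[SampleRecord] = []

    def add(period: str, hap_idx: int, k: int) -> None:
        for _ in range(k):
            i = len(ids) + 1
            sid = f"{period[:3]}_{i:02d}"
            ids.append(sid)
            seqs.append(hap_seqs[hap_idx])
            records.append(
                SampleRecord(
                    sample_id=sid,
                    population="scandinavia",
                    period=period,
                    age=float(PRESENT_YEAR if period == "modern" else PRESENT_YEAR - 120),
                    age_units="CE",
                    sampling_generation=0 if period == "modern" else 40,
                )
            )

    for h, c in enumerate(_HIST_COUNTS):
        add("historical", h, c)
    next_private = len(_HIST_COUNTS)
    for m, (src, c) in enumerate(zip(_MOD_SOURCE, _MOD_COUNTS)):
        if src is None:
            add("modern", next_private, c)
            next_private += 1
        else:
            add("modern", src, c)

    truth = {
        "n_hap_historical": len(_HIST_COUNTS),
        "n_hap_modern": len(_MOD_COUNTS),
        "n_shared": sum(1 for s in _MOD_SOURCE if s is not None),
        "n_modern_private": sum(1 for s in _MOD_SOURCE if s is None),
        "n_lost": len(_HIST_COUNTS) - sum(1 for s in _MOD_SOURCE if s is not None),
        "seed": None,
    }
    return DatasetBundle(
        fasta=_fasta_text(ids, seqs),
        metadata=_metadata_text(records),
        truth=truth,
    )
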