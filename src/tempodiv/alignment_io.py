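"""Reading, masking and haplotype-collapsing of temporally annotated alignments.

The central container is :class:`TemporalAlignment`: an aligned matrix of
mitogenome sequences plus one :class:`SampleRecord` per row carrying the
sampling period (pleistocene / historical / modern), an optional calendar
age and the sampling time in generations before present. Column masks are
logical (1-based, inclusive), so excluded regions such as tandem repeats or
suspected numt sites never mutate the underlying sequence data.

Missing data are handled by complete deletion: any analyzed column holding a
non-ACGT character (ambiguity code, N or gap) in the chosen sample subset is
dropped before haplotypes are collapsed or diversity is computed.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "PERIODS",
    "SampleRecord",
    "TemporalAlignment",
    "HaplotypeTable",
    "AlignmentError",
    "MetadataError",
    "read_alignment",
    "apply_masks",
    "usable_columns",
    "collapse_haplotypes",
    "write_haplotype_table",
    "write_nexus",
]

PERIODS = ("pleistocene", "historical", "modern")

#: sampling time in generations assumed for each period when the metadata
#: does not state one; pleistocene ages are converted from years BP instead.
DEFAULT_PERIOD_GENERATIONS = {"modern": 0, "historical": 40}

#: years per generation used to convert ages to generations.
DEFAULT_GENERATION_TIME = 3.0


class AlignmentError(ValueError):
    """Sequence-level problem: ragged alignment, bad coordinates."""


class MetadataError(ValueError):
    """Metadata table does not match the FASTA records."""


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample metadata attached to one alignment row."""

    sample_id: str
    population: str
    period: str
    age: float | None = None
    age_units: str | None = None  # "CE" or "BP"
    sampling_generation: int | None = None

    def __post_init__(self) -> None:
        if self.period not in PERIODS:
            raise MetadataError(
                f"sample {self.sample_id!r}: period {self.period!r} "
                f"not one of {PERIODS}"
            )
        if self.sampling_generation is not None and self.sampling_generation < 0:
            raise MetadataError(
                f"sample {self.sample_id!r}: sampling_generation must be >= 0"
            )


@dataclass(frozen=True)
class TemporalAlignment:
    """Aligned sequences with per-sample temporal metadata and column masks.

    ``data`` is an (n_samples, L) array of single-byte characters (dtype S1),
    upper-case, with U already mapped to T. ``masked_columns`` holds 1-based
    column indices excluded from every analysis.
    """

    data: np.ndarray
    samples: tuple[SampleRecord, ...]
    masked_columns: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise AlignmentError("alignment data must be a 2-D character matrix")
        if len(self.samples) != self.data.shape[0]:
            raise AlignmentError(
                f"{len(self.samples)} sample records for {self.data.shape[0]} rows"
            )
        ids = [s.sample_id for s in self.samples]
        dupes = [i for i, c in collections.Counter(ids).items() if c > 1]
        if dupes:
            raise MetadataError(f"duplicate sample ids: {dupes}")
        bad = [c for c in self.masked_columns if not (1 <= c <= self.L)]
        if bad:
            raise AlignmentError(f"masked columns out of range 1..{self.L}: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def L(self) -> int:
        return self.data.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def row_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = {s.sample_id: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise MetadataError(f"unknown sample id {exc.args[0]!r}") from exc

    def record(self, sample_id: str) -> SampleRecord:
        return self.samples[int(self.row_index([sample_id])[0])]

    def groups(self, by: str = "period") -> dict[str, list[str]]:
        """Sample ids grouped by a metadata field (period or population)."""
        out: dict[str, list[str]] = {}
        for s in self.samples:
            out.setdefault(str(getattr(s, by)), []).append(s.sample_id)
        return out


@dataclass(frozen=True)
class HaplotypeTable:
    """Distinct haplotypes over the analyzed columns, with group counts.

    ``haplotypes`` are the distinct sequence strings restricted to
    ``columns`` (1-based positions in the source alignment). ``assignment``
    maps every analyzed sample to a haplotype index; ``group_counts`` gives,
    per group label, the count of samples carrying each haplotype.
    """

    haplotypes: tuple[str, ...]
    assignment: Mapping[str, int]
    group_counts: Mapping[str, Mapping[int, int]]
    columns: tuple[int, ...]
    excluded_samples: tuple[tuple[str, str], ...] = ()

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def n_analyzed_columns(self) -> int:
        return len(self.columns)

    def counts(self, group: str) -> np.ndarray:
        """Haplotype count vector (length n_haplotypes) for one group."""
        by_hap = self.group_counts.get(group)
        if by_hap is None:
            raise KeyError(f"unknown group {group!r}; have {sorted(self.group_counts)}")
        out = np.zeros(self.n_haplotypes, dtype=int)
        for h, c in by_hap.items():
            out[h] = c
        return out

    def group_size(self, group: str) -> int:
        return int(self.counts(group).sum())


def _coerce_age(value: object) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def _default_generation(
    period: str, age: float | None, age_units: str | None,
    generation_time: float,
) -> int | None:
    if period in DEFAULT_PERIOD_GENERATIONS:
        return DEFAULT_PERIOD_GENERATIONS[period]
    # pleistocene: convert an age in years BP when available
    if age is not None and (age_units or "BP").upper() == "BP":
        return int(round(age / generation_time))
    return None


def read_alignment(
    fasta_path: str | Path,
    metadata_path: str | Path,
    generation_time: float = DEFAULT_GENERATION_TIME,
) -> TemporalAlignment:
    """Load a multi-FASTA alignment and its tab-separated metadata table.

    The metadata must carry ``sample_id``, ``population`` and ``period``
    columns; ``age``, ``age_units`` and ``sampling_generation`` are optional.
    FASTA records and metadata rows must match one-to-one by identifier and
    all sequences must have equal length. Characters are upper-cased and U is
    mapped to T; the returned alignment has an empty mask.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {fasta_path}")
    L = len(records[0].seq)
    for rec in records:
        if len(rec.seq) != L:
            raise AlignmentError(
                f"record {rec.id!r} has length {len(rec.seq)}, expected {L}"
            )

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "population", "period"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise MetadataError(f"metadata missing required columns: {sorted(missing_cols)}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise MetadataError(f"duplicate sample ids in metadata: {dupes}")

    meta_by_id = {row.sample_id: row for row in meta.itertuples(index=False)}
    fasta_ids = [rec.id for rec in records]
    absent = [i for i in fasta_ids if i not in meta_by_id]
    if absent:
        raise MetadataError(f"FASTA records absent from metadata: {absent}")
    extra = set(meta_by_id) - set(fasta_ids)
    if extra:
        raise MetadataError(f"metadata rows without FASTA record: {sorted(extra)}")

    samples = []
    for rec in records:
        row = meta_by_id[rec.id]
        age = _coerce_age(getattr(row, "age", None))
        age_units = getattr(row, "age_units", None)
        if isinstance(age_units, float) and np.isnan(age_units):
            age_units = None
        gen = getattr(row, "sampling_generation", None)
        if gen is None or (isinstance(gen, float) and np.isnan(gen)):
            gen = _default_generation(row.period, age, age_units, generation_time)
        else:
            gen = int(gen)
        samples.append(
            SampleRecord(
                sample_id=rec.id,
                population=str(row.population),
                period=str(row.period),
                age=age,
                age_units=age_units,
                sampling_generation=gen,
            )
        )

    seqs = [str(rec.seq).upper().replace("U", "T") for rec in records]
    data = np.frombuffer("".join(seqs).encode("ascii"), dtype="S1").reshape(len(seqs), L)
    return TemporalAlignment(data=data.copy(), samples=tuple(samples))


def apply_masks(
    aln: TemporalAlignment,
    regions: Iterable[tuple[int, int]] = (),
    sites: Iterable[int] = (),
) -> TemporalAlignment:
    """Mask 1-based inclusive column ranges and individual columns.

    Masking is logical: the returned alignment shares the sequence data and
    unions the new columns into ``masked_columns``.
    """
    cols: set[int] = set(aln.masked_columns)
    for a, b in regions:
        if not (1 <= a <= b <= aln.L):
            raise AlignmentError(
                f"region ({a}, {b}) out of range for 1-based columns 1..{aln.L}"
            )
        cols.update(range(a, b + 1))
    for s in sites:
        if not (1 <= s <= aln.L):
            raise AlignmentError(f"site {s} out of range for 1-based columns 1..{aln.L}")
        cols.add(int(s))
    return replace(aln, masked_columns=frozenset(cols))


_ACGT = np.frombuffer(b"ACGT", dtype="S1")


def usable_columns(
    aln: TemporalAlignment,
    sample_subset: Sequence[str] | None = None,
    policy: str = "complete_deletion",
) -> np.ndarray:
    """Unmasked 1-based columns where every subset row is a plain A/C/G/T.

    Implements complete deletion of missing data: a column with any gap,
    N or ambiguity code in the subset is excluded for all subset samples.
    """
    if policy != "complete_deletion":
        raise ValueError(f"unsupported missing-data policy {policy!r}")
    if sample_subset is None:
        sample_subset = aln.sample_ids
    if len(sample_subset) == 0:
        raise ValueError("sample subset must be non-empty")
    rows = aln.data[aln.row_index(sample_subset)]
    clean = np.isin(rows, _ACGT).all(axis=0)
    if aln.masked_columns:
        clean[np.fromiter(aln.masked_columns, dtype=int) - 1] = False
    return np.flatnonzero(clean) + 1


def collapse_haplotypes(
    aln: TemporalAlignment,
    sample_subset: Sequence[str] | None = None,
    group_by: str = "period",
) -> HaplotypeTable:
    """Collapse identical sequences (over usable columns) into haplotypes.

    Haplotypes are indexed in order of first appearance in the alignment,
    so the table is invariant to how samples are listed in the subset but
    follows alignment row order for numbering.
    """
    if sample_subset is None:
        sample_subset = aln.sample_ids
    idx = aln.row_index(sample_subset)
    order = np.argsort(idx)  # row order for deterministic numbering
    idx = idx[order]
    ids_in_row_order = [sample_subset[i] for i in order]

    cols = usable_columns(aln, sample_subset)
    sub = aln.data[np.ix_(idx, cols - 1)]

    hap_index: dict[bytes, int] = {}
    haplotypes: list[str] = []
    assignment: dict[str, int] = {}
    group_counts: dict[str, dict[int, int]] = {}
    for row, sid in zip(sub, ids_in_row_order):
        key = row.tobytes()
        h = hap_index.get(key)
        if h is None:
            h = len(haplotypes)
            hap_index[key] = h
            haplotypes.append(key.decode("ascii"))
        assignment[sid] = h
        grp = str(getattr(aln.record(sid), group_by))
        group_counts.setdefault(grp, {})
        group_counts[grp][h] = group_counts[grp].get(h, 0) + 1

    return HaplotypeTable(
        haplotypes=tuple(haplotypes),
        assignment=assignment,
        group_counts={g: dict(c) for g, c in group_counts.items()},
        columns=tuple(int(c) for c in cols),
    )


def write_haplotype_table(table: HaplotypeTable, path: str | Path) -> None:
    """Write a TSV of haplotype ids, sequences and per-group counts."""
    groups = sorted(table.group_counts)
    rows = []
    for h, seq in enumerate(table.haplotypes):
        row = {"haplotype_id": f"H{h + 1}", "sequence": seq}
        for g in groups:
            row[f"count_{g}"] = int(table.counts(g)[h])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_nexus(table: HaplotypeTable, path: str | Path) -> None:
    """Export collapsed haplotypes as NEXUS with a traits block of group counts."""
    groups = sorted(table.group_counts)
    n = table.n_haplotypes
    L = table.n_analyzed_columns
    lines = [
        "#NEXUS",
        "BEGIN TAXA;",
        f"DIMENSIONS NTAX={n};",
        "TAXLABELS",
        *[f"H{h + 1}" for h in range(n)],
        ";",
        "END;",
        "BEGIN CHARACTERS;",
        f"DIMENSIONS NCHAR={L};",
        "FORMAT DATATYPE=DNA MISSING=N GAP=-;",
        "MATRIX",
        *[f"H{h + 1} {seq}" for h, seq in enumerate(table.haplotypes)],
        ";",
        "END;",
        "BEGIN TRAITS;",
        f"Dimensions NTRAITS={len(groups)};",
        "Format labels=yes missing=? separator=Comma;",
        f"TraitLabels {' '.join(groups)};",
        "Matrix",
        *[
            f"H{h + 1} " + ",".join(str(int(table.counts(g)[h])) for g in groups)
            for h in range(n)
        ],
        ";",
        "END;",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
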