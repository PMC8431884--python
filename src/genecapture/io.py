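"""Genotype data model and tabular I/O for diploid codominant markers.

The central container is :class:`GenotypeDataset`: samples x loci diploid
allele calls (positive integer codes, typically microsatellite fragment
lengths in bp) with per-sample metadata — source population, role
(wild-population plant vs seed), maternal bunch, optional coordinates.

The exchange format is a delimited text table with one row per sample:

    sample_id, population, role, bunch, lat, lon, <locus>_1, <locus>_2, ...

Missing alleles are coded ``0`` (or left empty).  A call with only one
allele present is normalised to fully missing, since half-calls are not
meaningful for diploid scoring; a warning is emitted when that happens.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyDatasetError, GenotypeFormatError

MISSING = 0

__all__ = [
    "MISSING",
    "Role",
    "SampleRecord",
    "GenotypeDataset",
    "AlleleFrequencyTable",
    "FilterReport",
    "read_genotype_table",
    "write_genotype_table",
    "write_genalex",
    "filter_missing",
    "allele_frequencies",
    "allele_counts",
    "pool",
]


class Role(Enum):
    """Whether a sample is a wild-population plant or a collected seed."""

    POPULATION = "population"
    SEED = "seed"

    @classmethod
    def parse(cls, text: str) -> "Role":
        t = str(text).strip().lower()
        for role in cls:
            if t == role.value:
                return role
        raise GenotypeFormatError(f"unknown role {text!r}; expected 'population' or 'seed'")


def _norm_call(a: int, b: int, *, context: str = "") -> tuple[int, int]:
    """Normalise a diploid call: unordered, half-calls become fully missing."""
    a, b = int(a), int(b)
    if a < 0 or b < 0:
        raise GenotypeFormatError(f"negative allele code in call ({a},{b}) {context}")
    if (a == MISSING) != (b == MISSING):
        warnings.warn(
            f"half-missing call ({a},{b}) {context} treated as fully missing",
            stacklevel=3,
        )
        return (MISSING, MISSING)
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class SampleRecord:
    """One genotyped individual (plant or seed) and its metadata."""

    sample_id: str
    population: str
    role: Role
    calls: Mapping[str, tuple[int, int]]
    bunch_id: str | None = None
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self):
        if self.role is Role.SEED and not self.bunch_id:
            raise GenotypeFormatError(
                f"sample {self.sample_id!r} has role=seed but no bunch_id"
            )
        norm = {
            locus: _norm_call(*call, context=f"(sample {self.sample_id}, locus {locus})")
            for locus, call in self.calls.items()
        }
        object.__setattr__(self, "calls", norm)

    def is_missing(self, locus: str) -> bool:
        a, b = self.calls[locus]
        return a == MISSING or b == MISSING

    def missing_fraction(self, loci: Sequence[str] | None = None) -> float:
        loci = list(self.calls) if loci is None else list(loci)
        return sum(self.is_missing(l) for l in loci) / len(loci)


@dataclass
class GenotypeDataset:
    """Samples x loci diploid allele calls with grouping metadata."""

    loci: list[str]
    samples: list[SampleRecord]
    provenance: str = ""

    def __post_init__(self):
        if not self.loci:
            raise EmptyDatasetError("dataset has no loci")
        if not self.samples:
            raise EmptyDatasetError("dataset has no samples")
        if len(set(self.loci)) != len(self.loci):
            raise GenotypeFormatError("duplicate locus names")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise GenotypeFormatError(f"duplicate sample_id(s): {dupes}")
        locus_set = set(self.loci)
        for s in self.samples:
            if set(s.calls) != locus_set:
                raise GenotypeFormatError(
                    f"sample {s.sample_id!r} does not carry the dataset locus list"
                )

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def allele_array(self) -> np.ndarray:
        """Calls as an int array of shape (n_samples, n_loci, 2); 0 = missing."""
        out = np.zeros((self.n_samples, self.n_loci, 2), dtype=np.int64)
        for i, s in enumerate(self.samples):
            for j, locus in enumerate(self.loci):
                out[i, j, :] = s.calls[locus]
        return out

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "population": [s.population for s in self.samples],
                "role": [s.role.value for s in self.samples],
                "bunch": [s.bunch_id for s in self.samples],
                "lat": [s.latitude for s in self.samples],
                "lon": [s.longitude for s in self.samples],
            }
        )

    def subset(self, sample_idx: Iterable[int] | None = None,
               loci: Sequence[str] | None = None,
               provenance: str | None = None) -> "GenotypeDataset":
        keep_samples = (
            self.samples if sample_idx is None else [self.samples[i] for i in sample_idx]
        )
        keep_loci = list(self.loci) if loci is None else list(loci)
        if loci is not None:
            keep_samples = [
                replace(s, calls={l: s.calls[l] for l in keep_loci}) for s in keep_samples
            ]
        return GenotypeDataset(
            loci=keep_loci,
            samples=list(keep_samples),
            provenance=self.provenance if provenance is None else provenance,
        )


@dataclass(frozen=True)
class AlleleFrequencyTable:
    """Relative allele frequencies of one grouping, per locus.

    ``frequencies[locus][allele]`` is the share of that allele among the
    non-missing gene copies of the group; ``copies[locus]`` is the number of
    non-missing gene copies used.  Loci where the group has zero usable
    copies are listed in ``empty_loci`` and carry no frequencies.
    """

    label: str
    frequencies: Mapping[str, Mapping[int, float]]
    copies: Mapping[str, int]
    empty_loci: tuple[str, ...] = ()

    def alleles(self, locus: str) -> set[int]:
        return set(self.frequencies.get(locus, {}))

    def locus_names(self) -> list[str]:
        return list(self.frequencies) + list(self.empty_loci)


@dataclass(frozen=True)
class FilterReport:
    """What the missing-data filter removed, and why."""

    threshold: float
    dropped_loci: Mapping[str, float] = field(default_factory=dict)
    dropped_samples: Mapping[str, float] = field(default_factory=dict)
    final_missing_percent: float = 0.0

    @property
    def empty(self) -> bool:
        return not self.dropped_loci and not self.dropped_samples


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

_META_COLS = ["sample_id", "population", "role", "bunch", "lat", "lon"]


def _locus_pairs(columns: Sequence[str]) -> list[str]:
    """Extract the ordered locus list from ``<locus>_1``/``<locus>_2`` columns."""
    allele_cols = [c for c in columns if c not in _META_COLS]
    loci: list[str] = []
    seen: dict[str, set[str]] = {}
    for col in allele_cols:
        if "_" not in col or col.rsplit("_", 1)[1] not in ("1", "2"):
            raise GenotypeFormatError(
                f"column {col!r} is not of the form <locus>_1 / <locus>_2"
            )
        locus, which = col.rsplit("_", 1)
        if locus not in seen:
            seen[locus] = set()
            loci.append(locus)
        seen[locus].add(which)
    for locus, parts in seen.items():
        if parts != {"1", "2"}:
            missing = sorted({"1", "2"} - parts)
            raise GenotypeFormatError(
                f"locus {locus!r} is missing allele column(s) "
                + ", ".join(f"{locus}_{m}" for m in missing)
            )
    return loci


def read_genotype_table(source, *, sep: str = ",") -> GenotypeDataset:
    """Read a delimited genotype table (see module docstring for the schema).

    ``source`` may be a path or an open text stream.  Missing alleles may be
    coded ``0`` or left empty; within-call allele order is not meaningful.
    """
    df = pd.read_csv(source, sep=sep, dtype={"sample_id": str, "population": str,
                                             "bunch": str}, keep_default_na=True)
    missing_meta = [c for c in ("sample_id", "population", "role") if c not in df.columns]
    if missing_meta:
        raise GenotypeFormatError(f"missing required column(s): {missing_meta}")
    loci = _locus_pairs(df.columns)
    if not loci:
        raise GenotypeFormatError("no locus columns found")

    samples = []
    for _, row in df.iterrows():
        calls = {}
        for locus in loci:
            a = row[f"{locus}_1"]
            b = row[f"{locus}_2"]
            a = MISSING if pd.isna(a) else int(a)
            b = MISSING if pd.isna(b) else int(b)
            calls[locus] = (a, b)
        bunch = row.get("bunch")
        bunch = None if (bunch is None or pd.isna(bunch) or bunch == "") else str(bunch)
        lat = row.get("lat")
        lon = row.get("lon")
        samples.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                population=str(row["population"]),
                role=Role.parse(row["role"]),
                bunch_id=bunch,
                latitude=None if lat is None or pd.isna(lat) else float(lat),
                longitude=None if lon is None or pd.isna(lon) else float(lon),
                calls=calls,
            )
        )
    return GenotypeDataset(loci=loci, samples=samples)


def write_genotype_table(dataset: GenotypeDataset, dest, *, sep: str = ",") -> None:
    """Write ``dataset`` in the dialect accepted by :func:`read_genotype_table`."""
    rows = []
    for s in dataset.samples:
        row: dict[str, object] = {
            "sample_id": s.sample_id,
            "population": s.population,
            "role": s.role.value,
            "bunch": s.bunch_id or "",
            "lat": "" if s.latitude is None else s.latitude,
            "lon": "" if s.longitude is None else s.longitude,
        }
        for locus in dataset.loci:
            a, b = s.calls[locus]
            row[f"{locus}_1"] = a
            row[f"{locus}_2"] = b
        rows.append(row)
    cols = _META_COLS + [f"{l}_{i}" for l in dataset.loci for i in ("1", "2")]
    pd.DataFrame(rows, columns=cols).to_csv(dest, sep=sep, index=False)


def write_genalex(dataset: GenotypeDataset, dest) -> None:
    """Write a GenAlEx-compatible two-column-per-locus CSV (emit only).

    Layout version: GenAlEx 6.5 codominant. Row 1: n_loci, n_samples,
    n_populations, then per-population sample counts; row 2: title then
    population names over their count columns; row 3: headers.
    """
    pops: dict[str, int] = {}
    for s in dataset.samples:
        pops[s.population] = pops.get(s.population, 0) + 1
    pop_names = list(pops)
    own = hasattr(dest, "write")
    fh = dest if own else open(dest, "w", encoding="utf-8")
    try:
        line1 = [str(dataset.n_loci), str(dataset.n_samples), str(len(pop_names))]
        line1 += [str(pops[p]) for p in pop_names]
        fh.write(",".join(line1) + "\n")
        line2 = ["genecapture export", "", ""] + pop_names
        fh.write(",".join(line2) + "\n")
        header = ["Sample", "Pop"]
        for locus in dataset.loci:
            header += [locus, ""]
        fh.write(",".join(header) + "\n")
        for s in dataset.samples:
            row = [s.sample_id, s.population]
            for locus in dataset.loci:
                a, b = s.calls[locus]
                row += [str(a), str(b)]
            fh.write(",".join(row) + "\n")
    finally:
        if not own:
            fh.close()


# ---------------------------------------------------------------------------
# filtering, grouping, pooling
# ---------------------------------------------------------------------------


def filter_missing(
    dataset: GenotypeDataset, max_missing_fraction: float = 0.25
) -> tuple[GenotypeDataset, FilterReport]:
    """Drop loci, then samples, whose missing fraction strictly exceeds the cut.

    Loci are evaluated first against all samples; samples are then evaluated
    against the retained loci only.  A call is missing when either allele is
    absent.  Entities at exactly the threshold are retained ("more than").
    """
    if not 0 <= max_missing_fraction < 1:
        raise ValueError("max_missing_fraction must be in [0, 1)")
    n = dataset.n_samples
    dropped_loci: dict[str, float] = {}
    for locus in dataset.loci:
        frac = sum(s.is_missing(locus) for s in dataset.samples) / n
        if frac > max_missing_fraction:
            dropped_loci[locus] = frac
    keep_loci = [l for l in dataset.loci if l not in dropped_loci]
    if not keep_loci:
        raise EmptyDatasetError(
            f"all {dataset.n_loci} loci exceed {max_missing_fraction:.0%} missing data"
        )

    dropped_samples: dict[str, float] = {}
    keep_idx = []
    for i, s in enumerate(dataset.samples):
        frac = s.missing_fraction(keep_loci)
        if frac > max_missing_fraction:
            dropped_samples[s.sample_id] = frac
        else:
            keep_idx.append(i)
    if not keep_idx:
        raise EmptyDatasetError(
            f"all samples exceed {max_missing_fraction:.0%} missing data "
            "after locus filtering"
        )

    filtered = dataset.subset(keep_idx, keep_loci)
    n_missing = sum(
        s.is_missing(l) for s in filtered.samples for l in filtered.loci
    )
    report = FilterReport(
        threshold=max_missing_fraction,
        dropped_loci=dropped_loci,
        dropped_samples=dropped_samples,
        final_missing_percent=100.0 * n_missing / (filtered.n_samples * filtered.n_loci),
    )
    return filtered, report


def _group_key(sample: SampleRecord, by: Sequence[str]) -> tuple:
    parts = []
    for key in by:
        if key == "population":
            parts.append(sample.population)
        elif key == "role":
            parts.append(sample.role.value)
        elif key == "bunch":
            parts.append(sample.bunch_id)
        elif key == "sample":
            parts.append(sample.sample_id)
        else:
            raise ValueError(f"unknown grouping key {key!r}")
    return tuple(parts)


def group_samples(
    dataset: GenotypeDataset, by: str | Sequence[str]
) -> dict[str, list[SampleRecord]]:
    """Partition samples by metadata key(s): population, role, bunch, sample."""
    keys = [by] if isinstance(by, str) else list(by)
    groups: dict[str, list[SampleRecord]] = {}
    for s in dataset.samples:
        label = "/".join(str(p) for p in _group_key(s, keys))
        groups.setdefault(label, []).append(s)
    return groups


def allele_counts(
    samples: Sequence[SampleRecord], loci: Sequence[str]
) -> dict[str, dict[int, int]]:
    """Raw allele-copy counts per locus over non-missing calls."""
    counts: dict[str, dict[int, int]] = {l: {} for l in loci}
    for s in samples:
        for locus in loci:
            a, b = s.calls[locus]
            if a == MISSING or b == MISSING:
                continue
            counts[locus][a] = counts[locus].get(a, 0) + 1
            counts[locus][b] = counts[locus].get(b, 0) + 1
    return counts


def allele_frequencies(
    dataset: GenotypeDataset, by: str | Sequence[str] = "role"
) -> list[AlleleFrequencyTable]:
    """Per-group, per-locus relative allele frequencies over non-missing copies.

    Groups are defined by any combination of metadata keys (``"role"``,
    ``"population"``, ``"bunch"``, or a list such as ``["role",
    "population"]``).  A locus at which a group has no usable gene copies is
    flagged in the table's ``empty_loci`` and carries no frequencies.
    """
    tables = []
    for label, members in group_samples(dataset, by).items():
        counts = allele_counts(members, dataset.loci)
        freqs: dict[str, dict[int, float]] = {}
        copies: dict[str, int] = {}
        empty: list[str] = []
        for locus in dataset.loci:
            total = sum(counts[locus].values())
            copies[locus] = total
            if total == 0:
                empty.append(locus)
                continue
            freqs[locus] = {a: c / total for a, c in counts[locus].items()}
        tables.append(
            AlleleFrequencyTable(
                label=label, frequencies=freqs, copies=copies, empty_loci=tuple(empty)
            )
        )
    return tables


def pool(dataset: GenotypeDataset, role: Role | str) -> GenotypeDataset:
    """Regional pooling: the sub-dataset of all samples with the given role."""
    if isinstance(role, str):
        role = Role.parse(role)
    idx = [i for i, s in enumerate(dataset.samples) if s.role is role]
    if not idx:
        raise EmptyDatasetError(f"no samples with role={role.value!r}")
    return dataset.subset(idx, provenance=f"{dataset.provenance} [pool role={role.value}]")


def dataset_to_stream_text(dataset: GenotypeDataset) -> str:
    """Serialise a dataset to the exchange-table text (round-trip helper)."""
    buf = _io.StringIO()
    write_genotype_table(dataset, buf)
    return buf.getvalue()
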