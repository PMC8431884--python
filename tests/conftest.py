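"""Shared fixtures: small genotype datasets built programmatically."""

from __future__ import annotations

import pytest

from genecapture.io import GenotypeDataset, Role, SampleRecord


def make_sample(
    sample_id: str,
    calls: dict[str, tuple[int, int]],
    population: str = "pop1",
    role: Role = Role.POPULATION,
    bunch_id: str | None = None,
    latitude: float | None = None,
    longitude: float | None = None,
) -> SampleRecord:
    if role is Role.SEED and bunch_id is None:
        bunch_id = f"bunch_{population}"
    return SampleRecord(
        sample_id=sample_id,
        population=population,
        role=role,
        bunch_id=bunch_id,
        latitude=latitude,
        longitude=longitude,
        calls=calls,
    )


def make_dataset(rows, loci=None) -> GenotypeDataset:
    """rows: list of (sample_id, population, role, bunch, {locus: call})."""
    samples = []
    for sample_id, population, role, bunch, calls in rows:
        samples.append(
            make_sample(sample_id, calls, population=population, role=role,
                        bunch_id=bunch)
        )
    if loci is None:
        loci = list(rows[0][4])
    return GenotypeDataset(loci=loci, samples=samples)


@pytest.fixture
def two_pop_dataset() -> GenotypeDataset:
    """Two populations of three plants each plus one 2-seed bunch per
    population; two loci, a private allele in each population."""
    rows = [
        ("a1", "A", Role.POPULATION, None, {"L1": (101, 101), "L2": (201, 203)}),
        ("a2", "A", Role.POPULATION, None, {"L1": (101, 103), "L2": (201, 201)}),
        ("a3", "A", Role.POPULATION, None, {"L1": (101, 101), "L2": (203, 203)}),
        ("b1", "B", Role.POPULATION, None, {"L1": (105, 105), "L2": (201, 201)}),
        ("b2", "B", Role.POPULATION, None, {"L1": (105, 101), "L2": (201, 205)}),
        ("b3", "B", Role.POPULATION, None, {"L1": (105, 105), "L2": (205, 205)}),
        ("sa1", "A", Role.SEED, "bunchA", {"L1": (101, 101), "L2": (201, 203)}),
        ("sa2", "A", Role.SEED, "bunchA", {"L1": (101, 103), "L2": (201, 201)}),
        ("sb1", "B", Role.SEED, "bunchB", {"L1": (105, 105), "L2": (201, 205)}),
        ("sb2", "B", Role.SEED, "bunchB", {"L1": (105, 105), "L2": (205, 205)}),
    ]
    return make_dataset(rows)
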