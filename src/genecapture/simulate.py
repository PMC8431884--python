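"""Generative model for wild-population genotypes and maternal seed bunches.

The simulator produces :class:`~genecapture.io.GenotypeDataset` objects with
the structure the downstream analysis assumes: several local populations
drifted around regional allele frequencies, one maternal bunch of seeds per
population, and a mixed mating system.

Model
-----
Regional allele frequencies per locus are symmetric-Dirichlet draws
(concentration ``regional_alpha``; small values give skewed spectra with many
rare alleles).  Local population frequencies drift around the regional mean
under a Balding–Nichols parameterisation: ``Dirichlet(p * (1-theta)/theta)``,
so ``theta`` plays the role of Fst-like differentiation.  Adult genotypes are
drawn with inbreeding coefficient ``F``:

    P(homozygote ii)      = p_i^2 + F p_i (1 - p_i)
    P(heterozygote ij)    = 2 p_i p_j (1 - F)

Each seed of a bunch is generated by a hierarchical mating cascade: with
probability ``apomixis_rate`` the seed is an exact clone of the mother; else
a maternal gamete is drawn (independent Mendelian segregation per locus) and
the pollen source is the mother herself (prob ``selfing_rate``), a migrant
genotype drawn from the regional frequencies (prob ``migrant_pollen_rate``),
or a uniformly chosen other adult of the same population.  Missing data is
then masked per call, independently.

Presets named after the three wild banana (*Musa*) mating syndromes —
near-complete selfing with apomixis (``acuminata_like``), mixed mating with
low diversity (``balbisiana_like``) and outcrossing with high diversity and
isolation by distance (``maclayi_like``) — are shipped as YAML configs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import GenecaptureError
from .io import MISSING, GenotypeDataset, Role, SampleRecord

__all__ = [
    "SimulationConfig",
    "Parentage",
    "TruthRecord",
    "simulate_regional_frequencies",
    "simulate_population",
    "simulate_bunch",
    "simulate_dataset",
    "load_preset",
    "preset_names",
    "SELF",
    "APOMICT",
    "MIGRANT",
]

SELF = "SELF"
APOMICT = "APOMICT"
MIGRANT = "MIGRANT"

_ALLELE_BASE = 100  # allele code for index i is _ALLELE_BASE + 2*i (bp-like)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generative model; see the module docstring."""

    n_loci: int = 16
    alleles_per_locus: int = 8
    regional_alpha: float = 1.0
    n_populations: int = 5
    theta: float = 0.2
    n_adults_per_pop: int = 15
    inbreeding_f: float = 0.0
    selfing_rate: float = 0.0
    apomixis_rate: float = 0.0
    migrant_pollen_rate: float = 0.0
    seeds_per_bunch: int = 16
    missing_rate: float = 0.0
    spatial_gradient: bool = False
    dominant_weight: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.alleles_per_locus < 2:
            raise ValueError("alleles_per_locus must be >= 2 (polymorphic loci)")
        if self.regional_alpha <= 0:
            raise ValueError("regional_alpha must be > 0")
        if not 0 < self.theta < 1:
            raise ValueError("theta must be in (0, 1)")
        for name in ("inbreeding_f", "selfing_rate", "apomixis_rate",
                     "migrant_pollen_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.selfing_rate + self.migrant_pollen_rate > 1 + 1e-12:
            raise ValueError("selfing_rate + migrant_pollen_rate must be <= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.dominant_weight < 1:
            raise ValueError("dominant_weight must be >= 1")
        if min(self.n_populations, self.n_adults_per_pop, self.seeds_per_bunch) < 1:
            raise ValueError("counts must be >= 1")

    def locus_names(self) -> list[str]:
        return [f"L{j + 1:02d}" for j in range(self.n_loci)]


@dataclass(frozen=True)
class Parentage:
    """Recorded origin of one simulated seed."""

    seed_id: str
    mother_id: str
    father: str  # adult sample_id, or SELF / APOMICT / MIGRANT


@dataclass
class TruthRecord:
    """Ground truth of a simulated dataset, for parameter-recovery tests."""

    config: SimulationConfig
    regional_frequencies: np.ndarray  # (n_loci, k)
    local_frequencies: list[np.ndarray] = field(default_factory=list)
    parentage: dict[str, Parentage] = field(default_factory=dict)
    mothers: dict[str, str] = field(default_factory=dict)  # population -> mother id


def _allele_code(i: int) -> int:
    return _ALLELE_BASE + 2 * i


def simulate_regional_frequencies(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Per-locus regional allele-frequency vectors, shape (n_loci, k).

    Symmetric Dirichlet(regional_alpha) by default.  ``dominant_weight > 1``
    multiplies the first component's concentration, producing the spectrum
    highly selfing SSR surveys show — one reliably common allele per locus
    plus a tail of rare ones — which a symmetric Dirichlet cannot generate
    (its sparse limit concentrates the tail in a single second allele).
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    alpha = np.full(config.alleles_per_locus, config.regional_alpha)
    alpha[0] *= config.dominant_weight
    return rng.dirichlet(alpha, size=config.n_loci)


def _draw_genotype(freqs: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """Diploid genotype (allele indices per locus, shape (n_loci, 2)) with
    inbreeding coefficient ``f``."""
    n_loci, k = freqs.shape
    out = np.empty((n_loci, 2), dtype=np.int64)
    for j in range(n_loci):
        p = freqs[j]
        if f > 0 and rng.random() < f:
            a = rng.choice(k, p=p)
            out[j] = (a, a)
        else:
            out[j] = rng.choice(k, size=2, p=p)
    return out


def _to_calls(
    genotype: np.ndarray, loci: Sequence[str]
) -> dict[str, tuple[int, int]]:
    return {
        locus: (_allele_code(int(genotype[j, 0])), _allele_code(int(genotype[j, 1])))
        for j, locus in enumerate(loci)
    }


def simulate_population(
    regional: np.ndarray,
    config: SimulationConfig,
    population_index: int,
    rng: np.random.Generator,
    gradient_endpoint: np.ndarray | None = None,
) -> tuple[list[SampleRecord], np.ndarray, list[np.ndarray]]:
    """One local population: adults drawn from drifted local frequencies.

    Returns ``(adults, local_frequencies, adult_genotypes)``; the genotypes
    (allele indices, unmasked) are kept so bunches can be mated from them.
    When ``spatial_gradient`` is set the local Dirichlet mean is interpolated
    between the regional frequencies and ``gradient_endpoint`` along the
    population's transect position, inducing isolation by distance.
    """
    if not 0 < config.theta < 1:
        raise ValueError("theta must be in (0, 1)")
    n_pop = config.n_populations
    x = population_index / (n_pop - 1) if n_pop > 1 else 0.0
    mean = regional
    if config.spatial_gradient:
        if gradient_endpoint is None:
            raise GenecaptureError("spatial_gradient requires a gradient endpoint")
        mean = (1 - x) * regional + x * gradient_endpoint
    conc = (1 - config.theta) / config.theta
    local = np.empty_like(mean)
    for j in range(config.n_loci):
        alpha = np.maximum(mean[j] * conc, 1e-9)
        local[j] = rng.dirichlet(alpha)

    loci = config.locus_names()
    pop_name = f"pop{population_index + 1}"
    adults: list[SampleRecord] = []
    genotypes: list[np.ndarray] = []
    for i in range(config.n_adults_per_pop):
        g = _draw_genotype(local, config.inbreeding_f, rng)
        genotypes.append(g)
        adults.append(
            SampleRecord(
                sample_id=f"{pop_name}_A{i + 1:02d}",
                population=pop_name,
                role=Role.POPULATION,
                calls=_to_calls(g, loci),
                latitude=0.0,
                longitude=10.0 * population_index,
            )
        )
    return adults, local, genotypes


def _gamete(genotype: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One allele per locus, independent Mendelian segregation."""
    picks = rng.integers(0, 2, size=genotype.shape[0])
    return genotype[np.arange(genotype.shape[0]), picks]


def simulate_bunch(
    mother_index: int,
    adult_genotypes: Sequence[np.ndarray],
    adult_ids: Sequence[str],
    regional: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    population: str,
    bunch_id: str,
    latitude: float,
    longitude: float,
) -> tuple[list[SampleRecord], list[Parentage]]:
    """All seeds of one maternal bunch, via the apomixis/selfing/migrant cascade."""
    mother = adult_genotypes[mother_index]
    mother_id = adult_ids[mother_index]
    others = [i for i in range(len(adult_genotypes)) if i != mother_index]
    loci = config.locus_names()
    seeds: list[SampleRecord] = []
    parentage: list[Parentage] = []
    for snum in range(config.seeds_per_bunch):
        seed_id = f"{bunch_id}_S{snum + 1:02d}"
        if rng.random() < config.apomixis_rate:
            g = mother.copy()
            father = APOMICT
        else:
            maternal = _gamete(mother, rng)
            u = rng.random()
            if u < config.selfing_rate:
                paternal = _gamete(mother, rng)
                father = SELF
            elif u < config.selfing_rate + config.migrant_pollen_rate:
                migrant = _draw_genotype(regional, 0.0, rng)
                paternal = _gamete(migrant, rng)
                father = MIGRANT
            else:
                if not others:
                    raise GenecaptureError(
                        "no pollen source: population has no adult besides the "
                        "mother and selfing_rate + migrant_pollen_rate < 1"
                    )
                donor = others[rng.integers(0, len(others))]
                paternal = _gamete(adult_genotypes[donor], rng)
                father = adult_ids[donor]
            g = np.stack([maternal, paternal], axis=1)
        calls = _to_calls(g, loci)
        if config.missing_rate > 0:
            for locus in loci:
                if rng.random() < config.missing_rate:
                    calls[locus] = (MISSING, MISSING)
        seeds.append(
            SampleRecord(
                sample_id=seed_id,
                population=population,
                role=Role.SEED,
                bunch_id=bunch_id,
                calls=calls,
                latitude=latitude,
                longitude=longitude,
            )
        )
        parentage.append(Parentage(seed_id=seed_id, mother_id=mother_id, father=father))
    return seeds, parentage


def _mask_calls(
    record: SampleRecord, rate: float, rng: np.random.Generator
) -> SampleRecord:
    if rate <= 0:
        return record
    calls = dict(record.calls)
    for locus in calls:
        if rng.random() < rate:
            calls[locus] = (MISSING, MISSING)
    return SampleRecord(
        sample_id=record.sample_id,
        population=record.population,
        role=record.role,
        bunch_id=record.bunch_id,
        latitude=record.latitude,
        longitude=record.longitude,
        calls=calls,
    )


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenotypeDataset, TruthRecord]:
    """Full study design: populations on a 1-D transect, one bunch per
    population with a uniformly chosen mother.  Fully reproducible from
    ``config.rng_seed``."""
    rng = np.random.default_rng(config.rng_seed)
    regional = simulate_regional_frequencies(config, rng)
    endpoint = None
    if config.spatial_gradient:
        endpoint = rng.dirichlet(
            np.full(config.alleles_per_locus, config.regional_alpha),
            size=config.n_loci,
        )
    truth = TruthRecord(config=config, regional_frequencies=regional)
    samples: list[SampleRecord] = []
    for p in range(config.n_populations):
        adults, local, genotypes = simulate_population(
            regional, config, p, rng, gradient_endpoint=endpoint
        )
        truth.local_frequencies.append(local)
        mother_index = int(rng.integers(0, config.n_adults_per_pop))
        pop_name = adults[0].population
        truth.mothers[pop_name] = adults[mother_index].sample_id
        seeds, parentage = simulate_bunch(
            mother_index,
            genotypes,
            [a.sample_id for a in adults],
            regional,
            config,
            rng,
            population=pop_name,
            bunch_id=f"bunch{p + 1}",
            latitude=0.0,
            longitude=10.0 * p,
        )
        for rec in parentage:
            truth.parentage[rec.seed_id] = rec
        samples.extend(_mask_calls(a, config.missing_rate, rng) for a in adults)
        samples.extend(seeds)
    dataset = GenotypeDataset(
        loci=config.locus_names(),
        samples=samples,
        provenance=f"simulated (seed={config.rng_seed})",
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def preset_names() -> list[str]:
    files = resources.files("genecapture").joinpath("presets")
    return sorted(p.name[: -len(".yaml")] for p in files.iterdir()
                  if p.name.endswith(".yaml"))


def load_preset(
    name: str, *, rng_seed: int | None = None, **overrides
) -> SimulationConfig:
    """Load a named preset YAML config, optionally overriding fields."""
    path = resources.files("genecapture").joinpath("presets", f"{name}.yaml")
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise GenecaptureError(
            f"unknown preset {name!r}; available: {preset_names()}"
        ) from None
    params: Mapping = yaml.safe_load(text)
    params = dict(params)
    params.pop("description", None)
    params.update(overrides)
    if rng_seed is not None:
        params["rng_seed"] = rng_seed
    unknown = set(params) - set(SimulationConfig.__dataclass_fields__)
    if unknown:
        raise GenecaptureError(f"unknown config key(s) in preset {name!r}: {sorted(unknown)}")
    return SimulationConfig(**params)


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
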