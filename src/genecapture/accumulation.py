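"""Allele accumulation over collection units and total-richness extrapolation.

The central question for an ex situ collector: as collection units are added
(local populations, maternal seed bunches, or single seeds within a bunch),
how fast does the cumulative set of distinct alleles grow, what is the
extrapolated total allelic richness of the region (or bunch), and how many
units are needed to capture 70% (the Global Strategy for Plant Conservation
Target 9 benchmark) or 90% of it?

Everything is driven by an incidence matrix: unit x allele presence/absence,
the same structure community ecologists use for species accumulation, with
alleles playing the role of species and collection units the role of sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import EmptyDatasetError
from .io import MISSING, GenotypeDataset, Role, SampleRecord, group_samples

__all__ = [
    "IncidenceMatrix",
    "RichnessEstimate",
    "AccumulationCurve",
    "ThresholdResult",
    "NOT_REACHED",
    "build_incidence",
    "incidences_per_bunch",
    "extrapolate_total_richness",
    "accumulation_curve",
    "units_to_threshold",
    "allele_membership",
]

NOT_REACHED = "NOT_REACHED"

ESTIMATORS = ("bootstrap", "chao2", "jackknife1")


@dataclass(frozen=True)
class IncidenceMatrix:
    """Unit x allele presence matrix; alleles are (locus, allele-code) pairs."""

    units: tuple[str, ...]
    alleles: tuple[tuple[str, int], ...]
    presence: np.ndarray  # bool, shape (n_units, n_alleles)

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def s_obs(self) -> int:
        return len(self.alleles)

    def incidence_counts(self) -> np.ndarray:
        """f_i: number of units containing each allele."""
        return self.presence.sum(axis=0)


@dataclass(frozen=True)
class RichnessEstimate:
    s_hat: float
    s_obs: int
    estimator: str
    q1: int
    q2: int
    se: float | None = None


@dataclass
class AccumulationCurve:
    """Per-step accumulation of distinct alleles over unit orderings."""

    unit_type: str
    units: tuple[str, ...]
    k: np.ndarray  # 1..n_units
    mean: np.ndarray
    sd: np.ndarray  # NaN for the exact method
    method: str
    n_resamples: int | None
    s_obs: int
    richness: RichnessEstimate
    normalized: np.ndarray = field(init=False)  # percent of s_hat

    def __post_init__(self):
        self.normalized = 100.0 * self.mean / self.richness.s_hat


@dataclass(frozen=True)
class ThresholdResult:
    target: float
    k: int | None  # units needed; None when not reached and not extrapolable
    reached: bool
    extrapolated: bool = False


# ---------------------------------------------------------------------------
# incidence construction
# ---------------------------------------------------------------------------


def _unit_allele_set(samples: Sequence[SampleRecord], loci: Sequence[str]) -> set:
    out = set()
    for s in samples:
        for locus in loci:
            a, b = s.calls[locus]
            if a != MISSING:
                out.add((locus, a))
            if b != MISSING:
                out.add((locus, b))
    return out


def build_incidence(
    dataset: GenotypeDataset,
    unit: str,
    bunch_id: str | None = None,
) -> IncidenceMatrix:
    """Incidence of alleles across collection units.

    ``unit`` is ``"population"`` (wild-plant samples per population),
    ``"bunch"`` (seed samples per maternal bunch) or ``"seed"`` (single
    seeds of one bunch as units; requires ``bunch_id``).
    """
    if unit == "population":
        members = [s for s in dataset.samples if s.role is Role.POPULATION]
        if not members:
            raise EmptyDatasetError("no population samples")
        key = lambda s: s.population  # noqa: E731
    elif unit == "bunch":
        members = [s for s in dataset.samples if s.role is Role.SEED]
        if not members:
            raise EmptyDatasetError("no seed samples (unit='bunch')")
        key = lambda s: s.bunch_id  # noqa: E731
    elif unit == "seed":
        if bunch_id is None:
            raise ValueError("unit='seed' requires bunch_id")
        members = [
            s for s in dataset.samples
            if s.role is Role.SEED and s.bunch_id == bunch_id
        ]
        if not members:
            raise EmptyDatasetError(f"no seeds in bunch {bunch_id!r}")
        key = lambda s: s.sample_id  # noqa: E731
    else:
        raise ValueError("unit must be 'population', 'bunch' or 'seed'")

    units: dict[str, list[SampleRecord]] = {}
    for s in members:
        units.setdefault(key(s), []).append(s)
    unit_sets = {}
    for label, samples in units.items():
        alleles = _unit_allele_set(samples, dataset.loci)
        if not alleles:
            raise EmptyDatasetError(f"unit {label!r} has no non-missing calls")
        unit_sets[label] = alleles
    all_alleles = sorted(set().union(*unit_sets.values()))
    labels = tuple(unit_sets)
    presence = np.zeros((len(labels), len(all_alleles)), dtype=bool)
    col = {a: j for j, a in enumerate(all_alleles)}
    for i, label in enumerate(labels):
        for a in unit_sets[label]:
            presence[i, col[a]] = True
    return IncidenceMatrix(units=labels, alleles=tuple(all_alleles), presence=presence)


def incidences_per_bunch(dataset: GenotypeDataset) -> dict[str, IncidenceMatrix]:
    """Seed-level incidence matrices, one per maternal bunch."""
    bunches = sorted(
        {s.bunch_id for s in dataset.samples if s.role is Role.SEED and s.bunch_id}
    )
    if not bunches:
        raise EmptyDatasetError("dataset has no seed bunches")
    return {b: build_incidence(dataset, "seed", bunch_id=b) for b in bunches}


# ---------------------------------------------------------------------------
# richness extrapolation
# ---------------------------------------------------------------------------


def extrapolate_total_richness(
    incidence: IncidenceMatrix, estimator: str = "bootstrap"
) -> RichnessEstimate:
    """Incidence-based total-richness estimate.

    * ``bootstrap``:  S_hat = S_obs + sum_i (1 - p_i)^n, p_i = f_i / n
    * ``chao2``:      S_hat = S_obs + q1^2 / (2 q2) when q2 > 0,
      else the bias-corrected S_obs + q1 (q1 - 1) / 2
    * ``jackknife1``: S_hat = S_obs + q1 (n - 1) / n

    q1/q2 are the numbers of alleles found in exactly 1 / 2 units.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")
    n = incidence.n_units
    f = incidence.incidence_counts()
    s_obs = incidence.s_obs
    q1 = int(np.sum(f == 1))
    q2 = int(np.sum(f == 2))
    se = None
    if estimator == "bootstrap":
        if n < 1:
            raise EmptyDatasetError("bootstrap estimator needs >= 1 unit")
        p = f / n
        s_hat = s_obs + float(np.sum((1.0 - p) ** n))
    elif estimator == "chao2":
        if n < 2:
            raise EmptyDatasetError("chao2 needs >= 2 units")
        if q2 > 0:
            s_hat = s_obs + q1**2 / (2.0 * q2)
            se = math.sqrt(
                q2 * (0.5 * (q1 / q2) ** 2 + (q1 / q2) ** 3 + 0.25 * (q1 / q2) ** 4)
            )
        else:
            s_hat = s_obs + q1 * (q1 - 1) / 2.0
    else:  # jackknife1
        if n < 2:
            raise EmptyDatasetError("jackknife1 needs >= 2 units")
        s_hat = s_obs + q1 * (n - 1) / n
    return RichnessEstimate(
        s_hat=float(s_hat), s_obs=s_obs, estimator=estimator, q1=q1, q2=q2, se=se
    )


# ---------------------------------------------------------------------------
# accumulation curves
# ---------------------------------------------------------------------------


def _exact_mean_curve(incidence: IncidenceMatrix) -> np.ndarray:
    """Analytic mean cumulative richness: E[S_k] = sum_i [1 - C(n-f_i,k)/C(n,k)].

    Identical to averaging over all n! unit orderings (and all C(n,k)
    unordered subsets, which is the same thing for the mean)."""
    n = incidence.n_units
    f = incidence.incidence_counts()
    means = np.empty(n)
    for k in range(1, n + 1):
        denom = math.comb(n, k)
        total = 0.0
        for f_i in f:
            absent = math.comb(n - f_i, k) if n - f_i >= k else 0
            total += 1.0 - absent / denom
        means[k - 1] = total
    return means


def accumulation_curve(
    incidence: IncidenceMatrix,
    n_resamples: int = 999,
    rng_seed: int | None = None,
    method: str = "random",
    estimator: str = "bootstrap",
    richness: RichnessEstimate | None = None,
    unit_type: str = "unit",
    with_replacement: bool = False,
) -> AccumulationCurve:
    """Accumulation of distinct alleles as units are added in random order.

    ``method="random"`` averages ``n_resamples`` uniformly random unit
    orderings (permutations without replacement; ``with_replacement=True``
    switches to strict bootstrap draws of units).  ``method="exact"``
    evaluates the analytic mean (no SD).  The curve is normalised against
    ``richness.s_hat`` — pass a :class:`RichnessEstimate` computed on another
    incidence (e.g. regional populations) to normalise bunch curves against
    the regional total; by default the estimator is run on this incidence.
    """
    n = incidence.n_units
    if n < 1:
        raise EmptyDatasetError("no units")
    if richness is None:
        richness = extrapolate_total_richness(incidence, estimator)
    k = np.arange(1, n + 1)

    if method == "exact":
        if with_replacement:
            raise ValueError("exact method has no with-replacement variant")
        mean = _exact_mean_curve(incidence)
        sd = np.full(n, np.nan)
        n_res: int | None = None
    elif method == "random":
        if n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        rng = np.random.default_rng(rng_seed)
        acc = np.zeros((n_resamples, n))
        for r in range(n_resamples):
            if with_replacement:
                order = rng.integers(0, n, size=n)
            else:
                order = rng.permutation(n)
            cum = np.logical_or.accumulate(incidence.presence[order], axis=0)
            acc[r] = cum.sum(axis=1)
        mean = acc.mean(axis=0)
        sd = acc.std(axis=0, ddof=0)
        n_res = n_resamples
    else:
        raise ValueError("method must be 'random' or 'exact'")

    return AccumulationCurve(
        unit_type=unit_type,
        units=incidence.units,
        k=k,
        mean=mean,
        sd=sd,
        method=method,
        n_resamples=n_res,
        s_obs=incidence.s_obs,
        richness=richness,
    )


def _michaelis_menten_extrapolation(
    curve: AccumulationCurve, target_percent: float
) -> int | None:
    """Least-squares fit of S(k) = V k / (K + k) to the mean curve, solved for
    the unit count reaching ``target_percent`` of s_hat.  None when even the
    fitted asymptote V falls short of the target."""
    if len(curve.k) < 3:
        return None  # cannot fit two parameters on fewer than 3 points
    target_abs = target_percent / 100.0 * curve.richness.s_hat

    def mm(x, v, kk):
        return v * x / (kk + x)

    try:
        popt, _ = curve_fit(
            mm,
            curve.k.astype(float),
            curve.mean,
            p0=(curve.richness.s_hat, max(len(curve.k) / 2.0, 0.5)),
            maxfev=10000,
        )
    except RuntimeError:
        return None
    v, kk = popt
    if v <= target_abs:
        return None
    k_needed = target_abs * kk / (v - target_abs)
    if k_needed <= 0:
        return None
    return int(math.ceil(k_needed))


def units_to_threshold(
    curve: AccumulationCurve,
    targets: Sequence[float] = (70.0, 90.0),
    extrapolate: bool = True,
) -> dict[float, ThresholdResult]:
    """Smallest number of units whose mean normalised capture reaches each
    target percentage; NOT_REACHED targets get a saturating-curve
    (Michaelis-Menten) extrapolation, flagged as such, when possible."""
    out: dict[float, ThresholdResult] = {}
    for target in targets:
        if not 0 < target <= 100:
            raise ValueError(f"target {target} outside (0, 100]")
        hit = np.nonzero(curve.normalized >= target)[0]
        if hit.size:
            out[target] = ThresholdResult(
                target=target, k=int(curve.k[hit[0]]), reached=True
            )
        else:
            k_extra = (
                _michaelis_menten_extrapolation(curve, target) if extrapolate else None
            )
            out[target] = ThresholdResult(
                target=target, k=k_extra, reached=False, extrapolated=k_extra is not None
            )
    return out


# ---------------------------------------------------------------------------
# allele membership across groupings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MembershipTable:
    """Boolean allele x group membership with shared/unique tallies."""

    table: pd.DataFrame  # index (locus, allele), one bool column per group
    shared_by_all: int
    unique: Mapping[str, int]
    pairwise_shared: pd.DataFrame


def allele_membership(
    groups: Mapping[str, Sequence[SampleRecord]],
    loci: Sequence[str],
) -> MembershipTable:
    """Which alleles occur in which grouping (the numbers behind Euler/Venn
    displays of seed vs population allele sharing)."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groupings")
    sets = {label: _unit_allele_set(samples, loci) for label, samples in groups.items()}
    all_alleles = sorted(set().union(*sets.values()))
    labels = list(sets)
    data = {
        label: [a in sets[label] for a in all_alleles] for label in labels
    }
    table = pd.DataFrame(
        data, index=pd.MultiIndex.from_tuples(all_alleles, names=["locus", "allele"])
    )
    arr = table.to_numpy()
    shared_by_all = int(arr.all(axis=1).sum())
    unique = {
        label: int((arr[:, i] & ~np.delete(arr, i, axis=1).any(axis=1)).sum())
        for i, label in enumerate(labels)
    }
    pw = pd.DataFrame(
        [[int((arr[:, i] & arr[:, j]).sum()) for j in range(len(labels))]
         for i in range(len(labels))],
        index=labels,
        columns=labels,
    )
    return MembershipTable(
        table=table, shared_by_all=shared_by_all, unique=unique, pairwise_shared=pw
    )


def group_allele_sets(
    dataset: GenotypeDataset, by: str | Sequence[str]
) -> dict[str, list[SampleRecord]]:
    """Convenience partition for :func:`allele_membership`."""
    return group_samples(dataset, by)
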