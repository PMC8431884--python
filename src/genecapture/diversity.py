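"""Diversity indices for codominant genotype groups.

Implements the index panel used to compare wild populations with seed
collections: rarefied allelic richness (AR), private alleles (PA),
multilocus genotype counts (MLG), genotypic diversity (Shannon-Wiener H',
Simpson lambda, evenness E5), observed and expected heterozygosity (Ho,
Hexp with Nei's small-sample correction), the inbreeding coefficient Fis,
the seed-vs-population capture proportion, and Welch two-sample t tests.

Conventions
-----------
* AR is rarefied per locus by hypergeometric subsampling to ``g`` gene
  copies and *summed* over loci, so a 19-locus panel with ~4 alleles per
  locus yields AR near 70-80, matching how SSR survey tables report it.
* H', lambda and E5 are computed on multilocus-genotype abundances (clonal
  diversity), not allele frequencies; H' uses natural logs.
* Fis is the ratio-of-averages 1 - mean(Ho)/mean(Hexp) over loci with
  Hexp > 0, the standard hierarchical-F practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyDatasetError, UndefinedStatisticError
from .io import (
    MISSING,
    AlleleFrequencyTable,
    GenotypeDataset,
    SampleRecord,
    allele_counts,
    group_samples,
)

__all__ = [
    "DiversitySummary",
    "TTestResult",
    "rarefied_allelic_richness",
    "rarefied_richness_from_counts",
    "private_alleles",
    "count_mlg",
    "genotypic_diversity",
    "heterozygosity",
    "inbreeding_coefficient",
    "capture_proportion",
    "welch_t_test",
    "allele_frequency_spectrum",
    "summarize_diversity",
]


@dataclass(frozen=True)
class DiversitySummary:
    """One grouping's row of the diversity-index table."""

    label: str
    n: int
    ar: float
    pa: int | None
    mlg: int
    hprime: float
    lam: float
    e5: float
    hexp: float
    ho: float
    fis: float | None


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


# ---------------------------------------------------------------------------
# rarefied allelic richness
# ---------------------------------------------------------------------------


def _rarefied_locus_richness(counts: Mapping[int, int], g: int) -> float:
    """Expected distinct alleles in a hypergeometric subsample of g copies.

    AR_l = sum_i [1 - C(N - N_i, g) / C(N, g)]; terms with N - N_i < g
    contribute 1 (the allele is always sampled).
    """
    n_total = sum(counts.values())
    if g > n_total:
        raise ValueError(f"rarefaction depth g={g} exceeds {n_total} gene copies")
    denom = math.comb(n_total, g)
    ar = 0.0
    for n_i in counts.values():
        absent = math.comb(n_total - n_i, g) if n_total - n_i >= g else 0
        ar += 1.0 - absent / denom
    return ar


def rarefied_richness_from_counts(
    counts_by_group: Mapping[str, Mapping[str, Mapping[int, int]]],
    g: int | str = "auto",
) -> tuple[dict[str, float], pd.DataFrame]:
    """Rarefied AR from raw allele counts: group -> locus -> allele -> copies.

    ``g="auto"`` rarefies each locus to the minimum non-missing copy count
    across the groups being compared.  Loci where any group has fewer than 2
    usable copies are excluded from every group (flagged in the per-locus
    table) so groups stay comparable.
    """
    groups = list(counts_by_group)
    if not groups:
        raise EmptyDatasetError("no groups to rarefy")
    loci = list(next(iter(counts_by_group.values())))
    rows = []
    totals = {grp: 0.0 for grp in groups}
    for locus in loci:
        copies = {g_: sum(counts_by_group[g_][locus].values()) for g_ in groups}
        if g == "auto":
            depth = min(copies.values())
            if depth < 2:
                rows.append({"locus": locus, "g": depth, "included": False,
                             **{grp: np.nan for grp in groups}})
                continue
        else:
            depth = int(g)
            if depth < 2:
                raise ValueError("rarefaction depth must be >= 2")
            short = [grp for grp in groups if copies[grp] < depth]
            if short:
                raise ValueError(
                    f"g={depth} exceeds gene copies at locus {locus!r} for "
                    f"group(s) {short}"
                )
        row: dict[str, object] = {"locus": locus, "g": depth, "included": True}
        for grp in groups:
            ar_l = _rarefied_locus_richness(counts_by_group[grp][locus], depth)
            row[grp] = ar_l
            totals[grp] += ar_l
        rows.append(row)
    per_locus = pd.DataFrame(rows)
    return totals, per_locus


def rarefied_allelic_richness(
    dataset: GenotypeDataset,
    by: str | Sequence[str] = "role",
    g: int | str = "auto",
) -> tuple[dict[str, float], pd.DataFrame]:
    """Group AR (summed over loci) with a per-locus breakdown table."""
    grouped = group_samples(dataset, by)
    counts_by_group = {
        label: allele_counts(members, dataset.loci)
        for label, members in grouped.items()
    }
    return rarefied_richness_from_counts(counts_by_group, g)


# ---------------------------------------------------------------------------
# private alleles & spectra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrivateAlleles:
    count_a: int
    count_b: int
    alleles_a: Mapping[str, frozenset]
    alleles_b: Mapping[str, frozenset]


def private_alleles(
    table_a: AlleleFrequencyTable, table_b: AlleleFrequencyTable
) -> PrivateAlleles:
    """Alleles observed in one grouping and absent from the other, per locus."""
    loci_a = set(table_a.locus_names())
    loci_b = set(table_b.locus_names())
    shared = loci_a & loci_b
    if not shared:
        raise ValueError("groupings share no loci")
    only_a: dict[str, frozenset] = {}
    only_b: dict[str, frozenset] = {}
    for locus in shared:
        a = table_a.alleles(locus)
        b = table_b.alleles(locus)
        if a - b:
            only_a[locus] = frozenset(a - b)
        if b - a:
            only_b[locus] = frozenset(b - a)
    return PrivateAlleles(
        count_a=sum(len(v) for v in only_a.values()),
        count_b=sum(len(v) for v in only_b.values()),
        alleles_a=only_a,
        alleles_b=only_b,
    )


def allele_frequency_spectrum(
    table: AlleleFrequencyTable, rare_threshold: float = 0.05
) -> pd.DataFrame:
    """Flat (locus, allele, frequency, rare) list across loci of one grouping."""
    rows = [
        {"locus": locus, "allele": allele, "frequency": p, "rare": p < rare_threshold}
        for locus, freqs in table.frequencies.items()
        for allele, p in freqs.items()
    ]
    return pd.DataFrame(rows, columns=["locus", "allele", "frequency", "rare"])


# ---------------------------------------------------------------------------
# multilocus genotypes and genotypic diversity
# ---------------------------------------------------------------------------


def _mlg_signature(sample: SampleRecord, loci: Sequence[str]) -> tuple:
    return tuple(sample.calls[locus] for locus in loci)


def count_mlg(
    samples_or_dataset: GenotypeDataset | Sequence[SampleRecord],
    loci: Sequence[str] | None = None,
    missing: str = "distinct",
) -> tuple[int, list[int]]:
    """Distinct multilocus genotypes and the MLG id of each sample.

    A genotype is the tuple of unordered allele pairs across loci.  With
    ``missing="distinct"`` (default) a missing call is a state of its own;
    ``missing="wildcard"`` merges samples whose non-missing calls are
    compatible (transitively, via union-find — compatibility itself is not
    transitive, so merged groups may contain pairs differing only through a
    chain of intermediates).
    """
    if isinstance(samples_or_dataset, GenotypeDataset):
        samples = samples_or_dataset.samples
        loci = samples_or_dataset.loci
    else:
        samples = list(samples_or_dataset)
        if loci is None:
            raise ValueError("loci required when passing a bare sample list")
    if not samples:
        raise EmptyDatasetError("no samples")

    if missing == "distinct":
        seen: dict[tuple, int] = {}
        assignment = []
        for s in samples:
            sig = _mlg_signature(s, loci)
            assignment.append(seen.setdefault(sig, len(seen)))
        return len(seen), assignment

    if missing != "wildcard":
        raise ValueError("missing must be 'distinct' or 'wildcard'")

    n = len(samples)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def compatible(x: SampleRecord, y: SampleRecord) -> bool:
        for locus in loci:
            a, b = x.calls[locus], y.calls[locus]
            if MISSING in a or MISSING in b:
                continue
            if a != b:
                return False
        return True

    for i in range(n):
        for j in range(i + 1, n):
            if find(i) != find(j) and compatible(samples[i], samples[j]):
                parent[find(i)] = find(j)
    roots = sorted({find(i) for i in range(n)})
    index = {r: k for k, r in enumerate(roots)}
    assignment = [index[find(i)] for i in range(n)]
    return len(roots), assignment


@dataclass(frozen=True)
class GenotypicDiversity:
    hprime: float
    lam: float
    e5: float


def genotypic_diversity(abundances: Sequence[int]) -> GenotypicDiversity:
    """Shannon-Wiener H' (nats), Simpson lambda = 1 - sum p^2, and evenness
    E5 = ((1/sum p^2) - 1) / (exp(H') - 1) on MLG abundances."""
    ab = np.asarray(list(abundances), dtype=float)
    if ab.size == 0:
        raise EmptyDatasetError("empty abundance vector")
    if np.any(ab <= 0) or np.any(ab != np.round(ab)):
        raise ValueError("abundances must be positive integers")
    p = ab / ab.sum()
    hprime = float(-np.sum(p * np.log(p)))
    sum_p2 = float(np.sum(p**2))
    lam = 1.0 - sum_p2
    if ab.size == 1:
        e5 = 1.0
    else:
        e5 = (1.0 / sum_p2 - 1.0) / (math.exp(hprime) - 1.0)
    return GenotypicDiversity(hprime=hprime, lam=lam, e5=e5)


# ---------------------------------------------------------------------------
# heterozygosity and inbreeding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Heterozygosity:
    ho: float
    hexp: float
    per_locus: pd.DataFrame  # columns: locus, ho, hexp, copies


def heterozygosity(
    samples: Sequence[SampleRecord],
    loci: Sequence[str],
    unbiased: bool = True,
) -> Heterozygosity:
    """Observed and expected heterozygosity, per locus and averaged.

    Hexp_l = (n_c / (n_c - 1)) (1 - sum p_i^2), Nei's unbiased gene
    diversity over the n_c non-missing gene copies (``unbiased=False`` drops
    the correction).  Group values are unweighted means over loci with at
    least 2 gene copies; loci with fewer are excluded and flagged.
    """
    if not samples:
        raise EmptyDatasetError("empty group")
    counts = allele_counts(samples, loci)
    rows = []
    for locus in loci:
        n_c = sum(counts[locus].values())
        if n_c < 2:
            rows.append({"locus": locus, "ho": np.nan, "hexp": np.nan,
                         "copies": n_c, "included": False})
            continue
        n_calls = 0
        n_het = 0
        for s in samples:
            a, b = s.calls[locus]
            if a == MISSING or b == MISSING:
                continue
            n_calls += 1
            n_het += a != b
        p = np.array(list(counts[locus].values()), dtype=float) / n_c
        hexp_l = 1.0 - float(np.sum(p**2))
        if unbiased:
            hexp_l *= n_c / (n_c - 1)
        rows.append({"locus": locus, "ho": n_het / n_calls, "hexp": hexp_l,
                     "copies": n_c, "included": True})
    per_locus = pd.DataFrame(rows)
    used = per_locus[per_locus["included"]]
    if used.empty:
        raise UndefinedStatisticError("no locus has >= 2 gene copies")
    return Heterozygosity(
        ho=float(used["ho"].mean()),
        hexp=float(used["hexp"].mean()),
        per_locus=per_locus,
    )


def inbreeding_coefficient(
    samples: Sequence[SampleRecord],
    loci: Sequence[str],
    unbiased: bool = True,
) -> tuple[float, pd.DataFrame]:
    """Fis = 1 - mean(Ho) / mean(Hexp) over polymorphic loci (ratio of
    averages).  Also returns per-locus Fis.  Raises
    :class:`UndefinedStatisticError` when every locus is monomorphic."""
    het = heterozygosity(samples, loci, unbiased=unbiased)
    poly = het.per_locus[het.per_locus["included"] & (het.per_locus["hexp"] > 0)]
    if poly.empty:
        raise UndefinedStatisticError("Fis undefined: all loci monomorphic")
    fis = 1.0 - poly["ho"].mean() / poly["hexp"].mean()
    per_locus = poly.assign(fis=1.0 - poly["ho"] / poly["hexp"])
    return float(fis), per_locus[["locus", "ho", "hexp", "fis"]]


# ---------------------------------------------------------------------------
# comparisons
# ---------------------------------------------------------------------------


def capture_proportion(ar_seeds: float, ar_population: float) -> float:
    """Seed AR as a percentage of source-population AR (genetic capture)."""
    if ar_population <= 0:
        raise ValueError("population AR must be positive")
    return 100.0 * ar_seeds / ar_population


def welch_t_test(values_a: Sequence[float], values_b: Sequence[float]) -> TTestResult:
    """Welch unequal-variance two-sample t test, two-sided."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=float(a.size + b.size - 2), p=1.0)
        return TTestResult(t=math.copysign(math.inf, a.mean() - b.mean()),
                           df=float(a.size + b.size - 2), p=0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


# ---------------------------------------------------------------------------
# summary-table builder
# ---------------------------------------------------------------------------


def summarize_diversity(
    dataset: GenotypeDataset,
    by: str | Sequence[str] = "role",
    g: int | str = "auto",
    pa_reference: Mapping[str, str] | None = None,
    frequency_tables: Mapping[str, AlleleFrequencyTable] | None = None,
) -> list[DiversitySummary]:
    """One summary row per group: the survey-table analogue.

    ``pa_reference`` maps a group label to the label whose allele set it is
    compared against for private-allele counts (e.g. seeds vs populations);
    groups without an entry get ``pa=None``.  Fis is ``None`` where undefined
    (all loci monomorphic in the group).
    """
    from .io import allele_frequencies  # local import to avoid cycle at top

    grouped = group_samples(dataset, by)
    if frequency_tables is None:
        frequency_tables = {
            t.label: t for t in allele_frequencies(dataset, by)
        }
    ar_totals, _ = rarefied_allelic_richness(dataset, by, g)
    out = []
    for label, members in grouped.items():
        mlg_n, assignment = count_mlg(members, dataset.loci)
        abundances = np.bincount(assignment)
        gd = genotypic_diversity(abundances[abundances > 0])
        het = heterozygosity(members, dataset.loci)
        try:
            fis, _ = inbreeding_coefficient(members, dataset.loci)
        except UndefinedStatisticError:
            fis = None
        pa = None
        if pa_reference and label in pa_reference:
            ref = pa_reference[label]
            pa = private_alleles(
                frequency_tables[label], frequency_tables[ref]
            ).count_a
        out.append(
            DiversitySummary(
                label=label,
                n=len(members),
                ar=ar_totals[label],
                pa=pa,
                mlg=mlg_n,
                hprime=gd.hprime,
                lam=gd.lam,
                e5=gd.e5,
                hexp=het.hexp,
                ho=het.ho,
                fis=fis,
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[DiversitySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": s.label, "N": s.n, "AR": s.ar, "PA": s.pa, "MLG": s.mlg,
                "Hprime": s.hprime, "lambda": s.lam, "E5": s.e5,
                "Hexp": s.hexp, "Ho": s.ho, "Fis": s.fis,
            }
            for s in summaries
        ]
    )
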