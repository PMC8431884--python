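"""Population structure: AMOVA, genetic distances, clustering, Mantel tests.

AMOVA partitions molecular variance among vs within local populations from
inter-individual allele-mismatch distances, with a permutation test on the
phi statistic.  Pairwise Nei (1972) standard distances between groupings
feed a complete-linkage dendrogram; isolation by distance is tested by
Mantel correlation of geographic and genetic distance matrices.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import EmptyDatasetError, UndefinedStatisticError
from .io import (
    MISSING,
    AlleleFrequencyTable,
    GenotypeDataset,
    Role,
    SampleRecord,
    group_samples,
)

__all__ = [
    "AmovaResult",
    "DistanceMatrix",
    "MantelResult",
    "pairwise_mismatch_distances",
    "amova",
    "amova_permutation_test",
    "nei_distance_matrix",
    "geographic_distance_matrix",
    "hierarchical_clustering",
    "Dendrogram",
    "mantel_test",
]


@dataclass(frozen=True)
class AmovaResult:
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    sigma2_among: float
    sigma2_within: float
    phi: float
    percent_within: float
    truncated: bool  # sigma2_among clipped at zero
    p_value: float | None = None
    n_permutations: int | None = None

    @property
    def percent_among(self) -> float:
        return 100.0 - self.percent_within


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray
    metric: str

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        finite = np.isfinite(m)
        if not np.allclose(m[finite], m.T[finite], atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.all(np.diag(m) == 0):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def has_infinite(self) -> bool:
        return bool(np.any(np.isinf(self.matrix)))

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int


# ---------------------------------------------------------------------------
# inter-individual distances and AMOVA
# ---------------------------------------------------------------------------


def _locus_mismatch(a: tuple[int, int], b: tuple[int, int]) -> int:
    """0 if the unordered pairs are identical, 1 if they share exactly one
    allele copy, 2 if they share none (multiset overlap)."""
    overlap = sum((Counter(a) & Counter(b)).values())
    return 2 - overlap


def pairwise_mismatch_distances(
    samples: Sequence[SampleRecord],
    loci: Sequence[str],
    rescale_missing: bool = True,
) -> np.ndarray:
    """Allele-mismatch distance between all sample pairs, pairwise deletion.

    Loci with a missing call in either sample are skipped; with
    ``rescale_missing`` the distance is scaled by L / L_compared so samples
    with more missing data are not artificially closer."""
    n = len(samples)
    n_loci = len(loci)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            total = 0
            compared = 0
            for locus in loci:
                a = samples[i].calls[locus]
                b = samples[j].calls[locus]
                if MISSING in a or MISSING in b:
                    continue
                compared += 1
                total += _locus_mismatch(a, b)
            if compared == 0:
                raise EmptyDatasetError(
                    f"samples {samples[i].sample_id!r} and "
                    f"{samples[j].sample_id!r} share no scored locus"
                )
            dist = float(total)
            if rescale_missing and compared < n_loci:
                dist *= n_loci / compared
            d[i, j] = d[j, i] = dist
    return d


def _amova_components(
    d2: np.ndarray, labels: np.ndarray
) -> tuple[float, float, int, int, float, float, bool]:
    """Variance components from a squared-distance matrix and group labels."""
    n = len(labels)
    groups, counts = np.unique(labels, return_counts=True)
    n_groups = len(groups)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g_val, n_g in zip(groups, counts):
        idx = np.nonzero(labels == g_val)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / n_g
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (n - (counts**2).sum() / n) / df_among
    sigma2_within = ms_within
    sigma2_among = (ms_among - ms_within) / n0
    truncated = sigma2_among < 0
    if truncated:
        sigma2_among = 0.0
    return (ss_among, ss_within, df_among, df_within,
            sigma2_among, sigma2_within, truncated)


def amova(
    dataset_or_samples: GenotypeDataset | Sequence[SampleRecord],
    loci: Sequence[str] | None = None,
    by: str = "population",
    role: Role | None = Role.POPULATION,
    distances: np.ndarray | None = None,
) -> AmovaResult:
    """One-level AMOVA: molecular variance among vs within populations.

    Distances are allele-mismatch counts (0/1/2 per locus, pairwise
    deletion); sums of squares follow the standard squared-distance
    formulation with unequal group sizes, phi = sigma2_among / sigma2_total.
    A negative among-group component is truncated to 0 and flagged.
    """
    if isinstance(dataset_or_samples, GenotypeDataset):
        ds = dataset_or_samples
        samples = [s for s in ds.samples if role is None or s.role is role]
        loci = ds.loci
    else:
        samples = list(dataset_or_samples)
        if loci is None:
            raise ValueError("loci required when passing a bare sample list")
    if not samples:
        raise EmptyDatasetError("no samples for AMOVA")
    if by == "population":
        labels = np.array([s.population for s in samples])
    elif by == "bunch":
        labels = np.array([s.bunch_id for s in samples])
    else:
        raise ValueError("by must be 'population' or 'bunch'")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("AMOVA needs >= 2 populations")
    if counts.min() < 2:
        small = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"population(s) with a single sample: {small}")
    if distances is None:
        distances = pairwise_mismatch_distances(samples, loci)
    d2 = distances**2
    (ss_a, ss_w, df_a, df_w, s2_a, s2_w, truncated) = _amova_components(d2, labels)
    total = s2_a + s2_w
    if total <= 0:
        raise UndefinedStatisticError(
            "phi undefined: no molecular variance (all samples identical)"
        )
    return AmovaResult(
        ss_among=ss_a,
        ss_within=ss_w,
        df_among=df_a,
        df_within=df_w,
        sigma2_among=s2_a,
        sigma2_within=s2_w,
        phi=s2_a / total,
        percent_within=100.0 * s2_w / total,
        truncated=truncated,
    )


def amova_permutation_test(
    dataset_or_samples: GenotypeDataset | Sequence[SampleRecord],
    loci: Sequence[str] | None = None,
    n_permutations: int = 999,
    rng_seed: int | None = None,
    role: Role | None = Role.POPULATION,
) -> AmovaResult:
    """AMOVA plus a permutation p-value for phi.

    Individuals are permuted among populations (group sizes fixed), phi is
    recomputed, and p = (#(phi_perm >= phi_obs) + 1) / (n_permutations + 1).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if isinstance(dataset_or_samples, GenotypeDataset):
        ds = dataset_or_samples
        samples = [s for s in ds.samples if role is None or s.role is role]
        loci = ds.loci
    else:
        samples = list(dataset_or_samples)
        if loci is None:
            raise ValueError("loci required when passing a bare sample list")
    d = pairwise_mismatch_distances(samples, loci)
    base = amova(samples, loci, distances=d)
    d2 = d**2
    labels = np.array([s.population for s in samples])
    rng = np.random.default_rng(rng_seed)

    def phi_of(lab: np.ndarray) -> float:
        _, _, _, _, s2_a, s2_w, _ = _amova_components(d2, lab)
        total = s2_a + s2_w
        return s2_a / total if total > 0 else 0.0

    phi_obs = base.phi
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if phi_of(perm) >= phi_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return AmovaResult(
        **{k: getattr(base, k) for k in (
            "ss_among", "ss_within", "df_among", "df_within",
            "sigma2_among", "sigma2_within", "phi", "percent_within", "truncated",
        )},
        p_value=p,
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# Nei (1972) distance and clustering
# ---------------------------------------------------------------------------


def nei_distance_matrix(
    tables: Sequence[AlleleFrequencyTable],
) -> DistanceMatrix:
    """Nei's standard genetic distance D = -ln I between groupings.

    I = J_XY / sqrt(J_X J_Y) with J's summed over shared loci before the
    ratio.  A pair with I = 0 (no shared alleles) gets D = +inf, flagged via
    :attr:`DistanceMatrix.has_infinite` rather than raised."""
    if len(tables) < 2:
        raise ValueError("need >= 2 groupings")
    labels = tuple(t.label for t in tables)
    n = len(tables)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ti, tj = tables[i], tables[j]
            shared = [
                l for l in ti.frequencies if l in tj.frequencies
            ]
            if not shared:
                raise ValueError(
                    f"groupings {ti.label!r} and {tj.label!r} share no scored locus"
                )
            j_xy = j_x = j_y = 0.0
            for locus in shared:
                fx = ti.frequencies[locus]
                fy = tj.frequencies[locus]
                j_x += sum(p * p for p in fx.values())
                j_y += sum(p * p for p in fy.values())
                j_xy += sum(p * fy.get(a, 0.0) for a, p in fx.items())
            identity = j_xy / math.sqrt(j_x * j_y)
            if identity <= 0:
                m[i, j] = m[j, i] = math.inf
            else:
                # clip tiny floating excess above 1 for identical tables
                m[i, j] = m[j, i] = max(0.0, -math.log(min(identity, 1.0)))
    return DistanceMatrix(labels=labels, matrix=m, metric="nei1972")


def geographic_distance_matrix(
    labels: Sequence[str],
    coords: Mapping[str, tuple[float, float]],
    method: str = "euclidean",
) -> DistanceMatrix:
    """Pairwise geographic distance between groupings from (lat, lon).

    Default is plain Euclidean distance on raw coordinates; ``"greatcircle"``
    uses the haversine formula (km)."""
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            lat1, lon1 = coords[labels[i]]
            lat2, lon2 = coords[labels[j]]
            if method == "euclidean":
                d = math.hypot(lat1 - lat2, lon1 - lon2)
            elif method == "greatcircle":
                phi1, phi2 = math.radians(lat1), math.radians(lat2)
                dphi = phi2 - phi1
                dlam = math.radians(lon2 - lon1)
                h = (math.sin(dphi / 2) ** 2
                     + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2)
                d = 2 * 6371.0 * math.asin(math.sqrt(h))
            else:
                raise ValueError("method must be 'euclidean' or 'greatcircle'")
            m[i, j] = m[j, i] = d
    return DistanceMatrix(labels=tuple(labels), matrix=m, metric=method)


@dataclass(frozen=True)
class Dendrogram:
    labels: tuple[str, ...]
    linkage_matrix: np.ndarray  # scipy hierarchy linkage format

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        """Newick with branch lengths from merge-height differences."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        body = walk(tree, tree.dist)
        # root has zero-length stem; strip it
        return body.rsplit(":", 1)[0] + ";"


def hierarchical_clustering(
    dmatrix: DistanceMatrix, linkage: str = "complete"
) -> Dendrogram:
    """Agglomerative clustering of a distance matrix (default complete
    linkage: cluster distance = max pairwise).  Infinite distances are
    refused — cap them explicitly first if that is what you want."""
    if dmatrix.has_infinite:
        raise ValueError(
            "distance matrix contains infinite entries; cap them before clustering"
        )
    z = hierarchy.linkage(dmatrix.condensed(), method=linkage)
    return Dendrogram(labels=dmatrix.labels, linkage_matrix=z)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


def mantel_test(
    dmatrix_a: DistanceMatrix,
    dmatrix_b: DistanceMatrix,
    n_permutations: int = 999,
    rng_seed: int | None = None,
) -> MantelResult:
    """Mantel correlation between two distance matrices over the same labels.

    r is the Pearson correlation of upper-triangle entries; the one-sided
    (greater) p-value comes from simultaneous row/column permutations of the
    second matrix, with the plus-one correction."""
    if dmatrix_a.labels != dmatrix_b.labels:
        raise ValueError("distance matrices must have identical label order")
    n = len(dmatrix_a.labels)
    if n < 3:
        raise ValueError("Mantel test needs >= 3 labels")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    a = dmatrix_a.matrix
    b = dmatrix_b.matrix
    iu = np.triu_indices(n, k=1)

    def corr(mat_b: np.ndarray) -> float:
        x = a[iu]
        y = mat_b[iu]
        sx = x.std()
        sy = y.std()
        if sx == 0 or sy == 0:
            raise UndefinedStatisticError("constant distance matrix; r undefined")
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(b)
    rng = np.random.default_rng(rng_seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if corr(b[np.ix_(perm, perm)]) >= r_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return MantelResult(r=r_obs, p=p, n_permutations=n_permutations)
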