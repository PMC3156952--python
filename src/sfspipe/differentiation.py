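"""Population differentiation: Weir-Cockerham FST, Nei distance, principal
coordinates, and the heterozygosity-versus-distance correlation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GenotypeMatrix, SampleManifest

__all__ = [
    "DistanceMatrix",
    "PcoaResult",
    "GeoCorrelation",
    "wc_fst_components",
    "wc_fst",
    "pairwise_fst_matrix",
    "nei_distance",
    "nei_distance_matrix",
    "pcoa",
    "haversine_km",
    "geo_correlation",
    "ADDIS_ABABA",
]

EARTH_RADIUS_KM = 6371.0
ADDIS_ABABA = (9.03, 38.74)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray      # symmetric; diagonal semantics depend on statistic

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class PcoaResult:
    labels: list[str]
    coordinates: np.ndarray         # (units, components)
    variance_fraction: np.ndarray   # non-increasing, sums to <= 1

    def __post_init__(self) -> None:
        vf = self.variance_fraction
        if np.any(np.diff(vf) > 1e-12):
            raise ValueError("variance fractions must be non-increasing")
        if vf.sum() > 1 + 1e-9:
            raise ValueError("variance fractions sum above 1")


@dataclass
class GeoCorrelation:
    units: list[str]
    distances_km: np.ndarray
    values: np.ndarray
    r: float
    p: float


# ---------------------------------------------------------------------------
# Weir-Cockerham FST


def wc_fst_components(geno_by_pop: list[np.ndarray]) -> tuple[float, float, float]:
    """Variance components (a, b, c) for one biallelic locus.

    ``geno_by_pop`` holds the diploid alt-dosage vectors (missing removed)
    of each population at the locus.  a = among populations, b = among
    individuals within populations, c = within individuals.
    """
    r = len(geno_by_pop)
    if r < 2:
        raise ValueError("need at least two populations")
    n_i = np.array([len(g) for g in geno_by_pop], dtype=float)
    if (n_i < 1).any():
        raise ValueError("population with no genotyped individuals at locus")
    p_i = np.array([g.mean() / 2.0 for g in geno_by_pop])
    h_i = np.array([(g == 1).mean() for g in geno_by_pop])
    n_bar = n_i.mean()
    n_tot = n_i.sum()
    nc = (n_tot - (n_i**2).sum() / n_tot) / (r - 1)
    p_bar = (n_i * p_i).sum() / n_tot
    s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum() / n_tot
    if n_bar <= 1 or nc <= 0:
        return 0.0, 0.0, 0.0
    a = (n_bar / nc) * (s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0)
                        / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - s2 * (r - 1) / r
                                 - h_bar * (2 * n_bar - 1) / (4 * n_bar))
    c = h_bar / 2.0
    return float(a), float(b), float(c)


def _unit_genotypes(matrix: GenotypeMatrix, manifest: SampleManifest,
                    unit: str, level: str) -> np.ndarray:
    present = set(matrix.samples)
    samples = [s for s in manifest.samples_of(unit, level) if s in present]
    return matrix.genotypes[:, matrix.sample_index(samples)]


def wc_fst(matrix: GenotypeMatrix, manifest: SampleManifest,
           units: list[str], level: str = "population",
           expand_groups: bool = False) -> float:
    """Multi-locus Weir-Cockerham theta as a ratio of sums over loci.

    ``units`` are treated as the populations of the estimator.  With
    ``expand_groups=True`` a single continental-group label expands to its
    member populations (within-group mode).  Negative estimates are reported
    as computed.
    """
    if expand_groups:
        if len(units) != 1:
            raise ValueError("within-group mode takes exactly one group")
        pops = [p for p in manifest.populations if manifest.group_of(p) == units[0]]
        unit_level = [(p, "population") for p in pops]
    else:
        unit_level = [(u, level) for u in units]
    if len(unit_level) < 2:
        raise ValueError("need at least two populations")
    geno = [_unit_genotypes(matrix, manifest, u, lv) for u, lv in unit_level]
    for g, (u, _) in zip(geno, unit_level):
        if ((g >= 0).sum(axis=1) >= 2).sum() == 0:
            raise ValueError(f"unit {u!r} has <2 genotyped individuals at every locus")
    num = 0.0
    den = 0.0
    for s in range(matrix.n_sites):
        per_pop = []
        for g in geno:
            col = g[s]
            col = col[col >= 0]
            per_pop.append(col)
        if any(len(c) < 1 for c in per_pop):
            continue
        a, b, c = wc_fst_components(per_pop)
        num += a
        den += a + b + c
    if den == 0:
        return 0.0
    return num / den


def pairwise_fst_matrix(matrix: GenotypeMatrix, manifest: SampleManifest,
                        level: str = "population",
                        percent: bool = True,
                        within_group_diagonal: bool = False) -> DistanceMatrix:
    """Pairwise FST table; optionally the diagonal holds within-group
    among-population FST (group level only)."""
    units = manifest.units(level)
    k = len(units)
    vals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            f = wc_fst(matrix, manifest, [units[i], units[j]], level)
            vals[i, j] = vals[j, i] = f
        if within_group_diagonal and level == "group":
            pops = [p for p in manifest.populations if manifest.group_of(p) == units[i]]
            if len(pops) >= 2:
                vals[i, i] = wc_fst(matrix, manifest, [units[i]], expand_groups=True)
    if percent:
        vals = vals * 100.0
    return DistanceMatrix(units, vals)


# ---------------------------------------------------------------------------
# Nei's standard genetic distance


def nei_distance(freqs_a: np.ndarray, freqs_b: np.ndarray) -> float:
    """Nei's D = -ln I from per-locus allele-frequency vectors (loci, alleles)."""
    x = np.asarray(freqs_a, dtype=float)
    y = np.asarray(freqs_b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("frequency arrays must share shape")
    j_ab = (x * y).sum(axis=1).mean()
    j_a = (x**2).sum(axis=1).mean()
    j_b = (y**2).sum(axis=1).mean()
    identity = j_ab / np.sqrt(j_a * j_b)
    if identity <= 0:
        return float("inf")
    return float(-np.log(identity))


def _unit_freqs(matrix: GenotypeMatrix, manifest: SampleManifest,
                unit: str, level: str) -> np.ndarray:
    g = _unit_genotypes(matrix, manifest, unit, level)
    called = g >= 0
    tot = 2 * called.sum(axis=1)
    alt = np.where(called, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    return np.stack([1 - p, p], axis=1)


def nei_distance_matrix(matrix: GenotypeMatrix, manifest: SampleManifest,
                        level: str = "population") -> DistanceMatrix:
    units = manifest.units(level)
    freqs = {u: _unit_freqs(matrix, manifest, u, level) for u in units}
    k = len(units)
    vals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            fa, fb = freqs[units[i]], freqs[units[j]]
            ok = ~(np.isnan(fa).any(axis=1) | np.isnan(fb).any(axis=1))
            vals[i, j] = vals[j, i] = nei_distance(fa[ok], fb[ok])
    return DistanceMatrix(units, vals)


# ---------------------------------------------------------------------------
# principal coordinates (classical scaling of a distance matrix)


def pcoa(distance: DistanceMatrix | np.ndarray, n_components: int = 2,
         labels: list[str] | None = None) -> PcoaResult:
    """Classical multidimensional scaling with a deterministic sign convention
    (the largest-magnitude loading of each axis is positive).

    Variance fractions are relative to the sum of positive eigenvalues.
    """
    if isinstance(distance, DistanceMatrix):
        D = distance.values
        labels = distance.labels
    else:
        D = np.asarray(distance, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(D.shape[0])]
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("pcoa needs a symmetric matrix")
    k = D.shape[0]
    J = np.eye(k) - np.ones((k, k)) / k
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-12
    total = evals[pos].sum()
    n_components = min(n_components, k)
    coords = np.zeros((k, n_components))
    frac = np.zeros(n_components)
    for c in range(n_components):
        if evals[c] > 1e-12:
            v = evecs[:, c] * np.sqrt(evals[c])
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            coords[:, c] = v
            frac[c] = evals[c] / total if total > 0 else 0.0
    return PcoaResult(labels, coords, frac)


# ---------------------------------------------------------------------------
# geography


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance on a sphere of radius 6371 km."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def geo_correlation(values_per_unit: dict[str, float],
                    coords_per_unit: dict[str, tuple[float, float]],
                    origin: tuple[float, float] = ADDIS_ABABA) -> GeoCorrelation:
    """Pearson correlation of a per-unit statistic against great-circle
    distance from a reference origin; two-sided P from the t distribution."""
    units = [u for u in values_per_unit if u in coords_per_unit]
    if len(units) < 3:
        raise ValueError("need at least three units with coordinates")
    d = np.array([haversine_km(*origin, *coords_per_unit[u]) for u in units])
    v = np.array([values_per_unit[u] for u in units])
    r, p = stats.pearsonr(d, v)
    return GeoCorrelation(units, d, v, float(r), float(p))
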