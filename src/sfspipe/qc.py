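"""Dataset-construction filters and allele polarization.

Filter order is fixed: individual call rate, then fixed sites, then
multi-allelic sites, then the combined-Z Hardy-Weinberg screen.  Each removal
is tallied in :class:`FilterLog` so the site bookkeeping is always additive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import norm

from .datamodel import GenotypeMatrix, SampleManifest

__all__ = [
    "FilterLog",
    "filter_dataset",
    "fill_reference_genotypes",
    "hwe_exact_test",
    "combine_pvalues_stouffer",
    "hwe_filter",
    "polarize_alleles",
    "subsample_panel",
    "share_percent",
    "bp_per_snp",
]

_P_CLAMP = 1e-15


@dataclass
class FilterLog:
    """Counts of what each QC stage removed."""

    samples_in: int = 0
    samples_out: int = 0
    individuals_removed: int = 0
    sites_in: int = 0
    sites_out: int = 0
    fixed_removed: int = 0
    multiallelic_removed: int = 0
    hwe_removed: int = 0
    hwe_sites_untestable: int = 0
    bonferroni_m: int = 0
    alpha: float = 0.01

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if name != "alpha" and v < 0:
                raise ValueError(f"negative count {name}")

    def check_additive(self) -> None:
        removed = self.fixed_removed + self.multiallelic_removed + self.hwe_removed
        if self.sites_in != self.sites_out + removed:
            raise ValueError("FilterLog counts are not additive")

    def merge(self, other: "FilterLog") -> "FilterLog":
        return FilterLog(
            samples_in=self.samples_in,
            samples_out=other.samples_out or self.samples_out,
            individuals_removed=self.individuals_removed + other.individuals_removed,
            sites_in=self.sites_in,
            sites_out=other.sites_out,
            fixed_removed=self.fixed_removed + other.fixed_removed,
            multiallelic_removed=self.multiallelic_removed + other.multiallelic_removed,
            hwe_removed=self.hwe_removed + other.hwe_removed,
            hwe_sites_untestable=self.hwe_sites_untestable + other.hwe_sites_untestable,
            bonferroni_m=max(self.bonferroni_m, other.bonferroni_m),
            alpha=other.alpha,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def filter_dataset(matrix: GenotypeMatrix,
                   call_rate_min: float = 0.80) -> tuple[GenotypeMatrix, FilterLog]:
    """Drop low-call-rate individuals, then fixed sites, then multi-allelic sites.

    Call rate is the fraction of non-missing genotypes per individual over the
    sites present on input, evaluated before any site filter.
    """
    if matrix.n_sites < 1 or matrix.n_samples < 1:
        raise ValueError("matrix must have at least one site and one sample")
    log = FilterLog(samples_in=matrix.n_samples, sites_in=matrix.n_sites)

    call_rate = (matrix.genotypes >= 0).mean(axis=0)
    keep = call_rate >= call_rate_min
    log.individuals_removed = int((~keep).sum())
    if not keep.any():
        raise ValueError("no samples survive call-rate filter")
    m = matrix.take_samples([s for s, k in zip(matrix.samples, keep) if k])
    log.samples_out = m.n_samples

    alt, tot = m.alt_counts()
    fixed = (alt == 0) | (alt == tot)
    log.fixed_removed = int(fixed.sum())
    m = m.take_sites(np.flatnonzero(~fixed))

    multi = np.array(["," in a for a in m.alt], dtype=bool)
    log.multiallelic_removed = int(multi.sum())
    m = m.take_sites(np.flatnonzero(~multi))

    log.sites_out = m.n_sites
    log.check_additive()
    return m, log


def fill_reference_genotypes(matrix: GenotypeMatrix, mask: np.ndarray) -> GenotypeMatrix:
    """Set cells where no variant call was attempted to homozygous reference.

    ``mask`` is a boolean (sites, samples) array marking those cells; a masked
    cell that already carries a call is a contradiction and a hard error.
    Filled cells get code 0 and a provenance flag.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != matrix.genotypes.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match genotypes {matrix.genotypes.shape}")
    conflict = mask & (matrix.genotypes >= 0)
    if conflict.any():
        s, i = np.argwhere(conflict)[0]
        raise ValueError(f"masked cell (site {s}, sample {matrix.samples[i]!r}) already called")
    geno = matrix.genotypes.copy()
    geno[mask] = 0
    filled = matrix.filled.copy() if matrix.filled is not None else np.zeros_like(mask)
    filled = filled | mask
    from dataclasses import replace
    return replace(matrix, genotypes=geno, filled=filled)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test P-value (plain, not mid-P).

    Sums the probabilities of all heterozygote counts, conditional on allele
    counts, that are no more probable than the observed one.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_rare == 0:
        return 1.0
    # log-probabilities over all het counts with the same parity as n_rare
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    from scipy.special import gammaln
    n_a = n_rare
    n_b = 2 * n - n_rare
    logp = (np.log(2.0) * hets
            + gammaln(n + 1)
            - gammaln(hets + 1)
            - gammaln((n_a - hets) / 2 + 1)
            - gammaln((n_b - hets) / 2 + 1)
            + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1))
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = np.searchsorted(hets, n_het)
    if obs >= len(hets) or hets[obs] != n_het:
        raise ValueError("heterozygote count inconsistent with allele counts")
    return float(min(1.0, p[p <= p[obs] * (1 + 1e-12)].sum()))


def combine_pvalues_stouffer(pvalues: list[float]) -> tuple[float, float]:
    """Pool k P-values: Z_i = Phi^-1(1 - P_i), Z = sum(Z_i)/sqrt(k), and a
    two-sided P from Z.  P-values are clamped away from 0 and 1 first."""
    if not pvalues:
        raise ValueError("need at least one P-value")
    zs = [norm.isf(min(max(p, _P_CLAMP), 1 - _P_CLAMP)) for p in pvalues]
    z = float(np.sum(zs) / np.sqrt(len(zs)))
    return z, float(2 * norm.sf(abs(z)))


def _site_counts(matrix: GenotypeMatrix, idx: np.ndarray, s: int) -> tuple[int, int, int]:
    g = matrix.genotypes[s, idx]
    g = g[g >= 0]
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def hwe_filter(matrix: GenotypeMatrix, manifest: SampleManifest,
               alpha: float = 0.01) -> tuple[GenotypeMatrix, FilterLog]:
    """Combined-Z Hardy-Weinberg screen with Bonferroni correction.

    Per population an exact HWE P-value is computed, mapped to a Z-score by
    ``Z = Phi^-1(1 - P)``; monomorphic or under-sampled populations contribute
    no Z.  The k per-population Z-scores are pooled as ``sum(Z)/sqrt(k)`` and
    mapped back to a two-sided P.  Sites with pooled P below ``alpha / M``
    (M = number of testable sites) are removed.
    """
    pops = manifest.populations
    present = set(matrix.samples)
    pop_idx = {p: matrix.sample_index([s for s in manifest.samples_of(p)
                                       if s in present]) for p in pops}
    n_sites = matrix.n_sites
    combined_p = np.full(n_sites, np.nan)
    combined_z = np.full(n_sites, np.nan)
    for s in range(n_sites):
        pvals = []
        for p in pops:
            idx = pop_idx[p]
            if len(idx) == 0:
                continue
            aa, ab, bb = _site_counts(matrix, idx, s)
            if aa + ab + bb < 2:
                continue
            if ab == 0 and (aa == 0 or bb == 0):
                continue  # monomorphic in this population
            pvals.append(hwe_exact_test(aa, ab, bb))
        if pvals:
            combined_z[s], combined_p[s] = combine_pvalues_stouffer(pvals)
    testable = ~np.isnan(combined_p)
    m_tested = int(testable.sum())
    log = FilterLog(samples_in=matrix.n_samples, samples_out=matrix.n_samples,
                    sites_in=n_sites, alpha=alpha, bonferroni_m=m_tested,
                    hwe_sites_untestable=int((~testable).sum()))
    if m_tested == 0:
        log.sites_out = n_sites
        log.check_additive()
        return matrix, log
    # removal requires departure from HWE (positive combined Z): with discrete
    # exact tests P-values pile up at 1, and the negative tail of the pooled Z
    # would otherwise flag sites for fitting HWE too well
    fail = testable & (combined_p < alpha / m_tested) & (combined_z > 0)
    log.hwe_removed = int(fail.sum())
    out = matrix.take_sites(np.flatnonzero(~fail))
    log.sites_out = out.n_sites
    log.check_additive()
    return out, log


def polarize_alleles(matrix: GenotypeMatrix, outgroup_alleles: np.ndarray) -> GenotypeMatrix:
    """Assign derived alleles from an outgroup, minor-allele fallback otherwise.

    When the outgroup base matches ref or alt, the other allele is derived and
    the outgroup base becomes the ancestral annotation.  When it matches
    neither (or is unknown), the global minor allele is taken as derived and
    the site is flagged ``minor``.  Applying the operation twice equals
    applying it once.
    """
    outgroup = np.asarray(outgroup_alleles, dtype=object)
    if outgroup.shape[0] != matrix.n_sites:
        raise ValueError("outgroup allele array length does not match site count")
    alt_counts, tot = matrix.alt_counts()
    derived_is_alt = np.zeros(matrix.n_sites, dtype=bool)
    how = np.empty(matrix.n_sites, dtype=object)
    ancestral = matrix.ancestral.copy()
    for s in range(matrix.n_sites):
        og = outgroup[s]
        ref, alt = matrix.ref[s], matrix.alt[s].split(",")[0]
        if og == ref:
            derived_is_alt[s] = True
            ancestral[s] = ref
            how[s] = "outgroup"
        elif og == alt:
            derived_is_alt[s] = False
            ancestral[s] = alt
            how[s] = "outgroup"
        else:
            freq_alt = alt_counts[s] / tot[s] if tot[s] else 0.0
            derived_is_alt[s] = freq_alt <= 0.5
            ancestral[s] = alt if derived_is_alt[s] else ref
            how[s] = "minor"
    from dataclasses import replace
    return replace(matrix, derived_is_alt=derived_is_alt, polarization=how,
                   ancestral=ancestral)


def subsample_panel(manifest: SampleManifest, level: str, n_per_unit: int,
                    seed: int) -> SampleManifest:
    """Uniform random subsample without replacement, ``n_per_unit`` per unit.

    Units with fewer samples keep all of them.  Reproducible under ``seed``.
    """
    units = manifest.units(level)  # raises on unknown level
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for u in units:
        samples = manifest.samples_of(u, level)
        if len(samples) <= n_per_unit:
            chosen.extend(samples)
        else:
            pick = rng.choice(len(samples), size=n_per_unit, replace=False)
            chosen.extend(samples[i] for i in sorted(pick))
    return manifest.subset(chosen)


# -- dataset bookkeeping helpers --------------------------------------------

def share_percent(n_subset: int, n_total: int, ndigits: int | None = 1) -> float:
    """Percentage of a SNP set belonging to a subset."""
    if n_total <= 0:
        raise ValueError("total must be positive")
    pct = 100.0 * n_subset / n_total
    return pct if ndigits is None else round(pct, ndigits)


def bp_per_snp(region_length: int, n_snps: int) -> int:
    """SNP density expressed as base pairs per SNP, rounded to integer."""
    if n_snps <= 0:
        raise ValueError("need at least one SNP")
    return round(region_length / n_snps)
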