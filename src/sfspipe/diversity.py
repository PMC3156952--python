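"""Per-unit diversity statistics: S, private S, Watterson's theta, pi,
observed heterozygosity, windowed haplotype heterozygosity, Tajima's D.

Per-bp statistics are returned on the natural per-bp scale; report tables
multiply by 1e5.  Per-site sample sizes are missing-aware (callable
chromosomes at the site) for pi and H; Tajima's D uses the unit's full
chromosome count with region-wide S and pi totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .datamodel import GenotypeMatrix, RegionConfig, SampleManifest

__all__ = [
    "count_segregating",
    "watterson_theta",
    "nucleotide_diversity",
    "observed_heterozygosity",
    "haplotype_heterozygosity",
    "tajima_constants",
    "tajimas_d",
    "diversity_table",
]


def _harmonics(n: int) -> tuple[float, float]:
    i = np.arange(1, n)
    return float(np.sum(1.0 / i)), float(np.sum(1.0 / i**2))


def count_segregating(matrix: GenotypeMatrix, unit_samples: list[str],
                      all_samples: list[str] | None = None) -> tuple[int, int]:
    """(S, Sp): sites polymorphic in the unit; of those, the ones monomorphic
    in the complement of the unit within ``all_samples``."""
    if not unit_samples:
        raise ValueError("empty unit")
    idx = matrix.sample_index(unit_samples)
    alt, tot = matrix.alt_counts(idx)
    poly = (alt > 0) & (alt < tot)
    S = int(poly.sum())
    if all_samples is None:
        all_samples = matrix.samples
    comp = [s for s in all_samples if s not in set(unit_samples)]
    if not comp:
        return S, S
    cidx = matrix.sample_index(comp)
    calt, ctot = matrix.alt_counts(cidx)
    comp_mono = (calt == 0) | (calt == ctot)
    Sp = int((poly & comp_mono).sum())
    return S, Sp


def watterson_theta(S: int, n_chrom: int, L: int,
                    ci_z: float = 1.96) -> tuple[float, tuple[float, float]]:
    """Watterson's estimator per bp with a normal-approximation CI.

    The CI uses the total coalescent sampling variance of S under the
    standard neutral model without recombination,
    Var(S) = a1*thetaL + b1*thetaL^2, evaluated at the estimate.
    """
    if n_chrom < 2:
        raise ValueError("need at least two chromosomes")
    if L <= 0:
        raise ValueError("L must be positive")
    a1, b1 = _harmonics(n_chrom)
    theta_L = S / a1
    var = (a1 * theta_L + b1 * theta_L**2) / a1**2
    sd = np.sqrt(var)
    est = theta_L / L
    return est, (max(0.0, (theta_L - ci_z * sd) / L), (theta_L + ci_z * sd) / L)


def nucleotide_diversity(matrix: GenotypeMatrix, unit_samples: list[str], L: int,
                         ci_z: float = 1.96) -> tuple[float, tuple[float, float]]:
    """Average pairwise diversity per bp, missing-aware, with coalescent CI.

    Per site with n callable chromosomes and allele frequency p the unbiased
    contribution is 2*p*(1-p)*n/(n-1); sites with fewer than two callable
    chromosomes are skipped.
    """
    if not unit_samples:
        raise ValueError("empty unit")
    idx = matrix.sample_index(unit_samples)
    alt, tot = matrix.alt_counts(idx)
    ok = tot >= 2
    alt, tot = alt[ok], tot[ok]
    with np.errstate(invalid="ignore"):
        p = alt / tot
        per_site = 2.0 * p * (1 - p) * tot / (tot - 1)
    pi_L = float(per_site.sum())
    n = 2 * len(unit_samples)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    var = b1 * pi_L + b2 * pi_L**2
    sd = np.sqrt(var)
    return pi_L / L, (max(0.0, (pi_L - ci_z * sd) / L), (pi_L + ci_z * sd) / L)


def observed_heterozygosity(matrix: GenotypeMatrix, unit_samples: list[str],
                            L: int) -> float:
    """Mean observed heterozygote fraction summed over sites, per bp."""
    idx = matrix.sample_index(unit_samples)
    g = matrix.genotypes[:, idx]
    called = (g >= 0).sum(axis=1)
    het = (g == 1).sum(axis=1)
    ok = called > 0
    return float((het[ok] / called[ok]).sum() / L)


def haplotype_heterozygosity(matrix: GenotypeMatrix, unit_samples: list[str],
                             window_size: int = 10_000) -> float:
    """Unbiased haplotype heterozygosity averaged over non-overlapping windows.

    Windows are anchored at position 1; a window with no segregating site
    contributes zero.  Requires phased input.
    """
    if not matrix.phased or matrix.haplotypes is None:
        raise ValueError(
            "haplotype heterozygosity needs phased input: phase externally or simulate")
    idx = matrix.sample_index(unit_samples)
    hap_idx = np.stack([2 * idx, 2 * idx + 1], axis=1).ravel()
    haps = matrix.haplotypes[:, hap_idx]
    n = haps.shape[1]
    n_windows = -(-matrix.region_length // window_size)
    hets = []
    for w in range(n_windows):
        lo, hi = w * window_size + 1, (w + 1) * window_size
        sel = (matrix.positions >= lo) & (matrix.positions <= hi)
        if not sel.any():
            hets.append(0.0)
            continue
        block = haps[sel]
        ok = (block >= 0).all(axis=0)
        block = block[:, ok]
        m = block.shape[1]
        if m < 2:
            hets.append(0.0)
            continue
        _, counts = np.unique(block, axis=1, return_counts=True)
        f = counts / m
        hets.append(m / (m - 1) * (1.0 - float(np.sum(f**2))))
    return float(np.mean(hets))


def tajima_constants(n: int) -> dict[str, float]:
    a1, a2 = _harmonics(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": c1 / a1, "e2": c2 / (a1**2 + a2)}


def tajimas_d(S: int, pairwise_pi_sum: float, n_chrom: int,
              n_sims: int = 10_000, seed: int = 0,
              compute_p: bool = True) -> tuple[float, float | None]:
    """Tajima's D with a simulated two-sided significance.

    ``pairwise_pi_sum`` is the region total of unbiased per-site pairwise
    diversity.  The null distribution conditions on ``n_chrom`` and ``S``:
    standard neutral genealogies with exactly S mutations placed on branches
    proportionally to length.  S = 0 leaves D undefined (raises).
    """
    if S < 1:
        raise ValueError("Tajima's D undefined for S = 0")
    k = tajima_constants(n_chrom)
    denom = np.sqrt(k["e1"] * S + k["e2"] * S * (S - 1))
    d = float((pairwise_pi_sum - S / k["a1"]) / denom)
    if not compute_p:
        return d, None
    out = np.empty(n_sims)
    _kernels.tajima_null_kernel(n_chrom, S, n_sims, seed, out,
                                k["a1"], k["e1"], k["e2"])
    p = float(np.mean(np.abs(out) >= abs(d)))
    return d, p


def _pi_total(matrix: GenotypeMatrix, unit_samples: list[str]) -> float:
    idx = matrix.sample_index(unit_samples)
    alt, tot = matrix.alt_counts(idx)
    ok = tot >= 2
    alt, tot = alt[ok], tot[ok]
    p = alt / tot
    return float((2.0 * p * (1 - p) * tot / (tot - 1)).sum())


def diversity_table(matrix: GenotypeMatrix, manifest: SampleManifest,
                    config: RegionConfig, level: str = "population",
                    tajima_sims: int = 10_000, seed: int = 0,
                    include_hap_het: bool = True) -> list[dict]:
    """Per-unit summary rows in the report-table schema."""
    present = set(matrix.samples)
    rows = []
    for unit in manifest.units(level):
        unit_samples = [s for s in manifest.samples_of(unit, level) if s in present]
        if not unit_samples:
            continue
        S, Sp = count_segregating(matrix, unit_samples, matrix.samples)
        n_chrom = 2 * len(unit_samples)
        theta, theta_ci = watterson_theta(S, n_chrom, config.length)
        pi, pi_ci = nucleotide_diversity(matrix, unit_samples, config.length)
        H = observed_heterozygosity(matrix, unit_samples, config.length)
        hap = (haplotype_heterozygosity(matrix, unit_samples, config.window_size)
               if include_hap_het else None)
        if S >= 1:
            d, p = tajimas_d(S, _pi_total(matrix, unit_samples), n_chrom,
                             n_sims=tajima_sims, seed=seed)
        else:
            d, p = None, None
        rows.append({"unit": unit, "level": level, "nInd": len(unit_samples),
                     "S": S, "Sp": Sp,
                     "theta": theta, "theta_lo": theta_ci[0], "theta_hi": theta_ci[1],
                     "pi": pi, "pi_lo": pi_ci[0], "pi_hi": pi_ci[1],
                     "H": H, "hap_het": hap, "tajima_d": d, "tajima_p": p})
    return rows
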