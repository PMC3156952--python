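"""Core data containers shared by every pipeline stage.

The central object is :class:`GenotypeMatrix`, a sites-by-samples diploid
genotype table for a single named genomic region, optionally carrying phased
haplotypes and ancestral-allele annotation.  Sample metadata (population,
continental group, geographic origin) lives in :class:`SampleManifest`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = np.int8(-1)
UNKNOWN_ALLELE = "."

_NUCS = frozenset("ACGT")


@dataclass
class GenotypeMatrix:
    """Diploid genotypes (count of alt alleles: 0/1/2, -1 missing) at biallelic
    SNPs within a region of length ``region_length`` bp.

    ``positions`` are 1-based inclusive coordinates within the region; any
    genomic offset of the region itself is metadata only and never enters
    arithmetic.  ``alt`` may contain comma-separated alleles for multi-allelic
    records awaiting QC removal; genotypes referring to a third allele are
    stored as missing.
    """

    region: str
    region_length: int
    positions: np.ndarray          # (S,) int64, strictly increasing
    ref: np.ndarray                # (S,) str
    alt: np.ndarray                # (S,) str, may contain ','
    ancestral: np.ndarray          # (S,) str, '.' when unknown
    genotypes: np.ndarray          # (S, N) int8
    samples: list[str]
    phased: bool = False
    haplotypes: np.ndarray | None = None   # (S, 2N) int8 alt-dosage per haplotype
    derived_is_alt: np.ndarray | None = None   # (S,) bool, set by polarization
    polarization: np.ndarray | None = None     # (S,) str: 'outgroup' | 'minor'
    filled: np.ndarray | None = None           # (S, N) bool provenance of reference fill-in

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.ancestral = np.asarray(self.ancestral, dtype=object)
        self.validate()

    # -- invariants ----------------------------------------------------------
    def validate(self) -> None:
        S, N = self.genotypes.shape
        if len(self.positions) != S:
            raise ValueError("positions and genotypes disagree on site count")
        if len(self.samples) != N:
            raise ValueError("samples and genotypes disagree on sample count")
        if S and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if S and (self.positions[0] < 1 or self.positions[-1] > self.region_length):
            raise ValueError("positions must lie in [1, region_length]")
        bad = ~np.isin(self.genotypes, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2,missing}")
        for i in range(S):
            if self.ref[i] == self.alt[i].split(",")[0]:
                raise ValueError(f"ref == alt at site index {i}")
        if self.haplotypes is not None and self.haplotypes.shape != (S, 2 * N):
            raise ValueError("haplotypes shape must be (n_sites, 2*n_samples)")

    # -- basic geometry ------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    def sample_index(self, names: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in genotype matrix") from None

    # -- per-site summaries (missing-aware) ----------------------------------
    def called_mask(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        g = self.genotypes if sample_idx is None else self.genotypes[:, sample_idx]
        return g >= 0

    def alt_counts(self, sample_idx: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Return (alt allele count, called chromosome count) per site."""
        g = self.genotypes if sample_idx is None else self.genotypes[:, sample_idx]
        called = g >= 0
        alt = np.where(called, g, 0).sum(axis=1)
        return alt.astype(np.int64), 2 * called.sum(axis=1).astype(np.int64)

    def derived_counts(self, sample_idx: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site derived allele count and called chromosome count.

        Requires polarization (``derived_is_alt`` set).
        """
        if self.derived_is_alt is None:
            raise ValueError("matrix is not polarized; run polarize_alleles first")
        alt, tot = self.alt_counts(sample_idx)
        return np.where(self.derived_is_alt, alt, tot - alt), tot

    # -- subsetting ----------------------------------------------------------
    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            positions=self.positions[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            ancestral=self.ancestral[idx],
            genotypes=self.genotypes[idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[idx],
            derived_is_alt=None if self.derived_is_alt is None else self.derived_is_alt[idx],
            polarization=None if self.polarization is None else self.polarization[idx],
            filled=None if self.filled is None else self.filled[idx],
        )

    def take_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_index(names)
        hap_idx = np.stack([2 * idx, 2 * idx + 1], axis=1).ravel()
        return replace(
            self,
            genotypes=self.genotypes[:, idx],
            samples=list(names),
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, hap_idx],
            filled=None if self.filled is None else self.filled[:, idx],
        )


MANIFEST_COLUMNS = ["sample", "population", "group", "lat", "lon"]


@dataclass
class SampleManifest:
    """sample -> population -> continental group mapping with origin coordinates."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        if self.table["sample"].duplicated().any():
            dup = self.table.loc[self.table["sample"].duplicated(), "sample"].iloc[0]
            raise ValueError(f"duplicate sample id {dup!r} in manifest")
        pop_groups = self.table.groupby("population")["group"].nunique()
        if (pop_groups > 1).any():
            bad = pop_groups[pop_groups > 1].index[0]
            raise ValueError(f"population {bad!r} maps to more than one group")

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.table["population"]))

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    def units(self, level: str) -> list[str]:
        if level == "population":
            return self.populations
        if level == "group":
            return self.groups
        raise ValueError(f"unknown level {level!r}; expected 'population' or 'group'")

    def samples_of(self, unit: str, level: str = "population") -> list[str]:
        col = {"population": "population", "group": "group"}.get(level)
        if col is None:
            raise ValueError(f"unknown level {level!r}")
        sel = self.table.loc[self.table[col] == unit, "sample"]
        if sel.empty:
            raise KeyError(f"no samples for {level} {unit!r}")
        return list(sel)

    def group_of(self, population: str) -> str:
        sel = self.table.loc[self.table["population"] == population, "group"]
        if sel.empty:
            raise KeyError(f"unknown population {population!r}")
        return sel.iloc[0]

    def coords_of(self, unit: str, level: str = "population") -> tuple[float, float]:
        col = "population" if level == "population" else "group"
        sel = self.table.loc[self.table[col] == unit]
        if sel.empty:
            raise KeyError(f"unknown {level} {unit!r}")
        return float(sel["lat"].iloc[0]), float(sel["lon"].iloc[0])

    def subset(self, samples: Sequence[str]) -> "SampleManifest":
        keep = self.table[self.table["sample"].isin(set(samples))]
        order = {s: i for i, s in enumerate(samples)}
        keep = keep.sort_values("sample", key=lambda s: s.map(order))
        return SampleManifest(keep.reset_index(drop=True))


@dataclass
class RegionConfig:
    """Region geometry and the physical constants attached to it."""

    name: str = "region"
    length: int = 100_000
    window_size: int = 10_000
    generation_time: float = 25.0
    mutation_rate: float = 1.48e-8

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("region length must be positive")
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.generation_time <= 0:
            raise ValueError("generation time must be positive")
        if self.mutation_rate <= 0:
            raise ValueError("mutation rate must be positive")

    @property
    def n_windows(self) -> int:
        return -(-self.length // self.window_size)
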