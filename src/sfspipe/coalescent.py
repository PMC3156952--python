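"""Structured-coalescent simulator: splits, exponential growth, migration.

This module is both the synthetic-data generator for the pipeline and the
Monte-Carlo backend for expected joint site-frequency spectra.  Models are
expressed in diffusion scaling: sizes relative to a reference size ``N_ref``
(diploids) and times backward from the present in units of ``2 * N_ref``
generations.  Exponential epochs are handled by exact closed-form intensity
inversion, not Euler stepping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .datamodel import GenotypeMatrix, SampleManifest

__all__ = [
    "DemographicModel",
    "Timeline",
    "SimReplicate",
    "simulate_dataset",
    "joint_sfs",
    "sfs_by_block",
    "expected_sfs",
    "make_study_mimic",
    "STUDY_POPULATIONS",
]


# ---------------------------------------------------------------------------
# model grammar


@dataclass
class _Growth:
    young_time: float
    old_time: float
    young_size: float
    old_size: float


@dataclass
class _SizeChange:
    time: float
    size: float


@dataclass
class _Split:
    time: float
    derived: str
    ancestral: str


@dataclass
class _Migration:
    source: str
    dest: str
    rate: float        # backward per-lineage rate, per 2*N_ref generations
    start: float
    end: float


class DemographicModel:
    """Event-based population history in diffusion scaling.

    Populations are declared with present-day constant sizes; backward-time
    events (instantaneous size changes, exponential-growth epochs, splits,
    migration epochs) are layered on top.  ``compile()`` turns the event list
    into interval arrays for the simulation kernels and validates that every
    lineage can reach a single root.
    """

    def __init__(self, populations: Sequence[str], reference_size: float = 1.0):
        if len(set(populations)) != len(populations):
            raise ValueError("duplicate population names")
        self.populations = list(populations)
        if reference_size <= 0:
            raise ValueError("reference size must be positive")
        self.reference_size = float(reference_size)
        self._sizes: dict[str, float] = {p: 1.0 for p in self.populations}
        self._size_changes: dict[str, list[_SizeChange]] = {p: [] for p in self.populations}
        self._growths: dict[str, list[_Growth]] = {p: [] for p in self.populations}
        self._splits: list[_Split] = []
        self._migrations: list[_Migration] = []

    # -- construction --------------------------------------------------------
    def pop_index(self, name: str) -> int:
        try:
            return self.populations.index(name)
        except ValueError:
            raise KeyError(f"unknown population {name!r}") from None

    def set_initial_size(self, pop: str, size: float) -> "DemographicModel":
        self.pop_index(pop)
        if size <= 0:
            raise ValueError("size must be positive")
        self._sizes[pop] = float(size)
        return self

    def set_size(self, pop: str, size: float, time: float) -> "DemographicModel":
        """Instantaneous size change: backward of ``time`` the size is ``size``."""
        self.pop_index(pop)
        if size <= 0:
            raise ValueError("size must be positive")
        if time < 0:
            raise ValueError("time must be >= 0")
        self._size_changes[pop].append(_SizeChange(float(time), float(size)))
        return self

    def set_growth(self, pop: str, young_time: float, old_time: float,
                   young_size: float, old_size: float) -> "DemographicModel":
        """Exponential size trajectory between two backward times.

        Forward in time the population grows (or shrinks) from ``old_size`` at
        ``old_time`` to ``young_size`` at ``young_time``; beyond ``old_time``
        the size stays at ``old_size`` until another event overrides it.
        """
        self.pop_index(pop)
        if not (0 <= young_time < old_time):
            raise ValueError("need 0 <= young_time < old_time")
        if young_size <= 0 or old_size <= 0:
            raise ValueError("sizes must be positive")
        self._growths[pop].append(_Growth(float(young_time), float(old_time),
                                          float(young_size), float(old_size)))
        return self

    def add_split(self, time: float, derived: str, ancestral: str) -> "DemographicModel":
        self.pop_index(derived), self.pop_index(ancestral)
        if derived == ancestral:
            raise ValueError("derived and ancestral must differ")
        if time <= 0:
            raise ValueError("split time must be positive")
        self._splits.append(_Split(float(time), derived, ancestral))
        return self

    def add_migration(self, source: str, dest: str, rate: float,
                      start: float = 0.0, end: float = np.inf) -> "DemographicModel":
        """Backward per-lineage migration: a lineage in ``source`` jumps to
        ``dest`` at ``rate`` per 2*N_ref generations during [start, end)."""
        self.pop_index(source), self.pop_index(dest)
        if rate < 0:
            raise ValueError("rate must be >= 0")
        self._migrations.append(_Migration(source, dest, float(rate), float(start), float(end)))
        return self

    @property
    def has_migration(self) -> bool:
        return any(m.rate > 0 for m in self._migrations)

    # -- compilation ---------------------------------------------------------
    def _size_at(self, pop: str, t: float) -> tuple[float, float]:
        """(size, backward exponent) governing population ``pop`` at time t."""
        for g in self._growths[pop]:
            if g.young_time <= t < g.old_time:
                r = np.log(g.young_size / g.old_size) / (g.old_time - g.young_time)
                return g.young_size * np.exp(-r * (t - g.young_time)), -r
        # most recent instantaneous change at or before t, else growth old side
        best_t, best_sz = -1.0, None
        for c in self._size_changes[pop]:
            if c.time <= t and c.time > best_t:
                best_t, best_sz = c.time, c.size
        for g in self._growths[pop]:
            if g.old_time <= t and g.old_time > best_t:
                best_t, best_sz = g.old_time, g.old_size
        if best_sz is None:
            return self._sizes[pop], 0.0
        return best_sz, 0.0

    def compile(self) -> "Timeline":
        npop = len(self.populations)
        cuts = {0.0}
        for p in self.populations:
            for c in self._size_changes[p]:
                cuts.add(c.time)
            for g in self._growths[p]:
                cuts.add(g.young_time)
                cuts.add(g.old_time)
        for s in self._splits:
            cuts.add(s.time)
        for m in self._migrations:
            cuts.add(m.start)
            if np.isfinite(m.end):
                cuts.add(m.end)
        times = np.array(sorted(cuts))
        nb = len(times)
        size0 = np.empty((nb, npop))
        grow = np.empty((nb, npop))
        for j, tj in enumerate(times):
            for i, p in enumerate(self.populations):
                sz, b = self._size_at(p, tj)
                size0[j, i] = sz
                grow[j, i] = b
        merge_at, merge_src, merge_dst = [], [], []
        merged_time: dict[str, float] = {}
        for s in sorted(self._splits, key=lambda s: s.time):
            if s.derived in merged_time:
                raise ValueError(f"population {s.derived!r} splits twice")
            j = int(np.searchsorted(times, s.time))
            merge_at.append(j)
            merge_src.append(self.pop_index(s.derived))
            merge_dst.append(self.pop_index(s.ancestral))
            merged_time[s.derived] = s.time
        # resolve merge chains: a destination already merged by this time
        for k, s in enumerate(sorted(self._splits, key=lambda s: s.time)):
            anc = s.ancestral
            while anc in merged_time and merged_time[anc] <= s.time:
                nxt = next(x.ancestral for x in self._splits
                           if x.derived == anc and merged_time[anc] == x.time)
                anc = nxt
            merge_dst[k] = self.pop_index(anc)
        roots = [p for p in self.populations if p not in merged_time]
        if len(roots) != 1:
            raise ValueError(
                f"model must coalesce to exactly one root population, got {roots}")
        root_idx = self.pop_index(roots[0])
        if grow[-1, root_idx] > 0:
            raise ValueError("lineages cannot fully coalesce: root size diverges")
        mig = np.zeros((nb, npop, npop))
        for m in self._migrations:
            for j, tj in enumerate(times):
                if m.start <= tj and tj < m.end:
                    mig[j, self.pop_index(m.source), self.pop_index(m.dest)] += m.rate
        return Timeline(
            populations=list(self.populations),
            reference_size=self.reference_size,
            times=times, size0=size0, grow=grow,
            merge_at=np.array(merge_at, dtype=np.int64),
            merge_src=np.array(merge_src, dtype=np.int64),
            merge_dst=np.array(merge_dst, dtype=np.int64),
            mig=mig,
        )


@dataclass
class Timeline:
    """Compiled interval representation consumed by the simulation kernels."""

    populations: list[str]
    reference_size: float
    times: np.ndarray
    size0: np.ndarray
    grow: np.ndarray
    merge_at: np.ndarray
    merge_src: np.ndarray
    merge_dst: np.ndarray
    mig: np.ndarray

    @property
    def has_migration(self) -> bool:
        return bool((self.mig > 0).any())

    def lineage_pops(self, sample_sizes: dict[str, int]) -> np.ndarray:
        out = []
        for pop, n in sample_sizes.items():
            if n < 0:
                raise ValueError("sample sizes must be >= 0")
            out.extend([self.populations.index(pop)] * n)
        return np.array(out, dtype=np.int64)


# ---------------------------------------------------------------------------
# genealogy simulation and datasets


@dataclass
class SimReplicate:
    """One simulated dataset: phased 0/1 derived-allele haplotypes with truth."""

    haplotypes: np.ndarray          # (S, n_chrom) int8
    positions: np.ndarray           # (S,) int64 in [1, L]
    block: np.ndarray               # (S,) int64 sub-locus index
    sample_pops: list[str]          # per diploid individual
    region_length: int
    n_subloci: int
    seed: int
    truth: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_chrom(self) -> int:
        return self.haplotypes.shape[1]

    def pop_chrom_index(self) -> dict[str, np.ndarray]:
        idx: dict[str, list[int]] = {}
        for i, p in enumerate(self.sample_pops):
            idx.setdefault(p, []).extend([2 * i, 2 * i + 1])
        return {p: np.array(v) for p, v in idx.items()}

    def to_genotype_matrix(self, region: str = "simulated",
                           sample_ids: list[str] | None = None) -> GenotypeMatrix:
        """Collapse haplotype pairs into diploid genotypes.

        The derived allele is written as ALT and the ancestral as REF, with the
        ancestral state annotated, so polarization is known by construction.
        """
        n_ind = len(self.sample_pops)
        if sample_ids is None:
            sample_ids = [f"{p}_{i}" for i, p in enumerate(self.sample_pops)]
        geno = (self.haplotypes[:, 0::2] + self.haplotypes[:, 1::2]).astype(np.int8)
        S = self.n_sites
        ref = np.array(["A"] * S, dtype=object)
        alt = np.array(["G"] * S, dtype=object)
        return GenotypeMatrix(
            region=region, region_length=self.region_length,
            positions=self.positions, ref=ref, alt=alt,
            ancestral=ref.copy(), genotypes=geno, samples=sample_ids,
            phased=True, haplotypes=self.haplotypes,
            derived_is_alt=np.ones(S, dtype=bool),
            polarization=np.array(["outgroup"] * S, dtype=object),
        )


def _simulate_genealogy(tl: Timeline, lin_pop: np.ndarray, seed: int):
    n = len(lin_pop)
    parent = np.empty(2 * n - 1, np.int64)
    child1 = np.empty(2 * n - 1, np.int64)
    child2 = np.empty(2 * n - 1, np.int64)
    node_time = np.empty(2 * n - 1, np.float64)
    rc = _kernels.genealogy_kernel(tl.times, tl.size0, tl.grow, tl.merge_at,
                                   tl.merge_src, tl.merge_dst, tl.mig,
                                   lin_pop, seed, parent, child1, child2, node_time)
    if rc != 0:
        raise RuntimeError("lineages cannot fully coalesce under this model")
    return parent, child1, child2, node_time


def _leaf_sets(parent, child1, child2, n):
    """Boolean leaf-membership matrix for every non-root node."""
    n_nodes = len(parent)
    leaves = np.zeros((n_nodes, n), dtype=bool)
    leaves[np.arange(n), np.arange(n)] = True
    for v in range(n, n_nodes):      # children always precede parents
        leaves[v] = leaves[child1[v]] | leaves[child2[v]]
    return leaves


def simulate_dataset(model: DemographicModel | Timeline,
                     sample_sizes: dict[str, int],
                     mu: float, L: int, seed: int,
                     n_subloci: int = 100) -> SimReplicate:
    """Simulate an infinite-sites dataset of diploid samples.

    ``sample_sizes`` counts diploid individuals per present-day population.
    The region is split into ``n_subloci`` independent sub-loci (one genealogy
    each, no recombination within a sub-locus).  Mutations are Poisson with
    rate theta/2 per lineage per scaled time unit, theta = 4*N_ref*mu*L_sub.
    """
    tl = model.compile() if isinstance(model, DemographicModel) else model
    if mu * L <= 0:
        raise ValueError("mu * L must be positive")
    if any(v < 1 for v in sample_sizes.values()):
        raise ValueError("need at least one diploid per sampled population")
    rng = np.random.default_rng(seed)
    chrom_sizes = {p: 2 * n for p, n in sample_sizes.items()}
    lin_pop = tl.lineage_pops(chrom_sizes)
    n = len(lin_pop)
    bounds = np.linspace(0, L, n_subloci + 1).astype(np.int64)
    all_haps, all_pos, all_block = [], [], []
    for b in range(n_subloci):
        lo, hi = bounds[b], bounds[b + 1]
        L_sub = int(hi - lo)
        if L_sub == 0:
            continue
        theta = 4.0 * tl.reference_size * mu * L_sub
        parent, c1, c2, node_time = _simulate_genealogy(
            tl, lin_pop, int(rng.integers(2**31 - 1)))
        blen = node_time[parent[:-1]] - node_time[:-1]   # root excluded
        total = blen.sum()
        n_mut = int(min(rng.poisson(theta / 2.0 * total), L_sub))
        if n_mut == 0:
            continue
        branches = rng.choice(len(blen), size=n_mut, p=blen / total)
        leaves = _leaf_sets(parent, c1, c2, n)
        pos: set[int] = set()
        while len(pos) < n_mut:      # infinite sites: collisions redrawn
            pos.update(rng.integers(lo + 1, hi + 1, size=n_mut - len(pos)).tolist())
        for k, position in enumerate(sorted(pos)):
            all_pos.append(position)
            all_haps.append(leaves[branches[k]].astype(np.int8))
            all_block.append(b)
    if all_pos:
        haps = np.array(all_haps, dtype=np.int8)
        positions = np.array(all_pos, dtype=np.int64)
        block = np.array(all_block, dtype=np.int64)
        order = np.argsort(positions)
        haps, positions, block = haps[order], positions[order], block[order]
        # drop non-segregating (possible only if a branch above root slipped in)
        seg = (haps.sum(axis=1) > 0) & (haps.sum(axis=1) < n)
        haps, positions, block = haps[seg], positions[seg], block[seg]
    else:
        haps = np.zeros((0, n), dtype=np.int8)
        positions = np.zeros(0, dtype=np.int64)
        block = np.zeros(0, dtype=np.int64)
    sample_pops = [p for p, k in sample_sizes.items() for _ in range(k)]
    # random pairing of chromosomes into diploids within populations
    perm = []
    off = 0
    for p, k in chrom_sizes.items():
        perm.extend((off + rng.permutation(k)).tolist())
        off += k
    haps = haps[:, perm]
    return SimReplicate(haplotypes=haps, positions=positions, block=block,
                        sample_pops=sample_pops, region_length=L,
                        n_subloci=n_subloci, seed=seed,
                        truth={"sample_sizes": dict(sample_sizes), "mu": mu, "L": L})


# ---------------------------------------------------------------------------
# joint SFS


def _sfs_from_counts(counts: np.ndarray, sizes: Sequence[int]) -> np.ndarray:
    dims = [s + 1 for s in sizes]
    sfs = np.zeros(dims)
    flat = np.ravel_multi_index(tuple(counts.T), dims)
    np.add.at(sfs.reshape(-1), flat, 1.0)
    return sfs


def joint_sfs(data: SimReplicate | GenotypeMatrix,
              populations: Sequence[str],
              manifest: SampleManifest | None = None,
              fold: bool = False) -> np.ndarray:
    """Joint derived-allele-count tensor, one axis per population.

    Entry (i_1, ..., i_k) counts sites with derived count i_j in population j.
    Monomorphic corners are retained (mask them for likelihoods).  Genotype
    input must be polarized unless ``fold=True``; sites with missing calls in
    any listed population are dropped.
    """
    if isinstance(data, SimReplicate):
        idx = data.pop_chrom_index()
        for p in populations:
            if p not in idx:
                raise KeyError(f"population {p!r} not in replicate")
        sizes = [len(idx[p]) for p in populations]
        counts = np.stack([data.haplotypes[:, idx[p]].sum(axis=1)
                           for p in populations], axis=1)
        return _sfs_from_counts(counts, sizes)
    matrix = data
    if manifest is None:
        raise ValueError("manifest required for genotype-matrix input")
    if matrix.derived_is_alt is None and not fold:
        raise ValueError("unpolarized input: polarize first or pass fold=True")
    cols = {p: matrix.sample_index(
        [s for s in manifest.samples_of(p, "population" if p in manifest.populations else "group")])
        for p in populations}
    sizes = [2 * len(cols[p]) for p in populations]
    per_pop = []
    complete = np.ones(matrix.n_sites, dtype=bool)
    for p in populations:
        if fold:
            cnt, tot = matrix.alt_counts(cols[p])
        else:
            cnt, tot = matrix.derived_counts(cols[p])
        complete &= tot == 2 * len(cols[p])
        per_pop.append(cnt)
    counts = np.stack(per_pop, axis=1)[complete]
    if fold:
        tot = np.array(sizes)
        flip = counts.sum(axis=1) * 2 > tot.sum()
        counts[flip] = tot[None, :] - counts[flip]
    return _sfs_from_counts(counts, sizes)


def sfs_by_block(rep: SimReplicate, populations: Sequence[str]) -> list[np.ndarray]:
    """Per-sub-locus joint SFS tensors (block bootstrap currency)."""
    idx = rep.pop_chrom_index()
    sizes = [len(idx[p]) for p in populations]
    out = []
    for b in range(rep.n_subloci):
        sel = rep.block == b
        counts = np.stack([rep.haplotypes[np.ix_(sel, idx[p])].sum(axis=1)
                           for p in populations], axis=1)
        out.append(_sfs_from_counts(counts, sizes))
    return out


def sfs_blocks_from_matrix(matrix: GenotypeMatrix, populations: Sequence[str],
                           manifest: SampleManifest,
                           n_blocks: int = 100) -> list[np.ndarray]:
    """Joint SFS per contiguous window of the region (block-bootstrap input)."""
    if n_blocks < 1:
        raise ValueError("need at least one block")
    edges = np.linspace(0, matrix.region_length, n_blocks + 1)
    out = []
    for b in range(n_blocks):
        sel = (matrix.positions > edges[b]) & (matrix.positions <= edges[b + 1])
        out.append(joint_sfs(matrix.take_sites(np.flatnonzero(sel)),
                             populations, manifest))
    return out


def expected_sfs(model: DemographicModel | Timeline,
                 sample_sizes: dict[str, int],
                 theta: float,
                 n_replicates: int,
                 seed: int,
                 return_se: bool = False):
    """Monte-Carlo expectation of the joint SFS (real-valued, linear in theta).

    ``sample_sizes`` counts chromosomes per population.  The expectation is
    theta/2 times the mean branch length subtending each joint configuration;
    deterministic under ``seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    tl = model.compile() if isinstance(model, DemographicModel) else model
    pops = [p for p in sample_sizes]
    dims = [sample_sizes[p] + 1 for p in pops]
    if tl.has_migration:
        return _expected_sfs_python(tl, sample_sizes, theta, n_replicates, seed, return_se)
    strides = np.ones(len(dims), np.int64)
    for i in range(len(dims) - 2, -1, -1):
        strides[i] = strides[i + 1] * dims[i + 1]
    lin_pop = tl.lineage_pops(sample_sizes)
    axis_of = {tl.populations.index(p): k for k, p in enumerate(pops)}
    lin_flat = np.array([strides[axis_of[p]] for p in lin_pop], np.int64)
    out = np.zeros(int(np.prod(dims)))
    rc = _kernels.branch_sfs_kernel(tl.times, tl.size0, tl.grow, tl.merge_at,
                                    tl.merge_src, tl.merge_dst,
                                    lin_pop, lin_flat, out, n_replicates, seed)
    if rc != 0:
        raise RuntimeError("lineages cannot fully coalesce under this model")
    sfs = (theta / 2.0) * out.reshape(dims) / n_replicates
    if not return_se:
        return sfs
    # second pass in chunks for a standard error estimate
    chunks = min(16, n_replicates)
    per = np.zeros((chunks,) + tuple(dims))
    base = n_replicates // chunks
    for c in range(chunks):
        buf = np.zeros(int(np.prod(dims)))
        _kernels.branch_sfs_kernel(tl.times, tl.size0, tl.grow, tl.merge_at,
                                   tl.merge_src, tl.merge_dst,
                                   lin_pop, lin_flat, buf, base, seed + 1000 + c)
        per[c] = (theta / 2.0) * buf.reshape(dims) / base
    se = per.std(axis=0, ddof=1) / np.sqrt(chunks)
    return sfs, se


def _expected_sfs_python(tl: Timeline, sample_sizes: dict[str, int], theta: float,
                         n_replicates: int, seed: int, return_se: bool):
    """Migration-capable fallback: genealogy simulation plus branch counting."""
    pops = [p for p in sample_sizes]
    dims = [sample_sizes[p] + 1 for p in pops]
    lin_pop = tl.lineage_pops(sample_sizes)
    n = len(lin_pop)
    axes = np.empty(n, np.int64)
    k = 0
    for ax, p in enumerate(pops):
        axes[k:k + sample_sizes[p]] = ax
        k += sample_sizes[p]
    rng = np.random.default_rng(seed)
    acc = np.zeros(dims)
    acc2 = np.zeros(dims)
    for r in range(n_replicates):
        parent, c1, c2, node_time = _simulate_genealogy(
            tl, lin_pop, int(rng.integers(2**31 - 1)))
        leaves = _leaf_sets(parent, c1, c2, n)
        blen = node_time[parent[:-1]] - node_time[:-1]
        one = np.zeros(dims)
        for v in range(len(blen)):
            cfg = tuple(int(leaves[v, axes == ax].sum()) for ax in range(len(pops)))
            one[cfg] += blen[v]
        acc += one
        acc2 += one ** 2
    sfs = (theta / 2.0) * acc / n_replicates
    if not return_se:
        return sfs
    var = acc2 / n_replicates - (acc / n_replicates) ** 2
    se = (theta / 2.0) * np.sqrt(np.maximum(var, 0) / n_replicates)
    return sfs, se


# ---------------------------------------------------------------------------
# study-design mimic

STUDY_POPULATIONS: dict[str, tuple[str, int]] = {
    # population -> (continental group, diploid sample size)
    "Brahmin": ("India", 23),
    "GIH": ("India", 24),
    "Irula": ("India", 23),
    "Mala/Madiga": ("India", 24),
    "Yadava": ("India", 22),
    "LWK": ("Africa", 24),
    "YRI": ("Africa", 24),
    "CEU": ("Europe", 24),
    "TSI": ("Europe", 24),
    "CHB": ("EastAsia", 24),
    "CHD": ("EastAsia", 24),
    "JPT": ("EastAsia", 24),
}

HAPMAP_FULL_SIZES = {"Brahmin": 23, "GIH": 60, "Irula": 23, "Mala/Madiga": 24,
                     "Yadava": 22, "LWK": 90, "YRI": 90, "CEU": 90, "TSI": 66,
                     "CHB": 45, "CHD": 45, "JPT": 45}


def _mimic_model(params: dict, within_group_tau: float) -> DemographicModel:
    """Four-group history with per-group population splits layered on top."""
    NA = params["N_A"]
    g_size = {
        "Africa": params["N_Af"] / NA,
        "EastAsia": (params["N_1"] / NA, params["N_1_0"] / NA),
        "India": (params["N_3"] / NA, params["N_3_0"] / NA),
        "Europe": (params["N_2"] / NA, params["N_2_0"] / NA),
    }
    tau = {k: params[k] for k in ("tau_Af", "tau_B", "tau_C", "tau_23")}
    pops = list(STUDY_POPULATIONS)
    model = DemographicModel(pops, reference_size=NA)
    group_members: dict[str, list[str]] = {}
    for p, (grp, _n) in STUDY_POPULATIONS.items():
        group_members.setdefault(grp, []).append(p)
    leads = {g: members[0] for g, members in group_members.items()}
    for grp, members in group_members.items():
        split_t = tau["tau_C"] if grp == "EastAsia" else (
            tau["tau_B"] if grp == "Africa" else tau["tau_23"])
        for p in members:
            if grp == "Africa":
                model.set_initial_size(p, g_size["Africa"])
            else:
                young, old = g_size[grp]
                model.set_growth(p, 0.0, split_t, young, old)
            if p != leads[grp]:
                model.add_split(within_group_tau, p, leads[grp])
    # group-level topology: EastAsia first off the Eurasian stem
    model.add_split(tau["tau_23"], leads["Europe"], leads["India"])
    model.set_size(leads["India"], params["N_C"] / NA, tau["tau_23"])
    model.add_split(tau["tau_C"], leads["India"], leads["EastAsia"])
    model.set_size(leads["EastAsia"], params["N_B"] / NA, tau["tau_C"])
    model.add_split(tau["tau_B"], leads["EastAsia"], leads["Africa"])
    model.set_size(leads["Africa"], 1.0, tau["tau_Af"])
    return model


MIMIC_DEFAULTS = {
    # four-group history used by the study-design mimic (sizes in diploids,
    # times already diffusion-scaled by 2*N_A*g at g=25, N_A=13195)
    "N_A": 13195.0, "N_Af": 19023.0, "N_B": 12081.0, "N_C": 77786.0,
    "N_1_0": 2003.0, "N_1": 31020.0,      # East Asia
    "N_2_0": 2029.0, "N_2": 131889.0,     # Europe
    "N_3_0": 1881.0, "N_3": 77285.0,      # India
    "tau_Af": 119600.0 / 25.0 / (2 * 13195.0),
    "tau_B": 92200.0 / 25.0 / (2 * 13195.0),
    "tau_C": 43900.0 / 25.0 / (2 * 13195.0),
    "tau_23": 23900.0 / 25.0 / (2 * 13195.0),
}


def make_study_mimic(seed: int,
                     params: dict | None = None,
                     within_group_tau: float = 0.008,
                     sizes: str = "table1",
                     mu: float = 1.48e-8,
                     L: int = 100_000,
                     n_subloci: int = 100,
                     outgroup_divergence: float = 0.012,
                     ) -> tuple[GenotypeMatrix, SampleManifest, dict]:
    """Generate a full 12-population pipeline input with known truth.

    Returns a phased, polarized genotype matrix, the matching manifest with
    origin coordinates, and a truth record including the generating
    parameters and an outgroup divergence value for mutation-rate
    calibration exercises.
    """
    params = dict(MIMIC_DEFAULTS if params is None else params)
    model = _mimic_model(params, within_group_tau)
    size_table = ({p: n for p, (_g, n) in STUDY_POPULATIONS.items()}
                  if sizes == "table1" else dict(HAPMAP_FULL_SIZES))
    rep = simulate_dataset(model, size_table, mu=mu, L=L, seed=seed,
                           n_subloci=n_subloci)
    ids = []
    counters: dict[str, int] = {}
    for p in rep.sample_pops:
        counters[p] = counters.get(p, 0) + 1
        ids.append(f"{p.replace('/', '')}{counters[p]:03d}")
    matrix = rep.to_genotype_matrix(region="mimic100kb", sample_ids=ids)
    from .io import population_origins
    origins = population_origins().set_index("population")
    rows = []
    for sid, p in zip(ids, rep.sample_pops):
        rows.append({"sample": sid, "population": p,
                     "group": STUDY_POPULATIONS[p][0],
                     "lat": origins.loc[p, "lat"], "lon": origins.loc[p, "lon"]})
    manifest = SampleManifest(pd.DataFrame(rows))
    truth = {"params": params, "within_group_tau": within_group_tau,
             "mu": mu, "L": L, "seed": seed, "sizes": sizes,
             "outgroup_divergence": outgroup_divergence,
             "n_subloci": n_subloci}
    return matrix, manifest, truth


def write_truth(truth: dict, path: str) -> str:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
    return path
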