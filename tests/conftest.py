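import numpy as np
import pandas as pd
import pytest

from sfspipe.datamodel import GenotypeMatrix, SampleManifest


def build_matrix(genotypes, positions=None, ref=None, alt=None, ancestral=None,
                 samples=None, region_length=None, phased=False, haplotypes=None):
    """Terse constructor for small hand-written genotype matrices."""
    g = np.asarray(genotypes, dtype=np.int8)
    S, N = g.shape
    if positions is None:
        positions = np.arange(1, S + 1)
    if samples is None:
        samples = [f"s{i}" for i in range(N)]
    return GenotypeMatrix(
        region="test",
        region_length=region_length or int(max(positions)) if S else 1,
        positions=np.asarray(positions),
        ref=np.array(ref if ref is not None else ["A"] * S, dtype=object),
        alt=np.array(alt if alt is not None else ["G"] * S, dtype=object),
        ancestral=np.array(ancestral if ancestral is not None else ["."] * S, dtype=object),
        genotypes=g, samples=samples, phased=phased, haplotypes=haplotypes,
    )


def build_manifest(assignments, coords=None):
    """assignments: dict sample -> (population, group)."""
    rows = []
    for s, (pop, grp) in assignments.items():
        lat, lon = (coords or {}).get(pop, (0.0, 0.0))
        rows.append({"sample": s, "population": pop, "group": grp,
                     "lat": lat, "lon": lon})
    return SampleManifest(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def mimic_small():
    """Small 12-population mimic dataset shared across tests."""
    from sfspipe.coalescent import make_study_mimic
    matrix, manifest, truth = make_study_mimic(seed=20, L=20_000, n_subloci=20)
    return matrix, manifest, truth


@pytest.fixture
def two_pop_matrix():
    rng = np.random.default_rng(7)
    g = rng.integers(0, 3, size=(40, 12)).astype(np.int8)
    m = build_matrix(g)
    mani = build_manifest({f"s{i}": ("P1" if i < 6 else "P2", "G1") for i in range(12)})
    return m, mani
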