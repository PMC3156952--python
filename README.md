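# sfspipe

Population-genetics analysis pipeline for a single resequenced region:
quality control and polarization of multi-population SNP genotype matrices,
diversity and differentiation statistics, and joint site-frequency-spectrum
demographic inference under out-of-Africa divergence models — driven either
by user data (VCF/TSV + sample manifest) or by a built-in structured-coalescent
synthetic-data generator with known truth.

## What is in the box

| module | contents |
|---|---|
| `sfspipe.datamodel` / `sfspipe.io` | `GenotypeMatrix`, `SampleManifest`, `RegionConfig`; VCF 4.x (with `AA` ancestral-allele INFO tag) and TSV genotype readers/writers; report tables |
| `sfspipe.qc` | call-rate / fixed-site / multi-allelic filters, reference fill-in, exact Hardy-Weinberg test with combined-Z (Stouffer) screening and Bonferroni correction, outgroup polarization with minor-allele fallback, panel subsampling |
| `sfspipe.diversity` | segregating and private sites, Watterson's theta, nucleotide diversity, observed SNP heterozygosity, windowed haplotype heterozygosity, Tajima's D with simulated significance |
| `sfspipe.differentiation` | Weir-Cockerham FST (pairwise and within-group), Nei's standard genetic distance, principal-coordinates analysis, heterozygosity-versus-distance correlation (haversine great circles) |
| `sfspipe.coalescent` | structured-coalescent simulator (splits, exponential growth via exact time rescaling, migration), joint-SFS extraction, Monte-Carlo expected SFS (numba kernel), 12-population study-design mimic |
| `sfspipe.inference` | three- and four-population out-of-Africa model families, Poisson composite likelihood with analytic theta profiling, multi-start bounded fits, block-bootstrap CIs, physical-unit conversion, mutation-rate calibration, model comparison |
| `sfspipe.cli` | `sfspipe` command with `simulate`, `qc`, `diversity`, `fst`, `run` subcommands and a YAML-configured end-to-end pipeline |

## Quick start

```bash
# generate a 12-population synthetic dataset with known truth
sfspipe simulate --seed 1 --out sim/

# QC + diversity + FST on it
sfspipe qc sim/simulated.vcf sim/manifest.tsv --out sim/filtered.vcf
sfspipe diversity sim/simulated.vcf sim/manifest.tsv --level group --out div.tsv
sfspipe fst sim/simulated.vcf sim/manifest.tsv --level group --out fst.tsv

# full pipeline from a config (defaults used for anything omitted)
sfspipe run my_config.yaml
```

Python API sketch:

```python
from sfspipe.coalescent import joint_sfs, simulate_dataset
from sfspipe.inference import (FitSettings, PRESET_OOA3_AF_EASTASIA_EUROPE,
                               build_model, fit_model, project_sfs)

model, theta = build_model(PRESET_OOA3_AF_EASTASIA_EUROPE, mu=1.48e-8, L=1e5, g=25)
sim = simulate_dataset(model, {"AF": 10, "P1": 10, "P2": 10},
                       mu=1.48e-8, L=100_000, seed=1, n_subloci=100)
observed = project_sfs(joint_sfs(sim, ["AF", "P1", "P2"]), [10, 10, 10])
fit = fit_model(observed, "ooa3", FitSettings(seed=1))
print(fit.params.T_B / 1e3, "kya")
```

## Notes

- All coordinates are 1-based within the region; the genomic offset of the
  region is metadata only.
- The expected joint SFS is a Monte-Carlo branch-length expectation under
  common random numbers, which makes the composite-likelihood objective a
  deterministic function of the parameters for a fixed seed; the contract
  allows swapping in a diffusion solver without touching inference code.
- Every random stage takes an explicit seed; `sfspipe run` derives per-stage
  seeds from the master seed with a fixed counter scheme.
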