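"""Reusable parameter-recovery experiment harness.

Simulates datasets under a published-parameter preset, refits them by
Poisson composite likelihood, and reports the recovered physical parameters
per replicate.  Used by the acceptance machinery and handy for power
exploration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coalescent import joint_sfs, simulate_dataset
from .inference import FitSettings, ParamSetOOA3, build_model, fit_model, project_sfs

__all__ = ["recovery_experiment"]


def recovery_experiment(preset: ParamSetOOA3,
                        n_replicates: int,
                        seed: int,
                        sample_diploids: int = 10,
                        project_to: int = 10,
                        L: int = 100_000,
                        n_subloci: int = 100,
                        mu: float = 1.48e-8,
                        g: float = 25.0,
                        settings: FitSettings | None = None,
                        progress: bool = False) -> pd.DataFrame:
    """Simulate-and-refit replicates under ``preset``; one row per replicate.

    Data are simulated with ``sample_diploids`` diploids (2x chromosomes) per
    population as ``n_subloci`` independent sub-loci, the observed joint SFS
    is projected to ``project_to`` chromosomes per population, and each
    replicate is refit with the default multi-start schedule.
    """
    model, _ = build_model(preset, mu, L, g)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        sim_seed = int(rng.integers(2**31 - 1))
        fit_seed = int(rng.integers(2**31 - 1))
        sim = simulate_dataset(model, {"AF": sample_diploids, "P1": sample_diploids,
                                       "P2": sample_diploids},
                               mu=mu, L=L, seed=sim_seed, n_subloci=n_subloci)
        obs = project_sfs(joint_sfs(sim, ["AF", "P1", "P2"]),
                          [project_to] * 3)
        st = settings or FitSettings()
        st = FitSettings(**{**st.__dict__, "mu": mu, "L": float(L), "g": g,
                            "seed": fit_seed})
        fit = fit_model(obs, "ooa3", st)
        row = {"replicate": rep, "seed": sim_seed, "loglik": fit.loglik,
               "converged": fit.converged, "n_sites": int(sim.n_sites)}
        row.update(fit.params.to_dict())
        rows.append(row)
        if progress:
            print(f"replicate {rep + 1}/{n_replicates}: "
                  f"T_B={row['T_B'] / 1e3:.1f} kya T_12={row['T_12'] / 1e3:.1f} kya",
                  flush=True)
    return pd.DataFrame(rows)
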