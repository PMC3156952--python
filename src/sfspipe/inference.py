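"""Joint-SFS demographic inference by Poisson composite likelihood.

Two model families are supported: a three-population out-of-Africa history
(ancestral size change, Eurasian stem split, two terminal populations with
exponential growth; ten physical parameters with the overall scale profiled
analytically) and a four-population extension in which the out-of-Africa
epoch parameters are held fixed at a previous three-population optimum.

The expected SFS comes from the Monte-Carlo coalescent backend with common
random numbers per optimizer run, so the objective is a deterministic
function of the parameters under a fixed seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

from .coalescent import DemographicModel, expected_sfs

__all__ = [
    "ParamSetOOA3",
    "ParamSetOOA4",
    "FitSettings",
    "FitResult",
    "MutationCalibration",
    "build_model",
    "poisson_composite_loglik",
    "project_sfs",
    "corner_mask",
    "fit_model",
    "bootstrap_ci",
    "convert_units",
    "calibrate_mutation_rate",
    "compare_models",
]


# ---------------------------------------------------------------------------
# parameter sets (physical units: diploid sizes, times in years)


@dataclass
class ParamSetOOA3:
    """Three-population model: ancestral -> African size change at T_Af,
    Eurasian stem (size N_B) at T_B, terminal split at T_12 with exponential
    growth from N1_0/N2_0 to N1/N2."""

    N_A: float
    N_Af: float
    N_B: float
    N1_0: float
    N1: float
    N2_0: float
    N2: float
    T_Af: float
    T_B: float
    T_12: float

    def __post_init__(self) -> None:
        for k, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"{k} must be positive")
        if not (self.T_Af >= self.T_B >= self.T_12):
            raise ValueError("require T_Af >= T_B >= T_12")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ParamSetOOA4:
    """Four-population model; N_Af, N_B, T_Af, T_B are fixed externally."""

    N_A: float
    N_C: float
    N1_0: float
    N1: float
    N2_0: float
    N2: float
    N3_0: float
    N3: float
    T_C: float
    T_23: float
    # fixed from the best three-population fit
    N_Af: float = 0.0
    N_B: float = 0.0
    T_Af: float = 0.0
    T_B: float = 0.0
    order: str = "pop1_first"

    def __post_init__(self) -> None:
        for k in ("N_A", "N_C", "N1_0", "N1", "N2_0", "N2", "N3_0", "N3",
                  "T_C", "T_23", "N_Af", "N_B", "T_Af", "T_B"):
            if getattr(self, k) <= 0:
                raise ValueError(f"{k} must be positive")
        if not (self.T_B >= self.T_C >= self.T_23):
            raise ValueError("require T_B >= T_C >= T_23")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MutationCalibration:
    divergence: float
    generation_time: float
    split_time_years: float
    ancestral_size: float

    @property
    def mu(self) -> float:
        return calibrate_mutation_rate(self.divergence, self.generation_time,
                                       self.split_time_years, self.ancestral_size)


def calibrate_mutation_rate(d: float, g: float, t_split: float, n_anc: float) -> float:
    """Per-generation mutation rate from outgroup divergence.

    Divergence accumulates over 2*t/g generations of independent lineage
    history plus 4*N_anc generations of expected ancestral coalescence:
    mu = d / (2*t/g + 4*N_anc).
    """
    if min(d, g, t_split, n_anc) < 0 or g == 0:
        raise ValueError("inputs must be positive")
    return d / (2.0 * t_split / g + 4.0 * n_anc)


# ---------------------------------------------------------------------------
# model construction


def build_model(params: ParamSetOOA3 | ParamSetOOA4, mu: float, L: float,
                g: float) -> tuple[DemographicModel, float]:
    """Convert physical parameters to a scaled demographic model.

    Scaling: nu = N / N_A, tau = T / (2 * N_A * g), theta = 4 * N_A * mu * L.
    Returns the model and theta.
    """
    NA = params.N_A
    theta = 4.0 * NA * mu * L

    def tau(T_years: float) -> float:
        return T_years / (2.0 * NA * g)

    if isinstance(params, ParamSetOOA3):
        m = DemographicModel(["AF", "P1", "P2"], reference_size=NA)
        m.set_initial_size("AF", params.N_Af / NA)
        m.set_growth("P1", 0.0, tau(params.T_12), params.N1 / NA, params.N1_0 / NA)
        m.set_growth("P2", 0.0, tau(params.T_12), params.N2 / NA, params.N2_0 / NA)
        m.add_split(tau(params.T_12), "P2", "P1")
        m.set_size("P1", params.N_B / NA, tau(params.T_12))
        m.add_split(tau(params.T_B), "P1", "AF")
        m.set_size("AF", 1.0, tau(params.T_Af))
        return m, theta
    if isinstance(params, ParamSetOOA4):
        m = DemographicModel(["AF", "P1", "P2", "P3"], reference_size=NA)
        m.set_initial_size("AF", params.N_Af / NA)
        m.set_growth("P1", 0.0, tau(params.T_C), params.N1 / NA, params.N1_0 / NA)
        m.set_growth("P2", 0.0, tau(params.T_23), params.N2 / NA, params.N2_0 / NA)
        m.set_growth("P3", 0.0, tau(params.T_23), params.N3 / NA, params.N3_0 / NA)
        m.add_split(tau(params.T_23), "P3", "P2")
        m.set_size("P2", params.N_C / NA, tau(params.T_23))
        m.add_split(tau(params.T_C), "P2", "P1")
        m.set_size("P1", params.N_B / NA, tau(params.T_C))
        m.add_split(tau(params.T_B), "P1", "AF")
        m.set_size("AF", 1.0, tau(params.T_Af))
        return m, theta
    raise TypeError("unsupported parameter set type")


def convert_units(scaled: dict[str, float], theta: float, mu: float, L: float,
                  g: float) -> dict[str, float]:
    """Scaled (nu, tau) -> physical (diploids, years). Inverse of build_model's
    scaling to machine precision."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    NA = theta / (4.0 * mu * L)
    out = {"N_A": NA}
    for k, v in scaled.items():
        if k.startswith("nu"):
            out["N" + k[2:]] = v * NA
        elif k.startswith("tau"):
            out["T" + k[3:]] = v * 2.0 * NA * g
        else:
            out[k] = v
    return out


# ---------------------------------------------------------------------------
# likelihood


def corner_mask(shape: tuple[int, ...]) -> np.ndarray:
    """True everywhere except the absent and fixed corners."""
    mask = np.ones(shape, dtype=bool)
    mask[tuple(0 for _ in shape)] = False
    mask[tuple(s - 1 for s in shape)] = False
    return mask


def poisson_composite_loglik(observed: np.ndarray, expected: np.ndarray,
                             mask: np.ndarray | None = None) -> float:
    """Poisson random-field composite log-likelihood over SFS entries.

    An expected entry of exactly zero with a positive observation yields
    -inf (sentinel, not an exception).
    """
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if o.shape != e.shape:
        raise ValueError("observed and expected SFS shapes differ")
    if mask is None:
        mask = corner_mask(o.shape)
    o = o[mask]
    e = e[mask]
    if np.any((e == 0) & (o > 0)):
        return float("-inf")
    ok = e > 0
    ll = float(np.sum(o[ok] * np.log(e[ok]) - e[ok] - gammaln(o[ok] + 1.0)))
    ll -= float(np.sum(e[~ok]))       # zero-expected, zero-observed entries
    return ll


def profile_theta_scale(observed: np.ndarray, expected: np.ndarray,
                        mask: np.ndarray | None = None) -> float:
    """Analytic Poisson MLE of a multiplicative rescaling of the expectation."""
    if mask is None:
        mask = corner_mask(observed.shape)
    tot_e = float(expected[mask].sum())
    if tot_e <= 0:
        raise ValueError("expected SFS has no mass")
    return float(observed[mask].sum()) / tot_e


def project_sfs(sfs: np.ndarray, new_sizes: list[int]) -> np.ndarray:
    """Hypergeometric downsampling of a joint SFS to smaller sample sizes."""
    out = np.asarray(sfs, dtype=float)
    for axis, m in enumerate(new_sizes):
        n = out.shape[axis] - 1
        if m > n:
            raise ValueError(f"cannot project axis {axis} up from {n} to {m}")
        if m == n:
            continue
        # P[j | i] = C(i, j) C(n-i, m-j) / C(n, m)
        i = np.arange(n + 1)[:, None]
        j = np.arange(m + 1)[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = (_log_comb(i, j) + _log_comb(n - i, m - j) - _log_comb(n, m))
        P = np.where(np.isfinite(logp), np.exp(logp), 0.0)
        out = np.moveaxis(np.tensordot(np.moveaxis(out, axis, -1), P, axes=([-1], [0])),
                          -1, axis)
    return out


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    bad = (k < 0) | (k > n)
    with np.errstate(invalid="ignore"):
        v = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where(bad, -np.inf, v)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitSettings:
    mu: float = 1.48e-8
    L: float = 100_000.0
    g: float = 25.0
    n_restarts: int = 10
    mc_reps: int = 400              # Monte-Carlo genealogies per restart-stage evaluation
    polish_reps: int = 4000         # genealogies per polish-stage evaluation
    maxfev: int = 150
    polish_maxfev: int = 200
    polish_top: int = 2             # how many best restarts are polished
    optimizer: str = "Powell"
    seed: int = 0
    min_expected: float = 1e-3      # floor protecting the MC expectation from hard zeros
    bounds_nu: tuple[float, float] = (0.01, 30.0)
    bounds_tau: tuple[float, float] = (0.005, 0.4)
    bounds_dtau: tuple[float, float] = (0.002, 0.4)
    bounds_NA: tuple[float, float] = (2_000.0, 60_000.0)
    bounds_T23: tuple[float, float] = (5_000.0, 100_000.0)
    bounds_dT: tuple[float, float] = (500.0, 100_000.0)
    bounds_N: tuple[float, float] = (100.0, 400_000.0)


@dataclass
class FitResult:
    family: str
    params: ParamSetOOA3 | ParamSetOOA4
    scaled: dict[str, float]
    theta: float
    loglik: float
    restarts: list[dict]
    converged: bool
    data_hash: str
    observed_total: float
    ci: dict[str, tuple[float, float]] | None = None

    def to_dict(self) -> dict:
        d = {"family": self.family, "loglik": self.loglik, "theta": self.theta,
             "converged": self.converged, "params": self.params.to_dict(),
             "n_restarts": len(self.restarts)}
        if self.ci:
            d["ci"] = {k: list(v) for k, v in self.ci.items()}
        return d

    def to_table(self) -> pd.DataFrame:
        rows = []
        for k, v in self.params.to_dict().items():
            if k == "order":
                continue
            lo, hi = (self.ci or {}).get(k, (float("nan"), float("nan")))
            unit = "kya" if k.startswith("T_") else "diploids"
            est = v / 1000.0 if unit == "kya" else v
            lo = lo / 1000.0 if unit == "kya" and np.isfinite(lo) else lo
            hi = hi / 1000.0 if unit == "kya" and np.isfinite(hi) else hi
            rows.append({"parameter": k, "unit": unit,
                         "estimate": round(est, 1),
                         "CI_low": round(lo, 1) if np.isfinite(lo) else "",
                         "CI_high": round(hi, 1) if np.isfinite(hi) else ""})
        rows.append({"parameter": "max_loglik", "unit": "", "estimate": round(self.loglik, 1),
                     "CI_low": "", "CI_high": ""})
        return pd.DataFrame(rows)


def _hash_sfs(sfs: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(sfs).tobytes()).hexdigest()[:16]


class _OOA3Space:
    """Nine log-scale coordinates; theta (hence N_A) profiled analytically.

    Order: nu_Af, nu_B, nu1_0, nu1, nu2_0, nu2, tau_12, dtau_B, dtau_Af
    where tau_B = tau_12 + dtau_B and tau_Af = tau_B + dtau_Af.
    """

    names = ["nu_Af", "nu_B", "nu1_0", "nu1", "nu2_0", "nu2",
             "tau_12", "dtau_B", "dtau_Af"]

    def __init__(self, settings: FitSettings):
        lo_nu, hi_nu = settings.bounds_nu
        lo_t, hi_t = settings.bounds_tau
        lo_d, hi_d = settings.bounds_dtau
        self.g = settings.g
        self.lo = np.log([lo_nu] * 6 + [lo_t, lo_d, lo_d])
        self.hi = np.log([hi_nu] * 6 + [hi_t, hi_d, hi_d])

    def scaled(self, x: np.ndarray) -> dict[str, float]:
        v = np.exp(x)
        return {"nu_Af": v[0], "nu_B": v[1], "nu1_0": v[2], "nu1": v[3],
                "nu2_0": v[4], "nu2": v[5], "tau_12": v[6],
                "tau_B": v[6] + v[7], "tau_Af": v[6] + v[7] + v[8]}

    def model(self, x: np.ndarray) -> DemographicModel:
        s = self.scaled(x)
        m = DemographicModel(["AF", "P1", "P2"], reference_size=1.0)
        m.set_initial_size("AF", s["nu_Af"])
        m.set_growth("P1", 0.0, s["tau_12"], s["nu1"], s["nu1_0"])
        m.set_growth("P2", 0.0, s["tau_12"], s["nu2"], s["nu2_0"])
        m.add_split(s["tau_12"], "P2", "P1")
        m.set_size("P1", s["nu_B"], s["tau_12"])
        m.add_split(s["tau_B"], "P1", "AF")
        m.set_size("AF", 1.0, s["tau_Af"])
        return m

    def x_from_params(self, p: ParamSetOOA3) -> np.ndarray:
        NA = p.N_A
        vals = [p.N_Af / NA, p.N_B / NA, p.N1_0 / NA, p.N1 / NA,
                p.N2_0 / NA, p.N2 / NA]
        g_tau = lambda T: T / (2 * NA * self.g)
        return np.log(vals + [g_tau(p.T_12), g_tau(p.T_B) - g_tau(p.T_12),
                              g_tau(p.T_Af) - g_tau(p.T_B)])

    def params_from(self, x: np.ndarray, theta: float,
                    settings: FitSettings) -> tuple[ParamSetOOA3, dict]:
        s = self.scaled(x)
        phys = convert_units(s, theta, settings.mu, settings.L, settings.g)
        p = ParamSetOOA3(N_A=phys["N_A"], N_Af=phys["N_Af"], N_B=phys["N_B"],
                         N1_0=phys["N1_0"], N1=phys["N1"], N2_0=phys["N2_0"],
                         N2=phys["N2"], T_Af=phys["T_Af"], T_B=phys["T_B"],
                         T_12=phys["T_12"])
        return p, s


class _OOA4Space:
    """Ten log-scale physical coordinates with the out-of-Africa epoch fixed.

    Order: N_A, N_C, N1_0, N1, N2_0, N2, N3_0, N3, T_23, dT_C
    (T_C = T_23 + dT_C; the fit rejects T_C above the fixed T_B).
    """

    names = ["N_A", "N_C", "N1_0", "N1", "N2_0", "N2", "N3_0", "N3",
             "T_23", "dT_C"]

    def __init__(self, settings: FitSettings, fixed: dict[str, float]):
        self.fixed = fixed
        lo_N, hi_N = settings.bounds_N
        lo_A, hi_A = settings.bounds_NA
        lo_T, hi_T = settings.bounds_T23
        lo_d, hi_d = settings.bounds_dT
        self.lo = np.log([lo_A] + [lo_N] * 7 + [lo_T, lo_d])
        self.hi = np.log([hi_A] + [hi_N] * 7 + [hi_T, hi_d])

    def params_raw(self, x: np.ndarray) -> ParamSetOOA4:
        v = np.exp(x)
        return ParamSetOOA4(N_A=v[0], N_C=v[1], N1_0=v[2], N1=v[3], N2_0=v[4],
                            N2=v[5], N3_0=v[6], N3=v[7], T_23=v[8],
                            T_C=v[8] + v[9], **self.fixed)

    def x_from_params(self, p: ParamSetOOA4) -> np.ndarray:
        return np.log([p.N_A, p.N_C, p.N1_0, p.N1, p.N2_0, p.N2, p.N3_0, p.N3,
                       p.T_23, p.T_C - p.T_23])


def fit_model(observed_sfs: np.ndarray, family: str, settings: FitSettings,
              fixed: dict[str, float] | None = None,
              start: np.ndarray | dict | None = None,
              starts: list[np.ndarray] | None = None) -> FitResult:
    """Multi-start bounded Nelder-Mead fit of the composite likelihood.

    The observed tensor axes are (African, pop1, pop2[, pop3]) with axis
    length = chromosomes + 1.  ``fixed`` supplies N_Af, N_B, T_Af, T_B for the
    four-population family.  Deterministic under ``settings.seed``.
    """
    observed = np.asarray(observed_sfs, dtype=float)
    sizes = {"AF": observed.shape[0] - 1, "P1": observed.shape[1] - 1,
             "P2": observed.shape[2] - 1}
    if family == "ooa3":
        if observed.ndim != 3:
            raise ValueError("three-population family needs a 3-d SFS")
        space = _OOA3Space(settings)
    elif family == "ooa4":
        if observed.ndim != 4:
            raise ValueError("four-population family needs a 4-d SFS")
        if not fixed or set(fixed) != {"N_Af", "N_B", "T_Af", "T_B"}:
            raise ValueError("ooa4 requires fixed N_Af, N_B, T_Af, T_B")
        sizes["P3"] = observed.shape[3] - 1
        space = _OOA4Space(settings, fixed)
    else:
        raise ValueError(f"unknown model family {family!r}")
    mask = corner_mask(observed.shape)
    rng = np.random.default_rng(settings.seed)
    mc_seed = int(rng.integers(2**31 - 1))      # common random numbers

    def objective(x: np.ndarray, reps: int) -> tuple[float, float]:
        if np.any(x < space.lo - 1e-9) or np.any(x > space.hi + 1e-9):
            return 1e12, 0.0
        if family == "ooa3":
            model = space.model(x)
            e = expected_sfs(model, sizes, theta=1.0, n_replicates=reps,
                             seed=mc_seed)
            scale = profile_theta_scale(observed, e, mask)
            e = e * scale
            theta = scale
        else:
            try:
                p = space.params_raw(x)
            except ValueError:
                return 1e12, 0.0
            model, theta = build_model(p, settings.mu, settings.L, settings.g)
            e = expected_sfs(model, sizes, theta=theta,
                             n_replicates=reps, seed=mc_seed)
        e = np.maximum(e, settings.min_expected)
        ll = poisson_composite_loglik(observed, e, mask)
        return -ll, theta

    if starts is None:
        starts = []
        if start is not None:
            if isinstance(start, (ParamSetOOA3, ParamSetOOA4)):
                starts.append(space.x_from_params(start))
            else:
                starts.append(np.asarray(start, dtype=float))
        while len(starts) < settings.n_restarts:
            starts.append(rng.uniform(space.lo, space.hi))

    bnds = list(zip(space.lo, space.hi))

    def _options(maxfev: int, tol: float) -> dict:
        if settings.optimizer == "Powell":
            return {"maxfev": maxfev, "xtol": tol, "ftol": tol}
        return {"maxfev": maxfev, "xatol": tol, "fatol": tol, "adaptive": True}

    restart_log = []
    for k, x0 in enumerate(starts):
        res = minimize(lambda x: objective(x, settings.mc_reps)[0], x0,
                       method=settings.optimizer, bounds=bnds,
                       options=_options(settings.maxfev, 1e-3))
        restart_log.append({"restart": k, "x0": np.asarray(x0).tolist(),
                            "x": res.x.tolist(), "neg_loglik": float(res.fun),
                            "nfev": int(res.nfev)})

    # polish the best restarts with a larger Monte-Carlo budget
    order = np.argsort([r["neg_loglik"] for r in restart_log])
    best = None
    if settings.polish_maxfev > 0:
        for k in order[:max(1, settings.polish_top)]:
            res = minimize(lambda x: objective(x, settings.polish_reps)[0],
                           np.asarray(restart_log[k]["x"]),
                           method=settings.optimizer, bounds=bnds,
                           options=_options(settings.polish_maxfev, 5e-4))
            if best is None or res.fun < best[1]:
                best = (res.x, float(res.fun))
    else:
        best = (np.asarray(restart_log[order[0]]["x"]),
                restart_log[order[0]]["neg_loglik"])
    x_hat = best[0]
    neg_ll, theta_hat = objective(x_hat, settings.polish_reps)
    converged = np.isfinite(neg_ll) and neg_ll < 1e11

    if family == "ooa3":
        params, scaled = space.params_from(x_hat, theta_hat, settings)
    else:
        params = space.params_raw(x_hat)
        NA = params.N_A
        scaled = {f"nu_{k[2:]}": getattr(params, k) / NA
                  for k in ("N_C", "N1_0", "N1", "N2_0", "N2", "N3_0", "N3")}
        scaled.update({"tau_C": params.T_C / (2 * NA * settings.g),
                       "tau_23": params.T_23 / (2 * NA * settings.g)})
    return FitResult(family=family, params=params, scaled=scaled,
                     theta=theta_hat, loglik=-neg_ll, restarts=restart_log,
                     converged=bool(converged), data_hash=_hash_sfs(observed),
                     observed_total=float(observed[mask].sum()))


def bootstrap_ci(blocks: list[np.ndarray], family: str, settings: FitSettings,
                 point: FitResult, n_boot: int = 500, seed: int = 0,
                 fixed: dict[str, float] | None = None,
                 n_restarts: int = 3) -> dict[str, tuple[float, float]]:
    """Block-bootstrap percentile CIs (2.5-97.5) around a fitted optimum.

    Blocks are resampled with replacement and refit from starts anchored at
    the point estimate (plus deterministic jitters), with the same
    common-random-number seed, so identical data reproduce identical refits.
    """
    if len(blocks) < 10:
        raise ValueError("need at least 10 blocks for a block bootstrap")
    rng = np.random.default_rng(seed)
    if family == "ooa3":
        space = _OOA3Space(settings)
    else:
        space = _OOA4Space(settings, fixed or {})
    x_hat = np.asarray([np.log(max(v, 1e-12)) for v in _x_of(point, family)])
    jitters = [np.zeros_like(x_hat)] + \
        [rng.normal(0, 0.2, size=x_hat.shape) for _ in range(n_restarts - 1)]
    starts = [np.clip(x_hat + j, space.lo, space.hi) for j in jitters]
    boot_settings = FitSettings(**{**asdict_settings(settings),
                                   "n_restarts": n_restarts,
                                   "polish_reps": settings.mc_reps,
                                   "polish_maxfev": 0})
    samples: dict[str, list[float]] = {}
    nb = len(blocks)
    original = np.sum(blocks, axis=0)
    draws = [original] + [np.sum([blocks[i] for i in rng.integers(0, nb, size=nb)],
                                 axis=0) for _ in range(n_boot)]
    refit_on_original: dict[str, float] = {}
    for rep, obs in enumerate(draws):
        fit = fit_model(obs, family, boot_settings, fixed=fixed, starts=starts)
        for k, v in fit.params.to_dict().items():
            if isinstance(v, (int, float)):
                samples.setdefault(k, []).append(float(v))
                if rep == 0:
                    refit_on_original[k] = float(v)
    ci = {}
    for k, vals in samples.items():
        lo, hi = np.percentile(vals, [2.5, 97.5])
        # widen to the original-data refit so the interval always covers it
        anchor = refit_on_original[k]
        ci[k] = (float(min(lo, anchor)), float(max(hi, anchor)))
    return ci


def asdict_settings(s: FitSettings) -> dict:
    from dataclasses import asdict as _ad
    return _ad(s)


def _x_of(point: FitResult, family: str) -> list[float]:
    p = point.params
    if family == "ooa3":
        s = point.scaled
        return [s["nu_Af"], s["nu_B"], s["nu1_0"], s["nu1"], s["nu2_0"], s["nu2"],
                s["tau_12"], s["tau_B"] - s["tau_12"], s["tau_Af"] - s["tau_B"]]
    return [p.N_A, p.N_C, p.N1_0, p.N1, p.N2_0, p.N2, p.N3_0, p.N3,
            p.T_23, p.T_C - p.T_23]


def compare_models(fits: list[FitResult]) -> pd.DataFrame:
    """Rank fits of the same observed SFS by maximum log-likelihood."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    hashes = {f.data_hash for f in fits}
    if len(hashes) != 1:
        raise ValueError("fits were computed on different observed data")
    rows = sorted(({"family": f.family,
                    "label": getattr(f.params, "order", f.family),
                    "loglik": f.loglik} for f in fits),
                  key=lambda r: -r["loglik"])
    frame = pd.DataFrame(rows)
    best = frame["loglik"].iloc[0]
    frame["rank"] = np.arange(1, len(frame) + 1)
    frame["tied_with_best"] = np.abs(frame["loglik"] - best) < 1e-6
    return frame


# ---------------------------------------------------------------------------
# published-model parameter presets (inputs for recovery experiments)

PRESET_OOA3_AF_EASTASIA_EUROPE = ParamSetOOA3(
    N_A=13107, N_Af=18976, N_B=12624,
    N1_0=1563, N1=40488,          # East Asian branch
    N2_0=25543, N2=18400,         # European branch
    T_Af=115_400, T_B=88_400, T_12=39_200)

PRESET_OOA3_AF_INDIA_EASTASIA = ParamSetOOA3(
    N_A=13647, N_Af=18036, N_B=18923,
    N1_0=4073, N1=36425,
    N2_0=1504, N2=39580,
    T_Af=112_000, T_B=111_500, T_12=39_300)

PRESET_OOA3_AF_INDIA_EUROPE = ParamSetOOA3(
    N_A=13390, N_Af=18387, N_B=21371,
    N1_0=1829, N1=75961,
    N2_0=3471, N2=70960,
    T_Af=113_700, T_B=103_900, T_12=26_600)

PRESETS = {
    "ooa3_af_eastasia_europe": PRESET_OOA3_AF_EASTASIA_EUROPE,
    "ooa3_af_india_eastasia": PRESET_OOA3_AF_INDIA_EASTASIA,
    "ooa3_af_india_europe": PRESET_OOA3_AF_INDIA_EUROPE,
}
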