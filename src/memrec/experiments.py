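"""Scripted experiments: error-vs-noise curves and pattern capacity scans.

Three reproducible protocols built on the core modules:

* :func:`mse_vs_delta` — reconstruction error of AMP (random and informed
  starts), PCA on J and on the Fisher matrix S, and the state-evolution
  predictions, on a grid of effective noise levels.
* :func:`pcrit_scan` — the capacity experiment: at fixed network size and
  noise well below critical, how many patterns can mean-field AMP recover
  in at least half of a batch of independent runs?
* :func:`pcrit_scaling` — repeats the scan over several network sizes and
  fits the power law P_crit ~ N^γ.

Each experiment is fully determined by its config and master seed:
per-run seeds are derived from ``SeedSequence(seed, spawn_key=(P, run))``
so results do not depend on scan order.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .amp import AMPOptions, reconstruction_error, run_amp
from .channel import ChannelSpec, fisher_score, solve_nu_for_delta
from .netgen import generate_instance
from .priors import PriorSpec
from .spectral import pca_reconstruct
from .state_evolution import critical_delta, iterate_se

__all__ = [
    "ExperimentConfig",
    "PcritResult",
    "mse_vs_delta",
    "pcrit_scan",
    "pcrit_scaling",
    "fit_power_law",
]

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Shared configuration for the experiment protocols.

    ``delta_fractions`` are noise levels as fractions of the prior's
    critical noise (the natural axis: performance depends on (τ, ν) only
    through Δ/Δ_c); ν is derived by inverting the effective-noise map at
    the configured τ.  ``success_fraction`` is the capacity-experiment
    threshold: a run succeeds when its aligned per-pattern error is below
    this fraction of the trivial (random-guessing) error.  ``damping``
    applies to the capacity scans only (many-pattern mean-field runs
    oscillate without it); the single-pattern error curves run undamped.
    """

    prior_family: str = "binary"
    rho: float | None = None
    tau: float = 0.0
    delta_fractions: tuple[float, ...] = (0.3, 0.5, 0.7, 0.9, 1.2)
    N: int | tuple[int, ...] = 1000
    P: int = 1
    n_runs: int = 5
    delta_fraction: float = 0.2
    success_fraction: float = 0.2
    p_min: int | None = None
    p_max: int | None = None
    stop_after: int = 5
    mode: str = "meanfield"
    max_iter: int = 300
    tol: float = 1e-8
    damping: float = 0.3
    seed: int = 0

    @property
    def prior(self) -> PriorSpec:
        return PriorSpec(self.prior_family, self.rho)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("delta_fractions", "N"):
            if isinstance(d.get(key), list):
                d[key] = tuple(d[key])
        return cls(**d)


def _run_seed(master: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(master, spawn_key=key)


def _nu_for(delta: float, tau: float) -> float:
    roots = solve_nu_for_delta(delta, tau)
    return roots[-1]  # largest root; unique at tau = 0


# ---------------------------------------------------------------------------
# mse vs delta
# ---------------------------------------------------------------------------


def mse_vs_delta(
    cfg: ExperimentConfig,
    algorithms: tuple[str, ...] = (
        "amp",
        "amp_informed",
        "pca_j",
        "pca_s",
        "se",
        "se_informed",
    ),
) -> pd.DataFrame:
    """Reconstruction error of every algorithm across the Δ grid.

    Returns a tidy frame with one row per (Δ, algorithm, seed); the state
    evolution columns are deterministic (seed recorded as −1).
    """
    prior = cfg.prior
    dc = critical_delta(prior)
    N = cfg.N if isinstance(cfg.N, int) else cfg.N[0]
    rows = []
    for frac in cfg.delta_fractions:
        delta = frac * dc
        try:
            nu = _nu_for(delta, cfg.tau)
        except ValueError:
            logger.warning(
                "Delta=%.4g unreachable at tau=%.3g; skipping", delta, cfg.tau
            )
            continue
        ch = ChannelSpec(cfg.tau, nu)
        for se_init, name in (("random", "se"), ("informed", "se_informed")):
            if name not in algorithms:
                continue
            se = iterate_se(delta, prior, init=se_init)
            rows.append(
                dict(
                    delta=delta,
                    delta_rel=frac,
                    nu=nu,
                    algorithm=name,
                    seed=-1,
                    mse_raw=se.mse_predicted * cfg.P * prior.second_moment,
                    mse_norm=se.mse_predicted,
                    converged=se.converged,
                )
            )
        for run in range(cfg.n_runs):
            ss = _run_seed(cfg.seed, int(round(1e6 * frac)), run)
            inst = generate_instance(prior, ch, N, cfg.P, ss)
            S = fisher_score(inst.connectivity, ch)
            t0 = time.perf_counter()
            for name in algorithms:
                if name.startswith("se"):
                    continue
                if name in ("amp", "amp_informed"):
                    opts = AMPOptions(
                        mode=cfg.mode,
                        init="informed" if name.endswith("informed") else "random",
                        max_iter=cfg.max_iter,
                        tol=cfg.tol,
                        seed=int(ss.generate_state(1)[0] % 2**31),
                    )
                    res = run_amp(S, prior, opts, ground_truth=inst.patterns)
                    est, conv = res.estimate, res.converged
                elif name == "pca_j":
                    est = pca_reconstruct(
                        inst.connectivity, cfg.P, center=True
                    ).estimate
                    conv = True
                elif name == "pca_s":
                    est = pca_reconstruct(S, cfg.P, source="fisher").estimate
                    conv = True
                else:
                    raise ValueError(f"unknown algorithm {name!r}")
                raw = reconstruction_error(
                    est, inst.patterns, normalized=False, prior=prior
                )
                norm = raw / (cfg.P * prior.second_moment)
                rows.append(
                    dict(
                        delta=delta,
                        delta_rel=frac,
                        nu=nu,
                        algorithm=name,
                        seed=run,
                        mse_raw=raw,
                        mse_norm=norm,
                        converged=conv,
                    )
                )
            logger.info(
                "delta/dc=%.3g run %d done in %.2fs",
                frac,
                run,
                time.perf_counter() - t0,
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# capacity experiments
# ---------------------------------------------------------------------------


@dataclass
class PcritResult:
    """Outcome of a capacity scan at one network size."""

    p_crit: int
    successes: dict[int, int]
    n_runs: int
    errors: dict[int, list[float]] = field(default_factory=dict)


def _capacity_success(
    prior: PriorSpec,
    ch: ChannelSpec,
    N: int,
    P: int,
    seed: np.random.SeedSequence,
    cfg: ExperimentConfig,
) -> float:
    """Aligned per-pattern raw mse of one mean-field reconstruction run."""
    inst = generate_instance(prior, ch, N, P, seed)
    S = fisher_score(inst.connectivity, ch)
    # damping stabilises the many-pattern mean-field iteration, whose
    # time-lagged slot couplings otherwise oscillate at large P
    opts = AMPOptions(
        mode=cfg.mode,
        init="random",
        damping=cfg.damping,
        max_iter=cfg.max_iter,
        tol=cfg.tol,
        seed=int(seed.generate_state(1)[0] % 2**31),
    )
    res = run_amp(S, prior, opts, ground_truth=inst.patterns)
    raw = reconstruction_error(
        res.estimate, inst.patterns, normalized=False, prior=prior
    )
    return raw / P


def pcrit_scan(cfg: ExperimentConfig, N: int | None = None) -> PcritResult:
    """Largest pattern count recoverable in ≥ half of the runs.

    At Δ = delta_fraction·Δ_c, for increasing P, ``n_runs`` independent
    instances are reconstructed with mean-field AMP from random starts; a
    run succeeds when its aligned per-pattern error is below
    success_fraction · m2 (the trivial per-pattern error).  The scan uses
    unit steps (optionally after a doubling phase far below the
    transition) and stops ``stop_after`` consecutive sub-majority P values
    past the last success.
    """
    prior = cfg.prior
    if N is None:
        N = cfg.N if isinstance(cfg.N, int) else cfg.N[0]
    delta = cfg.delta_fraction * critical_delta(prior)
    nu = _nu_for(delta, cfg.tau)
    ch = ChannelSpec(cfg.tau, nu)
    threshold = cfg.success_fraction * prior.second_moment
    need = math.ceil(cfg.n_runs / 2)

    successes: dict[int, int] = {}
    errors: dict[int, list[float]] = {}

    def run_P(P: int) -> int:
        t0 = time.perf_counter()
        errs = [
            _capacity_success(prior, ch, N, P, _run_seed(cfg.seed, N, P, r), cfg)
            for r in range(cfg.n_runs)
        ]
        errors[P] = errs
        n_ok = int(sum(e < threshold for e in errs))
        successes[P] = n_ok
        logger.info(
            "N=%d P=%d: %d/%d runs succeeded (%.1fs)",
            N,
            P,
            n_ok,
            cfg.n_runs,
            time.perf_counter() - t0,
        )
        return n_ok

    # coarse doubling far below the transition, unless a range is pinned
    if cfg.p_min is not None:
        start = cfg.p_min
    else:
        last_all = 0
        P = 1
        while run_P(P) == cfg.n_runs:
            last_all = P
            P *= 2
        # first non-unanimous P observed; refine with unit steps from the
        # last all-success point
        start = last_all + 1

    last_success = max((P for P, n in successes.items() if n >= need), default=0)
    P = start
    while True:
        if P not in successes:
            run_P(P)
        if successes[P] >= need:
            last_success = max(last_success, P)
        if cfg.p_max is not None and P >= cfg.p_max:
            break
        if cfg.p_max is None and P - last_success >= cfg.stop_after:
            break
        P += 1

    p_crit = max((P for P, n in successes.items() if n >= need), default=0)
    return PcritResult(
        p_crit=p_crit, successes=dict(sorted(successes.items())), n_runs=cfg.n_runs,
        errors=errors,
    )


def fit_power_law(
    N_values: np.ndarray, p_values: np.ndarray
) -> tuple[float, float, float]:
    """Least-squares fit of log p = γ log N + c.

    Returns (gamma, stderr_gamma, prefactor exp(c)).
    """
    N_values = np.asarray(N_values, dtype=float)
    p_values = np.asarray(p_values, dtype=float)
    if len(N_values) < 3:
        raise ValueError("need at least three network sizes")
    if np.any(p_values <= 0):
        raise ValueError("cannot fit a power law through P_crit = 0")
    x, y = np.log(N_values), np.log(p_values)
    coeffs, cov = np.polyfit(x, y, 1, cov=True)
    gamma, intercept = coeffs
    return float(gamma), float(np.sqrt(cov[0, 0])), float(np.exp(intercept))


def pcrit_scaling(cfg: ExperimentConfig) -> tuple[float, float, pd.DataFrame]:
    """Fit P_crit ~ N^γ across the configured list of network sizes."""
    if isinstance(cfg.N, int):
        raise ValueError("pcrit_scaling needs a list of network sizes in cfg.N")
    rows = []
    for N in cfg.N:
        res = pcrit_scan(cfg, N=N)
        rows.append(dict(N=N, p_crit=res.p_crit))
    table = pd.DataFrame(rows)
    gamma, stderr, _ = fit_power_law(table["N"].values, table["p_crit"].values)
    return gamma, stderr, table
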