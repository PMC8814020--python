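"""Orchestrated desk-scale experiments: bias grids, sample-size sweeps, divergence test.

These pipelines wire the simulator and the estimators together to reproduce,
at desk scale, the qualitative signatures of assortative mating on
marker-based heritability estimates: HE regression inflated independently of
sample size, REML declining with sample size at fixed polygenicity, neither
rescued by principal components or annotation partitioning, and the paired
small-versus-large subsample divergence statistic that detects the REML
signature in a single dataset.

Unrelated estimation samples are obtained by drawing one offspring per
sibship (the pedigree is known to the simulator), which guarantees no pair
of close relatives at any marker count; the GRM-threshold pruning rule is
available separately as :func:`amherit.simulator.filter_relatives`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import theory
from .estimators import HERegression, REML, compute_grm
from .simulator import (
    Population,
    SimConfig,
    drop_variants,
    evolve,
    expand_genotypes,
    unrelated_indices,
)

__all__ = [
    "Cohort",
    "BiasExperimentResult",
    "DivergenceTestResult",
    "spawn_seeds",
    "simulate_unrelated_cohort",
    "bias_vs_r",
    "sample_size_sweep",
    "divergence_test",
    "missing_snp_experiment",
]


def spawn_seeds(master_seed: int, k: int) -> list:
    """k reproducible child seeds (each < 2^31) from one master seed."""
    return [
        int(child.generate_state(1)[0] >> 1)
        for child in np.random.SeedSequence(master_seed).spawn(k)
    ]


@dataclass
class Cohort:
    """An unrelated estimation sample drawn from a simulated population."""

    genotypes: np.ndarray
    phenotypes: np.ndarray
    population: Population
    panel: object
    architecture: object
    summaries: pd.DataFrame
    config: SimConfig


@dataclass
class BiasExperimentResult:
    estimates: pd.DataFrame
    summary: pd.DataFrame
    seeds: list


@dataclass
class DivergenceTestResult:
    deltas: np.ndarray
    delta_bar: float
    t_stat: float
    p_value: float
    n_pairs: int
    caveat: bool = True  # replicates share the complement data


def simulate_unrelated_cohort(config: SimConfig, n: int = None) -> Cohort:
    """Simulate to the final generation and return one offspring per sibship.

    With monogamous pairs and two offspring each, the final generation of N
    individuals contains N/2 sibships; taking one member per sibship yields
    an unrelated sample of N/2.
    """
    res = evolve(config)
    pop = res.population
    idx = unrelated_indices(pop)
    if n is not None:
        if idx.size < n:
            raise ValueError(
                f"simulated pool provides {idx.size} unrelated individuals, need {n}"
            )
        idx = idx[:n]
    sub = Population(
        generation=pop.generation,
        labels=pop.labels[idx],
        mating_regime=pop.mating_regime,
        phenotypes=pop.phenotypes[idx],
        family=pop.family[idx] if pop.family is not None else None,
    )
    G = expand_genotypes(sub, res.panel)
    return Cohort(G, sub.phenotypes, sub, res.panel, res.architecture,
                  res.summaries, config)


def _he_point(G, y):
    grm, _ = compute_grm(G)
    return HERegression().fit(grm, y).h2_


def _reml_point(G, y):
    grm, _ = compute_grm(G)
    return REML().fit(grm, y).h2_


def bias_vs_r(
    sim_config: SimConfig,
    r_grid,
    n_reps: int,
    n: int = None,
    include_reml: bool = False,
) -> BiasExperimentResult:
    """Mean HE (and optionally REML) estimates across mate correlations.

    For each r the population is simulated to the end of the assortative
    phase, relatives are excluded, and estimates are attached to the
    closed-form expectation ``h_inf^2 / (1 - r h_inf^2)`` and its corrected
    inversions.
    """
    r_grid = list(r_grid)
    seeds = spawn_seeds(sim_config.seed, len(r_grid) * n_reps)
    rows = []
    it = iter(seeds)
    for r in r_grid:
        if not 0.0 <= r < 1.0:
            raise ValueError(f"r grid values must lie in [0, 1), got {r}")
        for rep in range(n_reps):
            seed = next(it)
            cfg = replace(sim_config, r=float(r), seed=seed)
            cohort = simulate_unrelated_cohort(cfg, n=n)
            row = {
                "r": r,
                "rep": rep,
                "seed": seed,
                "n": cohort.phenotypes.size,
                "HE": _he_point(cohort.genotypes, cohort.phenotypes),
            }
            if include_reml:
                row["REML"] = _reml_point(cohort.genotypes, cohort.phenotypes)
            rows.append(row)
    df = pd.DataFrame(rows)

    methods = ["HE"] + (["REML"] if include_reml else [])
    summary_rows = []
    for r in r_grid:
        sub = df[df["r"] == r]
        eq = theory.solve_equilibrium(theory.AMModelParams(sim_config.h0_sq, float(r)))
        expected = theory.expected_he_exchangeable(eq.h_inf_sq, float(r))
        for method in methods:
            vals = sub[method].to_numpy()
            mean = float(vals.mean())
            mc_se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
            summary_rows.append(
                {
                    "r": r,
                    "method": method,
                    "mean": mean,
                    "mc_se": mc_se,
                    "n_reps": vals.size,
                    "theory_he": expected,
                    "h_inf_sq": eq.h_inf_sq,
                    "corrected_h_inf": theory.corrected_h_inf(mean, float(r)),
                    "corrected_h0": theory.corrected_h0(mean, float(r)),
                }
            )
    return BiasExperimentResult(df, pd.DataFrame(summary_rows), seeds)


def sample_size_sweep(
    sim_config: SimConfig,
    n_grid,
    n_reps: int,
    max_subsamples: int = 4,
) -> BiasExperimentResult:
    """HE and REML estimates across sample sizes, with log-linear trend fits.

    Each replicate simulates one pool of unrelated individuals of size
    ``max(n_grid)``; subsamples of each size are disjoint within a pool
    (up to ``max_subsamples`` per size), though sizes reuse the same pool.
    """
    n_grid = sorted(int(v) for v in n_grid)
    pool_n = n_grid[-1]
    if pool_n > sim_config.N // 2:
        raise ValueError(
            f"max(n_grid)={pool_n} exceeds the unrelated pool N/2={sim_config.N // 2}"
        )
    seeds = spawn_seeds(sim_config.seed, n_reps)
    rows = []
    for rep, seed in enumerate(seeds):
        cohort = simulate_unrelated_cohort(replace(sim_config, seed=seed), n=pool_n)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(pool_n)
        for size in n_grid:
            n_sub = min(pool_n // size, max_subsamples)
            for s in range(n_sub):
                idx = perm[s * size : (s + 1) * size]
                G, y = cohort.genotypes[idx], cohort.phenotypes[idx]
                rows.append(
                    {
                        "rep": rep,
                        "seed": seed,
                        "n": size,
                        "sub": s,
                        "HE": _he_point(G, y),
                        "REML": _reml_point(G, y),
                    }
                )
    df = pd.DataFrame(rows)

    summary_rows = []
    for method in ("HE", "REML"):
        x = np.log(df["n"].to_numpy(dtype=float))
        yv = df[method].to_numpy()
        res = stats.linregress(x, yv)
        summary_rows.append(
            {
                "method": method,
                "slope_vs_log_n": res.slope,
                "slope_se": res.stderr,
                "p_value": res.pvalue,
                "mean": float(yv.mean()),
            }
        )
    return BiasExperimentResult(df, pd.DataFrame(summary_rows), seeds)


def divergence_test(
    genotypes: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray = None,
    n_small: int = 1000,
    n_reps: int = 10,
    seed: int = 0,
    he_fn=None,
    reml_fn=None,
) -> DivergenceTestResult:
    """Paired small-vs-large subsample divergence of REML and HE estimates.

    For each of ``n_reps`` mutually exclusive small subsamples S^C (with
    complement S), computes

        delta = (h2_REML(S) - h2_REML(S^C)) - (h2_HE(S) - h2_HE(S^C))

    and tests delta_bar = 0 with a one-sample t statistic, analogous to the
    interaction contrast of a 2x2 within-subjects design.  Because all
    replicates share the bulk of the data, the p-value is descriptive
    (``caveat`` flag).  A trait under equilibrium assortment drives
    delta_bar negative: REML falls with sample size while HE does not.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n_reps * n_small > n:
        raise ValueError(
            f"{n_reps} disjoint subsamples of {n_small} do not fit in n={n}"
        )
    if he_fn is None:
        def he_fn(G, yy, cov):
            grm, _ = compute_grm(G)
            return HERegression().fit(grm, yy, covariates=cov).h2_
    if reml_fn is None:
        def reml_fn(G, yy, cov):
            grm, _ = compute_grm(G)
            return REML().fit(grm, yy, covariates=cov).h2_

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    deltas = np.empty(n_reps)
    for k in range(n_reps):
        small = np.sort(perm[k * n_small : (k + 1) * n_small])
        large = np.sort(np.setdiff1d(perm, small, assume_unique=True))
        def _sub(idx):
            G = genotypes[idx]
            cov = None if covariates is None else np.asarray(covariates)[idx]
            return G, y[idx], cov
        he_s, reml_s = (f(*_sub(large)) for f in (he_fn, reml_fn))
        he_c, reml_c = (f(*_sub(small)) for f in (he_fn, reml_fn))
        deltas[k] = (reml_s - reml_c) - (he_s - he_c)

    delta_bar = float(deltas.mean())
    sd = float(deltas.std(ddof=1)) if n_reps > 1 else 0.0
    if sd == 0.0:
        t_stat = 0.0 if delta_bar == 0.0 else np.inf * np.sign(delta_bar)
        p = 1.0 if delta_bar == 0.0 else 0.0
    else:
        t_stat = delta_bar / (sd / np.sqrt(n_reps))
        p = float(2.0 * stats.t.sf(abs(t_stat), df=n_reps - 1))
    return DivergenceTestResult(deltas, delta_bar, float(t_stat), p, n_reps)


def missing_snp_experiment(
    sim_config: SimConfig,
    fractions,
    n_reps: int,
    n: int = None,
    include_reml: bool = False,
) -> BiasExperimentResult:
    """Estimator attenuation when a random fraction of SNPs is unobserved.

    Drops causal and non-causal SNPs alike before GRM construction (paired
    across fractions within a replicate) and reports percent attenuation
    relative to the complete-data estimate.
    """
    fractions = sorted(float(f) for f in fractions)
    if 0.0 not in fractions:
        fractions = [0.0] + fractions
    seeds = spawn_seeds(sim_config.seed, n_reps)
    rows = []
    for rep, seed in enumerate(seeds):
        cohort = simulate_unrelated_cohort(replace(sim_config, seed=seed), n=n)
        for frac in fractions:
            G, kept = drop_variants(cohort.genotypes, frac, seed=seed)
            row = {
                "rep": rep,
                "seed": seed,
                "fraction": frac,
                "p_kept": kept.size,
                "HE": _he_point(G, cohort.phenotypes),
            }
            if include_reml:
                row["REML"] = _reml_point(G, cohort.phenotypes)
            rows.append(row)
    df = pd.DataFrame(rows)

    methods = ["HE"] + (["REML"] if include_reml else [])
    summary_rows = []
    base = df[df["fraction"] == 0.0].set_index("rep")
    for frac in fractions:
        sub = df[df["fraction"] == frac].set_index("rep")
        for method in methods:
            atten = 1.0 - sub[method] / base[method]
            summary_rows.append(
                {
                    "fraction": frac,
                    "method": method,
                    "mean_estimate": float(sub[method].mean()),
                    "mean_attenuation_pct": float(100.0 * atten.mean()),
                    "mc_se": float(
                        sub[method].std(ddof=1) / np.sqrt(len(sub))
                    ) if len(sub) > 1 else np.nan,
                    "n_reps": len(sub),
                }
            )
    return BiasExperimentResult(df, pd.DataFrame(summary_rows), seeds)
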