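"""Canonical validation experiments at desk scale.

Each function runs one self-contained, seeded experiment of the package's
validation battery — the same computations the acceptance script and the
acceptance test suite execute.  Problem sizes (steps, replicates) default
to the desk-scale profile documented in docs/methods.md; every function
returns a plain dict of computed numbers.

Seeding: every experiment derives its own independent seed stream from
(seed, experiment tag), so experiments can run in any order or subset
with identical results.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.stats import ks_1samp, linregress

from ddtasep import fpt_theory, phase_theory
from ddtasep.burst_analysis import burst_summary
from ddtasep.gene_model import build_uniform_gene, uniform_rates
from ddtasep.observables import bulk_observables
from ddtasep.simulator import first_passage_samples, run
from ddtasep.sweep import invert_gamma, invert_gamma_equal_rates

__all__ = [
    "headway_mean_experiment",
    "fpt_regression_experiment",
    "classical_recovery_experiment",
    "robust_bursting_experiment",
    "burst_size_experiment",
    "saturated_ceiling_experiment",
    "phase_agreement_experiment",
]

_TAGS = {
    "fpt": 11,
    "classical": 23,
    "bursting": 37,
    "burst_size": 41,
    "ceiling": 53,
    "phase": 67,
}


def _seeds(seed: int, tag: str, n: int) -> list[int]:
    ss = np.random.SeedSequence([int(seed), _TAGS[tag]])
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def headway_mean_experiment(rho: float = 0.5) -> dict:
    """Mean of the stationary time-headway distribution by numerical integration.

    Integrates t f(t; rho) over [0, inf); at rho = 1/2 the closed-form
    mean is 1/[rho(1-rho)] = 4.
    """
    mean, err = quad(lambda t: t * phase_theory.headway_pdf(t, rho), 0, np.inf,
                     epsabs=1e-10, limit=200)
    norm, _ = quad(lambda t: phase_theory.headway_pdf(t, rho), 0, np.inf,
                   epsabs=1e-10, limit=200)
    return {"mean": float(mean), "normalization": float(norm), "quad_error": float(err)}


def fpt_regression_experiment(
    seed: int,
    n_replicates: int = 400,
    h_c_values: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0),
    gamma_targets: tuple[float, ...] = (0.002, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 0.99),
    length_bp: int = 20_000,
) -> dict:
    """Simulated first-passage mean/variance vs the exact formulas across a rate grid.

    A 20-kbp gene (100 nucleosome units) at saturating initiation
    (alpha = beta = q = 1); for each (h_c, gamma) cell the unwrap rate is
    solved from the gamma target, ``n_replicates`` pioneer passages are
    simulated, and the per-cell sample means/variances are regressed
    against the analytic MFPT/VFPT.
    """
    geom = build_uniform_gene(length_bp)
    cells = [(h_c, g) for h_c in h_c_values for g in gamma_targets]
    seeds = _seeds(seed, "fpt", len(cells))
    sim_mean, th_mean, sim_var, th_var = [], [], [], []
    for s, (h_c, g) in zip(seeds, cells):
        h_o = invert_gamma(g, h_c)
        params = uniform_rates(geom, 1.0, 1.0, 1.0, h_c, h_o)
        fp = first_passage_samples(geom, params, n_replicates, seed=s)
        m, v = fpt_theory.gene_fpt(1.0, 1.0, 1.0, h_c, h_o, geom.n_units)
        sim_mean.append(fp.mean())
        th_mean.append(m)
        sim_var.append(fp.var(ddof=1))
        th_var.append(v)
    r2_m = float(linregress(th_mean, sim_mean).rvalue ** 2)
    r2_v = float(linregress(th_var, sim_var).rvalue ** 2)
    return {
        "r2_mfpt": r2_m,
        "r2_vfpt": r2_v,
        "n_cells": len(cells),
        "n_replicates": n_replicates,
        "sim_mean": sim_mean,
        "theory_mean": th_mean,
        "sim_var": sim_var,
        "theory_var": th_var,
    }


def classical_recovery_experiment(
    seed: int, n_steps_maxflux: int = 2_000_000, n_steps_ld: int = 1_000_000
) -> dict:
    """Classical open-boundary limits on bare DNA (wrapping off).

    At alpha = beta = q = 1 the flux saturates at the maximal current 1/4;
    at alpha = 0.1 the low-density phase gives (rho, v, J) =
    (alpha, 1 - alpha, alpha(1 - alpha)).
    """
    geom = build_uniform_gene(20_000)
    s1, s2 = _seeds(seed, "classical", 2)
    res = run(geom, uniform_rates(geom, 1.0, 1.0, 1.0, 0.0, 1.0),
              n_steps_maxflux, seed=s1, warn_short_window=False)
    obs_mf = bulk_observables(res)
    res = run(geom, uniform_rates(geom, 0.1, 1.0, 1.0, 0.0, 1.0),
              n_steps_ld, seed=s2, warn_short_window=False)
    obs_ld = bulk_observables(res)
    return {
        "J_maxflux": obs_mf.J,
        "rho_ld": obs_ld.rho,
        "v_ld": obs_ld.v,
        "J_ld": obs_ld.J,
    }


def robust_bursting_experiment(
    seed: int, n_replicates: int = 10, n_steps: int = 450_000
) -> dict:
    """Burst classification in a robust bursting regime (fast wrap, slow unwrap).

    alpha = 0.05, h_c = 0.1, h_o = 0.001 on a 20-kbp gene: transcription
    proceeds in convoys.  Reports the classifier threshold, the mean
    intra-burst waiting time, and the Kolmogorov-Smirnov distance of the
    intra-burst waits to the maximal-current time-headway distribution
    F(t; 1/2).
    """
    geom = build_uniform_gene(20_000)
    params = uniform_rates(geom, 0.05, 1.0, 1.0, 0.1, 0.001)
    results = [
        run(geom, params, n_steps, seed=s, warn_short_window=False)
        for s in _seeds(seed, "bursting", n_replicates)
    ]
    stats = burst_summary(results)
    out = {
        "bimodal": bool(stats.bimodal),
        "threshold": stats.threshold,
        "mean_t_in": stats.mean_t_in,
        "mean_NB": stats.mean_NB,
        "n_bursts": stats.n_bursts,
        "n_waits": stats.n_waits,
    }
    if stats.bimodal:
        intra = np.concatenate(
            [w[w <= stats.threshold] for w in (r.waiting_times() for r in results)]
        )
        ks = ks_1samp(intra, lambda t: phase_theory.headway_cdf(t, 0.5))
        out["ks_headway"] = float(ks.statistic)
    return out


def burst_size_experiment(
    seed: int, alpha: float, n_replicates: int = 10, n_steps: int = 1_000_000
) -> dict:
    """Mean burst size in the initiation-limited regime at gamma = 0.2.

    Equal wrap/unwrap rates h_c = h_o = 1/30 give a pioneer elongation
    rate gamma = 0.2; waiting times are pooled across replicates for the
    threshold, then burst sizes are aggregated.  Also reports the
    geometric-law variance ratio var/[mean(mean-1)] and the inter-burst
    interval dispersion var/mean^2 (1 for exponential IBIs).
    """
    geom = build_uniform_gene(20_000)
    h = invert_gamma_equal_rates(0.2)
    params = uniform_rates(geom, alpha, 1.0, 1.0, h, h)
    results = [
        run(geom, params, n_steps, seed=s, warn_short_window=False)
        for s in _seeds(int(seed) + int(alpha * 1e6), "burst_size", n_replicates)
    ]
    stats = burst_summary(results)
    out = {
        "bimodal": bool(stats.bimodal),
        "alpha": alpha,
        "h": h,
        "mean_NB": stats.mean_NB,
        "var_NB": stats.var_NB,
        "n_bursts": stats.n_bursts,
        "mean_t_ibi": stats.mean_t_ibi,
        "var_t_ibi": stats.var_t_ibi,
    }
    if stats.bimodal and stats.mean_NB is not None and stats.mean_NB > 1:
        out["geometric_var_ratio"] = stats.var_NB / (stats.mean_NB * (stats.mean_NB - 1.0))
    if stats.bimodal and stats.var_t_ibi is not None:
        out["ibi_dispersion"] = stats.var_t_ibi / stats.mean_t_ibi**2
    return out


def saturated_ceiling_experiment(
    seed: int,
    h_c: float = 0.1,
    gamma: float = 0.02,
    n_replicates: int = 10,
    n_steps: int = 1_000_000,
) -> dict:
    """Burst-size ceiling under saturating initiation.

    alpha = 1 with gamma driven low (h_o solved from gamma = 0.02 at
    h_c = 0.1): burst size is capped by how fast nucleosomes re-wrap and
    split the convoy, so the product mean_NB * h_c is reported.
    """
    geom = build_uniform_gene(20_000)
    h_o = invert_gamma(gamma, h_c)
    params = uniform_rates(geom, 1.0, 1.0, 1.0, h_c, h_o)
    results = [
        run(geom, params, n_steps, seed=s, warn_short_window=False)
        for s in _seeds(seed, "ceiling", n_replicates)
    ]
    stats = burst_summary(results)
    return {
        "bimodal": bool(stats.bimodal),
        "h_c": h_c,
        "h_o": h_o,
        "gamma": gamma,
        "mean_NB": stats.mean_NB,
        "NB_times_hc": None if stats.mean_NB is None else stats.mean_NB * h_c,
        "n_bursts": stats.n_bursts,
    }


def phase_agreement_experiment(
    seed: int,
    n_steps: int = 600_000,
    n_replicates: int = 3,
    h_c_values: tuple[float, ...] = (0.01, 0.1),
    gamma_accuracy: tuple[float, ...] = (0.4, 0.7),
    gamma_flatness: tuple[float, ...] = (0.2, 0.4, 0.7),
) -> dict:
    """Simulated flux vs the phase-plane estimate over a coarse grid.

    For each (h_c, gamma) cell the flux is simulated at alpha in
    {0.1, 0.5, 1.0} and compared with the initiation-limited branch below
    the critical line and the continuous plateau
    (:func:`ddtasep.phase_theory.flux_plateau`) above it.  Flatness of J
    in alpha above the transition is measured as J(alpha=1)/J(alpha=0.5).
    Returns per-cell relative errors and the worst-case magnitudes.
    """
    geom = build_uniform_gene(20_000)
    alphas = (0.1, 0.5, 1.0)
    gammas = tuple(sorted(set(gamma_accuracy) | set(gamma_flatness)))
    cells = [(h_c, g, a) for h_c in h_c_values for g in gammas for a in alphas]
    seeds = _seeds(seed, "phase", len(cells) * n_replicates)
    rows = []
    k = 0
    for h_c, g, a in cells:
        h_o = invert_gamma(g, h_c)
        params = uniform_rates(geom, a, 1.0, 1.0, h_c, h_o)
        js = []
        for _ in range(n_replicates):
            res = run(geom, params, n_steps, seed=seeds[k], warn_short_window=False)
            k += 1
            js.append(res.n_mrna_window / res.window)
        j_sim = float(np.mean(js))
        est = phase_theory.phase_estimates(a, g)
        j_th = (
            est.J_est
            if a < est.alpha_star
            else phase_theory.flux_plateau(g)
        )
        rows.append(
            {"h_c": h_c, "gamma": g, "alpha": a, "J_sim": j_sim, "J_theory": j_th,
             "rel_err": j_sim / j_th - 1.0}
        )
    accuracy_errs = [
        abs(r["rel_err"]) for r in rows if r["gamma"] in gamma_accuracy
    ]
    flatness = []
    for h_c in h_c_values:
        for g in gamma_flatness:
            j_half = next(r["J_sim"] for r in rows
                          if r["h_c"] == h_c and r["gamma"] == g and r["alpha"] == 0.5)
            j_one = next(r["J_sim"] for r in rows
                         if r["h_c"] == h_c and r["gamma"] == g and r["alpha"] == 1.0)
            flatness.append(abs(j_one / j_half - 1.0))
    return {
        "rows": rows,
        "max_abs_rel_err": float(max(accuracy_errs)),
        "max_flatness_dev": float(max(flatness)),
    }
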