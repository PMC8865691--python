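"""Phase behaviour in the (initiation rate, pioneer elongation rate) plane.

With termination fixed at beta = q, the transport observables of the
nucleosome-perturbed lattice are organized by two numbers: the initiation
rate alpha and the mean first-passage elongation rate gamma = 4/E_h (the
pioneer's ensemble speed through one nucleosome unit, gamma = 1 on bare
DNA).  A saturation-kinetics interpolation between the classical TASEP
limit (gamma = 1) and the strongly perturbed low-initiation limit gives

    v   = q gamma (1 - alpha)                    (initiation-limited)
    rho = alpha / (alpha + (1 - alpha) gamma)
    J   = rho v

with plateau values v_min = q gamma/(1+gamma), rho_max = 1/(1+gamma) and
J_max = q gamma/(1+gamma)^2 once initiation saturates.  The critical line

    alpha* = gamma / (1 + gamma)

separates the initiation-limited from the nucleosome-limited (jammed)
regime.  Note an internal tension of these closed forms: the zero of the
printed dJ/dalpha is at alpha_hat = sqrt(gamma)/(1 + sqrt(gamma)), not at
alpha*; the plateau constants are mutually consistent (rho_max * v_min =
J_max) but do not join the sub-critical branches continuously except at
gamma = 1.  This module exposes the conventional alpha* as
:func:`critical_alpha` and the flux-maximizing alpha_hat separately as
:func:`flux_maximizer`; continuity/zero-slope properties hold at the
latter.

Inside a polymerase convoy draining at the gene end the dynamics are a
maximal-current TASEP with effective density 1/2, so intra-burst waiting
times follow the stationary time-headway distribution f(t; rho) with
mean 1/[rho(1-rho)] = 4.  Burst sizes are geometric with mean N_B and
variance N_B(N_B - 1); under saturating initiation the mean burst size is
capped at roughly 3.3/h_c, set by how fast a nucleosome can close and
split the convoy.

This module is pure theory — no simulation; comparisons against the
simulator live in the test suite and sweep reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhaseEstimate",
    "HeadwayDistribution",
    "BurstSizeLaw",
    "critical_alpha",
    "flux_maximizer",
    "flux_plateau",
    "phase_estimates",
    "headway",
    "headway_pdf",
    "headway_cdf",
    "burst_size_law",
    "max_burst_size",
]


@dataclass(frozen=True)
class PhaseEstimate:
    alpha: float
    gamma: float
    q: float
    regime: str  # initiation_limited | nucleosome_limited
    v_est: float
    rho_est: float
    J_est: float
    alpha_star: float


@dataclass(frozen=True)
class HeadwayDistribution:
    """Stationary waiting-time distribution between successive particle exits."""

    rho_eff: float

    def pdf(self, t):
        return headway_pdf(t, self.rho_eff)

    def cdf(self, t):
        return headway_cdf(t, self.rho_eff)

    @property
    def mean(self) -> float:
        return 1.0 / (self.rho_eff * (1.0 - self.rho_eff))


@dataclass(frozen=True)
class BurstSizeLaw:
    """Geometric burst-size distribution with mean ``mean_NB``."""

    mean_NB: float
    p: float
    variance: float

    def pmf(self, k):
        k = np.asarray(k)
        out = np.where(k >= 1, (1.0 - self.p) ** (np.maximum(k, 1) - 1) * self.p, 0.0)
        return out if out.ndim else float(out)


def critical_alpha(gamma: float) -> float:
    """Critical initiation rate alpha* = gamma/(1+gamma) separating the regimes."""
    if not 0 < gamma <= 1:
        raise ValueError("gamma must lie in (0, 1]")
    return gamma / (1.0 + gamma)


def flux_maximizer(gamma: float) -> float:
    """The alpha at which the sub-critical flux branch is stationary:
    sqrt(gamma)/(1 + sqrt(gamma)).  See the module docstring for how this
    differs from :func:`critical_alpha`."""
    if not 0 < gamma <= 1:
        raise ValueError("gamma must lie in (0, 1]")
    rg = math.sqrt(gamma)
    return rg / (1.0 + rg)


def flux_plateau(gamma: float, q: float = 1.0) -> float:
    """Saturated flux as the maximum of the sub-critical branch.

    Evaluating J = q alpha (1-alpha) gamma / (alpha + (1-alpha) gamma) at
    its stationary point alpha_hat = sqrt(gamma)/(1+sqrt(gamma)) gives
    q gamma / (1 + sqrt(gamma))^2 — the plateau that joins the
    initiation-limited branch continuously with zero slope, and the value
    simulated fluxes level off at.  The conventional piecewise constants
    in :func:`phase_estimates` quote q gamma/(1+gamma)^2 instead; see the
    module docstring for the distinction.
    """
    if not 0 < gamma <= 1:
        raise ValueError("gamma must lie in (0, 1]")
    return q * gamma / (1.0 + math.sqrt(gamma)) ** 2


def phase_estimates(alpha: float, gamma: float, q: float = 1.0) -> PhaseEstimate:
    """Piecewise estimates of (v, rho, J) at one point of the alpha-gamma plane.

    ``alpha`` and ``gamma`` are understood as rescaled by the advance rate
    ``q`` (beta = q assumed).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if gamma == 0:
        raise ValueError("gamma = 0: nucleosomes never open; no transcription")
    if not 0 < gamma <= 1:
        raise ValueError("gamma must lie in (0, 1]")
    if q <= 0:
        raise ValueError("q must be > 0")
    a_star = critical_alpha(gamma)
    if alpha < a_star:
        v = q * gamma * (1.0 - alpha)
        rho = alpha / (alpha + (1.0 - alpha) * gamma)
        J = q * alpha * (1.0 - alpha) * gamma / (alpha + (1.0 - alpha) * gamma)
        regime = "initiation_limited"
    else:
        v = q * gamma / (1.0 + gamma)
        rho = 1.0 / (1.0 + gamma)
        J = q * gamma / (1.0 + gamma) ** 2
        regime = "nucleosome_limited"
    return PhaseEstimate(
        alpha=alpha, gamma=gamma, q=q, regime=regime,
        v_est=v, rho_est=rho, J_est=J, alpha_star=a_star,
    )


def headway_pdf(t, rho):
    """Density f(t; rho) of the stationary time headway at bulk density rho."""
    _check_rho(rho)
    t = np.asarray(t, dtype=float)
    # products expanded into decaying exponentials for large-t stability
    et = np.exp(-t)
    f = (
        rho / (1.0 - rho) * (np.exp(-rho * t) - et)
        + (1.0 - rho) / rho * (np.exp(-(1.0 - rho) * t) - et)
        - t * et
    )
    out = np.where(t >= 0, f, 0.0)
    return out if out.ndim else float(out)


def headway_cdf(t, rho):
    """Cumulative F(t; rho) of the stationary time headway."""
    _check_rho(rho)
    t = np.asarray(t, dtype=float)
    et = np.exp(-t)
    F = (
        1.0 / (1.0 - rho) * (1.0 - np.exp(-rho * t))
        - rho / (1.0 - rho) * (1.0 - et)
        + 1.0 / rho * (1.0 - np.exp(-(1.0 - rho) * t))
        - (1.0 - rho) / rho * (1.0 - et)
        + et * (1.0 + t)
        - 1.0
    )
    out = np.clip(np.where(t >= 0, F, 0.0), 0.0, 1.0)
    return out if out.ndim else float(out)


def headway(t, rho) -> tuple[np.ndarray, np.ndarray]:
    """(pdf, cdf) of the time-headway distribution evaluated at ``t``."""
    return headway_pdf(t, rho), headway_cdf(t, rho)


def _check_rho(rho: float) -> None:
    if not 0 < rho < 1:
        raise ValueError("rho must lie strictly inside (0, 1)")


def burst_size_law(mean_NB: float) -> BurstSizeLaw:
    """Geometric burst-size law: p = 1/mean, variance = mean(mean - 1)."""
    if mean_NB < 1:
        raise ValueError("mean burst size must be >= 1")
    p = 1.0 / mean_NB
    return BurstSizeLaw(mean_NB=mean_NB, p=p, variance=mean_NB * (mean_NB - 1.0))


def max_burst_size(h_c: float) -> float:
    """Saturated-initiation ceiling on the mean burst size: ~3.3/h_c."""
    if h_c <= 0:
        raise ValueError("h_c must be > 0")
    return 3.3 / h_c
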