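"""Bulk and profile observables of a simulation run.

Steady-state averages are taken over the window between the first
passage time t_FP (first completed mRNA) and the end of the run:

* density profile  rho_i = (1/(t_end - t_FP)) ∫ s_i dt
* bulk density     rho   = mean_i rho_i
* elongation rate  v     = mean_k N_sites / Δt_pass^k   (sites per time unit)
* flux             J     = N_mRNA / (t_end - t_FP)      (mRNA per time unit)
* nucleosome density rho_N = (mean wrap fraction) * k_N/(k_L + k_N),
  the linker-corrected fraction of the gene covered by wrapped nucleosomes.

Inter-site Pearson correlations are computed over per-step occupancy
snapshots (unweighted by the waiting times, following the estimator's
definition on Monte Carlo steps) from the start of the steady-state
window onward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ddtasep.simulator import SimResult

logger = logging.getLogger(__name__)

__all__ = ["BulkObservables", "CorrelationProfile", "bulk_observables", "correlation_profile", "kymograph_data"]


@dataclass(frozen=True)
class BulkObservables:
    """Steady-state transport summary of one run."""

    rho: float
    v: float | None
    J: float | None
    rho_N: float
    density_profile: np.ndarray
    nuc_profile: np.ndarray  # wrap fraction per nucleosome unit
    n_mrna: int
    window: float
    mrna_defined: bool

    def summary(self) -> dict[str, float]:
        return {
            "rho": self.rho,
            "v": np.nan if self.v is None else self.v,
            "J": np.nan if self.J is None else self.J,
            "rho_N": self.rho_N,
            "n_mrna": self.n_mrna,
            "window": self.window,
        }


@dataclass(frozen=True)
class CorrelationProfile:
    """Distance-averaged inter-site correlation r_Delta for Delta in [-d, d]."""

    d: int
    r_bar: np.ndarray
    R: np.ndarray | None = None

    @property
    def deltas(self) -> np.ndarray:
        return np.arange(-self.d, self.d + 1)


def bulk_observables(result: SimResult) -> BulkObservables:
    """Compute the transport summary (rho, v, J, nucleosome densities).

    When the run completed no mRNA, ``v`` and ``J`` are undefined
    (``None``, flagged by ``mrna_defined``) and densities are averaged
    over the whole run instead of the steady-state window.
    """
    geom = result.geom
    window = result.window
    if window <= 0:
        raise ValueError("run has zero measurement window")
    rho_i = result.occ_integral / window
    nuc_frac = result.wrap_integral / window
    rho_n = float(nuc_frac.mean()) * geom.k_N / (geom.k_L + geom.k_N)
    defined = result.n_terminations >= 1
    v = J = None
    if defined and len(result.passage_durations):
        v = float(np.mean(geom.n_sites / result.passage_durations))
        J = result.n_mrna_window / window
    return BulkObservables(
        rho=float(rho_i.mean()),
        v=v,
        J=J,
        rho_N=rho_n,
        density_profile=rho_i,
        nuc_profile=nuc_frac,
        n_mrna=result.n_mrna_window,
        window=window,
        mrna_defined=defined,
    )


def correlation_profile(
    result: SimResult, d: int = 50, keep_matrix: bool = False, n_sat: int | None = None
) -> CorrelationProfile:
    """Bulk inter-site correlation profile from per-step occupancy snapshots.

    Pearson r_ij is computed across snapshots taken at steps >= ``n_sat``
    (default: the first-passage step N_FP, the start of the steady-state
    window), then rows are centred on their diagonal and averaged so that
    r_Delta depends only on the inter-site distance Delta.  Constant site
    series get zero off-diagonal correlation (with a logged note) so that
    empty boundary sites do not poison the average.
    """
    if result.snapshots is None or not len(result.snapshots):
        raise ValueError("run was not recorded with sample_every > 0")
    n_sites = result.geom.n_sites
    if not 0 < d < n_sites // 2:
        raise ValueError("need 0 < d < n_sites/2")
    if n_sat is None:
        n_sat = result.n_fp if result.n_fp is not None else 0
    keep = result.snapshot_steps >= n_sat
    S = result.snapshots[keep].astype(np.float64)
    if S.shape[0] < 3:
        raise ValueError("too few snapshots after the saturation step")
    sd = S.std(axis=0)
    const = sd == 0
    if const.any():
        logger.info("correlation: %d constant site series set to r=0", int(const.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(S.T)
    R[np.isnan(R)] = 0.0
    np.fill_diagonal(R, 1.0)
    rows = np.arange(d, n_sites - d)
    r_bar = np.empty(2 * d + 1)
    for k, delta in enumerate(range(-d, d + 1)):
        r_bar[k] = R[rows + delta, rows].mean()
    return CorrelationProfile(d=d, r_bar=r_bar, R=R if keep_matrix else None)


def kymograph_data(result: SimResult) -> list[pd.DataFrame]:
    """Per-polymerase (time, site) traces reconstructed from the event log.

    Polymerases cannot pass each other, so FIFO pairing of initiations and
    terminations assigns a stable identity to every trajectory.  Sites are
    1-based; each trace starts at its initiation event.
    """
    if result.events is None:
        raise ValueError("run was not recorded with record_events=True")
    ev = result.events
    traces: dict[int, list[tuple[float, int]]] = {}
    site_pid: dict[int, int] = {}
    next_pid = 0
    for kind, idx, t in zip(ev["kind"], ev["index"], ev["time"]):
        if kind == "init":
            pid = next_pid
            next_pid += 1
            site_pid[0] = pid
            traces[pid] = [(t, 1)]
        elif kind in ("advance", "enter_nucleosome"):
            pid = site_pid.pop(idx)
            site_pid[idx + 1] = pid
            traces[pid].append((t, idx + 2))
        elif kind == "terminate":
            pid = site_pid.pop(idx)
            traces[pid].append((t, idx + 2))  # off-lattice marker
    if not traces and not len(ev):
        raise ValueError("empty event log")
    return [
        pd.DataFrame(tr, columns=["time", "site"]) for _, tr in sorted(traces.items())
    ]
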