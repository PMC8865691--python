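"""Exact stochastic simulation of transcription through breathing nucleosomes.

The model is a continuous-time Markov jump process simulated with the
Gillespie algorithm.  The legal moves and their propensities are

* initiation         — site 1 empty                       → alpha
* advance i → i+1    — site i occupied, i+1 empty, and (when i+1 is the
                       first nucleosome-associated site of unit m) the
                       nucleosome open                     → q_i
* termination        — last site occupied                  → beta
* wrap of unit m     — nucleosome open and all of its sites empty → h_c,m
* unwrap of unit m   — nucleosome wrapped                  → h_o,m

One "Monte Carlo step" is one executed event; the clock is event-driven
continuous time in units of the nominal advance rate (1/q).

Two engines are provided: a pure-Python reference that rebuilds the full
move list each step (:func:`enumerate_moves` / :func:`gillespie_step` /
:func:`run_reference`), and a fast compiled engine with incremental
propensity updates (:func:`run`) whose move distribution is checked
against the reference in the test suite.  Seeds are mandatory —
reproducibility is part of the contract.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from ddtasep import _engine
from ddtasep.gene_model import GeneGeometry, RateParams

__all__ = [
    "LatticeState",
    "Move",
    "Event",
    "SimResult",
    "enumerate_moves",
    "gillespie_step",
    "run_reference",
    "run",
    "first_passage_samples",
    "sample_resting_wraps",
]

EVENT_KINDS = ("init", "advance", "terminate", "wrap", "unwrap")


@dataclass
class LatticeState:
    """Binary occupancy ``s`` per site and wrap state ``h`` per nucleosome at time ``t``."""

    s: np.ndarray
    h: np.ndarray
    t: float = 0.0

    def validate(self, geom: GeneGeometry) -> None:
        """Hard-exclusion invariants: one polymerase per site, no wrapped
        nucleosome over an occupied site."""
        if self.s.shape != (geom.n_sites,) or self.h.shape != (geom.n_units,):
            raise ValueError("state arrays do not match the geometry")
        if np.any((self.s != 0) & (self.s != 1)) or np.any((self.h != 0) & (self.h != 1)):
            raise ValueError("state variables must be binary")
        for m, u in enumerate(geom.units):
            if self.h[m] and any(self.s[i - 1] for i in u.nuc_sites):
                raise ValueError(f"wrapped nucleosome {m + 1} over an occupied site")


@dataclass(frozen=True)
class Move:
    """A legal transition: kind plus 0-based site (polymerase moves) or unit index."""

    kind: str
    index: int


@dataclass(frozen=True)
class Event:
    """An executed move with its absolute time and waiting time."""

    kind: str
    index: int
    time: float
    dt: float


@dataclass
class SimResult:
    """Output of one simulation run.

    Completion times, per-mRNA passage durations (initiation to
    termination, FIFO pairing), time integrals of site occupancy and
    nucleosome wrap state over the steady-state window
    ``[t_fp, t_end]``, and (optionally) thinned occupancy snapshots and
    the full event log.
    """

    geom: GeneGeometry
    params: RateParams
    seed: int
    n_steps: int
    t_end: float
    n_terminations: int
    t_fp: float | None
    n_fp: int | None
    n_initiations: int
    completion_times: np.ndarray
    passage_durations: np.ndarray
    occ_integral: np.ndarray  # window [t_fp, t_end] (whole run if no mRNA)
    wrap_integral: np.ndarray
    occ_integral_total: np.ndarray  # whole run [0, t_end]
    wrap_integral_total: np.ndarray
    h_initial: np.ndarray
    snapshots: np.ndarray | None = None
    snapshot_steps: np.ndarray | None = None
    events: pd.DataFrame | None = None
    final_state: LatticeState | None = None

    @property
    def window(self) -> float:
        """Length of the steady-state measurement window."""
        return self.t_end - (self.t_fp if self.t_fp is not None else 0.0)

    @property
    def n_mrna_window(self) -> int:
        """mRNA completed inside the window (the first marks its start)."""
        return max(self.n_terminations - 1, 0)

    def waiting_times(self) -> np.ndarray:
        """Inter-termination waiting times t_w.  The time to the first mRNA
        (the first-passage transient) is not a waiting time."""
        return np.diff(self.completion_times)


def sample_resting_wraps(params: RateParams, rng: np.random.Generator) -> np.ndarray:
    """Initial wrap states: each nucleosome at its resting probability h_c/(h_c+h_o)."""
    tot = params.h_c_m + params.h_o_m
    p = np.divide(params.h_c_m, tot, out=np.zeros_like(tot), where=tot > 0)
    return (rng.random(p.shape) < p).astype(np.uint8)


def enumerate_moves(
    state: LatticeState, geom: GeneGeometry, params: RateParams
) -> list[tuple[Move, float]]:
    """All legal moves with their propensities, in canonical order.

    Canonical order: initiation, polymerase moves by source site, wraps by
    unit, unwraps by unit.  Only moves with positive propensity are listed.
    """
    state.validate(geom)
    s, h = state.s, state.h
    n = geom.n_sites
    gate = geom.gate_unit_of_site()
    moves: list[tuple[Move, float]] = []
    if s[0] == 0 and params.alpha > 0:
        moves.append((Move("init", 0), params.alpha))
    for i in range(n - 1):
        if s[i] == 1 and s[i + 1] == 0:
            g = gate[i + 1]
            if (g < 0 or h[g] == 0) and params.q_site[i] > 0:
                moves.append((Move("advance", i), params.q_site[i]))
    if s[n - 1] == 1 and params.beta > 0:
        moves.append((Move("terminate", n - 1), params.beta))
    nuc_sites = [u.nuc_sites for u in geom.units]
    for m in range(geom.n_units):
        if h[m] == 0:
            if all(s[i - 1] == 0 for i in nuc_sites[m]) and params.h_c_m[m] > 0:
                moves.append((Move("wrap", m), params.h_c_m[m]))
        elif params.h_o_m[m] > 0:
            moves.append((Move("unwrap", m), params.h_o_m[m]))
    return moves


def gillespie_step(
    state: LatticeState,
    moves: list[tuple[Move, float]],
    rng: np.random.Generator,
    geom: GeneGeometry,
) -> Event:
    """Select a move proportionally to its propensity, draw the exponential
    waiting time, and apply the move to ``state`` in place."""
    if not moves:
        raise RuntimeError("no legal moves (empty propensity set)")
    props = np.array([p for _, p in moves])
    total = props.sum()
    r = rng.random() * total
    k = int(np.searchsorted(np.cumsum(props), r, side="left"))
    k = min(k, len(moves) - 1)
    dt = -math.log(rng.random() or np.nextafter(0, 1)) / total
    move = moves[k][0]
    state.t += dt
    s, h = state.s, state.h
    if move.kind == "init":
        s[0] = 1
    elif move.kind == "advance":
        s[move.index] = 0
        s[move.index + 1] = 1
    elif move.kind == "terminate":
        s[move.index] = 0
    elif move.kind == "wrap":
        h[move.index] = 1
    else:
        h[move.index] = 0
    return Event(move.kind, move.index, state.t, dt)


def run_reference(
    geom: GeneGeometry,
    params: RateParams,
    n_steps: int,
    seed: int,
    stop_after_terminations: int = 0,
) -> Iterator[Event]:
    """Reference engine: rebuild the move list each step.  Yields events.

    Intended for small lattices and validation; :func:`run` is the
    production engine.
    """
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    state = LatticeState(
        s=np.zeros(geom.n_sites, dtype=np.uint8),
        h=sample_resting_wraps(params, rng),
    )
    n_term = 0
    for _ in range(n_steps):
        moves = enumerate_moves(state, geom, params)
        if not moves:
            return
        ev = gillespie_step(state, moves, rng, geom)
        yield ev
        if ev.kind == "terminate":
            n_term += 1
            if stop_after_terminations and n_term >= stop_after_terminations:
                return


def run(
    geom: GeneGeometry,
    params: RateParams,
    n_steps: int,
    seed: int,
    record_events: bool = False,
    sample_every: int = 0,
    stop_after_terminations: int = 0,
    warn_short_window: bool = True,
) -> SimResult:
    """Simulate ``n_steps`` Monte Carlo steps from the resting initial state.

    The lattice starts empty of polymerases with each nucleosome wrapped
    with its resting probability h_c,m/(h_c,m + h_o,m).  A warning is
    emitted when the run ends before eight first-passage times, the
    guideline for trustworthy steady-state averages.

    Parameters
    ----------
    record_events
        Keep the full event log (needed for kymographs).
    sample_every
        Record an occupancy snapshot every ``sample_every`` steps (needed
        for inter-site correlations).
    stop_after_terminations
        Stop early after this many completed mRNAs (0 = run all steps).
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if n_steps > 50_000_000 and (record_events or sample_every):
        raise ValueError("recording is limited to 5e7 steps; thin or split the run")
    out = _engine.run_kernel(
        geom.gate_unit_of_site(),
        geom.nuc_unit_of_site(),
        geom.entry_sites(),
        np.ascontiguousarray(params.q_site, dtype=np.float64),
        np.ascontiguousarray(params.h_c_m, dtype=np.float64),
        np.ascontiguousarray(params.h_o_m, dtype=np.float64),
        float(params.alpha),
        float(params.beta),
        int(n_steps),
        int(stop_after_terminations),
        int(seed) & 0x7FFFFFFF,
        int(sample_every),
        bool(record_events),
    )
    (
        step,
        t_end,
        n_term,
        t_fp,
        n_fp,
        n_init,
        term_times,
        pass_dur,
        occ_int,
        occ_fp,
        wrap_int,
        wrap_fp,
        snaps,
        snap_steps,
        ev_kind,
        ev_idx,
        ev_time,
        h_init,
        s_final,
        h_final,
    ) = out
    has_fp = n_term >= 1
    events = None
    if record_events:
        dts = np.diff(ev_time, prepend=0.0)
        entry = set(int(e) for e in geom.entry_sites())
        kinds = [
            "enter_nucleosome"
            if kk == _engine.EV_ADVANCE and int(ii) + 1 in entry
            else EVENT_KINDS[kk]
            for kk, ii in zip(ev_kind, ev_idx)
        ]
        events = pd.DataFrame(
            {
                "step": np.arange(1, len(ev_time) + 1),
                "time": ev_time,
                "dt": dts,
                "kind": kinds,
                "index": ev_idx,
            }
        )
    result = SimResult(
        geom=geom,
        params=params,
        seed=int(seed),
        n_steps=int(step),
        t_end=float(t_end),
        n_terminations=int(n_term),
        t_fp=float(t_fp) if has_fp else None,
        n_fp=int(n_fp) if has_fp else None,
        n_initiations=int(n_init),
        completion_times=term_times,
        passage_durations=pass_dur,
        occ_integral=(occ_int - occ_fp) if has_fp else occ_int.copy(),
        wrap_integral=(wrap_int - wrap_fp) if has_fp else wrap_int.copy(),
        occ_integral_total=occ_int,
        wrap_integral_total=wrap_int,
        h_initial=h_init,
        snapshots=snaps if sample_every else None,
        snapshot_steps=snap_steps if sample_every else None,
        events=events,
        final_state=LatticeState(s=s_final, h=h_final, t=float(t_end)),
    )
    if warn_short_window and has_fp and t_end < 8.0 * result.t_fp:
        warnings.warn(
            f"run ended at t = {t_end:.3g} < 8 x t_FP = {8 * result.t_fp:.3g}; "
            "steady-state averages may carry transient bias",
            stacklevel=2,
        )
    return result


def first_passage_samples(
    geom: GeneGeometry,
    params: RateParams,
    n_replicates: int,
    seed: int,
    max_steps_per_replicate: int = 2**62,
) -> np.ndarray:
    """First-passage times: full-model replicates run until the first mRNA.

    Each replicate starts from an independent resting initial state, so the
    sample includes the initiation wait (mean 1/alpha) and the termination
    wait (mean 1/beta) along the pioneer's nucleosome-passage time.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    seeds = derive_seeds(seed, n_replicates)
    out = np.empty(n_replicates)
    for r in range(n_replicates):
        res = run(
            geom,
            params,
            n_steps=max_steps_per_replicate,
            seed=int(seeds[r]),
            stop_after_terminations=1,
            warn_short_window=False,
        )
        if res.n_terminations < 1:
            raise RuntimeError("replicate exhausted its step budget before terminating")
        out[r] = res.completion_times[0]
    return out


def derive_seeds(base_seed: int, n: int) -> np.ndarray:
    """Independent child seeds (< 2^31) from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return np.array([int(s) & 0x7FFFFFFF for s in ss.generate_state(n)], dtype=np.int64)
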