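"""Move enumeration, Gillespie stepping, engine equivalence and first passage."""

import numpy as np
import pytest

from ddtasep import fpt_theory as ft
from ddtasep import gene_model as gm
from ddtasep.simulator import (
    LatticeState,
    derive_seeds,
    enumerate_moves,
    first_passage_samples,
    gillespie_step,
    run,
    run_reference,
)


def empty_state(geom, wrapped=False):
    return LatticeState(
        s=np.zeros(geom.n_sites, dtype=np.uint8),
        h=np.full(geom.n_units, 1 if wrapped else 0, dtype=np.uint8),
    )


class TestEnumerateMoves:
    def test_empty_lattice_all_wrapped(self, gene_20kbp):
        params = gm.uniform_rates(gene_20kbp, 0.05, 1.0, 1.0, 0.1, 0.001)
        state = empty_state(gene_20kbp, wrapped=True)
        moves = enumerate_moves(state, gene_20kbp, params)
        kinds = [m.kind for m, _ in moves]
        assert len(moves) == 101
        assert kinds.count("init") == 1 and kinds.count("unwrap") == 100
        total = sum(p for _, p in moves)
        assert total == pytest.approx(0.05 + 100 * 0.001)

    def test_wrapped_nucleosome_blocks_entry(self, gene_tiny):
        params = gm.uniform_rates(gene_tiny, 1.0, 1.0, 1.0, 0.1, 0.1)
        state = empty_state(gene_tiny, wrapped=True)
        state.s[0] = 1  # polymerase on the linker, downstream nucleosome wrapped
        moves = enumerate_moves(state, gene_tiny, params)
        assert not any(m.kind == "advance" for m, _ in moves)

    def test_occupied_nucleosome_site_blocks_wrap(self, gene_tiny):
        params = gm.uniform_rates(gene_tiny, 1.0, 1.0, 1.0, 0.1, 0.1)
        state = empty_state(gene_tiny)
        state.s[1] = 1  # first nucleosome-associated site
        moves = enumerate_moves(state, gene_tiny, params)
        assert not any(m.kind == "wrap" for m, _ in moves)

    def test_invalid_state_rejected(self, gene_tiny):
        params = gm.uniform_rates(gene_tiny, 1.0, 1.0)
        state = empty_state(gene_tiny, wrapped=True)
        state.s[2] = 1  # polymerase under a wrapped nucleosome
        with pytest.raises(ValueError, match="wrapped nucleosome"):
            enumerate_moves(state, gene_tiny, params)


class TestGillespieStep:
    def test_selection_frequencies(self, gene_tiny, rng):
        """Two channels with propensities 1:3 are chosen 25%/75%."""
        params = gm.uniform_rates(gene_tiny, 1.0, 3.0, 1.0, 0.0, 1.0)
        n = 100_000
        picked = 0
        for _ in range(n):
            state = empty_state(gene_tiny)
            state.s[0] = 1
            state.s[3] = 1  # advance (q=1) vs terminate (beta=3); init blocked
            ev = gillespie_step(
                state,
                [m for m in enumerate_moves(state, gene_tiny, params) if m[0].kind != "init"],
                rng,
                gene_tiny,
            )
            picked += ev.kind == "terminate"
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(picked / n - 0.75) < 3 * se

    def test_waiting_time_mean(self, gene_tiny, rng):
        params = gm.uniform_rates(gene_tiny, 2.0, 1.0, 1.0, 0.0, 1.0)
        n = 100_000
        dts = np.empty(n)
        for i in range(n):
            state = empty_state(gene_tiny)
            moves = enumerate_moves(state, gene_tiny, params)  # single init, a = 2
            assert len(moves) == 1
            dts[i] = gillespie_step(state, moves, rng, gene_tiny).dt
        assert abs(dts.mean() - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_empty_move_list_rejected(self, gene_tiny, rng):
        with pytest.raises(RuntimeError):
            gillespie_step(empty_state(gene_tiny), [], rng, gene_tiny)


class TestRun:
    def test_seed_mandatory(self, gene_tiny):
        params = gm.uniform_rates(gene_tiny, 1.0, 1.0)
        with pytest.raises(ValueError, match="seed"):
            run(gene_tiny, params, 100, seed=None)

    def test_equal_seeds_identical_events(self, gene_2kbp):
        params = gm.uniform_rates(gene_2kbp, 0.3, 1.0, 1.0, 0.05, 0.02)
        a = run(gene_2kbp, params, 20_000, seed=77, record_events=True,
                warn_short_window=False)
        b = run(gene_2kbp, params, 20_000, seed=77, record_events=True,
                warn_short_window=False)
        assert a.events.equals(b.events)
        np.testing.assert_array_equal(a.completion_times, b.completion_times)

    def test_alpha_zero_only_nucleosome_events(self, gene_2kbp):
        params = gm.uniform_rates(gene_2kbp, 0.0, 1.0, 1.0, 0.5, 0.5)
        res = run(gene_2kbp, params, 5_000, seed=3, record_events=True,
                  warn_short_window=False)
        assert res.n_terminations == 0 and res.n_initiations == 0
        assert set(res.events["kind"]) <= {"wrap", "unwrap"}

    def test_event_replay_preserves_hard_exclusion(self, gene_2kbp):
        """Replaying the engine's event log through the validated state
        object never violates exclusion or exclusive wrapping."""
        params = gm.uniform_rates(gene_2kbp, 0.5, 1.0, 1.0, 0.2, 0.05)
        res = run(gene_2kbp, params, 10_000, seed=11, record_events=True,
                  warn_short_window=False)
        state = LatticeState(
            s=np.zeros(gene_2kbp.n_sites, dtype=np.uint8), h=res.h_initial.copy()
        )
        state.validate(gene_2kbp)
        for kind, idx in zip(res.events["kind"], res.events["index"]):
            if kind == "init":
                assert state.s[0] == 0
                state.s[0] = 1
            elif kind in ("advance", "enter_nucleosome"):
                assert state.s[idx] == 1 and state.s[idx + 1] == 0
                state.s[idx] = 0
                state.s[idx + 1] = 1
            elif kind == "terminate":
                state.s[idx] = 0
            elif kind == "wrap":
                assert state.h[idx] == 0
                state.h[idx] = 1
            else:
                assert state.h[idx] == 1
                state.h[idx] = 0
            state.validate(gene_2kbp)

    def test_flux_conservation_across_bonds(self, gene_20kbp):
        """Long-run advance counts across fixed bonds match termination counts."""
        params = gm.uniform_rates(gene_20kbp, 0.1, 1.0, 1.0, 0.0, 1.0)
        res = run(gene_20kbp, params, 200_000, seed=13, record_events=True,
                  warn_short_window=False)
        adv = res.events[res.events["kind"].isin(["advance", "enter_nucleosome"])]
        for bond in (100, 250, 399):
            crossings = int((adv["index"] == bond - 1).sum())
            # counts can differ only by the particles still between the
            # bond and the exit when the run stops
            assert abs(crossings - res.n_terminations) <= gene_20kbp.n_sites

    def test_short_window_warning(self, gene_20kbp):
        params = gm.uniform_rates(gene_20kbp, 1.0, 1.0, 1.0, 0.0, 1.0)
        with pytest.warns(UserWarning, match="8 x t_FP"):
            run(gene_20kbp, params, 20_000, seed=5)


class TestEngineEquivalence:
    """The incremental-propensity kernel must be distributionally
    equivalent to the rebuild-all-moves reference on a small lattice."""

    def test_flux_and_headways_agree(self, gene_2kbp):
        params = gm.uniform_rates(gene_2kbp, 1.0, 1.0, 1.0, 0.1, 0.005)
        n_rep, steps = 5, 20_000

        def kernel_stats(seed):
            res = run(gene_2kbp, params, steps, seed=seed, warn_short_window=False)
            return res.n_mrna_window / res.window, res.waiting_times().mean()

        def reference_stats(seed):
            tt = [ev.time for ev in run_reference(gene_2kbp, params, steps, seed=seed)
                  if ev.kind == "terminate"]
            tt = np.asarray(tt)
            return (len(tt) - 1) / (tt[-1] - tt[0]), np.diff(tt).mean()

        ks = np.array([kernel_stats(int(s)) for s in derive_seeds(100, n_rep)])
        rs = np.array([reference_stats(int(s)) for s in derive_seeds(200, n_rep)])
        for col in range(2):
            se = np.sqrt(ks[:, col].var(ddof=1) / n_rep + rs[:, col].var(ddof=1) / n_rep)
            assert abs(ks[:, col].mean() - rs[:, col].mean()) < 3 * se


class TestFirstPassage:
    def test_bare_dna_mean(self, gene_20kbp, bare_dna_params):
        fp = first_passage_samples(gene_20kbp, bare_dna_params, 200, seed=7)
        se = np.sqrt(402.0 / 200)  # VFPT = MFPT on bare DNA at unit rates
        assert abs(fp.mean() - 402.0) < 3 * se

    def test_single_unit_gene(self, gene_tiny):
        params = gm.uniform_rates(gene_tiny, 1.0, 1.0, 1.0, 0.1, 0.1)
        fp = first_passage_samples(gene_tiny, params, 300, seed=8)
        mfpt, vfpt = ft.gene_fpt(1.0, 1.0, 1.0, 0.1, 0.1, 1)
        assert mfpt == pytest.approx(12.0)  # 1 + (3 + 7) + 1
        assert abs(fp.mean() - mfpt) < 3 * np.sqrt(vfpt / 300)

    def test_slow_breathing_gene(self, gene_20kbp):
        params = gm.uniform_rates(gene_20kbp, 1.0, 1.0, 1.0, 1 / 30, 1 / 30)
        fp = first_passage_samples(gene_20kbp, params, 150, seed=9)
        mfpt, vfpt = ft.gene_fpt(1.0, 1.0, 1.0, 1 / 30, 1 / 30, 100)
        assert mfpt == pytest.approx(2002.0)
        assert abs(fp.mean() - mfpt) < 3 * np.sqrt(vfpt / 150)

    def test_resting_wrap_initialisation(self, gene_20kbp):
        """Initial wrap states follow the resting probability h_c/(h_c+h_o)."""
        params = gm.uniform_rates(gene_20kbp, 0.0, 1.0, 1.0, 0.3, 0.1)
        draws = [run(gene_20kbp, params, 1, seed=s, warn_short_window=False).h_initial
                 for s in range(40)]
        frac = np.concatenate(draws).mean()
        p = 0.75
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / (40 * 100))
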