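# ddtasep

Stochastic lattice model of RNA polymerase II transcription through
breathing nucleosomes — a totally asymmetric simple exclusion process
(TASEP) whose lattice carries *dynamic defects* — with the exact
first-passage theory, phase-plane estimates, and burst analysis that go
with it.

## The problem

Nucleosomes wrap and unwrap on timescales of tens of seconds — slower
than a polymerase crosses them — so transcription elongation is not a
smooth march but a queue: polymerases pile up behind closed nucleosomes,
self-organize into convoys, and release mRNAs in bursts even when the
promoter fires at a constant rate.  This package is for anyone studying
that coupling quantitatively: it simulates the process exactly, computes
the analytic first-passage moments that calibrate it, and classifies the
resulting burst statistics.

## The model

A gene of 20 kbp is a lattice of 400 fifty-bp sites (one polymerase
footprint, one second at 50 bp/s, so `q = 1` site/time-unit sets the
clock), tiled by nucleosome units of one linker site plus three
nucleosome-associated sites.  Polymerases initiate at rate `α` when the
first site is free, hop forward at rate `q_i` under hard-core exclusion,
and terminate at rate `β = q`.  Nucleosome `m` wraps at rate `h_c,m` when
its three sites are empty and unwraps at rate `h_o,m`; a wrapped
nucleosome blocks entry.  The pioneering polymerase's passage of one unit
is a three-state absorbing Markov chain with mean

    E_h = 3/q + 1/q + (h_c/h_o)(1/q + 1/(h_c + h_o)),    γ = 4/E_h

and the mean first-passage elongation rate `γ` (the pioneer's speed
relative to bare DNA) organizes the whole phase diagram: gene-level
moments are `MFPT = 1/α + N_h E_h + 1/β` (likewise the variance), the
critical initiation rate is `α* = γ/(1+γ)`, and burst sizes are
geometric with exponential inter-burst intervals.  Sequence heterogeneity
enters as static defects (GC-dependent per-site advance rates, slowed on
CpG-island/exon annotations) or dynamic defects (GC-dependent
per-nucleosome wrap/unwrap rates, stabilized on annotations).

## Worked example

```python
import numpy as np
from ddtasep import build_uniform_gene, uniform_rates, run, bulk_observables
from ddtasep import fpt_theory
from ddtasep.burst_analysis import burst_summary

geom = build_uniform_gene(20_000)                  # 400 sites, 100 nucleosomes
params = uniform_rates(geom, alpha=0.05, beta=1.0, q=1.0, h_c=0.1, h_o=0.001)

mom = fpt_theory.fpt_moments(0.05, 1.0, 1.0, 0.1, 0.001, geom.n_units)
print(f"gamma = {mom.gamma:.4f}  MFPT = {mom.MFPT:.0f}  D_e = {mom.D_e:.0f}")

results = [run(geom, params, n_steps=450_000, seed=s, warn_short_window=False)
           for s in range(10)]
obs = bulk_observables(results[0])
print(f"rho = {obs.rho:.3f}  J = {obs.J:.5f}")

stats = burst_summary(results)
print(f"bimodal = {stats.bimodal}  threshold = {stats.threshold:.0f}  "
      f"mean burst size = {stats.mean_NB:.1f}  mean t_in = {stats.mean_t_in:.2f}")
```

prints

```
gamma = 0.0037  MFPT = 109431  D_e = 1109
rho = 0.641  J = 0.00223
bimodal = True  threshold = 97  mean burst size = 9.3  mean t_in = 3.40
```

Reading: with fast rewrapping and slow reopening (`h_c = 0.1`,
`h_o = 0.001`) the pioneer crawls (`γ ≈ 0.004`, first mRNA after ~1.1e5
time units) and entry waits are wildly overdispersed (`D_e ≈ 1100`
versus 1 on bare DNA).  The gene jams up behind closed nucleosomes
(`ρ ≈ 0.64` and still climbing over this 4.5e5-step replicate) and output
is bursty: the waiting-time distribution is bimodal, and mRNAs leave in
convoys of ~9 separated by long nucleosome-induced gaps, with intra-burst
spacing near the maximal-current headway of 4 time units.

The same machinery is scriptable from the shell:

```sh
ddtasep fixtures --out configs/            # nine example parameter sets
ddtasep simulate --config configs/grid_ho0.001_hc0.1.yaml --out out/
ddtasep theory --h-c 0,0.01,0.1 --h-o 0.01,0.1 --alpha 0.25
ddtasep sweep --config sweep.yaml --out sweep_out/
```

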