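# growthctl

Optimal-control analysis of cellular growth strategies in a discrete
stochastic logistic birth–death model.

Microbial serial-transfer evolution experiments select for whatever
growth strategy maximizes the population at the end of each fixed-length
culture cycle. `growthctl` asks what that optimal strategy *is* when a
cell can switch between two metabolic modes — a **defensive** mode
(birth/death rates 0.025/0.005 per step: long lifetime, slow growth) and
an **aggressive** mode (0.125/0.075: fast growth, short lifetime) —
under logistic density regulation and demographic noise. It is written
for theorists and experimentalists who want to reason quantitatively
about lag-phase evolution, cycle-length selection pressure, and
competition between growth phenotypes.

## Model and method

Population size `N_t` follows

    N_{t+1} = N_t + births − deaths,
    births ~ Poisson(N β_m),   deaths ~ Poisson(N (δ_m + (β_m−δ_m) N/K)),

with carrying capacity `K` realized entirely through death, absorption
at `N = 0`, and mode `m(N, t)` free to vary over the state grid. The
one-step increment is Skellam distributed, so distributions can be
propagated exactly. The optimal policy maximizes the expected final
size via the Bellman recursion

    J(N, t) = max_m Σ_{N′} J(N′, t+1) W(N′ | N; m),   J(N, T) = N,

yielding a *control map* `m_opt(N, t)`. In two-phenotype competitions
(shared carrying capacity) the map becomes a *control tensor* indexed by
the competitor's size; the package also solves the jointly optimal
strategy over the full `(N_a, N_c)` state space against a known
competitor, and simulates seeded serial-transfer competitions
(proportional or fixed-founder transfers).

Headline phenomena it reproduces: a lag phase emerges purely from
demographic stochasticity once cycles are long enough; the lag time is
selected by the cycle length (zero for short cycles, then growing and
finally plateauing); and in head-to-head serial transfers the adaptive
phenotypes drive non-adaptive ones extinct.

## Worked example

```python
import growthctl as g

cfg = g.default_config()            # K=500, l=1.5, T=750, N_initial=10
cmap = g.solve_bellman(cfg)         # optimal control map

comp = g.strategy_comparison(cfg)   # exact propagation of 4 strategies
print(comp.summaries[["median", "variance"]])
#             median     variance
# aggressive   497.0  2869.699839
# defensive    499.0   631.687246
# greedy       512.0  2442.543014
# optimal      515.0   946.264573

lag = g.lag_time(cmap, cfg, n_reps=1000, seed=1)
print(lag)                          # 36.0
```

Both pure strategies settle at the carrying capacity (medians 497/499,
the aggressive mode with 4.5× the variance), while the adaptive
strategies exceed it — the greedy rule (defensive iff `N > K`) reaches
median 512 and the optimal map 515, the margin coming from its
time-dependent boundaries. The lag readout says that with a 750-step
cycle the optimal strategy stays defensive for a median 36 steps before
igniting aggressive growth; at `T = 150` the same call returns 0.0 (no
lag region at all), and across cycle lengths `g.lag_curve` traces the
zero → linear-growth → plateau shape.

For competitions:

```python
cfg300 = cfg.replace(T=300)
tensor = g.build_anticipative_tensor(cfg300)     # ~5 min at K=500
proto = g.TransferProtocol(cycle_length=300, n_cycles=7, fraction=0.2)
labels = g.simulate_competition_batch(
    tensor.strategy(), g.PurePairStrategy(g.GrowthMode.AGGRESSIVE),
    proto, cfg300, n_runs=40, seed=1)
print(g.biculture.tabulate_outcomes(labels))
# {'focal_win': 0.425, 'focal_loss': 0.25, 'coexist': 0.325,
#  'all_extinct': 0.0, 'n_sims': 40}
```

Over seven 300-step cycles with 20% transfers the anticipative
phenotype drives the aggressive one extinct in a clear majority of the
decided runs (17 wins vs 10 losses here; the rest still coexist after
seven cycles), by out-yielding it whenever the community sits at or
above the carrying capacity.

A command-line entry point `growthctl` exposes the same operations
(`solve`, `lag-curve`, `compare-strategies`, `tensor`, `compete`,
`sweep`, `optimal-biculture`, `experiment`, `fixture`) on a YAML
configuration file; `growthctl experiment fig1 … fig5` writes the
canonical CSV/HDF5 artifact sets with JSON manifests.

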