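"""Config-driven reproduction harness for the canonical experiments.

Each named experiment runs one of the package's headline computations
with the default parameters (K = 500 unless overridden), writes its
artifacts (CSV / HDF5) into an output directory and returns a JSON
manifest recording the configuration, seeds and produced files.

* ``fig1`` - monoculture control maps at several cycle lengths
  (default T in {150, 300, 750}), showing the qualitative regime change
  of the low-density defensive (lag) region.
* ``fig2`` - propagated size distributions of the optimal vs the pure
  aggressive strategy at the two boundary-illustrating settings
  (N_initial=500 observed at t=200 and N_initial=10 at t=85).
* ``fig3`` - exact median trajectories of the four strategies plus the
  lag-time-vs-cycle-length curve.
* ``fig4`` - anticipative vs aggressive serial-transfer competitions
  (7 cycles, 20% transfers, 40 runs).
* ``fig5`` - cycle-length sweeps of pairwise competitions
  (fixed 0.1 K founders, 6 cycles) and the joint-optimal vs greedy
  pairing on a reduced carrying capacity.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

from . import __version__, biculture, control, io, kernel
from .model import ModelConfig, config_to_dict, default_config, validate_config
from .simulate import FIXED_FOUNDERS, PROPORTIONAL, TransferProtocol
from .strategies import PureStrategy
from .model import GrowthMode

EXPERIMENT_NAMES = ("fig1", "fig2", "fig3", "fig4", "fig5")


@dataclasses.dataclass
class ExperimentSpec:
    name: str
    out_dir: Path
    seed: int = 0
    overrides: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        if self.name not in EXPERIMENT_NAMES:
            raise ValueError(
                f"unknown experiment {self.name!r}; choose from {EXPERIMENT_NAMES}"
            )


def make_fixture(scale: str) -> ModelConfig:
    """Reduced configurations for fast exact tests.

    ``tiny`` (K=10, T=15) keeps the joint biculture solver instantaneous;
    ``small`` (K=50, T=60) preserves the qualitative control-map regimes
    at proportionally reduced horizons.  Both keep the default intrinsic
    rates, hence the growth-survival trade-off.
    """
    if scale == "tiny":
        return default_config(K=10, T=15, N_initial=2)
    if scale == "small":
        return default_config(K=50, T=60, N_initial=5)
    raise ValueError(f"unknown fixture scale {scale!r}; use 'tiny' or 'small'")


def _config_from_overrides(overrides: dict) -> ModelConfig:
    cfg = default_config()
    fields = {k: v for k, v in overrides.items() if k in ("K", "l", "T", "N_initial")}
    return cfg.replace(**fields)


def run_experiment(spec: ExperimentSpec) -> dict:
    """Execute a named experiment; returns (and writes) its manifest."""
    spec.out_dir.mkdir(parents=True, exist_ok=True)
    cfg = _config_from_overrides(spec.overrides)
    problems = validate_config(cfg)
    if problems:
        raise ValueError(f"invalid configuration: {problems}")
    manifest = {
        "experiment": spec.name,
        "seed": spec.seed,
        "config": config_to_dict(cfg, seed=spec.seed),
        "overrides": spec.overrides,
        "version": __version__,
        "files": [],
    }
    runner = {
        "fig1": _run_fig1,
        "fig2": _run_fig2,
        "fig3": _run_fig3,
        "fig4": _run_fig4,
        "fig5": _run_fig5,
    }[spec.name]
    runner(spec, cfg, manifest)
    io.write_manifest(manifest, spec.out_dir / "manifest.json")
    manifest["files"].append("manifest.json")
    return manifest


def _emit(manifest, spec, name):
    manifest["files"].append(name)
    return spec.out_dir / name


def _run_fig1(spec, cfg, manifest):
    T_values = spec.overrides.get("T_values", (150, 300, 750))
    regions = {}
    for T in T_values:
        cmap = control.solve_bellman(cfg.replace(T=int(T)))
        io.save_control_map(cmap, _emit(manifest, spec, f"control_map_T{T}.h5"))
        regions[str(T)] = control.low_density_defensive_extent(cmap)
    manifest["low_density_defensive_last_t"] = regions


def _run_fig2(spec, cfg, manifest):
    settings = spec.overrides.get("settings", ((500, 200), (10, 85)))
    T = spec.overrides.get("T_map", 750)
    cmap = control.solve_bellman(cfg.replace(T=int(T)))
    for N0, t_obs in settings:
        for strat_name, strat in (
            ("optimal", cmap.strategy()),
            ("aggressive", PureStrategy(GrowthMode.AGGRESSIVE)),
        ):
            dist = kernel.propagate(
                kernel.PopulationDistribution.point_mass(int(N0), cfg),
                strat,
                cfg,
                int(t_obs),
            )
            io.distribution_to_csv(
                dist, _emit(manifest, spec, f"dist_{strat_name}_N{N0}_t{t_obs}.csv")
            )
    manifest["settings"] = [list(s) for s in settings]


def _run_fig3(spec, cfg, manifest):
    T = spec.overrides.get("T", cfg.T)
    comparison = control.strategy_comparison(cfg.replace(T=int(T)))
    comparison.medians.to_csv(_emit(manifest, spec, "median_sizes.csv"))
    comparison.summaries.to_csv(_emit(manifest, spec, "final_summaries.csv"))
    grid = spec.overrides.get(
        "lag_grid", (100, 200, 300, 450, 600, 750, 900, 1050, 1200, 1500)
    )
    curve = control.lag_curve(
        cfg,
        grid,
        n_reps=spec.overrides.get("n_reps", 1000),
        seed=spec.seed,
    )
    curve.to_csv(_emit(manifest, spec, "lag_curve.csv"), index=False)


def _run_fig4(spec, cfg, manifest):
    T = spec.overrides.get("cycle_length", 300)
    n_runs = spec.overrides.get("n_runs", 40)
    protocol = TransferProtocol(
        cycle_length=int(T),
        n_cycles=spec.overrides.get("n_cycles", 7),
        rule=PROPORTIONAL,
        fraction=spec.overrides.get("fraction", 0.2),
    )
    run_cfg = cfg.replace(T=int(T))
    tensor = biculture.build_anticipative_tensor(run_cfg, progress=True)
    anticipative = tensor.strategy(name="anticipative")
    aggressive = biculture.resolve_pair_strategy("aggressive", run_cfg)
    labels = biculture.simulate_competition_batch(
        anticipative, aggressive, protocol, run_cfg, n_runs, spec.seed
    )
    import pandas as pd

    pd.DataFrame({"run": range(n_runs), "outcome": labels}).to_csv(
        _emit(manifest, spec, "outcomes.csv"), index=False
    )
    example = biculture.simulate_competition(
        anticipative, aggressive, protocol, run_cfg, spec.seed, record=True
    )
    io.trajectories_to_dataframe(example.trajectories).to_csv(
        _emit(manifest, spec, "example_run.csv"), index=False
    )
    manifest["outcome_fractions"] = biculture.tabulate_outcomes(labels)


def _run_fig5(spec, cfg, manifest):
    import pandas as pd

    cycle_lengths = spec.overrides.get("cycle_lengths", (50, 150, 300))
    n_sims = spec.overrides.get("n_sims", 2000)
    protocol = TransferProtocol(
        cycle_length=int(cycle_lengths[0]),
        n_cycles=spec.overrides.get("n_cycles", 6),
        rule=FIXED_FOUNDERS,
        founders=max(1, round(0.1 * cfg.K)),
    )
    cache: dict = {}
    for a, b in (
        ("anticipative", "defensive"),
        ("anticipative", "aggressive"),
        ("greedy", "anticipative"),
    ):
        table = biculture.sweep_cycle_lengths(
            (a, b), cycle_lengths, n_sims, protocol, cfg,
            seed=spec.seed, tensor_cache=cache,
        )
        table.to_csv(_emit(manifest, spec, f"sweep_{a}_vs_{b}.csv"), index=False)
    # joint-optimal pairing on a reduced carrying capacity (the joint
    # solver is cubic in the state count per step)
    K_joint = spec.overrides.get("K_joint", 50)
    joint_cfg = cfg.replace(K=int(K_joint))
    joint_T = spec.overrides.get("joint_cycle_lengths", (60, 120))
    joint_protocol = dataclasses.replace(
        protocol,
        n_cycles=spec.overrides.get("joint_n_cycles", 10),
        founders=max(1, round(0.1 * joint_cfg.K)),
    )
    table = biculture.sweep_cycle_lengths(
        ("biculture_optimal", "greedy"),
        joint_T,
        spec.overrides.get("joint_n_sims", n_sims),
        joint_protocol,
        joint_cfg,
        seed=spec.seed,
        tensor_cache=cache,
    )
    table.to_csv(
        _emit(manifest, spec, "sweep_biculture_optimal_vs_greedy.csv"), index=False
    )
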