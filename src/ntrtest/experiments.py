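"""Power / type-I-error study orchestration over scenario grids.

Each (scenario, method) cell reports the fraction of simulated replicates
with p < alpha, with its Monte-Carlo standard error sqrt(r(1-r)/reps). All
methods are evaluated on the *same* replicate datasets within a scenario,
so method contrasts are paired. Per-replicate seeds are spawned
deterministically from the master seed, making every cell individually
reproducible; with ``match_seeds=True`` replicate r shares its seed across
scenarios, pairing scenario contrasts too.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .comparators import run_comparator
from .ntr import ntr_region_test
from .simulate import ScenarioConfig, sample_case_control

__all__ = ["ExperimentGrid", "run_scenario", "run_grid", "summarize"]

METHODS = ("ntr", "cmc", "wss", "skat", "skat_o")


@dataclass
class ExperimentGrid:
    scenarios: list[ScenarioConfig]
    methods: tuple[str, ...] = ("ntr",)
    reps: int = 1000
    alpha: float = 0.05
    n_perm: int = 1000
    seed: int = 0
    match_seeds: bool = False

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        bad = set(self.methods) - set(METHODS)
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")


def _replicate_seedseq(
    master: int, scenario_index: int, rep: int, match_seeds: bool
) -> np.random.SeedSequence:
    key = (master, rep) if match_seeds else (master, scenario_index, rep)
    return np.random.SeedSequence(key)


def run_scenario(
    scenario: ScenarioConfig,
    methods: tuple[str, ...],
    reps: int,
    n_perm: int = 1000,
    seed: int = 0,
    scenario_index: int = 0,
    match_seeds: bool = False,
) -> dict[str, np.ndarray]:
    """P-values per method over ``reps`` simulated replicates (NaN = failed)."""
    pvals = {m: np.full(reps, np.nan) for m in methods}
    for rep in range(reps):
        ss = _replicate_seedseq(seed, scenario_index, rep, match_seeds)
        sim_rng, test_rng = [np.random.default_rng(c) for c in ss.spawn(2)]
        data = sample_case_control(scenario, seed=sim_rng)
        for m in methods:
            try:
                if m == "ntr":
                    res = ntr_region_test(
                        data.region, data.phenotype, n_perm=n_perm, seed=test_rng
                    )
                    pvals[m][rep] = res.p
                else:
                    pvals[m][rep] = run_comparator(
                        m, data.region, data.phenotype, n_perm=n_perm, seed=test_rng
                    ).p
            except ValueError:
                pass  # recorded as missing, never as a rejection
    return pvals


def _scenario_label(s: ScenarioConfig) -> dict:
    return {
        "rho": s.rho,
        "n_causal": s.n_causal,
        "n_noise": s.n_noise,
        "composition": s.composition,
        "or_model": str(s.or_model),
        "n_cases": s.n_cases,
        "n_controls": s.n_controls,
    }


def run_grid(
    grid: ExperimentGrid,
    cache_dir: str | Path | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every scenario x method cell; returns the long-format table.

    With ``cache_dir`` set, completed scenario cells are stored as JSON and
    reloaded on re-runs, making long grids resumable.
    """
    rows = []
    for si, scen in enumerate(grid.scenarios):
        cache_path = None
        pvals = None
        if cache_dir is not None:
            cache_path = Path(cache_dir) / f"cell_s{si}_seed{grid.seed}.json"
            if cache_path.exists():
                loaded = json.loads(cache_path.read_text())
                if set(loaded) >= set(grid.methods) and all(
                    len(v) == grid.reps for v in loaded.values()
                ):
                    pvals = {m: np.array(loaded[m]) for m in grid.methods}
        if pvals is None:
            pvals = run_scenario(
                scen, grid.methods, grid.reps, n_perm=grid.n_perm,
                seed=grid.seed, scenario_index=si, match_seeds=grid.match_seeds,
            )
            if cache_path is not None:
                cache_path.parent.mkdir(parents=True, exist_ok=True)
                cache_path.write_text(
                    json.dumps({m: list(map(float, v)) for m, v in pvals.items()})
                )
        if progress:
            print(f"scenario {si + 1}/{len(grid.scenarios)} done", flush=True)
        for m in grid.methods:
            p = pvals[m]
            ok = ~np.isnan(p)
            n_ok = int(ok.sum())
            rate = float((p[ok] < grid.alpha).mean()) if n_ok else float("nan")
            rows.append(
                {
                    **_scenario_label(scen),
                    "method": m,
                    "reps": grid.reps,
                    "n_ok": n_ok,
                    "rejections": int((p[ok] < grid.alpha).sum()),
                    "rate": rate,
                    "se": float(np.sqrt(rate * (1 - rate) / n_ok)) if n_ok else
                    float("nan"),
                }
            )
    return pd.DataFrame(rows)


def summarize(
    table: pd.DataFrame,
    out: str | Path | None = None,
    plot: bool = False,
) -> pd.DataFrame:
    """Pivot the grid table into a panel layout (rows: OR model x noise,
    columns: rho), one block per composition; optionally write TSV / plots."""
    wide = table.pivot_table(
        index=["composition", "or_model", "n_noise", "method"],
        columns="rho",
        values="rate",
    )
    if out is not None:
        out = Path(out)
        out.parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(out.with_suffix(".tsv"), sep="\t", index=False)
        wide.to_csv(out.with_suffix(".panels.tsv"), sep="\t")
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        for (comp, orm, noise, method), row in wide.iterrows():
            ax.plot(row.index, row.values, marker="o",
                    label=f"{method} {orm} noise={noise}")
        ax.set_xlabel("rho")
        ax.set_ylabel("rejection rate")
        ax.legend(fontsize=6)
        if out is not None:
            fig.savefig(Path(out).with_suffix(".png"), dpi=120)
        plt.close(fig)
    return wide
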