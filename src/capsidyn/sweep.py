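"""Parameter sweeps, assembly-mode comparison, and file output.

The sweep driver runs replicate ensembles over an ``(k_a, k_d)`` grid
with deterministic per-cell seeds, records yields and first-passage-time
statistics (censoring-aware: censored trajectories enter medians as
+infinity and a median is flagged censored when more than half of the
replicates are), and mean assembly speed over the completed trajectories
only.  The dominance classifier compares direct and hierarchical
first-passage times with the 10 %-of-sum indifference band.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .engine import ObservableSeries, SimulationConfig, ensemble_yield, run
from .geometry import build_capsomer_mixture_blueprint
from .ringme import METrajectory


def derive_seed(seed_base: int, *counters: int) -> int:
    """Independent, reproducible child seed from a base seed and counters."""
    ss = np.random.SeedSequence([int(seed_base), *map(int, counters)])
    return int(ss.generate_state(1)[0] % 2**31)


# ---------------------------------------------------------------------------
# censoring-aware statistics
# ---------------------------------------------------------------------------

def median_fpt(results: list[ObservableSeries], size: int) -> tuple[float, bool]:
    """Median first-passage time to ``size`` with censored values treated
    as +infinity; the median itself is flagged censored when more than
    half of the replicates never reached ``size``."""
    vals = [r.fpt_of(size) if r.reached(size) else math.inf for r in results]
    med = float(np.median(vals))
    return med, not math.isfinite(med)


def classify_dominance(
    fpt_direct: float,
    fpt_hier: float,
    censored_direct: bool = False,
    censored_hier: bool = False,
) -> str:
    """Which assembly mode reached the target faster.

    ``undecided`` when the FPT difference is below 10 % of the FPT sum or
    both values are censored; a censored value always loses against a
    finite one.
    """
    if censored_direct and censored_hier:
        return "undecided"
    if censored_direct:
        return "hierarchical"
    if censored_hier:
        return "direct"
    if abs(fpt_direct - fpt_hier) < 0.1 * (fpt_direct + fpt_hier):
        return "undecided"
    return "direct" if fpt_direct < fpt_hier else "hierarchical"


def scaled_capsomer_fpt(completion_times, ring_size: int) -> np.ndarray:
    """Capsomer completion times scaled by the monomers per ring (the
    common relative-progress axis for pentamer/hexamer comparison)."""
    if ring_size not in (5, 6):
        raise ValueError("ring_size must be 5 or 6")
    return np.asarray(completion_times, dtype=float) / ring_size


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepCell:
    k_a: float
    k_d: float
    results: list[ObservableSeries]

    def row(self, target_sizes: list[int]) -> dict:
        out = {"ka": self.k_a, "kd": self.k_d, "replicates": len(self.results)}
        for s in target_sizes:
            out[f"yield_{s}"] = ensemble_yield(self.results, s)
            med, cen = median_fpt(self.results, s)
            out[f"median_fpt_{s}"] = med
            out[f"median_fpt_{s}_censored"] = cen
        speeds = [r.assembly_speed for r in self.results if not r.censored]
        out["mean_speed"] = float(np.mean(speeds)) if speeds else 0.0
        out["censored_frac"] = float(np.mean([r.censored for r in self.results]))
        return out


@dataclass
class SweepResult:
    cells: list[SweepCell]
    target_sizes: list[int]
    config_echo: dict

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([c.row(self.target_sizes) for c in self.cells])


def run_sweep(
    base_config: SimulationConfig,
    ka_list,
    kd_list,
    replicates: int = 40,
    seed_base: int = 0,
    target_sizes: list[int] | None = None,
) -> SweepResult:
    """Replicated trajectories over the (k_a, k_d) grid.

    Per-cell, per-replicate seeds derive deterministically from
    ``seed_base`` and the grid indices, so any cell can be reproduced in
    isolation.  Grid values are validated (k dt <= 1) before any run.
    """
    ka_list = list(ka_list)
    kd_list = list(kd_list)
    if not ka_list or not kd_list or replicates < 1:
        raise ValueError("need non-empty grids and replicates >= 1")
    for ka in ka_list:
        for kd in kd_list:
            probe = dataclasses.replace(base_config, k_a=ka, k_d=kd)
            probe.validate()
    if target_sizes is None:
        nf = base_config.blueprint.n_f
        target_sizes = sorted({nf // 2, nf})

    cells = []
    for i, ka in enumerate(ka_list):
        for j, kd in enumerate(kd_list):
            results = []
            for r in range(replicates):
                cfg = dataclasses.replace(
                    base_config, k_a=ka, k_d=kd, seed=derive_seed(seed_base, i, j, r)
                )
                results.append(run(cfg))
            cells.append(SweepCell(k_a=ka, k_d=kd, results=results))
    echo = {
        f.name: repr(getattr(base_config, f.name))
        for f in dataclasses.fields(base_config)
        if f.name != "blueprint"
    }
    echo["blueprint"] = f"T={base_config.blueprint.T_number} {base_config.blueprint.kind}"
    echo["seed_base"] = seed_base
    return SweepResult(cells=cells, target_sizes=list(target_sizes), config_echo=echo)


def dominance_map(
    sweep_direct: SweepResult, sweep_hier: SweepResult, target_size: int
) -> pd.DataFrame:
    """Cell-wise dominance verdicts from two matched sweeps."""
    rows = []
    for cd, ch in zip(sweep_direct.cells, sweep_hier.cells):
        if (cd.k_a, cd.k_d) != (ch.k_a, ch.k_d):
            raise ValueError("sweeps have mismatched grids")
        fd, censd = median_fpt(cd.results, target_size)
        fh, censh = median_fpt(ch.results, target_size)
        rows.append(
            {
                "ka": cd.k_a,
                "kd": cd.k_d,
                "fpt_direct": fd,
                "fpt_hier": fh,
                "verdict": classify_dominance(fd, fh, censd, censh),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# down-scaled hexamer experiment
# ---------------------------------------------------------------------------

@dataclass
class HexamerExperimentConfig:
    """The half-size capsomer-formation study: 60 hexamer-forming monomers
    (one protein type, or two types binding alternately) assembling ten
    hexamers alongside 30 pentamer-forming monomers, at the full
    simulation's concentration in a half-volume box."""

    n_hex_monomers: int = 60
    n_pent_monomers: int = 30
    L: float = 55.0 / 2.0 ** (1.0 / 3.0)  # nm, half the T3 box volume
    k_a: float = 9.0       # ns^-1
    k_d: float = 1.5e-3    # ns^-1
    max_time: float = 2e4  # ns
    record_interval: float = 250.0
    replicates: int = 10
    seed_base: int = 0

    def validate(self):
        if self.n_hex_monomers % 6 or self.n_hex_monomers <= 0:
            raise ValueError("hexamer monomer count must be a positive multiple of 6")
        if self.n_pent_monomers % 5 or self.n_pent_monomers < 0:
            raise ValueError("pentamer monomer count must be a multiple of 5")


def downscaled_hexamer_experiment(
    config: HexamerExperimentConfig | None = None,
) -> dict[str, list[ObservableSeries]]:
    """Run the identical- and two-type-hexamer ensembles.

    Returns ``{"identical": [...], "t3like": [...]}``; each trajectory's
    census covers only the hexamer-forming species, ready for export to
    the master-equation fit.
    """
    config = config or HexamerExperimentConfig()
    config.validate()
    out: dict[str, list[ObservableSeries]] = {}
    for tag, identical in (("identical", True), ("t3like", False)):
        bp = build_capsomer_mixture_blueprint(identical)
        if identical:
            composition = {"H": config.n_hex_monomers, "P5": config.n_pent_monomers}
            census_types = ["H"]
        else:
            composition = {
                "A": config.n_hex_monomers // 2,
                "B": config.n_hex_monomers - config.n_hex_monomers // 2,
                "P5": config.n_pent_monomers,
            }
            census_types = ["A", "B"]
        results = []
        for r in range(config.replicates):
            cfg = SimulationConfig(
                blueprint=bp,
                mode="hierarchical",
                N=config.n_hex_monomers + config.n_pent_monomers,
                L=config.L,
                k_a=config.k_a,
                k_d=config.k_d,
                max_time=config.max_time,
                record_interval=config.record_interval,
                seed=derive_seed(config.seed_base, 0 if identical else 1, r),
                composition=composition,
            )
            results.append(run(cfg, census_types=census_types))
        out[tag] = results
    return out


def ensemble_mean_trajectory(
    results: list[ObservableSeries], n_f: int = 6
) -> METrajectory:
    """Ensemble-mean nu_n(t) table (populations up to ring size n_f)."""
    times = results[0].times
    for r in results[1:]:
        if len(r.times) != len(times) or not np.allclose(r.times, times):
            raise ValueError("trajectories do not share a time grid")
    nu = np.mean([r.nu[:, :n_f] for r in results], axis=0)
    return METrajectory(t_grid=times.copy(), nu=nu)


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def census_frame(series: ObservableSeries) -> pd.DataFrame:
    """Long-format census table: one row per (time, cluster size)."""
    rows = []
    n = np.arange(1, series.n_f + 1)
    for t, nu in zip(series.times, series.nu):
        nbar = float((nu * n * n).sum() / series.N)
        for size in np.nonzero(nu)[0] + 1:
            rows.append(
                {
                    "t_ns": t,
                    "n": int(size),
                    "nu_n": int(nu[size - 1]),
                    "p_n": nu[size - 1] * size / series.N,
                    "nbar": nbar,
                }
            )
    return pd.DataFrame(rows, columns=["t_ns", "n", "nu_n", "p_n", "nbar"])


def fpt_frame(series: ObservableSeries) -> pd.DataFrame:
    rows = [
        {"size": s, "fpt_ns": t, "censored": False}
        for s, t in sorted(series.fpt.items())
    ]
    return pd.DataFrame(rows, columns=["size", "fpt_ns", "censored"])


def frames_to_xyz(frames, type_labels, L: float) -> str:
    """Plain XYZ trajectory text from recorded (t, positions) frames."""
    lines = []
    for t, pos in frames:
        lines.append(str(len(pos)))
        lines.append(f"t_ns={t:.3f} box_L={L:.3f}")
        for lab, p in zip(type_labels, pos):
            lines.append(f"{lab[:2]} {p[0]:.4f} {p[1]:.4f} {p[2]:.4f}")
    return "\n".join(lines) + "\n"


def write_outputs(
    results,
    outdir: str,
    sweep: SweepResult | None = None,
    config_echo: dict | None = None,
    seed: int | None = None,
) -> list[str]:
    """Write observables to ``outdir``: per-trajectory census and FPT
    tables (CSV), the sweep grid (CSV), a config echo (JSON) and a run
    log carrying seed and package version."""
    os.makedirs(outdir, exist_ok=True)
    written = []
    for i, series in enumerate(results or []):
        p = os.path.join(outdir, f"census_{i:03d}.csv")
        census_frame(series).to_csv(p, index=False)
        written.append(p)
        p = os.path.join(outdir, f"fpt_{i:03d}.csv")
        fpt_frame(series).to_csv(p, index=False)
        written.append(p)
    if sweep is not None:
        p = os.path.join(outdir, "sweep.csv")
        sweep.table().to_csv(p, index=False)
        written.append(p)
        config_echo = config_echo or sweep.config_echo
    if config_echo is not None:
        p = os.path.join(outdir, "config.json")
        with open(p, "w") as fh:
            json.dump(config_echo, fh, indent=2, default=str)
        written.append(p)
    p = os.path.join(outdir, "run_log.json")
    with open(p, "w") as fh:
        json.dump(
            {
                "package": "capsidyn",
                "version": __version__,
                "seed": seed,
                "n_trajectories": len(results or []),
            },
            fh,
            indent=2,
        )
    written.append(p)
    return written
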