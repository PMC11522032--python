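"""Config-driven orchestration: single runs, sweeps, and report figures."""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ExperimentConfig, SweepConfig
from .engine import RunResult, run_protocol
from .forcefield import ForceFieldParams
from .io import archive_run
from .mechanics import summarize, terminal_broken_fractions

log = logging.getLogger(__name__)


def run_single(config: ExperimentConfig) -> tuple[RunResult, dict]:
    """Execute one full protocol run from a validated config.

    Returns the run result and its summary dict; archives to
    ``config.output`` when set.
    """
    params = ForceFieldParams.default().with_overrides(config.forcefield_overrides)
    t0 = time.perf_counter()
    result = run_protocol(
        config.fibril_spec(), config.crosslink_config(), config.protocol_obj(), params
    )
    metrics = summarize(result.series.strain, result.series.stress)
    metrics.broken_fractions = terminal_broken_fractions(result.topology)
    summary = metrics.to_dict()
    summary["n_break_events"] = len(result.events)
    log.info(
        "run finished in %.1f s: σ_peak=%.4g, W_f=%.4g, %d break events",
        time.perf_counter() - t0,
        summary["sigma_peak"],
        summary["work_to_failure"],
        len(result.events),
    )
    if config.output:
        archive_run(config.output, result, config.model_dump())
    return result, summary


def cell_seed(base_seed: int, n_age: float, content: float, valence: str) -> int:
    """Deterministic, order-independent seed for one sweep cell."""
    import zlib

    tag = f"{n_age:.3f}|{content:.1f}|{valence}".encode()
    return (base_seed * 1000003 + (zlib.crc32(tag) & 0xFFFFF)) & 0x7FFFFFFF


def sweep(config: SweepConfig) -> pd.DataFrame:
    """Run the grid of (N_AGE, ECL content, valence, seed) cells.

    Each cell is independently seeded (order-invariant) and resumable:
    cells already archived under the output root are loaded, failed cells
    are recorded and skipped.
    """
    base = config.base or ExperimentConfig(preset=config.preset)
    rows = []
    for valence in config.ecl_valences:
        for content in config.ecl_contents:
            for n_age in config.n_age_values:
                for seed in config.seeds:
                    s = cell_seed(seed, n_age, content, valence)
                    cell = base.model_copy(deep=True)
                    cell.preset = config.preset
                    cell.crosslinks.n_age = n_age
                    cell.crosslinks.ecl_content = content
                    cell.crosslinks.ecl_valence = valence
                    cell.crosslinks.seed = s
                    cell.protocol.seed = s
                    name = f"nage{n_age:g}_ecl{content:g}_{valence}_s{seed}"
                    cell.output = (
                        str(Path(config.output) / name) if config.output else None
                    )
                    row = {
                        "n_age": n_age,
                        "ecl_content": content,
                        "ecl_valence": valence,
                        "seed": seed,
                        "status": "ok",
                    }
                    if cell.output and (Path(cell.output) / "summary.json").exists():
                        import json

                        with open(Path(cell.output) / "summary.json") as fh:
                            row.update(
                                {k: v for k, v in json.load(fh).items() if k != "census"}
                            )
                        rows.append(row)
                        continue
                    try:
                        _, summary = run_single(cell)
                        row.update(
                            {k: v for k, v in summary.items() if k != "census"}
                        )
                    except Exception as exc:  # failed cell: record, keep going
                        log.error("cell %s failed: %s", name, exc)
                        row["status"] = f"failed: {exc}"
                    rows.append(row)
    df = pd.DataFrame(rows)
    if config.output:
        Path(config.output).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(config.output) / "sweep.csv", index=False)
    return df


def report(results_root) -> list[Path]:
    """Regenerate figures from archived runs (no re-simulation).

    Produces a stress–strain overlay and, when a sweep table is present,
    metric-vs-density grids.  Returns the list of written figure paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    root = Path(results_root)
    run_dirs = sorted(p.parent for p in root.glob("**/series.csv"))
    if not run_dirs:
        log.warning("nothing to report under %s", root)
        return []
    written = []

    fig, ax = plt.subplots(figsize=(6, 4))
    for d in run_dirs:
        s = pd.read_csv(d / "series.csv")
        ax.plot(s["strain"], s["stress_kcal_mol_A3"], label=d.name, lw=0.8)
    ax.set_xlabel("strain")
    ax.set_ylabel("stress (kcal mol$^{-1}$ Å$^{-3}$)")
    if len(run_dirs) <= 12:
        ax.legend(fontsize=6)
    fig.tight_layout()
    out = root / "stress_strain_overlay.png"
    fig.savefig(out, dpi=150)
    plt.close(fig)
    written.append(out)

    sweep_csv = root / "sweep.csv"
    if sweep_csv.exists():
        df = pd.read_csv(sweep_csv)
        metrics = ["sigma_peak", "work_to_failure", "delta_sigma"]
        fig, axes = plt.subplots(1, len(metrics), figsize=(4 * len(metrics), 3.2))
        for ax, m in zip(np.atleast_1d(axes), metrics):
            if m not in df:
                continue
            for (content, valence), grp in df.groupby(["ecl_content", "ecl_valence"]):
                med = grp.groupby("n_age")[m].median()
                ax.plot(med.index, med.values, "o-", label=f"{content:g}% {valence}")
            ax.set_xscale("symlog", linthresh=1)
            ax.set_xlabel("AGE cross-links per molecule")
            ax.set_ylabel(m)
        np.atleast_1d(axes)[0].legend(fontsize=6)
        fig.tight_layout()
        out = root / "metric_grids.png"
        fig.savefig(out, dpi=150)
        plt.close(fig)
        written.append(out)
    return written
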